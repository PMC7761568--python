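# Methods

## Logical model

Each molecular species, pathway or phenotype is a Boolean variable with
an update rule over its regulators.  The network covers antigen
recognition (Antigens, MHCI/MHCII, CD4/CD8, LCK_FYN, TCR, the LAT
signalosome), the downstream Ca/NFAT, MAPK, NFkB and PI3K/AKT pathways,
five inhibitory checkpoints (CTLA4, PD1, TIGIT, LAG3, TIM3) acting
through the SHP and SHIP1 phosphatases, activating checkpoints (CD28,
ICOS, TNFRs, CD226), four cytokine axes (IFNG→STAT1, IL12→STAT4,
IL27→STAT1/STAT3/MAF-PRDM1, TGFb→SMAD) and the FOXP3/FOXO1/Tbet
transcription-factor hub that sets the cell fate.  The three phenotype
nodes have no outgoing edges: `Proliferation_Survival = IL2 & PI3K`
(with `IL2 = Ca_NFAT & MAPK & NFkB`), `Th1_CTL = Tbet & Ca_NFAT`, and
`Treg = FOXP3 & FOXO1`.

Rule construction follows the *inhibitory bias*: alternative activators
enter with OR, obligatory partners with AND, and each inhibitor as an
AND-NOT veto.  The convention makes single inhibitory signals decisive,
which is the regime checkpoint biology operates in.

### Reconstruction conventions that carry the quantitative behaviour

The qualitative topology underdetermines the dynamics; the following
choices, each with direct literature support, fix it.  With all
transition speeds equal, the quantitative outcomes are *races* between
activation and inhibition chains, so what matters is which steps are
gated and which states latch.

- **Latches.**  `LCK_FYN` self-sustains once active (kinase
  autophosphorylation); TIM3 only blocks its initial activation.
  Ligand-engaged CTLA4 likewise self-sustains.  Mutual-exclusion
  latches: TIGIT and CD226 compete for CD155/CD112 (whichever engages
  first excludes the other, with SHIP1 arbitrating), and Tbet shuts off
  PD1 expression while PD1-driven signalling loss keeps Tbet off —
  bistability that splits trajectory ensembles into inhibited and
  escaped fractions.
- **Naive-cell initial state.**  GSK3 and FOXO1 start active (both are
  constitutively active in resting T cells); the CD4/CD8 co-receptors
  start engaged according to the MHC class presented; every other
  internal node starts at 0.  These initial values are part of the
  model: GSK3 keeps Tbet off until PI3K/AKT signalling is established,
  and nuclear FOXO1 makes PD1 inducible from the first instant.
- **Phosphatase wiring.**  SHP (SHP1/2) is recruited by PD1, LAG3 and
  CTLA4 and silences TCR *and* CD28 (PD1-SHP2 dephosphorylates CD28 as
  its primary target).  TIGIT acts through SHIP1, which blocks PI3K
  directly; PI3K is recruited at TCR/CD28/ICOS/CD226, so SHP removes
  all its sources indirectly.
- **Expression gating.**  ICOS, TNFRs, LAG3 and CD226 are
  activation-induced receptors (gated on LAT, IL2 and TCR
  respectively); LAG3's ligand is destabilized by Tbet, which is why
  LAG3 ligands alone never inhibit: every trajectory eventually mounts
  enough signalling to switch Tbet on and remove the ligand, and only
  forced LAG3 expression (rule := 1) inhibits.
- **Transcription-factor hub.**  Tbet activates through release of the
  GSK3 brake (PI3K→AKT⊣GSK3⊣Tbet) or through STAT1/STAT4, and is
  restrained by STAT3; FOXP3 is induced by FOXO1, CTLA4, SMAD or STAT1
  and blocked by PI3K and by STAT3/NFIL3.  FOXO1 as a FOXP3 activator
  makes every checkpoint-inhibited fate (PI3K off, FOXO1 nuclear) a
  regulatory fate, reproducing the Treg slices of the single-checkpoint
  pies; STAT3⊣Tbet makes IL27 the only cytokine that extinguishes both
  effector and regulatory fates.

Under these conventions the checkpoint strengths are parameter-free
race probabilities.  TIGIT's block (engage TIGIT, recruit SHIP1 — two
steps) races the CD226 escape (activate LCK, engage TCR, engage CD226 —
three steps): the inhibited fraction is the probability that two rate-1
events complete before three, 11/16 ≈ 69 %.  TIM3 versus LCK_FYN
activation is a symmetric one-event race, so exactly half the
trajectories are blocked before the kinase latch closes — the ~50 %
Treg reduction.  PD1's inhibited fraction (~74 % of ensembles) is a
longer pursuit race between the PD1→SHP chain and the PI3K/AKT lockout;
it has no closed form but is exact-CTMC-checkable.  CTLA4's block is
not a race at all — engagement is inevitable while CD80/86 is present
and self-sustains — hence complete inhibition with the Treg fate fully
retained.

### Cell conditions and treatments

A condition clamps each input ligand/cytokine to 0/1 (inputs have
identity rules, so clamping is just the initial value).  The catalogue
covers: single-checkpoint ligand panels on a generic T cell (both MHC
classes presented); lymph-node priming (CD80/86, ICOS_L, TNFRs_L — the
CTLA4/ICOS/TNFRs repertoire); tumour-microenvironment activation
(PD1_L, TIGIT_L, LAG3_L, TIM3_L, ICOS_L, TNFRs_L) where CTLA4 is not
expressed — encoded as a CTLA4 := 0 clamp carried by the condition,
which only matters for the CD4 TME context where CD80/86 is present
for CD28-dependent activation; and CD4+/CD8+ cell types via
MHCII/MHCI.  Treatments force receptor nodes to constant 0
(overexpression to 1); sub-population contexts (PD1+CTLA4±) clamp
CTLA4, with a treatment on the same node taking precedence.

The two-step protocol simulates the LN and TME stages independently
(same treatment applied in both; a no-op where the target is not
expressed) and combines them as the product of the LN proliferation
probability with each TME phenotype probability: no effector response
without successful priming.  Intensity arrows in the verdict tables are
treated as orderings (combination vs each monotherapy), never absolute
magnitudes.

## Simulation and analysis

- **Stochastic engine.**  Asynchronous continuous-time dynamics: each
  discordant node flips with its activation/deactivation rate (default
  1, per-node overrides supported but unused by the shipped scenarios).
  Ensembles (default 10,000 trajectories, horizon t_max = 50) are
  simulated in a trajectory-vectorized sweep with rules compiled to
  numpy boolean expressions, and recorded on a 100-point uniform grid.
  One Philox generator seeded from the config seed drives the whole
  ensemble, so runs are bit-reproducible for a fixed seed; the sweep
  draws across trajectories at each step, so reproducibility is per
  ensemble rather than per trajectory.
- **Asymptotics.**  Phenotype probabilities are the joint distribution
  of the three phenotype nodes averaged over the last 20 % of the
  horizon; a convergence flag compares the two halves of that window
  (total-variation tolerance 0.02).  t_max = 50 at rate 1 leaves all
  shipped scenarios converged (flag true); the horizon and window are
  this package's operationalization of "asymptotic" solutions.
- **Exact oracle.**  For small models the reachable state space
  (≤ 4096 states) is enumerated and the transient law computed by
  uniformization with truncation error below 1e-10; horizons are split
  into segments with uniformization constant ≤ 32 so the leading
  Poisson weight never underflows.  An independent sparse
  matrix-exponential route cross-checks it in tests to 1e-8.
- **Fixed points and attractors.**  Fixed points by DPLL-style
  constraint propagation over the rules (branch on the first
  undetermined node in declaration order), verified against exhaustive
  2^n enumeration; attractors as terminal strongly connected components
  of the reachable asynchronous transition graph.  States serialize
  lexicographically in declared node order, which fixes all output
  ordering.
- **Statistics.**  Inhibition strength is `100·(1 − P/P_baseline)` on
  the proliferation marginal (TIM3's Treg reduction uses the CTLA4
  condition, where the Treg fate is fully retained, as the reference).
  The Th1/Treg ratio divides the phenotype marginals and is reported as
  undefined when the Treg marginal is below 1e-6.  Directional verdicts
  require the change to exceed 3 Monte-Carlo standard errors (binomial
  SE, delta method for ratios); "no effect" must stay within that band.
  Within a protocol all simulations share one seed, so inert treatments
  reproduce the untreated ensemble exactly and null verdicts are exact.

## Synthetic networks

The generator draws random Boolean networks with controlled size,
in-degree and inhibitor fraction under two schemes: the inhibitory-bias
scheme mirrors the signalling model's rule shape, and the
random-truth-table scheme supplies adversarial non-monotone logic.  It
exists to verify the engines (fixed-point search against enumeration,
Gillespie against the exact CTMC) independently of the biology: passing
those tests certifies the dynamics machinery, not the biological
reconstruction, whose own support is the scenario verdicts.  The
generator makes no attempt to emulate realistic signalling topology
(no scale-free structure, no layered inputs/outputs).

## Numerical and degenerate cases

Empty rules and malformed files are rejected with positions/line
numbers; constant rules are legal (and are how perturbations are
encoded).  Networks with no enabled transition anywhere yield a
constant CTMC law.  Pure-veto random rules with no activator default to
ON-unless-inhibited.  The ratio guard (Treg < 1e-6) avoids dividing by
Monte-Carlo zeros; comparisons treat an undefined ratio with Th1 mass
as +infinity.

## Known limitations

- Two-valued logic with unit rates everywhere: checkpoint strengths are
  race probabilities set by network depth, not kinetic parameters; they
  should be read as orderings, not dose-response predictions.
- The LN→TME combination multiplies stage probabilities, ignoring any
  distributional coupling between priming and effector phases.
- nTreg development, Th2/Th17 subsets, cytokine-production feedback
  from the effector phenotypes and innate immunity are out of scope.
- Attractor analysis is explicit-state and limited to ~1M reachable
  states; the shipped biology never needs more, but large random
  networks can.
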