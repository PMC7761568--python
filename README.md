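# tcellnet

Logical (Boolean) modelling of T-cell activation under immune-checkpoint
control: a stochastic/exact dynamics engine for asynchronous Boolean
networks, a curated model of TCR signalling with its co-stimulatory and
co-inhibitory checkpoints, and reproducible in-silico protocols for
checkpoint-inhibitor therapy.

## The scientific problem

Whether a T cell proliferates, differentiates into an anti-tumour
Th1/cytotoxic effector, or into an immunosuppressive regulatory (Treg)
cell is decided by the interplay of T-cell-receptor (TCR) signalling,
immune checkpoints (inhibitory: CTLA4, PD1, TIGIT, LAG3, TIM3;
activating: CD28, ICOS, TNFRs, CD226) and cytokines (IFNG, IL12, IL27,
TGFb).  Checkpoint-inhibitor immunotherapy removes one or more of the
inhibitory receptors; which combinations work, and where (lymph node vs
tumour microenvironment), is hard to anticipate because the pathways
cross-talk.  This package implements that interplay as a two-valued
logical model and asks the quantitative questions in silico.

## Model and dynamics

Every node `x_i` takes values in {0, 1} with an update rule
`B_i : {0,1}^n -> {0,1}` over its regulators, written with `&`, `|`, `!`
(e.g. `TCR = Antigens & LCK_FYN & !SHP`).  Rules follow an *inhibitory
bias*: activators combine with OR, obligatory partners with AND, and any
active inhibitor vetoes its target (`... & !I`).

Dynamics are asynchronous: the state `s` jumps to `s^(i)` (node `i`
flipped) whenever `B_i(s) != s_i`, and the flip carries an exponential
clock with rate `r_i` (all rates 1 by default).  This defines a
continuous-time Markov chain whose transient law
`p_t(s) = [p_0 e^{Qt}](s)` the package computes two ways:

- **exactly**, by uniformization of the generator `Q` over the reachable
  state space (small networks; the test oracle), and
- **stochastically**, by a vectorized Gillespie simulator that averages
  ensembles of trajectories onto a time grid.

Phenotype read-outs are the joint states of the three output nodes
(`Proliferation_Survival`, `Th1_CTL`, `Treg`) averaged over the late
20 % of the horizon — the asymptotic "pie chart" of cell fates.  A
treatment (e.g. anti-PD1) replaces the target's rule by the constant 0.

## Worked example

Simulate a generic T cell whose only checkpoint ligand is the PD1
ligand, 10,000 trajectories to t = 50:

```sh
tcellnet simulate --condition PD1_L_only --n-traj 10000 --seed 1 --out-dir pd1_run
```

prints

```
wrote pd1_run/timecourse.tsv and pd1_run/summary.json
model=780c63d58c1c74ec seed=1 n_traj=10000 t_max=50.0 converged=True
```

and `pd1_run/summary.json` contains

```json
"phenotype_distribution": {
    "Proliferation_Survival-Th1_CTL": 0.2625,
    "Treg": 0.7375,
    ...
},
"proliferation_inhibition_vs_baseline_percent": 73.75
```

Read this as: with PD1 engaged, 26 % of cells still reach the
proliferating Th1 fate while 74 % are diverted into the regulatory
(Treg) fate — PD1 inhibits proliferation by ~74 % relative to the
checkpoint-free baseline (where the proliferating fate has probability
1).  The split is a genuine stochastic race between PD1/SHP silencing
the receptor complex and PI3K/AKT signalling locking PD1 out through
FOXO1 export and Tbet.

The four shipped protocols run as

```sh
tcellnet scenario all --seed 1 --out-dir reports
```

which writes verdict tables (`fig3_panel`: per-checkpoint inhibition
panel; `table3_two_step`: lymph-node/tumour two-step therapy table;
`table2_cd8`: PD1/CTLA4 co-expression subpopulations; `fig4_cytokines`:
cytokine modulation of the CD4+ response) and exits 0 only if every
directional verdict passes.

As a library:

```python
from tcellnet.scenarios import single_checkpoint_panel
from tcellnet.stochastic import SimulationConfig

panel = single_checkpoint_panel(SimulationConfig(seed=1))
print(panel.stats["inhibition_PD1_L_only"])   # ~74 (percent)
print(panel.stats["treg_reduction_TIM3"])     # ~50 (percent)
```

## Layout

- `src/tcellnet/logic.py` — rule language, expression AST, network model
- `src/tcellnet/exact.py` — fixed points, attractors, exact CTMC
- `src/tcellnet/stochastic.py` — Gillespie engine, ensembles, phenotypes
- `src/tcellnet/tcell.py` — the T-cell network, conditions, treatments
- `src/tcellnet/scenarios.py` — protocols and directional verdicts
- `src/tcellnet/synthetic.py` — random networks and fixtures for testing
- `src/tcellnet/modelio.py` — BoolNet-style model files, YAML configs
- `src/tcellnet/data/` — shipped model file and condition catalogue
- `docs/methods.md` — model construction, assumptions and numerics
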