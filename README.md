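# tmemix

Two-tier model of the lung-cancer tumor microenvironment (TME): how
cancer cells, cytotoxic T-cells and fibroblasts — in their quiescent
(NAF) and activated, cancer-associated (CAF) states — interact to
produce immune-desert, immune-excluded or immune-inflamed tumors.

The package is aimed at computational biologists and biophysicists who
want to explore T-cell exclusion by fibroblast barriers in non-small
cell lung cancer with a small, fully inspectable model rather than a
black-box simulator.

## The model

**Tier 1 — population dynamics.** Mass fractions `C, T, F_NA, F_A`
(active sum `S ≤ 1`; the remainder is interstitial fluid and
healthy/dead cells) evolve in units of the inverse cancer growth rate:

    dC/dt    = C − δ_CT·C·T/(1 + δ_TF·F_A) − δ·C·S
    dT/dt    = α_TC·C − δ·T·S
    dF_NA/dt = α_NA + α_NA,C·C − K_A·F_NA·C − δ·F_NA·S
    dF_A/dt  = K_A·F_NA·C − δ·F_A·S

Killing (`δ_CT`), CAF inhibition of killing (`δ_TF`), chemotactic
recruitment (`α_TC`, `α_NA,C`), irreversible NAF→CAF plasticity
(`K_A`), and crowding pressure (`δ·φ·S`) generate three long-time
outcomes — invasion, persistence, eradication — controlled by two
composites: the killing ability `α_TC δ_CT/(α_NA,C K_A δ_TF)` and the
crowding `α_NA,C + α_TC`.  Six order-of-magnitude scenario presets,
multistart fixed-point/stability analysis and a two-composite phase
diagram are built in.

**Tier 2 — spatial mixture model.** Local mass fractions `φ_i(x,t)`
obey `∂t φ_i + ∇·(φ_i v_i) = Γ_i` on a 2D tissue window, with
velocities from Onsager's variational principle:
`Σ_j A_ij v_j = −∇μ_i`, where the friction matrix `A` makes every pair
involving CAFs stickier by `ξ₁·φ_A` (matrix fibers), and `μ_i` derive
from a Flory–Huggins free energy with a square-gradient penalty
(dense nest phase `C ≈ 0.8`, interface ~10 µm).  A quasi-static
chemoattractant `λ_c²∇²c − c + α_cC·φ_C = 0` produced by the tumor
drives T-cell/NAF influx from the vasculature (domain boundary, vessel
disks, or one side) and CAF conversion.  Registered scenarios cover
free growth, fibrotic confinement, immune-excluded and immune-inflamed
tumors, two-nest coalescence, and localized vessel sources.

See `docs/methods.md` for the numerical scheme (conservative upwind
finite differences with an IMEX spectral stabilizer), the parameter
table, and the calibration decisions.

## Worked example

```python
from tmemix import ode

params = ode.scenario_params("efficient-T-inhibited")
traj = ode.simulate(ode.CellState(0.01, 0.01, 0.01, 0.01), params, t_end=600)
label, converged = ode.classify_outcome(traj)
print(label, converged, traj.states[-1].round(4))
for fp in ode.find_fixed_points(params):
    if fp.stable:
        print("stable fixed point:", fp.state.as_array().round(4))
```

prints

```
persistence True [0.3452 0.0425 0.2982 0.1267]
stable fixed point: [0.3452 0.0425 0.2982 0.1267]
```

— with CAFs inhibiting the T-cells (`δ_TF = 10`), the tumor persists at
a 0.35 mass fraction while the immune response is held at the `O(ε)`
level 0.04; removing the inhibition (`efficient-T-uninhibited`) drops
the cancer fraction to 0.25.  The long-time integration lands on the
same point as the independent root search.

A spatial scenario from the command line:

```bash
tmemix spatial-run --scenario immune-inflamed --n 64 --t-end 35 --out runs/
```

```
immune-inflamed: t=35.0 nest=0.000 fibrotic=0.000 meanC=0.0481
```

— with efficient T-cells and no CAF conversion the compact nest has
disappeared by t = 35 T0 (the nest area fraction is 0), leaving a
dilute remnant; the same run with `--scenario two-nests-desert` shows
two nests merging into one instead.  Each run writes the observable
time series (`observables.csv`: thresholded nest/fibrotic/T-cell area
fractions and species means) and gridded snapshots (`snapshots.nc`).

Other entry points: `tmemix ode-run`, `tmemix ode-phase`,
`tmemix ihc-summary` (cohort statistics — fibroblast coverage of the
stroma, class composition, tumor–stroma ratio — from a per-patient
staining-coverage CSV), `tmemix fixtures`.

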