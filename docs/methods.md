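# Methods

`tmemix` models the cellular composition of a non-small-cell lung-cancer
microenvironment at two levels of description: a well-mixed dynamical
system for the average mass fractions of four interacting cell
populations, and a two-dimensional multicomponent mixture model that
adds transport, mechanics and chemotaxis.  This note records the model
equations, the numerical choices, the parameter calibrations that were
genuinely open, and what the package's tests do and do not establish.

## 1. Population dynamics (`tmemix.ode`)

Four mass fractions — cancer cells `C`, cytotoxic T-cells `T`,
non-activated fibroblasts `F_NA` and activated, cancer-associated
fibroblasts `F_A` — share the tissue with a passive phase
`N = 1 − S`, `S = C + T + F_NA + F_A`.  Time is measured in units of
the inverse cancer growth rate, so all coefficients are dimensionless:

    dC/dt    = C − δ_CT·C·T/(1 + δ_TF·F_A) − δ_C·C·S
    dT/dt    = α_TC·C − δ_T·T·S
    dF_NA/dt = α_NA + α_NA,C·C − K_A·F_NA·C − δ_NA·F_NA·S
    dF_A/dt  = K_A·F_NA·C − δ_A·F_A·S

The `δ·φ·S` terms are crowding pressure (competition for space and
resources); `δ_CT` is the T-cell killing rate, attenuated by
CAF-mediated inhibition `δ_TF·F_A`; `α_TC` is chemotactic T-cell
recruitment; `α_NA` the homeostatic fibroblast influx; `α_NA,C` their
recruitment by the tumor; `K_A` the NAF→CAF conversion rate.  NAF→CAF
conversion is irreversible.  The standard reduction sets all four
pressure coefficients to one value `δ` (seven free parameters).

**Scaling structure.**  An efficient immune response corresponds to
`δ_CT = δ/ε` and `α_TC = a₀ε` with `ε ≪ 1`; CAF inhibition strong
enough to neutralize it corresponds to `δ_TF = d₀δ/ε`; the homeostatic
influx is `α_NA ~ δε⁴`.  The stable cancer/T-cell equilibrium then
scales as `(C⁺, T⁺) = O(ε/δ)` and exists for `a₀ > 1`.  The printed
closed form of that fixed point is typographically ambiguous in our
source material, so the package computes it numerically and the tests
assert only the `O(ε/δ)` magnitude (log–log slope 1 ± 0.1 over
`ε ∈ {0.1, 0.05, 0.01}`) and the `a₀ > 1` existence condition.  Note
that at `ε = 0.1` the finite-`ε` correction to `C⁺` is `O(1/(a₀−1))`;
the slope test uses `a₀ = 5` so that the asymptotic regime is already
visible at `ε = 0.1`.

**Fixed points and stability.**  `find_fixed_points` runs a multistart
root search (scrambled Sobol' starts folded into the simplex, plus the
origin and single-species corners), polishes roots by Newton iteration
to a residual below 1e−10, deduplicates at 1e−6 in max-norm, and
classifies stability from the finite-difference Jacobian spectrum;
eigenvalues within ±1e−8 of the imaginary axis mark a point as
*marginal* rather than stable/unstable (the origin with `α_NA = 0` is
the standard example).

**Integration.**  `simulate` uses LSODA at rtol 1e−8 (the killing and
inhibition coefficients sit an order of magnitude above the pressure
scale, which is mildly stiff) and falls back to Radau when LSODA's
stiffness switching fails in extreme corners of the phase diagram
(`δ_CT` of order 10²–10³).

**Outcome classification.**  From the final cancer fraction of a
near-stationary trajectory: *eradication* below 1e−3, *invasion* above
`0.5/δ`, otherwise *persistence*; stationarity requires relative drift
below 1e−4 over the final 10% of the run.  One caveat: scenario presets
with strong fibroblast recruitment (`α_NA,C = 1`) cap the cancer
fraction near 0.48 even with no immune response at all, so the
"invasion" label is not reachable for them under the 0.5 threshold; the
tests therefore assert the *contrast* between the CAF-inhibited and
uninhibited equilibria rather than a label for those presets.

**Phase diagram.**  The equilibrium cancer fraction is mapped over the
two composites that control the outcome: killing ability
`α_TC·δ_CT/(α_NA,C·K_A·δ_TF)` and crowding `α_NA,C + α_TC`.  The
reconstruction holds `δ_TF` and `K_A` at the CAF-inhibited preset
values, splits the crowding composite equally between `α_NA,C` and
`α_TC`, and solves `δ_CT` from the killing composite (with that split,
`α_TC` cancels `α_NA,C`, so `δ_CT = kill·K_A·δ_TF`).  Unreachable
composites yield NaN cells, never silent clipping.

## 2. Spatial mixture model (`tmemix.spatial`)

Each species has a local mass fraction `φ_i(x, t)`, a velocity
`v_i`, and a source `Γ_i`; conservation reads
`∂t φ_i + ∇·(φ_i v_i) = Γ_i`.  Velocities minimize a Rayleighian
(dissipation plus rate of free-energy change).  With
`φ̃_i = φ_i/φ₀`, the per-cell 4×4 friction matrix is

    A_ii = Σ_{j≠i} (ξ_ij + ξ_j0·φ̃_i)·φ_j + ξ_i0·(1 + φ̃_i)²
    A_ij = φ_j·(−ξ_ij + ξ_i0 + ξ_j0 + Σ_k ξ_k0·φ̃_k)

(the off-diagonal form is the published expression with the telescoping
`ξ(1+φ̃) − ξφ̃` collapsed).  All pairwise frictions are `ξ₀` except
pairs involving the CAF component, which carry `ξ₀ + ξ₁·φ_A`: CAF-laid
matrix fibers are a mechanical barrier for every motile species.  The
velocity system is solved cell-wise, `Σ_j A_ij v_j = −∇μ_i`.

**Free energy.**  Flory–Huggins mixing with a square-gradient penalty:

    f = Σ_i D_i φ_i ln φ_i + D₀ φ₀ ln φ₀ − λ_CC C² − λ_CT C·T − λ_CF C·(F_NA+F_A)
    F = ∫ (f + Σ_i κ|∇φ_i|²/2)

**The passive-phase osmotic term.**  The chain-rule contribution
`−D₀(1 + ln φ₀)` that `φ₀ = 1 − Σφ_j` would add to every chemical
potential is *disabled by default* (`SpatialParams.d0_osmotic`).  With
it, `min_C (D_C/C + D₀/φ₀) = (√D_C + √D₀)² ≈ 1.7e6` exceeds
`2λ_CC = 5e5` for every composition: the mixture is strictly convex, no
interface can exist, and every species acquires a dilute Fickian
diffusivity `~D₀/ξ₀ ≈ 3×10³ µm²/T0` that disperses a dense nest within
a few T0.  Without it, the same coefficients are exactly
self-consistent with the intended physics: a spinodal at
`C > D_C/(2λ_CC) = 0.2` and an interface width
`√(κ/2λ_CC) ≈ 8.5 µm`, matching the ~10 µm interface and the dense
phase `C ≈ 0.8` that the parameter table was built around.  The
energy bookkeeping (`total_free_energy`) uses the functional matching
whichever convention is active, so the Lyapunov property is checked
against the energy the dynamics actually descend.

**Chemoattractant.**  A single massless chemical produced by cancer
cells and degraded linearly equilibrates much faster than the tissue:
`λ_c²∇²c − c + α_cC·φ_C = 0` with `λ_c = 30 µm`, `α_cC = 3`, no-flux
boundaries.  (`λ_c` multiplies the Laplacian as a squared length; the
printed equation is dimensionally a length² but names a penetration
length.)  The 5-point Neumann Laplacian is diagonal in the type-II
cosine basis, so the solve is two FFT-sized transforms per step.

**Sources.**  Cancer cells proliferate in place,
`Γ_C = φ_C − δ_CT φ_C φ_T − δ φ_C S` (CAF inhibition of killing is not
re-introduced here: the fiber barrier acts through friction).  T-cells
and NAFs are produced far away and enter through the source geometry
(whole boundary, vessel disks, or one boundary side) at rate
`c·(1−S)·τ/Δx` on a one-cell layer — a surface flux spread over the
layer.  NAFs convert to CAFs at rate `K·φ_NA·c` (chemical-driven
plasticity); all species feel the pressure death `−δ·φ·S`.

**Proliferation threshold.**  Growth is active only where
`φ_C > 1e−4`.  The growth term is exponential where `S` is small, so
over a 35 T0 horizon it amplifies any numerically transported residue
by `e³⁵ ≈ 10¹⁵`; no discretization keeps far fields empty without a
nucleation cut.  Physically, a mass fraction of 1e−4 in a
representative volume of ~(10 µm)³ is less than a single cell: below
it there is no population to proliferate.  Initial tanh tails below the
threshold are truncated to exact zeros for the same reason.

**Velocity right-hand side.**  The solver supports three conventions
for the thermodynamic drive: the published `−∇μ_i` (default), the
force-density `−φ_i∇μ_i` (degenerate mobility: empty cells have zero
velocity), and a mixed law (degenerate for the cohesive phases C and
CAF, linear for the individually motile T and NAF).  The default is the
published form: it is the only convention under which an efficient
T-cell response eradicates the nest, because eradication requires
T-cells to keep full diffusive mobility inside dense tissue.  The
degenerate variants produce kill/growth stalemates in which the dense
cancer phase shields itself; they are retained as options because they
keep dilute tails compact.

### Discretization and time stepping

Uniform cell-centered grid, conservative flux-form advection with
donor-cell upwinding (face velocity = average of adjacent centers; zero
boundary flux), 5-point Laplacians with mirror ghosts.  Per-species
grid totals are conserved to round-off by construction.

The gradient-penalty term makes a fully explicit scheme impractical
(`dt ≲ ξ₀Δx⁴/32κ ≈ 5e−5 T0` at Δx ≈ 1.2 µm).  The default stepper is
first-order IMEX: advection and sources explicit, plus a
constant-coefficient damping operator `D̄∇² − S̄∇⁴` treated implicitly
through the DCT diagonalization of the Neumann Laplacian — the
classic linearly-stabilized splitting for Cahn–Hilliard-type equations.
`S̄ = 2·m·κ` and `D̄ = 2·m·(max D_i + [D₀/φ₀,min])` are refreshed every
20 steps from the current maximal mobility
`m = max φ_i^w (A⁻¹)_ii` (w = 1 for degenerate species).  The k = 0
mode is untouched, so the stabilizer conserves mass exactly.  The time
step is `0.8×` the advective CFL bound, capped at 1e−3 T0.  The fully
explicit mode (with the Δx⁴ bound) remains available and is what the
energy-decay test uses; under the IMEX stabilizer the free energy is
non-increasing over windows rather than strictly per step.

Negative undershoots (the stabilizer sheds ~1e−6-level ripples around
sharp interfaces) are zeroed; only undershoots beyond the tolerated
−1e−6 band are counted against the clip budget reported in the run
counters (< 0.1% of cell-steps in all registered scenarios).  Cells
whose active sum exceeds 1 are renormalized onto the simplex boundary.
Logarithm arguments are floored at 1e−8 (1e−6 for φ₀ inside φ̃);
floor usage is counted.  Near-singular velocity systems receive a
Tikhonov shift `1e−8·ξ₀` (counted); in practice the friction matrix is
strongly diagonally dominant and the shift never fires in the
registered scenarios.

The per-cell assembly/solve, the chemical potentials and the upwind
divergence are fused into single-pass numba kernels; a pure-numpy
implementation of each operation is retained and the two paths are
cross-checked to ~1e−13 in the test suite.

### Parameter calibrations that were genuinely open

Three constants of the published table could not be used as printed;
each was fixed by an a-priori argument, not by fitting outputs:

* **Boundary influx `τ_T = τ_NA`** (printed 2.5e−3 µm/T0).  A
  stationary balance — influx `τ·c_b·(1−S)` over the perimeter against
  the pressure-death sink `δ·φ·S` over the domain, with the screened
  chemoattractant level `c_b ≈ 0.3–0.6` at the boundary — requires
  `τ ≈ 25 µm/T0` to sustain the reported stromal occupancy of ~20–25%
  of the tissue.  The printed value yields a tissue with essentially no
  stroma (mean T-cell fraction below 1e−3), in which none of the
  immune scenarios can occur at all.  Influx saturates above
  `τ ≈ 25` because `(1−S)` self-limits at the boundary, so the
  calibration is insensitive to the exact value.  Default 25 µm/T0.

* **Window geometry** (unreported).  The defaults are a 150 µm window
  with a 20 µm single nest (two 15 µm nests at ±30 µm from the center
  in the two-nest scenarios).  Two independent constraints point to
  this scale: the published two-nest placement (30 µm from the center)
  only leaves room for nests of ~15 µm in a window of ~150 µm, and the
  boundary must lie within a few penetration lengths (`λ_c = 30 µm`)
  of the nest or the chemoattractant — and with it all influx,
  activation and immune behavior — vanishes at the vasculature.

* **The osmotic term and the velocity drive**, discussed above.

### What the scenario runs do and do not reproduce

The qualitative scenario physics is reproduced: free growth is the most
severe outcome; CAF conversion builds a fibrotic ring of elevated
friction around the advancing front; an efficient T-cell response
without CAF activation eradicates the nest (the compact nest disappears
and two inflamed nests never coalesce, while immune-desert nests merge
into one).  The *quantitative* area fractions of the confinement
scenarios are not reproduced: in this implementation the proliferating
front outruns the stroma, because the stroma the boundary influx can
build (S ≈ 0.2–0.3) never reaches the density `S ≈ 1/δ` needed to
arrest growth through the pressure term, and the printed conversion
rate `K = 10/T0` activates fibroblasts at the vasculature before they
can travel to the nest.  The published fractions (nest confined to
25%, fibrotic zone 70%) therefore appear unreachable under the printed
rate constants with any of the implemented transport conventions; the
scenario observables are reported as computed.  A residual dilute
cancer haze (~0.05 mass fraction) also survives eradication runs at
the kill/growth margin `δ_CT·T̄ ≈ growth`, so the eradicated state
sits near 5% of the immune-desert cancer mass rather than below 1%.

## 3. Observables (`tmemix.observables`)

Area fractions use a strict indicator (`φ > 0.1` at cell centers, no
subcell interpolation): nest (`C`), fibrotic (`F_A`), T-cell-rich
(`T`).  Nest counting uses 4-connected components of the thresholded
cancer field (conservative for coalescence claims).  Species means are
plain arithmetic means over cells.

## 4. Staining-coverage tables (`tmemix.ihc`)

`read_coverage_table` parses a delimited per-patient table (delimiter
sniffed among comma/semicolon/tab; a column-mapping argument adapts to
other schemas).  Cohort statistics: total fibroblast coverage of the
stroma = sum of the four class coverages (ADH1B, FAP+αSMA−, FAP+αSMA+,
FAP−αSMA+) per patient; composition = per-patient class shares averaged
across patients (a pooled-by-area alternative is available, since the
aggregation rule is a reporting choice); TSR = tumor area / stroma area
(values above 1 put tumor in the numerator); everything reported as
mean ± sd across patients.

The synthetic generator emulates the structure of such a table with
per-patient truncated-normal draws (location-corrected so the
*truncated* means match the configured cohort means) and Dirichlet
class compositions, for LUAD (47±13% cancer coverage, 31±17%
fibroblast coverage of stroma, TSR 1.07±0.68, composition
48/18/7/26%) and LUSC (54±10%, 35±12%, TSR 1.30±0.53, composition
6/37/25/31%).  It reproduces cohort-level marginals and is suitable
for testing the pipeline; it does not emulate inter-variable
correlations (e.g. TSR vs. fibroblast coverage) present in real
cohorts, so passing tests say nothing about such structure.

## 5. Problem sizes used by the tests

Unit and property tests run on 32²–64² grids with short horizons; the
scenario-level checks run the registered scenarios at 64² to t = 35 T0,
and `scripts/acceptance.py` recomputes the headline scenario fractions
at 128².  Spatial fractions at 64² agree with 128² to within a few
percent (the interface spans ~4 cells at 64²); the chemical decay-length
check uses a 512-cell 1D-like domain at Δx = 1 µm.
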