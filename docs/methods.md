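# Methods

## The two reaction networks

Both models describe the concentration dynamics of a TGF-β-family dimer
ligand in a well-mixed early embryo. Shared assumptions:

- **Windowed constitutive synthesis of Nodal.** λ_N(t) = λ_N for
  t_on < t < t_off and 0 otherwise, with t_on = 4 hpf (onset of zygotic
  transcription and translation) and t_off = 6 hpf (end of mesendodermal
  patterning). The value at the boundary instants themselves is defined as
  0 — a measure-zero convention that cannot affect any integral but makes
  `production_rate` deterministic and directly testable.
- **First-order monomer degradation**, half-lives ln2/β_N and ln2/β_V
  (≈ 1.66 h at the defaults).
- **Irreversible bimolecular dimerization** with a single rate λ_D for
  both pairing reactions; the dimer is not degraded and is never consumed,
  so D(t) is non-decreasing.
- **Vg1 is maternally provided**: no Vg1 synthesis term anywhere; the
  pool enters only through the initial condition V(0) = V₀. The primed
  model starts at (N, V, D) = (0, V₀, 0); cold-start at (N, D) = (0, 0).

Cold-start stoichiometry: the homodimer sink appears as λ_D·N² in dN/dt
and as +λ_D·N² in dD/dt, i.e. one monomer consumed per dimer formed. A
chemically standard 2:1 scheme would remove 2λ_D·N²; this package
implements the 1:1 form deliberately and consistently — the deterministic
equations, the mass ledger, and the stochastic twin all share it — and a
physical-stoichiometry variant is explicitly out of scope. With the 1:1
form the Nodal ledger ∫λ_N dt = N + D + ∫β_N·N dt holds exactly for both
models, which is what the conservation tests check.

## Default parameters

| symbol | meaning | default | units |
|---|---|---|---|
| λ_N | Nodal synthesis rate in window | 2×10⁻¹³ | M s⁻¹ |
| β_N | Nodal degradation rate | 1.16×10⁻⁴ | s⁻¹ |
| β_V | Vg1 degradation rate | 1.16×10⁻⁴ | s⁻¹ |
| λ_D | dimerization rate | 1×10⁶ | M⁻¹ s⁻¹ |
| V₀ | maternal Vg1 pool | 100 | nM |
| t_on, t_off | production window | 4, 6 | hpf |
| t_end | horizon | 10 | hpf |

t_end = 10 hpf is a package choice (no horizon is implied by the model
itself); it comfortably covers the post-window decay of all transients.
All internal computation is SI (M, s); serialization uses the units each
quantity is conventionally quoted in (rates in SI, V₀ in nM, window in
hpf), with exact conversion factors 1 nM = 10⁻⁹ M, 1 hpf = 3600 s.

Useful derived scales: λ_N/β_N ≈ 1.724 nM is the monomer plateau without
dimerization; the cold-start quasi-steady monomer, the positive root of
λ_D·N² + β_N·N = λ_N, is ≈ 0.393 nM; and the primed pairing timescale
1/(λ_D·V₀ + β_N) ≈ 10 s is far shorter than every other timescale in the
system — which is the mechanistic heart of the comparison: primed Nodal is
captured into dimer essentially as fast as it is made, while cold-start
dimerization is quadratically slow at low N.

## Numerical integration

The production discontinuity is handled structurally: integration is
piecewise on [0, t_on], [t_on, t_off], [t_off, t_end], with state handed
across boundaries, so the solver never sees a jump inside a segment (step
controllers mis-handle interior discontinuities). Each segment is solved
with the explicit 8th-order Runge–Kutta pair DOP853 at rtol = 10⁻⁸,
atol = 10⁻¹⁵ M. The step size is additionally capped at 120 s: in the flat
post-window phase the controller would otherwise take very large steps
whose dense-output interpolation error exceeds the endpoint error and puts
10⁻¹⁴-M-scale wiggles on the nearly constant dimer curve; with the cap the
λ_D = 0 solution matches the closed form at round-off level and D(t) is
exactly monotone on the default grid. Three cumulative integrals
(production, and both degradation outflows) are co-integrated with the
state so conservation can be checked pointwise rather than re-derived by
quadrature. Negative concentrations beyond 10⁻¹² M are an error, never
clipped — silent clipping hides solver failure. The default output grid is
one point per minute; trajectory CSV output rounds to 4 decimals in
nM/hpf, with a full-precision mode for oracle comparisons.

`tests/rk4_oracle.py` holds an independent fixed-step (1 s) classical RK4
re-implementation of both systems; the dominance and ordering claims are
asserted against it as well as against the package integrator.

## Stochastic twin

In volume Ω, counts are n = c·Ω·N_A and the networks become jump processes
simulated with the direct Gillespie method, exactly, segment by segment
(the production propensity is piecewise constant, so each segment is
time-homogeneous). The cold-start channel fires with propensity
λ_D·n_N(n_N−1)/(Ω·N_A) and removes one N — matching the deterministic 1:1
scheme's mean field, not the standard chemical 2:1 convention, because the
SSA's role here is to validate the integrator, and an oracle must share
the equations it checks. The default Ω ≈ 1.66×10⁻¹² L maps 100 nM to 10⁵
molecules: large enough that relative fluctuations (~Ω^−1/2) keep a
1000-replicate ensemble mean within a few parts in 10³ of the mean field,
small enough that the full two-model comparison runs in seconds. Replicate
seeds derive deterministically from the config seed via `SeedSequence`, so
every realization is reproducible bit-for-bit. The kernel is numba-jitted;
the first call in a fresh process pays a one-time compilation cost.

## Synthetic data and recovery

No trajectory-level measurements of this system exist, so the recovery
stage is a self-consistency study on synthetic data: observed dimer values
are the deterministic trajectory times exp(ε), ε ~ N(0, σ²) i.i.d. per
replicate and time (σ = 0.1, i.e. ~10% multiplicative error, is the
reference noise level; a lognormal model keeps observations positive and
is the natural multiplicative analogue of Gaussian assay noise). Fitting
minimizes squared *log* residuals — the maximum-likelihood objective under
that noise — via bounded `least_squares` in log10 parameter space
(parameters span 19 orders of magnitude; log-space makes the problem
well-conditioned), from a fixed starting point, with non-free parameters
pinned to the ground truth. Observation times with non-positive observed
values (before the window, where the noiseless dimer is zero) carry no
information under the log model and are excluded.

The default observation design samples every 30 s for the first 10 min
after t_on, then every 15 min to t_end. This is an identifiability choice,
made from the sensitivity profile: ∂logD/∂logλ_D ≈ 0.7–0.9 within a minute
of onset but decays to ≈ 0.07 by 15 min, because once free Nodal relaxes
onto its quasi-steady balance the dimer simply tracks cumulative
production. A coarse-only design therefore cannot constrain λ_D from a
dimer readout, while the dense-early design recovers it to a few percent
at the reference noise with 20 replicates. Only single-parameter recovery
is claimed: joint fits are supported, but several parameter combinations
(e.g. λ_N and V₀ jointly) are weakly identified from dimer-only data.

## What the synthetic tests do and do not show

The generator emulates exactly the model structure the analysis assumes —
windowed synthesis, first-order decay, mass-action pairing, multiplicative
i.i.d. noise. Passing tests therefore demonstrate internal consistency
(the integrator solves the stated equations; the estimator recovers
parameters when the model is true), not that the model describes a real
embryo: real data would add spatial transport, receptor feedback,
Lefty-mediated inhibition, correlated measurement error and
embryo-to-embryo variability, all outside scope here. The headline
comparison output — primed onset ~0.49 h earlier and pointwise dimer
dominance under the defaults — is a property of the printed parameter set,
robust across thresholds 0.01–1 nM (no signaling threshold is established
experimentally, so the claim is an ordering, not a particular θ).

## Known limitations

- No spatial component, receptor binding, or inhibitor dynamics.
- Dimers are indestructible in both schemes; long-horizon behavior
  (D plateaus, never declines) is a modeling artifact of that choice.
- The cold-start 1:1 stoichiometry halves the monomer drain relative to a
  chemical 2:1 scheme; conclusions about absolute cold-start dimer levels
  inherit that convention (the primed-vs-cold ordering does not: a 2:1
  scheme would only slow cold-start dimer accumulation further).
- The SSA is exact but unaccelerated (no tau-leaping); very large Ω or
  very long horizons scale linearly in event count.
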