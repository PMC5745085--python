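# vgnodal

Mass-action kinetics of ligand dimerization in the early zebrafish embryo:
does a maternally deposited pool of Vg1 let the embryo respond faster to low
concentrations of zygotic Nodal than Nodal–Nodal homodimerization would
allow?

Mesendoderm induction is driven by a TGF-β-family dimer ligand. Zygotic
Nodal transcription only begins at the maternal-to-zygotic transition
(~4 hpf), and patterning must be complete by ~6 hpf, so the speed of dimer
formation matters. `vgnodal` implements and compares two kinetic schemes
for the active dimer *D*:

**Primed heterodimer model** — Vg1 monomer *V* is preloaded maternally; the
newly made Nodal monomer *N* pairs with it:

```
dN/dt = λ_N(t) − β_N·N − λ_D·N·V
dV/dt =        − β_V·V − λ_D·N·V
dD/dt =                  λ_D·N·V
```

**Cold-start homodimer model** — no Vg1; Nodal must accumulate and pair
with itself:

```
dN/dt = λ_N(t) − β_N·N − λ_D·N²
dD/dt =                  λ_D·N²
```

Here λ_N(t) is a windowed constitutive synthesis rate (2×10⁻¹³ M s⁻¹ for
4 hpf < t < 6 hpf, zero outside), β_N = β_V = 1.16×10⁻⁴ s⁻¹ are first-order
degradation rates, λ_D = 10⁶ M⁻¹ s⁻¹ is the dimerization rate, and the
maternal pool starts at V₀ = 100 nM.

The package provides:

- `vgnodal.model` — the two networks, the production schedule, and the
  default parameterization (`KineticParameters`);
- `vgnodal.simulate` — piecewise deterministic integration with
  co-integrated conservation ledgers;
- `vgnodal.oracles` — closed-form solutions in degenerate limits;
- `vgnodal.stochastic` — an exact Gillespie realization of both networks in
  a finite volume, plus a lognormal-noise synthetic-data generator;
- `vgnodal.metrics` — onset delay, time-to-threshold and dominance metrics
  comparing the two models;
- `vgnodal.recovery` — parameter recovery from noisy dimer trajectories;
- a `vgnodal` command line (`simulate`, `compare`, `ssa`, `synth`, `fit`).

## Worked example

```python
>>> from vgnodal import default_parameters, compare_models
>>> report = compare_models(default_parameters())
>>> print(report.to_dict())
{'threshold_nM': 0.1,
 't_theta_primed_hpf': 4.15540171441705,
 't_theta_cold_hpf': 4.645669805942803,
 'onset_delay_hpf': 0.49026809152575274,
 'D_at_toff_primed_nM': 1.39887073622382,
 'D_at_toff_cold_nM': 0.7861285892018665,
 'dominance': True}
```

With the maternal Vg1 pool, the dimer passes 0.1 nM at ~4.16 hpf — about
nine minutes after Nodal production starts. Without it, homodimer formation
needs ~29 more minutes (4.65 hpf) to reach the same level: an onset delay
of ~0.49 h, a large fraction of the 2-hour patterning window. At the end of
the window the primed model has made ~1.40 nM of dimer against ~0.79 nM
for the cold start, and the primed dimer curve lies at or above the
cold-start curve at every time point (`dominance: True`). The same
comparison from a shell:

```sh
vgnodal compare --plot comparison.png
```

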