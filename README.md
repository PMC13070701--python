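# cestfit

Chemical Exchange Saturation Transfer (CEST) NMR probes "invisible"
protein states: transient conformations populated at only a few percent
that exchange with the observable ground state on the millisecond
timescale. A weak RF field saturates the minor state's resonance; exchange
carries that saturation into the ground-state signal, so a plot of
normalized intensity against the saturation carrier position (the
Z-spectrum) shows a large dip at the ground-state shift and a small dip at
the otherwise undetectable minor-state shift.

`cestfit` turns such Z-spectra into kinetics and thermodynamics for
two-state exchange A ⇌ B. It simulates profiles with three forward
kernels, corrects for RF-field inhomogeneity, and jointly fits profiles
acquired at two or more RF field strengths — the multi-field constraint
that breaks the classic (k_ex, p_B, R_2,B) degeneracy — returning the
exchange rate k_ex = k_AB + k_BA, the minor population p_B, chemical-shift
differences Δδ = δ_B − δ_A, and relaxation rates, with Monte-Carlo or
covariance uncertainties.

## Model

Magnetization evolves under the Bloch–McConnell equations. For each state
S ∈ {A, B} with exchange partner S′:

    dMx_S/dt = −(R2_S + k_SS′)·Mx_S − Ω_S·My_S + k_S′S·Mx_S′
    dMy_S/dt = +Ω_S·Mx_S − (R2_S + k_SS′)·My_S − ω1·Mz_S + k_S′S·My_S′
    dMz_S/dt = +ω1·My_S − (R1_S + k_SS′)·(Mz_S) + k_S′S·Mz_S′ + R1_S·p_S

with Ω_S = 2π(δ_S − δ_sat)·ν₀ the offset from the saturation carrier
(rad/s), ω1 = 2πν₁ the RF amplitude, k_AB = p_B·k_ex, k_BA = (1−p_B)·k_ex.
The recovery term makes the augmented evolution matrix 7×7 (constant first
element), so Mz relaxes toward its equilibrium p_S rather than zero and
the far-off-resonance baseline is 1.

Three kernels predict the normalized intensity I(δ_sat) = Mz_A(T_sat)/p_A
from an equilibrium start:

- **matrix** — exact propagation by the matrix exponential of the 7×7
  generator;
- **baldwin** — analytical rotating-frame model: the spin-locked mode's
  relaxation rate R1ρ is obtained exactly in exchange and RF (first order
  in relaxation) from the 6×6 coherent+exchange eigensystem, and
  I = Z_ss + (cos²θ − Z_ss)·e^(−R1ρ·T_sat) + sin²θ·Re e^(λ⊥·T_sat),
  with tilt tan θ = ω1/Ω_A, Z_ss the exact steady state and λ⊥ the
  transverse-mode eigenvalue (the short-T_sat transient). Matches the
  matrix kernel to < 0.01 intensity units across the benchmark while
  remaining a closed-form-style evaluation;
- **noex** — single-spin Bloch evolution, the no-exchange negative
  control.

RF inhomogeneity is modeled as a Gaussian distribution of ν₁ across the
sample; predicted profiles are averaged over a ±2σ quadrature grid with
renormalized Gaussian weights.

Fitting is two-stage: automatic initialization (dip detection on the
lowest-field profile, coarse analytical-kernel scans of Δδ and the
kinetics) followed by bound-constrained Trust-Region Reflective least
squares over shared (k_ex, p_B) plus per-residue (δ_A, Δδ, R1, R2_A,
R2_B), minimizing Σ((I_obs − I_calc)/σ)².

## Worked example

Regenerate the built-in five-residue benchmark (ground-state shifts
118.0/110.0/115.0/120.0/125.0 ppm, Δδ −5.0/−1.0/+2.0/+2.0/−3.0 ppm,
k_AB = 15 s⁻¹, k_BA = 285 s⁻¹, ¹⁵N Larmor frequency 80.12 MHz,
T_sat = 0.4 s, ν₁ = 10 and 100 Hz, 2% intensity and B1 errors) and fit it:

```python
from cestfit import FitSpec, generate, joint_fit, paper_validation_spec

spec = paper_validation_spec(seed=7)
profiles, truth = generate(spec)
fit = joint_fit(profiles, spec.acquisition, FitSpec(method="baldwin"))

kex, ekex = fit.global_params["k_ex"]
pb, epb = fit.global_params["p_B"]
kab, ekab = fit.global_params["k_AB"]
kba, ekba = fit.global_params["k_BA"]
print(f"k_ex = {kex:.1f} +/- {ekex:.1f} 1/s")
print(f"p_B  = {pb:.4f} +/- {epb:.4f}")
print(f"k_AB = {kab:.2f} +/- {ekab:.2f} 1/s   (generating value 15)")
print(f"k_BA = {kba:.1f} +/- {ekba:.1f} 1/s   (generating value 285)")
print(f"reduced chi^2 = {fit.red_chisq:.3f}")
a1 = fit.per_residue["A1"]
print(f"A1: delta_A = {a1['delta_A'][0]:.3f} ppm, "
      f"delta_delta = {a1['delta_delta'][0]:.3f} ppm (truth -5.0)")
```

prints

```
k_ex = 299.3 +/- 9.7 1/s
p_B  = 0.0467 +/- 0.0015
k_AB = 13.96 +/- 0.67 1/s   (generating value 15)
k_BA = 285.3 +/- 9.2 1/s   (generating value 285)
reduced chi^2 = 0.906
A1: delta_A = 118.006 ppm, delta_delta = -4.985 ppm (truth -5.0)
```

The shared rates land within noise of the generating values (this
realization's B1 calibration errors push k_AB a few percent low), the
reduced χ² near 1 says the model accounts for the data at the injected
noise level, and the per-residue shifts are recovered to ~0.01 ppm.

The same fit as a scikit-learn estimator, with rows
(residue_id, b1_Hz, offset_ppm):

```python
from cestfit import CestRegressor
est = CestRegressor(method="baldwin", larmor_MHz=80.12, T_sat=0.4)
est.fit(X, y)            # X: DataFrame with the three columns above
est.k_ex_, est.p_B_, est.red_chisq_
```

## Command line

```sh
cestfit simulate --paper --seed 1 --out data/     # profiles + config + truth
cestfit fit data/config.yaml --method baldwin --out results/
cestfit validate --seed 1 --out validation/       # all three kernels
```

`fit` reads a YAML project configuration (acquisition constants, file
manifest, fit options — see `cestfit.io_formats`), archives it with the
results for exact reproducibility, and writes `report.tsv` plus observed
vs fitted curves. Profile files are plain text: two or three
whitespace/comma-separated columns (offset_ppm, intensity[, sigma]),
`#` comments allowed, e.g.

```
# offset_ppm  intensity  sigma
113.0  0.42  0.02
118.0  0.05  0.02
125.0  0.99  0.02
```

Fitting with a single RF field is refused: without a second field the
exchange rate, minor population and minor-state R2 trade off against one
another.

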