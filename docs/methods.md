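# Methods

## Physical model

Two-state chemical exchange A ⇌ B is parameterized by the total exchange
rate `k_ex = k_AB + k_BA` (s⁻¹) and the minor-state population
`p_B ∈ (0, 1)`; the microscopic rates follow from detailed balance
(`k_AB = p_B·k_ex`, `k_BA = (1 − p_B)·k_ex`). This parameterization, rather
than the raw rate pair, is used inside the optimizer because the
multi-field experiment constrains (k_ex, p_B) with far less correlation
than (k_AB, k_BA); the rate pair is reported as a derived output with
error propagation through the full covariance.

Chemical shifts are absolute ppm; the signed convention is
`delta_delta = δ_B − δ_A`, so a residue at 118.0 ppm with Δδ = −5.0 shows
its minor dip at 113.0 ppm. ppm→rad/s conversion uses the observed
nucleus's Larmor frequency directly (ppm × MHz = Hz).

`R1_B` is tied to `R1_A` throughout: the minor state's longitudinal rate
is essentially unconstrained by CEST data at these conditions, and
freeing it only degrades conditioning.

## Kernels

**Matrix.** The augmented 7×7 generator acts on
`[1, MxA, MyA, MzA, MxB, MyB, MzB]`; the constant first element implements
recovery toward thermal equilibrium (`Mz_S → p_S`), which is what makes
the matrix 7×7 rather than 6×6 and puts the far-off-resonance baseline at
1. The initial condition is thermal equilibrium
(`[1, 0, 0, p_A, 0, 0, p_B]`; no transverse terms) and the reported
intensity is `Mz_A(T_sat)/p_A`, so the zero-duration reference is exactly
1 — the convention consistent with Z-spectra whose baseline ≈ 1. B1 is
applied along +x with constant phase for the whole saturation period.

Numerically the exponential is evaluated per offset through the
eigendecomposition of the homogeneous 6×6 block plus the affine
steady-state shift `M(T) = M_∞ + V e^{ΛT} V⁻¹ (M₀ − M_∞)`,
`M_∞ = −A⁻¹b` — mathematically identical to `expm` of the augmented
generator but vectorizable over the offset grid. A reconstruction check on
the eigenbasis triggers a per-offset `scipy.linalg.expm` fallback for
singular or ill-conditioned cases (e.g. all relaxation rates zero). The
kernel is validated against an independent fixed-step RK4 integrator to
1e−6 (random parameter draws within the fitting bounds) and 1e−7
(single-case, dt = 1e−5).

**Baldwin (analytical R1ρ).** The coherent + exchange part of the 6×6
generator is diagonalized exactly per offset; the relaxation matrix is
applied as a first-order complex eigenvalue shift. The spin-locked mode is
identified by overlap with the ground-state-frame effective-field
direction `(sin θ, 0, cos θ)`, `tan θ = ω1/Ω_A`, giving
`R1ρ = −Re λ_lock`; one of the transverse precessing pair (direction
`(−cos θ, 0, sin θ)`) supplies the complex `λ⊥`. At `k_ex = 0` the
construction reduces exactly to the textbook
`R1ρ = R1 cos²θ + R2 sin²θ` and
`λ⊥ = −(R2 + (R1 − R2) sin²θ/2) + iω_e`.

The intensity model decomposes the equilibrium magnetization along the
tilted effective field:

    I(T_sat) = Z_ss + (cos²θ − Z_ss)·exp(−R1ρ·T_sat)
             + sin²θ·Re[exp(λ⊥·T_sat)]

where `Z_ss` is the exact spin-lock steady state obtained from the linear
system `A M_∞ = −b` (not the common `R1 cos²θ/R1ρ` approximation, whose
error is the dominant term near overlapping dips). The third term is the
transient of the non-locked component; at `T_sat = 0.4 s` it still carries
up to ~2% intensity at ν₁ = 100 Hz and is required for the < 0.01
cross-kernel agreement. Consequences of this model: `I(0) = 1`
(equilibrium), far-off-resonance `I → 1`, on-resonance with the ground
state `I → 0`.

Two eigenvalue-selection details matter. The ground-state tilt (not the
population-averaged one) must define the lock direction: between the two
dips the averaged offset passes through zero while the observed A spin is
still off-resonance, and an averaged-frame projection mis-picks the mode
there (intensity error up to 0.25). And the transverse mode must be a
*different* eigenvector than the lock mode, enforced explicitly.

Cross-validation measured on the five-residue benchmark grid (both
fields): max |Baldwin − Matrix| = 0.0047; ≤ 0.0099 over wide random
parameter draws. An independent literature closed form (first-order
average-frame expression, valid for slow exchange and small p_B) agrees
with the package's R1ρ to < 2% in its validity domain; both checks are in
the test suite.

**NoEx.** Full single-spin Bloch evolution including R1 recovery during
saturation (3×3 affine system, same numerics). It is the matrix kernel's
`p_B → 0` limit and serves as the negative control: its reduced χ² on
exchange-bearing data exceeds the exchange models' by an order of
magnitude.

**B1 inhomogeneity.** Gaussian distribution of ν₁ with fractional width
`b1_frac_sigma`, truncated at ±2σ, evaluated on an equally spaced grid
(default 11 nodes) with weights renormalized to sum to 1. 11 vs 101 nodes
differ by < 1e−3 in intensity at a 10% width. The benchmark fits do not
enable averaging (`b1_frac_sigma = 0` default); the width is a user
parameter an analyst sets from their probe's calibration profile.

## Fitting

Weighted least squares `Σ((I_obs − I_calc)/σ)²` over shared `(k_ex, p_B)`
(optionally per residue) plus per-residue `(δ_A, Δδ, R1_A, R2_A, R2_B)`,
minimized with SciPy's Trust-Region Reflective `least_squares` under
bounds: k_ex [1, 1e5] s⁻¹, p_B [1e−4, 0.5], Δδ [−30, 30] ppm, δ_A within
the data window, R1 [0.05, 10] s⁻¹, R2 [0.5, 200] s⁻¹. Explicit `x_scale`
values (100 for k_ex, 0.01 for p_B, 0.1 ppm for shifts, 0.5/5 s⁻¹ for
R1/R2) keep the trust region well conditioned. Single-field input raises
a degeneracy error naming the two-field requirement.

Initialization is fully automatic and deliberately more robust than
"deepest two dips":

1. dip detection on the lowest-B1 profile — local minima (with prominence
   and a 0.4 ppm minimum separation to suppress noise-split twins) whose
   depth below the robust baseline (median of the upper intensity
   quartile) exceeds `snr_threshold`·median(σ); if the nominal σ exceeds
   the profile's dynamic range (e.g. unit σ on noiseless data) the
   threshold falls back to a baseline-scatter estimate;
2. the minor-dip candidate is restricted to |Δδ| ≤ 12 ppm; missing
   secondary dips fall back to +2 ppm (flagged);
3. a coarse joint scan of (k_ex, p_B, Δδ) per residue with the analytical
   kernel (including the mirror −Δδ candidate) locates the right basin —
   without it, shoulder dips (Δδ = −1 ppm at 10 Hz) are missed and the
   global fit lands in mirror local minima;
4. a kinetic grid search (k_ex ∈ {50…1600} × p_B ∈ {0.005…0.1}) shared
   across residues, a fine 0.5 ppm Δδ scan, and a re-run of the grid.

The mirror degeneracy of Δδ at high B1 is resolved by this low-B1-driven
initialization; no sign post-processing is applied.

σ handling: profiles lacking an uncertainty column get a per-profile σ
estimated as the SD of intensities at the 20% of offsets farthest from
any (coarsely detected) dip. χ² is reported as
`Σ((obs−calc)/σ)²/(n_data − n_params)`.

Uncertainties: linearized covariance `(JᵀJ)⁻¹·χ²_red` always;
parametric Monte-Carlo on request (best-fit curves + Gaussian σ noise,
refit from the best-fit start, SD over iterations; deterministic given
the seed; iterations that saturate a kinetic bound are retained and
counted, with a flag when they exceed half). MC spreads agree with the
covariance errors within a factor of two on well-conditioned fits. Model
selection across kernels is not automated; users compare reduced χ² as
the benchmark table does.

## Synthetic benchmark

`paper_validation_spec` encodes five residues A1–A5 with ground-state
shifts 118.0/110.0/115.0/120.0/125.0 ppm and Δδ −5.0/−1.0/+2.0/+2.0/−3.0
ppm — spanning slow through intermediate regimes — with k_AB = 15 s⁻¹,
k_BA = 285 s⁻¹ (k_ex = 300, p_B = 0.05), 80.12 MHz, T_sat = 0.4 s, fields
10 and 100 Hz. Choices the benchmark design leaves open were fixed once:

- relaxation R1 = 1.5 s⁻¹, R2 = 10 s⁻¹ — typical ¹⁵N backbone values at
  this field; the recovery and χ² properties tested are insensitive to
  them;
- offset grid 104–130 ppm, 0.25 ppm steps (105 points/profile) — covers
  every resonance with ≥ 2 ppm margin and resolves 10 Hz dips;
- intensity noise: additive Gaussian, σ = 0.02 of the normalized scale
  ("2% error" read as 1σ, additive because NMR noise is thermal and
  offset-independent);
- B1 calibration error: one multiplicative Gaussian draw (σ = 2%) per
  *field*, shared by all residues — a miscalibrated RF amplitude is a
  property of an experiment, not of a residue. Profiles carry the nominal
  ν₁, so fits must absorb the calibration error, and the generator
  (matrix kernel at the actual ν₁) returns the ground truth alongside.

What the generator emulates: realistic two-field CEST profile sets with
calibration-style systematics and point noise. What it does not: baseline
distortions, phase errors, peak overlap in the spectra themselves,
temperature drift, >2-state exchange. Passing the benchmark therefore
demonstrates correct model inversion under the stated noise model, not
robustness to every experimental artifact.

Noiseless datasets carry unit σ (an unweighted fit) since σ = 0 is
invalid in χ².

## Problem sizes and reproducibility

The test suite fits the full benchmark (1050 points, 27 parameters,
~5–10 s per fit), runs the replicate-recovery check at 4 seeded
replicates, and the Monte-Carlo checks at 3–20 iterations; these sizes
keep the whole suite at a few minutes while leaving the statistical
assertions well-resolved. All randomness flows through
`numpy.random.default_rng` seeds carried in the specs; writers emit
deterministic output (6 significant digits), and every CLI run archives
its configuration + seed, so re-running from the archived configuration
reproduces reports byte for byte.

## Known limitations

- Two-state exchange only; no linear/triangular three-state topologies,
  no temperature coupling of parameters.
- Constant-phase rectangular saturation; no shaped/DANTE irradiation, no
  scalar-coupling evolution.
- The analytical kernel is first order in relaxation: errors grow when
  R2 approaches the effective-field/exchange scales (watch the ~0.01
  cross-kernel margin for R2 ≳ 60 s⁻¹ at ν₁ = 10 Hz).
- The Monte-Carlo spread reflects the full 27-parameter fit; with all
  per-residue parameters free, the k_AB spread at 2% noise is ~1 s⁻¹
  (matching the covariance), not smaller magnitudes achievable with
  tighter parameterizations.
- Spectrometer raw formats are out of scope; inputs are plain-text
  tables.
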