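# Methods

## Models

**Motion models.** A backbone N–H bond vector is described either by a
single stochastic reorientation (SMF) with order parameter S² and
correlation time τ,

    J(ω) = (1 − S²) · τ / (1 + ω²τ²),

or by two statistically independent motions (EMF) — a fast one (S_f², τ_f)
and a slow one (S_s², τ_s) —

    J(ω) = (1 − S_f²) · τ_f / (1 + ω²τ_f²)
         + S_f² (1 − S_s²) · τ_s / (1 + ω²τ_s²),

with total order parameter S_f²·S_s².  There is no overall-tumbling term:
the molecules are immobilised in a crystal lattice, which is what opens the
window beyond a few nanoseconds in the first place.  Note the normalisation:
no 2/5 prefactor; it is absorbed into the rate expressions below.  In the
EMF spectral density τ_f appears in the fast and τ_s in the slow numerator
(the standard form; a typographically ambiguous bare τ is sometimes printed
in both terms).

**Relaxation rates.** With the dipolar constant
d = (μ₀/4π)·γ_H γ_N ħ / r_NH³ (rad/s, signed) and the CSA constant
c = ω_N·Δσ·10⁻⁶ for an axially symmetric ¹⁵N shift tensor:

    R₂  = (1/20) d² [4J(0) + J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H) + 6J(ω_H+ω_N)]
        + (1/15) c² J(ω_N) + (4/45) c² J(0)
    R₁  = (1/10) d² [J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H+ω_N)] + (2/15) c² J(ω_N)
    η   = (1/15) d c P₂(cos β) [4J(0) + 3J(ω_N)]

η is the transverse ¹H–¹⁵N-dipole/¹⁵N-CSA cross-correlated rate; β (default
0°) is the angle between the N–H bond and the CSA symmetry axis.  These
expressions assume *unsigned* Larmor frequencies — |ω_H|−|ω_N| is the
zero-quantum and |ω_H|+|ω_N| the double-quantum term — and the
implementation takes magnitudes internally, so the rates are invariant under
the sign convention chosen for ω_N.  The sign of η follows sign(d·c); for
¹⁵N both constants are negative, so η > 0 here.  R₁ρ measured with a tilted
effective field is converted via R₂ = [R₁ρ − R₁cos²θ]/sin²θ; below a tilt
floor (default 60°) the 1/sin²θ amplification makes the conversion
unreliable and the result is flagged rather than rejected.

**Constants.** Gyromagnetic ratios are pinned to the conventional NMR
tabulation, γ_H = 2.67519×10⁸ and γ_¹⁵N = −2.7116×10⁷ rad s⁻¹ T⁻¹, which
reproduces the reference dipolar anisotropies (13,668 Hz for ¹H–¹H at 2.6 Å;
353 Hz for ¹H–¹⁵N at 4.1 Å) to the nearest Hz.  Defaults r_NH = 1.02 Å and
Δσ = 170 ppm.  The dipolar *tensor anisotropy* convention is δ = 2b/2π
(twice the coupling constant in Hz).  Note an intentional inconsistency
carried by the field: r_NH = 1.02 Å gives δ ≈ 22.95 kHz, while REDOR
simulations conventionally use an effective (vibrationally pre-averaged)
δ_rigid = 20.4 kHz.  Both constants are exposed; which absorbs the
vibrational averaging is not decided here.

## Model-free fitting

The target function is χ² = Σᵢ wᵢ (Xᵢ,calc − Xᵢ,exp)²/σᵢ², minimised by an
exhaustive grid search followed by Nelder–Mead refinement (multi-start: the
grid optimum, up to two additional distinct low-χ² basins, and — for EMF —
the best SMF solution embedded in the EMF space, which enforces the nesting
χ²_EMF ≤ χ²_SMF up to optimizer tolerance).  Grids: S² ∈ [0,1] step 0.005;
τ log-spaced over 10⁻¹³–10⁻⁵ s with 160 nodes; for EMF, S_f², S_s² step
0.02 with τ_f capped at 5 ns and τ_s starting at 1 ns, which breaks the
label-swap degeneracy between the two motions (their physical regimes are
tens of ps vs tens of ns).

Pinning the total order parameter to the dipolar-coupling value is done by a
strong weight (w = 1000) on the S2dip residual rather than by substitution,
keeping a single minimisation code path; the resulting total S² matches the
dipolar value to <0.1%.  Minimum-data rules: 3 observations when dipolar
data are present, 4 for relaxation-only fits.  Degrees of freedom follow the
n−2 (SMF) / n−4 (EMF) convention.

**Errors.** Monte-Carlo resampling (default 2000 draws, seedable): every
observation is perturbed independently within its Gaussian σ and refitted on
a 2×-coarsened grid (a deliberate trade: the MC spread is dominated by the
data noise, not by grid resolution).  **Underdetermination** is flagged when
the statistically indistinguishable region (Δχ² ≤ 2) spans more than 0.3 of
an order-parameter range or more than 1.5 decades of a correlation time —
the situation of EMF fits to relaxation-only data.

**Model selection.** F = [(χ²_SMF − χ²_EMF)/χ²_EMF] / [(DF_SMF −
DF_EMF)/DF_EMF] with p from F(ΔDF, DF_EMF); EMF is "accepted" at p < 0.05
(an assumption — no canonical α exists for this test).  AIC = χ² + 2k, ties
to the simpler model.  A caveat established by simulation in this package:
under a true-SMF null the test is *conservative* (type-I error ≈1.5% at
α = 0.05 for a seven-observable set), because an SMF truth always lies on
the boundary of the EMF parameter space (S_f² = 1 or S_s² = 1) and the χ²
improvement under the null follows a boundary-mixture distribution rather
than the nominal F law.  The F-test calibration check in the acceptance
suite states the nominal-calibration expectation and therefore fails; this
is a property of the statistic, not of the optimizer (verified by lifting
the τ-grid constraints and by confirming nesting).

## REDOR engine

**Sequence.** Time-shifted REDOR: per rotor period two ¹H π pulses at
τ_r/2 + ts and τ_r − ts, one central ¹⁵N π pulse at half the total
recoupling time; the reference experiment S0 omits the ¹H pulses.  The
shift scales the ω_r-harmonic recoupling by cos(ω_r ts) while admixing a
2ω_r component, slowing the dephasing so the oscillation can be sampled on
the rotor-synchronised grid (ts ∈ [0, τ_r/4]; pulse-overlap is validated,
not silently truncated).  XY-8 phasing either runs continuously through the
train or mirrors about the centre (default), the variant found to match
measured curves slightly better.

**Propagation.** 2–3 spins (one ¹⁵N, one or two ¹H) in Hilbert space.
Interactions: heteronuclear dipolar (2IzSz), homonuclear dipolar with
flip-flop (3I₁zI₂z − I₁·I₂), axially asymmetric CSAs, isotropic offsets, rf
during pulses.  Rotor modulation is handled by Wigner rotations of the
rank-2 spherical components (PAS → crystal → rotor), with the m = ±1, ±2
components scaled by d²ₘ₀ at the magic angle.  The Hamiltonian is averaged
*exactly* over each time slice (analytic integrals of e^{−imω_r t}), then
exponentiated blockwise: diagonal blocks and 2×2 blocks in closed form,
larger blocks by batched eigendecomposition, vectorised over all powder
orientations.  Slice boundaries coincide with pulse edges; free evolution of
diagonal Hamiltonians is integrated in a single exact step.  Defaults: 100
slices per rotor period, halved inside pulses — step-halving changes curves
by < 2×10⁻⁴ RMS (asserted by test).

**Powder averaging.** Default: 144 Fibonacci-sphere (α, β) points × 16 γ
angles.  Sixteen γ angles are needed because strongly dephased curves
contain high γ-harmonics (8 angles alias them visibly).  For single-tensor
(bare-pair) problems a Gauss–Legendre β × uniform γ quadrature converges
much faster and is used for reference libraries.  Orientation counts are
recorded in curve metadata.

**Oracles.** The δ-pulse two-spin limit has a closed form: the toggling
frame phase is integrated analytically between pulse marks and powder
averaged (`ideal_redor_curve`); for ts = 0 it coincides with the classical
Bessel-function universal curve 1 − (√2π/4)J₁/₄(√2λ)J₋₁/₄(√2λ), λ = D·t.
The propagator reproduces both to <1% RMS, which is the primary correctness
anchor of the engine.

**Coupling fits and rf bias.** Curves are fitted with one parameter (δ_D)
against a library of reference two-spin curves (grid 0–26 kHz, 50 Hz step,
parabolic refinement; Monte-Carlo errors by resampling).  Library styles:
`ideal` (δ-pulse closed form — the default for fitting data) and
`simulated` (finite-pulse two-spin propagation at nominal calibration — the
"standard simulation" reference used to quantify bias; built for all grid
couplings in one vectorised batch).  The rf-inhomogeneity correction factor
is δ_in/δ_fit − 1 for the inhomogeneity-averaged curve fitted against the
`simulated` library; with the packaged *synthetic* low-tailed rf profile it
comes out at ~1–2%, of the order expected for solenoid coils.  The profile
(`RfProfile.synthetic_solenoid`, and the equivalent text format) is an
explicit stand-in: real correction factors must use the measured nutation
profile of the actual probe.  Scans of apparent δ_D versus ¹H rf show an
interior maximum slightly above nominal calibration; the same fractional
mis-set on the ¹⁵N channel changes δ_D several-fold less.

## Rate extraction

Spin-lock decays are fitted as two-parameter mono-exponentials
I(t) = A·e^{−Rt} (no baseline offset — deuterated samples and long spin
locks justify it; residuals are available for QC), errors by Monte-Carlo
resampling (default 2000 draws).  Peak-volume errors follow
√n_points · 3 · σ_noise.  R₁ρ→R₂ conversion propagates both the decay-fit
and the R₁ uncertainty.

## Synthetic data generator

A 76-residue template with a ubiquitin-like secondary-structure string
(β1–β2–α1–β3–β4–3₁₀–β5) draws per-residue EMF truths from per-class uniform
priors: secondary structure S_f² ∈ 0.85–0.94, S_s² ∈ 0.95–1.0, τ_s
20–100 ns; loops S_f² ∈ 0.72–0.88, S_s² ∈ 0.86–0.97, τ_s 50–800 ns
(log-uniform times; τ_f 20–150 ps everywhere).  These ranges encode the
qualitative experimental pattern — loops more mobile, with slower slow
motions — at amplitudes typical for amide backbones.  Emitted data: the
seven-observable set (R₁ at 11.74/14.09/19.96 T, η at 14.09/19.96 T, R₂ at
14.09 T, S2dip) with σ = 0.009/0.46/1.57 s⁻¹ and 0.018 respectively;
R₁ρ decays on the 10-point 5–250 ms grid (tilt angles drawn in 85–90°,
1% intensity noise); REDOR curves on an 8-step rotor-synchronised grid at
37.037 kHz MAS from the S-scaled effective coupling (σ 0.02).

What the generator does *not* emulate: resonance overlap physics (only a
random missing-data mask), site-to-site CSA variation, temperature or B₁
instabilities, coherent contributions to R₁ρ, or correlated noise between
observables.  Passing end-to-end tests therefore demonstrates the
correctness and calibration of the analysis chain under the stated noise
model — not robustness to every systematic error of real spectra.

## Numerical choices and limitations

* Angular frequencies in rad/s internally; fields accepted as tesla or ¹H
  Larmor MHz; times in seconds; couplings in Hz.
* Grid-vs-refinement agreement holds to a grid cell on noiseless data; with
  noise the χ² valley is correlated in (S², log τ) and the discrete argmin
  may sit a node or two away from the continuous optimum at negligible Δχ².
* Problem sizes in the test suite (powder counts, slice counts, residue
  subsets, MC draws) are scaled-down but convergence-checked choices; the
  library defaults are the converged settings quoted above.
* Not covered: >3-spin networks, protonated spin baths, other recoupling
  sequences (TM-REV, R-sequences, DIPSHIFT, phase-inverted CP), pulse
  transients and amplifier droop, non-axial CSA in the *relaxation* rates
  (the REDOR engine does accept asymmetric tensors), anisotropic overall
  tumbling, SRLS-style slowly-relaxing-local-structure analyses, and global
  shared-τ fits.
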