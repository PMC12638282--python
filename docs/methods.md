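# Methods

## Model family

The package treats FLASH normal-tissue sparing as a purely temporal,
phenomenological effect: a latent pool Q(t) ("resources" — oxygen,
scavenging capacity, any depletable substrate) is consumed in proportion to
the instantaneous dose rate and replenished toward its equilibrium Q0, and
the instantaneous relative radiosensitivity S_rel(Q) falls from 1 at
equilibrium to a floor S_min at full depletion. Spatial effects (diffusion,
non-uniform fields) are deliberately outside the model; delivery profiles
carry only Ḋ(t) at the dosimetric reference point.

Three first-order ODEs (constant-coefficient depletion/recovery ESD1,
proportional ESD2, mixed ESD3) cross three response shapes (step RRS1,
power RRS2, saturable RRS3) give nine combinations, of which ESD2+RRS1 is
excluded: ESD2's proportional depletion can never empty the pool, so a step
response pinned at S_rel = 1 predicts FMF = 1 for every profile. The
rejected pair remains constructible behind an `allow_degenerate` flag
solely so the degeneracy can be asserted.

Boundary handling follows the Heaviside convention Θ(x>0)=1, Θ(x≤0)=0 with
projected (Filippov) dynamics: on the surfaces Q=0 and Q=Q0 the state
slides while the interior field points outward. Concretely, for ESD1 under
beam-on with g·Ḋ > r the pool sticks at 0 (and S_rel = S_min for RRS1,
since Θ(0)=0); at Q=Q0 with g·Ḋ < r it stays pinned at equilibrium, which
keeps RRS_ref = 1 for slow reference irradiations. ESD3 instead settles at
the interior equilibrium Q0 − g·Ḋ/r under slow irradiation.

RRS2 is parameterized as S_min + (1−S_min)·(Q/Q0)^n (the minimal power form
satisfying both endpoints); RRS3 as the saturable form
(1+K)(m·q+K)/((m+K)(q+K)) with q = Q/Q0 and m = (1+K)/S_min − K, which is
exactly the oxygen-enhancement-ratio weighting under the parameter renaming
below.

## Numerics

Profiles are piecewise constant in dose rate, so the ODE is solved exactly:
linear pieces for ESD1 (and ESD3 with r = 0), single exponentials for
ESD2/ESD3, with analytic event times where Q reaches a boundary inserted as
breakpoints. Generic stiff integrators are avoided on purpose — the
right-hand side is discontinuous at the boundaries and at every segment
edge, and micro-pulse segments (µs pulses against minute-long pauses) span
eight orders of magnitude in time scale.

D_RRS is accumulated per piece: exactly for RRS1 (S_rel piecewise constant
along the trajectory) and for RRS2/RRS3 along linear pieces (closed-form
power/log primitives); by adaptive Gauss–Kronrod quadrature
(`scipy.integrate.quad`, epsabs 1e-13) along exponential pieces. The
isoeffect inversion for FMF exploits that F(D) = D·RRS_ref(D) is strictly
increasing with S_min·D ≤ F(D) ≤ D: the root is bracketed in
[D_RRS,test, D_RRS,test/S_min] and found by Brent's method (rtol 1e-13);
for ESD1+RRS1 the reference curve is piecewise linear and inverted in
closed form, which is the hot path of fitting. The tests cross-check the
analytic solver against an independent fixed-step clamped RK4 integrator on
the projected field (60 000 steps per segment; worst observed disagreement
|ΔQ| ~ 1e-11, |ΔD_RRS|/D ~ 5e-6) and the inversion against a grid-scan
oracle.

## Fitting and ranking

The objective is χ² = Σ(FMF_exp − FMF_pred)²/n, minimized by Nelder–Mead in
transformed coordinates — log g, log r, logit S_min, log shape — so box
constraints are implicit. Eight Latin-hypercube restarts (log-uniform over
g ∈ [0.02, 2] Gy⁻¹, r ∈ [0.01, 10] s⁻¹, S_min ∈ [0.2, 0.95],
shape ∈ [0.2, 8]) are followed by a tighter polishing run from the best
start; everything is deterministic given the seed. Q0 is fixed to 1
throughout (it is not separately identifiable from g), so the step variants
have k = 3 free parameters and the shaped variants k = 4.

Ranking uses the Gaussian-residual form BIC = n·ln(χ²) + k·ln(n). Additive
constants in the likelihood would shift BIC but not ΔBIC; this convention
reproduces the reference value −314.7 at n = 52, k = 3, RMSE 0.043 to
within the rounding of the printed RMSE. ΔBIC bands [0,2)/[2,6)/[6,10)/≥10
are labeled weak/positive/strong/very strong support for rejection.
Residual normality is assessed by Shapiro–Wilk at α = 0.05.

## NTCP layer

The dose-response curve is a two-parameter logistic
NTCP(D) = 1/(1+exp(−(D−d50)/s)) fitted by maximum likelihood on individual
binary outcomes (statsmodels logistic regression; d50 = −β0/β1, s = 1/β1).
Least squares on group fractions would also be defensible; MLE was chosen
as the standard estimator for Bernoulli data. Completely separated cohorts
have no finite ML slope; they return a flagged fit with the slope capped at
0.1 Gy and d50 mid-gap. Experimental FMFs use each test group's *raw*
responder fraction (not a smoothed value) inverted through the reference
curve, keeping only fractions strictly inside (1%, 99%) where an isoeffect
exists; per-group values from different toxicity grades are averaged with
equal weight.

## Synthetic data: what it emulates, what it does not

The default suite (n = 52) mirrors the structure of a murine acute-skin
FLASH study: doses 18–53 Gy; time-averaged dose rates 0.11–111 Gy/s;
archetypes in fractions 0.35 constant-rate (half spent on a dose-rate scan
at 39.3 Gy with log-spaced rates), 0.15 pulsed (1.8 µs pulses at 100 Hz,
pulse count setting the TADR), 0.25 spot scans (5–12 spots, 75–95% beam-on
fraction), 0.25 split schedules (39.3 Gy at 60 Gy/s sub-deliveries with
120 s pauses). The suite enforces the stated TADR range, which caps splits
at 3 parts — a 4+ way split with 2-minute pauses would fall below
0.11 Gy/s; the deeper 6-way split (TADR 0.065 Gy/s) is exercised separately
in tests. Exposure times straddle the ~1/r ≈ 3 s recovery time scale so r
is identifiable, and high-dose UHDR profiles push RRS near its floor so
S_min is identifiable.

Cohorts draw outcomes as Bernoulli(reference NTCP at D_RRS): binomial noise
only, no inter-animal frailty, no overdispersion, no grade correlation
structure, and fixture reference curves (d50 26/30 Gy, slope 1.5 Gy) chosen
to place the suite's doses on the informative range. Passing tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions — not that real skin data satisfy those
assumptions.

Desk-scale identifiability (27 groups × 25 animals, 5 seeded replicates):
the radiosensitivity floor S_min recovers to ~1–3%, the depletion
coefficient g to ~10–20%, while the recovery rate r is the least identified
quantity (median ~30%, occasional 2× excursions) because g and r enter the
constant-rate kinetics only through g·Ḋ − r and few groups sit in the
intermediate-rate regime where they decouple. Noise-free FMF-level fits
(bypassing the NTCP layer) recover all parameters to ~1e-10, confirming
that the end-to-end spread is sampling noise, not estimator bias.

## Degenerate inputs and edge conventions

Profiles must begin and end with beam-on segments (exposure is first
beam-on to last beam-off; pauses count toward TADR). Zero-duration
segments, negative rates, duty cycles ≥ 1 and mismatched spot lists are
rejected at construction. FMF observations must be positive; the synthetic
generator truncates its Gaussian noise by redrawing. χ² = 0 (perfect fit)
is floored at 1e-300 inside the BIC logarithm.

## Known limitations

- No spatial dynamics: repainted scans are represented only through their
  reference-point time structure.
- The recovery rate r is weakly constrained by dose-response data alone;
  split-dose designs with gap times near 1/r are the efficient remedy.
- BIC values (not differences) depend on the Gaussian-residual convention.
- FMF uncertainty is not propagated (no bootstrap/profile intervals).
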