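# Methods

This note documents the models, numerical choices, and design decisions
behind `laminarpop`, and what the synthetic validation does and does not
establish about real recordings.

## Forward model

Extracellular potential in a uniform, homogeneous, purely resistive medium
of conductivity σ:

    V(r, t) = (1 / 4πσ) Σⱼ Iⱼ(t) / |r − xⱼ|

for point sources, and the standard closed-form line-source expression
(integral of 1/distance along a segment, expressed through `asinh`) for
uniform line segments. Unit system: µm, nA, S/m, ms — with these, the
formula yields mV with no conversion constants. The point formula is the
default engine; the line formula exists to confirm (in the tests) that the
difference is negligible at the distances of interest. Potentials are
low-pass filtered to LFP with a second-order Butterworth filter at 500 Hz,
applied forward-backward (`sosfiltfilt`): zero phase, DC gain 1, squared
amplitude response (gain 0.5 at the cutoff). Published uses of such
filters rarely state a phase convention; zero-phase is the package's
choice so that filtering never shifts component timing.

Degenerate geometry (a source on a contact, a contact on a segment) raises
instead of returning divergent numbers.

**Coarse-grained CSD.** The physically meaningful density of a discrete
source cloud is its Gaussian running average; `coarse_grain_csd` uses a
normalized 1D kernel with σ = 80 µm by default, so the depth integral of
the map equals the total current.

## Kernel CSD

One-dimensional kCSD with sources assumed constant on discs of radius
R orthogonal to the probe axis. A basis of M profiles b̃ᵢ (Gaussian by
default; step available) covers the estimation span; each maps forward to

    bᵢ(x) = ∫ b̃ᵢ(z) · (√((x−z)² + R²) − |x−z|) / 2σ · dz,

evaluated by adaptive quadrature (scipy `quad`, interval split at the
|x−z| kink, tolerance 1e-8 of the peak basis potential; an independent
Monte Carlo evaluation of the disc integral agrees to < 0.5% in the
tests). With K = ΦΦᵀ at contact pairs and K̃ = B̃Φᵀ at (grid, contact)
pairs, the estimate is `C* = K̃ (K + λ·κ·I)⁻¹ V` columnwise over time.

Numerical choices:

- **λ is dimensionless**: the identity is scaled by κ = mean(diag K), so
  the same λ means the same relative regularization for any geometry or
  unit choice. Raw kernel entries here are ~10⁹–10¹⁰ in package units; an
  absolute λ would be meaningless across configurations.
- **λ selection**: leave-one-contact-out cross-validation over a candidate
  grid (default 10⁻¹²…10⁰), ties toward the smaller candidate, selected
  once per dataset. The method's own literature names ridge regression but
  no selection rule.
- **Defaults**: M = 3 × contacts, Gaussian width = contact pitch,
  R = 150 µm, estimation grid 100 points over 0–2700 µm. None of these are
  published values; all are configuration with documented defaults, and
  the tests check the reconstruction is stable under doubling M.
- Sign convention: positive CSD = source, negative = sink.

The traditional estimator (−σ times the second central difference over
uniformly spaced contacts, interior contacts only) is provided for
comparison.

## PCA and ICA

`pca_truncate` is a thin, sign-normalized truncated SVD (largest-|entry|
of each eigenimage made positive). All three ICA flavors are one
maximum-likelihood (infomax) objective over the unmixing matrix W acting
on the K retained eigenimages, with

    S = W U_Kᵀ            (candidate spatial profiles)
    T = W⁻ᵀ Γ_K V_K       (dual time courses; S ᵀT = X_K for any invertible W)

    f(W) = α [E log p_s(S) + log|det W|] + (1−α) [E log p_t(T) − log|det W|]

- spatial ICA: α = 1, heavy-tailed source model `p_s ∝ 1/cosh` (tanh
  score) — laminar CSD profiles are sparse over depth;
- temporal ICA: α = 0, sub-Gaussian model `p_t ∝ exp(−t⁴/4)` (cubic
  score) — appropriate for oscillatory courses;
- spatiotemporal ICA: intermediate α; the diagonal scaling trade-off
  between the two sides (the usual stICA Λ) is absorbed by the
  unconstrained W.

Because spatial and temporal ICA are literally the α = 1 and α = 0 cases
of the same objective, the degeneracy properties hold exactly by
construction. The objective is maximized by L-BFGS with an analytic
gradient (verified against finite differences in development), 5 restarts
from random orthogonal initializations (best objective kept), convergence
by the optimizer's gradient/function tolerances within a 10⁴-iteration
cap; failure of all restarts raises with diagnostics. Results are
bit-reproducible given (input, K, α, seed). sklearn's FastICA is wired in
as an independent cross-check backend (`solver="fastica"`) and is compared
against the infomax path in the tests; it is never the primary
implementation.

**Rank guard.** The rotation search is restricted to eigen-directions with
singular value ≥ 10⁻⁸ × the largest. Whitening gives every direction unit
variance, so on effectively rank-deficient input (e.g. noise-free data
with K above the true rank) the trailing directions are pure numerical
noise; left unrestricted, the optimizer rotates them *into* the real
components. Restricted directions pass through un-rotated, with a warning,
and carry negligible map energy.

Components are ordered by the variance of their rank-1 map and
sign-normalized (largest-|entry| of the spatial profile positive).

## Grouping

`assign_components` enumerates every assignment of K components into
(unused | +population | −population) — (2P+1)^K states — scoring each
population by the Pearson correlation between its signed component sum and
its reference map, computed from precomputed centered Gram matrices so
each state costs O(K²). Signed coefficients are the default because ICA
components carry arbitrary sign; a {0, 1} mode exists for sensitivity
analysis. Across populations the score vector is maximized
lexicographically in order of decreasing reference power, **compared at a
resolution of 10⁻³** (`score_tol`), with ties broken toward fewer
components. The resolution is essential: with exact-float comparison the
strongest population absorbs every component that improves its correlation
in the fourth decimal, starving weaker populations; at 10⁻³ a component
must earn its place. A population left with no components scores 0 (the
zero-signal convention). K is capped at 12 and the state count at 2×10⁷;
beyond that the function raises and suggests a greedy fallback rather than
silently approximating.

References are the kCSD reconstructions of each population's own LFP —
the representation an experimenter could in principle validate against —
not the raw ground-truth currents. Because kCSD is linear, the total
reconstruction contains each population's reference additively, which is
what makes the comparison well-posed.

`population_pca_match` relates matched components to the principal
components of one population's reference by greedy one-to-one matching of
absolute map correlations.

## Synthetic ground truth

Each population is a cloud of point sources, uniform in its depth range
within a 200-µm-radius cylinder (excluding a 30-µm cylinder around the
probe axis — the shank displaces tissue, and a source micrometers from a
contact would dominate the recording). Its currents are an exact rank-1 or
rank-2 sum Σₖ λₖ wₖ ⊗ bₖ(t): unit-norm, exactly zero-sum spatial weights
(current conservation at every sample) and unit-RMS time courses
(orthogonal pair for rank 2). Temporal classes: damped burst following a
stimulus at 20 ms (90 ms at dt = 0.1 ms → 900 samples) or ramped sinusoid
(500 ms → 5000 samples); populations share a common drive waveform at
weight 0.3 with per-population lags, so their courses are correlated, not
independent — mirroring real cortical coupling.

Spatial design, and why it looks the way it does:

- **Narrow lobes** (σ = extent/10): laminar sinks/sources are thin sheets
  relative to their separation, and the sparseness of the resulting kCSD
  images is exactly the property spatial ICA exploits. With broad lobes
  the images are too Gaussian and the unmixing rotation is only weakly
  identified.
- **Rank-2 population = two interleaved dipoles** (lobes at 5/35/65/95% of
  its depth range): two synaptic pathways targeting staggered dendritic
  subdomains. Interleaving keeps the two patterns spatially disjoint; for
  disjoint images the true rotation is a stationary point of the infomax
  objective, whereas nested or trilobe layouts allow lobe cancellations
  that bias the recovered rotation by 15–25°.
- **Default scenario**: layer-2/3 pyramids (sources 450–950 µm — deep L3
  dendrites reach upper L4 — rank 2, amplitude 1, second term 0.7),
  layer-5 pyramids (1150–1650 µm, rank 1, amplitude 1), and a weak deep
  population (1550–1950 µm, rank 1, amplitude 0.3) whose source range
  represents the proximal apical dendrites of layer-6 cells — placing it
  within reach of the probe, without which no analysis could see it.
  400 sources per population keep the realized patterns stable across
  placement seeds.
- **Probe**: 26 contacts at 50 µm pitch with the top contact at 450 µm
  (span 450–1700 µm). The contact count and pitch are fixed by the
  experimental setting being emulated; the absolute placement is chosen so
  the array covers the main dipole lobes of all three populations.

Noise is i.i.d. Gaussian per electrode and sample with standard deviation
set as a percentage of the pooled (all contacts, all times) standard
deviation of the clean total LFP; per-population ground truth stays clean.
Population shifts translate sources without changing currents. Electrode
subsampling uses the arithmetic stride (N−1)//(n−1) from the first
contact — for n = 2 the two extremes, for 13 of 26 every second contact.

**What the generator does not emulate**: spiking, synaptic kinetics,
dendritic morphology, cross-frequency structure, inhomogeneous or
anisotropic tissue, neighboring-column contamination, electrode drift. A
green test suite therefore shows that the chain recovers low-rank dipolar
population structure under calibrated noise — the structure the method
assumes — not that any particular real dataset satisfies those
assumptions.

## Experiments

Sweeps over noise level, electrode count, vertical shift of one
population, and the ICA order K, with 10 repetitions by default
(configurable), noise re-drawn and the ICA seed advanced per repetition,
and λ re-selected by CV once per dataset. Every result row carries the
seeds that produced it; identical inputs give byte-identical outputs. In
the electrode sweep the kCSD basis (width and M) is held at the full-array
configuration for every count: letting the basis coarsen with the
subsampled pitch changes the inverse model along with the measurements and
can *help* weaker populations (smoother reference, smoother estimate),
confounding what the sweep is meant to isolate.

The acceptance experiments run the noise sweep at 0/25/50/100% and the
electrode sweep at 26/13/8 contacts under 25% noise — a level at which
electrode count has a measurable effect; at low noise all counts saturate
near-perfect recovery. Problem sizes (900 time samples, 100 grid points,
10 repetitions, 5 in the acceptance script) are the package's default
desk-scale configuration.

## Known limitations

- The infomax rotation on smooth, partially overlapping spatial images
  carries a residual bias of a few degrees even for well-separated
  sources; recovered component/PC correlations saturate around 0.95–0.99,
  not 1.0.
- The weak population's recovery is fragile by construction: it fails
  first under noise (typically between 0 and 25%) and is not recovered at
  all for some source-placement realizations, consistent with the
  experimental expectation that only two to three populations are
  accessible.
- Exhaustive grouping is exponential in the number of components; K ≤ 8
  is practical, K > 12 refused.
- The aggregate objective across populations (lexicographic by reference
  power) and the signed coefficient domain are package decisions where the
  method's description is ambiguous; both are parameterized.
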