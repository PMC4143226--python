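# laminarpop

Recovery of individual neural-population activity from laminar local field
potential (LFP) recordings, with a synthetic ground-truth generator for
validating the whole analysis chain.

## The problem

The LFP recorded along a laminar probe is a superposition of transmembrane
currents from several cortical cell populations, blurred by volume
conduction over millimeters. Current source density (CSD) analysis
sharpens the picture spatially, but the reconstructed CSD is still a sum
over populations. This package implements the full chain that attempts to
undo that sum:

1. **Forward model** — point/line current sources in a homogeneous
   resistive medium, `V(r) = (1/4πσ) Σⱼ Iⱼ/|r−xⱼ|`, low-pass filtered
   (2nd-order Butterworth, zero-phase, 500 Hz) to the LFP band.
2. **Kernel CSD (kCSD)** — the 1D nonparametric inverse: sources are
   modeled as combinations of basis profiles constant on discs of radius
   *R*; with kernel `K` at contact pairs and cross-kernel `K̃` at
   (grid, contact) pairs, the ridge estimate is
   `C* = K̃ (K + λI)⁻¹ V`, with λ chosen by leave-one-contact-out
   cross-validation.
3. **PCA + ICA** — truncated SVD `X_K = U_K Γ_K V_K` followed by infomax
   ICA over the retained subspace: spatial ICA (heavy-tailed source model
   for sparse laminar profiles), temporal ICA (sub-Gaussian model), or
   spatiotemporal ICA maximizing `α·h(S) + (1−α)·h(T)`.
4. **Grouping** — exhaustive search over all signed assignments
   `βᵢₖ ∈ {−1, 0, +1}` (each component serving at most one population)
   maximizing the per-population Pearson correlations
   `mᵢ = r(Σₖ βᵢₖ Aₖ, C̃ᵢ)` lexicographically by reference power, plus a
   comparison of matched components with the principal components of each
   population's own activity.

Because ground truth is unobtainable in experiments, the package ships a
**synthetic generator**: layered cylindrical column, populations as point
source clouds whose currents are exact rank-1 or rank-2 sums of dipolar
spatial weight vectors times temporal activation courses, per-population
current conservation to machine precision, calibrated white measurement
noise, and seeded reproducibility. Intended users are electrophysiologists
and methods developers who want to know *when* this kind of decomposition
can be trusted.

## Worked example

```python
from laminarpop import (
    default_scenario, synthesize_dataset, recover_populations,
    population_pca_match,
)

scenario = default_scenario()          # 3 populations, 26 contacts, 50 um
dataset = synthesize_dataset(scenario, seed=1)
assignment, info = recover_populations(dataset, k=5, ica_seed=0)
print(info["scores"])
# {'pyr23': 0.99998, 'pyr5': 0.99921, 'pyr6': 0.99462}

i = info["names"].index("pyr23")
comps = assignment.components_of(i)     # -> array([0, 2]); exactly 2
match = population_pca_match(info["maps"][comps],
                             info["references"]["pyr23"], n_pcs=2)
print([round(r, 3) for _, _, r in match["pairs"]])
# [0.984, 0.963]
```

Reading: the two strong pyramidal-like populations (layer 2/3, layer 5)
are recovered with correlations ≥ 0.99 against their own kCSD-represented
activity, the weak layer-6 population is recoverable in the noise-free
case, the rank-2 layer-2/3 population needs exactly two independent
components, and those two components line up with the top two principal
components of that population's activity (|ρ| ≈ 0.96–0.98) — independent
components of the total signal recover principal components of individual
population activity, not whole populations.

The same pipeline is scriptable from the shell (`laminarpop simulate`,
`reconstruct`, `decompose`, `group`, `experiment`; see `--help`).

## Robustness experiments

`laminarpop.experiments` provides seeded sweeps over noise level (% of the
pooled LFP standard deviation), electrode count (regular subsampling
spanning the largest extent), vertical population shifts, and the assumed
number of ICA components, each with per-repetition noise and ICA seeds and
tidy DataFrame output.

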