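"""Assign independent components to populations by exhaustive search.

Given K rank-1 component maps and reference CSD maps of P populations, the
search considers every distribution of components into population groups
(each component used by at most one population, possibly by none) with
signed coefficients beta in {-1, 0, +1}, and scores each population by the
Pearson correlation, over all (space, time) entries, between its signed
component sum and its reference map:

    m_i = r( sum_k beta_ik A_k , C_i ).

Signed coefficients are the default because ICA components carry arbitrary
sign; a {0, 1}-only mode is available for sensitivity analysis.  Across
populations the assignment maximizes the score vector lexicographically in
order of decreasing reference signal power (strongest population first),
with ties broken toward assignments using fewer components; a population
left with no components scores 0 (the zero-signal convention).

The search is exact: all (2P+1)^K signed assignments are evaluated (via
precomputed Gram matrices, in chunks), which is why K is capped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .decompose import ICAResult, components_to_maps, pca_truncate
from .kcsd import CSDEstimate

__all__ = [
    "Assignment",
    "correlation_similarity",
    "assign_components",
    "population_pca_match",
]

#: hard cap on the exhaustive search (spec of the method, not a tunable)
MAX_COMPONENTS = 12
#: soft cap on the number of enumerated assignments
MAX_STATES = 20_000_000


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, CSDEstimate):
        return x.values
    return np.asarray(x, dtype=float)


def correlation_similarity(a, b) -> float:
    """Pearson correlation of two spatiotemporal maps flattened over
    (space x time).  Raises on constant input (undefined correlation)."""
    am = _as_matrix(a)
    bm = _as_matrix(b)
    if am.shape != bm.shape:
        raise ValueError(f"shape mismatch: {am.shape} vs {bm.shape}")
    av = am.ravel()
    bv = bm.ravel()
    ac = av - av.mean()
    bc = bv - bv.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined for a constant map")
    return float(ac @ bc / (na * nb))


@dataclass
class Assignment:
    """Result of the component-to-population search.

    ``coefficients`` is (P x K) with entries in {-1, 0, +1}; each column has
    at most one nonzero entry (a component serves at most one population).
    ``scores`` holds the per-population correlations m_i in input
    (reference) order; 0 means no components were assigned.
    """

    coefficients: np.ndarray
    scores: np.ndarray
    population_order: np.ndarray

    def components_of(self, i: int) -> np.ndarray:
        """Indices of the components assigned to population ``i``."""
        return np.flatnonzero(self.coefficients[i])

    @property
    def n_used(self) -> int:
        return int((self.coefficients != 0).any(axis=0).sum())


def _gram_terms(maps: np.ndarray, references: list[np.ndarray]):
    """Centered Gram matrix of the maps and cross-terms with references."""
    K = maps.shape[0]
    flat = maps.reshape(K, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    G = flat @ flat.T
    a = np.empty((len(references), K))
    ref_norms = np.empty(len(references))
    for i, ref in enumerate(references):
        rc = ref.ravel() - ref.mean()
        n = np.linalg.norm(rc)
        if n == 0:
            raise ValueError(f"reference {i} is constant; correlation undefined")
        ref_norms[i] = n
        a[i] = flat @ rc
    return G, a, ref_norms


def assign_components(
    maps,
    references,
    beta_domain: str = "signed",
    score_tol: float = 1e-3,
    return_all: bool = False,
) -> Assignment:
    """Exhaustively match component maps to population references.

    Parameters
    ----------
    maps : (K, n_grid, n_times) array or list of 2D maps or ICAResult
    references : list of CSDEstimate or 2D arrays, one per population
    beta_domain : {"signed", "binary"}
        Coefficient domain {-1, 0, +1} (default) or {0, 1}.
    score_tol : float
        Resolution at which per-population scores are compared in the
        lexicographic search; differences below it count as ties, which are
        broken toward fewer components.  0 compares exact floats.

    Raises
    ------
    ValueError
        If K exceeds the exhaustive-search cap; use fewer components or a
        greedy heuristic outside this function.
    """
    if isinstance(maps, ICAResult):
        maps = components_to_maps(maps)
    maps = np.asarray([_as_matrix(m) for m in maps], dtype=float)
    refs = [_as_matrix(r) for r in references]
    K = maps.shape[0]
    P = len(refs)
    if P == 0:
        raise ValueError("need at least one reference population")
    for r in refs:
        if r.shape != maps.shape[1:]:
            raise ValueError("reference shape differs from component map shape")
    if beta_domain not in ("signed", "binary"):
        raise ValueError("beta_domain must be 'signed' or 'binary'")
    n_labels = 2 * P + 1 if beta_domain == "signed" else P + 1
    n_states = n_labels**K
    if K > MAX_COMPONENTS or n_states > MAX_STATES:
        raise ValueError(
            f"exhaustive search over {n_states} assignments (K={K}, P={P}) "
            f"exceeds the combinatorial limit; reduce K or fall back to a "
            f"greedy assignment"
        )

    G, a, ref_norms = _gram_terms(maps, refs)
    power_order = np.argsort(-(ref_norms**2), kind="stable")

    # enumerate label vectors: 0 = unused, 1..P = +pop, P+1..2P = -pop
    labels = np.array(
        list(itertools.product(range(n_labels), repeat=K)), dtype=np.int8
    )  # (n_states, K)
    scores = np.empty((n_states, P))
    chunk = 1_000_000
    for lo in range(0, n_states, chunk):
        block = labels[lo : lo + chunk]
        for p in range(P):
            beta = (block == p + 1).astype(np.float64)
            if beta_domain == "signed":
                beta -= block == P + 1 + p
            num = beta @ a[p]
            den = np.sqrt(np.einsum("nk,kl,nl->n", beta, G, beta)) * ref_norms[p]
            with np.errstate(invalid="ignore", divide="ignore"):
                m = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
            scores[lo : lo + chunk, p] = m
    n_used = (labels != 0).sum(axis=1)

    # lexicographic: strongest population's score first, then next, ...,
    # then fewer components.  Scores are compared at resolution score_tol
    # so that the fewer-components tie-break has teeth: without it a strong
    # population absorbs components that improve its correlation only in
    # the 4th decimal.  np.lexsort keys are last-significant-first.
    if score_tol > 0:
        q = np.floor(scores / score_tol)
    else:
        q = scores
    keys = [n_used] + [-q[:, p] for p in power_order[::-1]]
    best = np.lexsort(keys)[0]

    coefficients = np.zeros((P, K), dtype=int)
    lab = labels[best]
    for p in range(P):
        coefficients[p][lab == p + 1] = 1
        if beta_domain == "signed":
            coefficients[p][lab == P + 1 + p] = -1
    assignment = Assignment(
        coefficients=coefficients,
        scores=scores[best].copy(),
        population_order=power_order,
    )
    if return_all:
        return assignment, labels, scores
    return assignment


def population_pca_match(
    matched_maps,
    reference,
    n_pcs: int | None = None,
) -> dict:
    """Relate a population's matched components to its principal components.

    Computes the PCA of the reference population's CSD, forms the rank-1
    map of each retained principal component, and reports the absolute
    Pearson correlation between every matched component map and every PC
    map, together with a greedy one-to-one matching (largest correlation
    first).

    Returns a dict with ``correlations`` (n_components x n_pcs), ``pairs``
    (list of (component index, pc index, |r|)) and ``explained`` (PC
    singular values).
    """
    matched_maps = np.asarray([_as_matrix(m) for m in matched_maps], dtype=float)
    ref = _as_matrix(reference)
    n_comp = matched_maps.shape[0]
    if n_pcs is None:
        n_pcs = max(n_comp, 1)
    pca = pca_truncate(ref, n_pcs)
    pc_maps = pca.singular_values[:, None, None] * (
        pca.eigenimages.T[:, :, None] * pca.eigensequences[:, None, :]
    )
    corr = np.empty((n_comp, n_pcs))
    for i in range(n_comp):
        for j in range(n_pcs):
            corr[i, j] = abs(correlation_similarity(matched_maps[i], pc_maps[j]))
    pairs = []
    c = corr.copy()
    for _ in range(min(n_comp, n_pcs)):
        i, j = np.unravel_index(np.argmax(c), c.shape)
        pairs.append((int(i), int(j), float(corr[i, j])))
        c[i, :] = -np.inf
        c[:, j] = -np.inf
    return {
        "correlations": corr,
        "pairs": pairs,
        "explained": pca.singular_values,
    }
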