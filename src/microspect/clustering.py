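"""Polarity-invariant topographic clustering and map-set algebra.

Microstate prototypes are extracted from GFP-peak topographies with a
modified (polarity-invariant) k-means: similarity is the absolute spatial
correlation, and each cluster's prototype is the dominant eigenvector of the
outer-product sum of its assigned topographies. Restarts are ranked by
global explained variance (GEV). Map sets from different subjects or groups
are compared after an optimal one-to-one alignment (permutation plus sign
flips), which also underlies multi-level averaging, reliability-based
selection of the number of maps, and the group map-equivalence check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .templates import CANONICAL_LABELS, make_canonical_templates

__all__ = [
    "MicrostateMapSet",
    "ClusterConfig",
    "spatial_correlation",
    "modified_kmeans",
    "align_map_sets",
    "apply_alignment",
    "average_map_sets",
    "select_k_by_reliability",
    "check_group_equivalence",
    "canonicalize_labels",
]

logger = logging.getLogger(__name__)


@dataclass
class MicrostateMapSet:
    """An ordered set of average-referenced, unit-norm topographies.

    ``level`` records the averaging level (subject, group, or grand) and
    ``gev`` the global explained variance achieved when the set was fitted
    (NaN for derived/averaged sets).
    """

    maps: np.ndarray  # k x channels
    labels: list[str]
    channel_labels: list[str]
    level: str = "subject"
    band: str = "broadband"
    gev: float = float("nan")

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if len(self.labels) != self.k:
            raise ValueError("one label per map required")
        if len(set(self.labels)) != self.k:
            raise ValueError("map labels must be unique")
        if len(self.channel_labels) != self.maps.shape[1]:
            raise ValueError("channel_labels length mismatch")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def normalized(self) -> "MicrostateMapSet":
        """Re-average-reference and re-normalize every map."""
        m = self.maps - self.maps.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(m, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return replace(self, maps=m / norms)


@dataclass
class ClusterConfig:
    k_range: tuple[int, ...] = (4, 5, 6, 7)
    n_repetitions: int = 100
    max_gfp_peaks: int = 1000
    polarity_invariant: bool = True
    convergence_tol: float = 1e-6
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        self.k_range = tuple(int(k) for k in self.k_range)
        if not self.k_range:
            raise ValueError("k_range must be nonempty")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


def _demean(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v - v.mean(axis=-1, keepdims=True)


def spatial_correlation(a, b, polarity_invariant: bool = True) -> float:
    """Pearson correlation across channels of two average-referenced maps.

    Absolute value when ``polarity_invariant``. A zero-variance topography
    yields correlation 0 (with a warning) rather than NaN.
    """
    a, b = _demean(a), _demean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("zero-variance topography; correlation defined as 0")
        return 0.0
    r = float(a @ b / (na * nb))
    r = float(np.clip(r, -1.0, 1.0))
    return abs(r) if polarity_invariant else r


def _normalize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean rows and scale to unit norm; zero rows stay zero."""
    X = _demean(X)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    return X / safe[:, None], norms


def corr_matrix(X: np.ndarray, M: np.ndarray, polarity_invariant: bool = True) -> np.ndarray:
    """Spatial correlations between rows of X (samples) and rows of M (maps)."""
    Xn, _ = _normalize_rows(X)
    Mn, _ = _normalize_rows(M)
    C = np.clip(Xn @ Mn.T, -1.0, 1.0)
    return np.abs(C) if polarity_invariant else C


def _principal_map(X: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of X^T X, average-referenced and unit-norm.

    This is the polarity-invariant cluster prototype: the direction
    maximizing the summed squared (signed) projections of the assigned maps.
    """
    S = X.T @ X
    _, vecs = np.linalg.eigh(S)
    m = vecs[:, -1]
    m = m - m.mean()
    m /= np.linalg.norm(m)
    # deterministic sign: largest-magnitude element positive
    if m[np.argmax(np.abs(m))] < 0:
        m = -m
    return m


def _gev(gfp2: np.ndarray, best_corr: np.ndarray) -> float:
    """Global explained variance: GFP^2-weighted mean squared correlation."""
    return float((gfp2 * best_corr**2).sum() / gfp2.sum())


def modified_kmeans(
    peak_maps: np.ndarray, k: int, cfg: ClusterConfig | None = None
) -> MicrostateMapSet:
    """Polarity-invariant k-means on (GFP-peak) topographies.

    Assignment labels each topography with the cluster of maximal absolute
    spatial correlation; the update replaces each prototype with the dominant
    eigenvector of its assigned topographies' outer-product sum. The best of
    ``cfg.n_repetitions`` random restarts by GEV is returned.

    ``peak_maps`` is an (n_peaks, n_channels) array of raw (unnormalized)
    topographies; they are average-referenced internally.
    """
    cfg = cfg or ClusterConfig()
    X = _demean(np.asarray(peak_maps, dtype=float))
    nonzero = np.linalg.norm(X, axis=1) > 0
    X = X[nonzero]
    n, n_ch = X.shape
    if n < k:
        raise ValueError(f"need at least k={k} peak maps, got {n}")
    Xn, norms = _normalize_rows(X)
    if np.unique(np.round(Xn, 12), axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct topographies")
    gfp2 = (X**2).mean(axis=1)  # squared GFP per peak

    rng = np.random.default_rng(cfg.seed)
    best = None
    for _ in range(cfg.n_repetitions):
        maps = Xn[rng.choice(n, size=k, replace=False)].copy()
        prev_gev = -np.inf
        for _ in range(cfg.max_iter):
            C = Xn @ maps.T
            if cfg.polarity_invariant:
                C = np.abs(C)
            assign = C.argmax(axis=1)
            best_corr = C[np.arange(n), assign]
            # re-seed empty clusters from the worst-fit peak
            for j in range(k):
                if not (assign == j).any():
                    worst = int(np.argmin(best_corr))
                    assign[worst] = j
                    best_corr[worst] = 1.0
            gev = _gev(gfp2, np.abs(Xn @ maps.T).max(axis=1))
            for j in range(k):
                members = X[assign == j]
                if cfg.polarity_invariant:
                    maps[j] = _principal_map(members)
                else:
                    m = _demean(members.mean(axis=0))
                    maps[j] = m / np.linalg.norm(m)
            if prev_gev > -np.inf and abs(gev - prev_gev) <= cfg.convergence_tol * max(
                abs(prev_gev), 1e-12
            ):
                break
            prev_gev = gev
        final_gev = _gev(gfp2, np.abs(Xn @ maps.T).max(axis=1))
        if best is None or final_gev > best[0]:
            best = (final_gev, maps.copy())

    gev, maps = best
    labels = [f"M{i + 1}" for i in range(k)]
    return MicrostateMapSet(
        maps=maps,
        labels=labels,
        channel_labels=[f"ch{i}" for i in range(n_ch)],
        level="subject",
        gev=gev,
    )


def align_map_sets(
    target: MicrostateMapSet, reference: MicrostateMapSet
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal one-to-one matching of ``target`` maps onto ``reference`` maps.

    Solves the assignment problem maximizing the mean absolute spatial
    correlation over all pairings. Returns ``(perm, signs, mean_corr)`` such
    that ``signs[j] * target.maps[perm[j]]`` matches ``reference.maps[j]``
    with positive signed correlation.
    """
    if target.k != reference.k:
        raise ValueError("map sets must have equal k")
    C = corr_matrix(reference.maps, target.maps, polarity_invariant=False)
    ref_idx, tgt_idx = linear_sum_assignment(-np.abs(C))
    perm = np.empty(reference.k, dtype=int)
    perm[ref_idx] = tgt_idx
    signed = C[np.arange(reference.k), perm]
    signs = np.where(signed < 0, -1.0, 1.0)
    mean_corr = float(np.abs(signed).mean())
    return perm, signs, mean_corr


def apply_alignment(
    target: MicrostateMapSet, reference: MicrostateMapSet
) -> MicrostateMapSet:
    """Reorder and sign-flip ``target`` to match ``reference`` label-for-label."""
    perm, signs, _ = align_map_sets(target, reference)
    return replace(
        target,
        maps=target.maps[perm] * signs[:, None],
        labels=list(reference.labels),
    )


_LEVEL_UP = {"subject": "group", "group": "grand", "grand": "grand"}


def average_map_sets(
    sets: list[MicrostateMapSet],
    reference: MicrostateMapSet | None = None,
    level: str | None = None,
) -> MicrostateMapSet:
    """Align each set to a reference, then average element-wise per label.

    The result is re-average-referenced and re-normalized and its level
    promoted (subject -> group -> grand). Input sets aligning to the
    reference with mean |correlation| < 0.5 are flagged with a warning.
    """
    if not sets:
        raise ValueError("no map sets to average")
    reference = reference or sets[0]
    stack = []
    for s in sets:
        perm, signs, mc = align_map_sets(s, reference)
        if mc < 0.5:
            logger.warning("map set %s aligns poorly to reference (mean |r|=%.2f)", s.level, mc)
        stack.append(s.maps[perm] * signs[:, None])
    mean_maps = np.mean(stack, axis=0)
    out = MicrostateMapSet(
        maps=mean_maps,
        labels=list(reference.labels),
        channel_labels=list(reference.channel_labels),
        level=level or _LEVEL_UP.get(sets[0].level, "group"),
        band=reference.band,
    )
    return out.normalized()


def select_k_by_reliability(
    subject_map_sets: dict[int, list[MicrostateMapSet]],
    group_mean_sets: dict[int, MicrostateMapSet],
) -> tuple[int, pd.DataFrame]:
    """Choose the number of maps by subject-to-group map reliability.

    For each candidate k, reliability is the mean over subjects and maps of
    the absolute spatial correlation between each (aligned) subject map and
    its matched group-mean map. Returns the k with maximal reliability (ties
    broken toward smaller k) and the full reliability table.
    """
    ks = sorted(subject_map_sets)
    if sorted(group_mean_sets) != ks:
        raise ValueError("subject and group map sets cover different k ranges")
    rows = []
    for k in ks:
        ref = group_mean_sets[k]
        per_subject = []
        for s in subject_map_sets[k]:
            aligned = apply_alignment(s, ref)
            matched = corr_matrix(aligned.maps, ref.maps)
            per_subject.append(float(np.diag(matched).mean()))
        rows.append({"k": k, "reliability": float(np.mean(per_subject))})
    table = pd.DataFrame(rows)
    best_row = table.loc[table["reliability"].idxmax()]  # idxmax: first max -> smallest k
    chosen = int(best_row["k"])
    logger.info("selected k=%d (reliability %.4f)", chosen, best_row["reliability"])
    return chosen, table


def check_group_equivalence(
    gA: MicrostateMapSet, gB: MicrostateMapSet, cutoff: float = 0.95
) -> tuple[np.ndarray, bool]:
    """Spatial-equivalence check between two group map sets.

    ``gB`` is aligned to ``gA``; the full k x k absolute-correlation matrix
    is returned along with a pass flag that requires every matched (diagonal)
    correlation to reach ``cutoff``.
    """
    aligned = apply_alignment(gB, gA)
    C = corr_matrix(gA.maps, aligned.maps)
    passed = bool(np.all(np.diag(C) >= cutoff))
    return C, passed


def canonicalize_labels(
    map_set: MicrostateMapSet, templates: np.ndarray | None = None
) -> MicrostateMapSet:
    """Relabel a 5-map set A-E by best match to the canonical template library."""
    if map_set.k != len(CANONICAL_LABELS):
        return map_set
    if templates is None:
        templates = make_canonical_templates(
            len(map_set.channel_labels), list(map_set.channel_labels)
        )
    ref = MicrostateMapSet(
        maps=templates,
        labels=list(CANONICAL_LABELS),
        channel_labels=list(map_set.channel_labels),
        level=map_set.level,
        band=map_set.band,
    )
    out = apply_alignment(map_set, ref)
    out.gev = map_set.gev
    return out
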