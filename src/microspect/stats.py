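"""Group-level permutation statistics on the temporal-measure table.

Each measure x band x map cell is compared between groups with a two-sided
label-shuffling permutation test on the difference of group means (10,000
replications by default, add-one p-value estimator), Bonferroni-corrected
over the full family of cells, with Cohen's d effect sizes. A permutation
test on Pearson's r links the top-ranked classifier feature to symptom
severity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .core import derive_seed

__all__ = [
    "TestFamily",
    "GroupTestResult",
    "permutation_test_mean_diff",
    "cohens_d",
    "run_test_family",
    "clinical_correlation",
    "MEASURE_COLUMNS",
]

#: Measure columns of the tidy table, in canonical order.
MEASURE_COLUMNS = ("occurrence_hz", "mean_duration_ms", "coverage")

#: Effect-size sign convention used throughout: patients (group 2) minus
#: controls (group 1), so a patient deficit appears as a negative d.
D_CONVENTION = "group2 (patient) minus group1 (control)"


@dataclass
class TestFamily:
    """Multiple-comparison family: all measure x band x map cells."""

    n_tests: int | None = None  # None -> number of cells actually tested
    alpha: float = 0.05
    n_permutations: int = 10000
    seed: int = 0


@dataclass
class GroupTestResult:
    measure: str
    band: str
    map: str
    d: float
    p_uncorrected: float
    p_fwe: float
    n_permutations: int
    observed_diff: float = float("nan")
    d_convention: str = D_CONVENTION


def permutation_test_mean_diff(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Two-sided permutation test on mean(x) - mean(y).

    The p-value uses the add-one estimator (1 + hits) / (n_perm + 1), so it
    is never zero. Zero pooled variance yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    pooled = np.concatenate([x, y])
    obs = float(x.mean() - y.mean())
    if pooled.std(ddof=0) == 0:
        return obs, 1.0
    rng = np.random.default_rng(seed)
    n, n1 = pooled.size, x.size
    # permute the sorted pool: the null distribution depends only on the
    # value multiset, making the estimate invariant to input ordering
    pooled_sorted = np.sort(pooled)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm = pooled_sorted[order]
    stats = perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1)
    hits = int(np.count_nonzero(np.abs(stats) >= abs(obs) - 1e-12))
    p = (1 + hits) / (n_perm + 1)
    return obs, float(p)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d: mean difference over the (n-1)-weighted pooled SD.

    Returns NaN (flagged missing) when the pooled SD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 values")
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def run_test_family(
    features: pd.DataFrame, family: TestFamily | None = None
) -> tuple[list[GroupTestResult], pd.DataFrame]:
    """One permutation test per measure x band x map cell, Bonferroni-corrected.

    ``features`` is the tidy measures table with columns subject_id, group,
    band, map and the three measure columns. Per-cell seeds derive
    deterministically from the family seed and the cell id. Results are
    returned sorted by corrected p.
    """
    family = family or TestFamily()
    bands = list(dict.fromkeys(features["band"]))
    maps = list(dict.fromkeys(features["map"]))
    cells = list(product(MEASURE_COLUMNS, bands, maps))
    n_tests = family.n_tests if family.n_tests is not None else len(cells)

    results = []
    for i, (measure, band, map_) in enumerate(cells):
        sub = features[(features["band"] == band) & (features["map"] == map_)]
        x = sub.loc[sub["group"] == 2, measure].to_numpy()  # patients
        y = sub.loc[sub["group"] == 1, measure].to_numpy()  # controls
        if x.size < 2 or y.size < 2:
            raise ValueError(f"cell ({measure}, {band}, {map_}) lacks both groups")
        cell_seed = derive_seed(family.seed, "cell", measure, band, map_)
        obs, p = permutation_test_mean_diff(
            x, y, n_perm=family.n_permutations, seed=cell_seed
        )
        results.append(
            GroupTestResult(
                measure=measure,
                band=band,
                map=map_,
                d=cohens_d(x, y),
                p_uncorrected=p,
                p_fwe=min(1.0, p * n_tests),
                n_permutations=family.n_permutations,
                observed_diff=obs,
            )
        )
    results.sort(key=lambda r: (r.p_fwe, r.p_uncorrected))
    table = pd.DataFrame(
        {
            "measure": [r.measure for r in results],
            "band": [r.band for r in results],
            "map": [r.map for r in results],
            "d": [r.d for r in results],
            "p_uncorrected": [r.p_uncorrected for r in results],
            "p_fwe": [r.p_fwe for r in results],
            "n_permutations": [r.n_permutations for r in results],
        }
    )
    return results, table


def clinical_correlation(
    feature: np.ndarray, symptom: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Pearson correlation with a two-sided permutation p-value on |r|."""
    feature = np.asarray(feature, dtype=float)
    symptom = np.asarray(symptom, dtype=float)
    if feature.size != symptom.size or feature.size < 3:
        raise ValueError("need >= 3 paired observations")
    if feature.std(ddof=0) == 0 or symptom.std(ddof=0) == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.corrcoef(feature, symptom)[0, 1])
    rng = np.random.default_rng(seed)
    fz = (feature - feature.mean()) / feature.std(ddof=0)
    sz = (symptom - symptom.mean()) / symptom.std(ddof=0)
    n = feature.size
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_r = (sz[order] * fz).mean(axis=1)
    hits = int(np.count_nonzero(np.abs(perm_r) >= abs(r) - 1e-12))
    p = (1 + hits) / (n_perm + 1)
    return r, float(p)
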