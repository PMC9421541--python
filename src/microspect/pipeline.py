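"""End-to-end orchestration: simulate/load -> maps -> measures -> stats -> models.

Mirrors the two experiments the analysis design defines: (1) group
permutation statistics over all measure x band x map cells, and (2) the
comparison of frequency-specific and map-specific SVM models. All stage
seeds derive deterministically from the global seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backfit import band_pipeline
from .classify import assemble_features, compare_models, evaluate_model
from .clustering import (
    ClusterConfig,
    MicrostateMapSet,
    average_map_sets,
    canonicalize_labels,
    check_group_equivalence,
    modified_kmeans,
    select_k_by_reliability,
)
from .core import DEFAULT_BANDS, EEGRecording, derive_seed
from .io import (
    map_set_to_json,
    measures_to_tidy,
    read_csv_recording,
    read_edf,
    read_sidecar,
)
from .signal import average_reference, bandpass, extract_gfp_peaks
from .simulate import SyntheticConfig, simulate_cohort
from .stats import TestFamily, run_test_family

__all__ = [
    "PipelineConfig",
    "run_full",
    "load_recordings",
    "fit_grand_maps",
    "simulate_measures",
]

logger = logging.getLogger(__name__)


@dataclass
class BackfitParams:
    threshold: float = 0.50
    window: int = 7
    factor: float = 10.0
    min_samples: int = 3


@dataclass
class PipelineConfig:
    """Full pipeline configuration; defaults equal the reference analysis."""

    simulate: SyntheticConfig | None = None
    input_dir: str | None = None
    input_format: str = "csv"
    bands: tuple[str, ...] = ("broadband", "delta", "theta", "alpha", "beta")
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    backfit: BackfitParams = field(default_factory=BackfitParams)
    stats: TestFamily = field(default_factory=TestFamily)
    classify_k_range: tuple[int, ...] = tuple(range(1, 16))
    classify_n_runs: int = 10
    classify_n_folds: int = 10
    output_dir: str = "microspect_out"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["simulate"] is not None:
            d["simulate"]["templates"] = np.asarray(d["simulate"]["templates"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            sim = dict(d["simulate"])
            if sim.get("templates") is not None:
                sim["templates"] = np.asarray(sim["templates"], dtype=float)
            if sim.get("carrier_bands") is not None:
                sim["carrier_bands"] = [tuple(b) for b in sim["carrier_bands"]]
            if sim.get("background_band") is not None:
                sim["background_band"] = tuple(sim["background_band"])
            d["simulate"] = SyntheticConfig(**sim)
        if isinstance(d.get("cluster"), dict):
            d["cluster"] = ClusterConfig(**d["cluster"])
        if isinstance(d.get("backfit"), dict):
            d["backfit"] = BackfitParams(**d["backfit"])
        if isinstance(d.get("stats"), dict):
            d["stats"] = TestFamily(**d["stats"])
        for key in ("bands", "classify_k_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


def load_recordings(path: str | Path, format: str = "csv") -> list[EEGRecording]:
    """Load all recordings from a directory (CSV or EDF plus JSON sidecars)."""
    path = Path(path)
    ext = {"csv": "*.csv", "edf": "*.edf"}[format]
    recs = []
    for f in sorted(path.glob(ext)):
        sidecar = f.with_suffix(".json")
        meta = read_sidecar(sidecar) if sidecar.exists() else {}
        group = meta.get("group")
        if group is None and "_g" in f.stem:  # filename convention: subj_g1.csv
            group = int(f.stem.rsplit("_g", 1)[1])
        if format == "csv":
            sfreq = meta.get("sfreq")
            if sfreq is None:
                raise ValueError(f"no sampling rate for {f.name} (sidecar missing)")
            recs.append(read_csv_recording(f, sfreq=sfreq, group=group))
        else:
            recs.append(read_edf(f, group=group))
    if not recs:
        raise FileNotFoundError(f"no {format} recordings under {path}")
    labels0 = recs[0].channel_labels
    bad = [r.subject_id for r in recs if r.channel_labels != labels0]
    if bad:
        raise ValueError(f"inconsistent channel sets across subjects: {bad}")
    if len({r.sfreq for r in recs}) > 1:
        raise ValueError("inconsistent sampling rates across subjects")
    return recs


def _subject_maps(
    rec: EEGRecording, cfg: ClusterConfig, band, seed: int
) -> dict[int, MicrostateMapSet]:
    filtered = average_reference(bandpass(rec, band))
    peaks = extract_gfp_peaks(filtered, max_peaks=cfg.max_gfp_peaks, seed=seed)
    peak_maps = filtered.data[:, peaks].T
    out = {}
    for k in cfg.k_range:
        sub_cfg = ClusterConfig(
            k_range=(k,),
            n_repetitions=cfg.n_repetitions,
            max_gfp_peaks=cfg.max_gfp_peaks,
            polarity_invariant=cfg.polarity_invariant,
            convergence_tol=cfg.convergence_tol,
            max_iter=cfg.max_iter,
            seed=derive_seed(seed, "kmeans", k),
        )
        ms = modified_kmeans(peak_maps, k, sub_cfg)
        ms.channel_labels = list(rec.channel_labels)
        ms.band = band.name
        out[k] = ms
    return out


def fit_grand_maps(
    recordings: list[EEGRecording], cluster: ClusterConfig, seed: int = 0
) -> dict:
    """Subject-level clustering -> group averages -> k selection -> grand maps.

    Returns a dict with the grand-mean map set (canonically labeled A-E when
    k = 5), the per-group sets, the reliability table, and the group
    map-equivalence check.
    """
    band = DEFAULT_BANDS["broadband"]
    by_group: dict[int, list[dict[int, MicrostateMapSet]]] = {1: [], 2: []}
    for i, rec in enumerate(recordings):
        g = rec.group or 1
        by_group[g].append(_subject_maps(rec, cluster, band, derive_seed(seed, "subject", i)))

    groups = [g for g in (1, 2) if by_group[g]]
    group_sets: dict[int, dict[int, MicrostateMapSet]] = {}
    all_subject_sets: dict[int, list[MicrostateMapSet]] = {k: [] for k in cluster.k_range}
    for g in groups:
        group_sets[g] = {}
        for k in cluster.k_range:
            subject_sets = [d[k] for d in by_group[g]]
            group_sets[g][k] = average_map_sets(subject_sets, level="group")
            all_subject_sets[k].extend(subject_sets)

    # reliability pooled over groups against the across-group mean set per k
    pooled_group_sets = {
        k: average_map_sets([group_sets[g][k] for g in groups], level="group")
        for k in cluster.k_range
    }
    chosen_k, reliability = select_k_by_reliability(all_subject_sets, pooled_group_sets)

    equivalence = None
    if len(groups) == 2:
        C, passed = check_group_equivalence(group_sets[1][chosen_k], group_sets[2][chosen_k])
        equivalence = {"matrix": C, "passed": passed}
        if not passed:
            logger.warning("group map sets are not spatially equivalent at r=0.95")

    grand = average_map_sets(
        [group_sets[g][chosen_k] for g in groups], level="grand"
    )
    if grand.k == 5 and len(grand.channel_labels) == 19:
        grand = canonicalize_labels(grand)
    return {
        "grand_maps": grand,
        "group_maps": {g: group_sets[g][chosen_k] for g in groups},
        "chosen_k": chosen_k,
        "reliability": reliability,
        "equivalence": equivalence,
    }


def simulate_measures(
    sim_cfg: SyntheticConfig,
    cluster: ClusterConfig | None = None,
    band_names: tuple[str, ...] = ("broadband", "delta", "theta", "alpha", "beta"),
    backfit: "BackfitParams | None" = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort, fit grand maps, backfit, and return the tidy table.

    Convenience wrapper over simulate_cohort / fit_grand_maps /
    band_pipeline for scripted experiments; returns (measures, fit_dict).
    """
    cluster = cluster or ClusterConfig()
    backfit_p = backfit or BackfitParams()
    cohort = simulate_cohort(sim_cfg)
    recordings = [rec for rec, _ in cohort]
    fit = fit_grand_maps(recordings, cluster, seed=derive_seed(seed, "cluster"))
    grand = fit["grand_maps"]
    bands = [DEFAULT_BANDS[b] for b in band_names]
    per_subject = {}
    for rec in recordings:
        bp = band_pipeline(
            rec,
            grand,
            bands,
            threshold=backfit_p.threshold,
            window=backfit_p.window,
            factor=backfit_p.factor,
            min_samples=backfit_p.min_samples,
        )
        per_subject[rec.subject_id] = (rec.group or 1, bp)
    fit["cohort"] = cohort
    return measures_to_tidy(per_subject), fit


def run_full(cfg: PipelineConfig) -> dict:
    """Execute the whole pipeline and write every artifact plus a manifest."""
    t0 = time.time()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cfg.simulate is not None:
        logger.info("simulating cohort: %d per group", cfg.simulate.n_per_group)
        cohort = simulate_cohort(cfg.simulate)
        recordings = [rec for rec, _ in cohort]
    elif cfg.input_dir is not None:
        recordings = load_recordings(cfg.input_dir, cfg.input_format)
    else:
        raise ValueError("config must provide either a simulate block or input_dir")

    logger.info("fitting microstate maps (%d subjects)", len(recordings))
    fit = fit_grand_maps(recordings, cfg.cluster, seed=derive_seed(cfg.seed, "cluster"))
    grand = fit["grand_maps"]
    map_set_to_json(grand, out_dir / "grand_maps.json")
    fit["reliability"].to_csv(out_dir / "reliability.csv", index=False)

    logger.info("backfitting %d bands", len(cfg.bands))
    bands = [DEFAULT_BANDS[b] for b in cfg.bands]
    per_subject = {}
    for rec in recordings:
        bp = band_pipeline(
            rec,
            grand,
            bands,
            threshold=cfg.backfit.threshold,
            window=cfg.backfit.window,
            factor=cfg.backfit.factor,
            min_samples=cfg.backfit.min_samples,
        )
        per_subject[rec.subject_id] = (rec.group or 1, bp)
    measures = measures_to_tidy(per_subject)
    measures.to_csv(out_dir / "measures.csv", index=False)

    logger.info("group statistics")
    stats_family = TestFamily(
        n_tests=cfg.stats.n_tests,
        alpha=cfg.stats.alpha,
        n_permutations=cfg.stats.n_permutations,
        seed=derive_seed(cfg.seed, "stats"),
    )
    _, stats_table = run_test_family(measures, stats_family)
    stats_table.to_csv(out_dir / "stats.csv", index=False)

    logger.info("classification models")
    eval_seed = derive_seed(cfg.seed, "classify")
    evaluations = {}
    for band in cfg.bands:
        table = assemble_features(measures, "frequency_specific", band)
        evaluations[table.name] = evaluate_model(
            table,
            n_runs=cfg.classify_n_runs,
            n_folds=cfg.classify_n_folds,
            k_range=cfg.classify_k_range,
            seed=eval_seed,
        )
    for map_label in grand.labels:
        table = assemble_features(measures, "map_specific", map_label)
        evaluations[table.name] = evaluate_model(
            table,
            n_runs=cfg.classify_n_runs,
            n_folds=cfg.classify_n_folds,
            k_range=cfg.classify_k_range,
            seed=eval_seed,
        )

    eval_report = {
        name: {
            "metrics": ev.metrics.to_dict(orient="records"),
            "top_feature": ev.top_feature,
        }
        for name, ev in evaluations.items()
    }
    comparisons = {}
    k1 = min(cfg.classify_k_range)
    alpha_name, broad_name = "frequency_specific[alpha]", "frequency_specific[broadband]"
    if alpha_name in evaluations and broad_name in evaluations:
        dauc, p = compare_models(
            evaluations[alpha_name], evaluations[broad_name], at_k=k1,
            seed=derive_seed(cfg.seed, "compare"),
        )
        comparisons["alpha_vs_broadband_k1"] = {"delta_auc": dauc, "p": p}
    (out_dir / "evaluation.json").write_text(
        json.dumps({"models": eval_report, "comparisons": comparisons}, indent=1)
    )

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "microspect_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "chosen_k": fit["chosen_k"],
        "n_subjects": len(recordings),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("pipeline complete in %.1f s", manifest["elapsed_s"])
    return {
        "fit": fit,
        "measures": measures,
        "stats": stats_table,
        "evaluations": evaluations,
        "comparisons": comparisons,
        "manifest": manifest,
    }
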