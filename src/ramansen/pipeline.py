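"""End-to-end orchestration: simulate/load -> preprocess -> analytics ->
stats -> SOM/SOMDI -> multivariate -> catabolite matching -> summary.

Each stage writes its artifacts plus a ``<stage>.done`` stamp containing the
config hash; rerunning with an unchanged config skips completed stages."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import analytics, catabolite, multivariate, prep, som, stats, synthgen
from .dataset import CLASS_LABELS, SpectralDataset
from .som import round_half_up

log = logging.getLogger("ramansen")


@dataclass
class PipelineConfig:
    output_dir: str = "ramansen_out"
    input_path: str | None = None  # long-format TSV; None requires simulate
    simulate: bool = True
    seed: int = 0
    n_per_class: int = 100
    acquisitions_per_map: int = 10
    cosmic_width: int = 2
    baseline_order: int = 11
    noise_tolerance: float = 1.5
    normalize_reference: float = 1003.0
    regions: list = field(default_factory=lambda: [list(r) for r in analytics.DEFAULT_REGIONS])
    ratios: list = field(default_factory=lambda: [list(r) for r in analytics.DEFAULT_RATIOS])
    som_grid: tuple[int, int] = (8, 8)
    som_iterations: int = 4000
    som_repeats: int = 3
    som_folds: int = 10
    pls_components: int = 5
    pls_folds: int = 5
    kmeans_k: int = 4
    rf_trees: int = 200
    rf_mtry: int = 7
    exclude_classes: list = field(default_factory=list)
    mva_classes: list = field(default_factory=lambda: ["HOL", "MinSOL", "ModSOL", "SOL"])

    def digest(self) -> str:
        d = asdict(self)
        d.pop("output_dir")  # where artifacts land does not change the analysis
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage


def _stage_done(outdir: Path, stage: str, digest: str) -> bool:
    stamp = outdir / f"{stage}.done"
    return stamp.exists() and stamp.read_text().strip() == digest


def _mark_done(outdir: Path, stage: str, digest: str) -> None:
    (outdir / f"{stage}.done").write_text(digest)


def run_full_pipeline(config: PipelineConfig) -> dict:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    fh = logging.FileHandler(outdir / "pipeline.log")
    log.addHandler(fh)
    log.info("config hash %s seed %s", digest, config.seed)
    summary: dict = {"config_hash": digest, "seed": config.seed}

    try:
        dataset = _stage_dataset(config, outdir, digest)
        pre = _stage_prep(config, outdir, digest, dataset)
        summary["n_spectra"] = len(pre)
        summary.update(_stage_analytics(config, outdir, digest, pre))
        summary.update(_stage_stats(config, outdir, digest))
        summary.update(_stage_som(config, outdir, digest, pre))
        summary.update(_stage_mva(config, outdir, digest, pre))
        summary.update(_stage_catabolite(config, outdir, digest))
    except PipelineError:
        raise
    except Exception as exc:  # halt with stage context, partial outputs kept
        raise PipelineError("summary", exc) from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    _write_markdown_summary(outdir, summary)
    return summary


def _stage_dataset(config, outdir: Path, digest: str) -> SpectralDataset:
    stage = "dataset"
    path = outdir / "dataset.tsv"
    if _stage_done(outdir, stage, digest) and path.exists():
        log.info("skip %s (stamp matches)", stage)
        return prep.read_dataset(path)
    try:
        if config.simulate:
            sim = synthgen.SimulationConfig(
                n_per_class=config.n_per_class,
                acquisitions_per_map=config.acquisitions_per_map,
                seed=config.seed,
            )
            ds = synthgen.simulate_dataset(sim)
            (outdir / "simulation_config.json").write_text(
                json.dumps(synthgen.config_to_dict(sim), indent=2)
            )
        else:
            if not config.input_path:
                raise synthgen.ConfigError("no input path and simulate is off")
            ds = prep.read_dataset(config.input_path)
        prep.write_dataset(ds, path)
        _mark_done(outdir, stage, digest)
        return ds
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


def _stage_prep(config, outdir: Path, digest: str, dataset: SpectralDataset) -> SpectralDataset:
    stage = "prep"
    path = outdir / "preprocessed.tsv"
    if _stage_done(outdir, stage, digest) and path.exists():
        log.info("skip %s", stage)
        return prep.read_dataset(path)
    try:
        cfg = prep.BaselineConfig(config.baseline_order, config.noise_tolerance)
        log.info(
            "prep defaults: cosmic width %d, baseline order %d, tolerance %.2f",
            config.cosmic_width, config.baseline_order, config.noise_tolerance,
        )
        pre = dataset.map_transform(
            lambda s: prep.preprocess(s, config.cosmic_width, cfg)
        )
        prep.write_dataset(pre, path)
        _mark_done(outdir, stage, digest)
        return pre
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


def _stage_analytics(config, outdir: Path, digest: str, pre: SpectralDataset) -> dict:
    stage = "analytics"
    try:
        norm = pre.map_transform(
            lambda s: prep.normalize_at(s, config.normalize_reference)
        )
        regions = analytics.region_table(norm, [tuple(r) for r in config.regions])
        ratios = analytics.ratio_table(pre, [tuple(r) for r in config.ratios])
        xc = analytics.crystallinity_table(pre)
        regions.to_csv(outdir / "region_areas.tsv", sep="\t", index=False)
        ratios.to_csv(outdir / "peak_ratios.tsv", sep="\t", index=False)
        xc.to_csv(outdir / "crystallinity.tsv", sep="\t", index=False)
        _mark_done(outdir, stage, digest)
        means = xc.groupby("class")["crystallinity"].mean()
        return {
            "crystallinity_class_means": {
                c: round(float(means[c]), 3) for c in means.index
            }
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


def _stage_stats(config, outdir: Path, digest: str) -> dict:
    stage = "stats"
    try:
        import pandas as pd

        xc = pd.read_csv(outdir / "crystallinity.tsv", sep="\t")
        table = stats.kw_dunn_table(xc, by="class", value="crystallinity")
        table.to_csv(outdir / "crystallinity_kw_dunn.tsv", sep="\t", index=False)
        ratios = pd.read_csv(outdir / "peak_ratios.tsv", sep="\t")
        for col in [c for c in ratios.columns if c not in ("sample_id", "class")]:
            t = stats.kw_dunn_table(ratios, by="class", value=col)
            t.to_csv(
                outdir / f"ratio_{col.replace('/', '_')}_kw_dunn.tsv", sep="\t", index=False
            )
        _mark_done(outdir, stage, digest)
        return {"crystallinity_kw_p": float(table["kw_p"].iloc[0])}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


def _stage_som(config, outdir: Path, digest: str, pre: SpectralDataset) -> dict:
    stage = "som"
    try:
        ds = pre.subset([c for c in pre.class_labels if c not in config.exclude_classes])
        X, y = ds.intensities, ds.labels
        report = som.split_and_cv(
            X, y,
            folds=config.som_folds,
            repeats=config.som_repeats,
            grid_shape=tuple(config.som_grid),
            iterations=config.som_iterations,
            seed=config.seed,
            feature_grid=ds.grid,
        )
        model = som.train_som(
            X, y, tuple(config.som_grid), config.som_iterations, seed=config.seed,
            feature_grid=ds.grid,
        )
        model.to_json(outdir / "som_model.json")
        profile = som.somdi(model)
        top = {c: profile.top_features(c, 5) for c in profile.classes}
        sub_model, sub_profile = som.subset_refit(
            X, y, ["SOL"], grid_shape=tuple(config.som_grid),
            iterations=config.som_iterations, seed=config.seed, feature_grid=ds.grid,
        ) if "SOL" in ds.class_labels else (None, None)
        out = {
            "som_training_accuracy": round_half_up(report.training_accuracy[0]),
            "som_testing_accuracy": round_half_up(report.testing_accuracy[0]),
            "som_overall_accuracy": report.overall_accuracy,
            "som_per_class_testing": {
                k: (round_half_up(v) if np.isfinite(v) else None)
                for k, v in report.per_class_accuracy.items()
            },
            "somdi_top_features": {c: [w for w, _ in feats] for c, feats in top.items()},
        }
        if sub_profile is not None:
            out["somdi_sol_excluded_top"] = {
                c: [w for w, _ in sub_profile.top_features(c, 5)] for c in sub_profile.classes
            }
        (outdir / "som_report.json").write_text(json.dumps(out, indent=2))
        _mark_done(outdir, stage, digest)
        return out
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


def _stage_mva(config, outdir: Path, digest: str, pre: SpectralDataset) -> dict:
    stage = "mva"
    try:
        ds = pre.subset([c for c in config.mva_classes if c in pre.class_labels])
        feats = multivariate.extract_features(ds)
        feats.to_csv(outdir / "features.tsv", sep="\t", index=False)
        pls = multivariate.plsda_fit(
            feats, n_components=config.pls_components, cv_folds=config.pls_folds,
            seed=config.seed,
        )
        km = multivariate.pca_kmeans(feats, k=config.kmeans_k, seed=config.seed)
        rf = multivariate.rf_fit(
            feats, n_trees=config.rf_trees, mtry=config.rf_mtry, seed=config.seed
        )
        km.contingency.to_csv(outdir / "kmeans_contingency.tsv", sep="\t")
        out = {
            "plsda": {
                "r2": round(pls.r_squared, 3),
                "q2": round(pls.q_squared, 3),
                "accuracy_pct": round_half_up(pls.accuracy_pct),
                "vip_top5": [n for n, _ in pls.vip_ranking(5)],
            },
            "rf": {
                "oob_error_pct": round_half_up(100.0 * rf.oob_error),
                "accuracy_pct": round_half_up(rf.accuracy_pct),
                "per_class_error": {k: round(v, 3) for k, v in rf.per_class_error.items()},
                "importance_top5": [n for n, _ in rf.importance_ranking(5)],
            },
            "kmeans_clusters": int(config.kmeans_k),
        }
        (outdir / "mva_report.json").write_text(json.dumps(out, indent=2))
        _mark_done(outdir, stage, digest)
        return out
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


def _stage_catabolite(config, outdir: Path, digest: str) -> dict:
    stage = "catabolite"
    try:
        table = catabolite.load_filtered_peak_table()
        counts = catabolite.stage_counts(table)
        bands = catabolite.unique_bands([table])
        unique = bands[bands["spatially_unique"]]
        class_tables = template_class_peak_tables()
        match = catabolite.match_to_classes(unique, class_tables)
        match.to_csv(outdir / "catabolite_match.tsv", sep="\t", index=False)
        _mark_done(outdir, stage, digest)
        return {
            "catabolite_stage_counts": counts,
            "unique_band_wavenumbers": [round(w, 1) for w in unique["wavenumber_cm1"]],
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


def template_class_peak_tables(min_amplitude: float = 0.005) -> dict[str, list[float]]:
    """Per-class experimental peak positions implied by the default synthetic
    templates (centers whose effective amplitude is non-negligible)."""
    tables = {}
    for tmpl in synthgen.default_templates():
        tables[tmpl.class_label] = [
            c for c, a, _w, m in tmpl.peaks if a * m >= min_amplitude
        ]
    return tables


def _write_markdown_summary(outdir: Path, summary: dict) -> None:
    lines = ["# Pipeline summary", ""]
    lines.append(f"- config hash: `{summary['config_hash']}`, seed {summary['seed']}")
    if "som_overall_accuracy" in summary:
        lines.append(
            f"- SOM: training {summary['som_training_accuracy']:.2f} %, "
            f"testing {summary['som_testing_accuracy']:.2f} %, "
            f"overall {summary['som_overall_accuracy']:.2f} %"
        )
    if "plsda" in summary:
        p = summary["plsda"]
        lines.append(
            f"- PLS-DA: R2 {p['r2']}, Q2 {p['q2']}, accuracy {p['accuracy_pct']:.2f} %"
        )
    if "rf" in summary:
        r = summary["rf"]
        lines.append(
            f"- Random forest: OOB error {r['oob_error_pct']:.2f} %, "
            f"accuracy {r['accuracy_pct']:.2f} %"
        )
    if "crystallinity_class_means" in summary:
        means = ", ".join(
            f"{k}: {v:.3g}" for k, v in summary["crystallinity_class_means"].items()
        )
        lines.append(f"- Crystallinity class means: {means}")
    if "catabolite_stage_counts" in summary:
        lines.append(f"- Catabolite stage counts: {summary['catabolite_stage_counts']}")
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")


__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_full_pipeline",
    "template_class_peak_tables",
    "CLASS_LABELS",
]
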