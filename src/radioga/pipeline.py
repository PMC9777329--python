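"""End-to-end orchestration: images -> features -> GA selection ->
logistic classification -> cross-validated report.

A run executes the five pipeline stages in order, records the config and
seed beside every artifact, and caches the extracted feature table under a
content hash of (manifest, segmentation config, feature config) so a rerun
with an unchanged configuration reuses it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .features import FeatureConfig, extract_features, registry_names
from .io import (
    BinaryMask,
    SampleManifest,
    ValidationError,
    read_feature_table,
    read_image,
    read_mask,
    write_feature_table,
)
from .model_eval import CVReport, kfold_cv
from .segmentation import SegmentationConfig, segment_breast
from .selection import (
    GAConfig,
    GAResult,
    collect_solutions,
    drop_zero_variance,
    forward_select,
    stable_genes,
    whiten,
)
from .tables import FeatureTable

log = logging.getLogger("radioga")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full run.

    mask_mode : "roi" uses the lesion masks from the manifest; "breast"
        segments the whole breast automatically.
    n_stable_genes : how many top-ranked stable genes seed the forward
        pass (default 7).
    cv_selection : "refit" reruns the GA selection inside every training
        fold (no leakage into the pooled metrics); "fixed" evaluates the
        full-data gene list on every fold.
    """

    mask_mode: str = "roi"
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    cv_folds: int = 3
    n_stable_genes: int = 7
    classification_threshold: float = 0.5
    cv_selection: str = "refit"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mask_mode not in ("roi", "breast"):
            raise ValidationError("mask_mode must be 'roi' or 'breast'")
        if self.cv_selection not in ("refit", "fixed"):
            raise ValidationError("cv_selection must be 'refit' or 'fixed'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationConfig(**d["segmentation"])
        if "features" in d and isinstance(d["features"], dict):
            f = dict(d["features"])
            if "angles" in f:
                f["angles"] = tuple(tuple(a) for a in f["angles"])
            d["features"] = FeatureConfig(**f)
        if "ga" in d and isinstance(d["ga"], dict):
            d["ga"] = GAConfig(**d["ga"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _config_hash(manifest: SampleManifest, config: PipelineConfig) -> str:
    payload = json.dumps(
        {
            "manifest": manifest.frame.to_csv(index=False),
            "mask_mode": config.mask_mode,
            "segmentation": dataclasses.asdict(config.segmentation),
            "features": dataclasses.asdict(config.features),
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def extract_table(
    manifest: SampleManifest, config: PipelineConfig, cache_dir: str | Path | None = None
) -> FeatureTable:
    """Stage 1-2: per-sample masks and the 94-feature table.

    With ``cache_dir`` set, the table is stored as
    ``features-<hash>.csv`` and reused when the relevant configuration is
    unchanged.
    """
    cache = None
    if cache_dir is not None:
        cache = Path(cache_dir) / f"features-{_config_hash(manifest, config)}.csv"
        if cache.exists():
            log.info("feature cache hit: %s", cache.name)
            return read_feature_table(cache)

    if config.mask_mode == "roi" and not manifest.has_lesion_masks:
        raise ValidationError("mask_mode='roi' requires lesion masks in the manifest")

    rows = []
    for i in range(len(manifest)):
        image = read_image(manifest.image_path(i))
        if config.mask_mode == "roi":
            mask = read_mask(manifest.mask_path(i))
        else:
            mask = segment_breast(image, config.segmentation)
            image = image.to_8bit()
        rows.append(extract_features(image, mask, config.features))
    names = list(rows[0].keys())
    table = FeatureTable(
        np.array([[r[n] for n in names] for r in rows]),
        names,
        manifest.binary_labels(),
    )
    if cache is not None:
        write_feature_table(table, cache)
    return table


@dataclass
class PipelineResult:
    """Everything a run produced, with the config and seed that made it."""

    config: PipelineConfig
    table: FeatureTable
    ga_result: GAResult
    stable: list[str]
    selected_genes: list[str]
    report: CVReport
    out_dir: Path | None = None


def _select_for_table(table: FeatureTable, config: PipelineConfig) -> tuple[GAResult, list[str], list[str]]:
    """GA -> stable ranking -> forward pass, on an already-whitened table."""
    ga_result = collect_solutions(table, config.ga)
    k = min(config.n_stable_genes, table.n_features)
    ranked = stable_genes(ga_result, k)
    selected = forward_select(
        table,
        ranked,
        inner_cv_folds=config.ga.inner_cv_folds,
        seed=config.ga.seed,
        classifier=config.ga.classifier,
    )
    return ga_result, ranked, selected


def run_pipeline(
    manifest: SampleManifest,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    plots: bool = False,
) -> PipelineResult:
    """Execute segment -> extract -> condition -> select -> evaluate.

    Any stage failure is re-raised with the stage name prefixed. When
    ``out_dir`` is given the features, GA result, report, config and log
    are all written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stages: list[tuple[str, float]] = []

    def _stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                dt = time.perf_counter() - self_.t0
                stages.append((name, dt))
                if exc is not None:
                    raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
                log.info("stage %s: done in %.2fs", name, dt)

        return _Timer()

    if config.mask_mode == "roi" and not manifest.has_lesion_masks:
        raise ValidationError("mask_mode='roi' requires lesion masks in the manifest")

    with _stage("extract"):
        raw = extract_table(manifest, config, cache_dir=out)
    with _stage("condition"):
        conditioned = drop_zero_variance(raw)
        whitened = whiten(conditioned)
    with _stage("select"):
        ga_result, ranked, selected = _select_for_table(whitened, config)
    with _stage("evaluate"):
        if config.cv_selection == "refit":
            select = lambda sub: _select_for_table(sub, config)[2]  # noqa: E731
        else:
            select = selected
        report = kfold_cv(
            conditioned,
            select,
            k=config.cv_folds,
            seed=config.seed,
            threshold=config.classification_threshold,
        )

    result = PipelineResult(
        config=config,
        table=conditioned,
        ga_result=ga_result,
        stable=ranked,
        selected_genes=selected,
        report=report,
        out_dir=out,
    )
    if out is not None:
        with _stage("write"):
            write_feature_table(conditioned, out / "features.csv")
            (out / "ga_result.json").write_text(json.dumps(ga_result.to_dict(), indent=1))
            (out / "report.json").write_text(
                json.dumps(
                    {
                        "config": config.to_dict(),
                        "stable_genes": ranked,
                        "selected_genes": selected,
                        "cv": report.to_dict(),
                        "stage_seconds": {n: round(t, 3) for n, t in stages},
                    },
                    indent=1,
                    default=str,
                )
            )
            with open(out / "config.yaml", "w") as fh:
                yaml.safe_dump(config.to_dict(), fh)
            if plots:
                plot_rank_stability(ga_result, out / "rank_stability.png")
                plot_roc(result, out / "roc.png")
    return result


def compare_modes(
    manifest: SampleManifest,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Run both mask modes on identical folds and seeds; tabulate deltas.

    This is the pipeline's headline comparison: how much of the lesion's
    class signal survives when the whole breast, not the radiologist ROI,
    is the feature region.
    """
    if not manifest.has_lesion_masks:
        raise ValidationError("compare_modes requires lesion masks")
    out = Path(out_dir) if out_dir is not None else None
    reports = {}
    for mode in ("roi", "breast"):
        cfg = dataclasses.replace(config, mask_mode=mode)
        sub = out / mode if out is not None else None
        reports[mode] = run_pipeline(manifest, cfg, out_dir=sub)
    metrics = ("auc", "sensitivity", "specificity", "accuracy")
    paired = {
        "roi": {m: getattr(reports["roi"].report, m) for m in metrics},
        "breast": {m: getattr(reports["breast"].report, m) for m in metrics},
    }
    paired["delta"] = {
        m: paired["roi"][m] - paired["breast"][m] for m in metrics
    }
    if out is not None:
        (out / "compare.json").write_text(json.dumps(paired, indent=1))
    return paired


def plot_rank_stability(ga_result: GAResult, path: str | Path, top: int = 50) -> None:
    """Gene-rank stability bar plot: features ordered by frequency across
    independently evolved solutions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    freq = ga_result.gene_frequency
    order = np.argsort(-freq)[: min(top, len(freq))]
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(range(len(order)), freq[order], color="0.2")
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(
        [ga_result.feature_names[i] for i in order], rotation=90, fontsize=5
    )
    ax.set_ylabel("frequency across solutions")
    ax.set_xlabel("genes ordered by rank")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(result: PipelineResult, path: str | Path) -> None:
    """Pooled ROC curve of the full-data refit model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    from .model_eval import LogisticRegressionModel

    w = whiten(result.table)
    res = LogisticRegressionModel.from_table(w, result.selected_genes).fit()
    probs = res.predict_prob(w.subset(result.selected_genes).values)
    fpr, tpr, _ = roc_curve(w.labels, probs)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, color="0.2")
    ax.plot([0, 1], [0, 1], ls="--", color="0.7")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
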