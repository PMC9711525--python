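"""End-to-end orchestration: aggregate → normalize → FC → Z → hits (+ extras).

``run_pipeline`` executes the standard stage sequence from a
:class:`PipelineConfig`, writes every intermediate table as TSV, and emits
a JSON manifest (package version, seed, config echo, per-stage shapes) that
is sufficient to reproduce the run byte-for-byte.  ``report_summary``
renders a human-readable markdown summary from a completed run directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classifier import build_features, fit_evaluate
from .counts_io import (
    CountMatrix,
    aggregate_to_gene,
    read_count_matrix,
    read_peptide_gene_map,
    read_sample_sheet,
)
from .enrichment import (
    DEFAULT_PROFILE_THRESHOLDS,
    enrichment_profile,
    fold_change,
    normalize,
    zscore,
)
from .hitcalling import (
    DEFAULT_DOWNSAMPLE_SIZES,
    HitCriteria,
    call_hits,
    downsample_controls,
)

logger = logging.getLogger(__name__)

# TSVs larger than this (in cells) are written gzip-compressed (mtime pinned
# to 0 so reruns stay byte-identical).
GZIP_CELL_THRESHOLD = 5_000_000


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML with flat CLI overrides."""

    counts: str
    sample_sheet: str
    out_dir: str
    peptide_gene_map: str | None = None  # required when counts are peptide-level
    level: str = "peptide"
    drop_unmapped: bool = False
    profile_thresholds: tuple[float, ...] = DEFAULT_PROFILE_THRESHOLDS
    criteria: HitCriteria = field(default_factory=HitCriteria)
    run_downsampling: bool = False
    downsample_sizes: tuple[int, ...] = DEFAULT_DOWNSAMPLE_SIZES
    downsample_reps: int = 10
    run_classifier: bool = False
    folds: int = 5
    l1_strength: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        crit = raw.pop("criteria", None)
        cfg = cls(**raw)
        if isinstance(crit, dict):
            cfg.criteria = HitCriteria(**crit)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["criteria"] = dataclasses.asdict(self.criteria)
        return d


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> Path:
    if df.size > GZIP_CELL_THRESHOLD:
        path = path.with_suffix(path.suffix + ".gz")
        df.to_csv(path, sep="\t", index_label=index_label,
                  compression={"method": "gzip", "mtime": 0})
    else:
        df.to_csv(path, sep="\t", index_label=index_label)
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "phipkit_version": __version__,
        "seed": cfg.seed,
        "config": cfg.echo(),
        "stages": [],
        "outputs": {},
    }

    def stage(name: str, fn):
        logger.info("stage %s", name)
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return result

    sheet = stage("read_inputs", lambda: read_sample_sheet(cfg.sample_sheet))
    cm = stage("read_counts", lambda: read_count_matrix(cfg.counts, level=cfg.level))
    if cfg.level == "peptide":
        if cfg.peptide_gene_map is None:
            raise RuntimeError("pipeline stage 'aggregate' failed: peptide-level "
                               "counts need a peptide_gene_map")
        pmap = read_peptide_gene_map(cfg.peptide_gene_map)
        gene_cm: CountMatrix = stage(
            "aggregate", lambda: aggregate_to_gene(cm, pmap, cfg.drop_unmapped))
    else:
        gene_cm = cm
    manifest["stages"].append({"name": "aggregate", "genes": gene_cm.shape[0],
                               "samples": gene_cm.shape[1]})

    freq = stage("normalize", lambda: normalize(gene_cm))
    fc = stage("fold_change", lambda: fold_change(freq, sheet))
    z = stage("zscore", lambda: zscore(fc, sheet))
    profile = stage("profile", lambda: enrichment_profile(fc, cfg.profile_thresholds))
    hits = stage("call_hits", lambda: call_hits(z, fc, sheet, cfg.criteria))
    logger.info("applied criteria: %s", dataclasses.asdict(cfg.criteria))
    for name, df, label in [
        ("gene_counts", gene_cm.counts, "gene"),
        ("frequency", freq.percent, "gene"),
        ("fold_change", fc.fc, "gene"),
        ("zscore", z.z, "gene"),
        ("profile", profile, "sample_id"),
        ("hits", hits.table, "gene"),
    ]:
        manifest["outputs"][name] = str(_write_tsv(df, out / f"{name}.tsv", label))
        manifest["stages"].append({"name": name, "rows": df.shape[0],
                                   "cols": df.shape[1]})
    manifest["n_hits"] = hits.n_passed
    manifest["passed_genes"] = hits.passed_genes

    if cfg.run_downsampling:
        curve = stage("downsample", lambda: downsample_controls(
            fc, sheet, cfg.criteria, sizes=cfg.downsample_sizes,
            reps=cfg.downsample_reps, seed=cfg.seed))
        manifest["outputs"]["downsampling"] = str(
            _write_tsv(curve.per_rep, out / "downsampling.tsv", "row"))
        manifest["downsampling_mean_hits"] = {
            str(k): float(v) for k, v in curve.summary["mean_hits"].items()
        }
    if cfg.run_classifier:
        fm = stage("features", lambda: build_features(gene_cm, sheet))
        cv = stage("classify", lambda: fit_evaluate(
            fm, sheet, folds=cfg.folds, l1_strength=cfg.l1_strength, seed=cfg.seed))
        manifest["outputs"]["roc"] = str(_write_tsv(cv.roc, out / "roc.tsv", "row"))
        scores = pd.DataFrame({"p_case": cv.oof_probability, "label": cv.labels,
                               "fold": cv.fold_assignment})
        manifest["outputs"]["oof_scores"] = str(
            _write_tsv(scores, out / "oof_scores.tsv", "sample_id"))
        manifest["outputs"]["coefficients"] = str(_write_tsv(
            cv.coefficients.to_frame(), out / "coefficients.tsv", "gene"))
        manifest["auc"] = cv.auc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report_summary(manifest: dict) -> str:
    """Render a markdown run summary (idempotent given the same manifest)."""
    lines = [
        "# PhIP-seq run summary",
        "",
        f"phipkit {manifest['phipkit_version']}, seed {manifest['seed']}",
        "",
    ]
    hits_path = manifest.get("outputs", {}).get("hits")
    if hits_path and Path(hits_path).exists():
        hits = pd.read_csv(hits_path, sep="\t", index_col=0)
        passed = hits[hits["passed"]].copy()
        passed["_gene"] = passed.index
        passed = passed.sort_values(["n_cases_positive", "_gene"],
                                    ascending=[False, True])
        lines.append(f"## Shared hits: {len(passed)} genes passed")
        lines.append("")
        if len(passed):
            lines.append("| gene | cases positive | controls positive | max case signal |")
            lines.append("|---|---|---|---|")
            for g, row in passed.iterrows():
                lines.append(
                    f"| {g} | {int(row['n_cases_positive'])} | "
                    f"{int(row['n_controls_positive'])} | {row['max_case_signal']:.2f} |"
                )
        else:
            lines.append("0 genes passed the shared-hit criteria.")
        lines.append("")
    else:
        lines.append("WARNING: hit table missing; partial report.")
    if "downsampling_mean_hits" in manifest:
        lines.append("## Control downsampling (mean apparent hits)")
        lines.append("")
        lines.append("| controls | mean hits |")
        lines.append("|---|---|")
        for k, v in manifest["downsampling_mean_hits"].items():
            lines.append(f"| {k} | {v:.1f} |")
        lines.append("")
    if "auc" in manifest:
        lines.append(f"## Classifier\n\nPooled out-of-fold AUC = {manifest['auc']:.3f}")
        lines.append("")
    return "\n".join(lines) + "\n"
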