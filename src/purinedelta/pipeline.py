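"""End-to-end orchestration: preprocess → differential → permutation/pathway.

A run is described by a YAML config (paths, contrast, thresholds, seed,
output directory).  Each stratum (tissue) is analysed fully
independently: missingness filtering, optional upper-quartile
normalization, PCA outlier exclusion, per-metabolite differential
testing, the permutation count test, direction-stratified pathway
scores and the purine-versus-rest comparison.  Outputs are TSV/JSON
plus a machine-readable manifest; identical config + seed gives
byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import yaml

from . import io as pdio
from .differential import diff_test, lineage_specific
from .permutation import permutation_count_test
from .pathway import pathway_cumulative_p, pb_vs_rest
from .preprocess import (detect_outlier_samples, filter_missingness,
                         upper_quartile_normalize)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    table: str
    meta: str
    pathway_map: str | None = None
    stratify_by: str | None = None  # e.g. "tissue"
    contrast: list = field(default_factory=list)  # [a, b] or [focal, out1, out2]
    alpha: float = 0.05
    alpha_inner: float = 0.05
    B: int = 1000
    pathway_cutoff: float = 0.01
    pathway_direction: str = "down"
    max_missing: float = 0.5
    outlier_sd: float = 3.0
    uq_normalize: bool = True
    test: str = "t"
    adjust: str = "none"
    min_group_n: int = 3
    seed: int = 0
    outdir: str = "purinedelta_run"

    def __post_init__(self) -> None:
        if len(self.contrast) not in (2, 3):
            raise ValueError("contrast must list 2 or 3 group labels")
        for name in ("alpha", "alpha_inner", "pathway_cutoff", "max_missing"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails, naming stage and stratum."""

    def __init__(self, stage: str, stratum: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed in stratum {stratum!r}: {cause}")
        self.stage, self.stratum, self.cause = stage, stratum, cause


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _run_stratum(name, table, pmap, cfg: PipelineConfig, outdir: Path) -> dict:
    record: dict = {"stratum": name, "n_samples": table.n_samples}

    def stage(label, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise StageError(label, name, exc) from exc

    table = stage("filter_missingness", filter_missingness, table,
                  max_missing_fraction=cfg.max_missing)
    record["n_metabolites_after_filter"] = table.n_metabolites
    if cfg.uq_normalize:
        table = stage("upper_quartile_normalize", upper_quartile_normalize, table)
    outliers = stage("detect_outlier_samples", detect_outlier_samples, table,
                     sd_threshold=cfg.outlier_sd, missing="impute")
    record["outlier_samples"] = sorted(outliers)
    if outliers:
        table = table.drop_samples(outliers)

    if len(cfg.contrast) == 2:
        a, b = cfg.contrast
        diffs = stage("diff_test", diff_test, table, a, b, test=cfg.test,
                      alpha=cfg.alpha, adjust=cfg.adjust,
                      min_group_n=cfg.min_group_n)
        diffs.to_csv(outdir / f"{name}_diff.tsv", sep="\t", index=False)
        perm = stage("permutation_count_test", permutation_count_test, table,
                     a, b, alpha_inner=cfg.alpha_inner, B=cfg.B, seed=cfg.seed,
                     min_group_n=cfg.min_group_n)
        _write_json({
            "observed_count": perm.observed_count,
            "p_value": perm.p_value,
            "B": perm.B,
            "exhaustive": perm.exhaustive,
            "n_metabolites_tested": perm.n_metabolites_tested,
            "null_count_histogram": {
                str(k): int(v)
                for k, v in zip(*np.unique(perm.null_counts,
                                           return_counts=True))},
        }, outdir / f"{name}_permutation.json")
        record["observed_count"] = perm.observed_count
        record["permutation_p"] = perm.p_value
    else:
        focal, out1, out2 = cfg.contrast
        calls = stage("lineage_specific", lineage_specific, table, focal,
                      out1, out2, alpha=cfg.alpha, test=cfg.test,
                      min_group_n=cfg.min_group_n, adjust=cfg.adjust)
        calls.to_csv(outdir / f"{name}_lineage.tsv", sep="\t", index=False)
        record["n_focal_specific"] = int(calls["is_focal_specific"].sum())
        diffs = stage("diff_test", diff_test, table, focal, out1,
                      test=cfg.test, alpha=cfg.alpha, adjust=cfg.adjust,
                      min_group_n=cfg.min_group_n)
        diffs.to_csv(outdir / f"{name}_diff.tsv", sep="\t", index=False)

    if pmap is not None:
        scores = stage("pathway_cumulative_p", pathway_cumulative_p, diffs,
                       pmap, cfg.pathway_direction, cutoff=cfg.pathway_cutoff)
        scores.to_csv(outdir / f"{name}_pathways.tsv", sep="\t", index=False)
        record["n_enriched_pathways"] = int(scores["enriched"].sum())
        try:
            p, shift = pb_vs_rest(diffs, pmap)
            _write_json({"p_value": p, "median_shift": shift},
                        outdir / f"{name}_pb_vs_rest.json")
            record["pb_vs_rest_p"] = p
            record["pb_vs_rest_median_shift"] = shift
        except ValueError as exc:
            record["pb_vs_rest_skipped"] = str(exc)
    return record


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = pdio.read_intensity_tsv(config.table, config.meta)
    pmap = (pdio.read_pathway_map_tsv(config.pathway_map)
            if config.pathway_map else None)

    strata = (table.split_by(config.stratify_by)
              if config.stratify_by else {"all": table})
    records = [
        _run_stratum(name, sub, pmap, config, outdir)
        for name, sub in sorted(strata.items())
    ]

    manifest = {
        "package": "purinedelta",
        "version": _pkg_version("purinedelta"),
        "config": asdict(config),
        "strata": records,
    }
    _write_json(manifest, outdir / "manifest.json")

    lines = [f"purinedelta run (seed={config.seed})"]
    for rec in records:
        lines.append(f"stratum {rec['stratum']}:")
        for key in sorted(rec):
            if key != "stratum":
                lines.append(f"  {key}: {rec[key]}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return manifest
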