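"""End-to-end discovery pipeline and cohort summary tables.

``run_discovery`` chains the stages — anchor co-expression ranking,
region-upregulated gene calling, three-way signature derivation, per-sample
scoring, high/low stratification, Kaplan-Meier / log-rank prognosis and ROC
diagnosis — from a single config, writing every intermediate artifact to an
output directory. Reruns with the same config and seed produce byte-identical
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import rank_coexpressed
from .io_formats import (
    GeneSet,
    GliosigWarning,
    read_expression_tsv,
    read_gmt,
    read_metadata_tsv,
    write_gmt,
)
from .regional import region_upregulated_genes
from .signature import derive_signature, score_samples, stratify
from .survival import km_estimate, logrank_test, roc_auc

__all__ = ["PipelineConfig", "StageError", "run_discovery", "cohort_summary", "percent_of"]

logger = logging.getLogger("gliosig")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and parameters of one discovery run."""

    expression_path: str
    metadata_path: str
    inflammation_gmt_path: str
    out_dir: str
    anchor: str = "S100A9"
    signature_name: str = "hypoxic_inflammation"
    k: int = 500
    direction: str = "positive"
    target_regions: tuple[str, ...] = ("PAN",)
    alpha: float = 0.05
    lfc_min: float = 1.0
    stratification_rule: str = "median"
    stratification_q: float = 0.5
    responder_alpha: float = 0.05
    seed: int = 0
    log2_transform: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "target_regions" in raw:
            raw["target_regions"] = tuple(raw["target_regions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["target_regions"] = list(self.target_regions)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs", name, dt)
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_discovery(config: PipelineConfig) -> dict:
    """Run the full discovery chain and write artifacts under ``config.out_dir``.

    Returns a manifest dict (also written as ``provenance.json``) listing the
    artifacts and headline numbers. When the derived signature is empty the
    scoring and evaluation stages are skipped gracefully and the manifest
    records the skip.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": {},
        "results": {},
    }

    with _stage("load"):
        matrix = read_expression_tsv(config.expression_path,
                                     log2_transform=config.log2_transform)
        metadata = read_metadata_tsv(config.metadata_path)
        gmt = read_gmt(config.inflammation_gmt_path)
        if not gmt:
            raise ValueError(f"no gene sets in {config.inflammation_gmt_path}")
        inflammation = gmt[0]

    meta = metadata.set_index("sample_id")
    is_case = (meta.loc[matrix.sample_ids, "diagnostic_label"] == "case").to_numpy()
    has_region = meta.loc[matrix.sample_ids, "region"].notna().to_numpy()
    tumor_samples = [s for s, c in zip(matrix.sample_ids, is_case) if c] or matrix.sample_ids
    region_samples = [s for s, r in zip(matrix.sample_ids, has_region) if r]

    with _stage("coexpress"):
        ranking = rank_coexpressed(
            matrix.subset_samples(tumor_samples), config.anchor,
            k=config.k, direction=config.direction,
        )
        rank_df = pd.DataFrame(ranking.entries, columns=["gene", "rho", "n_pairs"])
        rank_path = out / "coexpression_ranking.tsv"
        rank_df.to_csv(rank_path, sep="\t", index=False, float_format="%.10g")
        manifest["artifacts"]["coexpression_ranking"] = rank_path.name
        coexpr_set = ranking.gene_set()

    with _stage("regions"):
        if not region_samples:
            raise ValueError("no region-labelled samples in metadata")
        region_matrix = matrix.subset_samples(region_samples)
        region_set, region_results = region_upregulated_genes(
            region_matrix, metadata, config.target_regions,
            alpha=config.alpha, lfc_min=config.lfc_min,
        )
        reg_path = out / "regional_results.tsv"
        region_results.to_csv(reg_path, sep="\t", index=False, float_format="%.10g")
        write_gmt([region_set], out / "regional.gmt")
        manifest["artifacts"]["regional_results"] = reg_path.name
        manifest["artifacts"]["regional_gmt"] = "regional.gmt"

    with _stage("derive"):
        signature = derive_signature(
            coexpr_set, inflammation, region_set,
            name=config.signature_name, anchor=config.anchor,
        )
        write_gmt([GeneSet(signature.name, f"anchor {config.anchor}",
                           signature.genes.genes, empty_allowed=True)],
                  out / "signature.gmt")
        manifest["artifacts"]["signature_gmt"] = "signature.gmt"
        manifest["results"]["signature_size"] = len(signature)
        manifest["results"]["signature_provenance"] = signature.provenance

    if len(signature) == 0:
        warnings.warn(
            "empty derived signature: scoring and evaluation stages skipped",
            GliosigWarning,
            stacklevel=2,
        )
        manifest["results"]["skipped"] = ["score", "evaluate"]
        _write_json(manifest, out / "provenance.json")
        return manifest

    with _stage("score"):
        scores = score_samples(matrix, signature)
        score_df = pd.DataFrame(
            {"sample_id": scores.scores.index, "score": scores.scores.to_numpy()}
        )
        groups = stratify(scores, rule=config.stratification_rule, q=config.stratification_q)
        score_df["group"] = groups.to_numpy()
        score_path = out / "scores.tsv"
        score_df.to_csv(score_path, sep="\t", index=False, float_format="%.10g")
        manifest["artifacts"]["scores"] = score_path.name
        manifest["results"]["n_genes_used"] = scores.n_genes_used

    with _stage("evaluate"):
        surv = meta.loc[matrix.sample_ids]
        has_surv = surv["survival_time"].notna() & surv["event"].notna()
        if has_surv.sum() >= 4:
            ids = surv.index[has_surv]
            times = surv.loc[ids, "survival_time"].to_numpy(dtype=float)
            events = surv.loc[ids, "event"].to_numpy(dtype=float)
            labels = groups.loc[ids].to_numpy()
            if len(set(labels)) == 2:
                lr = logrank_test(times, events, labels)
                km_rows = []
                for grp in ("high", "low"):
                    curve = km_estimate(times[labels == grp], events[labels == grp])
                    for t, s, r in zip(curve.timeline, curve.survival, curve.at_risk):
                        km_rows.append((grp, t, s, r))
                pd.DataFrame(km_rows, columns=["group", "time", "survival", "at_risk"]).to_csv(
                    out / "km_curves.tsv", sep="\t", index=False, float_format="%.10g"
                )
                _write_json(
                    {
                        "statistic": lr.statistic,
                        "p": lr.p,
                        "observed": lr.observed,
                        "expected": lr.expected,
                    },
                    out / "logrank.json",
                )
                manifest["artifacts"]["km_curves"] = "km_curves.tsv"
                manifest["artifacts"]["logrank"] = "logrank.json"
                manifest["results"]["logrank_p"] = lr.p

        diag = surv["diagnostic_label"]
        if (diag == "case").any() and (diag == "control").any():
            labelled = diag.notna()
            ids = surv.index[labelled]
            roc = roc_auc(
                scores.scores.loc[ids].to_numpy(),
                (diag.loc[ids] == "case").to_numpy().astype(int),
            )
            pd.DataFrame(
                {
                    "threshold": roc.thresholds,
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                }
            ).to_csv(out / "roc.tsv", sep="\t", index=False, float_format="%.10g")
            manifest["artifacts"]["roc"] = "roc.tsv"
            manifest["results"]["auc"] = roc.auc

    _write_json(manifest, out / "provenance.json")
    return manifest


# ---------------------------------------------------------------------------
# Cohort summary tables
# ---------------------------------------------------------------------------


def percent_of(count: int, n: int) -> float:
    """Percentage rounded half-up to two decimals, as printed in clinical tables."""
    from decimal import ROUND_HALF_UP, Decimal

    if n <= 0:
        raise ValueError("cohort size must be positive")
    frac = Decimal(100 * count) / Decimal(n)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def cohort_summary(metadata: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Count/percent summary of categorical metadata columns.

    For each requested column, every observed category is reported with its
    count and its percentage of the full cohort (half-up, two decimals).
    Returns a DataFrame (column, category, count, percent) plus the cohort
    size as ``df.attrs['n']``.
    """
    if metadata.empty:
        raise ValueError("empty metadata table")
    n = len(metadata)
    if columns is None:
        columns = [c for c in metadata.columns if metadata[c].dtype == object]
    rows = []
    for col in columns:
        counts = metadata[col].value_counts(dropna=True)
        for category, count in counts.sort_index().items():
            rows.append((col, category, int(count), percent_of(int(count), n)))
    df = pd.DataFrame(rows, columns=["column", "category", "count", "percent"])
    df.attrs["n"] = n
    return df


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())
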