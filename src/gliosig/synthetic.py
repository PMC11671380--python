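"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator plants, inside a background of independent Gaussian noise on
the log2 scale:

* a co-expressed gene block tied to an anchor gene through one shared
  latent factor, calibrated so the anchor-member *Spearman* correlation hits
  a requested target (for bivariate normal data, a Pearson loading of
  ``2 sin(pi * rho_s / 6)`` yields Spearman ``rho_s``);
* genes upregulated by a fixed log2 fold change in designated anatomical
  regions (one region label per sample, uniform over LE/IT/CT/MVP/PAN);
* an inflammation annotation gene set (pure membership, no expression
  effect);
* right-censored exponential survival whose log-hazard is linear in the
  latent factor;
* control samples against which case samples carry a diagnostic mean shift
  on the planted signature genes.

The planted signature is, by construction, exactly the three-way
intersection block ∩ inflammation ∩ region-up, and the generator emits that
ground truth alongside the data. All randomness flows from one seed; the
same seed reproduces the outputs bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import REGIONS, ExpressionMatrix, GeneSet

__all__ = [
    "GENERATOR_VERSION",
    "CohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_pdtf_pairs",
    "generate_qpcr_plate",
]

GENERATOR_VERSION = "1"


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic glioma cohort.

    Defaults describe a mid-sized bulk RNA-seq cohort: 2000 genes, 200
    region-labelled tumor samples, a 300-gene co-expression block at target
    Spearman 0.8 with the anchor, 400 inflammation-annotated genes, 250
    region-upregulated genes (+2 log2FC in PAN), with a 60-gene planted
    signature at the triple intersection, exponential survival (baseline
    hazard 0.05/month, log-hazard slope 1 per latent-factor SD, 30%
    censoring) and a 50-control diagnostic arm with a +2 log2 case shift on
    signature genes.
    """

    n_genes: int = 2000
    n_samples: int = 200
    anchor_gene: str = "S100A9"
    block_size: int = 300
    block_correlation: float = 0.8  # target anchor-member Spearman
    n_inflammation_genes: int = 400
    n_region_up_genes: int = 250
    n_signature: int = 60  # triple-intersection size
    n_block_inflammation_extra: int = 60
    n_block_region_extra: int = 40
    n_inflammation_region_extra: int = 20
    target_regions: tuple[str, ...] = ("PAN",)
    region_effect_log2fc: float = 2.0
    noise_sd: float = 1.0
    baseline_hazard: float = 0.05  # events per month at latent score 0
    hazard_log_ratio: float = 1.0  # log hazard ratio per unit latent score
    censoring_rate: float = 0.3
    n_controls: int = 50
    case_effect: float = 2.0  # log2 shift of signature genes in cases vs controls
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.block_correlation < 1:
            raise ValueError("block_correlation must be in (0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.n_signature < 1:
            raise ValueError("triple-intersection size must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        unknown = [r for r in self.target_regions if r not in REGIONS]
        if unknown:
            raise ValueError(f"unknown target regions {unknown}")
        n_block = self.block_size
        n_infl = self.n_inflammation_genes
        n_reg = self.n_region_up_genes
        if self.n_signature + self.n_block_inflammation_extra + self.n_block_region_extra > n_block:
            raise ValueError("block overlaps exceed block_size")
        if self.n_signature + self.n_block_inflammation_extra + self.n_inflammation_region_extra > n_infl:
            raise ValueError("inflammation overlaps exceed n_inflammation_genes")
        if self.n_signature + self.n_block_region_extra + self.n_inflammation_region_extra > n_reg:
            raise ValueError("region overlaps exceed n_region_up_genes")
        union = (
            n_block + n_infl + n_reg
            - self.n_signature * 2
            - self.n_block_inflammation_extra
            - self.n_block_region_extra
            - self.n_inflammation_region_extra
        )
        if union + 1 > self.n_genes:  # +1 for the anchor
            raise ValueError("planted sets do not fit into n_genes")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """An effect-free cohort: no co-expression beyond noise, no regional
        shift, no survival coupling, no diagnostic shift."""
        defaults = dict(
            block_correlation=1e-3,
            region_effect_log2fc=0.0,
            hazard_log_ratio=0.0,
            case_effect=0.0,
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["target_regions"] = list(self.target_regions)
        return d


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic cohort."""

    planted_signature: GeneSet
    block_members: GeneSet
    region_up_members: GeneSet
    inflammation_members: GeneSet
    latent_score: pd.Series  # per case sample
    responder_labels: dict[str, bool] | None = None
    version: str = GENERATOR_VERSION
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "config": self.config,
            "planted_signature": sorted(self.planted_signature.genes),
            "block_members": sorted(self.block_members.genes),
            "region_up_members": sorted(self.region_up_members.genes),
            "inflammation_members": sorted(self.inflammation_members.genes),
            "latent_score": {k: float(v) for k, v in self.latent_score.items()},
            "responder_labels": self.responder_labels,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation giving Spearman ``rho_s`` under bivariate normality."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(config: CohortConfig) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a region-labelled tumor cohort plus controls, with truth.

    Case samples carry the latent factor (hence the co-expression block),
    one region label each, survival, and the diagnostic case shift; control
    samples are pure background noise. Returns
    ``(ExpressionMatrix, metadata, SyntheticTruth)``.
    """
    rng = np.random.default_rng(config.seed)
    n_g, n_s = config.n_genes, config.n_samples

    names = _gene_names(n_g - 1)
    order = rng.permutation(n_g - 1)
    shuffled = [names[i] for i in order]

    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = shuffled[cursor:cursor + k]
        cursor += k
        return out

    sig = take(config.n_signature)
    bi = take(config.n_block_inflammation_extra)
    br = take(config.n_block_region_extra)
    ir = take(config.n_inflammation_region_extra)
    b_only = take(config.block_size - config.n_signature
                  - config.n_block_inflammation_extra - config.n_block_region_extra)
    i_only = take(config.n_inflammation_genes - config.n_signature
                  - config.n_block_inflammation_extra - config.n_inflammation_region_extra)
    r_only = take(config.n_region_up_genes - config.n_signature
                  - config.n_block_region_extra - config.n_inflammation_region_extra)

    block = set(sig) | set(bi) | set(br) | set(b_only)
    inflammation = set(sig) | set(bi) | set(ir) | set(i_only)
    region_up = set(sig) | set(br) | set(ir) | set(r_only)

    gene_ids = [config.anchor_gene] + names
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # --- case samples ---------------------------------------------------
    sample_ids = [f"S{i:03d}" for i in range(1, n_s + 1)]
    regions = rng.choice(REGIONS, size=n_s)
    latent = rng.standard_normal(n_s)

    baseline = rng.uniform(2.0, 10.0, size=n_g)
    X = baseline[:, None] + config.noise_sd * rng.standard_normal((n_g, n_s))

    # anchor: baseline + latent factor, noiseless in the factor so the
    # anchor-member Pearson equals the member loading exactly
    X[0] = baseline[0] + latent
    lam = _spearman_to_pearson(config.block_correlation)
    loading = config.noise_sd * lam / math.sqrt(1.0 - lam**2)
    block_idx = np.array(sorted(gene_index[g] for g in block))
    X[block_idx] += loading * latent[None, :]

    in_target = np.isin(regions, config.target_regions)
    region_idx = np.array(sorted(gene_index[g] for g in region_up))
    X[np.ix_(region_idx, np.flatnonzero(in_target))] += config.region_effect_log2fc

    sig_idx = np.array(sorted(gene_index[g] for g in sig))
    X[sig_idx] += config.case_effect

    # --- survival -------------------------------------------------------
    rate = config.baseline_hazard * np.exp(config.hazard_log_ratio * latent)
    event_time = rng.exponential(1.0 / rate)
    if config.censoring_rate > 0:
        h_c = config.baseline_hazard * config.censoring_rate / (1.0 - config.censoring_rate)
        censor_time = rng.exponential(1.0 / h_c, size=n_s)
    else:
        censor_time = np.full(n_s, np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(float)

    # --- control samples ------------------------------------------------
    n_c = config.n_controls
    control_ids = [f"C{i:03d}" for i in range(1, n_c + 1)]
    if n_c:
        Xc = baseline[:, None] + config.noise_sd * rng.standard_normal((n_g, n_c))
        X = np.concatenate([X, Xc], axis=1)

    matrix = ExpressionMatrix(
        pd.DataFrame(X, index=gene_ids, columns=sample_ids + control_ids)
    )
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids + control_ids,
            "region": list(regions) + [None] * n_c,
            "diagnostic_label": ["case"] * n_s + ["control"] * n_c,
            "survival_time": list(observed) + [np.nan] * n_c,
            "event": list(event) + [np.nan] * n_c,
            "subject_id": sample_ids + control_ids,
            "condition": [None] * (n_s + n_c),
        }
    )
    truth = SyntheticTruth(
        planted_signature=GeneSet("planted_signature", "block & inflammation & region_up",
                                  frozenset(sig)),
        block_members=GeneSet("planted_block", f"co-expressed with {config.anchor_gene}",
                              frozenset(block)),
        region_up_members=GeneSet("planted_region_up",
                                  f"upregulated in {'+'.join(config.target_regions)}",
                                  frozenset(region_up)),
        inflammation_members=GeneSet("planted_inflammation", "inflammation annotation",
                                     frozenset(inflammation)),
        latent_score=pd.Series(latent, index=sample_ids, name="latent_score"),
        config=config.to_dict(),
    )
    return matrix, metadata, truth


def generate_pdtf_pairs(
    config: CohortConfig,
    truth: SyntheticTruth,
    n_subjects: int = 16,
    responder_fraction: float = 0.5,
    effect_log2fc: float = 1.0,
    noise_sd: float = 0.3,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Paired control/treated tumor-fragment profiles with planted responders.

    Each subject contributes one control and one treated expression profile
    over the cohort's gene universe. In responders the treated profile's
    planted-signature genes drop by ``effect_log2fc``; all other genes, and
    all genes of non-responders, differ only by measurement noise. The
    number of responders is ``round(responder_fraction * n_subjects)`` and
    their identities are recorded in the returned truth.
    """
    if not 0 <= responder_fraction <= 1:
        raise ValueError("responder_fraction must be in [0, 1]")
    if not truth.planted_signature.genes:
        raise ValueError("truth carries no planted signature")
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)

    n_g = config.n_genes
    gene_ids = [config.anchor_gene] + _gene_names(n_g - 1)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    sig_idx = np.array(sorted(gene_index[g] for g in truth.planted_signature.genes))

    n_resp = int(round(responder_fraction * n_subjects))
    responders = np.zeros(n_subjects, dtype=bool)
    responders[rng.choice(n_subjects, size=n_resp, replace=False)] = True

    subjects = [f"P{i:02d}" for i in range(1, n_subjects + 1)]
    baseline = rng.uniform(2.0, 10.0, size=n_g)
    cols, ids, meta_rows = [], [], []
    for j, subject in enumerate(subjects):
        ctrl = baseline + noise_sd * rng.standard_normal(n_g)
        trt = baseline + noise_sd * rng.standard_normal(n_g)
        if responders[j]:
            trt[sig_idx] -= effect_log2fc
        for cond, profile in (("control", ctrl), ("treated", trt)):
            sid = f"{subject}_{cond}"
            ids.append(sid)
            cols.append(profile)
            meta_rows.append((sid, None, None, np.nan, np.nan, subject, cond))

    matrix = ExpressionMatrix(pd.DataFrame(np.column_stack(cols), index=gene_ids, columns=ids))
    metadata = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "region", "diagnostic_label", "survival_time",
                 "event", "subject_id", "condition"],
    )
    new_truth = replace(
        truth,
        responder_labels={s: bool(r) for s, r in zip(subjects, responders)},
    )
    return matrix, metadata, new_truth


def generate_qpcr_plate(
    n_subjects: int,
    genes,
    reference_gene: str,
    fold_changes: dict[str, float],
    ct_noise_sd: float = 0.1,
    seed: int | None = None,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a paired control/treated qPCR plate as a Ct table.

    For each target gene the treated-condition mean Ct sits
    ``log2(fold_change)`` cycles *below* the control mean (one PCR cycle per
    doubling of template); the reference gene is unchanged (fold 1).
    Replicates add Gaussian cycle noise of SD ``ct_noise_sd``.
    """
    genes = list(genes)
    if reference_gene in fold_changes:
        raise ValueError("reference gene cannot have a planted fold change")
    bad = {g: f for g, f in fold_changes.items() if f <= 0}
    if bad:
        raise ValueError(f"fold changes must be > 0, got {bad}")
    if reference_gene not in genes:
        genes = [reference_gene] + genes
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(1, n_subjects + 1):
        subject = f"P{i:02d}"
        base = {g: rng.uniform(18.0, 30.0) for g in genes}
        for gene in genes:
            fold = fold_changes.get(gene, 1.0)
            for cond in ("control", "treated"):
                mean_ct = base[gene] - (math.log2(fold) if cond == "treated" else 0.0)
                for rep in range(1, n_replicates + 1):
                    ct = mean_ct + ct_noise_sd * rng.standard_normal()
                    rows.append((subject, cond, gene, float(ct), rep))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "gene", "ct", "replicate"])
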