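"""Normalization, signature scoring and DZ/LZ classification.

Per-cell scoring follows standard single-cell practice: library-size
normalization to the median library, ``log1p``, per-gene z-scaling, then a
signature score that is either the mean z-value over signature genes
(``mean_z``, default) or a control-gene-bin score in the style of
Seurat/Scanpy ``AddModuleScore`` (``ctrl_bins``).  The combined DZ−LZ score
(DZ score minus LZ score) with symmetric thresholds (+0.3 / −0.3 by default)
calls each cell DZ, LZ or intermediate (INT).  Bulk samples are stratified
into DZ-like / LZ-like / intermediate groups from the same signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CellTable, GCZoneError, GeneSignature

logger = logging.getLogger(__name__)

PHENOTYPES = ("DZ", "LZ", "INT")


@dataclass
class NormalizedExpression:
    """Median-library-scaled, log1p expression and its per-gene z-scaling."""

    z: np.ndarray          # cells x genes, per-gene mean 0 / SD 1 (constant -> 0)
    log1p: np.ndarray      # cells x genes, before z-scaling
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    library_target: float  # median library size used for scaling


@dataclass
class ZoneAnnotation:
    """Per-cell signature scores, phenotype call and (later) region label."""

    dz_score: np.ndarray
    lz_score: np.ndarray
    dzlz_score: np.ndarray
    phenotype: np.ndarray                # "DZ" / "LZ" / "INT"
    region: np.ndarray | None = None     # "DZ_region" / "LZ_region" / "unassigned"
    thresholds: tuple[float, float] = (0.3, -0.3)


@dataclass
class BulkStratification:
    """Per-sample signature scores and DZ-like/LZ-like/intermediate groups."""

    samples: pd.DataFrame        # columns: dz_score, lz_score, dzlz_score, group
    grouping_rule: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(cells: CellTable) -> NormalizedExpression:
    """Median-library scaling, log1p, then per-gene z-scaling (ddof=1).

    Constant genes map to z = 0.  Cells with zero total counts are an error
    (they should have been removed by QC).
    """
    counts = cells.counts_dense().astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = int((totals == 0).sum())
        raise GCZoneError(f"{bad} cells have zero total counts; run qc_filter first")
    target = float(np.median(totals))
    lognorm = np.log1p(counts / totals[:, None] * target)
    mean = lognorm.mean(axis=0)
    sd = lognorm.std(axis=0, ddof=1) if counts.shape[0] > 1 else np.zeros(counts.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (lognorm - mean) / sd
    z[:, sd == 0] = 0.0
    return NormalizedExpression(
        z=z,
        log1p=lognorm,
        gene_ids=cells.gene_ids,
        cell_ids=cells.cell_ids,
        library_target=target,
    )


# ---------------------------------------------------------------------------
# per-cell signature scoring
# ---------------------------------------------------------------------------

def _match_signature(gene_ids: np.ndarray, signature: GeneSignature) -> np.ndarray:
    """Case-sensitive exact-symbol match; unmatched genes logged and skipped."""
    index = {g: i for i, g in enumerate(gene_ids)}
    hit = [index[g] for g in signature.genes if g in index]
    n_miss = len(signature.genes) - len(hit)
    if not hit:
        raise GCZoneError(
            f"no gene of signature {signature.name!r} is present in the matrix"
        )
    if n_miss:
        logger.info(
            "signature %s: %d/%d genes absent from matrix (%.1f%% matched)",
            signature.name, n_miss, len(signature.genes),
            100 * len(hit) / len(signature.genes),
        )
    return np.asarray(hit, dtype=int)


def score_signature(
    normalized: NormalizedExpression,
    signature: GeneSignature,
    method: str = "mean_z",
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell signature score.

    ``mean_z``: mean of z-scaled expression over matched signature genes.
    ``ctrl_bins``: for each signature gene, subtract the mean expression of
    ``n_ctrl`` control genes drawn (seeded) from the same average-expression
    bin out of ``n_bins`` bins, on the log1p scale; the score is the mean of
    these differences.  Both are deterministic given ``seed``.
    """
    idx = _match_signature(normalized.gene_ids, signature)
    if method == "mean_z":
        return normalized.z[:, idx].mean(axis=1)
    if method != "ctrl_bins":
        raise GCZoneError(f"unknown scoring method {method!r}")

    rng = np.random.default_rng(seed)
    expr = normalized.log1p
    gene_means = expr.mean(axis=0)
    # equal-frequency bins of average expression
    order = np.argsort(gene_means, kind="stable")
    bin_of = np.empty(expr.shape[1], dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(expr.shape[1]) * n_bins) // expr.shape[1], n_bins - 1
    )
    diffs = np.empty((expr.shape[0], len(idx)))
    for j, gi in enumerate(idx):
        pool = np.flatnonzero(bin_of == bin_of[gi])
        pool = pool[pool != gi]
        if len(pool) == 0:
            ctrl_mean = np.zeros(expr.shape[0])
        else:
            take = rng.choice(pool, size=min(n_ctrl, len(pool)), replace=False)
            ctrl_mean = expr[:, take].mean(axis=1)
        diffs[:, j] = expr[:, gi] - ctrl_mean
    return diffs.mean(axis=1)


def classify_cells(
    dz_score: np.ndarray,
    lz_score: np.ndarray,
    upper: float = 0.3,
    lower: float = -0.3,
) -> ZoneAnnotation:
    """Call DZ / LZ / INT from the combined DZ−LZ score.

    ``dzlz = dz_score − lz_score``; DZ if strictly above ``upper``, LZ if
    strictly below ``lower``, intermediate otherwise.
    """
    if upper <= lower:
        raise GCZoneError(f"upper threshold ({upper}) must exceed lower ({lower})")
    dz = np.asarray(dz_score, float)
    lz = np.asarray(lz_score, float)
    if dz.shape != lz.shape:
        raise GCZoneError("dz_score and lz_score must have equal length")
    if not (np.isfinite(dz).all() and np.isfinite(lz).all()):
        raise GCZoneError("scores must be finite")
    dzlz = dz - lz
    phenotype = np.full(dz.shape, "INT", dtype=object)
    phenotype[dzlz > upper] = "DZ"
    phenotype[dzlz < lower] = "LZ"
    return ZoneAnnotation(
        dz_score=dz,
        lz_score=lz,
        dzlz_score=dzlz,
        phenotype=phenotype,
        region=np.full(dz.shape, "unassigned", dtype=object),
        thresholds=(upper, lower),
    )


# ---------------------------------------------------------------------------
# bulk stratification
# ---------------------------------------------------------------------------

def stratify_bulk(
    expr: pd.DataFrame,
    dz_sig: GeneSignature,
    lz_sig: GeneSignature,
    rule: str = "tertile",
) -> BulkStratification:
    """Group bulk samples into DZ-like / LZ-like / intermediate.

    ``expr`` is genes x samples.  Per-sample scores are means of per-gene
    z-scores (across samples) over signature genes.  The default ``tertile``
    rule ranks samples by the DZ−LZ score and assigns the top third to
    DZ-like and the bottom third to LZ-like (ties broken by sample name for
    determinism); ``kmeans`` clusters the DZ−LZ score into three groups.
    """
    if expr.shape[1] < 2:
        raise GCZoneError("need at least 2 samples")
    vals = expr.to_numpy(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    zdf = pd.DataFrame(z, index=expr.index, columns=expr.columns)

    def sig_score(sig):
        present = [g for g in sig.genes if g in zdf.index]
        if not present:
            raise GCZoneError(f"no gene of signature {sig.name!r} present in matrix")
        return zdf.loc[present].mean(axis=0)

    dz_score, lz_score = sig_score(dz_sig), sig_score(lz_sig)
    dzlz = dz_score - lz_score
    n = len(dzlz)

    if rule == "tertile":
        if n < 3:
            raise GCZoneError("tertile rule needs at least 3 samples")
        order = sorted(dzlz.index, key=lambda s: (dzlz[s], s))
        n_low = n_high = n // 3
        group = pd.Series("intermediate", index=dzlz.index, dtype=object)
        group[order[:n_low]] = "LZ-like"
        group[order[n - n_high:]] = "DZ-like"
        meta = {
            "rule": "tertile",
            "cut_low": float(dzlz[order[n_low - 1]]),
            "cut_high": float(dzlz[order[n - n_high]]),
        }
    elif rule == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=3, n_init=10, random_state=0)
        lab = km.fit_predict(dzlz.to_numpy().reshape(-1, 1))
        by_center = np.argsort(km.cluster_centers_.ravel())
        name_of = {by_center[0]: "LZ-like", by_center[1]: "intermediate",
                   by_center[2]: "DZ-like"}
        group = pd.Series([name_of[l] for l in lab], index=dzlz.index, dtype=object)
        meta = {"rule": "kmeans", "centers": sorted(km.cluster_centers_.ravel().tolist())}
    else:
        raise GCZoneError(f"unknown stratification rule {rule!r}")

    samples = pd.DataFrame(
        {"dz_score": dz_score, "lz_score": lz_score, "dzlz_score": dzlz, "group": group}
    )
    return BulkStratification(samples=samples, grouping_rule=meta)
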