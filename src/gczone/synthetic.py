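"""Synthetic germinal centers with known zone structure and T-cell gradients.

The generator emulates the tissue model the downstream pipeline assumes: a
disc-shaped GC split by a straight chord into a dark zone (DZ) and a light
zone (LZ); zone-structured expression (negative-binomial counts, signature
genes shifted up on the log scale in their own zone); and T-cell-like
subtypes whose membership probability follows a logistic function of signed
distance to the chord (``gradient_beta`` per micrometer, positive = enriched
toward the LZ) or is uniform for complete-spatial-randomness controls.

Every quantity needed for ground-truth evaluation is returned in
:class:`SyntheticTruth`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import CellTable, GCZoneError, load_packaged_signatures, write_cell_table

logger = logging.getLogger(__name__)

GRADIENT_TYPES = ("logistic", "uniform")


@dataclass(frozen=True)
class SubtypeSpec:
    """One simulated cell subtype: size and spatial gradient."""

    name: str
    n_cells: int
    gradient_beta: float = 0.0  # per μm of signed distance (LZ side positive)
    gradient_type: str = "logistic"

    def __post_init__(self):
        if self.gradient_type not in GRADIENT_TYPES:
            raise GCZoneError(f"gradient_type must be one of {GRADIENT_TYPES}")
        if self.n_cells <= 0:
            raise GCZoneError("subtype n_cells must be positive")
        if not np.isfinite(self.gradient_beta):
            raise GCZoneError("gradient_beta must be finite")


def _default_subtypes() -> tuple[SubtypeSpec, ...]:
    # one LZ-enriched T-cell subtype and one CSR control
    return (
        SubtypeSpec("Tfh", 150, gradient_beta=0.02, gradient_type="logistic"),
        SubtypeSpec("naive_CD8", 150, gradient_beta=0.0, gradient_type="uniform"),
    )


@dataclass
class SyntheticConfig:
    """Parameters of one simulated GC.

    ``signature_effect`` is the natural-log mean shift applied to signature
    genes in their own zone; ``label_noise`` is the fraction of cells whose
    expression-generating zone is flipped relative to geometric truth.
    """

    n_cells: int = 2000
    gc_radius: float = 150.0          # μm
    boundary_angle: float = 0.0       # chord angle, radians
    dz_fraction: float = 0.5          # disc-area fraction on the DZ side
    signature_effect: float = 1.5     # log-scale shift for in-zone signature genes
    label_noise: float = 0.1          # fraction of cells with flipped expression zone
    dispersion: float = 1.0           # NB dispersion α (var = μ + αμ²); 0 → Poisson
    base_mean: float = 2.0            # baseline counts per gene per cell
    gene_mean_sd: float = 0.5         # SD of per-gene baseline log-means
    n_background_genes: int = 130
    dz_genes: tuple[str, ...] | None = None  # default: packaged DZ signature
    lz_genes: tuple[str, ...] | None = None  # default: packaged LZ signature
    subtype_specs: tuple[SubtypeSpec, ...] = field(default_factory=_default_subtypes)
    seed: int = 0

    def __post_init__(self):
        if self.n_cells <= 0:
            raise GCZoneError("n_cells must be positive")
        if not 0 < self.dz_fraction < 1:
            raise GCZoneError("dz_fraction must lie in (0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise GCZoneError("label_noise must lie in [0, 0.5)")
        for name in ("gc_radius", "boundary_angle", "dz_fraction",
                     "signature_effect", "label_noise", "dispersion",
                     "base_mean", "gene_mean_sd"):
            if not np.isfinite(getattr(self, name)):
                raise GCZoneError(f"{name} must be finite")
        if self.gc_radius <= 0 or self.base_mean <= 0 or self.dispersion < 0:
            raise GCZoneError("gc_radius/base_mean must be > 0 and dispersion >= 0")
        if sum(s.n_cells for s in self.subtype_specs) > self.n_cells:
            raise GCZoneError("subtype cell counts exceed n_cells")
        names = [s.name for s in self.subtype_specs]
        if len(set(names)) != len(names):
            raise GCZoneError("duplicate subtype names")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated GC."""

    true_zone: np.ndarray            # per-cell "DZ"/"LZ" by geometry
    expression_zone: np.ndarray      # zone used to generate counts (noise applied)
    signed_distance: np.ndarray      # μm to the true chord, DZ negative
    boundary_angle: float
    boundary_offset: float           # chord offset c: boundary is {p·n = c}
    boundary_normal: tuple[float, float]
    subtype_membership: np.ndarray   # per-cell subtype name or ""
    gradient_params: dict            # subtype -> {"beta":…, "type":…}


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _chord_offset(dz_fraction: float, radius: float) -> float:
    """Offset c of the chord {p·n = c} so that area{p·n < c} = dz_fraction."""

    def frac(c):
        # area of the disc with p·n < c, as a fraction
        seg = radius**2 * np.arccos(np.clip(c / radius, -1, 1)) - c * np.sqrt(
            max(radius**2 - c**2, 0.0)
        )
        return 1.0 - seg / (np.pi * radius**2) - dz_fraction

    return brentq(frac, -radius, radius, xtol=1e-10 * radius)


def _sample_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


# ---------------------------------------------------------------------------
# subtype sampling
# ---------------------------------------------------------------------------

def _calibrated_inclusion(signed_dist: np.ndarray, beta: float, k: int) -> np.ndarray:
    """Per-cell inclusion probabilities σ(α + β·s), with α solved so they sum to k."""
    s = np.asarray(signed_dist, float)

    def excess(alpha):
        return np.minimum(1.0, expit(alpha + beta * s)).sum() - k

    lo, hi = -60.0, 60.0
    # widen in the unlikely event beta*s pushes everything outside the bracket
    while excess(lo) > 0:
        lo *= 2
    while excess(hi) < 0:
        hi *= 2
    alpha = brentq(excess, lo, hi, xtol=1e-12)
    return np.minimum(1.0, expit(alpha + beta * s))


def _systematic_pps(rng: np.random.Generator, p: np.ndarray, k: int) -> np.ndarray:
    """Fixed-size sample with inclusion probability exactly ``p`` (sum(p)=k).

    Systematic probability-proportional-to-size sampling on a randomly
    ordered list: every unit is included with probability p_i and exactly k
    units are drawn.
    """
    n = len(p)
    order = rng.permutation(n)
    cum = np.cumsum(p[order])
    targets = rng.random() + np.arange(k)
    picks = np.searchsorted(cum, targets, side="right")
    picks = np.clip(picks, 0, n - 1)
    return order[picks]


def _assign_subtypes(rng, specs, signed_dist, n_cells):
    membership = np.full(n_cells, "", dtype=object)
    available = np.arange(n_cells)
    for spec in specs:
        if spec.n_cells > len(available):
            raise GCZoneError(
                f"subtype {spec.name!r}: {spec.n_cells} cells requested but only "
                f"{len(available)} unassigned cells remain"
            )
        if spec.gradient_type == "uniform" or spec.gradient_beta == 0:
            p = np.full(len(available), spec.n_cells / len(available))
        else:
            p = _calibrated_inclusion(signed_dist[available], spec.gradient_beta, spec.n_cells)
        picked_local = _systematic_pps(rng, p, spec.n_cells)
        picked = available[picked_local]
        membership[picked] = spec.name
        available = np.setdiff1d(available, picked, assume_unique=False)
    return membership


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_gc(config: SyntheticConfig) -> tuple[CellTable, SyntheticTruth]:
    """Simulate one germinal center; reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cells

    # --- geometry and true zones
    normal = (np.cos(config.boundary_angle), np.sin(config.boundary_angle))
    offset = (
        0.0 if config.dz_fraction == 0.5
        else _chord_offset(config.dz_fraction, config.gc_radius)
    )
    coords = _sample_disc(rng, n, config.gc_radius)
    signed = coords @ np.asarray(normal) - offset  # DZ negative, LZ positive
    true_zone = np.where(signed < 0, "DZ", "LZ").astype(object)

    # --- expression zone (label noise)
    expression_zone = true_zone.copy()
    if config.label_noise > 0:
        n_flip = int(round(config.label_noise * n))
        flip = rng.choice(n, size=n_flip, replace=False)
        expression_zone[flip] = np.where(expression_zone[flip] == "DZ", "LZ", "DZ")

    # --- genes
    if config.dz_genes is None or config.lz_genes is None:
        dz_sig, lz_sig = load_packaged_signatures()
        dz_genes = tuple(config.dz_genes or dz_sig.genes)
        lz_genes = tuple(config.lz_genes or lz_sig.genes)
    else:
        dz_genes, lz_genes = tuple(config.dz_genes), tuple(config.lz_genes)
    bg_genes = tuple(f"BG{i:04d}" for i in range(1, config.n_background_genes + 1))
    gene_ids = np.asarray(dz_genes + lz_genes + bg_genes, dtype=object)
    n_genes = len(gene_ids)

    # --- negative-binomial counts with zone-dependent means
    log_mu = np.log(config.base_mean) + rng.normal(0, config.gene_mean_sd, n_genes)
    shift = np.zeros((n, n_genes))
    in_dz = expression_zone == "DZ"
    shift[np.ix_(in_dz, np.arange(len(dz_genes)))] = config.signature_effect
    shift[np.ix_(~in_dz, len(dz_genes) + np.arange(len(lz_genes)))] = config.signature_effect
    mu = np.exp(log_mu[None, :] + shift)
    if config.dispersion > 0:
        size = 1.0 / config.dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)

    # --- subtypes
    membership = _assign_subtypes(rng, config.subtype_specs, signed, n)

    cell_ids = np.asarray([f"cell{i:05d}" for i in range(n)], dtype=object)
    metadata = pd.DataFrame(
        {"subtype": membership}, index=pd.Index(cell_ids, name="cell_id")
    )
    cells = CellTable(
        cell_ids=cell_ids,
        x=coords[:, 0],
        y=coords[:, 1],
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        metadata=metadata,
    )
    truth = SyntheticTruth(
        true_zone=true_zone,
        expression_zone=expression_zone,
        signed_distance=signed,
        boundary_angle=config.boundary_angle,
        boundary_offset=offset,
        boundary_normal=normal,
        subtype_membership=membership,
        gradient_params={
            s.name: {"beta": s.gradient_beta, "type": s.gradient_type}
            for s in config.subtype_specs
        },
    )
    return cells, truth


def write_synthetic(outdir, cells: CellTable, truth: SyntheticTruth,
                    config: SyntheticConfig) -> dict:
    """Write the MTX triplet plus truth.csv and the echoed config.json."""
    outdir = Path(outdir)
    paths = write_cell_table(cells, outdir)
    truth_df = pd.DataFrame(
        {
            "cell_id": cells.cell_ids,
            "true_zone": truth.true_zone,
            "expression_zone": truth.expression_zone,
            "signed_distance": truth.signed_distance,
            "subtype": truth.subtype_membership,
        }
    )
    truth_path = outdir / "truth.csv"
    truth_df.to_csv(truth_path, index=False)
    cfg = dataclasses.asdict(config)
    cfg["dz_genes"] = list(cfg["dz_genes"]) if cfg["dz_genes"] else None
    cfg["lz_genes"] = list(cfg["lz_genes"]) if cfg["lz_genes"] else None
    cfg_path = outdir / "config.json"
    cfg_path.write_text(json.dumps(cfg, indent=2, default=str))
    paths.update({"truth": str(truth_path), "config": str(cfg_path)})
    return paths


# ---------------------------------------------------------------------------
# bulk cohort generator (for DZ-like / LZ-like stratification)
# ---------------------------------------------------------------------------

def generate_bulk_cohort(
    n_samples: int = 60,
    dz_like_fraction: float = 0.3,
    effect: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a bulk genes x samples matrix with two latent classes.

    Class ``DZ_like`` samples have the DZ signature genes shifted up and the
    LZ signature genes shifted down by ``effect`` (in units of the per-gene
    noise SD).  Returns (expression DataFrame, per-sample class labels).
    """
    if n_samples < 3:
        raise GCZoneError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    dz_sig, lz_sig = load_packaged_signatures()
    genes = list(dz_sig.genes) + list(lz_sig.genes) + [f"BG{i:04d}" for i in range(1, 51)]
    n_dz, n_lz = len(dz_sig.genes), len(lz_sig.genes)

    n_class1 = int(round(dz_like_fraction * n_samples))
    labels = np.array(["DZ_like"] * n_class1 + ["other"] * (n_samples - n_class1), dtype=object)
    rng.shuffle(labels)

    expr = rng.normal(0, noise_sd, (len(genes), n_samples))
    is_dz_like = labels == "DZ_like"
    expr[:n_dz, :][:, is_dz_like] += effect
    expr[n_dz:n_dz + n_lz, :][:, is_dz_like] -= effect
    df = pd.DataFrame(
        expr,
        index=genes,
        columns=[f"sample{i:03d}" for i in range(n_samples)],
    )
    return df, labels
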