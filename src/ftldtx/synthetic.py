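"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator here emulates one of the real inputs of the imaging
transcriptomics pipeline — parcellated brain geometry, spatially
autocorrelated regional gene expression, subtype atrophy maps with planted
gene correlates, normative control / patient cohorts, HAR and cryptic
splicing gene labels, GU-repeat-enriched DNA sequences and a seed-based
connectivity library — so the full analysis can be exercised and validated
without any external download.  All generators are deterministic under a
fixed seed, and each records the ground truth it planted so recovery can be
measured.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RegionGeometry:
    """Abstract parcellation: region ids, centroid coordinates, distances.

    Stands in for a cortical atlas (a few hundred parcels with centroid
    coordinates); `dist` is the Euclidean centroid distance matrix used for
    spatial fields, variograms and surrogate maps.
    """

    region_ids: list[str]
    coords: np.ndarray          # (n, 3)
    dist: np.ndarray            # (n, n) symmetric, zero diagonal
    cortical: np.ndarray        # (n,) bool
    hemisphere: np.ndarray      # (n,) "L"/"R"

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_regions, 3)")
        if self.dist.shape != (n, n):
            raise ValueError("dist must be square")
        if not np.allclose(self.dist, self.dist.T):
            raise ValueError("dist must be symmetric")
        if not np.allclose(np.diag(self.dist), 0.0):
            raise ValueError("dist must have zero diagonal")
        off = self.dist[~np.eye(n, dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("off-diagonal distances must be positive")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth planted by the generators, for recovery tests."""

    planted_genes: dict[str, float] = dataclasses.field(default_factory=dict)
    realized_r: dict[str, float] = dataclasses.field(default_factory=dict)
    true_epicentre: dict[str, str] = dataclasses.field(default_factory=dict)
    covariate_betas: pd.DataFrame | None = None
    overlap_odds_ratio: float | None = None


def make_geometry(n_regions: int, layout: str = "sphere", *, seed: int = 0) -> RegionGeometry:
    """Generate a region geometry with `n_regions` parcels.

    layout="grid" places points on an evenly spaced 3D lattice; "sphere"
    places quasi-uniform points on the unit sphere (Fibonacci lattice with a
    small seeded jitter so distances are generic).
    """
    if n_regions < 4:
        raise ValueError("n_regions must be >= 4")
    rng = np.random.default_rng(seed)
    if layout == "grid":
        side = math.ceil(n_regions ** (1 / 3))
        pts = np.array(
            [(i, j, k) for i in range(side) for j in range(side) for k in range(side)],
            dtype=float,
        )[:n_regions]
        # tiny jitter keeps off-diagonal distances strictly positive and generic
        pts = pts + rng.normal(0, 1e-6, pts.shape)
    elif layout == "sphere":
        i = np.arange(n_regions)
        golden = (1 + 5 ** 0.5) / 2
        theta = 2 * np.pi * i / golden
        z = 1 - (2 * i + 1) / n_regions
        r = np.sqrt(np.clip(1 - z ** 2, 0, None))
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        jitter = rng.normal(0, 1e-4, pts.shape)
        pts = pts + jitter
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    dist = squareform(pdist(pts))
    ids = [f"R{i:03d}" for i in range(n_regions)]
    hemi = np.where(pts[:, 0] < np.median(pts[:, 0]), "L", "R")
    cortical = np.ones(n_regions, dtype=bool)
    return RegionGeometry(ids, pts, dist, cortical, hemi)


# ---------------------------------------------------------------------------
# Gaussian-field expression
# ---------------------------------------------------------------------------

def _field_cholesky(geom: RegionGeometry, autocorr_scale: float) -> np.ndarray:
    """Cholesky factor of the exponential covariance exp(-d/scale)."""
    cov = np.exp(-geom.dist / autocorr_scale)
    # small nugget for numerical positive-definiteness
    cov[np.diag_indices_from(cov)] += 1e-9
    return np.linalg.cholesky(cov)


def sample_field(geom: RegionGeometry, autocorr_scale: float, rng: np.random.Generator,
                 size: int = 1) -> np.ndarray:
    """Draw `size` zero-mean unit-variance fields with covariance exp(-d/scale)."""
    L = _field_cholesky(geom, autocorr_scale)
    return (L @ rng.standard_normal((geom.n_regions, size))).T


def make_expression(geom: RegionGeometry, n_genes: int, autocorr_scale: float,
                    n_donors: int = 1, donor_noise_sd: float = 0.3,
                    *, seed: int = 0) -> list[pd.DataFrame]:
    """Donor-level region × gene expression matrices.

    Each gene has one latent spatial profile drawn from a zero-mean Gaussian
    field with covariance exp(-dist/autocorr_scale); each donor observes that
    profile plus independent N(0, donor_noise_sd²) noise, emulating
    inter-donor variability in microarray measurements.
    """
    if autocorr_scale <= 0:
        raise ValueError("autocorr_scale must be positive")
    rng = np.random.default_rng(seed)
    latent = sample_field(geom, autocorr_scale, rng, size=n_genes)  # (genes, regions)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    donors = []
    for _ in range(n_donors):
        obs = latent + donor_noise_sd * rng.standard_normal(latent.shape)
        donors.append(pd.DataFrame(obs.T, index=geom.region_ids, columns=genes))
    return donors


def average_expression(donors: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Donor-average region × gene matrix (the downstream ExpressionMatrix)."""
    return sum(donors) / len(donors)


# ---------------------------------------------------------------------------
# Atrophy maps with planted gene correlates
# ---------------------------------------------------------------------------

def make_atrophy(geom: RegionGeometry, expr: pd.DataFrame,
                 planted: Mapping[str, float], noise_sd: float,
                 autocorr_scale: float, *, seed: int = 0
                 ) -> tuple[pd.Series, SyntheticTruth]:
    """Parcel-level atrophy map built from weighted gene profiles plus noise.

    atrophy = Σ weight · z(gene profile) + noise_sd · autocorrelated field.
    The truth records each planted gene's realized Pearson r with the map.
    """
    missing = [g for g in planted if g not in expr.columns]
    if missing:
        raise KeyError(f"planted genes not in expression matrix: {missing}")
    rng = np.random.default_rng(seed)
    signal = np.zeros(geom.n_regions)
    for g, w in planted.items():
        prof = expr[g].to_numpy(dtype=float)
        z = (prof - prof.mean()) / prof.std()
        signal = signal + w * z
    if noise_sd > 0:
        noise = noise_sd * sample_field(geom, autocorr_scale, rng)[0]
    else:
        noise = np.zeros(geom.n_regions)
    atrophy = pd.Series(signal + noise, index=geom.region_ids, name="W")
    truth = SyntheticTruth(planted_genes=dict(planted))
    for g in planted:
        truth.realized_r[g] = float(np.corrcoef(atrophy, expr[g])[0, 1])
    return atrophy, truth


def plant_gene_correlates(expr: pd.DataFrame, atrophy: pd.Series,
                          gene_ids: Sequence[str], target_r: float,
                          geom: RegionGeometry, autocorr_scale: float,
                          *, seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Rewrite the given genes so each correlates with the map at ~target_r.

    Each planted profile is target_r · z(map) + sqrt(1−target_r²) · g where g
    is an independent autocorrelated field — so many genes can share the same
    target correlation to a single map, which a weighted-sum construction
    cannot deliver.  Returns a copy of `expr` and the truth record.
    """
    if not -1 <= target_r <= 1:
        raise ValueError("target_r must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    z = (atrophy - atrophy.mean()) / atrophy.std()
    out = expr.copy()
    truth = SyntheticTruth()
    fields = sample_field(geom, autocorr_scale, rng, size=len(gene_ids))
    for i, g in enumerate(gene_ids):
        prof = target_r * z.to_numpy() + math.sqrt(1 - target_r ** 2) * fields[i]
        out[g] = prof
        truth.planted_genes[g] = target_r
        truth.realized_r[g] = float(np.corrcoef(atrophy, prof)[0, 1])
    return out, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: default covariate specification: name -> (kind, params)
DEFAULT_COVARIATES: dict[str, tuple] = {
    "age": ("normal", 65.0, 8.0),
    "sex": ("categorical", ("F", "M")),
    "education": ("normal", 14.0, 3.0),
    "tiv": ("normal", 1450.0, 120.0),
}


def make_cohort(geom: RegionGeometry, n_controls: int, n_patients: int,
                atrophy: pd.Series | None = None, *,
                covariates: Mapping[str, tuple] | None = None,
                beta_sd: float = 0.05, noise_sd: float = 0.5,
                baseline: float = 10.0, severity_mean: float = 1.0,
                severity_sd: float = 0.2, seed: int = 0
                ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a normative control cohort and an atrophied patient cohort.

    Control grey matter per region = baseline + linear covariate effects +
    N(0, noise_sd²).  Patients additionally lose tissue proportional to the
    (z-scored) truth atrophy map times a per-patient severity factor, so the
    downstream W-score of a patient is elevated where the map is high.

    Returns (controls, patients, truth); truth.covariate_betas holds the
    generating per-region effects (regions × covariate columns).
    """
    covariates = dict(covariates or DEFAULT_COVARIATES)
    rng = np.random.default_rng(seed)
    # numeric design columns (categoricals become 0/1 indicator of level 2)
    def draw_cov(n: int) -> pd.DataFrame:
        cols = {}
        for name, spec in covariates.items():
            if spec[0] == "normal":
                cols[name] = rng.normal(spec[1], spec[2], n)
            elif spec[0] == "categorical":
                levels = spec[1]
                cols[name] = rng.choice(levels, n)
            else:
                raise ValueError(f"unknown covariate kind {spec[0]!r}")
        return pd.DataFrame(cols)

    n_numeric = len(covariates)
    if n_controls < n_numeric + 2:
        raise ValueError("underdetermined model: need n_controls >= n_covariates + 2")

    betas = pd.DataFrame(
        rng.normal(0, beta_sd, (geom.n_regions, n_numeric)),
        index=geom.region_ids, columns=list(covariates),
    )

    def numeric_design(cov: pd.DataFrame) -> np.ndarray:
        cols = []
        for name, spec in covariates.items():
            if spec[0] == "categorical":
                ref = spec[1][0]
                cols.append((cov[name] != ref).astype(float).to_numpy())
            else:
                x = cov[name].to_numpy(dtype=float)
                cols.append(x - x.mean())  # centred so baseline is the mean
        return np.column_stack(cols)

    def build(n: int, ids: list[str], atrophy_z: np.ndarray | None) -> pd.DataFrame:
        if n == 0:
            cols = ["subject_id", *covariates, *geom.region_ids]
            return pd.DataFrame(columns=cols)
        cov = draw_cov(n)
        X = numeric_design(cov)
        gm = baseline + X @ betas.T.to_numpy() + rng.normal(0, noise_sd, (n, geom.n_regions))
        if atrophy_z is not None:
            sev = np.clip(rng.normal(severity_mean, severity_sd, n), 0, None)
            gm = gm - sev[:, None] * atrophy_z[None, :]
        df = pd.concat(
            [cov, pd.DataFrame(gm, columns=geom.region_ids)], axis=1)
        df.insert(0, "subject_id", ids)
        return df

    controls = build(n_controls, [f"C{i:04d}" for i in range(n_controls)], None)
    atrophy_z = None
    if atrophy is not None and n_patients > 0:
        a = atrophy.reindex(geom.region_ids).to_numpy(dtype=float)
        atrophy_z = (a - a.mean()) / a.std() if a.std() > 0 else np.zeros_like(a)
    patients = build(n_patients, [f"P{i:04d}" for i in range(n_patients)], atrophy_z)
    truth = SyntheticTruth(covariate_betas=betas)
    return controls, patients, truth


# ---------------------------------------------------------------------------
# Gene lists (HAR / cryptic splicing)
# ---------------------------------------------------------------------------

def make_gene_lists(genes: Sequence[str], frac_har: float, frac_cs: float,
                    overlap_enrichment: float = 1.0, *, seed: int = 0
                    ) -> tuple[dict[str, set[str]], SyntheticTruth]:
    """Bernoulli HAR/CS labels with a tunable HAR×CS association.

    CS probability is multiplied by `overlap_enrichment` for HAR genes
    (clipped to 1), so overlap_enrichment=1 gives independent labels.
    Returns ({"HAR": set, "CS": set, "background": set}, truth) with the
    realized sample odds ratio recorded.
    """
    for name, f in (("frac_har", frac_har), ("frac_cs", frac_cs)):
        if not 0 <= f < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    har = rng.random(len(genes)) < frac_har
    # enrichment multiplies the CS odds for HAR genes, so the generating
    # odds ratio equals overlap_enrichment exactly
    odds = frac_cs / (1 - frac_cs) * overlap_enrichment
    p_cs = np.where(har, odds / (1 + odds), frac_cs)
    cs = rng.random(len(genes)) < p_cs
    catalog = {
        "HAR": {g for g, h in zip(genes, har) if h},
        "CS": {g for g, c in zip(genes, cs) if c},
        "background": set(genes),
    }
    a = int(np.sum(har & cs))
    b = int(np.sum(har & ~cs))
    c = int(np.sum(~har & cs))
    d = int(np.sum(~har & ~cs))
    truth = SyntheticTruth()
    truth.overlap_odds_ratio = (a * d) / (b * c) if b * c > 0 else math.inf
    return catalog, truth


# ---------------------------------------------------------------------------
# Sequences with planted GU(GT)-repeat content
# ---------------------------------------------------------------------------

def make_sequences(gene_ids: Sequence[str], length_range: tuple[int, int],
                   gu_weight: Mapping[str, float] | float = 0.0,
                   *, seed: int = 0) -> dict[str, str]:
    """Random DNA sequences with per-gene elevated GT-run insertion.

    Background positions are i.i.d. uniform over ACGT; at each position a
    GT-run of geometric length (2–6 dinucleotide units) is started with
    per-gene probability `gu_weight`.  Planting operates on runs, not motif
    counts, so k-mer counting code is validated against an independent
    mechanism.
    """
    lo, hi = length_range
    if lo < 6:
        raise ValueError("minimum length must be >= 6 (hexamer must fit)")
    if hi < lo:
        raise ValueError("length_range must be (min, max) with max >= min")
    rng = np.random.default_rng(seed)
    if not isinstance(gu_weight, Mapping):
        gu_weight = {g: float(gu_weight) for g in gene_ids}
    out: dict[str, str] = {}
    for g in gene_ids:
        w = gu_weight.get(g, 0.0)
        length = int(rng.integers(lo, hi + 1))
        chars: list[str] = []
        while len(chars) < length:
            if w > 0 and rng.random() < w:
                units = 2 + int(rng.geometric(0.5))  # >= 3 GT units
                chars.extend("GT" * min(units, 6))
            else:
                chars.append("ACGT"[rng.integers(4)])
        out[g] = "".join(chars[:length])
    return out


def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=g, description="synthetic") for g, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Connectivity library
# ---------------------------------------------------------------------------

def make_connectivity_library(geom: RegionGeometry, n_seeds: int,
                              kernel_scale: float, noise_sd: float = 0.01,
                              *, seed: int = 0) -> pd.DataFrame:
    """Seed-based connectivity maps: row s = exp(-dist(s, ·)/kernel_scale) + noise.

    Emulates a normative seed-connectivity library; self-connectivity is
    maximal when noise is small.  Rows are seed regions, columns regions.
    """
    if n_seeds > geom.n_regions:
        raise ValueError("n_seeds cannot exceed n_regions")
    rng = np.random.default_rng(seed)
    seeds = geom.region_ids[:n_seeds]
    idx = np.arange(n_seeds)
    maps = np.exp(-geom.dist[idx] / kernel_scale)
    if noise_sd > 0:
        maps = maps + rng.normal(0, noise_sd, maps.shape)
    return pd.DataFrame(maps, index=seeds, columns=geom.region_ids)
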