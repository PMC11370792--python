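"""Microarray expression preprocessing: donor probe data to a region × gene matrix.

A simplified reimplementation of the standard processing chain for
donor-level brain microarray data (background filtering, representative
probe selection by differential stability, nearest-centroid sample
assignment, per-donor scaled-robust-sigmoid normalization, inter-donor
consistency filtering, donor averaging and cortical subsetting).  The output
schema matches the synthetic expression generator, so downstream stages are
agnostic to the data source.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .synthetic import RegionGeometry


@dataclasses.dataclass
class ProbeMatrix:
    """Donor-level probe data.

    expression: probes × samples; background: same shape, boolean
    "exceeds background signal"; probe_genes: probe -> gene symbol;
    samples: per-sample metadata with columns donor, x, y, z.
    """

    expression: pd.DataFrame
    background: pd.DataFrame
    probe_genes: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.background.shape != self.expression.shape:
            raise ValueError("background flags must match expression shape")
        for c in ("donor", "x", "y", "z"):
            if c not in self.samples.columns:
                raise ValueError(f"sample annotation needs column {c!r}")


def filter_background(probes: ProbeMatrix, min_fraction: float = 0.5) -> ProbeMatrix:
    """Keep probes exceeding background in strictly more than `min_fraction` of samples."""
    frac = probes.background.mean(axis=1)
    keep = frac > min_fraction
    return ProbeMatrix(
        expression=probes.expression.loc[keep],
        background=probes.background.loc[keep],
        probe_genes=probes.probe_genes.loc[keep],
        samples=probes.samples,
    )


def _regional_profiles(values: pd.DataFrame, samples: pd.DataFrame,
                       assignment: pd.Series) -> dict[str, pd.DataFrame]:
    """Per-donor region × row matrices (mean over samples in each region)."""
    out = {}
    assigned = assignment[assignment != "unassigned"]
    for donor, meta in samples.loc[assigned.index].groupby("donor"):
        cols = meta.index
        by_region = values[cols].T.groupby(assigned.loc[cols]).mean()
        out[donor] = by_region  # regions × rows
    return out


def differential_stability(profiles: Mapping[str, pd.DataFrame]) -> pd.Series:
    """Mean pairwise inter-donor Spearman correlation of regional profiles.

    Rows (probes or genes) with undefined correlation in a donor pair
    (constant profile) contribute -inf, so constant probes always lose to
    informative ones during probe selection.
    """
    donors = list(profiles)
    rows = profiles[donors[0]].columns
    if len(donors) < 2:
        warnings.warn("single donor: differential stability undefined, returning 1")
        return pd.Series(1.0, index=rows)
    acc = pd.DataFrame(index=rows, columns=range(0), dtype=float)
    k = 0
    for i in range(len(donors)):
        for j in range(i + 1, len(donors)):
            a, b = profiles[donors[i]], profiles[donors[j]]
            shared = a.index.intersection(b.index)
            if len(shared) < 3:
                continue
            av, bv = a.loc[shared], b.loc[shared]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = np.array([
                    spearmanr(av[c], bv[c]).statistic for c in rows
                ])
            rho = np.where(np.isfinite(rho), rho, -np.inf)
            acc[k] = rho
            k += 1
    if k == 0:
        warnings.warn("no donor pair shares >=3 regions; stability undefined")
        return pd.Series(-np.inf, index=rows)
    return acc.mean(axis=1)


def collapse_probes(probes: ProbeMatrix, geom: RegionGeometry,
                    assignment: pd.Series) -> pd.DataFrame:
    """One representative probe per gene, chosen by differential stability.

    For multi-probe genes the probe with the highest mean inter-donor
    Spearman correlation of its regional profile is kept; single-probe genes
    pass through.  Returns a gene × sample matrix.
    """
    chosen: list[str] = []
    # per-donor regions × probes profiles drive the stability ranking
    profiles = _regional_profiles(probes.expression, probes.samples, assignment)
    stab = differential_stability(profiles)
    for gene, group in probes.probe_genes.groupby(probes.probe_genes):
        cand = list(group.index)
        if len(cand) == 1:
            chosen.append(cand[0])
        else:
            s = stab.loc[cand]
            chosen.append(s.idxmax())
    mat = probes.expression.loc[chosen]
    mat.index = probes.probe_genes.loc[chosen].to_numpy()
    return mat.sort_index()


def assign_samples_to_parcels(samples: pd.DataFrame, geom: RegionGeometry,
                              max_dist: float | None = None) -> pd.Series:
    """Nearest-centroid assignment of tissue samples to regions.

    Samples farther than `max_dist` from every centroid are "unassigned".
    Default max_dist is twice the median nearest-centroid spacing.  Left
    hemisphere samples are never mirrored to the right.
    """
    coords = samples[["x", "y", "z"]].to_numpy(dtype=float)
    d = np.linalg.norm(coords[:, None, :] - geom.coords[None, :, :], axis=2)
    if max_dist is None:
        cd = geom.dist.copy()
        np.fill_diagonal(cd, np.inf)
        max_dist = 2.0 * float(np.median(cd.min(axis=1)))
    nearest = d.argmin(axis=1)
    mind = d.min(axis=1)
    labels = np.array(geom.region_ids, dtype=object)[nearest]
    labels[mind > max_dist] = "unassigned"
    return pd.Series(labels, index=samples.index, name="region")


def scaled_robust_sigmoid(x: np.ndarray) -> np.ndarray:
    """1/(1+exp(-(x-median)/(IQR/1.35))), min-max rescaled to [0, 1]."""
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        raise ValueError("zero IQR")
    s = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
    return (s - s.min()) / (s.max() - s.min())


def normalize_expression(gene_by_sample: pd.DataFrame, samples: pd.DataFrame,
                         method: str = "srs") -> pd.DataFrame:
    """Per-gene, per-donor normalization of a gene × sample matrix.

    method="srs" is the scaled robust sigmoid (default); "zscore" is a plain
    per-gene z-score within donor.  Genes with zero IQR (constant within a
    donor) are dropped for that donor (NaN) with a warning.
    """
    out = gene_by_sample.copy().astype(float)
    dropped = set()
    for donor, meta in samples.loc[gene_by_sample.columns.intersection(samples.index)].groupby("donor"):
        cols = meta.index
        block = gene_by_sample[cols].to_numpy(dtype=float)
        for i, g in enumerate(gene_by_sample.index):
            x = block[i]
            if method == "zscore":
                sd = x.std()
                out.loc[g, cols] = (x - x.mean()) / sd if sd > 0 else np.nan
                if sd == 0:
                    dropped.add(g)
            else:
                try:
                    out.loc[g, cols] = scaled_robust_sigmoid(x)
                except ValueError:
                    out.loc[g, cols] = np.nan
                    dropped.add(g)
    if dropped:
        warnings.warn(f"{len(dropped)} gene(s) constant within a donor; dropped there")
    all_nan = out.isna().all(axis=1)
    if all_nan.any():
        warnings.warn(f"{int(all_nan.sum())} gene(s) constant in all donors; removed")
        out = out.loc[~all_nan]
    return out


def filter_inconsistent_genes(donor_matrices: Mapping[str, pd.DataFrame],
                              threshold: float = 0.1) -> list[str]:
    """Genes whose inter-donor differential stability exceeds `threshold`.

    donor_matrices: donor -> region × gene matrix.  With a single donor the
    filter is the identity (warning).
    """
    if len(donor_matrices) < 2:
        warnings.warn("single donor: consistency filter is the identity")
        only = next(iter(donor_matrices.values()))
        return list(only.columns)
    stab = differential_stability(dict(donor_matrices))
    return list(stab.index[stab > threshold])


def finalize_matrix(donor_matrices: Mapping[str, pd.DataFrame],
                    geom: RegionGeometry) -> pd.DataFrame:
    """Average region × gene expression over contributing donors; cortex only.

    A region's value is the mean over donors that contributed at least one
    sample there; regions with no samples in any donor, and subcortical
    regions, are removed.
    """
    stacked = pd.concat(donor_matrices.values(), keys=list(donor_matrices))
    mean = stacked.groupby(level=1).mean()
    cortical = {r for r, c in zip(geom.region_ids, geom.cortical) if c}
    keep = [r for r in mean.index if r in cortical]
    out = mean.loc[keep].dropna(axis=1, how="any")
    if out.empty:
        raise ValueError("no data after cortical subsetting and donor averaging")
    return out


def prepare_expression(probes: ProbeMatrix, geom: RegionGeometry,
                       *, max_dist: float | None = None,
                       stability_threshold: float = 0.1,
                       norm_method: str = "srs") -> pd.DataFrame:
    """Full chain: background filter, probe collapse, assignment,
    normalization, consistency filter, donor averaging, cortical subset."""
    probes = filter_background(probes)
    assignment = assign_samples_to_parcels(probes.samples, geom, max_dist)
    gene_by_sample = collapse_probes(probes, geom, assignment)
    norm = normalize_expression(gene_by_sample, probes.samples, norm_method)
    donor_mats = _regional_profiles(norm, probes.samples, assignment)
    keep = filter_inconsistent_genes(donor_mats, stability_threshold)
    donor_mats = {d: m[[g for g in keep if g in m.columns]] for d, m in donor_mats.items()}
    return finalize_matrix(donor_mats, geom)
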