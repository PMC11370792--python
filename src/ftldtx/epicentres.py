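"""Connectivity-derived disease epicentres.

A patient's epicentre is the library seed region whose normative
connectivity map is most similar (Pearson) to the patient's parcel-level
atrophy W-map — the putative network origin of the disease.  Epicentre
frequencies summarize where each subtype's disease tends to originate, and
gene expression at epicentre regions can be compared across subtypes.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon

from .spatial import fdr_adjust


def find_epicentre(wmap: pd.Series, library: pd.DataFrame
                   ) -> tuple[str | None, float]:
    """Best-fit seed: argmax over library rows of Pearson r with the W-map.

    Ties break to the lowest seed index (library row order).  A constant
    W-map has no defined correlation and yields (None, nan).
    """
    shared = wmap.index.intersection(library.columns)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared regions")
    w = wmap.loc[shared].to_numpy(dtype=float)
    if w.std() == 0:
        warnings.warn("constant W-map: no epicentre")
        return None, float("nan")
    M = library[shared].to_numpy(dtype=float)
    wc = w - w.mean()
    Mc = M - M.mean(axis=1, keepdims=True)
    denom = np.sqrt((wc @ wc) * (Mc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc @ wc) / denom
    r = np.where(np.isfinite(r), r, -np.inf)
    # lowest-index tie rule, with a tolerance absorbing vectorization jitter
    best = int(np.flatnonzero(r >= r.max() - 1e-12)[0])
    return str(library.index[best]), float(r[best])


def assign_epicentres(wmaps: pd.DataFrame, library: pd.DataFrame,
                      subtypes: Mapping[str, str] | pd.Series | None = None
                      ) -> pd.DataFrame:
    """Per-patient epicentre assignment table.

    `wmaps` has one row per patient (parcel-level W).  Returns a table with
    columns subtype, epicentre, fit_r indexed by patient id.
    """
    rows = []
    for pid, w in wmaps.iterrows():
        seed, r = find_epicentre(w, library)
        rows.append({"patient": pid, "epicentre": seed, "fit_r": r})
    out = pd.DataFrame(rows).set_index("patient")
    if subtypes is not None:
        out.insert(0, "subtype", pd.Series(dict(subtypes)).reindex(out.index))
    return out


def epicentre_frequency(assignments: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, set]]:
    """Per-subtype relative seed frequencies plus a unique/shared partition.

    Returns (frequency table: subtype × seed, {"unique:<subtype>": seeds,
    "shared": seeds}).
    """
    if assignments.empty:
        raise ValueError("no assignments")
    counts = (assignments.groupby(["subtype", "epicentre"]).size()
              .unstack(fill_value=0))
    freq = counts.div(counts.sum(axis=1), axis=0)
    used = {s: set(counts.columns[counts.loc[s] > 0]) for s in counts.index}
    shared = set()
    for a in used:
        for b in used:
            if a < b:
                shared |= used[a] & used[b]
    partition = {f"unique:{s}": used[s] - shared for s in used}
    partition["shared"] = shared
    return freq, partition


def compare_epicentre_expression(genes: Sequence[str],
                                 assignments_a: pd.DataFrame,
                                 assignments_b: pd.DataFrame,
                                 expr: pd.DataFrame, *,
                                 test: str = "ranksum",
                                 q: float = 0.05) -> pd.DataFrame:
    """Compare gene expression at the two groups' epicentre regions.

    For each gene, collect its expression value at every patient's
    epicentre region in group A and group B, compare the two samples with
    an exact Mann–Whitney rank-sum test (default) or a signed-rank test
    (requires equal group sizes; patients paired by rank order), and report
    the cross-fold change mean(A)/mean(B).  P-values are BH-FDR adjusted
    across genes.
    """
    for name, a in (("A", assignments_a), ("B", assignments_b)):
        if len(a) < 2:
            raise ValueError(f"group {name} needs >= 2 assignments")
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    regions_a = assignments_a["epicentre"].tolist()
    regions_b = assignments_b["epicentre"].tolist()
    rows = []
    for g in genes:
        xa = expr.loc[regions_a, g].to_numpy(dtype=float)
        xb = expr.loc[regions_b, g].to_numpy(dtype=float)
        if test == "ranksum":
            if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
                p = 1.0
            else:
                p = float(mannwhitneyu(xa, xb, alternative="two-sided",
                                       method="auto").pvalue)
        elif test == "signed-rank":
            if len(xa) != len(xb):
                raise ValueError("signed-rank mode requires equal group sizes")
            d = np.sort(xa) - np.sort(xb)
            p = 1.0 if np.all(d == 0) else float(
                wilcoxon(np.sort(xa), np.sort(xb)).pvalue)
        else:
            raise ValueError("test must be 'ranksum' or 'signed-rank'")
        mb = xb.mean()
        fold = xa.mean() / mb if mb != 0 else np.nan
        rows.append({"gene": g, "p": p, "fold_change": fold})
    out = pd.DataFrame(rows).set_index("gene")
    p_fdr, _ = fdr_adjust(out["p"])
    out["p_fdr"] = p_fdr.to_numpy()
    return out
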