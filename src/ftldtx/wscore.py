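"""Normative W-score atrophy maps.

A W-score is a covariate-adjusted z-like atrophy score per brain unit
(voxel or parcel): a multiple regression fitted on healthy controls predicts
the expected grey matter value for a subject from their covariates (age,
sex, education, scanner, total intracranial volume, ...), and

    W = -(Raw - Expected) / SD_resid

where SD_resid is the residual standard deviation of the control model at
that unit.  The sign flip makes lower-than-expected grey matter (atrophy)
come out as a HIGHER W, so atrophy maps read "warmer = more atrophic";
pass ``atrophy_positive=False`` to keep the raw (Raw-Expected)/SD sign.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass
class ControlModel:
    """Per-unit OLS fit of grey matter on covariates, from controls only."""

    coefs: pd.DataFrame          # (intercept + design columns) × units
    resid_sd: pd.Series          # per-unit residual SD, (n - p - 1) denominator
    covariates: list[str]        # covariate names as supplied
    design_info: dict            # name -> ("numeric",) | ("categorical", levels)
    degenerate_units: list[str]  # units with zero residual SD (excluded)

    @property
    def units(self) -> list[str]:
        return list(self.resid_sd.index)


def _build_design(table: pd.DataFrame, covariates: Sequence[str],
                  design_info: dict | None = None
                  ) -> tuple[np.ndarray, list[str], dict]:
    """Design matrix with intercept; categoricals one-hot, first level reference."""
    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise KeyError(f"missing covariates: {missing}")
    if table[list(covariates)].isna().any().any():
        raise ValueError("missing covariate values")
    info = {} if design_info is None else design_info
    cols: list[np.ndarray] = [np.ones(len(table))]
    names = ["intercept"]
    for c in covariates:
        col = table[c]
        if design_info is None:
            if pd.api.types.is_numeric_dtype(col):
                info[c] = ("numeric",)
            else:
                info[c] = ("categorical", sorted(col.unique()))
        spec = info[c]
        if spec[0] == "numeric":
            cols.append(col.to_numpy(dtype=float))
            names.append(c)
        else:
            levels = spec[1]
            unknown = set(col.unique()) - set(levels)
            if unknown:
                raise ValueError(f"unseen levels for {c}: {sorted(unknown)}")
            for lev in levels[1:]:
                cols.append((col == lev).astype(float).to_numpy())
                names.append(f"{c}[{lev}]")
    return np.column_stack(cols), names, info


def fit_control_model(controls: pd.DataFrame, covariates: Sequence[str],
                      units: Sequence[str] | None = None) -> ControlModel:
    """Per-unit OLS of control grey matter on the covariates.

    `units` defaults to every numeric column not named in `covariates` (and
    not subject_id).  Residual SD uses the (n - p - 1) denominator.  Units
    with zero residual SD are flagged and excluded from the model.
    """
    if units is None:
        units = [c for c in controls.columns
                 if c not in covariates and c != "subject_id"
                 and pd.api.types.is_numeric_dtype(controls[c])]
    units = list(units)
    X, names, info = _build_design(controls, covariates, None)
    n, p1 = X.shape
    if n < p1 + 1:
        raise ValueError("underdetermined model: need n_controls >= n_params + 1")
    if np.linalg.matrix_rank(X) < p1:
        raise ValueError("collinear covariates: design matrix is rank deficient")
    Y = controls[units].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - p1
    sd = np.sqrt((resid ** 2).sum(axis=0) / dof)
    # zero residual variance up to floating-point noise marks a degenerate unit
    tol = 1e-10 * max(np.abs(Y).max(), 1.0)
    degenerate = [u for u, s in zip(units, sd) if s <= tol or not np.isfinite(s)]
    keep = [i for i, u in enumerate(units) if u not in degenerate]
    kept = [units[i] for i in keep]
    return ControlModel(
        coefs=pd.DataFrame(beta[:, keep], index=names, columns=kept),
        resid_sd=pd.Series(sd[keep], index=kept),
        covariates=list(covariates),
        design_info=info,
        degenerate_units=degenerate,
    )


def compute_wmap(subjects: pd.DataFrame, model: ControlModel,
                 *, atrophy_positive: bool = True) -> pd.DataFrame:
    """W-score maps for one or more subjects (rows) over the model's units.

    W = sign · (Raw − Expected) / SD_resid with sign = −1 under the default
    atrophy-positive convention.
    """
    X, _, _ = _build_design(subjects, model.covariates, model.design_info)
    expected = X @ model.coefs.to_numpy()
    raw = subjects[model.units].to_numpy(dtype=float)
    w = (raw - expected) / model.resid_sd.to_numpy()
    if atrophy_positive:
        w = -w
    index = subjects["subject_id"] if "subject_id" in subjects else subjects.index
    return pd.DataFrame(w, index=pd.Index(index, name="subject_id"),
                        columns=model.units)


def aggregate_to_parcels(wmap: pd.Series, parcel_labels: pd.Series,
                         *, unassigned: str = "unassigned") -> pd.Series:
    """Mean W per parcel; voxels labelled `unassigned` are ignored.

    Raises on parcels that appear in the label map but receive no voxels
    (all members missing from the W-map).
    """
    labels = parcel_labels.reindex(wmap.index)
    if labels.isna().any():
        raise KeyError("every voxel needs a parcel label (or the unassigned label)")
    keep = labels != unassigned
    out = wmap[keep].groupby(labels[keep]).mean()
    expected = set(parcel_labels[parcel_labels != unassigned].unique())
    empty = expected - set(out.index)
    if empty:
        raise ValueError(f"empty parcels: {sorted(empty)}")
    return out


def read_nifti_parcel_table(volume_path, label_path, *,
                            subject_id: str = "subject") -> pd.DataFrame:
    """I/O adapter: voxel volume + integer parcel-label volume -> subject row.

    Produces one table row with a column per parcel (mean voxel value inside
    each non-zero label), matching the TSV schema used everywhere else.
    Requires nibabel (optional dependency); contains no analysis logic.
    """
    import nibabel as nib

    vol = np.asarray(nib.load(str(volume_path)).dataobj, dtype=float)
    labels = np.asarray(nib.load(str(label_path)).dataobj).astype(int)
    if vol.shape != labels.shape:
        raise ValueError("volume and label image shapes differ")
    row = {f"P{lab:03d}": float(vol[labels == lab].mean())
           for lab in np.unique(labels) if lab != 0}
    out = pd.DataFrame([row])
    out.insert(0, "subject_id", subject_id)
    return out


def group_average(wmaps: Sequence[pd.Series]) -> pd.Series:
    """Element-wise mean of W-maps sharing the same units."""
    if len(wmaps) == 0:
        raise ValueError("need at least one W-map")
    first = wmaps[0]
    for m in wmaps[1:]:
        if not first.index.equals(m.index):
            raise ValueError("W-maps must share unit ids")
    return pd.concat(wmaps, axis=1).mean(axis=1)
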