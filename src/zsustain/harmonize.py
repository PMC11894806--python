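"""Control-anchored covariate harmonization and z-scoring of regional volumes.

Per-region ordinary least squares of (hemisphere-combined) volume on scanner
field strength, scanner manufacturer, sex, age at scan and total intracranial
volume, fitted on controls only and propagated unchanged to cases. The
adjusted volume is the residual plus the control grand mean, keeping values
on the mm³ scale. z-scores are computed against the adjusted control
distribution with an atrophy-positive sign: smaller volume → larger z.

Region-of-interest selection retains regions whose case/control standardized
mean difference (pooled-SD Cohen's d) meets a threshold, 0.6 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from zsustain.schema import RegionSchema, SchemaError

__all__ = [
    "HarmonizationModel",
    "SingularDesignError",
    "fit_covariate_model",
    "apply_harmonization",
    "combine_hemispheres",
    "cohens_d",
    "select_rois",
    "to_zscores",
    "laterality_index",
]

#: covariate columns every scan table must carry
COVARIATES = ["field_strength", "manufacturer", "sex", "age_at_scan", "tiv"]

#: non-volume metadata columns in a scan table
META_COLUMNS = ["subject_id", "scan_id", "visit", "group", "pathology"] + COVARIATES


class SingularDesignError(ValueError):
    """Covariate design matrix is rank-deficient (e.g. a one-level factor)."""


@dataclass
class HarmonizationModel:
    """Frozen control regression: per-region OLS coefficients + control stats.

    Attributes
    ----------
    design_columns
        Names of the design matrix columns (intercept first).
    reference_levels
        For each categorical covariate, the level coded 0 (the control-
        majority level) and the level coded 1.
    coefficients
        DataFrame (design column × region) of OLS coefficients.
    control_mean, control_sd
        Per-region mean and SD of *adjusted* control volumes. The mean is the
        control grand mean used for re-centering.
    """

    design_columns: list[str]
    reference_levels: dict[str, tuple[str, str]]
    coefficients: pd.DataFrame
    control_mean: pd.Series
    control_sd: pd.Series

    def __post_init__(self) -> None:
        if (self.control_sd <= 0).any():
            bad = self.control_sd.index[self.control_sd <= 0].tolist()
            raise ValueError(f"zero/negative control SD for regions: {bad}")

    @property
    def regions(self) -> list[str]:
        return list(self.coefficients.columns)

    def to_dict(self) -> dict:
        return {
            "design_columns": self.design_columns,
            "reference_levels": {k: list(v) for k, v in self.reference_levels.items()},
            "coefficients": {r: self.coefficients[r].tolist() for r in self.regions},
            "control_mean": self.control_mean.to_dict(),
            "control_sd": self.control_sd.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HarmonizationModel":
        cols = d["design_columns"]
        coef = pd.DataFrame({r: v for r, v in d["coefficients"].items()}, index=cols)
        return cls(
            design_columns=cols,
            reference_levels={k: tuple(v) for k, v in d["reference_levels"].items()},
            coefficients=coef,
            control_mean=pd.Series(d["control_mean"]),
            control_sd=pd.Series(d["control_sd"]),
        )


_CATEGORICAL = ["field_strength", "manufacturer", "sex"]
_CONTINUOUS = ["age_at_scan", "tiv"]


def _encode_design(scans: pd.DataFrame, reference_levels: dict[str, tuple[str, str]]) -> np.ndarray:
    cols = [np.ones(len(scans))]
    for cov in _CATEGORICAL:
        ref, other = reference_levels[cov]
        vals = scans[cov].astype(str)
        unseen = set(vals.unique()) - {ref, other}
        if unseen:
            raise SchemaError(f"unseen level(s) {sorted(unseen)} for covariate {cov!r}")
        cols.append((vals == other).to_numpy(dtype=float))
    for cov in _CONTINUOUS:
        v = scans[cov].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise SchemaError(f"missing or non-finite values in covariate {cov!r}")
        cols.append(v)
    return np.column_stack(cols)


def _check_scan_table(scans: pd.DataFrame) -> None:
    missing = [c for c in COVARIATES if c not in scans.columns]
    if missing:
        raise SchemaError(f"scan table lacks covariate columns: {missing}")
    if scans[COVARIATES].isna().any().any():
        bad = scans[COVARIATES].columns[scans[COVARIATES].isna().any()].tolist()
        raise SchemaError(f"missing covariate values in columns: {bad}")


def combine_hemispheres(table: pd.DataFrame, schema: RegionSchema) -> pd.DataFrame:
    """Sum ``_L``/``_R`` columns of paired regions; pass midline regions through.

    Non-region columns (identifiers, covariates) are preserved. Total volume
    is conserved exactly.
    """
    out = table.copy()
    for region in schema.regions:
        if schema.is_paired(region):
            left, right = f"{region}_L", f"{region}_R"
            for side in (left, right):
                if side not in table.columns:
                    raise SchemaError(f"missing hemisphere column {side!r} for region {region!r}")
            out[region] = table[left].to_numpy() + table[right].to_numpy()
            out = out.drop(columns=[left, right])
        elif region not in table.columns:
            raise SchemaError(f"missing column for midline region {region!r}")
    meta = [c for c in out.columns if c not in schema.regions]
    return out[meta + list(schema.regions)]


def fit_covariate_model(controls: pd.DataFrame, schema: RegionSchema) -> HarmonizationModel:
    """Fit per-region OLS of volume on covariates, on controls only.

    ``controls`` must be a hemisphere-combined scan table (one column per
    schema region plus the covariate columns). Categorical covariates are
    coded 0/1 with the control-majority level as reference. Raises
    :class:`SingularDesignError` naming the offending column when the design
    is rank-deficient (e.g. all controls share one manufacturer).
    """
    _check_scan_table(controls)
    schema.validate_regions([r for r in schema.regions if r not in controls.columns] or [])
    missing = [r for r in schema.regions if r not in controls.columns]
    if missing:
        raise SchemaError(f"control table lacks region columns: {missing}")

    reference_levels: dict[str, tuple[str, str]] = {}
    for cov in _CATEGORICAL:
        levels = controls[cov].astype(str).value_counts()
        if len(levels) < 2:
            raise SingularDesignError(
                f"covariate {cov!r} has a single level ({levels.index[0]!r}) in controls"
            )
        if len(levels) > 2:
            raise SchemaError(f"covariate {cov!r} has >2 levels; expected binary")
        # majority level is the reference (coded 0); ties broken alphabetically
        ordered = sorted(levels.index.tolist(), key=lambda l: (-levels[l], l))
        reference_levels[cov] = (ordered[0], ordered[1])

    X = _encode_design(controls, reference_levels)
    design_columns = ["intercept"] + _CATEGORICAL + _CONTINUOUS
    if len(controls) < X.shape[1] + 2:
        raise ValueError(f"need at least {X.shape[1] + 2} controls, got {len(controls)}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a dependent column by dropping each in turn
        for k in range(1, X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, k, axis=1)) == rank:
                raise SingularDesignError(
                    f"design is singular; column {design_columns[k]!r} is degenerate"
                )
        raise SingularDesignError("design is singular")

    Y = controls[list(schema.regions)].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    grand_mean = Y.mean(axis=0)
    adjusted = Y - fitted + grand_mean
    coef = pd.DataFrame(beta, index=design_columns, columns=list(schema.regions))
    return HarmonizationModel(
        design_columns=design_columns,
        reference_levels=reference_levels,
        coefficients=coef,
        control_mean=pd.Series(adjusted.mean(axis=0), index=list(schema.regions)),
        control_sd=pd.Series(adjusted.std(axis=0, ddof=1), index=list(schema.regions)),
    )


def apply_harmonization(scans: pd.DataFrame, model: HarmonizationModel, schema: RegionSchema) -> pd.DataFrame:
    """Adjust volumes of any scans (controls or cases) with the control model.

    adjusted = raw − (fitted − control grand mean); applied once, to raw
    hemisphere-combined volumes.
    """
    _check_scan_table(scans)
    X = _encode_design(scans, model.reference_levels)
    regions = model.regions
    missing = [r for r in regions if r not in scans.columns]
    if missing:
        raise SchemaError(f"scan table lacks region columns: {missing}")
    Y = scans[regions].to_numpy(dtype=float)
    fitted = X @ model.coefficients.to_numpy()
    grand = model.control_mean.to_numpy() + 0.0  # adjusted control mean == grand mean
    adjusted = Y - fitted + grand
    out = scans.copy()
    out[regions] = adjusted
    return out


def cohens_d(cases: np.ndarray, controls: np.ndarray) -> float:
    """Pooled-SD standardized mean difference, positive when cases are smaller.

    d = (mean_controls − mean_cases) / s_pooled, with the pooled SD using
    n−1 weights.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 observations per group")
    n1, n2 = len(controls), len(cases)
    s2 = ((n1 - 1) * controls.var(ddof=1) + (n2 - 1) * cases.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        raise ValueError("pooled SD is zero")
    return float((controls.mean() - cases.mean()) / math.sqrt(s2))


def select_rois(
    adjusted: pd.DataFrame,
    schema: RegionSchema,
    threshold: float = 0.6,
    group_column: str = "group",
) -> tuple[list[str], pd.Series]:
    """Select regions with |Cohen's d| >= threshold between baseline cases and controls.

    Returns the selected region names in schema order plus the full d table.
    Uses baseline scans only (visit 0) if a ``visit`` column is present.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    tbl = adjusted
    if "visit" in tbl.columns:
        tbl = tbl[tbl["visit"] == 0]
    ctrl = tbl[tbl[group_column] == "control"]
    case = tbl[tbl[group_column] == "case"]
    d = pd.Series(
        {r: cohens_d(case[r].to_numpy(), ctrl[r].to_numpy()) for r in schema.regions},
        name="cohens_d",
    )
    selected = [r for r in schema.regions if abs(d[r]) >= threshold]
    return selected, d


def to_zscores(adjusted: pd.DataFrame, model: HarmonizationModel, rois: list[str]) -> pd.DataFrame:
    """Atrophy-positive z-scores of adjusted volumes vs the control distribution.

    z = (control mean − adjusted) / control SD; smaller volume → larger z.
    Metadata columns are preserved; region columns are replaced by the ROI
    z-score columns.
    """
    missing = [r for r in rois if r not in model.regions]
    if missing:
        raise SchemaError(f"ROIs not covered by the harmonization model: {missing}")
    mu = model.control_mean[rois].to_numpy()
    sd = model.control_sd[rois].to_numpy()
    if np.any(sd <= 0):
        raise ValueError("zero control SD")
    Z = (mu - adjusted[list(rois)].to_numpy(dtype=float)) / sd
    meta = [c for c in META_COLUMNS if c in adjusted.columns]
    out = adjusted[meta].copy()
    out[list(rois)] = Z
    return out


def laterality_index(scan: pd.Series, schema: RegionSchema) -> float:
    """Percent hemispheric asymmetry of one raw scan.

    LI = |Σ left paired volumes − Σ right paired volumes| / total brain
    volume × 100, where total brain volume is the sum of all regional raw
    volumes (both hemispheres plus midline regions).
    """
    left = sum(float(scan[f"{r}_L"]) for r in schema.regions if schema.is_paired(r))
    right = sum(float(scan[f"{r}_R"]) for r in schema.regions if schema.is_paired(r))
    total = left + right + sum(
        float(scan[r]) for r in schema.regions if not schema.is_paired(r)
    )
    if total <= 0:
        raise ValueError("total brain volume is zero")
    return abs(left - right) / total * 100.0
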