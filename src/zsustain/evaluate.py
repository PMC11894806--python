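"""Longitudinal validation and post-hoc subtype comparisons.

Three families of checks on staged cohorts:

* longitudinal consistency — subtype stability at follow-up (same subtype,
  or normal-appearing at baseline becoming subtypable) and stage progression
  (advanced / same / regressed between consecutive visits);
* subtype–pathology enrichment — Pearson χ² on the pathology × subtype
  contingency of subtypable scans;
* regional and laterality comparisons — pairwise two-tailed unpaired
  (pooled-variance) t-tests between subtypes with Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from zsustain.harmonize import laterality_index
from zsustain.schema import RegionSchema

__all__ = [
    "StabilityReport",
    "ProgressionReport",
    "EnrichmentTable",
    "subtype_stability",
    "stage_progression",
    "enrichment_test",
    "regional_comparison",
    "laterality_comparison",
]

logger = logging.getLogger(__name__)


@dataclass
class StabilityReport:
    """Subtype stability at follow-up."""

    n_followups: int
    n_stable: int
    stability: float
    transitions: pd.DataFrame
    switchers: pd.DataFrame


@dataclass
class ProgressionReport:
    """Stage progression between consecutive visits, per subtype and overall."""

    counts: pd.DataFrame  # rows: strata; columns advanced/same/regressed
    proportions: pd.DataFrame


@dataclass
class EnrichmentTable:
    """Pathology × subtype contingency with Pearson χ²."""

    counts: pd.DataFrame
    row_percent: pd.DataFrame
    chi2: float
    df: int
    p_value: float


def _ordered_visits(assignments: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "visit", "ml_subtype", "ml_stage", "normal_appearing"}
    missing = required - set(assignments.columns)
    if missing:
        raise ValueError(f"assignment table lacks columns: {sorted(missing)}")
    df = assignments.sort_values(["subject_id", "visit"]).reset_index(drop=True)
    fu_subjects = set(df.loc[df["visit"] > 0, "subject_id"])
    base_subjects = set(df.loc[df["visit"] == 0, "subject_id"])
    orphans = sorted(fu_subjects - base_subjects)
    if orphans:
        raise ValueError(f"follow-up scans without a baseline for subjects: {orphans}")
    return df


def subtype_stability(assignments: pd.DataFrame) -> StabilityReport:
    """Proportion of follow-up scans keeping their baseline subtype.

    A follow-up counts stable when it has the baseline subtype, or when the
    baseline was normal appearing (stage 0) and the follow-up is subtypable.
    Pairs normal-appearing at both visits are excluded from the denominator.
    Subtype at each comparison is taken against the subject's baseline scan.
    """
    df = _ordered_visits(assignments)
    baselines = df[df["visit"] == 0].set_index("subject_id")
    fu = df[df["visit"] > 0]
    subtypes = sorted(set(df.loc[~df["normal_appearing"], "ml_subtype"]))
    trans = pd.DataFrame(0, index=subtypes + ["normal"], columns=subtypes + ["normal"])
    n_total = n_stable = 0
    switch_rows = []
    for _, row in fu.iterrows():
        base = baselines.loc[row["subject_id"]]
        b_lab = "normal" if base["normal_appearing"] else base["ml_subtype"]
        f_lab = "normal" if row["normal_appearing"] else row["ml_subtype"]
        trans.loc[b_lab, f_lab] += 1
        if b_lab == "normal" and f_lab == "normal":
            continue  # never subtypable: outside the denominator
        n_total += 1
        if b_lab == f_lab or (b_lab == "normal" and f_lab != "normal"):
            n_stable += 1
        else:
            switch_rows.append(
                {
                    "subject_id": row["subject_id"],
                    "visit": row["visit"],
                    "baseline_subtype": b_lab,
                    "followup_subtype": f_lab,
                    "baseline_subtype_prob": float(base["subtype_prob"])
                    if "subtype_prob" in base
                    else np.nan,
                }
            )
    return StabilityReport(
        n_followups=n_total,
        n_stable=n_stable,
        stability=n_stable / n_total if n_total else float("nan"),
        transitions=trans,
        switchers=pd.DataFrame(switch_rows),
    )


def stage_progression(assignments: pd.DataFrame, from_baseline: bool = False) -> ProgressionReport:
    """Classify each follow-up as advanced / same / regressed in stage.

    By default each follow-up is compared with the immediately preceding
    visit; ``from_baseline=True`` compares every follow-up with the baseline
    scan instead. Strata are the baseline subtype of subtypable subjects plus
    an overall row; pairs normal-appearing at both visits are excluded.
    """
    df = _ordered_visits(assignments)
    rows = []
    for subject, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("visit")
        base = grp.iloc[0]
        prev_stage = int(base["ml_stage"])
        for _, row in grp.iloc[1:].iterrows():
            ref = int(base["ml_stage"]) if from_baseline else prev_stage
            cur = int(row["ml_stage"])
            if not (base["normal_appearing"] and row["normal_appearing"]):
                cls = "advanced" if cur > ref else ("same" if cur == ref else "regressed")
                stratum = "normal" if base["normal_appearing"] else base["ml_subtype"]
                rows.append({"stratum": stratum, "class": cls})
            prev_stage = cur
    if not rows:
        empty = pd.DataFrame(columns=["advanced", "same", "regressed"])
        return ProgressionReport(counts=empty, proportions=empty)
    tall = pd.DataFrame(rows)
    counts = (
        tall.pivot_table(index="stratum", columns="class", aggfunc="size", fill_value=0)
        .reindex(columns=["advanced", "same", "regressed"], fill_value=0)
    )
    counts.loc["overall"] = counts.sum(axis=0)
    props = counts.div(counts.sum(axis=1), axis=0)
    return ProgressionReport(counts=counts, proportions=props)


def enrichment_test(table: pd.DataFrame) -> EnrichmentTable:
    """Pearson χ² (no continuity correction) on a pathology × subtype table.

    ``table`` is a counts DataFrame (rows: pathology, columns: subtype).
    Small expected counts trigger a warning, not a method switch.
    """
    counts = table.astype(float)
    counts = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table needs >= 2 non-empty rows and columns")
    chi2, p, dof, expected = stats.chi2_contingency(counts.to_numpy(), correction=False)
    if (expected < 5).any():
        logger.warning("χ² expected counts below 5 in %d cells", int((expected < 5).sum()))
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return EnrichmentTable(
        counts=counts.astype(int), row_percent=row_pct, chi2=float(chi2), df=int(dof), p_value=float(p)
    )


def contingency_from_assignments(assignments: pd.DataFrame) -> pd.DataFrame:
    """Pathology × subtype counts over subtypable scans with a pathology label."""
    df = assignments[(~assignments["normal_appearing"]) & (assignments["pathology"] != "none")]
    return pd.crosstab(df["pathology"], df["ml_subtype"])


def regional_comparison(
    adjusted: pd.DataFrame,
    assignments: pd.DataFrame,
    schema: RegionSchema,
    welch: bool = False,
) -> pd.DataFrame:
    """Pairwise subtype t-tests on every baseline adjusted regional volume.

    All schema regions are compared (not only the modeled ROIs). Normal-
    appearing scans are excluded. p-values are Bonferroni-adjusted over the
    full family (regions × subtype pairs). Zero-variance regions are flagged
    and skipped.
    """
    merged = adjusted.merge(
        assignments[["scan_id", "ml_subtype", "normal_appearing"]], on="scan_id"
    )
    merged = merged[~merged["normal_appearing"]]
    if "visit" in merged.columns:
        merged = merged[merged["visit"] == 0]
    subtypes = sorted(merged["ml_subtype"].unique())
    pairs = list(combinations(subtypes, 2))
    m = len(schema.regions) * len(pairs)
    rows = []
    for region in schema.regions:
        for a, b in pairs:
            xa = merged.loc[merged["ml_subtype"] == a, region].to_numpy(dtype=float)
            xb = merged.loc[merged["ml_subtype"] == b, region].to_numpy(dtype=float)
            if len(xa) < 2 or len(xb) < 2:
                raise ValueError(f"subtype group with <2 scans for region {region!r}")
            if np.var(xa, ddof=1) == 0 and np.var(xb, ddof=1) == 0:
                logger.warning("region %r has zero variance; test skipped", region)
                continue
            t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
            rows.append(
                {
                    "region": region,
                    "subtype_a": a,
                    "subtype_b": b,
                    "mean_a": float(xa.mean()),
                    "mean_b": float(xb.mean()),
                    "lower_in": a if xa.mean() < xb.mean() else b,
                    "t": float(t),
                    "p": float(p),
                    "p_bonferroni": min(1.0, float(p) * m),
                }
            )
    return pd.DataFrame(rows)


def laterality_comparison(
    scans: pd.DataFrame,
    assignments: pd.DataFrame,
    schema: RegionSchema,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Laterality-index summaries per subtype/visit plus pairwise t-tests.

    Returns (summary, tests): per-group mean (SD) LI at baseline and
    follow-up, pairwise between-subtype tests at baseline and baseline-vs-
    follow-up tests within subtype, all Bonferroni-adjusted over the family.
    """
    merged = scans.merge(
        assignments[["scan_id", "ml_subtype", "normal_appearing"]], on="scan_id"
    )
    merged = merged[~merged["normal_appearing"]].copy()
    merged["li"] = [laterality_index(row, schema) for _, row in merged.iterrows()]
    merged["phase"] = np.where(merged["visit"] == 0, "baseline", "followup")

    summary = (
        merged.groupby(["ml_subtype", "phase"])["li"]
        .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )

    subtypes = sorted(merged["ml_subtype"].unique())
    between = [
        (f"subtype{a}", f"subtype{b}",
         merged.loc[(merged["ml_subtype"] == a) & (merged["phase"] == "baseline"), "li"].to_numpy(),
         merged.loc[(merged["ml_subtype"] == b) & (merged["phase"] == "baseline"), "li"].to_numpy())
        for a, b in combinations(subtypes, 2)
    ]
    within = [
        (f"subtype{c}_baseline", f"subtype{c}_followup",
         merged.loc[(merged["ml_subtype"] == c) & (merged["phase"] == "baseline"), "li"].to_numpy(),
         merged.loc[(merged["ml_subtype"] == c) & (merged["phase"] == "followup"), "li"].to_numpy())
        for c in subtypes
    ]
    family = between + within
    m = len(family)
    rows = []
    for name_a, name_b, xa, xb in family:
        if len(xa) < 2 or len(xb) < 2:
            logger.warning("group with <2 scans skipped: %s vs %s", name_a, name_b)
            continue
        if np.var(xa, ddof=1) == 0 and np.var(xb, ddof=1) == 0:
            logger.warning("zero LI variance: %s vs %s; test skipped", name_a, name_b)
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=True)
        rows.append(
            {
                "group_a": name_a,
                "group_b": name_b,
                "mean_a": float(xa.mean()),
                "mean_b": float(xb.mean()),
                "t": float(t),
                "p": float(p),
                "p_bonferroni": min(1.0, float(p) * m),
            }
        )
    return summary, pd.DataFrame(rows)
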