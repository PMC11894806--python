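"""Synthetic cohort generator with known subtype/stage ground truth.

Emulates the statistical structure of a multi-site volumetric MRI study of
corticobasal syndrome: ~252 controls and ~135 cases scanned at 1.5T or 3T on
two manufacturers, linear covariate effects (age, sex, TIV, scanner) on
regional volumes, 2–3 latent atrophy subtypes with distinct event orderings,
uniform stage occupancy among cases, pathology labels (CBD/PSP/AD/IDT) mixed
across subtypes, and ~1-year follow-up scans with non-negative stage
increments.

Generative recipe per scan: latent z-scores come from the subtype's
trajectory at the latent stage plus Gaussian noise (controls: zero signal
plus noise); combined volumes are control mean − z·control SD; covariate
effects are then added; paired regions are split into left/right halves with
a configurable asymmetry fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from zsustain.model import EventGrid, EventSequence, trajectory_matrix
from zsustain.schema import RegionSchema, SchemaError, default_schema

__all__ = [
    "CovariateEffects",
    "CohortSettings",
    "GroundTruth",
    "default_settings",
    "default_grid",
    "default_sequences",
    "generate_cohort",
    "generate_followups",
]

PATHOLOGIES = ["CBD", "PSP", "AD", "IDT"]


@dataclass(frozen=True)
class CovariateEffects:
    """Linear covariate effects on a region's combined volume.

    age: mm³ per year (about a reference of 66 y); sex_offset: mm³ added for
    female; tiv_slope: mm³ per mm³ of TIV about its reference; field/
    manufacturer offsets: mm³ added for 3T / the second manufacturer.
    """

    age: float = 0.0
    sex_offset: float = 0.0
    tiv_slope: float = 0.0
    field_offset: float = 0.0
    manufacturer_offset: float = 0.0


@dataclass(frozen=True)
class CohortSettings:
    """Everything needed to generate a cohort deterministically from a seed."""

    n_controls: int = 252
    n_cases: int = 135
    schema: RegionSchema = field(default_factory=default_schema)
    grid: EventGrid | None = None
    true_sequences: tuple[EventSequence, ...] = ()
    true_fractions: tuple[float, ...] = (0.46, 0.54)
    region_means: dict[str, float] = field(default_factory=dict)
    region_sds: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, CovariateEffects] = field(default_factory=dict)
    noise_sd: float = 1.0
    #: left/right asymmetry fraction per subtype (0 = symmetric); controls 0
    subtype_asymmetry: tuple[float, ...] = (0.0, 0.0)
    #: per-scan, per-region jitter of the left/right split fraction
    lr_noise_sd: float = 0.01
    #: P(pathology) marginal and P(subtype | pathology) rows
    pathology_marginal: dict[str, float] = field(
        default_factory=lambda: {"CBD": 12 / 135, "PSP": 6 / 135, "AD": 34 / 135, "IDT": 83 / 135}
    )
    pathology_mixing: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "CBD": (0.75, 0.25),
            "PSP": (0.83, 0.17),
            "AD": (0.19, 0.81),
            "IDT": (0.49, 0.51),
        }
    )
    followup_fraction: float = 0.5
    #: ("constant", k) or ("poisson", rate): stages advanced per follow-up interval
    followup_stage_increment: tuple[str, float] = ("poisson", 1.5)
    followup_interval: float = 1.04
    #: P(1, 2, 3 follow-up visits) for cases selected for follow-up
    followup_visit_probs: tuple[float, ...] = (0.39, 0.58, 0.03)
    age_mean: float = 66.0
    age_sd: float = 8.0
    tiv_mean: float = 1.4e6
    tiv_sd: float = 1.3e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls <= 0 or self.n_cases <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if abs(sum(self.true_fractions) - 1.0) > 1e-12:
            raise ValueError("true_fractions must sum to 1")
        kind, param = self.followup_stage_increment
        if kind not in ("constant", "poisson"):
            raise ValueError(f"unknown increment distribution {kind!r}")
        if param < 0:
            raise ValueError("stage increment parameter must be non-negative")


@dataclass
class GroundTruth:
    """Latent labels per case and per follow-up scan."""

    #: baseline: scan_id -> (subtype index, stage, pathology)
    cases: pd.DataFrame
    #: follow-ups: scan_id -> (subject_id, visit, stage)
    followups: pd.DataFrame | None = None


# -- defaults emulating the study conditions ---------------------------------

#: the 19 regions a moderate-effect-size screen retains (of the 24)
DEFAULT_ROIS = [
    "medulla", "pons", "scp", "midbrain",
    "cerebellar_cortex", "dentate_nucleus",
    "thalamus", "globus_pallidus", "caudate", "putamen", "ventral_dc", "amygdala",
    "corpus_callosum", "frontal_anterior", "frontal_posterior", "insula",
    "temporal", "parietal", "occipital",
]

#: subcortical-first ordering (brainstem → deep grey → posterior cortex)
_SUBCORTICAL_FIRST = [
    "scp", "midbrain", "pons", "medulla", "ventral_dc", "dentate_nucleus",
    "thalamus", "frontal_posterior", "insula", "parietal", "occipital",
    "globus_pallidus", "putamen", "caudate", "cerebellar_cortex",
    "corpus_callosum", "amygdala", "frontal_anterior", "temporal",
]

#: fronto-parieto-occipital-first ordering (posterior cortex → deep grey → brainstem)
_CORTICAL_FIRST = [
    "parietal", "frontal_posterior", "insula", "occipital", "temporal",
    "putamen", "globus_pallidus", "corpus_callosum", "frontal_anterior",
    "caudate", "amygdala", "cerebellar_cortex", "thalamus", "ventral_dc",
    "dentate_nucleus", "midbrain", "pons", "scp", "medulla",
]

#: plausible combined control volumes, mm³ (order-of-magnitude realistic)
_DEFAULT_MEANS = {
    "medulla": 4600, "pons": 14500, "scp": 300, "midbrain": 6200,
    "cerebellar_cortex": 104000, "dentate_nucleus": 780, "vermis": 9500,
    "thalamus": 15800, "globus_pallidus": 3100, "caudate": 7200,
    "putamen": 9400, "ventral_dc": 8200, "hippocampus": 7700,
    "amygdala": 2400, "nucleus_accumbens": 900, "basal_forebrain": 700,
    "cingulate": 21000, "corpus_callosum": 18500, "frontal_anterior": 95000,
    "frontal_posterior": 78000, "insula": 14000, "temporal": 110000,
    "parietal": 92000, "occipital": 66000,
}


def default_grid(rois: list[str] | None = None, thresholds=(1.0, 2.0), z_max: float = 5.0) -> EventGrid:
    """Event grid over the default ROI panel (two thresholds per region)."""
    return EventGrid.create(rois or DEFAULT_ROIS, thresholds=thresholds, z_max=z_max)


def _ordering_to_sequence(region_order: list[str], grid: EventGrid) -> EventSequence:
    """Interleave each region's threshold events following a region ordering.

    The first threshold of every region occurs in ``region_order``; higher
    thresholds follow in the same region order, round by round.
    """
    unknown = [r for r in region_order if r not in grid.biomarkers]
    if unknown:
        raise SchemaError(f"ordering references unknown regions: {unknown}")
    max_th = max(len(t) for t in grid.thresholds)
    events = {(grid.biomarkers[i], j): k for k, (i, j) in enumerate(grid.events)}
    order = []
    for j in range(max_th):
        for r in region_order:
            if (r, j) in events:
                order.append(events[(r, j)])
    return EventSequence(order, grid)


def default_sequences(grid: EventGrid) -> tuple[EventSequence, EventSequence]:
    """Two latent subtypes: subcortical-first and fronto-parieto-occipital-first."""
    names = [r for r in _SUBCORTICAL_FIRST if r in grid.biomarkers]
    names2 = [r for r in _CORTICAL_FIRST if r in grid.biomarkers]
    return _ordering_to_sequence(names, grid), _ordering_to_sequence(names2, grid)


def _default_effects(schema: RegionSchema) -> dict[str, CovariateEffects]:
    eff = {}
    for r in schema.regions:
        m = _DEFAULT_MEANS[r]
        eff[r] = CovariateEffects(
            age=-0.003 * m,
            sex_offset=-0.06 * m,
            tiv_slope=0.4 * m / 1.4e6,
            field_offset=0.02 * m,
            manufacturer_offset=0.01 * m,
        )
    return eff


def default_settings(**overrides) -> CohortSettings:
    """Study-condition defaults: 252 controls, 135 cases, two latent subtypes."""
    schema = overrides.pop("schema", default_schema())
    grid = overrides.pop("grid", None) or default_grid()
    seqs = overrides.pop("true_sequences", None) or default_sequences(grid)
    means = overrides.pop("region_means", None) or dict(_DEFAULT_MEANS)
    sds = overrides.pop("region_sds", None) or {r: 0.08 * m for r, m in means.items()}
    effects = overrides.pop("covariate_effects", None) or _default_effects(schema)
    return CohortSettings(
        schema=schema,
        grid=grid,
        true_sequences=tuple(seqs),
        region_means=means,
        region_sds=sds,
        covariate_effects=effects,
        **overrides,
    )


def _sample_covariates(rng: np.random.Generator, n: int, s: CohortSettings) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age_at_scan": np.clip(rng.normal(s.age_mean, s.age_sd, n), 40, 95),
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
            "tiv": np.clip(rng.normal(s.tiv_mean, s.tiv_sd, n), 8e5, 2.2e6),
            "field_strength": np.where(rng.random(n) < 0.7, "3T", "1.5T"),
            "manufacturer": np.where(rng.random(n) < 0.5, "Siemens", "GE"),
        }
    )


def _covariate_shift(cov: pd.DataFrame, s: CohortSettings, region: str) -> np.ndarray:
    e = s.covariate_effects.get(region, CovariateEffects())
    return (
        e.age * (cov["age_at_scan"].to_numpy() - s.age_mean)
        + e.sex_offset * (cov["sex"].to_numpy() == "F")
        + e.tiv_slope * (cov["tiv"].to_numpy() - s.tiv_mean)
        + e.field_offset * (cov["field_strength"].to_numpy() == "3T")
        + e.manufacturer_offset * (cov["manufacturer"].to_numpy() == "Siemens")
    )


def _emit_volumes(
    z_by_region: dict[str, np.ndarray],
    cov: pd.DataFrame,
    s: CohortSettings,
    asym: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Convert latent z-scores to raw volume columns (left/right for paired)."""
    n = len(cov)
    out = {}
    for region in s.schema.regions:
        z = z_by_region.get(region, np.zeros(n))
        combined = s.region_means[region] - z * s.region_sds[region]
        combined = combined + _covariate_shift(cov, s, region)
        if s.schema.is_paired(region):
            a = asym + (rng.normal(0.0, s.lr_noise_sd, n) if s.lr_noise_sd > 0 else 0.0)
            out[f"{region}_L"] = combined * (0.5 + a / 2.0)
            out[f"{region}_R"] = combined * (0.5 - a / 2.0)
        else:
            out[region] = combined
    return pd.DataFrame(out)


def generate_cohort(settings: CohortSettings) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a baseline cohort of controls and cases.

    Returns a scan table (one row per scan: identifiers, group, pathology,
    covariates, raw per-region volumes with ``_L``/``_R`` columns for paired
    regions) and the latent ground truth for cases. Deterministic given
    ``settings.seed``.
    """
    s = settings
    grid = s.grid
    if grid is None or not s.true_sequences:
        raise ValueError("settings must carry an event grid and true sequences")
    grid_regions = set(grid.biomarkers)
    unknown = grid_regions - set(s.schema.regions)
    if unknown:
        raise SchemaError(f"grid references regions outside the schema: {sorted(unknown)}")
    if len(s.true_fractions) != len(s.true_sequences):
        raise ValueError("one mixture fraction per true sequence required")

    rng = np.random.default_rng(s.seed)
    n_events = grid.n_events

    # controls: zero latent signal plus noise
    cov_ctrl = _sample_covariates(rng, s.n_controls, s)
    z_ctrl = {
        r: rng.normal(0.0, s.noise_sd, s.n_controls) for r in s.schema.regions
    }
    vols_ctrl = _emit_volumes(z_ctrl, cov_ctrl, s, np.zeros(s.n_controls), rng)

    # cases: subtype ~ fractions, stage ~ uniform{0..N}
    cov_case = _sample_covariates(rng, s.n_cases, s)
    subtype = rng.choice(len(s.true_sequences), size=s.n_cases, p=np.asarray(s.true_fractions))
    stage = rng.integers(0, n_events + 1, size=s.n_cases)
    trajs = [trajectory_matrix(seq, grid) for seq in s.true_sequences]
    z_case: dict[str, np.ndarray] = {}
    bio_index = {name: i for i, name in enumerate(grid.biomarkers)}
    for r in s.schema.regions:
        noise = rng.normal(0.0, s.noise_sd, s.n_cases)
        if r in bio_index:
            signal = np.array(
                [trajs[c][k, bio_index[r]] for c, k in zip(subtype, stage)]
            )
            z_case[r] = signal + noise
        else:
            z_case[r] = noise

    # pathology sampled so that P(subtype | pathology) follows the mixing table:
    # P(pathology | subtype) ∝ P(subtype|path) * P(path)
    asym_levels = np.asarray(s.subtype_asymmetry, dtype=float)
    if len(asym_levels) < len(s.true_sequences):
        raise ValueError("one asymmetry level per subtype required")
    marg = np.array([s.pathology_marginal[p] for p in PATHOLOGIES])
    mix = np.array([s.pathology_mixing[p] for p in PATHOLOGIES])  # (P, C)
    pathology = np.empty(s.n_cases, dtype=object)
    for c in range(len(s.true_sequences)):
        idx = np.flatnonzero(subtype == c)
        w = mix[:, c] * marg
        w = w / w.sum()
        pathology[idx] = rng.choice(PATHOLOGIES, size=len(idx), p=w)

    vols_case = _emit_volumes(z_case, cov_case, s, asym_levels[subtype], rng)

    def _assemble(cov, vols, group, start):
        n = len(cov)
        meta = pd.DataFrame(
            {
                "subject_id": [f"{group[:4]}{start + i:04d}" for i in range(n)],
                "scan_id": [f"{group[:4]}{start + i:04d}_v0" for i in range(n)],
                "visit": 0,
                "group": group,
                "pathology": "none",
            }
        )
        return pd.concat([meta, cov, vols], axis=1)

    controls = _assemble(cov_ctrl, vols_ctrl, "control", 0)
    cases = _assemble(cov_case, vols_case, "case", 0)
    cases["pathology"] = pathology
    scans = pd.concat([controls, cases], ignore_index=True)

    truth = GroundTruth(
        cases=pd.DataFrame(
            {
                "scan_id": cases["scan_id"],
                "subject_id": cases["subject_id"],
                "subtype": subtype,
                "stage": stage,
                "pathology": pathology,
            }
        ).set_index("scan_id")
    )
    return scans, truth


def latent_zscore_matrix(truth_table: pd.DataFrame, settings: CohortSettings) -> np.ndarray:
    """Noise-free z-scores implied by latent (subtype, stage) labels.

    ``truth_table`` must carry ``subtype`` and ``stage`` columns (baseline
    or follow-up truth). Rows are in table order; columns follow the grid's
    biomarker order. Useful for exercising staging logic free of sampling
    noise.
    """
    grid = settings.grid
    trajs = [trajectory_matrix(seq, grid) for seq in settings.true_sequences]
    return np.array(
        [trajs[int(c)][int(k)] for c, k in zip(truth_table["subtype"], truth_table["stage"])]
    )


def _draw_increment(rng: np.random.Generator, spec: tuple[str, float], n: int) -> np.ndarray:
    kind, param = spec
    if kind == "constant":
        if param < 0:
            raise ValueError("constant stage increment must be non-negative")
        return np.full(n, int(param))
    if kind == "poisson":
        return rng.poisson(param, n)
    raise ValueError(f"unknown increment distribution {kind!r}")


def generate_followups(
    cohort: pd.DataFrame, truth: GroundTruth, settings: CohortSettings
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate 1–3 follow-up scans for a seeded subset of cases.

    Latent stage advances by non-negative draws from the configured increment
    distribution (capped at N); scanner covariates are held fixed per subject
    and age advances by the follow-up interval. Returns the follow-up scan
    table and the truth extended with per-visit latent stages.
    """
    s = settings
    grid = s.grid
    rng = np.random.default_rng(s.seed + 1)
    n_events = grid.n_events
    cases = cohort[cohort["group"] == "case"].set_index("scan_id")
    base = truth.cases

    n_sel = int(round(s.followup_fraction * len(base)))
    selected = rng.choice(base.index.to_numpy(), size=n_sel, replace=False)
    visit_counts = rng.choice(
        [1, 2, 3], size=n_sel, p=np.asarray(s.followup_visit_probs)
    )
    trajs = [trajectory_matrix(seq, grid) for seq in s.true_sequences]
    bio_index = {name: i for i, name in enumerate(grid.biomarkers)}

    rows_meta, rows_cov, z_cols, stages_rec = [], [], [], []
    for scan_id, n_visits in zip(selected, visit_counts):
        info = base.loc[scan_id]
        baseline_row = cases.loc[scan_id]
        stage = int(info["stage"])
        for v in range(1, n_visits + 1):
            inc = int(_draw_increment(rng, s.followup_stage_increment, 1)[0])
            stage = min(stage + inc, n_events)
            rows_meta.append(
                {
                    "subject_id": info["subject_id"],
                    "scan_id": f"{info['subject_id']}_v{v}",
                    "visit": v,
                    "group": "case",
                    "pathology": info["pathology"],
                }
            )
            rows_cov.append(
                {
                    "age_at_scan": baseline_row["age_at_scan"] + v * s.followup_interval,
                    "sex": baseline_row["sex"],
                    "tiv": baseline_row["tiv"],
                    "field_strength": baseline_row["field_strength"],
                    "manufacturer": baseline_row["manufacturer"],
                }
            )
            z_cols.append((int(info["subtype"]), stage))
            stages_rec.append(
                {
                    "scan_id": f"{info['subject_id']}_v{v}",
                    "subject_id": info["subject_id"],
                    "visit": v,
                    "stage": stage,
                    "subtype": int(info["subtype"]),
                }
            )

    if not rows_meta:
        empty = pd.DataFrame(columns=cohort.columns)
        return empty, GroundTruth(cases=base, followups=pd.DataFrame())

    cov = pd.DataFrame(rows_cov)
    n = len(cov)
    z_by_region = {}
    for r in s.schema.regions:
        noise = rng.normal(0.0, s.noise_sd, n)
        if r in bio_index:
            signal = np.array([trajs[c][k, bio_index[r]] for c, k in z_cols])
            z_by_region[r] = signal + noise
        else:
            z_by_region[r] = noise
    asym_levels = np.asarray(s.subtype_asymmetry, dtype=float)
    asym = asym_levels[[c for c, _ in z_cols]]
    vols = _emit_volumes(z_by_region, cov, s, asym, rng)
    followups = pd.concat([pd.DataFrame(rows_meta), cov, vols], axis=1)
    truth_fu = pd.DataFrame(stages_rec).set_index("scan_id")
    return followups, GroundTruth(cases=base, followups=truth_fu)
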