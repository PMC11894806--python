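"""Maximum-likelihood subtype and stage assignment of individual scans.

Subtype first: ĉ = argmax_c f_c · p(x | S_c); stage conditional on ĉ:
k̂ = argmax_k P(k | x, S_ĉ). Ties break toward the lower index/stage. A scan
assigned stage 0 is "normal appearing" — no detectable atrophy relative to
controls — and carries no subtype label in reports. The same trained model
stages baseline and follow-up scans; follow-up z-scores must come from the
baseline harmonization (no refit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from zsustain.model import SubtypeModel, stage_posteriors

__all__ = ["Assignment", "assign_scan", "assign_cohort", "assignments_to_frame"]


@dataclass
class Assignment:
    """One scan's subtype/stage assignment under a trained model."""

    scan_id: str
    subtype_posterior: np.ndarray
    ml_subtype: int
    subtype_prob: float
    stage_posterior: np.ndarray
    ml_stage: int
    normal_appearing: bool

    @property
    def subtype_label(self) -> int | None:
        """Reported subtype: None for normal-appearing scans."""
        return None if self.normal_appearing else self.ml_subtype


def _assign_matrix(X: np.ndarray, model: SubtypeModel) -> list[tuple[np.ndarray, int, np.ndarray, int]]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.grid.n_biomarkers:
        raise ValueError(
            f"z-vector has {X.shape[1]} entries, model expects {model.grid.n_biomarkers}"
        )
    L = model.subject_loglik_matrix(X)
    with np.errstate(divide="ignore"):
        logw = L + np.log(model.fractions)[None, :]
    post = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    out = []
    for s in range(X.shape[0]):
        c_hat = int(np.argmax(post[s]))  # argmax takes the first (lowest) maximum
        stage_post = stage_posteriors(X[s : s + 1], model.sequences[c_hat], model.grid, model.noise)[0]
        k_hat = int(np.argmax(stage_post))
        out.append((post[s], c_hat, stage_post, k_hat))
    return out


def assign_scan(x: np.ndarray, model: SubtypeModel, scan_id: str = "") -> Assignment:
    """Assign one z-vector to its maximum-likelihood subtype and stage."""
    post, c_hat, stage_post, k_hat = _assign_matrix(np.atleast_2d(x), model)[0]
    return Assignment(
        scan_id=scan_id,
        subtype_posterior=post,
        ml_subtype=c_hat,
        subtype_prob=float(post[c_hat]),
        stage_posterior=stage_post,
        ml_stage=k_hat,
        normal_appearing=(k_hat == 0),
    )


def assign_cohort(zscores: pd.DataFrame, model: SubtypeModel) -> list[Assignment]:
    """Assign every scan of a z-score table with one trained model.

    ``zscores`` must carry the model's biomarker columns (extra metadata
    columns pass through to the output identifiers) and, if present, a
    ``scan_id`` column.
    """
    missing = [b for b in model.grid.biomarkers if b not in zscores.columns]
    if missing:
        raise ValueError(f"z-score table lacks model biomarkers: {missing}")
    if len(zscores) == 0:
        return []
    X = zscores[list(model.grid.biomarkers)].to_numpy(dtype=float)
    ids = (
        zscores["scan_id"].astype(str).tolist()
        if "scan_id" in zscores.columns
        else [str(i) for i in range(len(zscores))]
    )
    results = _assign_matrix(X, model)
    return [
        Assignment(
            scan_id=sid,
            subtype_posterior=post,
            ml_subtype=c_hat,
            subtype_prob=float(post[c_hat]),
            stage_posterior=stage_post,
            ml_stage=k_hat,
            normal_appearing=(k_hat == 0),
        )
        for sid, (post, c_hat, stage_post, k_hat) in zip(ids, results)
    ]


def assignments_to_frame(assignments: list[Assignment], meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate assignments; normal-appearing scans get a blank subtype label.

    ``meta`` (optional) is joined on ``scan_id`` to carry subject/visit/
    pathology columns alongside.
    """
    rows = [
        {
            "scan_id": a.scan_id,
            "ml_subtype": -1 if a.normal_appearing else a.ml_subtype,
            "subtype_prob": a.subtype_prob,
            "ml_stage": a.ml_stage,
            "normal_appearing": a.normal_appearing,
            "subtype_posterior": json.dumps(np.round(a.subtype_posterior, 6).tolist()),
        }
        for a in assignments
    ]
    df = pd.DataFrame(rows)
    if meta is not None:
        keep = [c for c in ("subject_id", "visit", "group", "pathology") if c in meta.columns]
        df = meta[["scan_id"] + keep].merge(df, on="scan_id", how="right")
    return df
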