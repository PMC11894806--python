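"""Shared fixtures: tiny grids, reversed-order subtype cohorts, brute-force oracles."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest

from zsustain.model import (
    EventGrid,
    EventSequence,
    NoiseModel,
    sequence_is_valid,
    subject_logliks,
    trajectory_matrix,
)


@pytest.fixture
def grid6x2() -> EventGrid:
    """Six biomarkers, two thresholds each (the recovery-experiment grid)."""
    return EventGrid.create([f"b{i}" for i in range(6)], thresholds=(2.0, 4.0), z_max=5.0)


def reversed_sequences(grid: EventGrid) -> tuple[EventSequence, EventSequence]:
    """Two subtypes whose region orderings are exact reverses of each other."""
    lookup = {e: k for k, e in enumerate(grid.events)}
    nb = grid.n_biomarkers
    nth = len(grid.thresholds[0])
    fwd = [lookup[(i, j)] for j in range(nth) for i in range(nb)]
    rev = [lookup[(i, j)] for j in range(nth) for i in reversed(range(nb))]
    return EventSequence(fwd, grid), EventSequence(rev, grid)


def two_subtype_cohort(
    grid: EventGrid,
    n: int = 300,
    frac_second: float = 0.4,
    sigma: float = 1.0,
    seed: int = 0,
    stage_range: tuple[int, int] | None = None,
):
    """z-matrix sampled from two reversed orderings; returns (X, subtype, stage)."""
    sA, sB = reversed_sequences(grid)
    tA, tB = trajectory_matrix(sA, grid), trajectory_matrix(sB, grid)
    rng = np.random.default_rng(seed)
    lo, hi = stage_range or (0, grid.n_events)
    subtype = (rng.random(n) < frac_second).astype(int)
    stage = rng.integers(lo, hi + 1, n)
    X = np.array([(tB if c else tA)[k] for c, k in zip(subtype, stage)])
    X = X + rng.normal(0.0, sigma, X.shape)
    return X, subtype, stage


def enumerate_valid_orderings(grid: EventGrid):
    """All event orderings respecting within-biomarker threshold order (N small)."""
    n = grid.n_events
    for perm in permutations(range(n)):
        order = np.asarray(perm, dtype=np.intp)
        if sequence_is_valid(order, grid):
            yield order


def brute_force_best_loglik(X: np.ndarray, grid: EventGrid, noise: NoiseModel) -> float:
    """Global maximum of the summed subject log-likelihood over all valid orderings."""
    best = -np.inf
    for order in enumerate_valid_orderings(grid):
        seq = EventSequence(order, grid)
        best = max(best, float(subject_logliks(X, seq, grid, noise).sum()))
    return best


def random_small_grid(rng: np.random.Generator, n_max_events: int = 5) -> EventGrid:
    """Random grid with at most ``n_max_events`` total events."""
    n_bio = int(rng.integers(1, 4))
    budget = int(rng.integers(n_bio, n_max_events + 1))
    counts = np.ones(n_bio, dtype=int)
    for _ in range(budget - n_bio):
        counts[rng.integers(n_bio)] += 1
    thresholds = tuple(
        tuple(np.round(np.sort(rng.uniform(0.5, 4.0, c)) + np.arange(c) * 0.1, 3))
        for c in counts
    )
    z_max = tuple(float(t[-1]) + float(rng.uniform(0.5, 2.0)) for t in thresholds)
    return EventGrid(
        biomarkers=tuple(f"m{i}" for i in range(n_bio)), thresholds=thresholds, z_max=z_max
    )
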