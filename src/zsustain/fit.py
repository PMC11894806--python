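"""Fitting the subtype mixture of event sequences.

Four pieces:

1. ``optimize_sequence`` — greedy coordinate ascent over event orderings
   (remove each event, reinsert at the best valid position) from multiple
   random valid starts, maximizing the responsibility-weighted stage-marginal
   log-likelihood.
2. ``fit_subtypes`` — hierarchical model growth: the C-subtype model is
   seeded by splitting one cluster of the fitted (C−1)-model in two, the
   children starting from independent random valid sequences, refined by EM
   (E: posterior responsibilities; M: re-optimize each sequence under its
   responsibilities, update mixture fractions), keeping the best split,
   then a final joint EM.
3. ``mcmc_sample`` — Metropolis–Hastings over sequences (single-event
   relocation to a valid position) and mixture fractions (Gaussian jitter,
   renormalized), yielding positional-variance matrices.
4. ``cross_validate`` — K-fold out-of-sample log-likelihoods and
   CVIC(C) = Σ_folds −2·loglik_test, minimized to choose the subtype count.

All randomness flows from a single integer seed; within-biomarker threshold
order is a hard constraint never violated by proposals or search moves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from zsustain.model import (
    EventGrid,
    EventSequence,
    NoiseModel,
    SubtypeModel,
    mixture_loglik,
)

__all__ = [
    "FitSettings",
    "CVResult",
    "PositionalVariance",
    "optimize_sequence",
    "fit_subtypes",
    "mcmc_sample",
    "cross_validate",
]

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FitSettings:
    """Search, EM, MCMC and cross-validation configuration."""

    n_random_starts: int = 25
    max_greedy_passes: int = 50
    em_max_iter: int = 100
    em_tol: float = 1e-6
    mcmc_iterations: int = 100_000
    mcmc_burnin_frac: float = 0.1
    #: probability of a sequence move (vs fraction jitter) per MCMC iteration
    mcmc_seq_move_prob: float = 0.9
    mcmc_fraction_step: float = 0.01
    #: thin retained samples to at most this many (memory bound); 0 = keep all
    mcmc_max_retained: int = 10_000
    c_max: int = 3
    k_folds: int = 10
    n_split_attempts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_random_starts, self.max_greedy_passes, self.em_max_iter,
               self.mcmc_iterations, self.c_max, self.k_folds) < 1:
            raise ValueError("all iteration/count settings must be >= 1")
        if self.em_tol <= 0:
            raise ValueError("EM tolerance must be positive")


@dataclass
class CVResult:
    """Per-fold out-of-sample log-likelihoods and the CVIC per subtype count."""

    #: DataFrame indexed by fold, one column per C ("C=1", ...), test loglik
    fold_logliks: pd.DataFrame
    cvic: pd.Series
    selected_c: int


@dataclass
class PositionalVariance:
    """Per subtype, P(event e at position p) across retained MCMC samples."""

    matrices: list[np.ndarray]

    def __post_init__(self) -> None:
        for m in self.matrices:
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("positional-variance rows must sum to 1")


# ---------------------------------------------------------------------------
# fast internals operating on raw order arrays (no per-move object creation)


class _GridCache:
    """Precomputed event arrays for fast trajectory evaluation."""

    def __init__(self, grid: EventGrid, noise: NoiseModel):
        self.grid = grid
        self.bio, self.th_idx, self.zs = grid.event_arrays()
        self.n = grid.n_events
        self.b = grid.n_biomarkers
        self.z_max = np.asarray(grid.z_max, dtype=float)
        self.sigma = noise.sigma
        self.events_of = [np.flatnonzero(self.bio == i) for i in range(self.b)]
        self.log_norm = -np.sum(np.log(self.sigma)) - 0.5 * self.b * _LOG_2PI
        self.stages = np.arange(self.n + 1, dtype=float)

    def trajectory(self, order: np.ndarray) -> np.ndarray:
        pos = np.empty(self.n, dtype=np.intp)
        pos[order] = np.arange(1, self.n + 1)
        out = np.empty((self.n + 1, self.b))
        for i in range(self.b):
            ev = self.events_of[i]
            p = pos[ev].astype(float)
            xs = np.concatenate(([0.0], p))
            ys = np.concatenate(([0.0], self.zs[ev]))
            if p[-1] < self.n:
                xs = np.concatenate((xs, [float(self.n)]))
                ys = np.concatenate((ys, [self.z_max[i]]))
            out[:, i] = np.interp(self.stages, xs, ys)
        return out

    def subject_logliks(self, X: np.ndarray, order: np.ndarray) -> np.ndarray:
        traj = self.trajectory(order)
        diff = (X[:, None, :] - traj[None, :, :]) / self.sigma
        ld = -0.5 * np.einsum("skb,skb->sk", diff, diff) + self.log_norm
        return logsumexp(ld, axis=1) - np.log(self.n + 1)

    def weighted_loglik(self, X: np.ndarray, order: np.ndarray, weights: np.ndarray) -> float:
        return float(weights @ self.subject_logliks(X, order))


def _random_valid_order(cache: _GridCache, rng: np.random.Generator) -> np.ndarray:
    """Uniform random keys, sorted within each biomarker to respect threshold order."""
    keys = rng.random(cache.n)
    for ev in cache.events_of:
        keys[ev] = np.sort(keys[ev])
    return np.argsort(keys, kind="stable").astype(np.intp)


def _valid_slots(cache: _GridCache, remaining: np.ndarray, event: int) -> range:
    """Insertion slots for `event` into `remaining` respecting threshold order."""
    i = cache.bio[event]
    j = cache.th_idx[event]
    lo, hi = 0, len(remaining)
    sib = cache.events_of[i]
    if j > 0:
        prev = sib[j - 1]
        lo = int(np.flatnonzero(remaining == prev)[0]) + 1
    if j < len(sib) - 1:
        nxt = sib[j + 1]
        hi = int(np.flatnonzero(remaining == nxt)[0])
    return range(lo, hi + 1)


def _greedy(
    X: np.ndarray,
    cache: _GridCache,
    weights: np.ndarray,
    order: np.ndarray,
    max_passes: int,
) -> tuple[np.ndarray, float]:
    """Repeated remove-and-best-reinsert passes until a full pass changes nothing."""
    order = order.copy()
    best_ll = cache.weighted_loglik(X, order, weights)
    for _ in range(max_passes):
        changed = False
        for event in range(cache.n):
            cur = int(np.flatnonzero(order == event)[0])
            remaining = np.delete(order, cur)
            best_slot, best_slot_ll = cur, best_ll
            for slot in _valid_slots(cache, remaining, event):
                if slot == cur:
                    continue
                cand = np.insert(remaining, slot, event)
                ll = cache.weighted_loglik(X, cand, weights)
                if ll > best_slot_ll + 1e-12:
                    best_slot, best_slot_ll = slot, ll
            if best_slot != cur:
                order, best_ll = np.insert(remaining, best_slot, event), best_slot_ll
                changed = True
        if not changed:
            break
    return order, best_ll


def optimize_sequence(
    X: np.ndarray,
    grid: EventGrid,
    noise: NoiseModel,
    weights: np.ndarray | None = None,
    settings: FitSettings | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[EventSequence, float]:
    """Best event ordering by greedy coordinate ascent over random restarts.

    Maximizes Σ_subjects w_s · log p(x_s | sequence); returns the best
    sequence and its weighted log-likelihood. Deterministic given the
    settings seed (or a supplied generator).
    """
    settings = settings or FitSettings()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty data matrix")
    if grid.n_events == 0:
        raise ValueError("grid defines no events")
    weights = np.ones(X.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    if np.any(weights < 0) or np.any(weights > 1):
        raise ValueError("weights must lie in [0, 1]")
    rng = rng or np.random.default_rng(settings.seed)
    cache = _GridCache(grid, noise)
    if cache.n == 1:
        order = np.array([0], dtype=np.intp)
        return EventSequence(order, grid), cache.weighted_loglik(X, order, weights)
    best_order, best_ll = None, -np.inf
    for _ in range(settings.n_random_starts):
        start = _random_valid_order(cache, rng)
        order, ll = _greedy(X, cache, weights, start, settings.max_greedy_passes)
        if ll > best_ll:
            best_order, best_ll = order, ll
    return EventSequence(best_order, grid), best_ll


# ---------------------------------------------------------------------------
# EM over C clusters


def _responsibilities(L: np.ndarray, fractions: np.ndarray) -> tuple[np.ndarray, float]:
    """Posterior responsibilities and total mixture loglik from a (n, C) loglik matrix."""
    with np.errstate(divide="ignore"):
        logw = L + np.log(fractions)[None, :]
    norm = logsumexp(logw, axis=1)
    return np.exp(logw - norm[:, None]), float(norm.sum())


def _em_refine(
    X: np.ndarray,
    cache: _GridCache,
    orders: list[np.ndarray],
    fractions: np.ndarray,
    settings: FitSettings,
) -> tuple[list[np.ndarray], np.ndarray, float]:
    """Joint EM: E-step responsibilities, M-step greedy re-optimization per cluster."""
    n = X.shape[0]
    L = np.column_stack([cache.subject_logliks(X, o) for o in orders])
    _, ll = _responsibilities(L, fractions)
    for _ in range(settings.em_max_iter):
        r, ll_prev = _responsibilities(L, fractions)
        # guard: re-seed a cluster that lost all its subjects
        mass = r.sum(axis=0)
        for c in np.flatnonzero(mass < 1.0):
            logger.warning("EM cluster %d collapsed; re-seeding from worst-fit subjects", c)
            mix_ll = logsumexp(L + np.log(np.maximum(fractions, 1e-300))[None, :], axis=1)
            worst = np.argsort(mix_ll)[: max(2, n // 20)]
            r[worst, :] = 0.0
            r[worst, c] = 1.0
        for c, o in enumerate(orders):
            orders[c], _ = _greedy(X, cache, r[:, c], o, settings.max_greedy_passes)
        fractions = r.mean(axis=0)
        fractions = fractions / fractions.sum()
        L = np.column_stack([cache.subject_logliks(X, o) for o in orders])
        _, ll = _responsibilities(L, fractions)
        if abs(ll - ll_prev) <= settings.em_tol * max(1.0, abs(ll_prev)):
            break
    return orders, fractions, ll


def fit_subtypes(
    X: np.ndarray,
    grid: EventGrid,
    noise: NoiseModel,
    c: int,
    settings: FitSettings | None = None,
) -> SubtypeModel:
    """Fit a C-subtype mixture of event sequences by hierarchical growth + EM.

    For C = 1 this is exactly :func:`optimize_sequence` with unit weights.
    For C > 1 a (C−1)-model is fitted internally; each sufficiently large
    cluster is split in two, the children seeded with independent random
    valid sequences and half the parent's mixture mass each, the resulting
    C-cluster configuration EM-refined, and the best-loglik split kept
    (``n_split_attempts`` seeds per parent).
    """
    settings = settings or FitSettings()
    if c < 1:
        raise ValueError("subtype count must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cache = _GridCache(grid, noise)
    rng = np.random.default_rng(settings.seed)

    seq, _ = optimize_sequence(X, grid, noise, None, settings, rng)
    orders = [seq.order]
    fractions = np.array([1.0])

    for c_cur in range(2, c + 1):
        L = np.column_stack([cache.subject_logliks(X, o) for o in orders])
        r, _ = _responsibilities(L, fractions)
        labels = np.argmax(r, axis=1)
        best: tuple[float, list[np.ndarray], np.ndarray] | None = None
        for parent in range(c_cur - 1):
            members = np.flatnonzero(labels == parent)
            if len(members) < 4:
                continue
            for _ in range(settings.n_split_attempts):
                # seed the two children with independent random valid
                # sequences: random bisections of the parent both refit to the
                # same near-parent ordering, so EM cannot break the symmetry
                new_orders = [_random_valid_order(cache, rng) for _ in range(2)]
                cand_orders = [o.copy() for k, o in enumerate(orders) if k != parent] + new_orders
                parent_frac = fractions[parent]
                cand_fracs = np.concatenate(
                    (np.delete(fractions, parent), [parent_frac / 2, parent_frac / 2])
                )
                cand_orders, cand_fracs, ll = _em_refine(
                    X, cache, cand_orders, cand_fracs, settings
                )
                if best is None or ll > best[0]:
                    best = (ll, cand_orders, cand_fracs)
        if best is None:
            raise ValueError(f"no cluster large enough to split when growing to C={c_cur}")
        _, orders, fractions = best

    if c > 1:
        orders, fractions, _ = _em_refine(X, cache, orders, fractions, settings)
    return SubtypeModel(
        grid=grid,
        sequences=[EventSequence(o, grid) for o in orders],
        fractions=fractions,
        noise=noise,
    )


# ---------------------------------------------------------------------------
# MCMC


def mcmc_sample(
    model: SubtypeModel,
    X: np.ndarray,
    settings: FitSettings | None = None,
) -> tuple[SubtypeModel, PositionalVariance]:
    """Metropolis–Hastings over sequences and fractions around a fitted model.

    Each iteration either relocates one random event of one random subtype to
    a random valid position (probability ``mcmc_seq_move_prob``) or jitters
    the mixture fractions with a renormalized Gaussian step. Acceptance is
    min(1, exp(Δ total log-likelihood)). Post-burn-in samples are retained
    (thinned to ``mcmc_max_retained``) and summarized as positional-variance
    matrices. Returns a copy of the model carrying the samples.
    """
    settings = settings or FitSettings()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rng = np.random.default_rng(settings.seed)
    cache = _GridCache(model.grid, model.noise)
    n_events, c = cache.n, model.n_subtypes

    orders = [s.order.copy() for s in model.sequences]
    fractions = model.fractions.copy()
    L = np.column_stack([cache.subject_logliks(X, o) for o in orders])
    _, ll = _responsibilities(L, fractions)

    burnin = int(settings.mcmc_iterations * settings.mcmc_burnin_frac)
    n_retain = settings.mcmc_iterations - burnin
    if n_retain <= 0:
        raise ValueError("no retained samples after burn-in")
    thin = max(1, n_retain // settings.mcmc_max_retained) if settings.mcmc_max_retained else 1

    kept_orders, kept_fracs = [], []
    for it in range(settings.mcmc_iterations):
        if rng.random() < settings.mcmc_seq_move_prob or c == 1:
            k = int(rng.integers(c))
            event = int(rng.integers(n_events))
            cur = int(np.flatnonzero(orders[k] == event)[0])
            remaining = np.delete(orders[k], cur)
            slots = _valid_slots(cache, remaining, event)
            slot = int(rng.integers(slots.start, slots.stop))
            cand = np.insert(remaining, slot, event)
            L_cand = L.copy()
            L_cand[:, k] = cache.subject_logliks(X, cand)
            _, ll_cand = _responsibilities(L_cand, fractions)
            if np.log(rng.random()) < ll_cand - ll:
                orders[k], L, ll = cand, L_cand, ll_cand
        else:
            cand_f = fractions + rng.normal(0.0, settings.mcmc_fraction_step, c)
            cand_f = np.maximum(cand_f, 1e-9)
            cand_f = cand_f / cand_f.sum()
            _, ll_cand = _responsibilities(L, cand_f)
            if np.log(rng.random()) < ll_cand - ll:
                fractions, ll = cand_f, ll_cand
        if it >= burnin and (it - burnin) % thin == 0:
            kept_orders.append([o.copy() for o in orders])
            kept_fracs.append(fractions.copy())

    if not kept_orders:
        raise ValueError("MCMC retained zero samples")
    orders_arr = np.asarray(kept_orders, dtype=np.intp)  # (S, C, N)
    fracs_arr = np.asarray(kept_fracs, dtype=float)

    matrices = []
    for k in range(c):
        pvd = np.zeros((n_events, n_events))
        for sample in orders_arr[:, k, :]:
            pvd[sample, np.arange(n_events)] += 1.0
        pvd /= len(orders_arr)
        matrices.append(pvd)

    sampled = SubtypeModel(
        grid=model.grid,
        sequences=[EventSequence(o, model.grid) for o in orders],
        fractions=fractions,
        noise=model.noise,
        mcmc_samples={"orders": orders_arr, "fractions": fracs_arr},
    )
    return sampled, PositionalVariance(matrices=matrices)


# ---------------------------------------------------------------------------
# cross-validated model selection


def cross_validate(
    X: np.ndarray,
    grid: EventGrid,
    noise: NoiseModel,
    settings: FitSettings | None = None,
) -> CVResult:
    """K-fold out-of-sample log-likelihoods and CVIC per subtype count.

    CVIC(C) = Σ_folds −2 · (test log-likelihood); the selected C minimizes
    CVIC. Folds partition subjects with a seeded shuffle.
    """
    settings = settings or FitSettings()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if settings.k_folds > n:
        raise ValueError(f"k_folds={settings.k_folds} exceeds {n} subjects")
    rng = np.random.default_rng(settings.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, settings.k_folds)

    rows = {}
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        row = {}
        for c in range(1, settings.c_max + 1):
            fold_settings = replace(settings, seed=settings.seed + 1000 * (f + 1) + c)
            model = fit_subtypes(X[train_idx], grid, noise, c, fold_settings)
            row[f"C={c}"] = mixture_loglik(X[test_idx], model)
        rows[f] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "fold"
    cvic = -2.0 * table.sum(axis=0)
    cvic.name = "cvic"
    selected = int(cvic.idxmin().split("=")[1])
    return CVResult(fold_logliks=table, cvic=cvic, selected_c=selected)
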