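"""z-score event-based model core.

An *event* is a biomarker crossing a fixed abnormality threshold on the
z-scale (atrophy-positive, relative to controls). A subtype is an ordering
of all events; an individual's *stage* is how far along that ordering they
have progressed. The expected z-score of biomarker *i* at integer stage *t*
is a piecewise-linear curve anchored at z = 0 at stage 0, at each threshold
z_{i,j} at the stage where that event occurs, and at z_max_i at the final
stage N (unless the biomarker's last event itself occupies stage N, in which
case the curve is capped at the last threshold).

Observation model: independent Gaussian noise per biomarker around the
expected trajectory, a uniform prior over the N+1 stages, and a categorical
mixture over subtypes. All likelihood accumulation is done in log-space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "EventGrid",
    "EventSequence",
    "NoiseModel",
    "SubtypeModel",
    "trajectory_value",
    "trajectory_matrix",
    "stage_likelihood_vector",
    "stage_logdensity_matrix",
    "subject_loglik",
    "subject_logliks",
    "stage_posteriors",
    "mixture_loglik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class EventGrid:
    """Thresholds and ceiling z-values defining the event set.

    Parameters
    ----------
    biomarkers
        Biomarker (region) names, fixing column order of the data matrix.
    thresholds
        Per biomarker, the strictly increasing z-thresholds whose crossings
        are events. Default {1, 2, 3}.
    z_max
        Per biomarker, the z-value anchored at the final stage N. Must be
        >= the biomarker's last threshold. Default 5.
    """

    biomarkers: tuple[str, ...]
    thresholds: tuple[tuple[float, ...], ...]
    z_max: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.biomarkers) or len(self.z_max) != len(self.biomarkers):
            raise ValueError("thresholds and z_max must have one entry per biomarker")
        for name, th, zm in zip(self.biomarkers, self.thresholds, self.z_max):
            if len(th) == 0:
                raise ValueError(f"biomarker {name!r} has no thresholds")
            if any(b <= a for a, b in zip(th, th[1:])):
                raise ValueError(f"thresholds for {name!r} must be strictly increasing")
            if zm < th[-1]:
                raise ValueError(f"z_max for {name!r} below its last threshold")
        if self.n_events < 1:
            raise ValueError("grid defines no events")

    @classmethod
    def create(cls, biomarkers, thresholds=(1.0, 2.0, 3.0), z_max=5.0) -> "EventGrid":
        """Build a grid, broadcasting shared thresholds/z_max to all biomarkers."""
        biomarkers = tuple(biomarkers)
        if thresholds and np.isscalar(thresholds[0]):
            thresholds = tuple(tuple(float(t) for t in thresholds) for _ in biomarkers)
        else:
            thresholds = tuple(tuple(float(t) for t in th) for th in thresholds)
        if np.isscalar(z_max):
            z_max = tuple(float(z_max) for _ in biomarkers)
        else:
            z_max = tuple(float(z) for z in z_max)
        return cls(biomarkers=biomarkers, thresholds=thresholds, z_max=z_max)

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarkers)

    @property
    def n_events(self) -> int:
        return sum(len(t) for t in self.thresholds)

    @property
    def events(self) -> list[tuple[int, int]]:
        """All events as (biomarker index, threshold index) pairs."""
        return [(i, j) for i, th in enumerate(self.thresholds) for j in range(len(th))]

    def event_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(biomarker index, threshold index, threshold z) per event index."""
        bio = np.array([i for i, _ in self.events], dtype=np.intp)
        idx = np.array([j for _, j in self.events], dtype=np.intp)
        zs = np.array([self.thresholds[i][j] for i, j in self.events], dtype=float)
        return bio, idx, zs

    def to_dict(self) -> dict:
        return {
            "biomarkers": list(self.biomarkers),
            "thresholds": [list(t) for t in self.thresholds],
            "z_max": list(self.z_max),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventGrid":
        return cls.create(d["biomarkers"], d["thresholds"], d["z_max"])


class EventSequence:
    """An ordering of all grid events (positions 1..N).

    Internally an integer permutation of event indices; ``order[p]`` is the
    event occurring at position p+1. Within each biomarker, threshold events
    must appear in increasing threshold order (a hard validity constraint).
    """

    __slots__ = ("order", "_grid_n")

    def __init__(self, order, grid: EventGrid):
        order = np.asarray(order, dtype=np.intp)
        n = grid.n_events
        if sorted(order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of all event indices")
        if not sequence_is_valid(order, grid):
            raise ValueError("within-biomarker threshold order violated")
        self.order = order
        self._grid_n = n

    def __len__(self) -> int:
        return self._grid_n

    def __eq__(self, other) -> bool:
        return isinstance(other, EventSequence) and np.array_equal(self.order, other.order)

    def __repr__(self) -> str:
        return f"EventSequence({self.order.tolist()})"

    def position_of(self, event_index: int) -> int:
        """1-based stage position at which the event occurs."""
        return int(np.flatnonzero(self.order == event_index)[0]) + 1

    def events(self, grid: EventGrid) -> list[tuple[int, int]]:
        ev = grid.events
        return [ev[k] for k in self.order]


def sequence_is_valid(order: np.ndarray, grid: EventGrid) -> bool:
    """Do a biomarker's threshold events appear in increasing threshold order?"""
    bio, idx, _ = grid.event_arrays()
    pos = np.empty(len(order), dtype=np.intp)
    pos[order] = np.arange(len(order))
    for i in range(grid.n_biomarkers):
        mask = bio == i
        p = pos[np.flatnonzero(mask)]
        # event indices for a biomarker are contiguous and in threshold order
        if np.any(np.diff(p) < 0):
            return False
    return True


@dataclass(frozen=True)
class NoiseModel:
    """Per-biomarker Gaussian noise scale on the z-scale (default 1)."""

    sigma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma <= 0):
            raise ValueError("all noise scales must be positive")

    @classmethod
    def default(cls, n_biomarkers: int, sigma: float = 1.0) -> "NoiseModel":
        return cls(sigma=np.full(n_biomarkers, float(sigma)))


def trajectory_matrix(seq: EventSequence, grid: EventGrid) -> np.ndarray:
    """Expected z-scores, shape (N+1 stages, n_biomarkers).

    Piecewise-linear through (0, 0), (pos(i,j), z_{i,j}), and (N, z_max_i)
    when the biomarker's last event sits before stage N; if the last event
    occupies stage N itself, the curve is capped at that threshold.
    """
    n = grid.n_events
    bio, _, zs = grid.event_arrays()
    stages = np.arange(n + 1, dtype=float)
    out = np.empty((n + 1, grid.n_biomarkers))
    pos = np.empty(n, dtype=np.intp)
    pos[seq.order] = np.arange(1, n + 1)
    for i in range(grid.n_biomarkers):
        ev = np.flatnonzero(bio == i)
        p = pos[ev].astype(float)
        z = zs[ev]
        xs = np.concatenate(([0.0], p))
        ys = np.concatenate(([0.0], z))
        if p[-1] < n:
            xs = np.concatenate((xs, [float(n)]))
            ys = np.concatenate((ys, [grid.z_max[i]]))
        out[:, i] = np.interp(stages, xs, ys)
    return out


def trajectory_value(seq: EventSequence, grid: EventGrid, biomarker: int, stage: int) -> float:
    """Expected z-score of one biomarker at one integer stage."""
    n = grid.n_events
    if not (0 <= stage <= n):
        raise ValueError(f"stage must lie in [0, {n}], got {stage}")
    return float(trajectory_matrix(seq, grid)[stage, biomarker])


def stage_logdensity_matrix(X: np.ndarray, seq: EventSequence, grid: EventGrid, noise: NoiseModel) -> np.ndarray:
    """Log p(x | stage k, sequence) for every subject and stage.

    Parameters
    ----------
    X : array (n_subjects, n_biomarkers)

    Returns
    -------
    array (n_subjects, N+1)
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != grid.n_biomarkers:
        raise ValueError(
            f"data has {X.shape[1]} biomarkers, grid expects {grid.n_biomarkers}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("z-score matrix contains non-finite entries")
    traj = trajectory_matrix(seq, grid)  # (N+1, B)
    sig = noise.sigma
    if sig.shape[0] != grid.n_biomarkers:
        raise ValueError("noise model dimension mismatch")
    diff = (X[:, None, :] - traj[None, :, :]) / sig
    const = -np.sum(np.log(sig)) - 0.5 * grid.n_biomarkers * _LOG_2PI
    return -0.5 * np.einsum("skb,skb->sk", diff, diff) + const


def stage_likelihood_vector(x: np.ndarray, seq: EventSequence, grid: EventGrid, noise: NoiseModel) -> np.ndarray:
    """p(x | stage k) for k = 0..N, one subject. Densities, not normalized."""
    return np.exp(stage_logdensity_matrix(np.atleast_2d(x), seq, grid, noise)[0])


def subject_logliks(X: np.ndarray, seq: EventSequence, grid: EventGrid, noise: NoiseModel) -> np.ndarray:
    """log p(x) per subject, marginalized over a uniform stage prior."""
    ld = stage_logdensity_matrix(X, seq, grid, noise)
    return logsumexp(ld, axis=1) - np.log(grid.n_events + 1)


def subject_loglik(x: np.ndarray, seq: EventSequence, grid: EventGrid, noise: NoiseModel) -> float:
    """Stage-marginal log-likelihood of one subject's z-vector."""
    return float(subject_logliks(np.atleast_2d(x), seq, grid, noise)[0])


def stage_posteriors(X: np.ndarray, seq: EventSequence, grid: EventGrid, noise: NoiseModel) -> np.ndarray:
    """P(stage k | x) per subject under the uniform stage prior; rows sum to 1."""
    ld = stage_logdensity_matrix(X, seq, grid, noise)
    ld = ld - logsumexp(ld, axis=1, keepdims=True)
    return np.exp(ld)


@dataclass
class SubtypeModel:
    """A mixture of C event sequences with fractions, noise and grid.

    ``mcmc_samples`` optionally stores the retained MCMC chain as a dict with
    keys ``orders`` (iterations, C, N) and ``fractions`` (iterations, C).
    """

    grid: EventGrid
    sequences: list[EventSequence]
    fractions: np.ndarray
    noise: NoiseModel
    mcmc_samples: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.sequences) != len(self.fractions):
            raise ValueError("one fraction required per sequence")
        if np.any(self.fractions < 0) or abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    def subject_loglik_matrix(self, X: np.ndarray) -> np.ndarray:
        """log p(x | subtype c), shape (n_subjects, C)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack(
            [subject_logliks(X, s, self.grid, self.noise) for s in self.sequences]
        )

    def to_dict(self) -> dict:
        d = {
            "grid": self.grid.to_dict(),
            "sequences": [s.order.tolist() for s in self.sequences],
            "fractions": self.fractions.tolist(),
            "sigma": self.noise.sigma.tolist(),
        }
        if self.mcmc_samples is not None:
            d["mcmc_samples"] = {
                "orders": np.asarray(self.mcmc_samples["orders"]).tolist(),
                "fractions": np.asarray(self.mcmc_samples["fractions"]).tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubtypeModel":
        grid = EventGrid.from_dict(d["grid"])
        seqs = [EventSequence(o, grid) for o in d["sequences"]]
        samples = None
        if "mcmc_samples" in d:
            samples = {
                "orders": np.asarray(d["mcmc_samples"]["orders"], dtype=np.intp),
                "fractions": np.asarray(d["mcmc_samples"]["fractions"], dtype=float),
            }
        return cls(
            grid=grid,
            sequences=seqs,
            fractions=np.asarray(d["fractions"], dtype=float),
            noise=NoiseModel(np.asarray(d["sigma"], dtype=float)),
            mcmc_samples=samples,
        )

    def save(self, path, metadata: dict | None = None) -> None:
        d = self.to_dict()
        if metadata:
            d["metadata"] = metadata
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def load(cls, path) -> "SubtypeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def mixture_loglik(X: np.ndarray, model: SubtypeModel) -> float:
    """Total data log-likelihood under the subtype mixture, log-space stable."""
    L = model.subject_loglik_matrix(X)
    with np.errstate(divide="ignore"):
        logf = np.log(model.fractions)
    return float(np.sum(logsumexp(L + logf[None, :], axis=1)))
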