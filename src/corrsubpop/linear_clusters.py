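"""Robust detection of linear clusters in a scatter, and the 3-point seed rule.

The agglomerative subpopulation search needs initial linear axes: directions
in the (X, Y) plane along which a subset of subjects is concentrated.  They
are found by trimmed k-lines clustering — the line-cluster analogue of
trimmed k-means: points are assigned to the line with the smallest squared
vertical residual, a fixed fraction of worst-fit points is trimmed as noise,
each line is refit by OLS on its untrimmed members, and the whole procedure
is restarted from many random 2-point initializations, keeping the solution
with the smallest total trimmed squared residual.

Vertical (y-on-x) residuals are used throughout, not orthogonal distances,
because the downstream seed rule is defined via an OLS regression of Y on X.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import VariablePair

_MAX_ITER = 100


@dataclass
class LinearAxis:
    """A fitted line y = beta0 + beta1*x with its member subjects."""

    beta0: float
    beta1: float
    member_ids: tuple[str, ...]
    residuals: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusterSolution:
    """Axes plus trimmed-as-noise subjects; partitions the input pair.

    ``objective_history`` records the total trimmed squared residual after
    each assignment step of the winning restart (non-increasing unless an
    emptied axis had to be re-seeded).
    """

    axes: list[LinearAxis]
    unassigned_ids: tuple[str, ...]
    seed: int
    objective: float
    objective_history: list[float] = field(default_factory=list, repr=False)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Plain least-squares line; vertical line degenerates to the mean level."""
    if np.ptp(x) == 0:
        return float(np.mean(y)), 0.0
    beta1, beta0 = np.polyfit(x, y, 1)
    return float(beta0), float(beta1)


def robust_linear_clusters(
    pair: VariablePair,
    k: int = 3,
    trim: float = 0.10,
    seed: int = 0,
    restarts: int = 50,
) -> ClusterSolution:
    """Trimmed k-lines clustering of a scatter.

    Parameters
    ----------
    pair
        The point cloud; needs at least ``3*k`` points so every axis can
        support a seed triple.
    k
        Number of linear axes to fit.
    trim
        Fraction of points (rounded up) discarded as noise each iteration.
    seed
        RNG seed; the solution is deterministic given (seed, restarts).
    restarts
        Random 2-point re-initializations; the best objective wins.
    """
    n = len(pair)
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0 <= trim < 0.5):
        raise ValueError("trim must lie in [0, 0.5)")
    if 2 * k > n:
        raise ValueError(f"need at least 2 points per axis: n={n}, k={k}")
    if n < 3 * k:
        raise ValueError(f"need n >= 3k for seedable axes: n={n}, k={k}")

    x, y = pair.x, pair.y
    n_trim = int(np.ceil(trim * n))
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(restarts):
        lines = np.empty((k, 2))  # rows (beta0, beta1)
        for j in range(k):
            idx = rng.choice(n, size=2, replace=False)
            lines[j] = _ols(x[idx], y[idx])

        prev_assign = None
        history: list[float] = []
        for _ in range(_MAX_ITER):
            # squared vertical residual of every point to every line
            res2 = (y[:, None] - (lines[:, 0][None, :] + lines[:, 1][None, :] * x[:, None])) ** 2
            assign = np.argmin(res2, axis=1)
            best_res2 = res2[np.arange(n), assign]
            trimmed = np.zeros(n, dtype=bool)
            if n_trim:
                # ties on residual broken by index for determinism
                order = np.lexsort((np.arange(n), -best_res2))
                trimmed[order[:n_trim]] = True
            history.append(float(best_res2[~trimmed].sum()))

            state = (assign, trimmed)
            if prev_assign is not None and np.array_equal(prev_assign[0], assign) and np.array_equal(
                prev_assign[1], trimmed
            ):
                break
            prev_assign = state

            for j in range(k):
                members = (assign == j) & ~trimmed
                if members.sum() < 2:
                    # re-seed a dying axis from the worst-fit points
                    worst = np.argsort(-best_res2)[:2]
                    lines[j] = _ols(x[worst], y[worst])
                else:
                    lines[j] = _ols(x[members], y[members])

        objective = history[-1]
        if best is None or objective < best[0]:
            best = (objective, lines.copy(), assign.copy(), trimmed.copy(), history)

    objective, lines, assign, trimmed, history = best
    axes: list[LinearAxis] = []
    for j in range(k):
        members = (assign == j) & ~trimmed
        idx = np.flatnonzero(members)
        b0, b1 = lines[j]
        axes.append(
            LinearAxis(
                beta0=float(b0),
                beta1=float(b1),
                member_ids=tuple(pair.subjects[i] for i in idx),
                residuals=y[idx] - (b0 + b1 * x[idx]),
            )
        )
    # largest axis first: the downstream selection rule prefers it
    axes.sort(key=lambda a: (-len(a), a.member_ids))
    return ClusterSolution(
        axes=axes,
        unassigned_ids=tuple(pair.subjects[i] for i in np.flatnonzero(trimmed)),
        seed=seed,
        objective=objective,
        objective_history=history,
    )


def seed_triple(axis: LinearAxis) -> tuple[str, str, str]:
    """The three member subjects nearest the axis (smallest |residual|).

    This is the starting set M(0) of the agglomerative search.  Ties are
    broken by ascending subject id so reruns are bit-identical.
    """
    if len(axis) < 3:
        raise ValueError(f"axis has only {len(axis)} members; need >= 3")
    order = sorted(range(len(axis)), key=lambda i: (abs(axis.residuals[i]), axis.member_ids[i]))
    return tuple(axis.member_ids[i] for i in order[:3])
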