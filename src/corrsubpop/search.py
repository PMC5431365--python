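"""Greedy subpopulation search by correlation loss and correlation gain.

Both procedures look for a subset M of subjects within which the Pearson
correlation rho(X_M, Y_M) of two chosen biomarkers reaches a target r*
(0.95 by default):

* the **agglomerative** search starts from a near-collinear three-subject
  seed M(0) (see :mod:`corrsubpop.linear_clusters`) and at each step adds
  the subject i* minimizing the *correlation loss*
  ``CLM(M, i) = rho(M) - rho(M + {i})``, stopping just before the enlarged
  set would fall below r*;
* the **divisive** search starts from the whole cohort and at each step
  deletes the subject i* maximizing the *correlation gain*
  ``CGM(M, i) = rho(M - {i}) - rho(M)``, stopping as soon as rho reaches
  r* (so it returns the largest — first — set that satisfies the target).

The two measures are two views of the same algebra:
``CGM(M, i) == CLM(M - {i}, i)`` exactly (both equal
``rho(M - {i}) - rho(M)``).

Every step scans all candidates, so a naive implementation recomputes
Pearson from scratch O(n) times per step, O(n^3) per run.  Here the five
running sums (n, Sx, Sy, Sxx, Syy, Sxy) are updated in O(1) per candidate,
giving O(n) per step and O(n^2) per run — comfortable for cohorts of a few
hundred.  Coordinates are centred on the full-pair means first so the
update is numerically benign; tests cross-check it against direct
recomputation.

Ties in the argmin/argmax are broken by ascending subject id, making every
run bit-identical; neither procedure uses randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import VariablePair

#: Default target correlation for a returned subpopulation.
DEFAULT_RSTAR = 0.95


@dataclass(frozen=True)
class SubjectSet:
    """An ordered set of subject ids indexing one variable pair."""

    ids: tuple[str, ...]
    pair_ref: VariablePair

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in subject set")
        unknown = set(ids) - set(self.pair_ref.subjects)
        if unknown:
            raise ValueError(f"ids not in the pair: {sorted(unknown)}")
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in set(self.ids)


@dataclass(frozen=True)
class SearchConfig:
    """Target correlation r*, step cap and procedure choice."""

    target_correlation: float = DEFAULT_RSTAR
    max_steps: int | None = None
    mode: str = "divisive"

    def __post_init__(self) -> None:
        if not (0.0 < self.target_correlation < 1.0):
            raise ValueError("target correlation must lie in (0, 1)")
        if self.mode not in ("agglomerative", "divisive"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SearchStep:
    """One accepted move: step index, chosen subject, set size and rho after."""

    k: int
    subject_id: str
    set_size: int
    rho: float


@dataclass
class SearchTrace:
    """Full per-step record of a search run."""

    steps: list[SearchStep]
    final_set: SubjectSet
    final_r: float
    terminated_by: str  # "threshold" | "exhausted" | "max_steps"

    def chosen_ids(self) -> list[str]:
        return [s.subject_id for s in self.steps]


class _PearsonState:
    """Running Pearson sums over a membership subset, O(1) add/remove/peek.

    Coordinates are centred on the full-pair means, which leaves rho
    unchanged but keeps the raw-sum formula well conditioned.
    """

    __slots__ = ("x", "y", "n", "sx", "sy", "sxx", "syy", "sxy")

    def __init__(self, pair: VariablePair, member_idx) -> None:
        self.x = pair.x - pair.x.mean()
        self.y = pair.y - pair.y.mean()
        self.n = 0
        self.sx = self.sy = self.sxx = self.syy = self.sxy = 0.0
        for i in member_idx:
            self.add(i)

    def add(self, i: int) -> None:
        xi, yi = self.x[i], self.y[i]
        self.n += 1
        self.sx += xi
        self.sy += yi
        self.sxx += xi * xi
        self.syy += yi * yi
        self.sxy += xi * yi

    def remove(self, i: int) -> None:
        xi, yi = self.x[i], self.y[i]
        self.n -= 1
        self.sx -= xi
        self.sy -= yi
        self.sxx -= xi * xi
        self.syy -= yi * yi
        self.sxy -= xi * yi

    @staticmethod
    def _rho(n, sx, sy, sxx, syy, sxy) -> float:
        """Pearson r from raw sums; NaN when a coordinate has zero variance."""
        if n < 2:
            return math.nan
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        if vx <= 0 or vy <= 0:
            return math.nan
        r = (n * sxy - sx * sy) / math.sqrt(vx * vy)
        return max(-1.0, min(1.0, r))

    def rho(self) -> float:
        return self._rho(self.n, self.sx, self.sy, self.sxx, self.syy, self.sxy)

    def rho_with(self, i: int) -> float:
        """rho of the current set plus point i, without mutating."""
        xi, yi = self.x[i], self.y[i]
        return self._rho(
            self.n + 1,
            self.sx + xi,
            self.sy + yi,
            self.sxx + xi * xi,
            self.syy + yi * yi,
            self.sxy + xi * yi,
        )

    def rho_without(self, i: int) -> float:
        """rho of the current set minus point i, without mutating."""
        xi, yi = self.x[i], self.y[i]
        return self._rho(
            self.n - 1,
            self.sx - xi,
            self.sy - yi,
            self.sxx - xi * xi,
            self.syy - yi * yi,
            self.sxy - xi * yi,
        )


def _indices(pair: VariablePair, ids) -> list[int]:
    pos = {s: i for i, s in enumerate(pair.subjects)}
    return [pos[s] for s in ids]


def subset_rho(pair: VariablePair, ids) -> float:
    """Pearson rho of a subject subset (NaN when undefined)."""
    return _PearsonState(pair, _indices(pair, ids)).rho()


def correlation_loss(current: SubjectSet, candidate: str) -> float:
    """Drop in rho caused by adding ``candidate`` to ``current``.

    Negative values mean the candidate *increases* the correlation.  When
    adding the candidate leaves a coordinate with zero variance the loss is
    +inf so the candidate can never win the argmin.
    """
    if candidate in current:
        raise ValueError(f"candidate {candidate!r} already in the set")
    if len(current) < 3:
        raise ValueError("need at least 3 members for a defined correlation")
    pair = current.pair_ref
    state = _PearsonState(pair, _indices(pair, current.ids))
    before = state.rho()
    if math.isnan(before):
        raise ValueError("correlation undefined on the current set (constant coordinate)")
    after = state.rho_with(pair.index_of(candidate))
    if math.isnan(after):
        return math.inf
    return before - after


def correlation_gain(current: SubjectSet, candidate: str) -> float:
    """Rise in rho caused by deleting ``candidate`` from ``current``.

    When the removal leaves a coordinate with zero variance the gain is
    -inf so the candidate can never win the argmax.  Identity:
    ``correlation_gain(M, i) == correlation_loss(M - {i}, i)``.
    """
    if candidate not in current:
        raise ValueError(f"candidate {candidate!r} not in the set")
    if len(current) < 4:
        raise ValueError("need at least 4 members so the reduced set keeps 3")
    pair = current.pair_ref
    state = _PearsonState(pair, _indices(pair, current.ids))
    before = state.rho()
    after = state.rho_without(pair.index_of(candidate))
    if math.isnan(after):
        return -math.inf
    if math.isnan(before):
        raise ValueError("correlation undefined on the current set (constant coordinate)")
    return after - before


def agglomerative_search(
    pair: VariablePair, seed_set, config: SearchConfig | None = None
) -> SearchTrace:
    """Grow a seed set by repeatedly adding the least-damaging subject.

    At each step the subject with the smallest correlation loss is added
    tentatively; if the enlarged set's rho falls below the target the
    addition is rejected and the search stops (``terminated_by:
    "threshold"``), so the returned set always satisfies rho >= r*.  When
    every subject has been absorbed the trace says ``"exhausted"``.

    Raises
    ------
    ValueError
        If the seed's own correlation is already below r* ("seed below
        threshold" — the chosen axis cannot support growth).
    """
    config = config or SearchConfig(mode="agglomerative")
    seed_ids = tuple(seed_set.ids) if isinstance(seed_set, SubjectSet) else tuple(seed_set)
    members = SubjectSet(seed_ids, pair)
    state = _PearsonState(pair, _indices(pair, members.ids))
    rho = state.rho()
    rstar = config.target_correlation
    if math.isnan(rho) or rho < rstar:
        raise ValueError(
            f"seed below threshold: rho(seed) = {rho:.4f} < r* = {rstar}"
        )

    pos = {s: i for i, s in enumerate(pair.subjects)}
    in_set = set(members.ids)
    # candidates scanned in ascending id order => ties go to the smallest id
    candidates = sorted(set(pair.subjects) - in_set)
    steps: list[SearchStep] = []
    ids = list(members.ids)
    terminated = "exhausted"
    k = 0
    while candidates:
        if config.max_steps is not None and k >= config.max_steps:
            terminated = "max_steps"
            break
        best_rho, best_id = -math.inf, None
        for cid in candidates:
            r_new = state.rho_with(pos[cid])
            if not math.isnan(r_new) and r_new > best_rho:
                best_rho, best_id = r_new, cid
        if best_id is None or best_rho < rstar:
            terminated = "threshold"
            break
        state.add(pos[best_id])
        ids.append(best_id)
        candidates.remove(best_id)
        k += 1
        steps.append(SearchStep(k=k, subject_id=best_id, set_size=len(ids), rho=best_rho))
        rho = best_rho

    final = SubjectSet(tuple(s for s in pair.subjects if s in set(ids)), pair)
    return SearchTrace(steps=steps, final_set=final, final_r=rho, terminated_by=terminated)


def divisive_search(pair: VariablePair, config: SearchConfig | None = None) -> SearchTrace:
    """Prune the whole cohort down to the first set reaching the target rho.

    While rho < r*, the subject with the largest correlation gain is
    removed; the search stops as soon as rho >= r* (``"threshold"``),
    returning the largest set that satisfies the target.  If the set
    shrinks to 3 subjects without reaching r* the trace says
    ``"exhausted"`` — no high-correlation subpopulation exists down this
    greedy path — with the final rho reported.
    """
    config = config or SearchConfig(mode="divisive")
    if len(pair) < 4:
        raise ValueError(f"need at least 4 subjects, got {len(pair)}")
    rstar = config.target_correlation
    ids = list(pair.subjects)
    state = _PearsonState(pair, range(len(pair)))
    rho = state.rho()
    if math.isnan(rho):
        raise ValueError("correlation undefined on the full cohort (constant coordinate)")

    pos = {s: i for i, s in enumerate(pair.subjects)}
    steps: list[SearchStep] = []
    terminated = "threshold"
    k = 0
    while rho < rstar:
        if len(ids) <= 3:
            terminated = "exhausted"
            break
        if config.max_steps is not None and k >= config.max_steps:
            terminated = "max_steps"
            break
        best_rho, best_id = -math.inf, None
        for cid in sorted(ids):
            r_new = state.rho_without(pos[cid])
            if not math.isnan(r_new) and r_new > best_rho:
                best_rho, best_id = r_new, cid
        if best_id is None:
            terminated = "exhausted"
            break
        state.remove(pos[best_id])
        ids.remove(best_id)
        k += 1
        steps.append(SearchStep(k=k, subject_id=best_id, set_size=len(ids), rho=best_rho))
        rho = best_rho

    final = SubjectSet(tuple(s for s in pair.subjects if s in set(ids)), pair)
    return SearchTrace(steps=steps, final_set=final, final_r=rho, terminated_by=terminated)
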