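"""Agreement between agglomerative and divisive solutions, and the cohort report.

When both searches succeed on the same variable pair, agreement is the
percentage of subjects in common relative to the larger of the two sets —
the conservative choice of denominator.  When the agglomerative run fails
(no axis yields a seed whose correlation reaches the target), the report
row records the divisive solution alone, with the agreement column absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .linear_clusters import robust_linear_clusters, seed_triple
from .preprocessing import pairwise_complete, screen_outliers
from .search import SearchConfig, SubjectSet, agglomerative_search, divisive_search
from .tabular_io import BiomarkerTable

logger = logging.getLogger(__name__)


@dataclass
class AgreementReport:
    """One variable-pair row: set sizes, overlap and agreement percentage.

    ``n_agglomerative`` and ``agreement_pct`` are None when the
    agglomerative search produced no solution.  ``reported_n`` is the
    divisive set size — the method that always offers exactly one solution.
    """

    pair_label: str
    n_agglomerative: int | None
    n_divisive: int
    n_common: int | None
    agreement_pct: float | None
    reported_n: int
    note: str = ""


def agreement_percentage(a_ids, d_ids, denominator: str = "max") -> float:
    """100 * |A ∩ D| / denom, with denom in {"max", "min", "union"}."""
    a, d = set(a_ids), set(d_ids)
    common = len(a & d)
    if denominator == "max":
        denom = max(len(a), len(d))
    elif denominator == "min":
        denom = min(len(a), len(d))
    elif denominator == "union":
        denom = len(a | d)
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    if denom == 0:
        return 100.0  # two empty sets agree vacuously
    return 100.0 * common / denom


def compare_solutions(
    a: SubjectSet | None,
    d: SubjectSet,
    *,
    label: str | None = None,
    denominator: str = "max",
) -> AgreementReport:
    """Overlap report for one pair's agglomerative (a) and divisive (d) sets."""
    pair = d.pair_ref
    if a is not None and a.pair_ref is not pair and (
        a.pair_ref.x_name != pair.x_name
        or a.pair_ref.y_name != pair.y_name
        or a.pair_ref.subjects != pair.subjects
    ):
        raise ValueError("solutions index different variable pairs")
    label = label or f"{pair.x_name} vs {pair.y_name}"
    if a is None:
        return AgreementReport(
            pair_label=label,
            n_agglomerative=None,
            n_divisive=len(d),
            n_common=None,
            agreement_pct=None,
            reported_n=len(d),
            note="agglomerative method produced no solution",
        )
    common = len(set(a.ids) & set(d.ids))
    return AgreementReport(
        pair_label=label,
        n_agglomerative=len(a),
        n_divisive=len(d),
        n_common=common,
        agreement_pct=agreement_percentage(a.ids, d.ids, denominator),
        reported_n=len(d),
    )


def run_pair(
    table: BiomarkerTable,
    x_name: str,
    y_name: str,
    config: SearchConfig | None = None,
    *,
    k: int = 3,
    trim: float = 0.10,
    seed: int = 0,
    restarts: int = 50,
    outlier_method: str = "mad",
    outlier_threshold: float = 4.0,
) -> tuple[SubjectSet | None, SubjectSet, AgreementReport]:
    """Full workflow for one variable pair.

    Pairwise-complete extraction, outlier screen, trimmed k-lines seeding,
    agglomerative growth of every axis (the largest grown cluster is
    selected), divisive pruning, and the agreement report.  Returns
    ``(agglomerative_set_or_None, divisive_set, report)``.
    """
    config = config or SearchConfig()
    pair = pairwise_complete(table, x_name, y_name)
    pair, removed = screen_outliers(pair, method=outlier_method, threshold=outlier_threshold)
    if removed:
        logger.info("removed %d outliers for %s vs %s", len(removed), x_name, y_name)

    d_trace = divisive_search(pair, config)
    d_set = d_trace.final_set

    a_best: SubjectSet | None = None
    try:
        solution = robust_linear_clusters(pair, k=k, trim=trim, seed=seed, restarts=restarts)
    except ValueError as exc:
        logger.warning("linear clustering failed for %s vs %s: %s", x_name, y_name, exc)
        solution = None
    if solution is not None:
        for axis in solution.axes:
            if len(axis) < 3:
                continue
            try:
                trace = agglomerative_search(pair, seed_triple(axis), config)
            except ValueError as exc:  # seed below threshold: axis not viable
                logger.info("axis rejected for %s vs %s: %s", x_name, y_name, exc)
                continue
            if a_best is None or len(trace.final_set) > len(a_best):
                a_best = trace.final_set

    report = compare_solutions(a_best, d_set, label=f"{x_name} vs {y_name}")
    return a_best, d_set, report


def table4_report(
    table: BiomarkerTable,
    anchor_vars: list[str],
    target_vars: list[str],
    config: SearchConfig | None = None,
    **run_kwargs,
) -> list[AgreementReport]:
    """One agreement row per (target, anchor) combination.

    Mirrors the cohort-report layout: rows are enzyme activities, columns
    the anchors (CoQ content, CS activity) each activity is paired with.
    Per-pair failures are recorded in the row's note, never fatal.
    """
    rows: list[AgreementReport] = []
    for target in target_vars:
        for anchor in anchor_vars:
            label = f"{target} vs {anchor}"
            try:
                _, _, report = run_pair(table, anchor, target, config, **run_kwargs)
                report.pair_label = label
                rows.append(report)
            except (ValueError, KeyError) as exc:
                logger.warning("pair %s failed: %s", label, exc)
                rows.append(
                    AgreementReport(
                        pair_label=label,
                        n_agglomerative=None,
                        n_divisive=0,
                        n_common=None,
                        agreement_pct=None,
                        reported_n=0,
                        note=f"failed: {exc}",
                    )
                )
    return rows
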