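"""Analysis-ready variable pairs: ratios, pairwise-complete extraction, outlier screen.

The downstream search algorithms operate on a :class:`VariablePair`: two
equal-length vectors over the subjects for which *both* variables were
measured.  Normalization ratios (activity per citrate-synthase unit, per CoQ
content) are appended as derived columns before pair extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tabular_io import BiomarkerTable

logger = logging.getLogger(__name__)

#: 1.4826 rescales the median absolute deviation to a normal-consistent SD.
_MAD_SCALE = 1.4826
#: 1.349 is the normal IQR/SD ratio, used as fallback scale when MAD is 0.
_IQR_SCALE = 1.349


@dataclass(frozen=True)
class VariablePair:
    """Two variables restricted to their pairwise-complete subjects."""

    x_name: str
    y_name: str
    subjects: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if not (len(self.x) == len(self.y) == len(self.subjects)):
            raise ValueError("subjects, x and y must have equal length")
        if len(self.x) and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("pair values must be finite (no missing entries)")

    def __len__(self) -> int:
        return len(self.subjects)

    def index_of(self, subject_id: str) -> int:
        return self.subjects.index(subject_id)

    def subset(self, ids) -> "VariablePair":
        """Restrict to the given subject ids, preserving pair order."""
        keep = set(ids)
        idx = [i for i, s in enumerate(self.subjects) if s in keep]
        return VariablePair(
            self.x_name,
            self.y_name,
            tuple(self.subjects[i] for i in idx),
            self.x[idx],
            self.y[idx],
        )


def pairwise_complete(table: BiomarkerTable, x_name: str, y_name: str) -> VariablePair:
    """Extract the subjects with both variables measured, order preserved."""
    x = table.column(x_name)
    y = table.column(y_name)
    keep = ~(np.isnan(x) | np.isnan(y))
    subjects = tuple(s for s, k in zip(table.subject_ids, keep) if k)
    return VariablePair(x_name, y_name, subjects, x[keep], y[keep])


def normalize_ratio(
    table: BiomarkerTable,
    numerator: str,
    denominator: str,
    *,
    scale: float | str = "auto",
    new_name: str | None = None,
) -> BiomarkerTable:
    """Append the per-subject ratio ``numerator/denominator`` as a new variable.

    The cell is missing when either operand is missing or the denominator is
    zero.  With ``scale="auto"`` the ratio of a respiratory-chain activity to
    citrate synthase is multiplied by 1000 so that it lands on the customary
    mUnits-per-CS-Units scale (reference ranges for e.g. CIV/CS are printed
    in hundreds); CoQ/CS and every other ratio stay unscaled.
    """
    if numerator == denominator:
        raise ValueError("numerator and denominator are the same variable (constant ratio)")
    num = table.column(numerator)
    den = table.column(denominator)
    if scale == "auto":
        is_cs_denom = denominator.split("[")[0].strip().upper() == "CS"
        is_activity_num = not numerator.split("[")[0].strip().upper().startswith("COQ")
        factor = 1000.0 if (is_cs_denom and is_activity_num) else 1.0
    else:
        factor = float(scale)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = factor * num / den
    zero_den = (den == 0) & ~np.isnan(num)
    if zero_den.any():
        bad = [s for s, z in zip(table.subject_ids, zero_den) if z]
        logger.warning(
            "zero denominator %s for subjects %s; ratio cells set missing",
            denominator,
            bad,
        )
    ratio[~np.isfinite(ratio)] = np.nan

    name = new_name or f"{numerator}/{denominator}"
    return BiomarkerTable(
        subject_ids=list(table.subject_ids),
        variables=list(table.variables) + [name],
        values=np.column_stack([table.values, ratio]),
    )


def _robust_scale(v: np.ndarray) -> float:
    """Normal-consistent robust SD: MAD, falling back to IQR, else 0."""
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad > 0:
        return _MAD_SCALE * mad
    q1, q3 = np.percentile(v, [25, 75])
    if q3 > q1:
        return (q3 - q1) / _IQR_SCALE
    return 0.0


def screen_outliers(
    pair: VariablePair,
    method: str = "mad",
    threshold: float = 4.0,
) -> tuple[VariablePair, list[str]]:
    """Single-pass univariate robust-z outlier screen on both coordinates.

    A subject is removed when ``|value - median| / robust_sd > threshold`` on
    either coordinate, with the robust SD taken as 1.4826*MAD (IQR-based
    fallback when the MAD is zero; if that is also zero the coordinate is
    skipped with a warning).  Exactly one pass is applied: survivors are not
    re-screened, so the output is not guaranteed to be a fixed point of the
    rule.  ``method="none"`` is the identity.

    Returns
    -------
    (survivors, removed_ids)
    """
    if method not in ("mad", "none"):
        raise ValueError(f"unknown outlier method {method!r}")
    if len(pair) == 0:
        raise ValueError("cannot screen an empty pair")
    if method == "none":
        return pair, []

    bad = np.zeros(len(pair), dtype=bool)
    for coord, v in (("x", pair.x), ("y", pair.y)):
        s = _robust_scale(v)
        if s == 0.0:
            logger.warning(
                "degenerate scale on %s coordinate (%s); outlier screen skipped there",
                coord,
                pair.x_name if coord == "x" else pair.y_name,
            )
            continue
        bad |= np.abs(v - np.median(v)) / s > threshold
    removed = [s for s, b in zip(pair.subjects, bad) if b]
    if removed:
        logger.info(
            "outlier screen removed %d of %d subjects for (%s, %s): %s",
            len(removed),
            len(pair),
            pair.x_name,
            pair.y_name,
            removed,
        )
    keep = [s for s, b in zip(pair.subjects, bad) if not b]
    return pair.subset(keep), removed
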