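"""Pre-fit diagnostics for slope-comparison analyses.

Two checks guard the interpretation of tolerance/benevolence comparisons:

* density overlap — groups whose observed density ranges barely overlap can
  show spurious slope differences, because each group's slope is then
  estimated over a different stretch of the density axis;
* linearity — the health-density relationship must actually be close to a
  line; curvature is assessed by comparing the quadratic-extension model
  against the linear one.

Diagnostics never mutate the records they inspect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import pandas as pd

from .core import DEFAULT_ALPHA, DEFAULT_SCALE, ExperimentRecord, records_to_frame, to_analysis_scale
from .errors import DesignError
from .inference import FitResult, fit_quadratic_extension

DEFAULT_OVERLAP_THRESHOLD = 0.5


@dataclass(frozen=True)
class OverlapReport:
    """Pairwise overlap of observed density ranges between groups.

    The coefficient for a pair is length(intersection of ranges) /
    length(union of ranges), in [0, 1]; pairs below the threshold are
    flagged.  Degenerate single-point ranges are listed separately.
    """

    pairs: list[tuple[str, str, float]]
    flagged_pairs: list[tuple[str, str, float]]
    threshold: float
    degenerate_groups: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pairs": [
                {"group_i": a, "group_j": b, "overlap": o} for a, b, o in self.pairs
            ],
            "flagged_pairs": [
                {"group_i": a, "group_j": b, "overlap": o}
                for a, b, o in self.flagged_pairs
            ],
            "threshold": self.threshold,
            "degenerate_groups": self.degenerate_groups,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def interval_overlap(lo1: float, hi1: float, lo2: float, hi2: float) -> float:
    """Intersection-over-union of two closed intervals.

    Zero-length union (both intervals degenerate at the same point) is
    defined as full overlap (1.0).
    """
    inter = max(0.0, min(hi1, hi2) - max(lo1, lo2))
    union = max(hi1, hi2) - min(lo1, lo2)
    if union == 0.0:
        return 1.0
    return inter / union


def density_overlap(
    records: Iterable[ExperimentRecord] | pd.DataFrame,
    grouping: str,
    *,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    scale: str = DEFAULT_SCALE,
) -> OverlapReport:
    """Pairwise density-range overlap between group levels.

    Measured on observed min-max ranges on the analysis scale; below the
    threshold a pair is flagged, and slope comparisons on the same data are
    downgraded to unreliable rather than suppressed.
    """
    df = records_to_frame(records)
    if "d" not in df.columns:
        df = df.copy()
        df["d"] = to_analysis_scale(df["density"].to_numpy(), scale)
    levels = sorted(df[grouping].astype(str).unique())
    if len(levels) < 2:
        raise DesignError(f"need >=2 {grouping} levels for an overlap check")

    ranges: dict[str, tuple[float, float]] = {}
    degenerate = []
    for lev in levels:
        sub = df.loc[df[grouping].astype(str) == lev, "d"]
        lo, hi = float(sub.min()), float(sub.max())
        ranges[lev] = (lo, hi)
        if lo == hi:
            degenerate.append(lev)

    pairs = []
    flagged = []
    for a, b in combinations(levels, 2):
        o = interval_overlap(*ranges[a], *ranges[b])
        pairs.append((a, b, o))
        if o < threshold:
            flagged.append((a, b, o))
    return OverlapReport(
        pairs=pairs,
        flagged_pairs=flagged,
        threshold=threshold,
        degenerate_groups=degenerate,
    )


@dataclass(frozen=True)
class CurvatureReport:
    """Linearity assessment from the quadratic-extension comparison."""

    pvalue: float
    group_quadratic: dict[str, float]
    curved: bool
    advisory: str
    fit: FitResult

    def to_dict(self) -> dict:
        return {
            "pvalue": self.pvalue,
            "group_quadratic": self.group_quadratic,
            "curved": self.curved,
            "advisory": self.advisory,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def linearity_check(
    records: Iterable[ExperimentRecord] | pd.DataFrame,
    grouping: str,
    *,
    scale: str = DEFAULT_SCALE,
    alpha: float = DEFAULT_ALPHA,
) -> CurvatureReport:
    """Check that health is linear in density before trusting slope fits.

    Wraps the quadratic-extension fit; when curvature is detected at the
    configured alpha the advisory recommends reporting the quadratic model.
    """
    fit = fit_quadratic_extension(records, grouping, scale=scale, alpha=alpha)
    p = fit.term_tests["curvature"].pvalue
    curved = (p == p) and p < alpha  # NaN-safe
    if curved:
        advisory = (
            "curvature detected: the health-density relationship deviates from "
            "a line; report the quadratic model rather than the linear slopes"
        )
    else:
        advisory = "no evidence of curvature; the linear model is adequate"
    return CurvatureReport(
        pvalue=p,
        group_quadratic=dict(fit.group_quadratic or {}),
        curved=curved,
        advisory=advisory,
        fit=fit,
    )
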