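"""Classify effector molecules from wild-type vs isogenic-knockout contrasts.

A gene knockout changes at most two summary traits of the infection: the
slope of host health on microbial density and the mean density itself.  For
a microbial gene, a significantly higher wild-type slope marks a benevolence
factor, a lower one a malevolence factor, and a higher wild-type mean
density a proliferation factor.  For a host gene the analogous calls are
tolerance factor (shallower wild-type slope) and resistance factor (lower
wild-type density).  A factor is "pure" when exactly one of the two tests is
significant; since non-significance is weak evidence of absence, purity is
reported together with the non-significant test's p-value and the minimum
effect it could plausibly have detected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DEFAULT_ALPHA,
    DEFAULT_SCALE,
    ExperimentRecord,
    records_to_frame,
)
from .errors import DesignError
from .inference import (
    FitResult,
    fit_binary_outcome,
    test_density_variation,
    test_slope_variation,
)

MICROBE_LABELS = ("benevolence_factor", "malevolence_factor", "proliferation_factor")
HOST_LABELS = ("tolerance_factor", "resistance_factor")

WT = "wt"
KO = "ko"


@dataclass(frozen=True)
class FactorCall:
    """Verdict of a wild-type vs knockout classification.

    ``labels`` holds the factor calls; ``pure`` is True when exactly one of
    the slope and density tests was significant.  ``mde`` gives, for each
    non-significant test, the smallest difference the contrast had roughly
    80% power to detect given the observed standard error.
    """

    labels: frozenset[str]
    pure: bool
    b_wt: float
    b_ko: float
    c_bar_wt: float
    c_bar_ko: float
    p_slope: float
    p_density: float
    alpha: float
    kind: str  # "microbial" or "host"
    flags: tuple[str, ...] = ()
    mde: dict = field(default_factory=dict)
    slope_fit: FitResult | None = None
    density_fit: FitResult | None = None

    def __post_init__(self) -> None:
        if {"benevolence_factor", "malevolence_factor"} <= self.labels:
            raise ValueError("benevolence and malevolence factor calls are exclusive")

    def verdict(self) -> str:
        """One-line human-readable verdict."""
        if not self.labels:
            body = "no factor call (neither test significant)"
        else:
            body = " + ".join(sorted(self.labels))
            body += " (pure)" if self.pure else " (mixed)"
        if self.flags:
            body += " [flags: " + ", ".join(self.flags) + "]"
        return body

    def to_dict(self) -> dict:
        return {
            "labels": sorted(self.labels),
            "pure": self.pure,
            "b_wt": self.b_wt,
            "b_ko": self.b_ko,
            "c_bar_wt": self.c_bar_wt,
            "c_bar_ko": self.c_bar_ko,
            "p_slope": self.p_slope,
            "p_density": self.p_density,
            "alpha": self.alpha,
            "kind": self.kind,
            "flags": list(self.flags),
            "mde": self.mde,
            "verdict": self.verdict(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _relabel(
    wt_records: Iterable[ExperimentRecord] | pd.DataFrame,
    ko_records: Iterable[ExperimentRecord] | pd.DataFrame,
    column: str,
) -> pd.DataFrame:
    wt = records_to_frame(wt_records).copy()
    ko = records_to_frame(ko_records).copy()
    if len(wt) == 0 or len(ko) == 0:
        raise DesignError("both wild-type and knockout data are required")
    wt[column] = WT
    ko[column] = KO
    return pd.concat([wt, ko], ignore_index=True)


def _slope_diff_mde(fit: FitResult, alpha: float) -> float:
    """Smallest slope difference detectable with ~80% power at the observed
    standard error of the wt-ko slope contrast (normal approximation)."""
    try:
        se = math.sqrt(
            fit.line_for(WT).se_b ** 2 + fit.line_for(KO).se_b ** 2
        )
    except KeyError:
        return math.nan
    if se == 0 or not math.isfinite(se):
        return math.nan
    return (stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(0.8)) * se


def _density_diff_mde(df: pd.DataFrame, column: str, alpha: float, scale: str) -> float:
    from .core import to_analysis_scale

    d = to_analysis_scale(df["density"].to_numpy(), scale)
    g = df[column].astype(str).to_numpy()
    parts = [d[g == lev] for lev in (WT, KO)]
    se = math.sqrt(sum(np.var(p, ddof=1) / len(p) for p in parts))
    if se == 0 or not math.isfinite(se):
        return math.nan
    return (stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(0.8)) * se


def _classify(
    wt_records,
    ko_records,
    *,
    column: str,
    alpha: float,
    scale: str,
    bonferroni: bool,
    point_estimate: bool,
    overlap_threshold: float,
):
    df = _relabel(wt_records, ko_records, column)
    kinds = set(df["outcome_kind"].unique())
    binary = kinds == {"binary"}

    alpha_eff = alpha / 2 if bonferroni else alpha
    if binary:
        slope_fit = fit_binary_outcome(df, column, scale=scale, alpha=alpha_eff)
    else:
        slope_fit = test_slope_variation(
            df, column, scale=scale, alpha=alpha_eff, overlap_threshold=overlap_threshold
        )
    dens_fit = test_density_variation(df, column, scale=scale, alpha=alpha_eff)

    p_slope = slope_fit.interaction_p
    p_density = dens_fit.term_tests[column].pvalue

    flags = [f for f in slope_fit.flags if f.startswith("unreliable")]
    flags += [f for f in slope_fit.flags if f in ("complete_separation", "penalized_fallback")]

    if point_estimate:
        sig_slope = slope_fit.line_for(WT).b != slope_fit.line_for(KO).b
        sig_density = (
            dens_fit.summary_for(WT).c_bar != dens_fit.summary_for(KO).c_bar
        )
        flags.append("point_estimate_mode")
    else:
        sig_slope = (p_slope == p_slope) and p_slope < alpha_eff
        sig_density = (p_density == p_density) and p_density < alpha_eff
    return df, slope_fit, dens_fit, p_slope, p_density, sig_slope, sig_density, alpha_eff, flags


def classify_microbial_factor(
    wt_records: Iterable[ExperimentRecord] | pd.DataFrame,
    ko_records: Iterable[ExperimentRecord] | pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    *,
    scale: str = DEFAULT_SCALE,
    bonferroni: bool = False,
    point_estimate: bool = False,
    overlap_threshold: float = 0.5,
) -> FactorCall:
    """Classify a microbial effector molecule from a WT/KO strain contrast.

    Runs the slope-comparison and mean-density tests with strain in
    {wt, ko}: a significant slope difference with b_wt > b_ko yields a
    benevolence factor, with b_wt < b_ko a malevolence factor; a significant
    density difference with c_bar_wt > c_bar_ko a proliferation factor.
    """
    (
        df,
        slope_fit,
        dens_fit,
        p_slope,
        p_density,
        sig_slope,
        sig_density,
        alpha_eff,
        flags,
    ) = _classify(
        wt_records,
        ko_records,
        column="strain",
        alpha=alpha,
        scale=scale,
        bonferroni=bonferroni,
        point_estimate=point_estimate,
        overlap_threshold=overlap_threshold,
    )
    b_wt, b_ko = slope_fit.line_for(WT).b, slope_fit.line_for(KO).b
    c_wt, c_ko = dens_fit.summary_for(WT).c_bar, dens_fit.summary_for(KO).c_bar

    labels: set[str] = set()
    if sig_slope:
        if b_wt > b_ko:
            labels.add("benevolence_factor")
        elif b_wt < b_ko:
            labels.add("malevolence_factor")
    if sig_density and c_wt > c_ko:
        labels.add("proliferation_factor")

    pure = (int(sig_slope) + int(sig_density)) == 1
    mde = {}
    if not sig_slope:
        mde["slope_difference"] = _slope_diff_mde(slope_fit, alpha_eff)
    if not sig_density:
        mde["density_difference"] = _density_diff_mde(df, "strain", alpha_eff, scale)

    return FactorCall(
        labels=frozenset(labels),
        pure=pure,
        b_wt=b_wt,
        b_ko=b_ko,
        c_bar_wt=c_wt,
        c_bar_ko=c_ko,
        p_slope=p_slope,
        p_density=p_density,
        alpha=alpha_eff,
        kind="microbial",
        flags=tuple(flags),
        mde=mde,
        slope_fit=slope_fit,
        density_fit=dens_fit,
    )


def classify_host_factor(
    wt_host_records: Iterable[ExperimentRecord] | pd.DataFrame,
    ko_host_records: Iterable[ExperimentRecord] | pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    *,
    scale: str = DEFAULT_SCALE,
    bonferroni: bool = False,
    point_estimate: bool = False,
    overlap_threshold: float = 0.5,
) -> FactorCall:
    """Classify a host molecule from a WT/KO host contrast.

    A significantly lower wild-type mean density marks a resistance factor.
    A significantly shallower wild-type slope (b_wt > b_ko, for harmful
    infections where slopes are non-positive) marks a tolerance factor; when
    the two slopes straddle zero the direction of "shallower" is ambiguous
    and the call is flagged instead of made.
    """
    (
        df,
        slope_fit,
        dens_fit,
        p_slope,
        p_density,
        sig_slope,
        sig_density,
        alpha_eff,
        flags,
    ) = _classify(
        wt_host_records,
        ko_host_records,
        column="host_type",
        alpha=alpha,
        scale=scale,
        bonferroni=bonferroni,
        point_estimate=point_estimate,
        overlap_threshold=overlap_threshold,
    )
    b_wt, b_ko = slope_fit.line_for(WT).b, slope_fit.line_for(KO).b
    c_wt, c_ko = dens_fit.summary_for(WT).c_bar, dens_fit.summary_for(KO).c_bar

    labels: set[str] = set()
    flags = list(flags)
    if sig_slope:
        if b_wt > 0 and b_ko < 0 or (b_wt < 0 and b_ko > 0):
            flags.append("ambiguous_tolerance_direction_slopes_straddle_zero")
        elif b_wt > b_ko:
            labels.add("tolerance_factor")
    if sig_density and c_wt < c_ko:
        labels.add("resistance_factor")

    pure = (int(sig_slope) + int(sig_density)) == 1
    mde = {}
    if not sig_slope:
        mde["slope_difference"] = _slope_diff_mde(slope_fit, alpha_eff)
    if not sig_density:
        mde["density_difference"] = _density_diff_mde(df, "host_type", alpha_eff, scale)

    return FactorCall(
        labels=frozenset(labels),
        pure=pure,
        b_wt=b_wt,
        b_ko=b_ko,
        c_bar_wt=c_wt,
        c_bar_ko=c_ko,
        p_slope=p_slope,
        p_density=p_density,
        alpha=alpha_eff,
        kind="host",
        flags=tuple(flags),
        mde=mde,
        slope_fit=slope_fit,
        density_fit=dens_fit,
    )
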