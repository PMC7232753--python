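"""Model fitting and hypothesis tests for infection-experiment designs.

Four designs are covered, each a fit-and-test operation:

* density against a grouping (host type or strain) — a one-way comparison of
  mean microbial density; a significant group effect indicates variation in
  resistance (host grouping) or proliferation (strain grouping);
* health against grouping, density, and their interaction — the classical
  slope-comparison ANCOVA; a significant interaction indicates variation in
  tolerance (host grouping) or benevolence (strain grouping);
* the combined factorial with both host types and strains;
* binomial GLM and quadratic-extension variants of the slope comparison.

Continuous-outcome interaction tests use the extra-sum-of-squares F
comparing the full model against the additive one; binary outcomes use a
binomial likelihood-ratio test.  Groups are coded with treatment contrasts
(alphabetically first level as reference), but every result also reports
per-group intercepts and slopes derived from the full-model coefficients so
interpretation does not depend on the coding.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import (
    DEFAULT_ALPHA,
    DEFAULT_SCALE,
    ExperimentRecord,
    GroupSummary,
    HealthDensityLine,
    records_to_frame,
    to_analysis_scale,
    validate_scale,
)
from .errors import DesignError, DomainError

SCHEMA_VERSION = 1

Grouping = Literal["host_type", "strain"]

# property named by each (model, grouping) pair
_DENSITY_PROPERTY = {"host_type": "resistance", "strain": "proliferation"}
_SLOPE_PROPERTY = {"host_type": "tolerance", "strain": "benevolence"}


@dataclass(frozen=True)
class TermTest:
    """One model-comparison test (extra-SS F or likelihood ratio)."""

    name: str
    statistic: float
    df_num: float
    df_den: float | None
    pvalue: float
    kind: Literal["F", "LRT"] = "F"


@dataclass
class FitResult:
    """Everything one fitted model reports: coefficient table, per-term
    tests, per-group lines and trait summaries, and data-quality flags."""

    model_name: str
    property_label: str
    grouping: str
    formula_terms: list[str]
    coefficients: pd.DataFrame
    term_tests: dict[str, TermTest]
    interaction_p: float | None
    group_lines: list[HealthDensityLine]
    group_summaries: list[GroupSummary]
    n_obs: int
    n_excluded: int
    analysis_scale: str
    alpha: float
    outcome_kind: str = "continuous"
    group_quadratic: dict[str, float] | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interaction_p is not None and not math.isnan(self.interaction_p):
            if not 0 <= self.interaction_p <= 1:
                raise DomainError(f"interaction p-value {self.interaction_p} outside [0,1]")

    def line_for(self, group: str) -> HealthDensityLine:
        for ln in self.group_lines:
            if ln.group == group:
                return ln
        raise KeyError(group)

    def summary_for(self, group: str) -> GroupSummary:
        for s in self.group_summaries:
            if s.group == group:
                return s
        raise KeyError(group)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "model_name": self.model_name,
            "property_label": self.property_label,
            "grouping": self.grouping,
            "formula_terms": self.formula_terms,
            "coefficients": self.coefficients.to_dict(orient="records"),
            "term_tests": {
                k: {
                    "statistic": t.statistic,
                    "df_num": t.df_num,
                    "df_den": t.df_den,
                    "pvalue": t.pvalue,
                    "kind": t.kind,
                }
                for k, t in self.term_tests.items()
            },
            "interaction_p": self.interaction_p,
            "group_lines": [
                {
                    "group": ln.group,
                    "a": ln.a,
                    "b": ln.b,
                    "se_a": ln.se_a,
                    "se_b": ln.se_b,
                    "df_resid": ln.df_resid,
                }
                for ln in self.group_lines
            ],
            "group_summaries": [
                {
                    "group": s.group,
                    "c_bar": s.c_bar,
                    "b": s.b,
                    "virulence": s.virulence,
                    "n": s.n,
                }
                for s in self.group_summaries
            ],
            "group_quadratic": self.group_quadratic,
            "n_obs": self.n_obs,
            "n_excluded": self.n_excluded,
            "analysis_scale": self.analysis_scale,
            "alpha": self.alpha,
            "outcome_kind": self.outcome_kind,
            "flags": self.flags,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=_jsonable, **kwargs)

    def coefficients_tsv(self) -> str:
        return self.coefficients.to_csv(sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class FactorialResult:
    """The two fits of the combined factorial design plus the host x strain
    screen applied to the density model."""

    density_model: FitResult
    health_model: FitResult
    host_strain_screen_p: float
    interaction_retained: bool
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "density_model": self.density_model.to_dict(),
            "health_model": self.health_model.to_dict(),
            "host_strain_screen_p": self.host_strain_screen_p,
            "interaction_retained": self.interaction_retained,
            "flags": self.flags,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=_jsonable, **kwargs)


# --------------------------------------------------------------------------
# data preparation

def _prepare(
    records: Iterable[ExperimentRecord] | pd.DataFrame,
    scale: str,
    require_kind: str | None = None,
) -> tuple[pd.DataFrame, int]:
    """Frame with analysis-scale density column ``d``; rows with missing
    density or outcome are excluded and counted (no imputation)."""
    validate_scale(scale)
    df = records_to_frame(records)
    n0 = len(df)
    df = df.dropna(subset=["density", "outcome"]).reset_index(drop=True)
    n_excluded = n0 - len(df)
    if len(df) == 0:
        raise DesignError("no usable records after exclusions")
    kinds = set(df["outcome_kind"].unique())
    if len(kinds) > 1:
        raise DomainError(f"mixed outcome kinds in one analysis: {sorted(kinds)}")
    if require_kind is not None and kinds != {require_kind}:
        raise DomainError(
            f"this model requires outcome_kind={require_kind!r}, got {sorted(kinds)}"
        )
    df["d"] = to_analysis_scale(df["density"].to_numpy(), scale)
    return df, n_excluded


def _levels(df: pd.DataFrame, grouping: str) -> list[str]:
    if grouping not in ("host_type", "strain"):
        raise DesignError(f"grouping must be 'host_type' or 'strain', got {grouping!r}")
    levels = sorted(df[grouping].astype(str).unique())
    if len(levels) < 2:
        raise DesignError(
            f"need >=2 {grouping} levels to compare groups, found {levels}"
        )
    return levels


def _dummies(df: pd.DataFrame, grouping: str, levels: list[str]) -> np.ndarray:
    """Treatment-contrast dummy columns for levels[1:]."""
    g = df[grouping].astype(str).to_numpy()
    return np.column_stack([(g == lev).astype(float) for lev in levels[1:]]) if len(levels) > 1 else np.empty((len(df), 0))


def _coef_table(params, bse, pvalues, names) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": names,
            "estimate": np.asarray(params, dtype=float),
            "se": np.asarray(bse, dtype=float),
            "p": np.asarray(pvalues, dtype=float),
        }
    )


def _extra_ss_f(fit_full, fit_reduced, tol_scale: float) -> tuple[float, float, float, float]:
    """Extra-sum-of-squares F of full vs nested reduced OLS fit.

    Returns (F, df_num, df_den, p).  Degenerate cases (zero residual
    variance) return NaN statistics; the caller flags them.
    """
    ssr_f, ssr_r = fit_full.ssr, fit_reduced.ssr
    df_num = fit_reduced.df_resid - fit_full.df_resid
    df_den = fit_full.df_resid
    tol = 1e-12 * (tol_scale + 1.0)
    if df_den <= 0 or ssr_f <= tol:
        if ssr_r - ssr_f <= tol:
            return math.nan, df_num, df_den, math.nan
        return math.inf, df_num, df_den, 0.0
    F = max((ssr_r - ssr_f) / df_num, 0.0) / (ssr_f / df_den)
    return float(F), float(df_num), float(df_den), float(stats.f.sf(F, df_num, df_den))


def _group_lines_from_full(
    params: np.ndarray,
    cov: np.ndarray,
    levels: list[str],
    df_resid: float,
) -> list[HealthDensityLine]:
    """Per-group intercepts/slopes from a saturated interaction fit.

    Parameter layout: [const, g_1..g_{k-1}, d, g_1:d .. g_{k-1}:d].
    Group j's line is a contrast of these, so SEs come from the covariance.
    """
    k = len(levels)
    p = len(params)
    lines = []
    for j, lev in enumerate(levels):
        la = np.zeros(p)
        lb = np.zeros(p)
        la[0] = 1.0
        lb[k] = 1.0  # density coefficient index
        if j > 0:
            la[j] = 1.0
            lb[k + j] = 1.0
        a = float(la @ params)
        b = float(lb @ params)
        se_a = float(np.sqrt(max(la @ cov @ la, 0.0)))
        se_b = float(np.sqrt(max(lb @ cov @ lb, 0.0)))
        lines.append(
            HealthDensityLine(
                group=lev, a=a, b=b, se_a=se_a, se_b=se_b, df_resid=df_resid
            )
        )
    return lines


def _group_summaries(
    df: pd.DataFrame,
    grouping: str,
    levels: list[str],
    lines: list[HealthDensityLine] | None,
) -> list[GroupSummary]:
    out = []
    bmap = {ln.group: ln.b for ln in lines} if lines else {}
    for lev in levels:
        sub = df.loc[df[grouping].astype(str) == lev, "d"]
        out.append(
            GroupSummary.from_parts(
                group=lev,
                c_bar=float(sub.mean()),
                b=bmap.get(lev),
                n=int(len(sub)),
            )
        )
    return out


# --------------------------------------------------------------------------
# operations

def test_density_variation(
    records: Iterable[ExperimentRecord] | pd.DataFrame,
    grouping: Grouping,
    *,
    scale: str = DEFAULT_SCALE,
    alpha: float = DEFAULT_ALPHA,
) -> FitResult:
    """One-way comparison of mean microbial density across group levels.

    A significant omnibus group effect indicates variation in resistance
    (host-type grouping) or proliferation (strain grouping).  Densities are
    compared on the analysis scale.
    """
    df, n_excluded = _prepare(records, scale)
    levels = _levels(df, grouping)
    counts = df[grouping].astype(str).value_counts()
    thin = [lev for lev in levels if counts.get(lev, 0) < 2]
    if thin:
        raise DesignError(f"need >=2 records per {grouping} level; too few in {thin}")

    y = df["d"].to_numpy()
    G = _dummies(df, grouping, levels)
    X = np.column_stack([np.ones(len(df)), G])
    names = ["Intercept"] + [f"{grouping}[{lev}]" for lev in levels[1:]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.OLS(y, X).fit()

    # omnibus F from the one-way decomposition of sums of squares
    flags: list[str] = []
    grand = y.mean()
    ssb = ssw = 0.0
    for lev in levels:
        sub = y[df[grouping].astype(str).to_numpy() == lev]
        ssb += len(sub) * (sub.mean() - grand) ** 2
        ssw += float(np.sum((sub - sub.mean()) ** 2))
    df_b, df_w = len(levels) - 1, len(df) - len(levels)
    tol = 1e-12 * (float(np.sum((y - grand) ** 2)) + 1.0)
    if ssw <= tol:
        F, p = math.nan, math.nan
        flags.append("zero_within_group_variance")
    else:
        F = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(F, df_b, df_w))

    test = TermTest(name=grouping, statistic=F, df_num=df_b, df_den=df_w, pvalue=p)
    summaries = _group_summaries(df, grouping, levels, lines=None)
    return FitResult(
        model_name=f"density ~ {grouping}",
        property_label=_DENSITY_PROPERTY[grouping],
        grouping=grouping,
        formula_terms=["Intercept", grouping],
        coefficients=_coef_table(fit.params, fit.bse, fit.pvalues, names),
        term_tests={grouping: test},
        interaction_p=None,
        group_lines=[],
        group_summaries=summaries,
        n_obs=int(len(df)),
        n_excluded=n_excluded,
        analysis_scale=scale,
        alpha=alpha,
        flags=flags,
    )


def _require_density_variation(df: pd.DataFrame, grouping: str, levels: list[str]) -> None:
    bad = []
    for lev in levels:
        sub = df.loc[df[grouping].astype(str) == lev, "d"]
        if len(sub) < 2 or float(sub.max() - sub.min()) == 0.0:
            bad.append(lev)
    if bad:
        raise DesignError(
            f"density does not vary within {grouping} level(s) {bad}: "
            "slope unidentifiable"
        )


def _interaction_design(
    df: pd.DataFrame, grouping: str, levels: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    n = len(df)
    d = df["d"].to_numpy()
    G = _dummies(df, grouping, levels)
    ones = np.ones(n)
    X_add = np.column_stack([ones, G, d])
    X_full = np.column_stack([ones, G, d, G * d[:, None]])
    names_add = (
        ["Intercept"]
        + [f"{grouping}[{lev}]" for lev in levels[1:]]
        + ["density"]
    )
    names_full = names_add + [f"{grouping}[{lev}]:density" for lev in levels[1:]]
    return X_add, X_full, names_add, names_full


def test_slope_variation(
    records: Iterable[ExperimentRecord] | pd.DataFrame,
    grouping: Grouping,
    *,
    scale: str = DEFAULT_SCALE,
    alpha: float = DEFAULT_ALPHA,
    overlap_threshold: float = 0.5,
) -> FitResult:
    """Slope-comparison ANCOVA: health against group, density, and their
    interaction.

    The interaction is tested with an extra-sum-of-squares F against the
    additive model; a significant interaction indicates variation in
    tolerance (host-type grouping) or benevolence (strain grouping).
    Per-group lines are derived from the saturated fit and therefore equal
    independent per-group least-squares fits.  Group pairs with poor density
    overlap downgrade the result with an ``unreliable_slope_comparison``
    flag.
    """
    df, n_excluded = _prepare(records, scale, require_kind="continuous")
    levels = _levels(df, grouping)
    _require_density_variation(df, grouping, levels)

    y = df["outcome"].to_numpy(dtype=float)
    X_add, X_full, _, names_full = _interaction_design(df, grouping, levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_full = sm.OLS(y, X_full).fit()
        fit_add = sm.OLS(y, X_add).fit()

    tss = float(np.sum((y - y.mean()) ** 2))
    F, df_num, df_den, p = _extra_ss_f(fit_full, fit_add, tss)
    flags: list[str] = []
    if math.isnan(p):
        flags.append("degenerate_p_zero_residual_variance")

    lines = _group_lines_from_full(
        np.asarray(fit_full.params),
        np.asarray(fit_full.cov_params()),
        levels,
        df_resid=float(fit_full.df_resid),
    )
    summaries = _group_summaries(df, grouping, levels, lines)

    # density-overlap caveat: poor overlap can fabricate slope differences
    from .diagnostics import density_overlap

    overlap = density_overlap(df, grouping, threshold=overlap_threshold, scale=scale)
    if overlap.flagged_pairs:
        flags.append(
            "unreliable_slope_comparison:low_density_overlap:"
            + ";".join(f"{a}~{b}" for a, b, _ in overlap.flagged_pairs)
        )

    interaction = TermTest(
        name=f"{grouping}:density", statistic=F, df_num=df_num, df_den=df_den, pvalue=p
    )
    return FitResult(
        model_name=f"health ~ {grouping} + density + {grouping}:density",
        property_label=_SLOPE_PROPERTY[grouping],
        grouping=grouping,
        formula_terms=names_full,
        coefficients=_coef_table(fit_full.params, fit_full.bse, fit_full.pvalues, names_full),
        term_tests={interaction.name: interaction},
        interaction_p=p,
        group_lines=lines,
        group_summaries=summaries,
        n_obs=int(len(df)),
        n_excluded=n_excluded,
        analysis_scale=scale,
        alpha=alpha,
        flags=flags,
    )


def fit_binary_outcome(
    records: Iterable[ExperimentRecord] | pd.DataFrame,
    grouping: Grouping,
    *,
    scale: str = DEFAULT_SCALE,
    alpha: float = DEFAULT_ALPHA,
) -> FitResult:
    """Binomial (logit) analogue of the slope comparison for 0/1 survival.

    Per-group slopes are on the log-odds scale; the interaction is tested by
    likelihood ratio against the additive model.  Complete separation is
    detected, flagged, and handled with a small-ridge penalized refit whose
    p-values are not reported.
    """
    df, n_excluded = _prepare(records, scale, require_kind="binary")
    y = df["outcome"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise DesignError(
            "degenerate binary outcome: all hosts share the same survival status"
        )
    levels = _levels(df, grouping)
    _require_density_variation(df, grouping, levels)
    X_add, X_full, _, names_full = _interaction_design(df, grouping, levels)

    flags: list[str] = []
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit_full = sm.GLM(y, X_full, family=sm.families.Binomial()).fit(maxiter=100)
            fit_add = sm.GLM(y, X_add, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception:
            separated = True
            fit_full = fit_add = None
    if fit_full is not None:
        mu = np.asarray(fit_full.fittedvalues)
        if np.max(np.abs(np.asarray(fit_full.params))) > 30 or np.all(
            (mu < 1e-8) | (mu > 1 - 1e-8)
        ):
            separated = True

    if separated:
        # monotone likelihood: fall back to an L2-penalized fit for estimates
        flags += ["complete_separation", "penalized_fallback"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_full = sm.GLM(y, X_full, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-3, L1_wt=0.0
            )
        params = np.asarray(fit_full.params, dtype=float)
        bse = np.full_like(params, np.nan)
        pvals = np.full_like(params, np.nan)
        p_int = math.nan
        cov = np.full((len(params), len(params)), np.nan)
        df_resid = float(len(df) - len(params))
    else:
        params = np.asarray(fit_full.params, dtype=float)
        bse = np.asarray(fit_full.bse, dtype=float)
        pvals = np.asarray(fit_full.pvalues, dtype=float)
        cov = np.asarray(fit_full.cov_params())
        df_resid = float(fit_full.df_resid)
        lr = 2.0 * (fit_full.llf - fit_add.llf)
        df_num = len(levels) - 1
        p_int = float(stats.chi2.sf(max(lr, 0.0), df_num))

    k = len(levels)
    lines = []
    for j, lev in enumerate(levels):
        la = np.zeros(len(params))
        lb = np.zeros(len(params))
        la[0] = 1.0
        lb[k] = 1.0
        if j > 0:
            la[j] = 1.0
            lb[k + j] = 1.0
        se_a = float(np.sqrt(la @ cov @ la)) if not separated else math.nan
        se_b = float(np.sqrt(lb @ cov @ lb)) if not separated else math.nan
        lines.append(
            HealthDensityLine(
                group=lev,
                a=float(la @ params),
                b=float(lb @ params),
                se_a=0.0 if math.isnan(se_a) else se_a,
                se_b=0.0 if math.isnan(se_b) else se_b,
                df_resid=df_resid,
            )
        )
    summaries = _group_summaries(df, grouping, levels, lines)

    if separated:
        stat = math.nan
        df_num = len(levels) - 1
    else:
        stat = float(2.0 * (fit_full.llf - fit_add.llf))
    interaction = TermTest(
        name=f"{grouping}:density",
        statistic=stat,
        df_num=float(len(levels) - 1),
        df_den=None,
        pvalue=p_int,
        kind="LRT",
    )
    return FitResult(
        model_name=f"survival ~ {grouping} + density + {grouping}:density (binomial logit)",
        property_label=_SLOPE_PROPERTY[grouping] + " (log-odds scale)",
        grouping=grouping,
        formula_terms=names_full,
        coefficients=_coef_table(params, bse, pvals, names_full),
        term_tests={interaction.name: interaction},
        interaction_p=p_int,
        group_lines=lines,
        group_summaries=summaries,
        n_obs=int(len(df)),
        n_excluded=n_excluded,
        analysis_scale=scale,
        alpha=alpha,
        outcome_kind="binary",
        flags=flags,
    )


def fit_quadratic_extension(
    records: Iterable[ExperimentRecord] | pd.DataFrame,
    grouping: Grouping,
    *,
    scale: str = DEFAULT_SCALE,
    alpha: float = DEFAULT_ALPHA,
) -> FitResult:
    """Slope comparison extended with density^2 and its group interaction.

    The curvature evidence is the extra-sum-of-squares F of the quadratic
    model against the linear interaction model.  Per-group quadratic
    coefficients are reported alongside the linear terms of each group.
    """
    df, n_excluded = _prepare(records, scale, require_kind="continuous")
    levels = _levels(df, grouping)
    _require_density_variation(df, grouping, levels)
    bad = [
        lev
        for lev in levels
        if df.loc[df[grouping].astype(str) == lev, "d"].nunique() < 3
    ]
    if bad:
        raise DesignError(
            f"quadratic term unidentifiable: <3 distinct densities in {grouping} "
            f"level(s) {bad}"
        )

    y = df["outcome"].to_numpy(dtype=float)
    d = df["d"].to_numpy()
    G = _dummies(df, grouping, levels)
    ones = np.ones(len(df))
    X_lin = np.column_stack([ones, G, d, G * d[:, None]])
    X_quad = np.column_stack([ones, G, d, d**2, G * d[:, None], G * (d**2)[:, None]])
    names = (
        ["Intercept"]
        + [f"{grouping}[{lev}]" for lev in levels[1:]]
        + ["density", "density^2"]
        + [f"{grouping}[{lev}]:density" for lev in levels[1:]]
        + [f"{grouping}[{lev}]:density^2" for lev in levels[1:]]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_quad = sm.OLS(y, X_quad).fit()
        fit_lin = sm.OLS(y, X_lin).fit()

    tss = float(np.sum((y - y.mean()) ** 2))
    F, df_num, df_den, p = _extra_ss_f(fit_quad, fit_lin, tss)
    flags: list[str] = []
    if math.isnan(p):
        flags.append("degenerate_p_zero_residual_variance")

    # per-group coefficients from the quadratic fit
    params = np.asarray(fit_quad.params)
    cov = np.asarray(fit_quad.cov_params())
    k = len(levels)
    i_d, i_d2 = k, k + 1
    lines = []
    quad: dict[str, float] = {}
    for j, lev in enumerate(levels):
        la = np.zeros(len(params))
        lb = np.zeros(len(params))
        lq = np.zeros(len(params))
        la[0] = 1.0
        lb[i_d] = 1.0
        lq[i_d2] = 1.0
        if j > 0:
            la[j] = 1.0
            lb[i_d2 + j] = 1.0
            lq[i_d2 + (k - 1) + j] = 1.0
        lines.append(
            HealthDensityLine(
                group=lev,
                a=float(la @ params),
                b=float(lb @ params),
                se_a=float(np.sqrt(max(la @ cov @ la, 0.0))),
                se_b=float(np.sqrt(max(lb @ cov @ lb, 0.0))),
                df_resid=float(fit_quad.df_resid),
            )
        )
        quad[lev] = float(lq @ params)
    summaries = _group_summaries(df, grouping, levels, lines)

    curvature = TermTest(
        name="curvature", statistic=F, df_num=df_num, df_den=df_den, pvalue=p
    )
    return FitResult(
        model_name=(
            f"health ~ {grouping} + density + density^2 "
            f"+ {grouping}:density + {grouping}:density^2"
        ),
        property_label=_SLOPE_PROPERTY[grouping] + " (quadratic extension)",
        grouping=grouping,
        formula_terms=names,
        coefficients=_coef_table(fit_quad.params, fit_quad.bse, fit_quad.pvalues, names),
        term_tests={"curvature": curvature},
        interaction_p=p,
        group_lines=lines,
        group_summaries=summaries,
        group_quadratic=quad,
        n_obs=int(len(df)),
        n_excluded=n_excluded,
        analysis_scale=scale,
        alpha=alpha,
        flags=flags,
    )


def fit_combined_factorial(
    records: Iterable[ExperimentRecord] | pd.DataFrame,
    *,
    scale: str = DEFAULT_SCALE,
    alpha: float = DEFAULT_ALPHA,
) -> FactorialResult:
    """Fully factorial design: >=2 host types crossed with >=2 strains.

    Two models are fitted.  The density model (density against host type and
    strain) tests variation in resistance and proliferation; the host x
    strain interaction is screened first and retained only if significant,
    in which case the result is flagged because the density outcome then
    depends on the specific host-strain combination.  The health model adds
    density and its interactions with both factors, testing variation in
    tolerance (host x density) and benevolence (strain x density).
    """
    df, n_excluded = _prepare(records, scale, require_kind="continuous")
    hosts = _levels(df, "host_type")
    strains = _levels(df, "strain")
    present = set(zip(df["host_type"].astype(str), df["strain"].astype(str)))
    missing = [
        (h, s) for h in hosts for s in strains if (h, s) not in present
    ]
    if missing:
        raise DesignError(
            "empty host_type x strain cells make the interaction screen "
            f"inestimable: {missing}"
        )

    n = len(df)
    ones = np.ones(n)
    H = _dummies(df, "host_type", hosts)
    S = _dummies(df, "strain", strains)
    HS = np.column_stack(
        [H[:, i] * S[:, j] for i in range(H.shape[1]) for j in range(S.shape[1])]
    ) if H.shape[1] and S.shape[1] else np.empty((n, 0))
    d = df["d"].to_numpy()
    y = df["outcome"].to_numpy(dtype=float)

    host_names = [f"host_type[{h}]" for h in hosts[1:]]
    strain_names = [f"strain[{s}]" for s in strains[1:]]
    hs_names = [
        f"host_type[{h}]:strain[{s}]" for h in hosts[1:] for s in strains[1:]
    ]

    # ---- density model with host x strain screen
    X_add = np.column_stack([ones, H, S])
    X_hs = np.column_stack([ones, H, S, HS])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_hs = sm.OLS(d, X_hs).fit()
        fit_add = sm.OLS(d, X_add).fit()
    tss_d = float(np.sum((d - d.mean()) ** 2))
    F_s, dfn_s, dfd_s, p_screen = _extra_ss_f(fit_hs, fit_add, tss_d)
    retained = (not math.isnan(p_screen)) and p_screen < alpha

    flags: list[str] = []
    if retained:
        flags.append("outcome_depends_on_host_strain_combination")
        dens_fit, dens_names = fit_hs, ["Intercept"] + host_names + strain_names + hs_names
    else:
        dens_fit, dens_names = fit_add, ["Intercept"] + host_names + strain_names

    # per-term F tests on the reported density model (model comparison)
    def _drop_fit(X, keep_cols):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.OLS(d, X[:, keep_cols]).fit()

    dens_X = X_hs if retained else X_add
    nb_h, nb_s = H.shape[1], S.shape[1]
    cols = np.arange(dens_X.shape[1])
    host_cols = cols[1 : 1 + nb_h]
    strain_cols = cols[1 + nb_h : 1 + nb_h + nb_s]
    dens_tests: dict[str, TermTest] = {}
    for name, drop in (("host_type", host_cols), ("strain", strain_cols)):
        keep = [c for c in cols if c not in set(drop)]
        fit_red = _drop_fit(dens_X, keep)
        F, dfn, dfd, p = _extra_ss_f(dens_fit, fit_red, tss_d)
        dens_tests[name] = TermTest(name=name, statistic=F, df_num=dfn, df_den=dfd, pvalue=p)
    dens_tests["host_type:strain"] = TermTest(
        name="host_type:strain", statistic=F_s, df_num=dfn_s, df_den=dfd_s, pvalue=p_screen
    )

    dens_summaries_h = _group_summaries(df, "host_type", hosts, lines=None)
    dens_summaries_s = _group_summaries(df, "strain", strains, lines=None)
    density_model = FitResult(
        model_name="density ~ host_type + strain"
        + (" + host_type:strain" if retained else ""),
        property_label="resistance+proliferation",
        grouping="host_type+strain",
        formula_terms=dens_names,
        coefficients=_coef_table(dens_fit.params, dens_fit.bse, dens_fit.pvalues, dens_names),
        term_tests=dens_tests,
        interaction_p=p_screen,
        group_lines=[],
        group_summaries=dens_summaries_h + dens_summaries_s,
        n_obs=n,
        n_excluded=n_excluded,
        analysis_scale=scale,
        alpha=alpha,
        flags=list(flags),
    )

    # ---- health model with both density interactions
    Xh_full = np.column_stack([ones, H, S, d, H * d[:, None], S * d[:, None]])
    health_names = (
        ["Intercept"]
        + host_names
        + strain_names
        + ["density"]
        + [f"{t}:density" for t in host_names]
        + [f"{t}:density" for t in strain_names]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_health = sm.OLS(y, Xh_full).fit()
    tss_y = float(np.sum((y - y.mean()) ** 2))
    colsh = np.arange(Xh_full.shape[1])
    i_d = 1 + nb_h + nb_s
    hd_cols = colsh[i_d + 1 : i_d + 1 + nb_h]
    sd_cols = colsh[i_d + 1 + nb_h : i_d + 1 + nb_h + nb_s]
    health_tests: dict[str, TermTest] = {}
    for name, drop in (("host_type:density", hd_cols), ("strain:density", sd_cols)):
        keep = [c for c in colsh if c not in set(drop)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_red = sm.OLS(y, Xh_full[:, keep]).fit()
        F, dfn, dfd, p = _extra_ss_f(fit_health, fit_red, tss_y)
        health_tests[name] = TermTest(name=name, statistic=F, df_num=dfn, df_den=dfd, pvalue=p)

    # per-cell lines: slope(h, s) = density + host:density + strain:density
    params = np.asarray(fit_health.params)
    cov = np.asarray(fit_health.cov_params())
    lines = []
    cell_summaries = []
    for hi, h in enumerate(hosts):
        for si, s in enumerate(strains):
            la = np.zeros(len(params))
            lb = np.zeros(len(params))
            la[0] = 1.0
            lb[i_d] = 1.0
            if hi > 0:
                la[hi] = 1.0
                lb[i_d + hi] = 1.0
            if si > 0:
                la[nb_h + si] = 1.0
                lb[i_d + nb_h + si] = 1.0
            label = f"{h}|{s}"
            line = HealthDensityLine(
                group=label,
                a=float(la @ params),
                b=float(lb @ params),
                se_a=float(np.sqrt(max(la @ cov @ la, 0.0))),
                se_b=float(np.sqrt(max(lb @ cov @ lb, 0.0))),
                df_resid=float(fit_health.df_resid),
            )
            lines.append(line)
            mask = (df["host_type"].astype(str) == h) & (df["strain"].astype(str) == s)
            cell_summaries.append(
                GroupSummary.from_parts(
                    group=label,
                    c_bar=float(df.loc[mask, "d"].mean()),
                    b=line.b,
                    n=int(mask.sum()),
                )
            )

    health_model = FitResult(
        model_name=(
            "health ~ host_type + strain + density "
            "+ host_type:density + strain:density"
        ),
        property_label="tolerance+benevolence",
        grouping="host_type+strain",
        formula_terms=health_names,
        coefficients=_coef_table(
            fit_health.params, fit_health.bse, fit_health.pvalues, health_names
        ),
        term_tests=health_tests,
        interaction_p=None,
        group_lines=lines,
        group_summaries=cell_summaries,
        n_obs=n,
        n_excluded=n_excluded,
        analysis_scale=scale,
        alpha=alpha,
        flags=list(flags),
    )

    return FactorialResult(
        density_model=density_model,
        health_model=health_model,
        host_strain_screen_p=p_screen,
        interaction_retained=retained,
        flags=flags,
    )
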