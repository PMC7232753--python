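"""Core algebra of the health–density framework.

The framework rests on a linear description of one infected host group,

    health = a + b * density,

where ``a`` is the baseline health of uninfected hosts (vigour), ``b`` the
change in health per unit microbial density, and the group mean density
``c_bar`` summarises how well the microbe grows in that host.  Read across
host types, ``c_bar`` measures (inverse) resistance and ``b`` tolerance;
read across microbial strains in one host, they measure proliferation and
benevolence.  The signed product ``b * c_bar`` is the virulence of a
malevolent (``b < 0``) microbe.

Densities may be analysed on the raw cfu scale or, by default, on
``log10(cfu + 1)``, since colony counts commonly span orders of magnitude.
Every result object records the scale it was computed on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DiagnosticError, DomainError

Scale = Literal["raw", "log10p1"]

#: Density analysis scales understood by the package.
SCALES: tuple[str, ...] = ("raw", "log10p1")

DEFAULT_SCALE: Scale = "log10p1"
DEFAULT_ALPHA: float = 0.05


def validate_scale(scale: str) -> str:
    if scale not in SCALES:
        raise ConfigurationError(
            f"unknown analysis scale {scale!r}; expected one of {SCALES}"
        )
    return scale


def to_analysis_scale(density_raw, scale: str = DEFAULT_SCALE):
    """Transform raw cfu densities onto the configured analysis scale."""
    validate_scale(scale)
    arr = np.asarray(density_raw, dtype=float)
    if np.any(arr < 0):
        raise DomainError("raw microbial density must be non-negative")
    if scale == "raw":
        return arr if arr.ndim else float(arr)
    out = np.log10(arr + 1.0)
    return out if out.ndim else float(out)


def from_analysis_scale(density, scale: str = DEFAULT_SCALE):
    """Invert :func:`to_analysis_scale` (analysis scale back to raw cfu)."""
    validate_scale(scale)
    arr = np.asarray(density, dtype=float)
    if scale == "raw":
        return arr if arr.ndim else float(arr)
    out = np.power(10.0, arr) - 1.0
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ExperimentRecord:
    """One infected host: who was infected, with what, and the outcome.

    ``density`` is always stored on the raw cfu scale; analyses transform it
    onto the configured scale.  ``outcome`` is either a continuous health
    score or a 0/1 survival indicator, disambiguated by ``outcome_kind``.
    """

    host_type: str
    strain: str
    density: float
    outcome: float
    outcome_kind: Literal["continuous", "binary"] = "continuous"

    def __post_init__(self) -> None:
        if not str(self.host_type):
            raise DomainError("host_type label must be non-empty")
        if not str(self.strain):
            raise DomainError("strain label must be non-empty")
        if not math.isfinite(self.density):
            raise DomainError("density must be finite")
        if self.density < 0:
            raise DomainError(f"density must be >= 0 on the raw scale, got {self.density}")
        if self.outcome_kind == "binary":
            if self.outcome not in (0, 0.0, 1, 1.0):
                raise DomainError(f"binary outcome must be 0 or 1, got {self.outcome}")
        elif self.outcome_kind == "continuous":
            if not math.isfinite(self.outcome):
                raise DomainError("continuous outcome must be finite")
        else:
            raise DomainError(f"unknown outcome_kind {self.outcome_kind!r}")

    @property
    def uninfected(self) -> bool:
        """Hosts with zero density contribute to the intercept only."""
        return self.density == 0


def records_to_frame(records: Iterable[ExperimentRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalise a record list (or an equivalent DataFrame) to a DataFrame
    with columns host_type, strain, density, outcome, outcome_kind."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        required = {"host_type", "strain", "density", "outcome", "outcome_kind"}
        missing = required - set(df.columns)
        if missing:
            raise DomainError(f"record frame missing columns: {sorted(missing)}")
        return df
    rows = list(records)
    return pd.DataFrame(
        {
            "host_type": [r.host_type for r in rows],
            "strain": [r.strain for r in rows],
            "density": [r.density for r in rows],
            "outcome": [r.outcome for r in rows],
            "outcome_kind": [r.outcome_kind for r in rows],
        }
    )


@dataclass(frozen=True)
class HealthDensityLine:
    """Fitted line for one group: intercept ``a`` (vigour) and slope ``b``
    (tolerance for a host type, benevolence for a strain)."""

    group: str
    a: float
    b: float
    se_a: float = 0.0
    se_b: float = 0.0
    df_resid: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.a) or not math.isfinite(self.b):
            raise DomainError("line parameters must be finite")
        if self.se_a < 0 or self.se_b < 0:
            raise DomainError("standard errors must be non-negative")


@dataclass(frozen=True)
class GroupSummary:
    """Per-group traits: mean density, slope, and their signed product.

    Density-only models estimate no slope; ``b`` and ``virulence`` are then
    ``None``.  When present, ``virulence`` must equal ``b * c_bar``.
    """

    group: str
    c_bar: float
    b: float | None
    virulence: float | None
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("group size n must be positive")
        if self.c_bar < 0:
            raise DomainError("mean density must be non-negative on the analysis scale")
        if (self.b is None) != (self.virulence is None):
            raise DomainError("b and virulence must both be set or both be None")
        if self.b is not None:
            expected = self.b * self.c_bar
            if not math.isclose(self.virulence, expected, rel_tol=1e-12, abs_tol=1e-12):
                raise DomainError(
                    f"virulence {self.virulence} inconsistent with b*c_bar = {expected}"
                )

    @classmethod
    def from_parts(
        cls, group: str, c_bar: float, b: float | None, n: int
    ) -> "GroupSummary":
        v = None if b is None else b * c_bar
        return cls(group=group, c_bar=c_bar, b=b, virulence=v, n=n)


def predict_health(line: HealthDensityLine, density: float) -> float:
    """Expected health at a given density under a fitted line."""
    if not math.isfinite(density):
        raise DomainError("density must be finite")
    if density < 0:
        raise DomainError("density must be non-negative")
    return line.a + line.b * density


def virulence(b: float, c_bar: float) -> float:
    """Signed virulence ``b * c_bar``; negative means net harm."""
    if not (math.isfinite(b) and math.isfinite(c_bar)):
        raise DomainError("virulence inputs must be finite")
    if c_bar < 0:
        raise DomainError("mean density must be non-negative")
    return b * c_bar


def slope_pvalue(line: HealthDensityLine) -> float:
    """Two-sided p-value for the slope differing from zero.

    Uses a t reference when the line carries residual degrees of freedom,
    otherwise a normal approximation.  A zero standard error with a nonzero
    slope yields p = 0 (exact fit); a zero slope yields p = 1.
    """
    if line.se_b == 0:
        return 1.0 if line.b == 0 else 0.0
    t = line.b / line.se_b
    if line.df_resid is not None and line.df_resid > 0:
        return float(2 * stats.t.sf(abs(t), line.df_resid))
    return float(2 * stats.norm.sf(abs(t)))


def classify_direction(
    line: HealthDensityLine,
    density_range: Sequence[float],
    alpha: float | None = DEFAULT_ALPHA,
) -> str:
    """Call a group's health effect benevolent, neutral, or malevolent.

    The call applies within the observed span of densities.  With ``alpha``
    set, a two-sided test of b != 0 gates the call; with ``alpha=None`` the
    sign of the point estimate decides.
    """
    lo, hi = float(density_range[0]), float(density_range[1])
    if not (hi > lo):
        raise DiagnosticError(
            f"zero-width density range [{lo}, {hi}] for group {line.group!r}: "
            "slope unidentifiable"
        )
    if line.b == 0:
        return "neutral"
    if alpha is None:
        return "benevolent" if line.b > 0 else "malevolent"
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0,1), got {alpha}")
    if slope_pvalue(line) >= alpha:
        return "neutral"
    return "benevolent" if line.b > 0 else "malevolent"
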