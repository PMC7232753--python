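"""Synthetic infection experiments with known ground truth.

Each scenario is a factorial design of (host type, strain) cells.  Within a
cell, microbial densities are drawn from a normal distribution on the
analysis scale (lognormal-like cfu under the default log10(cfu+1) scale,
matching how colony counts are usually reported), truncated at zero.
Continuous health is the cell's line ``a + b*d`` (plus an optional quadratic
term) with Gaussian noise; binary survival is Bernoulli with logit
``a + b*d``, so the generative ``a`` and ``b`` are then log-odds parameters.

Presets encode the canonical qualitative regimes: host types differing only
in resistance or only in tolerance, strains spanning benevolent / neutral /
malevolent slopes, and wild-type/knockout pairs that isolate a pure
benevolence, malevolence, or proliferation factor.

Scenario seeds are mandatory: an omitted seed raises instead of silently
drawing a random one, so every dataset is reproducible.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import (
    DEFAULT_SCALE,
    ExperimentRecord,
    from_analysis_scale,
    records_to_frame,
    validate_scale,
)
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

TRUNCATION_WARN_FRACTION = 0.001


@dataclass(frozen=True)
class CellParams:
    """Ground-truth parameters of one (host type, strain) cell."""

    host_type: str
    strain: str
    a: float
    b: float
    mu_density: float
    sd_density: float
    n: int
    quad: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"cell n must be >= 1, got {self.n}")
        if not self.sd_density > 0:
            raise ConfigurationError(f"sd_density must be > 0, got {self.sd_density}")
        for name in ("a", "b", "mu_density", "quad"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"cell parameter {name} must be finite")


@dataclass(frozen=True)
class SimulationScenario:
    """A complete simulated experiment: cells, noise, outcome type, seed."""

    cells: tuple[CellParams, ...]
    sigma_health: float
    outcome_kind: Literal["continuous", "binary"] = "continuous"
    seed: int | None = None
    analysis_scale: str = DEFAULT_SCALE
    name: str = "custom"
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.cells) < 1:
            raise ConfigurationError("scenario needs at least one cell")
        if self.outcome_kind not in ("continuous", "binary"):
            raise ConfigurationError(
                f"outcome_kind must be continuous|binary, got {self.outcome_kind!r}"
            )
        if self.outcome_kind == "continuous" and not self.sigma_health >= 0:
            raise ConfigurationError(
                f"sigma_health must be >= 0 for continuous outcomes, got {self.sigma_health}"
            )
        validate_scale(self.analysis_scale)

    def with_seed(self, seed: int) -> "SimulationScenario":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cells"] = [asdict(c) for c in self.cells]
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        d = dict(d)
        if d.get("seed") is None:
            raise ConfigurationError(
                "scenario has no seed: seeds are mandatory, add an integer 'seed'"
            )
        cells = tuple(CellParams(**c) for c in d.pop("cells"))
        return cls(cells=cells, **d)


def simulate_experiment(scenario: SimulationScenario) -> list[ExperimentRecord]:
    """Draw one dataset from a scenario; the seed fully determines it.

    Densities below zero on the analysis scale are redrawn (truncation); if
    more than 0.1% of draws are affected a warning is logged, since heavy
    truncation distorts the nominal mean and spread.
    """
    if scenario.seed is None:
        raise ConfigurationError(
            "scenario has no seed: seeds are mandatory, add an integer 'seed'"
        )
    rng = np.random.default_rng(scenario.seed)
    records: list[ExperimentRecord] = []
    n_total = 0
    n_truncated = 0
    for cell in scenario.cells:
        d = rng.normal(cell.mu_density, cell.sd_density, size=cell.n)
        n_total += cell.n
        neg = d < 0
        while neg.any():
            n_truncated += int(neg.sum())
            d[neg] = rng.normal(cell.mu_density, cell.sd_density, size=int(neg.sum()))
            neg = d < 0
        eta = cell.a + cell.b * d + cell.quad * d**2
        if scenario.outcome_kind == "continuous":
            outcome = eta + rng.normal(0.0, scenario.sigma_health, size=cell.n)
        else:
            outcome = rng.binomial(1, expit(eta)).astype(float)
        raw = from_analysis_scale(d, scenario.analysis_scale)
        # guard against tiny negative round-off when inverting log10(x+1)
        raw = np.maximum(raw, 0.0)
        for di, oi in zip(raw, outcome):
            records.append(
                ExperimentRecord(
                    host_type=cell.host_type,
                    strain=cell.strain,
                    density=float(di),
                    outcome=float(oi),
                    outcome_kind=scenario.outcome_kind,
                )
            )
    if n_truncated > TRUNCATION_WARN_FRACTION * n_total:
        logger.warning(
            "density truncation at zero affected %d of %d draws (%.2f%%)",
            n_truncated,
            n_total,
            100 * n_truncated / n_total,
        )
    return records


def simulate_frame(scenario: SimulationScenario) -> pd.DataFrame:
    """Same as :func:`simulate_experiment` but returned as a DataFrame."""
    return records_to_frame(simulate_experiment(scenario))


# --------------------------------------------------------------------------
# presets

def _strains(host: str, specs: list[tuple[str, float, float, float]], n: int,
             sd: float = 1.0) -> tuple[CellParams, ...]:
    return tuple(
        CellParams(host_type=host, strain=s, a=a, b=b, mu_density=mu,
                   sd_density=sd, n=n)
        for s, a, b, mu in specs
    )


def _hosts(strain: str, specs: list[tuple[str, float, float, float]], n: int,
           sd: float = 1.0) -> tuple[CellParams, ...]:
    return tuple(
        CellParams(host_type=h, strain=strain, a=a, b=b, mu_density=mu,
                   sd_density=sd, n=n)
        for h, a, b, mu in specs
    )


PRESET_NAMES = (
    "null",
    "fig1_resistance",
    "fig1_tolerance",
    "fig2_strains",
    "knockout_pure_benevolence",
    "knockout_pure_malevolence",
    "knockout_pure_proliferation",
    "knockout_mixed",
)


def make_preset(name: str, *, n: int = 50, seed: int | None = None) -> SimulationScenario:
    """Named scenario with documented ground truth.

    All presets use baseline health a = 10, health noise sigma = 1, and
    density spread sd = 1 on the log10(cfu+1) scale; n is the per-cell
    sample size.  Slope and mean-density offsets between cells are 1 unit
    where a difference is intended, a typical clearly-resolvable effect at
    the default n = 50.
    """
    if name == "null":
        cells = _strains("host", [("ko", 10, -1.0, 4.0), ("wt", 10, -1.0, 4.0)], n)
        truth = {"labels": [], "note": "identical wild type and knockout"}
    elif name == "fig1_resistance":
        cells = _hosts(
            "microbe",
            [("hostA", 10, -1.0, 2.0), ("hostB", 10, -1.0, 3.5), ("hostC", 10, -1.0, 5.0)],
            n,
            sd=0.75,
        )
        truth = {
            "varies": "resistance",
            "constant": "tolerance",
            "note": "host types differ in mean density only; slopes identical",
        }
    elif name == "fig1_tolerance":
        cells = _hosts(
            "microbe",
            [("hostA", 10, -0.5, 4.0), ("hostB", 10, -1.0, 4.0), ("hostC", 10, -1.5, 4.0)],
            n,
        )
        truth = {
            "varies": "tolerance",
            "constant": "resistance",
            "note": "host types differ in slope only; mean densities identical",
        }
    elif name == "fig2_strains":
        cells = _strains(
            "host",
            [
                ("benevolent", 10, 1.0, 3.0),
                ("malevolent", 10, -1.0, 5.0),
                ("neutral", 10, 0.0, 4.0),
            ],
            n,
        )
        truth = {
            "slope_signs": {"benevolent": 1, "neutral": 0, "malevolent": -1},
            "c_bar_order": ["benevolent", "neutral", "malevolent"],
        }
    elif name == "knockout_pure_benevolence":
        cells = _strains("host", [("ko", 10, -1.2, 4.0), ("wt", 10, -0.2, 4.0)], n)
        truth = {"labels": ["benevolence_factor"], "pure": True}
    elif name == "knockout_pure_malevolence":
        cells = _strains("host", [("ko", 10, -0.2, 4.0), ("wt", 10, -1.2, 4.0)], n)
        truth = {"labels": ["malevolence_factor"], "pure": True}
    elif name == "knockout_pure_proliferation":
        cells = _strains("host", [("ko", 10, -1.0, 4.0), ("wt", 10, -1.0, 5.0)], n)
        truth = {"labels": ["proliferation_factor"], "pure": True}
    elif name == "knockout_mixed":
        cells = _strains("host", [("ko", 10, -0.5, 4.0), ("wt", 10, -1.3, 5.0)], n)
        truth = {
            "labels": ["malevolence_factor", "proliferation_factor"],
            "pure": False,
        }
    else:
        raise ConfigurationError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        )
    return SimulationScenario(
        cells=cells,
        sigma_health=1.0,
        outcome_kind="continuous",
        seed=seed,
        analysis_scale=DEFAULT_SCALE,
        name=name,
        truth=truth,
    )


# --------------------------------------------------------------------------
# Monte-Carlo power machinery

_CELL_FIELD_RE = re.compile(r"^cells\[(\d+)\]\.(\w+)$")

_TEST_GROUPING = {
    "resistance": "host_type",
    "tolerance": "host_type",
    "proliferation": "strain",
    "benevolence": "strain",
    "binary": "strain",
    "curvature": "strain",
}


def _apply_parameter(scenario: SimulationScenario, parameter: str, value) -> SimulationScenario:
    cells = list(scenario.cells)
    if parameter == "n":
        cells = [replace(c, n=int(value)) for c in cells]
    elif parameter == "sigma_health":
        return replace(scenario, sigma_health=float(value))
    elif parameter in ("delta_b", "delta_mu"):
        if len(cells) < 2:
            raise ConfigurationError(f"{parameter} requires >=2 cells")
        if parameter == "delta_b":
            cells[1] = replace(cells[1], b=cells[0].b + float(value))
        else:
            cells[1] = replace(cells[1], mu_density=cells[0].mu_density + float(value))
    else:
        m = _CELL_FIELD_RE.match(parameter)
        if not m:
            raise ConfigurationError(
                f"unknown varied parameter {parameter!r}; use 'n', 'sigma_health', "
                "'delta_b', 'delta_mu', or 'cells[i].<field>'"
            )
        i, fname = int(m.group(1)), m.group(2)
        if i >= len(cells):
            raise ConfigurationError(f"cell index {i} out of range")
        if not hasattr(cells[i], fname):
            raise ConfigurationError(f"unknown cell field {fname!r}")
        cells[i] = replace(cells[i], **{fname: type(getattr(cells[i], fname))(value)})
    return replace(scenario, cells=tuple(cells))


def _test_pvalue(records, test: str, scale: str):
    from .inference import (
        fit_binary_outcome,
        fit_quadratic_extension,
        test_density_variation,
        test_slope_variation,
    )

    grouping = _TEST_GROUPING[test]
    if test in ("resistance", "proliferation"):
        fit = test_density_variation(records, grouping, scale=scale)
        return fit.term_tests[grouping].pvalue
    if test in ("tolerance", "benevolence"):
        return test_slope_variation(records, grouping, scale=scale).interaction_p
    if test == "binary":
        return fit_binary_outcome(records, grouping, scale=scale).interaction_p
    if test == "curvature":
        fit = fit_quadratic_extension(records, grouping, scale=scale)
        return fit.term_tests["curvature"].pvalue
    raise ConfigurationError(f"unknown test {test!r}; known: {sorted(_TEST_GROUPING)}")


def power_sweep(
    base_scenario: SimulationScenario,
    varied_parameter: str,
    grid: Iterable,
    reps: int,
    alpha: float = 0.05,
    *,
    test: str = "benevolence",
) -> pd.DataFrame:
    """Monte-Carlo rejection rate of one test along a parameter grid.

    For each grid value the scenario is re-parameterised, ``reps`` datasets
    are simulated, and the fraction rejecting at ``alpha`` is reported with
    its binomial Monte-Carlo standard error.  All replicate seeds derive
    from the base scenario's seed.
    """
    grid = list(grid)
    if not grid:
        raise ConfigurationError("power sweep grid is empty")
    if reps < 1:
        raise ConfigurationError(f"reps must be >= 1, got {reps}")
    if test not in _TEST_GROUPING:
        raise ConfigurationError(f"unknown test {test!r}; known: {sorted(_TEST_GROUPING)}")
    if base_scenario.seed is None:
        raise ConfigurationError("base scenario needs a seed for a power sweep")

    master = np.random.default_rng(base_scenario.seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=(len(grid), reps))
    rows = []
    for gi, value in enumerate(grid):
        scen = _apply_parameter(base_scenario, varied_parameter, value)
        rejections = 0
        for r in range(reps):
            records = simulate_experiment(scen.with_seed(int(rep_seeds[gi, r])))
            p = _test_pvalue(records, test, scen.analysis_scale)
            if p == p and p < alpha:  # NaN-safe
                rejections += 1
        power = rejections / reps
        rows.append(
            {
                "parameter": varied_parameter,
                "value": value,
                "power": power,
                "mc_se": math.sqrt(power * (1 - power) / reps),
                "reps": reps,
                "test": test,
                "alpha": alpha,
            }
        )
    return pd.DataFrame(rows)
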