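"""Reading and writing experiment records, scenarios, and results.

The on-disk record format is a plain CSV/TSV with header columns
``host_type, strain, density`` and exactly one outcome column, ``health``
(continuous) or ``survived`` (0/1).  Densities are on the raw cfu scale.
Column aliases can be supplied for files that use other names.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

from .core import ExperimentRecord
from .errors import ConfigurationError, FormatError
from .simulate import SimulationScenario

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("host_type", "strain", "density")
OUTCOME_COLUMNS = ("health", "survived")


@dataclass
class ReadReport:
    """Outcome of parsing a record file: good records plus row-level errors."""

    records: list[ExperimentRecord]
    errors: list[tuple[int, str]] = field(default_factory=list)  # (row index, message)
    outcome_kind: str = "continuous"

    @property
    def n_rejected(self) -> int:
        return len(self.errors)


def _sniff_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_records_report(
    path: str | Path,
    *,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> ReadReport:
    """Parse a record CSV/TSV, rejecting malformed rows individually.

    ``column_map`` maps the standard names to the file's actual column
    names, e.g. ``{"density": "cfu_per_ml"}``.  Row indices in error
    messages are 1-based data rows (header excluded).
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    cmap = {k: k for k in REQUIRED_COLUMNS + OUTCOME_COLUMNS}
    if column_map:
        cmap.update(column_map)

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for col in REQUIRED_COLUMNS:
            if cmap[col] not in header:
                raise FormatError(
                    f"missing required column {cmap[col]!r} in {path.name} "
                    f"(header: {header})"
                )
        has_health = cmap["health"] in header
        has_survived = cmap["survived"] in header
        if has_health == has_survived:
            raise FormatError(
                f"{path.name} must have exactly one outcome column, "
                f"'{cmap['health']}' or '{cmap['survived']}'"
            )
        outcome_col = cmap["health"] if has_health else cmap["survived"]
        outcome_kind = "continuous" if has_health else "binary"

        records: list[ExperimentRecord] = []
        errors: list[tuple[int, str]] = []
        for i, row in enumerate(reader, start=1):
            try:
                density = float(row[cmap["density"]])
                outcome = float(row[outcome_col])
                rec = ExperimentRecord(
                    host_type=str(row[cmap["host_type"]]).strip(),
                    strain=str(row[cmap["strain"]]).strip(),
                    density=density,
                    outcome=outcome,
                    outcome_kind=outcome_kind,
                )
            except (TypeError, ValueError) as exc:
                errors.append((i, f"row {i}: {exc}"))
                continue
            records.append(rec)
    if errors:
        logger.warning(
            "%s: rejected %d malformed row(s): %s",
            path.name,
            len(errors),
            "; ".join(msg for _, msg in errors[:5]),
        )
    return ReadReport(records=records, errors=errors, outcome_kind=outcome_kind)


def read_records(
    path: str | Path,
    *,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
    strict: bool = True,
) -> list[ExperimentRecord]:
    """Read records; with ``strict`` (default) any malformed row raises,
    otherwise malformed rows are skipped with a logged count."""
    report = read_records_report(path, column_map=column_map, delimiter=delimiter)
    if strict and report.errors:
        raise FormatError(
            f"{Path(path).name}: {report.n_rejected} malformed row(s): "
            + "; ".join(msg for _, msg in report.errors)
        )
    return report.records


def write_records(
    records: Iterable[ExperimentRecord], path: str | Path, *, delimiter: str | None = None
) -> None:
    """Write records to CSV/TSV in the standard column layout.

    Float formatting uses repr round-tripping, so write-then-read is the
    identity on all fields.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    rows = list(records)
    kinds = {r.outcome_kind for r in rows}
    if len(kinds) > 1:
        raise FormatError(f"cannot mix outcome kinds in one file: {sorted(kinds)}")
    outcome_col = "survived" if kinds == {"binary"} else "health"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["host_type", "strain", "density", outcome_col])
        for r in rows:
            outcome = int(r.outcome) if outcome_col == "survived" else repr(float(r.outcome))
            writer.writerow([r.host_type, r.strain, repr(float(r.density)), outcome])


def read_scenario(path: str | Path) -> SimulationScenario:
    """Load a simulation scenario from YAML or JSON; the seed is mandatory."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise FormatError(f"cannot parse scenario file {path.name}: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"scenario file {path.name} must hold a mapping")
    try:
        return SimulationScenario.from_dict(data)
    except TypeError as exc:
        raise ConfigurationError(f"invalid scenario in {path.name}: {exc}") from exc


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_clean(obj), indent=2) + "\n")


def _clean(obj):
    """Make nested results JSON-safe (NaN -> null, numpy scalars -> python)."""
    import numpy as np

    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj
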