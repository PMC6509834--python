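"""Patient-sample IO, positivity thresholding, and synthetic samples.

Samples are partial assignments of expression statuses to (marker,
location) pairs.  Percent-positive measurements are thresholded at a
configurable cutoff (default 20%, boundary inclusive) and never yield
high/low calls — relative amounts are not derivable from one percentage.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .kb import KnowledgeBase
from .model import ExpressionStatus, Location, Phenotype, literal_world_statuses
from .reasoner import is_satisfiable

__all__ = [
    "DEFAULT_CUTOFF",
    "PatientSample",
    "SimulationSpec",
    "MalformedRowError",
    "threshold_percent",
    "read_samples",
    "simulate_samples",
    "write_samples",
]

DEFAULT_CUTOFF = 20.0

MeasurementKey = Tuple[str, Location]


class MalformedRowError(ValueError):
    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass
class PatientSample:
    """Measured statuses for one specimen; ``percents`` holds the original
    percent-positive values when the sample came from (or is destined for)
    percent-based data."""

    sample_id: str
    measurements: Dict[MeasurementKey, ExpressionStatus] = field(default_factory=dict)
    percents: Optional[Dict[MeasurementKey, float]] = None


@dataclass
class SimulationSpec:
    """Parameters for the seeded synthetic-sample generator."""

    target_class: str
    n_samples: int
    seed: int
    noise_rate: float = 0.0
    panel: Optional[Sequence[MeasurementKey]] = None
    emit_percent: bool = False
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be within [0, 1]")
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")


def threshold_percent(value: float, cutoff: float = DEFAULT_CUTOFF) -> ExpressionStatus:
    """Positivity call for a percent-positive value (boundary inclusive)."""
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"percent value {value!r} outside [0, 100]")
    return ExpressionStatus.PRESENT if value >= cutoff else ExpressionStatus.ABSENT


_LOCATION_TOKENS = {loc.value: loc for loc in Location}
_STATUS_TOKENS = {st.value: st for st in ExpressionStatus}


def read_samples(
    path: Union[str, Path, io.TextIOBase],
    cutoff: float = DEFAULT_CUTOFF,
) -> List[PatientSample]:
    """Read patient samples from CSV.

    Columns: ``sample_id``, ``marker``, ``location``, and ``status`` and/or
    ``percent_positive`` — each row must fill exactly one of the latter two.
    Samples are grouped by ``sample_id`` preserving file order; duplicate
    (marker, location) rows within a sample are an error.
    """
    frame = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    required = {"sample_id", "marker", "location"}
    missing = required - set(frame.columns)
    if missing:
        raise MalformedRowError(1, f"missing columns: {', '.join(sorted(missing))}")
    has_status = "status" in frame.columns
    has_percent = "percent_positive" in frame.columns
    if not (has_status or has_percent):
        raise MalformedRowError(1, "need a status or percent_positive column")

    samples: Dict[str, PatientSample] = {}
    order: List[str] = []
    for index, row in frame.iterrows():
        line = int(index) + 2  # header is line 1
        sample_id = row["sample_id"]
        if pd.isna(sample_id) or not str(sample_id).strip():
            raise MalformedRowError(line, "empty sample_id")
        sample_id = str(sample_id).strip()
        marker = row["marker"]
        if pd.isna(marker) or not str(marker).strip():
            raise MalformedRowError(line, "empty marker")
        marker = str(marker).strip()
        raw_location = row["location"]
        location = _LOCATION_TOKENS.get(str(raw_location).strip().casefold())
        if location is None:
            raise MalformedRowError(line, f"unknown location {raw_location!r}")

        status_cell = row["status"] if has_status else None
        percent_cell = row["percent_positive"] if has_percent else None
        status_set = status_cell is not None and not pd.isna(status_cell)
        percent_set = percent_cell is not None and not pd.isna(percent_cell)
        if status_set and percent_set:
            raise MalformedRowError(line, "both status and percent_positive set")
        if not status_set and not percent_set:
            raise MalformedRowError(line, "neither status nor percent_positive set")

        percent: Optional[float] = None
        if status_set:
            status = _STATUS_TOKENS.get(str(status_cell).strip().casefold())
            if status is None:
                raise MalformedRowError(line, f"unknown status {status_cell!r}")
        else:
            try:
                percent = float(percent_cell)
            except (TypeError, ValueError):
                raise MalformedRowError(
                    line, f"percent_positive {percent_cell!r} is not a number"
                ) from None
            try:
                status = threshold_percent(percent, cutoff)
            except ValueError as exc:
                raise MalformedRowError(line, str(exc)) from None

        if sample_id not in samples:
            samples[sample_id] = PatientSample(sample_id=sample_id)
            order.append(sample_id)
        sample = samples[sample_id]
        key = (marker, location)
        if key in sample.measurements:
            raise MalformedRowError(
                line, f"duplicate measurement for ({marker}, {location.value})"
            )
        sample.measurements[key] = status
        if percent is not None:
            if sample.percents is None:
                sample.percents = {}
            sample.percents[key] = percent
    return [samples[sid] for sid in order]


def write_samples(
    samples: Iterable[PatientSample],
    path: Union[str, Path, io.TextIOBase],
    emit_percent: bool = False,
) -> None:
    """Write samples back to the CSV schema used by :func:`read_samples`."""
    own = not hasattr(path, "write")
    handle = open(path, "w", newline="", encoding="utf-8") if own else path
    try:
        writer = csv.writer(handle)
        value_column = "percent_positive" if emit_percent else "status"
        writer.writerow(["sample_id", "marker", "location", value_column])
        for sample in samples:
            for (marker, location), status in sample.measurements.items():
                if emit_percent:
                    if sample.percents is None or (marker, location) not in sample.percents:
                        raise ValueError(
                            f"sample {sample.sample_id!r} has no percent for "
                            f"({marker}, {location.value})"
                        )
                    value = f"{sample.percents[(marker, location)]:.2f}"
                else:
                    value = status.value
                writer.writerow([sample.sample_id, marker, location.value, value])
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _default_panel(expansion: Phenotype, kb: KnowledgeBase) -> List[MeasurementKey]:
    keys = {
        (lit.marker.label, lit.location): lit.marker.label.casefold()
        for lit in expansion.literals()
    }
    return sorted(keys, key=lambda key: (keys[key], key[1].value))


def simulate_samples(spec: SimulationSpec, kb: KnowledgeBase) -> List[PatientSample]:
    """Generate seeded synthetic samples consistent with a target class.

    Per sample: one literal of every clause of the target's expanded
    differentia is chosen uniformly at random and asserted; remaining panel
    markers are drawn present/absent with equal probability (which cannot
    falsify an already-witnessed clause); marker flips are then applied with
    probability ``noise_rate``; percent-positive values, when requested,
    straddle the cutoff accordingly.
    """
    if spec.target_class not in kb.classes:
        from .model import UnknownClassError

        raise UnknownClassError(spec.target_class)
    expansion = kb.expand(spec.target_class)
    if not is_satisfiable(expansion):
        raise ValueError(f"target class {spec.target_class!r} is unsatisfiable")

    label_of = {marker.id: marker.label for marker in kb.markers.values()}
    required = {
        (label_of[marker_id], Location(loc)) for marker_id, loc in expansion.variables()
    }
    if spec.panel is None:
        panel: List[MeasurementKey] = _default_panel(expansion, kb)
    else:
        panel = [(kb.resolve_marker(m).label, Location(loc)) for m, loc in spec.panel]
        missing = required - set(panel)
        if missing:
            names = ", ".join(sorted(f"{m}/{loc.value}" for m, loc in missing))
            raise ValueError(f"panel missing required marker-locations: {names}")

    rng = np.random.default_rng(spec.seed)
    samples: List[PatientSample] = []
    for i in range(spec.n_samples):
        assignment = _draw_assignment(expansion, label_of, rng)
        for key in panel:
            if key not in assignment:
                assignment[key] = (
                    ExpressionStatus.PRESENT
                    if rng.random() < 0.5
                    else ExpressionStatus.ABSENT
                )
        if spec.noise_rate > 0:
            for key in panel:
                if rng.random() < spec.noise_rate:
                    assignment[key] = (
                        ExpressionStatus.PRESENT
                        if assignment[key] is ExpressionStatus.ABSENT
                        else ExpressionStatus.ABSENT
                    )
        measurements = {key: assignment[key] for key in panel}
        percents = None
        if spec.emit_percent:
            percents = {}
            for key, status in measurements.items():
                if status is ExpressionStatus.ABSENT:
                    percents[key] = float(rng.uniform(0.0, spec.cutoff))
                else:
                    percents[key] = float(rng.uniform(spec.cutoff, 100.0))
                measurements[key] = threshold_percent(percents[key], spec.cutoff)
        samples.append(
            PatientSample(
                sample_id=f"sim-{spec.target_class}-{i + 1:03d}",
                measurements=measurements,
                percents=percents,
            )
        )
    return samples


_SET_STATUS = {
    ExpressionStatus.PRESENT: "present",
    ExpressionStatus.ABSENT: "absent",
    ExpressionStatus.HIGH: "high",
    ExpressionStatus.LOW: "low",
}


def _draw_assignment(
    expansion: Phenotype,
    label_of: Mapping[str, str],
    rng: np.random.Generator,
) -> Dict[MeasurementKey, ExpressionStatus]:
    """One witnessing literal per clause, chosen uniformly among those
    compatible with what earlier clauses already fixed."""
    for _ in range(100):
        world: Dict[MeasurementKey, str] = {}
        ok = True
        for clause in expansion.clauses:
            options = []
            for lit in clause:
                key = (label_of[lit.marker.id], lit.location)
                current = world.get(key)
                if current is None or current in literal_world_statuses(lit.status):
                    options.append((lit, key))
            if not options:
                ok = False
                break
            lit, key = options[int(rng.integers(len(options)))]
            if key not in world:
                world[key] = _SET_STATUS[lit.status]
        if ok:
            return {
                key: ExpressionStatus(value if value != "present" else "present")
                for key, value in world.items()
            }
    raise RuntimeError("could not draw a consistent witnessing assignment")
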