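"""Domain types, file readers/writers and run configuration.

The in-memory containers mirror what an instrumented-insole study produces:
a :class:`SensorLayout` per foot (sensor coordinates in mm), a bilateral
:class:`Recording` of per-sensor vertical ground reaction force, a
:class:`StepIndex` of detected foot contacts, and a :class:`WindowingPlan`
describing the step-level sliding-window augmentation.

Two text dialects are read: a canonical wide CSV
(``time_s, L1..Ln, R1..Rn``) and the PhysioNet-style VGRF text used by the
public Parkinson's gait records (19 whitespace-separated columns: time,
8 left sensors, 8 right sensors, 2 per-foot totals which are dropped).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml


# ---------------------------------------------------------------------------
# Errors and warnings
# ---------------------------------------------------------------------------

class WeakfootError(Exception):
    """Base class for all package errors."""


class ParseError(WeakfootError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SchemaError(WeakfootError):
    """Column/field arity or name mismatch."""


class ValidationError(WeakfootError):
    """Values violate a domain invariant (negative pressure, bad range...)."""


class EmptyGaitError(WeakfootError):
    """No foot contact detected in a recording."""


class InsufficientDataError(WeakfootError):
    """Too few steps/windows for the requested operation."""


class InsufficientSamplesError(WeakfootError):
    """Fewer than two feature vectors where a pairwise statistic is needed."""


class UndefinedCOPError(WeakfootError):
    """Centre of pressure undefined (no stance frames)."""


class UndefinedFeatureError(WeakfootError):
    """A feature could not be computed; names the missing features."""

    def __init__(self, features: Sequence[str]):
        self.features = list(features)
        super().__init__(f"undefined feature value(s): {', '.join(self.features)}")


class DegenerateGaitError(WeakfootError):
    """All long windows identical: the DDI baseline distance is zero."""


class UndefinedMetricsError(WeakfootError):
    """All confusion counts zero."""


class DegenerateCohortWarning(UserWarning):
    """All training DDI values equal; the threshold collapses."""


class UndefinedMetricWarning(UserWarning):
    """A ratio metric had a zero denominator and was reported as 0."""


class ShortRecordingWarning(UserWarning):
    """A recording was too short for the configured long window length."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

SIDES = ("left", "right")


@dataclass(frozen=True)
class SensorLayout:
    """Per-foot sensor coordinates.

    ``coords[i] = (x_i, y_i)`` in mm, in a per-foot local frame: y grows
    posterior -> anterior (heel to toes), x grows medial -> lateral.  Left
    x-coordinates are negated when the two feet must share one frame, so
    anatomically homologous sensors align.
    """

    side: str
    coords: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if len(self.coords) < 1:
            raise ValidationError("layout needs at least one sensor")
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise SchemaError("coords must be (x, y) pairs")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("layout coordinates must be finite")

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def xy(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class Recording:
    """Bilateral plantar-pressure time series.

    ``left``/``right`` are ``frames x n`` matrices of non-negative pressure
    in arbitrary linear units (raw ADC counts or N); no calibration is
    applied because every downstream statistic is either scale-invariant or
    documented as scale-dependent.
    """

    subject_id: str
    label: str  # "HR", "LR" or "unlabeled"
    rate: float  # Hz
    left: np.ndarray
    right: np.ndarray
    layout: dict[str, SensorLayout]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.label not in ("HR", "LR", "unlabeled"):
            raise ValidationError(f"label must be HR/LR/unlabeled, got {self.label!r}")
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.left.shape[0] != self.right.shape[0]:
            raise ValidationError("left/right must share the frame count")
        for side in SIDES:
            mat = getattr(self, side)
            lay = self.layout[side]
            if mat.ndim != 2 or mat.shape[1] != lay.n:
                raise SchemaError(
                    f"{side} matrix has {mat.shape[1] if mat.ndim == 2 else '?'} "
                    f"sensors, layout has {lay.n}"
                )
            if not np.all(np.isfinite(mat)):
                raise ValidationError(f"{side} pressures must be finite")
            if np.any(mat < 0):
                raise ValidationError(f"{side} pressures must be non-negative")
        if self.layout["left"].n != self.layout["right"].n:
            raise ValidationError("both feet must carry the same sensor count")

    @property
    def n_frames(self) -> int:
        return self.left.shape[0]

    def foot(self, side: str) -> np.ndarray:
        return getattr(self, side)


@dataclass(frozen=True)
class StepEvent:
    onset: int  # first frame of contact (inclusive)
    end: int    # one past the last frame of contact
    side: str


@dataclass
class StepIndex:
    """Detected foot-contact events, ordered by onset across both feet."""

    events: list[StepEvent]
    startup_discarded: int = 0

    def __post_init__(self):
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise ValidationError("step events must be ordered by onset")
        for e in self.events:
            if e.onset < 0 or e.end <= e.onset:
                raise ValidationError("step events need 0 <= onset < end")

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class WindowingPlan:
    """Step-level sliding-window plan: N = floor((S - L) / s) + 1."""

    S: int  # total steps after start-up discard
    L: int  # window length in steps
    s: int  # stride in steps

    def __post_init__(self):
        if not (1 <= self.L <= self.S):
            raise InsufficientDataError(f"need 1 <= L <= S, got L={self.L}, S={self.S}")
        if self.s < 1:
            raise ValidationError("stride must be >= 1")

    @property
    def N(self) -> int:
        return (self.S - self.L) // self.s + 1

    @property
    def starts(self) -> list[int]:
        return [i * self.s for i in range(self.N)]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

ALL_FEATURES = (
    "Std_x", "Mean_x", "Std_y", "Mean_y", "MRD", "SRD", "TOTEX", "CCA",
    "GA", "SIM", "JSD",
    "GIC", "SSIM", "SJSD",
)
#: Weak-foot-only subset (computed on the weak foot's COP trajectory).
WEAK_FOOT_FEATURES = ("Std_x", "Mean_x", "Std_y", "Mean_y", "MRD", "SRD", "TOTEX", "CCA")
#: Default 5-D weak-foot vector entering the full-connection distance.
DEFAULT_WEAK_VECTOR = ("Std_y", "Mean_y", "Std_x", "MRD", "TOTEX")

CLASSIFIER_ROSTER = ("LR", "SVM", "KNN", "DT", "RF", "GBDT", "AdaBoost")


@dataclass
class RunConfig:
    """All tunable knobs of the pipeline with their documented defaults."""

    # windowing
    low_length: int = 20          # d_l window length (steps)
    high_length: int = 130        # d_h / stage-two window length (steps)
    stride: int = 10              # sliding-window stride (steps)
    startup_discard: int = 2      # gait start-up steps removed
    sweep_lengths: tuple[int, ...] = tuple(range(20, 181, 10))
    # segmentation
    eps_frac: float = 0.02        # contact threshold as fraction of p95 total force
    min_dur_ms: float = 50.0      # debounce for contact gaps / spurious blips
    # features
    registry: tuple[str, ...] = ALL_FEATURES
    weak_features: tuple[str, ...] = DEFAULT_WEAK_VECTOR
    # adaptive threshold
    alpha_min: float = 0.14
    alpha_max: float = 0.40
    alpha_step: float = 0.02
    robust_bounds: bool = False   # DDI_min/max as mu +/- 3 sigma (clipped)
    # two-stage model
    roster: tuple[str, ...] = CLASSIFIER_ROSTER
    surrogate: str = "SVM"        # stage-one default-hyperparameter classifier
    branch_min_subjects: int = 3
    gate_margin: float = -1.0     # optional guard: CV edge a branch must show
                                  # over the pooled model (negative = off)
    specialize: str = "both"      # which branches may train their own model
    n_nominate: int = 5           # subset size each selector nominates
    p_threshold: float = 0.05     # phase-1 t-test cut
    inner_cv: int = 5             # subject-grouped CV folds for tuning
    selection_cv: int = 3         # CV folds for phase-3 cardinality choice
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.alpha_min <= self.alpha_max <= 1.0):
            raise ValidationError("alpha grid must satisfy 0 <= min <= max <= 1")
        if self.alpha_step <= 0:
            raise ValidationError("alpha step must be positive")
        if self.low_length >= self.high_length:
            raise ValidationError("low_length must be smaller than high_length")
        if self.stride < 1 or self.low_length < 1:
            raise ValidationError("stride and window lengths must be >= 1")
        unknown = set(self.weak_features) - set(self.registry)
        if unknown:
            raise ValidationError(f"weak features outside registry: {sorted(unknown)}")
        unknown = set(self.roster) - set(CLASSIFIER_ROSTER)
        if unknown:
            raise ValidationError(f"unknown classifiers: {sorted(unknown)}")
        if self.specialize not in ("rwf_only", "both"):
            raise ValidationError("specialize must be 'rwf_only' or 'both'")

    @property
    def alphas(self) -> np.ndarray:
        n = int(round((self.alpha_max - self.alpha_min) / self.alpha_step)) + 1
        return np.round(self.alpha_min + self.alpha_step * np.arange(n), 10)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; missing keys fall back to the defaults above."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParseError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    for key in ("registry", "weak_features", "roster", "sweep_lengths"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_layout(path: str | Path) -> dict[str, SensorLayout]:
    """Read a sensor-layout JSON: {"left": [[x, y], ...], "right": [...]} (mm)."""
    with open(path) as fh:
        data = json.load(fh)
    if set(data) != {"left", "right"}:
        raise SchemaError("layout JSON must contain exactly 'left' and 'right'")
    return {
        side: SensorLayout(side, tuple((float(x), float(y)) for x, y in data[side]))
        for side in SIDES
    }


def write_layout(layout: dict[str, SensorLayout], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({s: [list(c) for c in layout[s].coords] for s in SIDES}, fh, indent=1)


def _parse_float(token: str, line_no: int) -> float:
    try:
        val = float(token)
    except ValueError:
        raise ParseError(f"cannot parse {token!r} as a number", line_no) from None
    if not math.isfinite(val):
        raise ParseError(f"non-finite value {token!r}", line_no)
    return val


def read_recording(
    path: str | Path,
    layout: dict[str, SensorLayout],
    dialect: str = "wide_csv",
    subject_id: str | None = None,
    label: str = "unlabeled",
    rate: float | None = None,
) -> Recording:
    """Read a recording file in one of the supported text dialects.

    ``wide_csv``: header ``time_s, L1..Ln, R1..Rn`` then one row per frame.
    ``physionet_vgrf``: 19 whitespace-separated columns per row (time,
    8 left sensors, 8 right sensors, left total, right total); the two
    total columns are dropped.  The sampling rate is inferred from the
    time column unless given.
    """
    path = Path(path)
    n = layout["left"].n
    times: list[float] = []
    rows_l: list[list[float]] = []
    rows_r: list[list[float]] = []

    if dialect == "wide_csv":
        expected = 1 + 2 * n
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise ParseError("empty file", 1) from None
            if len(header) != expected:
                raise SchemaError(
                    f"wide CSV needs {expected} columns (time + 2x{n} sensors), "
                    f"got {len(header)}"
                )
            for line_no, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != expected:
                    raise ParseError(f"expected {expected} fields, got {len(row)}", line_no)
                vals = [_parse_float(tok, line_no) for tok in row]
                times.append(vals[0])
                rows_l.append(vals[1 : 1 + n])
                rows_r.append(vals[1 + n :])
    elif dialect == "physionet_vgrf":
        if n != 8:
            raise SchemaError("physionet_vgrf carries 8 sensors per foot; layout must match")
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                tokens = line.split()
                if not tokens:
                    continue
                if len(tokens) != 19:
                    raise SchemaError(
                        f"physionet_vgrf needs 19 columns, got {len(tokens)} on line {line_no}"
                    )
                vals = [_parse_float(tok, line_no) for tok in tokens]
                times.append(vals[0])
                rows_l.append(vals[1:9])
                rows_r.append(vals[9:17])  # columns 18-19 are per-foot totals
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")

    if not times:
        raise ParseError("no data rows", 1)
    if rate is None:
        if len(times) > 1:
            dt = np.median(np.diff(times))
            if dt <= 0:
                raise ValidationError("time column is not increasing")
            rate = 1.0 / dt
        else:
            raise ValidationError("cannot infer rate from a single frame")
    return Recording(
        subject_id=subject_id or path.stem,
        label=label,
        rate=float(rate),
        left=np.asarray(rows_l, dtype=float),
        right=np.asarray(rows_r, dtype=float),
        layout=layout,
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a Recording in the canonical wide-CSV dialect."""
    n = rec.layout["left"].n
    header = ["time_s"] + [f"L{i+1}" for i in range(n)] + [f"R{i+1}" for i in range(n)]
    t = np.arange(rec.n_frames) / rec.rate
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i in range(rec.n_frames):
            writer.writerow(
                [repr(float(t[i]))]
                + [repr(float(v)) for v in rec.left[i]]
                + [repr(float(v)) for v in rec.right[i]]
            )


KEY_COLUMNS = ("subject", "label", "length", "start", "weak_side")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-window feature table; round-trips exactly via repr floats."""
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing key columns: {missing}")
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing key columns: {missing}")
    return table


def vectors_to_table(vectors: Sequence["FeatureVector"]) -> pd.DataFrame:  # noqa: F821
    """Stack FeatureVector records into one table; name sets must agree."""
    if not vectors:
        return pd.DataFrame(columns=list(KEY_COLUMNS))
    names = list(vectors[0].values)
    rows = []
    for v in vectors:
        if list(v.values) != names:
            raise SchemaError(
                f"heterogeneous feature-name sets: {names} vs {list(v.values)}"
            )
        rows.append(
            {
                "subject": v.subject,
                "label": v.label,
                "length": v.length,
                "start": v.start,
                "weak_side": v.weak_side,
                **v.values,
            }
        )
    return pd.DataFrame(rows, columns=list(KEY_COLUMNS) + names)


def warn(category: type[Warning], message: str) -> None:
    warnings.warn(message, category, stacklevel=3)
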