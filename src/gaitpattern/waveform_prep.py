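"""Trial containers, time normalization and feature-matrix assembly.

One observation is a single running cycle of one body side, described by
nine sagittal-plane angle waveforms (foot, ankle, knee, hip, pelvis, spine,
thorax, neck, head).  Each cycle is time-normalized to a fixed number of
equidistant points spanning 0-100% of the cycle (201 by default) and the
nine angle blocks are concatenated into one feature row, giving the
trials x 1809 input matrix used by clustering, classification and the
symmetry analysis.

Standardization subtracts the per-column mean over all trials and then
scales each angle's 201-column block by a single pooled standard deviation,
so that each "variable set" (one angle over the whole cycle) has zero mean
and unit pooled SD while the within-cycle shape of its variance is kept.
The parameters are retained so discriminant directions and group means can
be mapped back to degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import (
    ConsistencyError,
    DegenerateDataError,
    DuplicateTrialError,
    ParameterError,
    SchemaError,
)

#: Fixed angle order of the feature-matrix blocks.
ANGLES: tuple[str, ...] = (
    "foot",
    "ankle",
    "knee",
    "hip",
    "pelvis",
    "spine",
    "thorax",
    "neck",
    "head",
)

#: Splint study condition labels; the first entry is the reference (no splint).
CONDITIONS: tuple[str, ...] = ("Neutral", "Centric", "DPS", "Max")

SIDES: tuple[str, ...] = ("L", "R")

#: Default number of equidistant samples per cycle (0%..100% inclusive).
DEFAULT_N_TIME = 201

_LABEL_COLUMNS = ("subject", "condition", "side", "trial")


@dataclass
class TrialRecord:
    """One running cycle of one side: labels plus nine angle waveforms (deg)."""

    subject: str
    condition: str
    side: str
    trial: int
    angles: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [a for a in ANGLES if a not in self.angles]
        if missing:
            raise SchemaError(f"trial {self.key} missing angle(s): {missing}")
        for name in ANGLES:
            w = np.asarray(self.angles[name], dtype=float)
            if w.ndim != 1 or w.size < 2:
                raise SchemaError(
                    f"trial {self.key}: angle '{name}' must be a 1-D series of length >= 2"
                )
            if not np.all(np.isfinite(w)):
                raise SchemaError(f"trial {self.key}: angle '{name}' has non-finite values")
            self.angles[name] = w
        if self.side not in SIDES:
            raise SchemaError(f"trial {self.key}: side must be one of {SIDES}")

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.subject, self.condition, self.side, self.trial)

    def stacked(self) -> np.ndarray:
        """Concatenate the nine waveforms in canonical angle order."""
        return np.concatenate([self.angles[a] for a in ANGLES])


@dataclass
class TrialSet:
    """Ordered collection of trials with optional per-subject/per-trial metadata.

    ``sex`` maps subject id to "F"/"M"; ``speed`` maps a trial key to running
    speed in m/s.  Both are optional and survive CSV round-trips.
    """

    trials: list[TrialRecord]
    sex: dict[str, str] = field(default_factory=dict)
    speed: dict[tuple[str, str, str, int], float] = field(default_factory=dict)
    source: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for t in self.trials:
            if t.key in seen:
                raise DuplicateTrialError(f"duplicate trial key {t.key}")
            seen.add(t.key)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)

    @property
    def subjects(self) -> list[str]:
        out: list[str] = []
        for t in self.trials:
            if t.subject not in out:
                out.append(t.subject)
        return out

    @property
    def conditions(self) -> list[str]:
        out: list[str] = []
        for t in self.trials:
            if t.condition not in out:
                out.append(t.condition)
        return out

    def subset(self, predicate) -> "TrialSet":
        kept = [t for t in self.trials if predicate(t)]
        return TrialSet(
            trials=kept,
            sex=dict(self.sex),
            speed={t.key: self.speed[t.key] for t in kept if t.key in self.speed},
            source=self.source,
            seed=self.seed,
        )


def time_normalize(waveform: Sequence[float] | np.ndarray, n_time: int = DEFAULT_N_TIME) -> np.ndarray:
    """Resample one cycle to ``n_time`` equidistant points on [0, 1].

    Cubic piecewise-polynomial interpolation (natural cubic spline) is used
    when the input has at least four samples, linear interpolation otherwise.
    Endpoints are preserved exactly.
    """
    if n_time < 2:
        raise ParameterError(f"n_time must be >= 2, got {n_time}")
    y = np.asarray(waveform, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ParameterError("waveform must be a 1-D series of length >= 2")
    x = np.linspace(0.0, 1.0, y.size)
    xq = np.linspace(0.0, 1.0, n_time)
    if y.size >= 4:
        out = CubicSpline(x, y, bc_type="natural")(xq)
    else:
        out = np.interp(xq, x, y)
    # guard against interpolation round-off at the boundary knots
    out[0], out[-1] = y[0], y[-1]
    return out


@dataclass
class FeatureMatrix:
    """Trials x (n_angles * n_time) matrix with aligned row labels.

    Rows follow the order of the originating TrialSet; columns are the nine
    angle blocks in canonical order, each ``n_time`` contiguous columns.
    """

    values: np.ndarray
    row_labels: pd.DataFrame
    angle_names: tuple[str, ...] = ANGLES
    n_time: int = DEFAULT_N_TIME
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConsistencyError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.angle_names) * self.n_time:
            raise ConsistencyError(
                f"column count {self.values.shape[1]} != "
                f"{len(self.angle_names)} angles x {self.n_time} points"
            )
        if len(self.row_labels) != self.values.shape[0]:
            raise ConsistencyError("row labels do not align with matrix rows")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def column_labels(self) -> pd.DataFrame:
        angles = np.repeat(self.angle_names, self.n_time)
        times = np.tile(np.arange(self.n_time), len(self.angle_names))
        return pd.DataFrame({"angle": angles, "time_index": times})

    def block(self, angle: str) -> np.ndarray:
        """View of one angle's n_time-column block."""
        i = self.angle_names.index(angle)
        return self.values[:, i * self.n_time : (i + 1) * self.n_time]

    def rows_where(self, **label_values) -> np.ndarray:
        """Boolean row mask for label equality, e.g. rows_where(condition="Neutral")."""
        mask = np.ones(self.n_rows, dtype=bool)
        for col, val in label_values.items():
            mask &= (self.row_labels[col] == val).to_numpy()
        return mask


@dataclass
class NormalizationParams:
    """Inverse-standardization parameters.

    ``column_means`` holds the per-column mean over all trials; ``block_sds``
    holds one pooled scale per angle block (mode "block") or per column
    (mode "column"), already expanded to per-column length in ``column_sds``.
    """

    column_means: np.ndarray
    block_sds: np.ndarray
    mode: Literal["block", "column"]
    n_time: int = DEFAULT_N_TIME
    angle_names: tuple[str, ...] = ANGLES

    @property
    def column_sds(self) -> np.ndarray:
        if self.mode == "column":
            return self.block_sds
        return np.repeat(self.block_sds, self.n_time)


def build_feature_matrix(
    trials: TrialSet | Iterable[TrialRecord], n_time: int = DEFAULT_N_TIME
) -> FeatureMatrix:
    """Time-normalize every waveform and assemble one row per trial."""
    records = list(trials)
    if not records:
        raise ParameterError("cannot build a feature matrix from zero trials")
    rows = []
    for t in records:
        rows.append(
            np.concatenate([time_normalize(t.angles[a], n_time) for a in ANGLES])
        )
    widths = {r.size for r in rows}
    if len(widths) != 1:
        raise ConsistencyError(f"heterogeneous row widths after normalization: {widths}")
    labels = pd.DataFrame(
        [(t.subject, t.condition, t.side, t.trial) for t in records],
        columns=list(_LABEL_COLUMNS),
    )
    return FeatureMatrix(np.vstack(rows), labels, ANGLES, n_time)


def standardize(
    matrix: FeatureMatrix, mode: Literal["block", "column"] = "block"
) -> tuple[FeatureMatrix, NormalizationParams]:
    """Center every column and scale to unit pooled SD per angle block.

    In the default "block" mode, each angle's 201 columns are divided by one
    pooled SD computed over all rows and all columns of the centered block,
    which preserves the cycle's time-dependent variance profile.  "column"
    mode scales every column to unit SD individually.
    """
    if matrix.n_rows < 2:
        raise ParameterError("standardize requires at least 2 rows")
    X = matrix.values
    means = X.mean(axis=0)
    centered = X - means
    n_time = matrix.n_time
    if mode == "block":
        sds = np.empty(len(matrix.angle_names))
        for i in range(len(matrix.angle_names)):
            blk = centered[:, i * n_time : (i + 1) * n_time]
            sds[i] = np.sqrt(np.mean(blk * blk))
        if np.any(sds <= 1e-12):
            bad = [matrix.angle_names[i] for i in np.flatnonzero(sds <= 1e-12)]
            raise DegenerateDataError(f"zero-variance angle block(s): {bad}")
        scaled = centered / np.repeat(sds, n_time)
    elif mode == "column":
        sds = centered.std(axis=0)
        if np.any(sds <= 1e-12):
            raise DegenerateDataError("zero-variance column(s) in feature matrix")
        scaled = centered / sds
    else:
        raise ParameterError(f"unknown SD mode {mode!r}")
    params = NormalizationParams(means, sds, mode, n_time, matrix.angle_names)
    out = FeatureMatrix(
        scaled, matrix.row_labels.copy(), matrix.angle_names, n_time, standardized=True
    )
    return out, params


def inverse_standardize(vector: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Map a standardized profile (or rows of profiles) back to degrees."""
    v = np.asarray(vector, dtype=float)
    if v.shape[-1] != params.column_means.size:
        raise ParameterError(
            f"profile length {v.shape[-1]} != params length {params.column_means.size}"
        )
    return v * params.column_sds + params.column_means


def standardize_row(vector: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Apply an existing standardization to a raw angle-space row."""
    v = np.asarray(vector, dtype=float)
    if v.shape[-1] != params.column_means.size:
        raise ParameterError("profile length does not match params")
    return (v - params.column_means) / params.column_sds


# ---------------------------------------------------------------------------
# Delimited-text I/O (long layout: one row per time sample)
# ---------------------------------------------------------------------------

def write_trials(trials: TrialSet, path: str | Path) -> None:
    """Write a TrialSet as long-layout CSV.

    Columns: subject, condition, side, trial, time_index, the nine angles,
    and (when available) sex and speed repeated per row.
    """
    frames = []
    for t in trials:
        n = t.angles[ANGLES[0]].size
        if any(t.angles[a].size != n for a in ANGLES):
            raise ConsistencyError(f"trial {t.key}: angle waveforms differ in length")
        df = pd.DataFrame({a: t.angles[a] for a in ANGLES})
        df.insert(0, "time_index", np.arange(n))
        for col, val in zip(_LABEL_COLUMNS[::-1], t.key[::-1]):
            df.insert(0, col, val)
        if trials.sex:
            df["sex"] = trials.sex.get(t.subject, "")
        if t.key in trials.speed:
            df["speed"] = trials.speed[t.key]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials(path: str | Path, layout: str = "long") -> TrialSet:
    """Read a TrialSet from delimited text.

    Only the "long" layout is currently supported (the format written by
    :func:`write_trials`).  Malformed rows are reported with their line
    numbers; a missing angle column raises :class:`SchemaError`.
    """
    if layout != "long":
        raise ParameterError(f"unsupported layout {layout!r}")
    path = Path(path)
    df = pd.read_csv(path)
    required = list(_LABEL_COLUMNS) + ["time_index"] + list(ANGLES)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    bad = df.index[df[list(ANGLES)].isna().any(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in bad[:10]]
        raise SchemaError(f"{path}: malformed angle values at line(s) {lines}")
    records: list[TrialRecord] = []
    sex: dict[str, str] = {}
    speed: dict[tuple, float] = {}
    for key, grp in df.groupby(list(_LABEL_COLUMNS), sort=False):
        subject, condition, side, trial = key
        grp = grp.sort_values("time_index")
        rec = TrialRecord(
            subject=str(subject),
            condition=str(condition),
            side=str(side),
            trial=int(trial),
            angles={a: grp[a].to_numpy(dtype=float) for a in ANGLES},
        )
        records.append(rec)
        if "sex" in grp.columns:
            val = grp["sex"].iloc[0]
            if isinstance(val, str) and val:
                sex[rec.subject] = val
        if "speed" in grp.columns and np.isfinite(grp["speed"].iloc[0]):
            speed[rec.key] = float(grp["speed"].iloc[0])
    return TrialSet(records, sex=sex, speed=speed, source=str(path))


def read_matlab_database(
    path: str | Path,
    matrix_var: str = "database",
    label_vars: Mapping[str, str] | None = None,
    n_time: int = DEFAULT_N_TIME,
) -> FeatureMatrix:
    """Adapter for a MATLAB matrix database of assembled waveform rows.

    This is a documented adapter, not a core reader: it expects a ``.mat``
    file (v5 via scipy.io, v7.3 via h5py) containing a trials x 1809 matrix
    plus per-row label vectors, after the user has un-archived any split
    archive externally.  ``label_vars`` maps the canonical label names
    (subject, condition, side, trial) to the variable names inside the file;
    labels absent from the file are filled with placeholders.
    """
    path = Path(path)
    try:
        from scipy.io import loadmat

        data = loadmat(path, squeeze_me=True)
    except NotImplementedError:  # MATLAB >= 7.3 is HDF5
        import h5py

        with h5py.File(path, "r") as f:
            data = {k: np.asarray(f[k]) for k in f.keys()}
    if matrix_var not in data:
        raise SchemaError(f"{path}: variable {matrix_var!r} not found")
    values = np.asarray(data[matrix_var], dtype=float)
    if values.ndim != 2:
        raise SchemaError(f"{path}: {matrix_var!r} is not a 2-D matrix")
    if values.shape[1] != len(ANGLES) * n_time and values.shape[0] == len(ANGLES) * n_time:
        values = values.T  # h5py stores MATLAB arrays transposed
    n = values.shape[0]
    labels = {c: [f"{c}{i}" if c == "subject" else "" for i in range(n)] for c in _LABEL_COLUMNS}
    labels["trial"] = list(range(n))
    for canon, var in (label_vars or {}).items():
        if var in data:
            labels[canon] = [str(x) for x in np.ravel(data[var])[:n]]
    row_labels = pd.DataFrame(labels)[list(_LABEL_COLUMNS)]
    return FeatureMatrix(values, row_labels, ANGLES, n_time)
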