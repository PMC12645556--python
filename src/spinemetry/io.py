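"""Data model and readers/writers for the three input kinds.

The package works with three kinds of raw data:

* vertebral landmark point clouds (micro-CT annotations; several 3-D
  landmarks per vertebra, in mm),
* protein quantification tables (identifier, fold change on linear or
  log2 scale, q-value, peptide count),
* fluorescence traces (uniformly sampled calcium-indicator intensity).

Coordinate convention (right-handed, mm): x = medio-lateral,
y = dorso-ventral, z = rostro-caudal.  The coronal plane is therefore
spanned by (x, z) and the sagittal plane by (y, z).
"""

from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError, ValidationError

__all__ = [
    "Vertebra",
    "SpinePointCloud",
    "ProteinQuantRecord",
    "FluorescenceTrace",
    "RunConfig",
    "read_landmarks",
    "write_landmarks",
    "read_protein_table",
    "write_protein_table",
    "read_trace",
    "write_trace",
]

LANDMARK_COLUMNS = [
    "spine_id",
    "group",
    "vertebra_index",
    "landmark_index",
    "x_mm",
    "y_mm",
    "z_mm",
]


@dataclass
class Vertebra:
    """One vertebra: its rostral-to-caudal index and its 3-D landmarks (mm)."""

    index: int
    landmarks: np.ndarray  # (k, 3) float array, k >= 1

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.ndim != 2 or self.landmarks.shape[1] != 3:
            raise ValidationError(
                f"vertebra {self.index}: landmarks must be an (k, 3) array"
            )
        if self.landmarks.shape[0] < 1:
            raise ValidationError(f"vertebra {self.index}: needs >= 1 landmark")
        if not np.all(np.isfinite(self.landmarks)):
            raise ValidationError(f"vertebra {self.index}: non-finite coordinate")


@dataclass
class SpinePointCloud:
    """Ordered vertebral landmark sets of one mouse spine, with a group label.

    Invariants: at least 4 vertebrae, strictly increasing and unique
    vertebra indices, finite coordinates, >= 1 landmark per vertebra.
    """

    spine_id: str
    group: str
    vertebrae: list[Vertebra]
    units: str = "mm"

    def __post_init__(self) -> None:
        if len(self.vertebrae) < 4:
            raise ValidationError(
                f"spine {self.spine_id!r}: needs >= 4 vertebrae, "
                f"got {len(self.vertebrae)}"
            )
        idx = [v.index for v in self.vertebrae]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"spine {self.spine_id!r}: vertebra indices must be strictly "
                f"increasing, got {idx}"
            )

    @property
    def n_landmarks(self) -> int:
        return sum(v.landmarks.shape[0] for v in self.vertebrae)


@dataclass
class ProteinQuantRecord:
    """One protein's differential quantification between two conditions."""

    protein_id: str
    log2_fold_change: float
    q_value: float
    n_peptides: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2_fold_change):
            raise ValidationError(
                f"{self.protein_id}: log2 fold change must be finite"
            )
        if not (0.0 <= self.q_value <= 1.0):
            raise ValidationError(
                f"{self.protein_id}: q_value {self.q_value} outside [0, 1]"
            )
        if self.n_peptides < 0:
            raise ValidationError(f"{self.protein_id}: negative peptide count")

    @property
    def fold_change(self) -> float:
        """Fold change on the linear scale."""
        return float(2.0 ** self.log2_fold_change)


@dataclass
class FluorescenceTrace:
    """A uniformly sampled fluorescence trace.

    ``values[i]`` is the intensity at time ``i / sampling_rate`` seconds.
    ``stimulus_time`` (seconds, same time axis) marks the electrical
    stimulus; it may be None for traces that are not stimulus-locked.
    """

    sampling_rate: float = 300.0  # Hz; camera frame rate of the recordings
    values: np.ndarray = field(default_factory=lambda: np.zeros(0))
    stimulus_time: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trace contains non-finite values")
        if np.any(self.values < 0):
            raise ValidationError("fluorescence intensities must be non-negative")
        if self.stimulus_time is not None:
            t = self.times
            if np.sum(t < self.stimulus_time) < 2 or np.sum(t >= self.stimulus_time) < 2:
                raise ValidationError(
                    "need >= 2 samples on each side of stimulus_time"
                )

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.values.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return (self.values.size - 1) / self.sampling_rate


@dataclass
class RunConfig:
    """Run configuration shared by the pipeline stages.

    All pipeline outputs embed this record (including the seed) so a run
    can be reproduced exactly.
    """

    grid_size: int = 512
    smoothing: float = 1e-7  # roughness penalty suited to ~0.1-0.3 mm landmark noise
    plane: str = "coronal"
    n_permutations: int = 10_000
    seed: int = 0
    min_peptides: int = 2
    log2fc_lower: float = -0.321
    log2fc_upper: float = 0.263
    q_max: float = 0.05
    output_dir: str = "spinemetry_out"

    def __post_init__(self) -> None:
        if self.grid_size < 8:
            raise ValidationError("grid_size must be >= 8")
        if self.smoothing < 0:
            raise ValidationError("smoothing must be >= 0")
        if self.plane not in ("coronal", "sagittal"):
            raise ValidationError("plane must be 'coronal' or 'sagittal'")
        if self.n_permutations < 100:
            raise ValidationError("n_permutations must be >= 100")
        if not (self.log2fc_lower < 0 < self.log2fc_upper):
            raise ValidationError("log2FC thresholds must bracket 0")
        if not (0 < self.q_max <= 1):
            raise ValidationError("q_max must be in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# landmark point clouds


def _clouds_from_frame(df: pd.DataFrame) -> list[SpinePointCloud]:
    clouds: list[SpinePointCloud] = []
    for spine_id in df["spine_id"].unique():
        sub = df[df["spine_id"] == spine_id]
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValidationError(
                f"spine {spine_id!r}: inconsistent group labels {list(groups)}"
            )
        vertebrae = []
        for vi in sorted(sub["vertebra_index"].unique()):
            rows = sub[sub["vertebra_index"] == vi]
            coords = rows[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
            vertebrae.append(Vertebra(index=int(vi), landmarks=coords))
        clouds.append(
            SpinePointCloud(
                spine_id=str(spine_id), group=str(groups[0]), vertebrae=vertebrae
            )
        )
    return clouds


def read_landmarks(
    path: str | Path, dialect: Literal["csv", "json"] | None = None
) -> list[SpinePointCloud]:
    """Read vertebral landmark point clouds from CSV or JSON.

    The CSV schema is ``spine_id,group,vertebra_index,landmark_index,
    x_mm,y_mm,z_mm``; the JSON schema is
    ``[{spine_id, group, vertebrae: [{index, landmarks: [[x,y,z], ...]}]}]``.
    One :class:`SpinePointCloud` is returned per distinct ``spine_id``
    (in order of first appearance); vertebrae are sorted by index and
    landmark order within a vertebra is preserved.
    """
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "json":
        with open(path) as fh:
            raw = json.load(fh)
        clouds = []
        for entry in raw:
            vertebrae = [
                Vertebra(index=int(v["index"]), landmarks=np.asarray(v["landmarks"]))
                for v in sorted(entry["vertebrae"], key=lambda v: v["index"])
            ]
            clouds.append(
                SpinePointCloud(
                    spine_id=str(entry["spine_id"]),
                    group=str(entry["group"]),
                    vertebrae=vertebrae,
                )
            )
        return clouds
    if dialect != "csv":
        raise UsageError(f"unknown dialect {dialect!r}")

    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    coords = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(coords), axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header line
        raise ValidationError(f"{path}: non-finite coordinate at line {row}")
    # within-vertebra landmark order = file order (no re-sorting)
    return _clouds_from_frame(df)


def write_landmarks(
    clouds: Sequence[SpinePointCloud],
    path: str | Path,
    dialect: Literal["csv", "json"] | None = None,
) -> None:
    """Write point clouds in either on-disk schema (inverse of read)."""
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "json":
        payload = [
            {
                "spine_id": c.spine_id,
                "group": c.group,
                "vertebrae": [
                    {"index": v.index, "landmarks": v.landmarks.tolist()}
                    for v in c.vertebrae
                ],
            }
            for c in clouds
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    rows = []
    for c in clouds:
        for v in c.vertebrae:
            for li, (x, y, z) in enumerate(v.landmarks):
                rows.append((c.spine_id, c.group, v.index, li, x, y, z))
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(
        path, index=False, float_format="%.9f"
    )


# ---------------------------------------------------------------------------
# protein tables


def read_protein_table(path: str | Path) -> list[ProteinQuantRecord]:
    """Read a TSV protein quantification table.

    Required columns: ``protein_id``, exactly one of ``log2_fc`` /
    ``fold_change``, ``q_value``, ``n_peptides``.  A linear
    ``fold_change`` column is converted with log2; the two scales are
    never accepted together.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    for col in ("protein_id", "q_value", "n_peptides"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    has_log = "log2_fc" in df.columns
    has_lin = "fold_change" in df.columns
    if has_log and has_lin:
        raise FormatError(
            f"{path}: give either 'log2_fc' or 'fold_change', not both"
        )
    if not (has_log or has_lin):
        raise FormatError(f"{path}: missing column 'log2_fc' or 'fold_change'")
    records = []
    for i, row in df.iterrows():
        if has_lin:
            fc = float(row["fold_change"])
            if not (fc > 0) or not math.isfinite(fc):
                raise ValidationError(
                    f"{path}: fold_change must be > 0 (row {i + 2}, got {fc})"
                )
            log2fc = math.log2(fc)
        else:
            log2fc = float(row["log2_fc"])
        records.append(
            ProteinQuantRecord(
                protein_id=str(row["protein_id"]),
                log2_fold_change=log2fc,
                q_value=float(row["q_value"]),
                n_peptides=int(row["n_peptides"]),
            )
        )
    return records


def write_protein_table(
    records: Sequence[ProteinQuantRecord], path: str | Path
) -> None:
    """Write records as TSV on the log2 scale."""
    df = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "log2_fc": [r.log2_fold_change for r in records],
            "q_value": [r.q_value for r in records],
            "n_peptides": [r.n_peptides for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# fluorescence traces


def read_trace(
    path: str | Path, stimulus_time: float | None = None
) -> FluorescenceTrace:
    """Read a trace CSV with columns ``time_s, fluorescence``.

    The sampling rate is inferred from the median time step; the time
    column must be strictly increasing and uniform to within ~1% jitter.
    ``stimulus_time`` is on the same time axis as the file, measured
    from the first sample.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    for col in ("time_s", "fluorescence"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    t = df["time_s"].to_numpy(dtype=float)
    f = df["fluorescence"].to_numpy(dtype=float)
    if t.size < 4:
        raise ValidationError(f"{path}: need >= 4 samples, got {t.size}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValidationError(f"{path}: time column not strictly increasing")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise ValidationError(f"{path}: sampling jitter exceeds 1% of the step")
    return FluorescenceTrace(
        sampling_rate=1.0 / med, values=f, stimulus_time=stimulus_time
    )


def write_trace(trace: FluorescenceTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times, "fluorescence": trace.values}).to_csv(
        path, index=False, float_format="%.9f"
    )
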