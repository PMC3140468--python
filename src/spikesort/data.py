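"""Core data containers: electrode geometry, recordings, clips, cropped events.

A recording is a dense channels x samples voltage matrix tied to a rectangular
electrode grid. Spike-scale excerpts of a recording are ``Clip`` objects; the
unit of clustering is the ``CroppedEvent``, a 3x3-electrode neighborhood around
a leader channel (the electrode with the deepest negative peak).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "ElectrodeGeometry",
    "Recording",
    "Clip",
    "CroppedEvent",
    "load_recording",
    "save_recording",
]


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Rectangular electrode grid; channel index = row * cols + col (raster scan)."""

    rows: int
    cols: int
    pitch_um: float = 100.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pitch_um <= 0:
            raise ValueError("electrode pitch must be positive")

    @property
    def n_electrodes(self) -> int:
        return self.rows * self.cols

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) electrode coordinates in µm, raster-scan channel order."""
        r, c = np.divmod(np.arange(self.n_electrodes), self.cols)
        return np.column_stack([c, r]).astype(float) * self.pitch_um

    def channel_at(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(f"grid position ({row}, {col}) out of bounds")
        return row * self.cols + col

    def grid_position(self, channel: int) -> tuple[int, int]:
        return divmod(int(channel), self.cols)

    def neighborhood(self, channel: int) -> tuple[np.ndarray, np.ndarray]:
        """3x3 neighborhood of ``channel`` in fixed raster order.

        Returns (indices, valid): 9 channel indices (raster scan of the 3x3
        patch, center at position 4) and a boolean mask; positions falling off
        the array edge carry index -1 and valid False.
        """
        row, col = self.grid_position(channel)
        idx = np.full(9, -1, dtype=int)
        valid = np.zeros(9, dtype=bool)
        k = 0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                r, c = row + dr, col + dc
                if 0 <= r < self.rows and 0 <= c < self.cols:
                    idx[k] = r * self.cols + c
                    valid[k] = True
                k += 1
        return idx, valid

    def are_grid_neighbors(self, a: int, b: int) -> bool:
        """4-connectivity: nearest neighbors on the grid (no diagonals)."""
        ra, ca = self.grid_position(a)
        rb, cb = self.grid_position(b)
        return abs(ra - rb) + abs(ca - cb) == 1


@dataclass
class Recording:
    """Multi-channel extracellular voltage recording.

    voltages is (channels, samples) in µV (or whitened units once ``whitened``
    is set); ``sample_interval`` is Δt in seconds.
    """

    voltages: np.ndarray
    sample_interval: float
    geometry: ElectrodeGeometry
    whitened: bool = False
    filtered: bool = False

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.ndim != 2:
            raise ValueError("voltages must be a channels x samples matrix")
        if self.voltages.shape[0] != self.geometry.n_electrodes:
            raise ValueError(
                f"{self.voltages.shape[0]} channels but geometry has "
                f"{self.geometry.n_electrodes} electrodes"
            )
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not np.all(np.isfinite(self.voltages)):
            raise ValueError("voltages contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.sample_interval

    @property
    def duration(self) -> float:
        return self.n_samples * self.sample_interval

    def with_voltages(self, voltages: np.ndarray, **flags) -> "Recording":
        return replace(self, voltages=voltages, **flags)


@dataclass
class Clip:
    """A fixed-length excerpt of a recording (all channels)."""

    voltages: np.ndarray  # (channels, W)
    start_sample: int
    kind: str  # "noise" | "spike"

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.kind not in ("noise", "spike"):
            raise ValueError(f"unknown clip kind {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]


@dataclass
class CroppedEvent:
    """A 9-channel x W spike waveform cropped around its leader electrode.

    Channel order is the fixed raster scan of the 3x3 neighborhood (leader at
    row 4). Rows for off-array positions are zero with ``valid`` False.
    ``peak_sample`` is the absolute-peak time in recording samples.
    """

    voltages: np.ndarray  # (9, W)
    leader_channel: int
    peak_sample: int
    channel_indices: np.ndarray = field(default_factory=lambda: np.full(9, -1))
    valid: np.ndarray = field(default_factory=lambda: np.zeros(9, bool))
    clip_index: int = -1

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.shape[0] != 9:
            raise ValueError("cropped events carry exactly 9 channel rows")

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]


# ---------------------------------------------------------------------------
# Recording container I/O (HDF5, plus flat binary + JSON sidecar)

def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to HDF5 (datasets /voltages; grid metadata as attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("voltages", data=rec.voltages.astype(np.float32))
        f.attrs["sample_rate_hz"] = rec.sample_rate
        f.attrs["grid_rows"] = rec.geometry.rows
        f.attrs["grid_cols"] = rec.geometry.cols
        f.attrs["electrode_pitch_um"] = rec.geometry.pitch_um
        f.attrs["whitened"] = rec.whitened
        f.attrs["filtered"] = rec.filtered


def load_recording(path: str | Path) -> Recording:
    """Read a recording from HDF5, or flat binary (.dat/.bin) + JSON sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if path.suffix in (".dat", ".bin", ".raw"):
        return _load_flat_binary(path)
    with h5py.File(path, "r") as f:
        geom = ElectrodeGeometry(
            rows=int(f.attrs["grid_rows"]),
            cols=int(f.attrs["grid_cols"]),
            pitch_um=float(f.attrs.get("electrode_pitch_um", 100.0)),
        )
        return Recording(
            voltages=f["voltages"][()].astype(float),
            sample_interval=1.0 / float(f.attrs["sample_rate_hz"]),
            geometry=geom,
            whitened=bool(f.attrs.get("whitened", False)),
            filtered=bool(f.attrs.get("filtered", False)),
        )


def _load_flat_binary(path: Path) -> Recording:
    meta_path = path.with_suffix(".json")
    if not meta_path.exists():
        raise FileNotFoundError(f"sidecar metadata not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    geom = ElectrodeGeometry(
        rows=int(meta["grid_rows"]),
        cols=int(meta["grid_cols"]),
        pitch_um=float(meta.get("electrode_pitch_um", 100.0)),
    )
    raw = np.fromfile(path, dtype=np.float32)
    volts = raw.reshape(geom.n_electrodes, -1)
    return Recording(
        voltages=volts.astype(float),
        sample_interval=1.0 / float(meta["sample_rate_hz"]),
        geometry=geom,
        whitened=bool(meta.get("whitened", False)),
        filtered=bool(meta.get("filtered", False)),
    )
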