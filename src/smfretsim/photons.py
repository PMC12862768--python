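"""Timestamped photon records.

A :class:`PhotonStream` holds integer clock-tick timestamps, a detector
channel per photon (donor/acceptor) and the emitting molecule id (-1 for
background).  Streams round-trip losslessly through CSV and through a
Photon-HDF5-style HDF5 layout (``/photon_data/timestamps`` + unit +
``detectors``, with molecule ids under a custom ``/user`` group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhotonStream", "DONOR", "ACCEPTOR", "BACKGROUND_ID",
           "write_photons", "read_photons"]

DONOR = 0
ACCEPTOR = 1
BACKGROUND_ID = -1


@dataclass
class PhotonStream:
    timestamps: np.ndarray          # int64 clock ticks, sorted non-decreasing
    channels: np.ndarray            # uint8: 0 donor, 1 acceptor
    molecule_ids: np.ndarray        # int32, -1 for background
    tick: float                     # seconds per tick

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.channels = np.asarray(self.channels, dtype=np.uint8)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.int32)
        n = self.timestamps.size
        if self.channels.size != n or self.molecule_ids.size != n:
            raise ValueError("timestamps, channels and molecule_ids must match in length")
        if n and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be sorted non-decreasing")
        if not self.tick > 0:
            raise ValueError("tick must be > 0 seconds")
        if n and not np.all(np.isin(np.unique(self.channels), [DONOR, ACCEPTOR])):
            raise ValueError("channels must be 0 (donor) or 1 (acceptor)")

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def times(self) -> np.ndarray:
        """Timestamps in seconds."""
        return self.timestamps * self.tick

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] * self.tick) if len(self) else 0.0

    def select(self, mask) -> "PhotonStream":
        return PhotonStream(self.timestamps[mask], self.channels[mask],
                            self.molecule_ids[mask], self.tick)

    def without_background(self) -> "PhotonStream":
        return self.select(self.molecule_ids != BACKGROUND_ID)

    @classmethod
    def empty(cls, tick: float) -> "PhotonStream":
        return cls(np.empty(0, np.int64), np.empty(0, np.uint8),
                   np.empty(0, np.int32), tick)


def write_photons(stream: PhotonStream, path) -> None:
    """Write a stream; format chosen by suffix (.h5/.hdf5 vs CSV fallback)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        _write_hdf5(stream, path)
    else:
        _write_csv(stream, path)


def read_photons(path) -> PhotonStream:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        return _read_hdf5(path)
    return _read_csv(path)


def _write_csv(stream: PhotonStream, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tick_seconds={stream.tick!r}\n")
        fh.write("timestamp_tick,channel,molecule_id\n")
        for t, c, m in zip(stream.timestamps, stream.channels, stream.molecule_ids):
            fh.write(f"{t},{c},{m}\n")


def _read_csv(path) -> PhotonStream:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# tick_seconds="):
            raise ValueError(f"{path}: missing tick_seconds header")
        tick = float(header.split("=", 1)[1])
        cols = fh.readline().strip().split(",")
        if cols != ["timestamp_tick", "channel", "molecule_id"]:
            raise ValueError(f"{path}: unexpected column header {cols}")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty data section is legal
            data = np.loadtxt(fh, delimiter=",", dtype=np.int64, ndmin=2)
    if data.size == 0:
        return PhotonStream.empty(tick)
    return PhotonStream(data[:, 0], data[:, 1].astype(np.uint8),
                        data[:, 2].astype(np.int32), tick)


def _write_hdf5(stream: PhotonStream, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        pd_grp = f.create_group("photon_data")
        pd_grp.create_dataset("timestamps", data=stream.timestamps, dtype=np.int64)
        spec = pd_grp.create_group("timestamps_specs")
        spec.create_dataset("timestamps_unit", data=stream.tick)
        pd_grp.create_dataset("detectors", data=stream.channels, dtype=np.uint8)
        user = f.create_group("user")
        user.create_dataset("molecule_ids", data=stream.molecule_ids, dtype=np.int32)


def _read_hdf5(path) -> PhotonStream:
    import h5py

    with h5py.File(path, "r") as f:
        try:
            ts = f["photon_data/timestamps"][...]
            tick = float(f["photon_data/timestamps_specs/timestamps_unit"][()])
            det = f["photon_data/detectors"][...]
            mol = f["user/molecule_ids"][...]
        except KeyError as exc:
            raise ValueError(f"{path}: not a recognised photon file ({exc})") from exc
    return PhotonStream(ts, det, mol, tick)
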