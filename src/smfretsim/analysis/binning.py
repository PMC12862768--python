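"""Binning, thresholding and apparent efficiencies.

The apparent efficiency of a time bin is the acceptor fraction of its photons,
E_hat = I_A / (I_A + I_D); bins are half-open, zero-based and anchored at
t = 0.  "Burst regions" are maximal runs of consecutive bins whose combined
count exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..photons import ACCEPTOR, DONOR, PhotonStream

__all__ = ["BinnedTrace", "bin_photons", "threshold_bins", "burst_regions",
           "region_efficiency_sequences", "mean_region_length"]


@dataclass
class BinnedTrace:
    bin_width: float
    donor_counts: np.ndarray
    acceptor_counts: np.ndarray

    def __post_init__(self) -> None:
        self.donor_counts = np.asarray(self.donor_counts, dtype=np.int64)
        self.acceptor_counts = np.asarray(self.acceptor_counts, dtype=np.int64)
        if self.donor_counts.shape != self.acceptor_counts.shape:
            raise ValueError("donor and acceptor count arrays must match")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be > 0")

    @property
    def combined_counts(self) -> np.ndarray:
        return self.donor_counts + self.acceptor_counts

    @property
    def apparent_efficiency(self) -> np.ndarray:
        """E_hat per bin; NaN where the bin is empty."""
        comb = self.combined_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            e = self.acceptor_counts / comb
        return np.where(comb > 0, e, np.nan)

    @property
    def n_bins(self) -> int:
        return self.donor_counts.size

    def __len__(self) -> int:
        return self.n_bins


def bin_photons(stream: PhotonStream, bin_width: float,
                duration: float | None = None) -> BinnedTrace:
    """Count donor/acceptor photons in half-open bins [k w, (k+1) w)."""
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    if len(stream) == 0:
        n = 0 if duration is None else int(np.ceil(duration / bin_width))
        z = np.zeros(n, np.int64)
        return BinnedTrace(bin_width, z, z.copy())
    idx = (stream.timestamps * (stream.tick / bin_width)).astype(np.int64)
    n_bins = int(idx[-1]) + 1
    if duration is not None:
        n_bins = max(n_bins, int(np.ceil(duration / bin_width)))
    donor = np.bincount(idx[stream.channels == DONOR], minlength=n_bins)
    acceptor = np.bincount(idx[stream.channels == ACCEPTOR], minlength=n_bins)
    return BinnedTrace(bin_width, donor, acceptor)


def threshold_bins(trace: BinnedTrace, threshold: int) -> np.ndarray:
    """Mask of bins whose combined count strictly exceeds ``threshold``."""
    return trace.combined_counts > threshold


def burst_regions(trace: BinnedTrace, threshold: int) -> list[tuple[int, int]]:
    """Maximal runs of consecutive above-threshold bins as [start, stop) pairs."""
    mask = threshold_bins(trace, threshold)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def region_efficiency_sequences(trace: BinnedTrace,
                                regions: list[tuple[int, int]]) -> list[np.ndarray]:
    """Apparent-efficiency sequence of each burst region."""
    e = trace.apparent_efficiency
    return [e[a:b] for a, b in regions]


def mean_region_length(regions: list[tuple[int, int]]) -> float:
    """Mean region length in bins (NaN for an empty region list)."""
    if not regions:
        return float("nan")
    return float(np.mean([b - a for a, b in regions]))
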