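"""Sliding-window burst search, burst selection and burst variance analysis.

A photon belongs to a burst when any window of ``m`` consecutive timestamps
containing it has local rate (m-1)/(t_last - t_first) above the threshold;
maximal runs of in-burst photons form bursts.  BVA splits each selected burst
into consecutive non-overlapping sub-bursts of n photons and compares the
standard deviation of sub-burst efficiencies with the static (binomial)
expectation sqrt(E (1 - E) / n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..photons import ACCEPTOR, PhotonStream

__all__ = ["BurstSet", "BVAResult", "sliding_window_burst_search",
           "select_bursts", "burst_variance_analysis", "static_bva_std"]


@dataclass
class BurstSet:
    """Non-overlapping, ordered bursts as [start, stop) photon-index pairs."""

    starts: np.ndarray
    stops: np.ndarray
    tick: float
    search_params: dict

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.stops = np.asarray(self.stops, dtype=np.int64)
        if self.starts.shape != self.stops.shape:
            raise ValueError("starts and stops must match")
        if np.any(self.stops <= self.starts):
            raise ValueError("bursts must be non-empty")
        if self.starts.size > 1 and np.any(self.starts[1:] < self.stops[:-1]):
            raise ValueError("bursts must be ordered and non-overlapping")

    @property
    def counts(self) -> np.ndarray:
        return self.stops - self.starts

    def __len__(self) -> int:
        return self.starts.size

    def durations(self, stream: PhotonStream) -> np.ndarray:
        t = stream.times
        return t[self.stops - 1] - t[self.starts]

    def apparent_efficiencies(self, stream: PhotonStream) -> np.ndarray:
        """Acceptor fraction of each burst."""
        acc = np.cumsum(np.concatenate([[0], stream.channels == ACCEPTOR]))
        n_acc = acc[self.stops] - acc[self.starts]
        return n_acc / self.counts


def sliding_window_burst_search(stream: PhotonStream, m: int = 200,
                                rate_threshold: float = 40_000.0) -> BurstSet:
    """Find bursts with the m-photon sliding-window rate criterion.

    The local rate of the window starting at photon i is
    (m-1) / (t[i+m-1] - t[i]); photon j is in a burst when any passing window
    covers it.  Returns the maximal runs of in-burst photons.
    """
    if m < 2:
        raise ValueError("window size m must be >= 2")
    params = {"m": m, "rate_threshold": rate_threshold}
    n = len(stream)
    if n < m:
        return BurstSet(np.empty(0, np.int64), np.empty(0, np.int64),
                        stream.tick, params)
    t = stream.times
    span = t[m - 1:] - t[: n - m + 1]
    with np.errstate(divide="ignore"):
        passing = np.where(span > 0, (m - 1) / np.maximum(span, 1e-300), np.inf) > rate_threshold
    # photon j is covered by windows starting in [j-m+1, j]
    csum = np.concatenate([[0], np.cumsum(passing)])
    j = np.arange(n)
    lo = np.clip(j - m + 1, 0, passing.size)
    hi = np.clip(j + 1, 0, passing.size)
    in_burst = (csum[hi] - csum[lo]) > 0
    padded = np.concatenate([[False], in_burst, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return BurstSet(starts, stops, stream.tick, params)


def select_bursts(bursts: BurstSet, min_photons: int) -> BurstSet:
    """Keep bursts with at least ``min_photons`` photons (boundary inclusive)."""
    keep = bursts.counts >= min_photons
    params = dict(bursts.search_params, min_photons=min_photons)
    return BurstSet(bursts.starts[keep], bursts.stops[keep], bursts.tick, params)


def static_bva_std(E, n: int):
    """Binomial (static-molecule) reference curve sqrt(E (1 - E) / n)."""
    E = np.asarray(E, dtype=float)
    out = np.sqrt(E * (1.0 - E) / n)
    return float(out) if np.ndim(E) == 0 else out


@dataclass
class BVAResult:
    """Per-burst BVA summary.

    ``mean_efficiency`` is the mean of the sub-burst efficiencies, ``sigma``
    their sample standard deviation (Bessel-corrected), ``n_sub_bursts`` the
    number of complete n-photon windows; bursts with fewer than 2 complete
    windows are excluded and counted in ``n_excluded``.
    """

    mean_efficiency: np.ndarray
    sigma: np.ndarray
    n_sub_bursts: np.ndarray
    n: int
    n_excluded: int

    def reference_curve(self, E):
        return static_bva_std(E, self.n)


def burst_variance_analysis(bursts: BurstSet, stream: PhotonStream,
                            n: int = 10) -> BVAResult:
    """Sub-burst efficiency standard deviation per burst.

    Each burst is segmented into consecutive non-overlapping windows of ``n``
    photons (trailing remainder discarded); the sub-burst efficiency is the
    acceptor fraction of the window.
    """
    if n < 2:
        raise ValueError("sub-burst size n must be >= 2")
    is_acc = (stream.channels == ACCEPTOR).astype(np.int64)
    means, sigmas, counts = [], [], []
    n_excluded = 0
    for a, b in zip(bursts.starts, bursts.stops):
        n_win = (b - a) // n
        if n_win < 2:
            n_excluded += 1
            continue
        windows = is_acc[a:a + n_win * n].reshape(n_win, n)
        e_sub = windows.mean(axis=1)
        means.append(e_sub.mean())
        sigmas.append(e_sub.std(ddof=1))
        counts.append(n_win)
    return BVAResult(mean_efficiency=np.asarray(means),
                     sigma=np.asarray(sigmas),
                     n_sub_bursts=np.asarray(counts, dtype=np.int64),
                     n=n, n_excluded=n_excluded)
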