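"""From regional BOLD time series to weighted and binary connectivity graphs.

The construction follows the standard resting-state workflow: each regional
series is reduced to a low-frequency sub-band with a shift-invariant
discrete wavelet transform, pairwise Pearson correlations form a weighted
adjacency matrix, and thresholding at a correlation level r yields an
undirected binary graph.  Node *strength* (the row sum of weights) is the
one measure computed on the complete weighted matrix rather than the
thresholded graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy.fft import irfft, rfft, rfftfreq

from .graph import BinaryGraph

DEFAULT_BAND = (0.06, 0.1)
DEFAULT_WAVELET = "db4"


@dataclass(frozen=True)
class RegionalTimeSeries:
    """Region-by-timepoint matrix of BOLD signals for one subject-session.

    ``values`` has shape (n_regions, n_timepoints); ``sampling_interval``
    is the repetition time TR in seconds.
    """

    values: np.ndarray
    region_labels: tuple[str, ...]
    sampling_interval: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D (regions x timepoints) matrix")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contain non-finite values")
        labels = tuple(str(x) for x in self.region_labels)
        if len(labels) != v.shape[0]:
            raise ValueError("one label per region required")
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_labels", labels)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.sampling_interval

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.region_labels))

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "region"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, sampling_interval: float) -> "RegionalTimeSeries":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), tuple(df.index.astype(str)), sampling_interval)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric region-by-region Pearson correlation matrix.

    The diagonal is defined as 0: self-connections carry no information
    and are excluded from strength sums.
    """

    weights: np.ndarray
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(w) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        labels = tuple(str(x) for x in self.region_labels)
        if len(labels) != w.shape[0]:
            raise ValueError("one label per region required")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "region_labels", labels)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.weights, index=list(self.region_labels), columns=list(self.region_labels)
        )
        df.index.name = "region"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), tuple(df.index.astype(str)))


def _swt_detail_levels(band: tuple[float, float], sampling_interval: float):
    """Detail levels whose dyadic band [fs/2^(j+1), fs/2^j] overlaps ``band``."""
    lo, hi = band
    fs = 1.0 / sampling_interval
    if not (0 < lo < hi):
        raise ValueError("band must satisfy 0 < low < high")
    if hi > fs / 2 + 1e-12:
        raise ValueError(
            f"band upper edge {hi} Hz exceeds Nyquist {fs / 2:.4f} Hz"
        )
    levels = []
    j = 1
    while fs / 2**j > lo:
        f_lo, f_hi = fs / 2 ** (j + 1), fs / 2**j
        if f_lo < hi and f_hi > lo:
            levels.append(j)
        j += 1
        if j > 30:  # pragma: no cover - safety stop
            break
    if not levels:
        raise ValueError("band overlaps no dyadic detail level")
    return levels


def wavelet_subband_filter(
    ts: RegionalTimeSeries,
    band: tuple[float, float] = DEFAULT_BAND,
    wavelet: str = DEFAULT_WAVELET,
    method: str = "swt",
) -> RegionalTimeSeries:
    """Reduce each regional series to the wavelet sub-band overlapping ``band``.

    The default path decomposes each series with a stationary (shift
    invariant) discrete wavelet transform and reconstructs only the detail
    levels whose dyadic frequency support [fs/2^(j+1), fs/2^j] overlaps the
    requested band; the approximation (DC and slow drift) is always
    discarded.  Periodic wrap padding makes the transform well defined for
    any length, and the output keeps the input length.  ``method="fft"``
    offers an ideal zero-phase band-pass behind the same interface.

    The transform is linear: filtering a sum of series equals the sum of
    the filtered series.
    """
    if method == "fft":
        return _fft_bandpass(ts, band)
    if method != "swt":
        raise ValueError("method must be 'swt' or 'fft'")

    levels = _swt_detail_levels(band, ts.sampling_interval)
    deepest = max(levels)
    t = ts.n_timepoints
    block = 2**deepest
    padded_len = -(-t // block) * block
    w = pywt.Wavelet(wavelet)
    if t < w.dec_len:
        raise ValueError(
            f"series of length {t} shorter than the {wavelet} filter support"
        )
    out = np.empty_like(ts.values)
    for r in range(ts.n_regions):
        x = np.resize(ts.values[r], padded_len)  # periodic extension
        coeffs = pywt.swt(x, wavelet, level=deepest, norm=True)
        # coeffs[0] is the deepest level; level j sits at index deepest - j
        y = np.zeros(padded_len)
        for j in levels:
            sel = [(np.zeros(padded_len), np.zeros(padded_len)) for _ in range(deepest)]
            sel[deepest - j] = (np.zeros(padded_len), coeffs[deepest - j][1])
            y += pywt.iswt(sel, wavelet, norm=True)
        out[r] = y[:t]
    return RegionalTimeSeries(out, ts.region_labels, ts.sampling_interval)


def _fft_bandpass(ts: RegionalTimeSeries, band: tuple[float, float]) -> RegionalTimeSeries:
    lo, hi = band
    if not (0 < lo < hi <= ts.nyquist + 1e-12):
        raise ValueError("band must lie within (0, Nyquist]")
    freqs = rfftfreq(ts.n_timepoints, d=ts.sampling_interval)
    mask = (freqs >= lo) & (freqs <= hi)
    spec = rfft(ts.values, axis=1)
    spec[:, ~mask] = 0.0
    out = irfft(spec, n=ts.n_timepoints, axis=1)
    return RegionalTimeSeries(out, ts.region_labels, ts.sampling_interval)


def correlation_matrix(ts: RegionalTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of regional series.

    Raises if any region has zero variance (its correlation is undefined),
    reporting the offending label.
    """
    sd = ts.values.std(axis=1)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        names = ", ".join(ts.region_labels[i] for i in dead[:5])
        raise ValueError(f"zero-variance region(s): {names}")
    w = np.corrcoef(ts.values)
    w = np.clip(w, -1.0, 1.0)
    return ConnectivityMatrix(w, ts.region_labels)


def threshold_binarize(cm: ConnectivityMatrix, r: float) -> BinaryGraph:
    """Binary graph with an edge wherever the correlation is >= r.

    Only positive thresholds are meaningful; ties at the threshold are kept
    as edges.  Negative correlations never produce edges.
    """
    if not (0 < r < 1):
        raise ValueError("threshold r must lie in (0, 1)")
    a = cm.weights >= r
    np.fill_diagonal(a, False)
    return BinaryGraph(a, labels=cm.region_labels, threshold_r=float(r))


def node_strength(cm: ConnectivityMatrix) -> tuple[np.ndarray, float]:
    """Per-node strength S_i = sum_j w_ij (j != i) and the graph mean S.

    Strength is defined on the complete weighted matrix, not on any
    thresholded graph.
    """
    s = cm.weights.sum(axis=1)  # diagonal is 0 by construction
    return s, float(s.mean())
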