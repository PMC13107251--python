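"""Functional analysis chain for block-design dual-slope time series.

Order of operations (fixed): fold the per-type traces over the 45 s
stimulus-rest cycles (baselines excluded), smooth with a 3 s centred moving
average, estimate the noise level sigma on a designated 2 s segment, apply a
3*sigma detection threshold to the cycle maximum, and report the mean over a
±1 s window centred on the detected peak time.  Across the DS sets of a
module, peaks are summarised as mean ± SEM per data type.

The noise sigma is taken from the *folded, pre-smoothing* trace: the moving
average correlates neighbouring samples so strongly that a short segment of
the smoothed trace would underestimate its own dispersion several-fold,
making a 3*sigma threshold on it fire on pure noise.  The folded-trace sigma
is an honest per-sample noise scale against which the smoothed (i.e.
noise-reduced) peak is tested conservatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import FunctionalTimeSeries, ProtocolDefinition

__all__ = [
    "FoldedTrace",
    "PeakResult",
    "folding_average",
    "moving_average",
    "detect_peak",
    "run_functional_pipeline",
    "summarize_module",
]


@dataclass
class FoldedTrace:
    """Cycle-folded mean trace(s): time-in-cycle axis plus per-type means."""

    time: np.ndarray
    mean: pd.DataFrame
    n_cycles: int
    std: pd.DataFrame | None = None
    sample_rate: float = 10.0


def folding_average(series, protocol: ProtocolDefinition | None = None) -> FoldedTrace:
    """Sample-wise mean across complete stimulus-rest cycles.

    ``series`` is a :class:`~layerlight.synth.FunctionalTimeSeries` or a
    DataFrame indexed like ``protocol.times()``.  Cycles are aligned to
    stimulus onset; the pre/post baselines are excluded (they serve the
    absolute-property fit, not the response average).
    """
    if isinstance(series, FunctionalTimeSeries):
        protocol = series.protocol
        df = series.data
    else:
        if protocol is None:
            raise ValueError("protocol required when passing a bare table")
        df = pd.DataFrame(series)
    fs = protocol.sample_rate
    cyc_len = int(round(protocol.cycle_s * fs))
    start = int(round(protocol.baseline_pre * fs))
    n_cyc = protocol.n_cycles
    avail = (len(df) - start) // cyc_len
    n_cyc = min(n_cyc, avail)
    if n_cyc < 1:
        raise ValueError("no complete stimulus-rest cycle in the series")
    arr = df.iloc[start : start + n_cyc * cyc_len].to_numpy()
    folded = arr.reshape(n_cyc, cyc_len, arr.shape[1])
    return FoldedTrace(
        time=np.arange(cyc_len) / fs,
        mean=pd.DataFrame(folded.mean(axis=0), columns=df.columns),
        std=pd.DataFrame(folded.std(axis=0, ddof=1) if n_cyc > 1 else np.zeros((cyc_len, arr.shape[1])), columns=df.columns),
        n_cycles=int(n_cyc),
        sample_rate=fs,
    )


def moving_average(trace, window_s: float = 3.0, sample_rate: float = 10.0):
    """Centred moving mean with shrunken windows at the edges (no padding)."""
    x = np.asarray(trace, float)
    w = int(round(window_s * sample_rate))
    w = max(w | 1, 1)  # odd window for a centred mean
    if w > x.shape[0]:
        raise ValueError("window longer than the trace")
    kernel = np.ones(w)
    if x.ndim == 1:
        num = np.convolve(x, kernel, mode="same")
        den = np.convolve(np.ones_like(x), kernel, mode="same")
        return num / den
    return np.column_stack([moving_average(x[:, j], window_s, sample_rate) for j in range(x.shape[1])])


@dataclass(frozen=True)
class PeakResult:
    peak_value: float
    peak_time: float
    sigma_est: float
    detected: bool
    window_truncated: bool = False


def detect_peak(
    folded,
    noise_segment: tuple[float, float] = (20.0, 22.0),
    *,
    smooth_window_s: float = 3.0,
    threshold: float = 3.0,
    peak_window_s: float = 1.0,
    column=None,
    sample_rate: float | None = None,
    polarity: str = "positive",
) -> PeakResult:
    """3*sigma peak detection on a folded trace.

    sigma is the sample SD of the folded (pre-smoothing) trace over
    ``noise_segment`` (seconds in cycle); the candidate is the maximum of the
    smoothed trace over the whole cycle (ties broken toward earlier times);
    the reported value is the mean over ±``peak_window_s`` around the peak.
    ``detected`` requires the smoothed maximum to exceed ``threshold * sigma``.

    ``polarity`` selects the response sign: "positive" (default) looks for a
    maximum, "negative" for a minimum (the peak value is reported with its
    original sign), "auto" picks whichever smoothed extremum is larger in
    magnitude.  Raw data-type traces respond with the sign of their
    absorption Jacobian (negative for the intensity types), so feed either
    retrieved Delta mua traces or set the polarity accordingly.
    """
    if isinstance(folded, FoldedTrace):
        t = folded.time
        fs = folded.sample_rate
        y = folded.mean[column].to_numpy() if column is not None else folded.mean.iloc[:, 0].to_numpy()
    else:
        t = np.asarray(folded[0], float)
        y = np.asarray(folded[1], float)
        fs = sample_rate or 1.0 / (t[1] - t[0])

    lo, hi = noise_segment
    seg = (t >= lo) & (t < hi)
    if seg.sum() < 3:
        raise ValueError("noise segment too short (need >= 3 samples)")
    sigma = float(np.std(y[seg], ddof=1))

    ys = moving_average(y, smooth_window_s, fs)
    if polarity == "positive":
        sign = 1.0
    elif polarity == "negative":
        sign = -1.0
    elif polarity == "auto":
        sign = 1.0 if ys.max() >= -ys.min() else -1.0
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    imax = int(np.argmax(sign * ys))  # first occurrence = earlier time on ties
    half = int(round(peak_window_s * fs))
    a, b = imax - half, imax + half + 1
    truncated = a < 0 or b > ys.size
    a = max(a, 0)
    b = min(b, ys.size)
    peak_value = float(np.mean(ys[a:b]))
    return PeakResult(
        peak_value=peak_value,
        peak_time=float(t[imax]),
        sigma_est=sigma,
        detected=bool(sign * ys[imax] > threshold * sigma),
        window_truncated=bool(truncated),
    )


def run_functional_pipeline(
    series,
    protocol: ProtocolDefinition | None = None,
    noise_segment: tuple[float, float] = (20.0, 22.0),
    retrieve: bool | None = None,
    **detect_kw,
) -> dict:
    """fold -> smooth -> sigma -> threshold -> window-average, per data type.

    With ``retrieve`` (the default whenever ``series`` is a
    :class:`~layerlight.synth.FunctionalTimeSeries` carrying Jacobians), the
    folded traces are the retrieved effective Delta mua(t) = Delta M(t)/J_M,
    so an absorption increase peaks positively in every data type.  On raw
    Delta M tables the intensity types respond negatively; pass
    ``polarity="auto"`` (or per-type polarities) in that case.
    """
    if retrieve is None:
        retrieve = isinstance(series, FunctionalTimeSeries) and series.jacobians is not None
    if retrieve:
        if not isinstance(series, FunctionalTimeSeries):
            raise ValueError("retrieve=True requires a FunctionalTimeSeries")
        folded = folding_average(series.retrieve_dmua(), series.protocol)
    else:
        folded = folding_average(series, protocol)
    return {
        col: detect_peak(folded, noise_segment, column=col, **detect_kw)
        for col in folded.mean.columns
    }


def summarize_module(peaks_by_set) -> pd.DataFrame:
    """Mean ± SEM of peak values per data type across the DS sets of a module.

    ``peaks_by_set`` maps DS-set id to either a dict of
    :class:`PeakResult` per data type (as from
    :func:`run_functional_pipeline`) or a dict of plain peak values.  With a
    single set the SEM is undefined (NaN) and flagged.
    """
    rows = {}
    for set_id, peaks in peaks_by_set.items():
        rows[set_id] = {
            m: (p.peak_value if isinstance(p, PeakResult) else float(p))
            for m, p in peaks.items()
        }
    df = pd.DataFrame(rows).T  # sets x data types
    n = len(df)
    out = pd.DataFrame(
        {
            "mean": df.mean(axis=0),
            "sem": df.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "n_sets": n,
            "sem_defined": n > 1,
        }
    )
    return out
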