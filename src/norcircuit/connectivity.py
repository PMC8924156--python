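"""Event-locked spectral coherence and time-lagged cross-correlation.

Epochs span 2 s before to 1 s after each novel-object bout onset.
Magnitude-squared coherence is a Welch estimate,
``msc(f) = |P_xy|^2 / (P_xx * P_yy)``, with 1 s Hann segments at 50%
overlap; segments may be pooled across an animal's epochs into a
single average (the default), or averaged per epoch first.
Cross-correlograms are normalized so the zero-lag autocorrelation is 1
(``r(l) = sum_t x(t) y(t+l) / sqrt(sum x^2 * sum y^2)``); the peak
coefficient and its signed lag are the synchrony parameters, with the
convention that a positive lag means the first-named region leads —
the direction of information influx.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import DEFAULT_BANDS, PAIRS, Recording
from .preprocess import bandpass


@dataclass
class Epoch:
    """One event-locked trial: a (n_channels, n_samples) slice of the
    preprocessed recording around a bout onset at ``t0``."""

    channels: tuple
    data: np.ndarray
    fs: float
    t0: float
    pre: float = 2.0
    post: float = 1.0
    animal_id: str = ""
    index: int = 0

    def channel(self, name: str) -> np.ndarray:
        lower = [c.lower() for c in self.channels]
        return self.data[lower.index(name.lower())]


@dataclass
class CoherenceSpectrum:
    pair: tuple
    freqs: np.ndarray
    msc: np.ndarray
    n_segments: int


@dataclass
class CrossCorrResult:
    pair: tuple
    band: str
    lags_ms: np.ndarray
    r: np.ndarray
    r_max: float
    lag_at_max_ms: float


@dataclass
class AnimalConnectivity:
    """Per-animal trial-averaged connectivity: pair x band maps of band
    coherence, peak cross-correlation and its signed lag (ms)."""

    animal_id: str
    group_label: str
    coherence: dict = field(default_factory=dict)
    r_max: dict = field(default_factory=dict)
    lag_ms: dict = field(default_factory=dict)
    n_trials: int = 0


def extract_epochs(rec: Recording, onsets, pre: float = 2.0,
                   post: float = 1.0) -> tuple:
    """Cut event-locked epochs around each onset time.

    An epoch must fit entirely inside the recording and contain no
    artifact-masked samples; others are dropped, with reasons returned
    in the log list. Returns ``(epochs, dropped_log)``.
    """
    epochs, dropped = [], []
    n = rec.n_samples
    n_pre = int(round(pre * rec.fs))
    n_post = int(round(post * rec.fs))
    for k, t0 in enumerate(onsets):
        i0 = int(round(t0 * rec.fs)) - n_pre
        i1 = i0 + n_pre + n_post
        if i0 < 0 or i1 > n:
            dropped.append((t0, "outside recording (truncated window)"))
            continue
        if rec.artifact_mask[i0:i1].any():
            dropped.append((t0, "overlaps artifact mask"))
            continue
        epochs.append(Epoch(rec.channels, rec.data[:, i0:i1].copy(), rec.fs,
                            float(t0), pre, post, rec.animal_id, k))
    return epochs, dropped


# ---------------------------------------------------------------------------
# Welch coherence with segment pooling

def _segments(x: np.ndarray, nperseg: int, step: int):
    for start in range(0, len(x) - nperseg + 1, step):
        yield x[start:start + nperseg]


def _accumulate_spectra(x, y, win, nperseg, step):
    """Sum of per-segment auto/cross periodograms (scaling cancels in msc)."""
    pxx = pyy = 0.0
    pxy = 0.0
    k = 0
    for sx, sy in zip(_segments(x, nperseg, step), _segments(y, nperseg, step)):
        fx = np.fft.rfft((sx - sx.mean()) * win)
        fy = np.fft.rfft((sy - sy.mean()) * win)
        pxx = pxx + np.abs(fx) ** 2
        pyy = pyy + np.abs(fy) ** 2
        pxy = pxy + fx * np.conj(fy)
        k += 1
    return pxx, pyy, pxy, k


def msc(x, y=None, fs: float = 1000.0, seg_len_s: float = 1.0,
        overlap: float = 0.5, window: str = "hann",
        pair: tuple = ("x", "y")) -> CoherenceSpectrum:
    """Welch magnitude-squared coherence.

    ``x, y`` may be two equal-length 1-D arrays, or ``x`` may be a list
    of ``(x_i, y_i)`` epoch pairs whose segments are pooled into one
    average (per-epoch segmentation, single pooled estimate). At least
    2 segments overall are required: a single segment makes the
    estimator degenerate (msc = 1 identically).
    """
    if y is None:
        pairs = list(x)
    else:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        pairs = [(x, y)]
    nperseg = int(round(seg_len_s * fs))
    step = max(int(round(nperseg * (1.0 - overlap))), 1)
    win = sps.get_window(window, nperseg)
    pxx = pyy = 0.0
    pxy = 0.0
    k = 0
    for xi, yi in pairs:
        a, b, c, kk = _accumulate_spectra(np.asarray(xi, dtype=float),
                                          np.asarray(yi, dtype=float),
                                          win, nperseg, step)
        pxx = pxx + a
        pyy = pyy + b
        pxy = pxy + c
        k += kk
    if k < 2:
        raise ValueError(f"only {k} Welch segment(s); need >= 2 "
                         "(msc is degenerately 1 for a single segment)")
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    with np.errstate(divide="ignore", invalid="ignore"):
        c2 = np.abs(pxy) ** 2 / (pxx * pyy)
    c2 = np.nan_to_num(c2, nan=0.0)
    c2 = np.clip(c2, 0.0, 1.0)  # guard numerical epsilon only
    return CoherenceSpectrum(tuple(pair), freqs, c2, k)


def band_mean(coh: CoherenceSpectrum, band) -> float:
    """Unweighted mean msc over frequency bins with f_lo <= f <= f_hi."""
    lo, hi = band
    sel = (coh.freqs >= lo) & (coh.freqs <= hi)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band ({lo}, {hi})")
    return float(coh.msc[sel].mean())


# ---------------------------------------------------------------------------
# normalized cross-correlation

def _tiebreak_peak(lags: np.ndarray, r: np.ndarray, rtol: float = 1e-12):
    """Peak of r with ties broken toward smallest |lag|, then positive lag."""
    rmax = r.max()
    cand = np.flatnonzero(r >= rmax - rtol * max(abs(rmax), 1.0))
    order = sorted(cand, key=lambda i: (abs(lags[i]), -np.sign(lags[i])))
    return order[0]


def xcorr_norm(x, y, fs: float, max_lag_ms: float = 100.0,
               pair: tuple = ("x", "y"), band: str = "",
               absolute_peak: bool = False) -> CrossCorrResult:
    """Normalized cross-correlogram over a symmetric lag grid.

    ``r(l) = sum_t x(t) y(t+l) / sqrt(sum x^2 sum y^2)`` — the "coeff"
    normalization, so an autocorrelation peaks at exactly 1. Positive
    ``lag_at_max_ms`` means x (the first-named region) leads y. The
    peak is the signed maximum of r by default; ``absolute_peak``
    switches to the maximum of |r|. Ties break toward the smallest
    |lag|, then toward the positive lag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    x = x - x.mean()
    y = y - y.mean()
    ex, ey = float(np.sum(x * x)), float(np.sum(y * y))
    if ex == 0 or ey == 0:
        raise ValueError("zero-variance input")
    max_lag = int(round(max_lag_ms * fs / 1000.0))
    if max_lag >= len(x) // 4:
        raise ValueError("max_lag must be < signal length / 4")
    # correlate(y, x)[k] = sum_n y[n + l] x[n] at l = k - (N-1):
    # peaks at l = d when y is x delayed by d (x leads).
    full = sps.correlate(y, x, mode="full", method="fft")
    lags = sps.correlation_lags(len(y), len(x), mode="full")
    sel = np.abs(lags) <= max_lag
    r = full[sel] / np.sqrt(ex * ey)
    lags_ms = lags[sel] * 1000.0 / fs
    peak_on = np.abs(r) if absolute_peak else r
    i = _tiebreak_peak(lags_ms, peak_on)
    return CrossCorrResult(tuple(pair), band, lags_ms, r,
                           float(r[i]), float(lags_ms[i]))


def influx_lag(ccr: CrossCorrResult) -> float:
    """Signed lag of information influx (ms): the cross-correlogram's
    peak lag. Positive = first-named region leads (influx first->second)."""
    return ccr.lag_at_max_ms


def default_max_lag_ms(band) -> float:
    """250 ms for low (theta-range) bands, 100 ms otherwise.

    A narrow low band repeats its correlogram peak every cycle
    (~125 ms at 8 Hz); the wider grid keeps the true peak in view."""
    return 250.0 if band[0] < 15.0 else 100.0


# ---------------------------------------------------------------------------
# per-animal aggregation

def animal_connectivity(epochs: list, bands: dict | None = None,
                        pairs=PAIRS, seg_len_s: float = 1.0,
                        overlap: float = 0.5, pool: str = "animal",
                        max_lag_ms: dict | float | None = None,
                        absolute_peak: bool = False) -> AnimalConnectivity:
    """Aggregate epochs into per-animal connectivity.

    Coherence: with ``pool="animal"`` (default) Welch segments from all
    epochs are pooled into one estimate per pair; ``pool="trial"``
    estimates per epoch and averages the band means. Cross-correlation
    is always per trial (band-filtered, mean-removed epochs), and the
    per-trial peak coefficients and lags are arithmetically averaged —
    the per-animal synchrony parameters.
    """
    if not epochs:
        raise ValueError("zero valid epochs: animal must be flagged missing")
    if pool not in ("animal", "trial"):
        raise ValueError("pool must be 'animal' or 'trial'")
    bands = dict(bands or DEFAULT_BANDS)
    fs = epochs[0].fs
    out = AnimalConnectivity(epochs[0].animal_id, "", n_trials=len(epochs))
    for a, b in pairs:
        key = f"{a}-{b}"
        pair_sig = [(ep.channel(a), ep.channel(b)) for ep in epochs]
        out.coherence[key] = {}
        out.r_max[key] = {}
        out.lag_ms[key] = {}
        for bn, band in bands.items():
            if pool == "animal":
                coh = msc(pair_sig, fs=fs, seg_len_s=seg_len_s,
                          overlap=overlap, pair=(a, b))
                out.coherence[key][bn] = band_mean(coh, band)
            else:
                vals = [band_mean(msc(xi, yi, fs=fs, seg_len_s=seg_len_s,
                                      overlap=overlap, pair=(a, b)), band)
                        for xi, yi in pair_sig]
                out.coherence[key][bn] = float(np.mean(vals))
            if max_lag_ms is None:
                ml = default_max_lag_ms(band)
            elif isinstance(max_lag_ms, dict):
                ml = max_lag_ms[bn]
            else:
                ml = float(max_lag_ms)
            rs, ls = [], []
            for xi, yi in pair_sig:
                xf = bandpass(xi, band, fs)
                yf = bandpass(yi, band, fs)
                ccr = xcorr_norm(xf, yf, fs, max_lag_ms=ml, pair=(a, b),
                                 band=bn, absolute_peak=absolute_peak)
                rs.append(ccr.r_max)
                ls.append(ccr.lag_at_max_ms)
            out.r_max[key][bn] = float(np.mean(rs))
            out.lag_ms[key][bn] = float(np.mean(ls))
    return out
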