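"""Fiber-photometry dF/F and infraslow norepinephrine (NE) oscillations.

The 465 nm channel excites the NE biosensor; the 405 nm channel excites at
an isosbestic wavelength insensitive to ligand binding, so it carries the
shared bleaching and motion artifacts.  A least-squares fit scales the
405 nm channel onto the 465 nm channel::

    scaled405 = a * f405 + b
    dF/F (%)  = (f465 - scaled405) * 100 / scaled405

During NREM sleep the NE signal oscillates at infraslow frequencies
(~0.02 Hz, period tens of seconds).  Per NREM bout the dF/F trace is
polynomial-detrended and its Welch power spectral density (PSD) computed;
bout PSDs are averaged (bout-duration weighted).  The oscillation is
summarized by the maximum of the averaged PSD (amplitude), its argmax
frequency, the integrated infraslow-band power, and the rate of discrete NE
peaks (prominence >= 0.5 %dF/F, >= 10 s apart) per second of NREM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .sleep import Bout, Hypnogram, SpectralDensity, extract_bouts


@dataclass
class IsosbesticFit:
    """Affine coupling of the isosbestic channel: scaled405 = a*f405 + b."""

    a: float
    b: float
    residual_sd: float
    n: int

    def scaled(self, f405: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(f405, dtype=float) + self.b


@dataclass
class DffTrace:
    """Percent dF/F series at a fixed sample rate."""

    values: np.ndarray
    sample_rate_hz: float
    method: str = "fitted_405"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("dF/F values must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        self.values = v

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.sample_rate_hz


@dataclass
class NEOscillationMetrics:
    """Summary of NREM infraslow NE oscillations for one session."""

    psd_amplitude: float  # max of the averaged PSD (a.u.)
    psd_peak_freq_hz: float  # argmax of the averaged PSD within the band
    infraslow_power: float  # trapezoid integral of the averaged PSD over band
    peak_rate_hz: float  # detected NE peaks / total NREM seconds
    n_bouts_used: int
    n_peaks: int


class IsosbesticScaler(RegressorMixin, BaseEstimator):
    """Least-squares affine fit of the 465 nm signal on the 405 nm channel.

    sklearn-style: ``fit(f405, f465)`` estimates ``a_`` and ``b_``;
    ``transform`` (or :meth:`scaled`) maps a 405 nm series onto the scaled
    control channel ``a_ * f405 + b_``.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "IsosbesticScaler":
        f405 = np.asarray(X, dtype=float).ravel()
        f465 = np.asarray(y, dtype=float).ravel()
        if f405.shape != f465.shape:
            raise ValueError("channels must have equal length")
        if f405.size < 2:
            raise ValueError("need at least 2 samples")
        if not (np.all(np.isfinite(f405)) and np.all(np.isfinite(f465))):
            raise ValueError("channels must be finite")
        if np.ptp(f405) == 0:
            raise ValueError("singular fit: f405 is constant")
        a, b = np.polyfit(f405, f465, deg=1)
        resid = f465 - (a * f405 + b)
        self.a_, self.b_ = float(a), float(b)
        self.residual_sd_ = float(resid.std())
        self.n_features_in_ = 1
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "a_")
        return self.a_ * np.asarray(X, dtype=float).ravel() + self.b_

    transform = predict

    def to_fit(self, n: int | None = None) -> IsosbesticFit:
        check_is_fitted(self, "a_")
        return IsosbesticFit(
            a=self.a_, b=self.b_, residual_sd=self.residual_sd_, n=n or -1
        )


def fit_isosbestic(f465: np.ndarray, f405: np.ndarray) -> IsosbesticFit:
    """Ordinary least squares of f465 on f405 (degree-1 polynomial)."""
    est = IsosbesticScaler().fit(f405, f465)
    return IsosbesticFit(
        a=est.a_, b=est.b_, residual_sd=est.residual_sd_, n=len(np.ravel(f465))
    )


def compute_dff(
    f465: np.ndarray,
    f405: np.ndarray | None,
    sample_rate_hz: float,
    method: str = "fitted_405",
) -> DffTrace:
    """Percent dF/F from the two-channel pair (or a single channel).

    ``fitted_405``: subtract and divide by the fitted scaled 405 channel,
    ``(f465 - (a*f405+b)) * 100 / (a*f405+b)``.  ``self_median``: baseline
    is the median of f465 itself.  A baseline that is zero or negative
    anywhere is an error (reported with the first offending index).
    """
    f465 = np.asarray(f465, dtype=float)
    if method == "fitted_405":
        if f405 is None:
            raise ValueError("fitted_405 requires the 405 nm channel")
        fit = fit_isosbestic(f465, np.asarray(f405, dtype=float))
        baseline = fit.scaled(f405)
    elif method == "self_median":
        med = float(np.median(f465))
        baseline = np.full_like(f465, med)
    else:
        raise ValueError(f"unknown method {method!r}")
    bad = np.flatnonzero(baseline <= 0)
    if bad.size:
        raise ValueError(
            f"baseline crosses <= 0 at sample {int(bad[0])}; cannot divide"
        )
    values = (f465 - baseline) * 100.0 / baseline
    return DffTrace(values=values, sample_rate_hz=sample_rate_hz, method=method)


def detrend_bout(segment: np.ndarray, poly_order: int = 2) -> np.ndarray:
    """Subtract a least-squares polynomial; residual mean is 0 (within 1e-9)."""
    segment = np.asarray(segment, dtype=float)
    if len(segment) <= poly_order + 1:
        raise ValueError(
            f"segment of {len(segment)} samples too short for order "
            f"{poly_order} detrend"
        )
    x = np.arange(len(segment), dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(x, segment, deg=poly_order)
    resid = segment - np.polynomial.polynomial.polyval(x, coeffs)
    return resid - resid.mean()


# alias matching the NREM-bout analysis context
detrend_nrem_bout = detrend_bout


def _nrem_bout_slices(
    dff: DffTrace, hypnogram: Hypnogram
) -> list[tuple[Bout, np.ndarray]]:
    fs = dff.sample_rate_hz
    out = []
    for b in extract_bouts(hypnogram):
        if b.state != "NREM":
            continue
        i0 = int(round((b.start_s - hypnogram.start_time_s) * fs))
        i1 = min(int(round((b.end_s - hypnogram.start_time_s) * fs)), len(dff.values))
        if i1 > i0:
            out.append((b, dff.values[i0:i1]))
    return out


def nrem_psd(
    dff: DffTrace,
    hypnogram: Hypnogram,
    min_bout_s: float = 120.0,
    welch_window_s: float = 120.0,
    overlap_frac: float = 0.5,
    poly_order: int = 2,
    duration_weighted: bool = True,
) -> tuple[SpectralDensity, list[tuple[Bout, SpectralDensity]]]:
    """Averaged (and per-bout) Welch PSD of detrended NREM dF/F.

    Each NREM bout at least ``max(min_bout_s, welch_window_s)`` long is
    polynomial-detrended and Welch-transformed (Hann taper); the fixed
    segment length puts every bout on a common frequency grid, and bout
    PSDs are averaged with bout-duration weights (or unweighted).
    """
    fs = dff.sample_rate_hz
    nperseg = int(round(welch_window_s * fs))
    noverlap = int(round(overlap_frac * nperseg))
    min_len = max(min_bout_s, welch_window_s)
    per_bout, weights = [], []
    for bout, seg in _nrem_bout_slices(dff, hypnogram):
        if bout.duration_s < min_len or len(seg) < nperseg:
            continue
        resid = detrend_bout(seg, poly_order=poly_order)
        freqs, p = signal.welch(
            resid, fs=fs, nperseg=nperseg, noverlap=noverlap, window="hann"
        )
        per_bout.append((bout, SpectralDensity(freqs_hz=freqs, power=p)))
        weights.append(bout.duration_s)
    if not per_bout:
        raise ValueError(
            f"insufficient NREM: no bout of at least {min_len:.0f} s"
        )
    w = np.asarray(weights, dtype=float)
    if not duration_weighted:
        w = np.ones_like(w)
    stacked = np.vstack([sd.power for _, sd in per_bout])
    avg = np.average(stacked, axis=0, weights=w / w.sum())
    return SpectralDensity(freqs_hz=per_bout[0][1].freqs_hz, power=avg), per_bout


def suppress_close_peaks(
    times_s: np.ndarray, heights: np.ndarray, min_interval_s: float
) -> np.ndarray:
    """Greedy tallest-first suppression of peaks closer than the interval.

    Among candidates within ``min_interval_s`` of each other the taller
    survives (ties: the earlier one).  Returns indices of survivors in
    time order.
    """
    order = sorted(range(len(times_s)), key=lambda i: (-heights[i], times_s[i]))
    accepted: list[int] = []
    for i in order:
        if all(abs(times_s[i] - times_s[j]) >= min_interval_s for j in accepted):
            accepted.append(i)
    return np.array(sorted(accepted, key=lambda i: times_s[i]), dtype=int)


def detect_ne_peaks(
    dff: DffTrace,
    hypnogram: Hypnogram,
    min_interval_s: float = 10.0,
    min_amplitude_pct: float = 0.5,
    poly_order: int = 2,
    lowpass_hz: float | None = 0.1,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Discrete NE peaks during NREM and their rate per NREM second.

    Within each NREM bout (hard edges; the minimum interval is not enforced
    across bout boundaries) the detrended trace's local maxima with
    prominence >= ``min_amplitude_pct`` are candidates; peaks closer than
    ``min_interval_s`` are thinned tallest-first.  Because the rule set
    itself declares events closer than ``min_interval_s`` meaningless, the
    detrended trace is first zero-phase low-pass filtered at ``lowpass_hz``
    (default 0.1 Hz = 1 / the 10 s minimum interval; skipped when ``None``
    or not below Nyquist) so faster fluctuations do not register as peaks.
    Returns peak times (s), peak heights (prominence, %dF/F) and
    ``peak_rate_hz`` = surviving count / total NREM seconds.
    """
    fs = dff.sample_rate_hz
    slices = _nrem_bout_slices(dff, hypnogram)
    if not slices:
        raise ValueError("hypnogram contains no NREM time")
    total_nrem_s = sum(b.duration_s for b, _ in slices)
    sos = None
    if lowpass_hz is not None and lowpass_hz < 0.45 * fs:
        sos = signal.butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
    all_times, all_heights = [], []
    for bout, seg in slices:
        if len(seg) <= poly_order + 1:
            continue
        resid = detrend_bout(seg, poly_order=poly_order)
        if sos is not None and len(resid) > 24:  # sosfiltfilt padding needs margin
            resid = signal.sosfiltfilt(sos, resid)
        idx, props = signal.find_peaks(resid, prominence=min_amplitude_pct)
        if idx.size == 0:
            continue
        t = bout.start_s + idx / fs
        h = props["prominences"]
        keep = suppress_close_peaks(t, h, min_interval_s)
        all_times.extend(t[keep])
        all_heights.extend(h[keep])
    times = np.asarray(all_times, dtype=float)
    heights = np.asarray(all_heights, dtype=float)
    return times, heights, len(times) / total_nrem_s


def ne_metrics(
    dff: DffTrace,
    hypnogram: Hypnogram,
    infraslow_band_hz: tuple[float, float] = (0.005, 0.1),
    min_bout_s: float = 120.0,
    welch_window_s: float = 120.0,
    overlap_frac: float = 0.5,
    poly_order: int = 2,
    min_interval_s: float = 10.0,
    min_amplitude_pct: float = 0.5,
    lowpass_hz: float | None = 0.1,
) -> NEOscillationMetrics:
    """Assemble the NREM infraslow-oscillation summary for one session.

    Amplitude is the maximum of the averaged PSD and peak frequency its
    argmax, both restricted to the analysis band; infraslow power is the
    trapezoid integral of the averaged PSD over the band; the peak rate
    comes from :func:`detect_ne_peaks`.
    """
    avg, per_bout = nrem_psd(
        dff,
        hypnogram,
        min_bout_s=min_bout_s,
        welch_window_s=welch_window_s,
        overlap_frac=overlap_frac,
        poly_order=poly_order,
    )
    lo, hi = infraslow_band_hz
    sel = (avg.freqs_hz >= lo) & (avg.freqs_hz <= hi)
    if not sel.any():
        raise ValueError("infraslow band selects no PSD bins")
    band_f = avg.freqs_hz[sel]
    band_p = avg.power[sel]
    i_max = int(np.argmax(band_p))
    times, _heights, rate = detect_ne_peaks(
        dff,
        hypnogram,
        min_interval_s=min_interval_s,
        min_amplitude_pct=min_amplitude_pct,
        poly_order=poly_order,
        lowpass_hz=lowpass_hz,
    )
    return NEOscillationMetrics(
        psd_amplitude=float(band_p[i_max]),
        psd_peak_freq_hz=float(band_f[i_max]),
        infraslow_power=float(np.trapezoid(band_p, band_f)),
        peak_rate_hz=rate,
        n_bouts_used=len(per_bout),
        n_peaks=len(times),
    )
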