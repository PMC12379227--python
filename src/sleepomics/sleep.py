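"""Vigilance-state scoring, sleep architecture and EEG spectral statistics.

Sleep states (WAKE / NREM / REM) are defined by EEG spectral content and EMG
tone: wakefulness shows high muscle tone with fast low-amplitude EEG, NREM
sleep shows absent muscle tone with slow high-amplitude (delta, 1-4 Hz) EEG,
and REM sleep shows absent muscle tone with fast low-amplitude (theta,
4-8 Hz) EEG.  The module epochs a recording, extracts band-power and EMG
features, scores epochs with a transparent threshold tree
(:class:`ThresholdSleepScorer`), and computes bout, architecture, state
spectral-density and slow-wave-activity (SWA) statistics from the resulting
hypnogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

STATES = ("WAKE", "NREM", "REM")

#: Canonical EEG frequency bands (Hz): delta 1-4, theta 4-8.
DELTA_BAND = ("delta", 1.0, 4.0)
THETA_BAND = ("theta", 4.0, 8.0)


@dataclass
class BandDefinition:
    """A half-open frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )


@dataclass
class Recording:
    """Uniformly sampled multichannel time series (EEG, EMG, photometry).

    Parameters
    ----------
    channels
        Mapping of channel name -> 1-D float array.  All channels must have
        equal length and contain no NaN.
    sample_rate_hz
        Common sampling rate in Hz.
    """

    channels: Mapping[str, np.ndarray]
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not self.channels:
            raise ValueError("Recording needs at least one channel")
        chans = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {len(v) for v in chans.values()}
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        for name, v in chans.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"channel {name!r} contains non-finite values")
        self.channels = chans

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"recording has no channel {name!r}; available: "
                f"{sorted(self.channels)}"
            ) from None


@dataclass
class Hypnogram:
    """Sequence of vigilance-state labels at fixed epoch length."""

    labels: np.ndarray
    epoch_length_s: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        if labels.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(labels) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")
        self.labels = labels

    @property
    def n_epochs(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def epoch_times(self) -> np.ndarray:
        """Start time (s) of each epoch."""
        return self.start_time_s + self.epoch_length_s * np.arange(self.n_epochs)


@dataclass
class Bout:
    """Maximal run of consecutive epochs in one state, in seconds."""

    state: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("bout must have end_s > start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SpectralDensity:
    """Welch power spectral density on a frequency grid (unit: x**2/Hz)."""

    freqs_hz: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape:
            raise ValueError("frequency grid and power must have equal shape")
        if f.size and np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("power must be non-negative")
        self.freqs_hz, self.power = f, p


@dataclass
class ArchitectureStats:
    """Per-state time percentage, bout counts/durations and onset latency."""

    percent_time: dict[str, float]
    bout_count: dict[str, int]
    mean_bout_duration_s: dict[str, float]
    latency_s: dict[str, float]
    n_epochs: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percent_time": self.percent_time,
                "bout_count": self.bout_count,
                "mean_bout_duration_s": self.mean_bout_duration_s,
                "latency_s": self.latency_s,
            }
        ).loc[list(STATES)]


# ---------------------------------------------------------------------------
# epoch features


def epoch_features(
    recording: Recording,
    epoch_length_s: float,
    bands: Sequence[BandDefinition] | None = None,
    eeg_channel: str = "eeg",
    emg_channel: str = "emg",
) -> pd.DataFrame:
    """Per-epoch band powers, EMG RMS and EEG amplitude.

    Band power is the mean Welch PSD over each half-open band.  One row per
    complete epoch; a trailing partial epoch is dropped.
    """
    if bands is None:
        bands = [BandDefinition(*DELTA_BAND), BandDefinition(*THETA_BAND)]
    eeg = recording[eeg_channel]
    emg = recording[emg_channel]
    fs = recording.sample_rate_hz
    spe = int(round(epoch_length_s * fs))
    n_epochs = len(eeg) // spe
    if n_epochs == 0:
        raise ValueError(
            f"recording shorter ({recording.duration_s:.3f} s) than one epoch"
        )
    eeg = eeg[: n_epochs * spe].reshape(n_epochs, spe)
    emg = emg[: n_epochs * spe].reshape(n_epochs, spe)

    nperseg = min(spe, int(round(2 * fs)))  # >=0.5 Hz resolution for 2 s windows
    freqs, psd = signal.welch(eeg, fs=fs, nperseg=nperseg, axis=1, window="hann")

    out = {
        "t_start_s": epoch_length_s * np.arange(n_epochs),
        "emg_rms": np.sqrt(np.mean(emg**2, axis=1)),
        "eeg_amplitude": np.sqrt(np.mean(eeg**2, axis=1)),
    }
    for band in bands:
        sel = (freqs >= band.f_lo) & (freqs < band.f_hi)
        if not sel.any():
            raise ValueError(f"band {band.name!r} selects no PSD bins")
        out[f"{band.name}_power"] = psd[:, sel].mean(axis=1)
    df = pd.DataFrame(out)
    if {"delta_power", "theta_power"} <= set(df.columns):
        with np.errstate(divide="ignore", invalid="ignore"):
            df["theta_delta_ratio"] = df["theta_power"] / df["delta_power"]
            df["delta_fraction"] = df["delta_power"] / (
                df["delta_power"] + df["theta_power"]
            )
    return df


# ---------------------------------------------------------------------------
# scoring


class ThresholdSleepScorer(ClassifierMixin, BaseEstimator):
    """Threshold decision tree over epoch features.

    The rule set mirrors classical manual scoring criteria: an epoch with
    high EMG tone is WAKE; among atonic epochs, delta-dominant EEG is NREM
    and the remainder (theta-dominant, low amplitude) is REM::

        EMG RMS > emg_rms_hi          -> WAKE
        elif delta_fraction > delta_ratio_hi -> NREM
        else                          -> REM

    The EMG threshold is scale-dependent, so when left ``None`` it is
    auto-calibrated by :meth:`fit` as the geometric midpoint of the
    (10th, 90th) percentile range of EMG RMS -- robust for the strongly
    bimodal tone distribution.  The delta fraction is already normalized to
    (0, 1) with NREM near 1 and REM near 0, so its default is the fixed
    midpoint 0.5; pass ``None`` to quantile-calibrate it instead (only
    sensible when both NREM and REM are present).

    Parameters
    ----------
    emg_rms_hi : float or None
        EMG RMS above which an epoch is WAKE (None: auto-calibrate).
    delta_ratio_hi : float or None, default 0.5
        delta/(delta+theta) power fraction above which an atonic epoch is
        NREM (None: auto-calibrate).
    theta_ratio_hi : float or None
        Accepted for interface compatibility; the default decision tree is
        fully determined by the two thresholds above and does not use it.
    """

    def __init__(
        self,
        emg_rms_hi: float | None = None,
        delta_ratio_hi: float | None = 0.5,
        theta_ratio_hi: float | None = None,
    ):
        self.emg_rms_hi = emg_rms_hi
        self.delta_ratio_hi = delta_ratio_hi
        self.theta_ratio_hi = theta_ratio_hi

    @staticmethod
    def _validate(features: pd.DataFrame) -> pd.DataFrame:
        if len(features) == 0:
            raise ValueError("empty feature table")
        needed = {"emg_rms", "delta_fraction"}
        missing = needed - set(features.columns)
        if missing:
            raise ValueError(f"feature table lacks columns {sorted(missing)}")
        return features

    @staticmethod
    def _geometric_mid(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        x = x[x > 0]
        if x.size == 0:
            return 0.0
        lo, hi = np.percentile(np.log(x), [10, 90])
        return float(np.exp((lo + hi) / 2))

    def fit(self, features: pd.DataFrame, y=None) -> "ThresholdSleepScorer":
        """Calibrate any unset thresholds from the feature distribution."""
        features = self._validate(features)
        emg = features["emg_rms"].to_numpy()
        self.emg_rms_hi_ = (
            self.emg_rms_hi if self.emg_rms_hi is not None else self._geometric_mid(emg)
        )
        if self.delta_ratio_hi is not None:
            self.delta_ratio_hi_ = self.delta_ratio_hi
        else:
            atonic = features.loc[emg <= self.emg_rms_hi_, "delta_fraction"]
            src = atonic if len(atonic) else features["delta_fraction"]
            lo, hi = np.nanpercentile(src.to_numpy(dtype=float), [10, 90])
            self.delta_ratio_hi_ = float((lo + hi) / 2)
        self.classes_ = np.asarray(STATES, dtype=object)
        return self

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "emg_rms_hi_")
        features = self._validate(features)
        emg = features["emg_rms"].to_numpy(dtype=float)
        delta_frac = features["delta_fraction"].to_numpy(dtype=float)
        labels = np.where(
            emg > self.emg_rms_hi_,
            "WAKE",
            np.where(delta_frac > self.delta_ratio_hi_, "NREM", "REM"),
        )
        return labels.astype(object)

    def score(self, features: pd.DataFrame, y) -> float:
        return float(np.mean(self.predict(features) == np.asarray(y, dtype=object)))


def score_epochs(
    features: pd.DataFrame,
    thresholds: Mapping[str, float] | None = None,
    epoch_length_s: float = 5.0,
) -> Hypnogram:
    """Score epochs into a hypnogram with :class:`ThresholdSleepScorer`.

    ``thresholds`` may fix any of ``emg_rms_hi`` / ``delta_ratio_hi`` /
    ``theta_ratio_hi``; unset ones are auto-calibrated from the features.
    """
    thresholds = dict(thresholds or {})
    scorer = ThresholdSleepScorer(
        emg_rms_hi=thresholds.get("emg_rms_hi"),
        delta_ratio_hi=thresholds.get("delta_ratio_hi", 0.5),
        theta_ratio_hi=thresholds.get("theta_ratio_hi"),
    )
    labels = scorer.fit(features).predict(features)
    return Hypnogram(labels=labels, epoch_length_s=epoch_length_s)


# ---------------------------------------------------------------------------
# bouts & architecture


def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Maximal same-label runs as (state, start_epoch, end_epoch_exclusive)."""
    runs: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i))
            start = i
    return runs


def extract_bouts(hypnogram: Hypnogram, min_bout_s: float = 0.0) -> list[Bout]:
    """Maximal same-state runs; runs shorter than ``min_bout_s`` are merged.

    A short run is absorbed into whichever neighbour run is longer (tie:
    the preceding neighbour); merging repeats until every bout satisfies
    the minimum, always absorbing the currently shortest offender first.
    """
    eps = hypnogram.epoch_length_s
    runs = [[s, e - b] for s, b, e in _runs(hypnogram.labels)]  # [state, n_epochs]
    if min_bout_s > 0:
        while len(runs) > 1:
            durs = [n * eps for _, n in runs]
            short = [i for i, d in enumerate(durs) if d < min_bout_s]
            if not short:
                break
            i = min(short, key=lambda k: (durs[k], k))
            if i == 0:
                j = 1
            elif i == len(runs) - 1:
                j = i - 1
            else:
                j = i - 1 if durs[i - 1] >= durs[i + 1] else i + 1
            runs[j][1] += runs[i][1]
            del runs[i]
            # re-coalesce neighbours that became same-state
            k = 1
            while k < len(runs):
                if runs[k][0] == runs[k - 1][0]:
                    runs[k - 1][1] += runs[k][1]
                    del runs[k]
                else:
                    k += 1
    bouts, t = [], hypnogram.start_time_s
    for state, n in runs:
        bouts.append(Bout(state=state, start_s=t, end_s=t + n * eps))
        t += n * eps
    return bouts


def architecture_stats(hypnogram: Hypnogram) -> ArchitectureStats:
    """Time-in-state percentages, bout counts/durations and state latencies.

    Percentages are exact rationals on epoch counts (they sum to 100
    exactly); latency is the start of the first bout of each state measured
    from the recording start, NaN when the state never occurs.
    """
    labels = hypnogram.labels
    n = labels.size
    counts = {s: int(np.sum(labels == s)) for s in STATES}
    percent = {s: counts[s] * 100.0 / n for s in STATES}
    bouts = extract_bouts(hypnogram)
    bout_count = {s: 0 for s in STATES}
    durations: dict[str, list[float]] = {s: [] for s in STATES}
    latency = {s: math.nan for s in STATES}
    for b in bouts:
        bout_count[b.state] += 1
        durations[b.state].append(b.duration_s)
        if math.isnan(latency[b.state]):
            latency[b.state] = b.start_s - hypnogram.start_time_s
    mean_dur = {
        s: (float(np.mean(d)) if d else math.nan) for s, d in durations.items()
    }
    return ArchitectureStats(
        percent_time=percent,
        bout_count=bout_count,
        mean_bout_duration_s=mean_dur,
        latency_s=latency,
        n_epochs=n,
    )


# ---------------------------------------------------------------------------
# state spectra


def state_psd(
    recording: Recording,
    hypnogram: Hypnogram,
    state: str,
    window_s: float = 4.0,
    overlap_frac: float = 0.5,
    channel: str = "eeg",
) -> SpectralDensity:
    """Welch PSD of the EEG restricted to bouts of one vigilance state.

    Each bout at least one Welch segment long gets its own PSD; bout PSDs
    share the frequency grid (fixed segment length) and are averaged with
    bout-duration weights.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    x = recording[channel]
    fs = recording.sample_rate_hz
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap_frac * nperseg))
    psds, weights = [], []
    freqs = None
    for b in extract_bouts(hypnogram):
        if b.state != state:
            continue
        i0 = int(round((b.start_s - hypnogram.start_time_s) * fs))
        i1 = int(round((b.end_s - hypnogram.start_time_s) * fs))
        seg = x[i0 : min(i1, len(x))]
        if len(seg) < nperseg:
            continue
        freqs, p = signal.welch(
            seg, fs=fs, nperseg=nperseg, noverlap=noverlap, window="hann"
        )
        psds.append(p)
        weights.append(b.duration_s)
    if not psds:
        raise ValueError(
            f"insufficient data: no {state} bout of at least {window_s} s"
        )
    w = np.asarray(weights) / np.sum(weights)
    return SpectralDensity(freqs_hz=freqs, power=np.average(psds, axis=0, weights=w))


def band_power(psd: SpectralDensity, band: BandDefinition) -> float:
    """Mean PSD over the half-open band [f_lo, f_hi)."""
    sel = (psd.freqs_hz >= band.f_lo) & (psd.freqs_hz < band.f_hi)
    if not sel.any():
        raise ValueError(f"band {band.name!r} selects no PSD bins")
    return float(psd.power[sel].mean())


# ---------------------------------------------------------------------------
# slow-wave activity


def swa_timecourse(
    recording: Recording,
    hypnogram: Hypnogram,
    baseline: float,
    bin_s: float = 3600.0,
    band: BandDefinition | None = None,
) -> pd.DataFrame:
    """NREM delta power per time bin as a percentage of a baseline value.

    ``baseline`` is a reference NREM delta power (same units as the epoch
    delta-power feature), typically the mean NREM delta power of a baseline
    recording computed with :func:`nrem_delta_power`.  Bins with no NREM
    epochs yield NaN, never zero.
    """
    if baseline <= 0 or not np.isfinite(baseline):
        raise ValueError("baseline must be a positive finite delta power")
    band = band or BandDefinition(*DELTA_BAND)
    feats = epoch_features(recording, hypnogram.epoch_length_s, bands=[band])
    n = min(len(feats), hypnogram.n_epochs)
    delta = feats[f"{band.name}_power"].to_numpy()[:n]
    labels = hypnogram.labels[:n]
    t = feats["t_start_s"].to_numpy()[:n]
    bins = np.floor(t / bin_s).astype(int)
    rows = []
    for b in range(int(bins.max()) + 1 if n else 0):
        sel = (bins == b) & (labels == "NREM")
        val = float(delta[sel].mean()) if sel.any() else math.nan
        rows.append(
            {"bin_start_s": b * bin_s, "swa_percent": val * 100.0 / baseline}
        )
    return pd.DataFrame(rows)


def nrem_delta_power(
    recording: Recording,
    hypnogram: Hypnogram,
    band: BandDefinition | None = None,
) -> float:
    """Mean per-epoch delta power over all NREM epochs (baseline helper)."""
    band = band or BandDefinition(*DELTA_BAND)
    feats = epoch_features(recording, hypnogram.epoch_length_s, bands=[band])
    n = min(len(feats), hypnogram.n_epochs)
    sel = hypnogram.labels[:n] == "NREM"
    if not sel.any():
        raise ValueError("no NREM epochs in baseline recording")
    return float(feats[f"{band.name}_power"].to_numpy()[:n][sel].mean())
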