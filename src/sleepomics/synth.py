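"""Synthetic-data generators with ground truth for every pipeline stage.

Each generator is a pure function of its spec (seed included), producing
data with exactly the statistical structure the downstream estimators
assume:

* Markov-chain hypnograms over WAKE/NREM/REM,
* EEG/EMG with state-dependent spectral content and muscle tone,
* two-channel fiber photometry in which the 465 nm signal is an affine
  function of the 405 nm isosbestic channel (shared bleaching and motion)
  plus a multiplicative norepinephrine (NE) component -- an infraslow
  (~0.02 Hz) sinusoid during NREM and a raised plateau in WAKE,
* LFQ log2-intensity matrices with injected group effects and
  intensity-dependent (MNAR) missingness,
* binary particle images with known component areas, and vessel line
  profiles with known peak/background structure.

Ground truth (state labels, NE component, regulated flags, true areas)
is returned alongside so parameter recovery can be tested offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .imaging import VesselProfile
from .proteomics import LFQMatrix
from .sleep import Hypnogram, Recording, STATES

# ---------------------------------------------------------------------------
# specs


@dataclass
class HypnogramSpec:
    """Markov-chain hypnogram: 3x3 row-stochastic per-epoch transitions."""

    epoch_length_s: float = 5.0
    total_duration_s: float = 172800.0  # 48 h recording
    transition_matrix: Sequence[Sequence[float]] = (
        # rows/cols ordered WAKE, NREM, REM; dwell-heavy defaults give
        # realistic mouse bout lengths at 5 s epochs
        (0.95, 0.05, 0.00),
        (0.03, 0.95, 0.02),
        (0.05, 0.05, 0.90),
    )
    initial_state: str = "WAKE"
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.shape != (3, 3) or np.any(P < 0):
            raise ValueError("transition_matrix must be 3x3 non-negative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition_matrix rows must sum to 1 (within 1e-9)")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")
        n = self.total_duration_s / self.epoch_length_s
        if self.total_duration_s <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                "total_duration_s must be a positive multiple of epoch_length_s"
            )
        if self.initial_state not in STATES:
            raise ValueError(f"initial_state must be one of {STATES}")
        self.transition_matrix = P

    @property
    def n_epochs(self) -> int:
        return int(round(self.total_duration_s / self.epoch_length_s))


@dataclass
class PhotometrySpec:
    """Two-channel photometry with shared bleach/motion and gated NE."""

    sample_rate_hz: float = 1000.0
    bleach_tau_s: float = 2000.0
    osc_freq_hz: float = 0.02
    osc_amp_pct: float = 2.0
    wake_level_pct: float = 3.0
    motion_amp: float = 0.02
    noise_sd: float = 0.002
    true_gain_a: float = 2.0
    true_offset_b: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.osc_freq_hz >= self.sample_rate_hz / 2:
            raise ValueError("osc_freq_hz must be below the Nyquist frequency")
        if self.osc_amp_pct < 0:
            raise ValueError("osc_amp_pct must be >= 0")
        if self.bleach_tau_s <= 0:
            raise ValueError("bleach_tau_s must be positive")


@dataclass
class LFQSimSpec:
    """LFQ matrix with group effects and intensity-dependent missingness."""

    n_proteins: int = 1000
    groups: Sequence[tuple[str, int]] = (("control", 6), ("treated", 6))
    base_mean_log2: float = 25.0
    base_sd_log2: float = 2.0
    noise_sd_log2: float = 0.5
    effect_log2fc: float = 2.0
    frac_regulated: float = 0.1
    mnar_slope: float = 1.0
    mnar_midpoint_log2: float = 22.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for label, n in self.groups:
            if n < 1:
                raise ValueError(f"group {label!r} must have >= 1 samples")
        if not (0 <= self.frac_regulated <= 1):
            raise ValueError("frac_regulated must be in [0, 1]")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be positive")


@dataclass
class ImageSimSpec:
    """Binary particle image and Gaussian vessel line profiles."""

    shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.0
    particle_areas_um2: Sequence[float] = (50.0, 20.0, 3.0)
    vessel_profiles: Sequence[tuple[float, float, float]] = (
        # (peak_height, background_level, peak_position_um)
        (100.0, 20.0, 10.0),
    )
    profile_sigma_um: float = 1.2
    profile_step_um: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if any(a <= 0 for a in self.particle_areas_um2):
            raise ValueError("particle areas must be positive")
        for peak, bg, pos in self.vessel_profiles:
            if peak < bg:
                raise ValueError("peak_height must be >= background_level")
            if pos < 0:
                raise ValueError("peak_position_um must be >= 0")


# ---------------------------------------------------------------------------
# hypnogram


def gen_hypnogram(spec: HypnogramSpec) -> Hypnogram:
    """Markov-chain label sequence; deterministic given the spec seed."""
    rng = np.random.default_rng(spec.seed)
    P = np.asarray(spec.transition_matrix)
    cum = np.cumsum(P, axis=1)
    state = STATES.index(spec.initial_state)
    u = rng.random(spec.n_epochs)
    labels = np.empty(spec.n_epochs, dtype=object)
    for i in range(spec.n_epochs):
        labels[i] = STATES[state]
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, 2)
    return Hypnogram(labels=labels, epoch_length_s=spec.epoch_length_s)


def markov_stationary(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    P = np.asarray(transition_matrix, dtype=float)
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# EEG / EMG

#: (delta weight, theta weight, broadband weight, EMG amplitude) per state.
_EEG_STATE_WEIGHTS = {
    "WAKE": (0.3, 0.3, 1.0, 1.0),
    "NREM": (3.0, 0.3, 0.2, 0.05),
    "REM": (0.3, 2.0, 0.2, 0.05),
}


def gen_eeg_emg(
    hypnogram: Hypnogram,
    sample_rate_hz: float = 512.0,
    seed: int = 0,
    emg_wake_rms: float = 1.0,
    emg_sleep_rms: float = 0.05,
) -> Recording:
    """EEG/EMG with state-gated spectral content and muscle tone.

    The EEG is a per-state weighted mix of three unit-variance noise
    components: band-limited delta (1-4 Hz), band-limited theta (4-8 Hz)
    and broadband noise.  NREM is delta-dominant and high amplitude, REM is
    theta-dominant, WAKE is broadband low amplitude.  EMG is white noise
    whose RMS is high in WAKE and near the floor in sleep states.
    """
    if sample_rate_hz < 200:
        raise ValueError("sample_rate_hz must be >= 200 for EEG band content")
    rng = np.random.default_rng(seed)
    spe = int(round(hypnogram.epoch_length_s * sample_rate_hz))
    n = spe * hypnogram.n_epochs
    if n == 0:
        raise ValueError("empty hypnogram")

    def _band_noise(lo: float, hi: float) -> np.ndarray:
        sos = signal.butter(4, [lo, hi], btype="band", fs=sample_rate_hz, output="sos")
        x = signal.sosfiltfilt(sos, rng.standard_normal(n))
        return x / x.std()

    delta = _band_noise(1.0, 4.0)
    theta = _band_noise(4.0, 8.0)
    broad = rng.standard_normal(n)
    emg_noise = rng.standard_normal(n)

    weights = {
        s: _EEG_STATE_WEIGHTS[s][:3] for s in STATES
    }
    emg_amp = {"WAKE": emg_wake_rms, "NREM": emg_sleep_rms, "REM": emg_sleep_rms}
    per_sample = np.repeat(hypnogram.labels, spe)
    wd = np.array([weights[s][0] for s in per_sample])
    wt = np.array([weights[s][1] for s in per_sample])
    wb = np.array([weights[s][2] for s in per_sample])
    we = np.array([emg_amp[s] for s in per_sample])
    eeg = wd * delta + wt * theta + wb * broad
    emg = we * emg_noise
    return Recording(
        channels={"eeg": eeg, "emg": emg}, sample_rate_hz=sample_rate_hz
    )


# ---------------------------------------------------------------------------
# photometry


def gen_photometry(
    hypnogram: Hypnogram, spec: PhotometrySpec
) -> tuple[Recording, pd.DataFrame]:
    """Two-channel photometry plus the noiseless NE ground truth.

    The isosbestic channel is ``f405 = bleach + motion + noise``; the signal
    channel is ``f465 = (a*f405_clean + b) * (1 + ne_pct/100) + noise`` where
    ``f405_clean`` carries the same bleach and motion (shared, pre-gain, so
    isosbestic correction can remove them exactly) and ``ne_pct`` is the NE
    component in %dF/F: ``osc_amp_pct * sin(2*pi*osc_freq*t)`` during NREM,
    a ``wake_level_pct`` plateau in WAKE, zero in REM.

    Returns the recording (channels ``f465``, ``f405``) and a truth table
    with per-sample ``time_s``, ``state``, ``ne_pct``, plus the coupling
    coefficients in ``truth.attrs`` (``gain_a``, ``offset_b``).
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate_hz
    n = int(round(hypnogram.duration_s * fs))
    if n == 0:
        raise ValueError("empty hypnogram")
    t = np.arange(n) / fs
    bleach = np.exp(-t / spec.bleach_tau_s)
    if spec.motion_amp > 0:
        sos = signal.butter(2, min(0.5, fs / 4), btype="low", fs=fs, output="sos")
        motion = signal.sosfiltfilt(sos, rng.standard_normal(n))
        motion = spec.motion_amp * motion / max(motion.std(), 1e-12)
    else:
        motion = np.zeros(n)
    base = bleach + motion

    spe = int(round(hypnogram.epoch_length_s * fs))
    per_sample = np.repeat(hypnogram.labels, spe)[:n]
    ne_pct = np.zeros(n)
    nrem = per_sample == "NREM"
    wake = per_sample == "WAKE"
    ne_pct[nrem] = spec.osc_amp_pct * np.sin(2 * np.pi * spec.osc_freq_hz * t[nrem])
    ne_pct[wake] = spec.wake_level_pct

    f405 = base + rng.normal(0, spec.noise_sd, n)
    scaled = spec.true_gain_a * base + spec.true_offset_b
    f465 = scaled * (1 + ne_pct / 100) + rng.normal(0, spec.noise_sd, n)
    rec = Recording(channels={"f465": f465, "f405": f405}, sample_rate_hz=fs)
    truth = pd.DataFrame({"time_s": t, "state": per_sample, "ne_pct": ne_pct})
    truth.attrs["gain_a"] = spec.true_gain_a
    truth.attrs["offset_b"] = spec.true_offset_b
    return rec, truth


# ---------------------------------------------------------------------------
# LFQ


def gen_lfq_matrix(spec: LFQSimSpec) -> tuple[LFQMatrix, pd.DataFrame]:
    """Simulated LFQ matrix with MNAR dropout and a ground-truth table.

    Per-protein baselines are drawn from Normal(``base_mean_log2``,
    ``base_sd_log2``); replicate values add Normal(0, ``noise_sd_log2``)
    noise and, for the regulated fraction, a ``+-effect_log2fc`` shift of
    the second group (random sign).  Each cell then goes missing with
    probability ``logistic(mnar_slope * (mnar_midpoint_log2 - intensity))``,
    making low-abundance values preferentially undetected.
    """
    rng = np.random.default_rng(spec.seed)
    labels: list[str] = []
    groups: list[str] = []
    for gname, gn in spec.groups:
        for i in range(gn):
            labels.append(f"{gname}_{i + 1}")
            groups.append(gname)
    design = pd.Series(groups, index=labels, name="group")
    n_p, n_s = spec.n_proteins, len(labels)

    base = rng.normal(spec.base_mean_log2, spec.base_sd_log2, n_p)
    n_reg = int(round(spec.frac_regulated * n_p))
    regulated = np.zeros(n_p, dtype=bool)
    regulated[:n_reg] = True
    rng.shuffle(regulated)
    sign = np.where(rng.random(n_p) < 0.5, 1.0, -1.0)
    true_fc = np.where(regulated, sign * spec.effect_log2fc, 0.0)

    second_group = spec.groups[1][0] if len(spec.groups) > 1 else None
    in_second = np.array([g == second_group for g in groups])
    values = (
        base[:, None]
        + true_fc[:, None] * in_second[None, :]
        + rng.normal(0, spec.noise_sd_log2, (n_p, n_s))
    )

    if math.isinf(spec.mnar_midpoint_log2) and spec.mnar_midpoint_log2 < 0:
        p_missing = np.zeros_like(values)
    else:
        z = spec.mnar_slope * (spec.mnar_midpoint_log2 - values)
        p_missing = 1.0 / (1.0 + np.exp(-z))
    drop = rng.random((n_p, n_s)) < p_missing
    observed = np.where(drop, np.nan, values)

    protein_ids = [f"P{i + 1:05d}" for i in range(n_p)]
    matrix = LFQMatrix(
        values=pd.DataFrame(observed, index=protein_ids, columns=labels),
        design=design,
    )
    truth = pd.DataFrame(
        {
            "regulated": regulated,
            "true_log2fc": true_fc,
            "base_log2": base,
        },
        index=pd.Index(protein_ids, name="protein"),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# images & profiles


def _blob_mask(n_px: int) -> np.ndarray:
    """Compact blob of exactly ``n_px`` pixels (near-square block)."""
    w = math.ceil(math.sqrt(n_px))
    h = n_px // w
    rem = n_px - h * w
    rows = h + (1 if rem else 0)
    m = np.zeros((rows, w), dtype=bool)
    m[:h, :] = True
    if rem:
        m[h, :rem] = True
    return m


def gen_particle_image(spec: ImageSimSpec) -> tuple[np.ndarray, list[float]]:
    """Binary image whose connected components have the requested areas.

    Particles are placed on a jittered grid with a 2-pixel margin so no two
    touch, even diagonally.  Returns the boolean image and the realized
    areas in um^2 (pixel counts x pixel_size^2; equal to the requested areas
    within one pixel-area of quantization).
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape_px
    img = np.zeros((rows, cols), dtype=bool)
    masks = []
    for area in spec.particle_areas_um2:
        n_px = max(1, int(round(area / spec.pixel_size_um**2)))
        masks.append(_blob_mask(n_px))
    if not masks:
        return img, []
    cell_h = max(m.shape[0] for m in masks) + 2
    cell_w = max(m.shape[1] for m in masks) + 2
    slots = [
        (r, c)
        for r in range(1, rows - cell_h, cell_h)
        for c in range(1, cols - cell_w, cell_w)
    ]
    if len(slots) < len(masks):
        raise ValueError(
            f"cannot place {len(masks)} particles of this size in {spec.shape_px}"
        )
    order = rng.permutation(len(slots))[: len(masks)]
    realized = []
    for m, k in zip(masks, order):
        r, c = slots[k]
        img[r : r + m.shape[0], c : c + m.shape[1]] |= m
        realized.append(int(m.sum()) * spec.pixel_size_um**2)
    return img, realized


def gen_vessel_profiles(
    spec: ImageSimSpec,
) -> tuple[list[VesselProfile], list[float]]:
    """Gaussian vessel-wall bumps on flat background, with truth indices.

    Each profile is ``bg + (peak - bg) * exp(-(x - pos)^2 / (2*sigma^2))``
    sampled every ``profile_step_um``.  The truth value per vessel is the
    analytic background-corrected peak: ``(peak - bg) * (1 -
    exp(-offset^2 / (2*sigma^2)))`` at the 5 um background offset.
    """
    profiles, truths = [], []
    sig = spec.profile_sigma_um
    for peak, bg, pos in spec.vessel_profiles:
        extent = pos + max(10.0, 3 * sig)
        x = np.arange(0.0, extent + spec.profile_step_um / 2, spec.profile_step_um)
        y = bg + (peak - bg) * np.exp(-((x - pos) ** 2) / (2 * sig**2))
        profiles.append(VesselProfile(positions_um=x, intensity=y))
        tail = math.exp(-(5.0**2) / (2 * sig**2))
        truths.append((peak - bg) * (1.0 - tail))
    return profiles, truths
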