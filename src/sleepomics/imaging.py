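"""Histology quantification: microglial morphometry and AQP4 polarization.

Two measurements on maximum-projection immunofluorescence images:

* size-binned particle analysis of binarized microglial (Iba1) images --
  connected components of 30-90 um^2 count as cell somata, 5-30 um^2 as
  ramifications, below 5 um^2 are excluded;
* the aquaporin-4 (AQP4) vascular polarization index -- per vessel line
  profile, the wall peak intensity minus the perivascular background read
  5 um away from the peak, averaged per image and normalized to the cohort
  maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import filters, measure


@dataclass
class BinaryImage:
    """2-D boolean pixel grid with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.pixels = px.astype(bool)

    @property
    def area_mm2(self) -> float:
        return self.pixels.size * (self.pixel_size_um / 1000.0) ** 2


@dataclass
class ParticleSummary:
    """Binned particle counts and densities for one image."""

    n_cells: int
    n_ramifications: int
    n_excluded: int
    n_oversize: int
    cells_per_mm2: float
    ramifications_per_cell: float
    areas_um2: np.ndarray

    @property
    def n_total(self) -> int:
        return self.n_cells + self.n_ramifications + self.n_excluded + self.n_oversize


@dataclass
class VesselProfile:
    """Fluorescence intensity along a line drawn across a blood vessel."""

    positions_um: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.positions_um, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if x.shape != y.shape or x.ndim != 1 or x.size < 2:
            raise ValueError("positions and intensity must be equal-length 1-D")
        if np.any(np.diff(x) <= 0):
            raise ValueError("positions_um must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("intensity must be non-negative")
        self.positions_um, self.intensity = x, y

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.intensity))


@dataclass
class PolarizationResult:
    """Per-vessel corrected peaks, per-image indices, cohort-normalized."""

    per_vessel: pd.DataFrame
    per_image: pd.Series
    normalized: pd.Series


def binarize(
    image: np.ndarray, pixel_size_um: float, threshold: float | None = None
) -> BinaryImage:
    """Fixed-threshold (or Otsu, when ``threshold`` is None) binarization."""
    image = np.asarray(image, dtype=float)
    if threshold is None:
        threshold = filters.threshold_otsu(image)
    return BinaryImage(pixels=image > threshold, pixel_size_um=pixel_size_um)


def particle_analysis(
    image: BinaryImage,
    cell_bin_um2: tuple[float, float] = (30.0, 90.0),
    ramification_bin_um2: tuple[float, float] = (5.0, 30.0),
    min_area_um2: float = 5.0,
    connectivity: int = 8,
) -> ParticleSummary:
    """Size-binned connected-component analysis of a binary image.

    Components are labeled with 8-connectivity (configurable to 4); the
    component area in um^2 is pixel count x pixel_size^2.  Bins follow
    [5, 30) for ramifications and [30, 90] for cells; areas below
    ``min_area_um2`` are excluded and areas above the cell bin are counted
    separately as oversize.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = measure.label(image.pixels, connectivity=2 if connectivity == 8 else 1)
    counts = np.bincount(labels.ravel())[1:]  # drop background
    areas = counts * image.pixel_size_um**2
    lo_r, hi_r = ramification_bin_um2
    lo_c, hi_c = cell_bin_um2
    n_excluded = int(np.sum(areas < min_area_um2))
    n_ram = int(np.sum((areas >= lo_r) & (areas < hi_r)))
    n_cells = int(np.sum((areas >= lo_c) & (areas <= hi_c)))
    n_oversize = int(np.sum(areas > hi_c))
    return ParticleSummary(
        n_cells=n_cells,
        n_ramifications=n_ram,
        n_excluded=n_excluded,
        n_oversize=n_oversize,
        cells_per_mm2=n_cells / image.area_mm2,
        ramifications_per_cell=(n_ram / n_cells) if n_cells else math.nan,
        areas_um2=np.sort(areas)[::-1],
    )


def _corrected_peak(
    profile: VesselProfile, background_offset_um: float
) -> float | None:
    """Peak intensity minus mean background at +-offset; None if too short."""
    x, y = profile.positions_um, profile.intensity
    ipk = profile.peak_index
    xpk = x[ipk]
    bg = []
    for sgn in (-1, 1):
        xq = xpk + sgn * background_offset_um
        if x[0] <= xq <= x[-1]:
            bg.append(float(np.interp(xq, x, y)))
    if not bg:
        return None
    return float(y[ipk]) - float(np.mean(bg))


def aqp4_polarization(
    profiles: Mapping[str, Sequence[VesselProfile]] | Sequence[VesselProfile],
    background_offset_um: float = 5.0,
) -> PolarizationResult:
    """AQP4 polarization index: corrected vessel peaks, cohort-normalized.

    Per vessel the corrected peak is the profile maximum minus the mean of
    the intensities exactly ``background_offset_um`` away on each side of
    the peak (linearly interpolated; one-sided when the profile ends
    sooner).  Per image the index is the mean over its vessels; the
    normalized index divides by the cohort maximum so exactly one image
    scores 1.  Vessels too short to read any background are skipped with a
    warning; an image losing all vessels is an error.
    """
    if not isinstance(profiles, Mapping):
        profiles = {"image": list(profiles)}
    rows = []
    for image_id, vessels in profiles.items():
        if not vessels:
            raise ValueError(f"image {image_id!r} has no vessel profiles")
        kept = 0
        for i, prof in enumerate(vessels):
            corrected = _corrected_peak(prof, background_offset_um)
            if corrected is None:
                warnings.warn(
                    f"image {image_id!r} vessel {i}: profile shorter than the "
                    f"{background_offset_um} um background offset; skipped",
                    stacklevel=2,
                )
                continue
            kept += 1
            rows.append(
                {"image": image_id, "vessel": i, "corrected_peak": corrected}
            )
        if kept == 0:
            raise ValueError(f"image {image_id!r}: all vessel profiles skipped")
    per_vessel = pd.DataFrame(rows)
    per_image = per_vessel.groupby("image")["corrected_peak"].mean()
    per_image.name = "polarization_index"
    cohort_max = per_image.max()
    if cohort_max <= 0:
        normalized = per_image * 0.0
    else:
        normalized = per_image / cohort_max
    normalized.name = "normalized_index"
    return PolarizationResult(
        per_vessel=per_vessel, per_image=per_image, normalized=normalized
    )
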