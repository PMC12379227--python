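"""Readers and writers for the pipeline's plain-text formats.

Canonical formats are TSV: recordings (``time_s`` plus one column per
channel), hypnograms (``epoch_index``, ``t_start_s``, ``label``), LFQ
matrices (proteins x samples, blank cell = missing) with a separate design
table (``sample``, ``group``), vessel line profiles (``vessel``,
``position_um``, ``intensity``), GMT gene sets, and TIFF/PNG images.
Writers can prepend ``# key=value`` provenance headers (seed, parameters);
readers skip ``#`` comment lines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import VesselProfile
from .proteomics import LFQMatrix
from .sleep import Hypnogram, Recording


def _write_with_header(
    df: pd.DataFrame, path: Path | str, header: Mapping[str, object] | None = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def _read_tsv(path: Path | str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_header(path: Path | str) -> dict[str, str]:
    """Parse leading ``# key=value`` comment lines of a TSV file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                out[k.strip()] = v.strip()
    return out


# -- recordings -------------------------------------------------------------


def write_recording(
    recording: Recording, path: Path | str, header: Mapping[str, object] | None = None
) -> None:
    t = np.arange(recording.n_samples) / recording.sample_rate_hz
    df = pd.DataFrame({"time_s": t, **recording.channels})
    hdr = {"sample_rate_hz": recording.sample_rate_hz, **(header or {})}
    _write_with_header(df, path, hdr)


def read_recording(path: Path | str) -> Recording:
    hdr = read_header(path)
    df = _read_tsv(path)
    if "time_s" not in df.columns:
        raise ValueError("recording TSV must have a time_s column")
    if "sample_rate_hz" in hdr:
        fs = float(hdr["sample_rate_hz"])
    else:
        dt = np.diff(df["time_s"].to_numpy())
        fs = 1.0 / float(np.median(dt))
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time_s"}
    return Recording(channels=channels, sample_rate_hz=fs)


def read_recording_edf(path: Path | str) -> Recording:
    """Read an EDF recording via :mod:`mne` (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    channels = {name.lower(): data[i] for i, name in enumerate(raw.ch_names)}
    return Recording(channels=channels, sample_rate_hz=float(raw.info["sfreq"]))


# -- hypnograms -------------------------------------------------------------


def write_hypnogram(
    hypnogram: Hypnogram, path: Path | str, header: Mapping[str, object] | None = None
) -> None:
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(hypnogram.n_epochs),
            "t_start_s": hypnogram.epoch_times(),
            "label": hypnogram.labels,
        }
    )
    hdr = {"epoch_length_s": hypnogram.epoch_length_s, **(header or {})}
    _write_with_header(df, path, hdr)


def read_hypnogram(path: Path | str) -> Hypnogram:
    hdr = read_header(path)
    df = _read_tsv(path)
    if "epoch_length_s" in hdr:
        epoch = float(hdr["epoch_length_s"])
    elif len(df) > 1:
        epoch = float(np.median(np.diff(df["t_start_s"].to_numpy())))
    else:
        raise ValueError("cannot infer epoch length from a single-epoch file")
    start = float(df["t_start_s"].iloc[0]) if "t_start_s" in df.columns else 0.0
    return Hypnogram(
        labels=df["label"].to_numpy(dtype=object),
        epoch_length_s=epoch,
        start_time_s=start,
    )


# -- LFQ matrices -----------------------------------------------------------


def write_lfq_matrix(
    matrix: LFQMatrix,
    matrix_path: Path | str,
    design_path: Path | str,
    header: Mapping[str, object] | None = None,
) -> None:
    _write_with_header(
        matrix.values.rename_axis("protein").reset_index(), matrix_path, header
    )
    design = matrix.design.rename_axis("sample").reset_index()
    _write_with_header(design, design_path, header)


def read_lfq_matrix(matrix_path: Path | str, design_path: Path | str) -> LFQMatrix:
    values = _read_tsv(matrix_path, index_col="protein")
    design_df = _read_tsv(design_path)
    design = pd.Series(
        design_df["group"].to_numpy(), index=design_df["sample"], name="group"
    )
    return LFQMatrix(values=values, design=design)


# -- vessel profiles --------------------------------------------------------


def write_profiles(
    profiles: Sequence[VesselProfile],
    path: Path | str,
    header: Mapping[str, object] | None = None,
) -> None:
    frames = [
        pd.DataFrame(
            {"vessel": i, "position_um": p.positions_um, "intensity": p.intensity}
        )
        for i, p in enumerate(profiles)
    ]
    _write_with_header(pd.concat(frames, ignore_index=True), path, header)


def read_profiles(path: Path | str) -> list[VesselProfile]:
    df = _read_tsv(path)
    out = []
    for _, grp in df.groupby("vessel", sort=True):
        out.append(
            VesselProfile(
                positions_um=grp["position_um"].to_numpy(dtype=float),
                intensity=grp["intensity"].to_numpy(dtype=float),
            )
        )
    return out


# -- gene sets --------------------------------------------------------------


def read_gmt(path: Path | str) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> member...; one per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: Path | str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, name, *sorted(members)]) + "\n")


# -- images -----------------------------------------------------------------


def write_image(image: np.ndarray, path: Path | str) -> None:
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image).astype(np.uint8) * (
        255 if np.asarray(image).dtype == bool else 1
    ))


def read_image(path: Path | str) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    from PIL import Image

    return np.asarray(Image.open(path))
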