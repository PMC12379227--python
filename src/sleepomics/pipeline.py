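"""End-to-end orchestration: configured runs, demo mode, provenance.

A :class:`RunConfig` bundles input paths and per-stage parameter blocks
(YAML on disk).  ``run_photometry_session`` executes dF/F -> NREM PSD ->
peak detection -> oscillation metrics; ``run_proteomics`` executes sample
QC -> completeness filter -> mixed imputation -> permutation t-test ->
enrichment.  ``run_demo`` regenerates synthetic fixtures for every module
and runs the full chain.  Every output file carries a ``# key=value``
provenance header (package version, seed, config hash), so reruns with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, imaging, io, photometry, proteomics, sleep, synth

logger = logging.getLogger("sleepomics")


@dataclass
class RunConfig:
    """Input paths plus per-stage parameter blocks for one pipeline run."""

    recording: str | None = None
    hypnogram: str | None = None
    matrix: str | None = None
    design: str | None = None
    gene_sets: str | None = None
    out_dir: str = "sleepomics_out"
    seed: int = 0
    sleep_params: dict = field(default_factory=dict)
    photometry_params: dict = field(default_factory=dict)
    proteomics_params: dict = field(default_factory=dict)
    imaging_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"config is missing required input {name!r}")
            if not Path(value).exists():
                raise ValueError(f"{name} path does not exist: {value}")

    def hash(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header(self) -> dict:
        return {
            "sleepomics_version": __version__,
            "seed": self.seed,
            "config_hash": self.hash(),
        }


def _write_json(obj: dict, path: Path, header: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"provenance": header, **obj}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def run_photometry_session(config: RunConfig) -> dict:
    """dF/F -> NREM PSD -> NE peaks -> metrics, with artifacts on disk."""
    config.validate_paths("recording", "hypnogram")
    out = Path(config.out_dir)
    hdr = config.header()
    params = dict(config.photometry_params)
    stage = "load"
    try:
        rec = io.read_recording(config.recording)
        hyp = io.read_hypnogram(config.hypnogram)
        stage = "dff"
        dff = photometry.compute_dff(
            rec["f465"],
            rec.channels.get("f405"),
            rec.sample_rate_hz,
            method=params.pop("method", "fitted_405"),
        )
        io._write_with_header(
            pd.DataFrame(
                {
                    "time_s": np.arange(len(dff.values)) / dff.sample_rate_hz,
                    "dff_pct": dff.values,
                }
            ),
            out / "dff.tsv",
            hdr,
        )
        stage = "nrem_psd"
        psd_kwargs = {
            k: params[k]
            for k in ("min_bout_s", "welch_window_s", "overlap_frac", "poly_order")
            if k in params
        }
        avg, per_bout = photometry.nrem_psd(dff, hyp, **psd_kwargs)
        io._write_with_header(
            pd.DataFrame({"freq_hz": avg.freqs_hz, "power": avg.power}),
            out / "psd_nrem.tsv",
            hdr,
        )
        stage = "peaks"
        peak_kwargs = {
            k: params[k]
            for k in ("min_interval_s", "min_amplitude_pct", "lowpass_hz")
            if k in params
        }
        times, heights, rate = photometry.detect_ne_peaks(dff, hyp, **peak_kwargs)
        io._write_with_header(
            pd.DataFrame({"time_s": times, "height_pct": heights}),
            out / "peaks.tsv",
            hdr,
        )
        stage = "metrics"
        metrics = photometry.ne_metrics(dff, hyp, **psd_kwargs, **peak_kwargs)
        result = dataclasses.asdict(metrics)
        _write_json(result, out / "ne_metrics.json", hdr)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    logger.info("photometry session complete: %d bouts, %d peaks",
                metrics.n_bouts_used, metrics.n_peaks)
    return result


def run_proteomics(config: RunConfig) -> dict:
    """Sample QC -> completeness filter -> imputation -> DE -> enrichment."""
    config.validate_paths("matrix", "design")
    out = Path(config.out_dir)
    hdr = config.header()
    p = dict(config.proteomics_params)
    stage = "load"
    try:
        matrix = io.read_lfq_matrix(config.matrix, config.design)
        orphans = [s for s in matrix.values.columns if s not in matrix.design.index]
        if orphans:
            raise ValueError(f"design references absent samples: {orphans}")
        stage = "sample_qc"
        matrix = proteomics.filter_sample_qc(
            matrix, p.get("min_fraction_of_median", 0.5)
        )
        stage = "completeness_filter"
        matrix = proteomics.filter_group_completeness(
            matrix, p.get("min_fraction", 0.7)
        )
        stage = "imputation"
        matrix = proteomics.impute_mixed(
            matrix,
            width=p.get("width", 0.3),
            downshift_sd=p.get("downshift_sd", 1.8),
            knn_cutoff=p.get("knn_cutoff", 0.6),
            k_neighbors=p.get("k_neighbors", 3),
            seed=config.seed,
        )
        io.write_lfq_matrix(
            matrix, out / "imputed_matrix.tsv", out / "design.tsv", hdr
        )
        stage = "permutation_ttest"
        de = proteomics.permutation_ttest(
            matrix,
            s0=p.get("s0", 0.5),
            n_permutations=p.get("n_permutations", 250),
            fdr_threshold=p.get("fdr_threshold", 0.05),
            seed=config.seed,
        )
        io._write_with_header(de.reset_index(), out / "de_table.tsv", hdr)
        result = {
            "n_proteins_tested": int(len(de)),
            "n_significant": int(de["significant"].sum()),
        }
        stage = "enrichment"
        if config.gene_sets:
            sets = io.read_gmt(config.gene_sets)
            hits = set(de.index[de["significant"]])
            if hits:
                enr = proteomics.fisher_enrichment(hits, set(de.index), sets)
                io._write_with_header(enr.table, out / "enrichment.tsv", hdr)
                result["n_enriched_sets"] = int(enr.table["significant"].sum())
        _write_json(result, out / "proteomics_summary.json", hdr)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    logger.info("proteomics run complete: %s", result)
    return result


def run_demo(out_dir: str | Path, seed: int = 7) -> dict:
    """Regenerate synthetic fixtures for every module and run the chain."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    summary: dict = {"seed": seed}

    # -- sleep: hypnogram, EEG/EMG, scoring, architecture ------------------
    hspec = synth.HypnogramSpec(
        epoch_length_s=5.0, total_duration_s=3600.0, seed=int(rng.integers(2**31))
    )
    truth_hyp = synth.gen_hypnogram(hspec)
    rec = synth.gen_eeg_emg(truth_hyp, 256.0, seed=int(rng.integers(2**31)))
    io.write_recording(rec, out / "eeg_emg.tsv", {"seed": seed})
    io.write_hypnogram(truth_hyp, out / "hypnogram_truth.tsv", {"seed": seed})
    feats = sleep.epoch_features(rec, hspec.epoch_length_s)
    scored = sleep.score_epochs(feats, epoch_length_s=hspec.epoch_length_s)
    io.write_hypnogram(scored, out / "hypnogram_scored.tsv", {"seed": seed})
    summary["scoring_accuracy"] = float(np.mean(scored.labels == truth_hyp.labels))
    arch = sleep.architecture_stats(scored)
    io._write_with_header(
        arch.to_frame().reset_index(names="state"),
        out / "architecture.tsv",
        {"seed": seed},
    )
    summary["percent_time"] = arch.percent_time

    # -- photometry session ------------------------------------------------
    labels = np.array(
        ["WAKE"] * 12 + ["NREM"] * 480 + ["WAKE"] * 12, dtype=object
    )
    phyp = sleep.Hypnogram(labels=labels, epoch_length_s=5.0)
    pspec = synth.PhotometrySpec(
        sample_rate_hz=50.0, seed=int(rng.integers(2**31))
    )
    prec, _ = synth.gen_photometry(phyp, pspec)
    io.write_recording(prec, out / "photometry.tsv", {"seed": seed})
    io.write_hypnogram(phyp, out / "photometry_hypnogram.tsv", {"seed": seed})
    cfg = RunConfig(
        recording=str(out / "photometry.tsv"),
        hypnogram=str(out / "photometry_hypnogram.tsv"),
        out_dir=str(out / "photometry_session"),
        seed=seed,
    )
    summary["ne_metrics"] = run_photometry_session(cfg)

    # -- proteomics --------------------------------------------------------
    lspec = synth.LFQSimSpec(
        n_proteins=400, seed=int(rng.integers(2**31))
    )
    matrix, truth = synth.gen_lfq_matrix(lspec)
    io.write_lfq_matrix(
        matrix, out / "lfq_matrix.tsv", out / "lfq_design.tsv", {"seed": seed}
    )
    io._write_with_header(
        truth.reset_index(), out / "lfq_truth.tsv", {"seed": seed}
    )
    regulated = list(truth.index[truth["regulated"]])
    null_pool = list(truth.index[~truth["regulated"]])
    sets = {
        "REGULATED_SET": regulated[: max(5, len(regulated) // 2)],
        "RANDOM_SET": null_pool[:40],
    }
    io.write_gmt(sets, out / "gene_sets.gmt")
    pcfg = RunConfig(
        matrix=str(out / "lfq_matrix.tsv"),
        design=str(out / "lfq_design.tsv"),
        gene_sets=str(out / "gene_sets.gmt"),
        out_dir=str(out / "proteomics_run"),
        seed=seed,
    )
    summary["proteomics"] = run_proteomics(pcfg)

    # -- imaging -----------------------------------------------------------
    ispec = synth.ImageSimSpec(
        shape_px=(256, 256),
        particle_areas_um2=(50.0, 45.0, 20.0, 12.0, 3.0),
        seed=int(rng.integers(2**31)),
    )
    img, areas = synth.gen_particle_image(ispec)
    io.write_image(img, out / "particles.tif")
    summary_img = imaging.particle_analysis(
        imaging.BinaryImage(pixels=img, pixel_size_um=ispec.pixel_size_um)
    )
    summary["imaging"] = {
        "n_cells": summary_img.n_cells,
        "n_ramifications": summary_img.n_ramifications,
        "n_excluded": summary_img.n_excluded,
    }
    profiles, truths = synth.gen_vessel_profiles(ispec)
    io.write_profiles(profiles, out / "vessel_profiles.tsv", {"seed": seed})
    pol = imaging.aqp4_polarization(profiles)
    summary["aqp4_index"] = float(pol.per_image.iloc[0])

    _write_json(
        summary,
        out / "demo_summary.json",
        {"sleepomics_version": __version__, "seed": seed},
    )
    return summary
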