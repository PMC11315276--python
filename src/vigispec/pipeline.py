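"""End-to-end pipeline: filter → reject → score → state PSD → fit → stats.

``run_pipeline`` consumes a directory of recordings (EDF files and/or the
raw fixture format), applies the preprocessing, scoring and spectral
parameterization stages per subject, pools channel fits to one exponent
per subject × state, and — when the cohort has at least two groups —
runs the masking analysis.  All outputs are plain CSV/JSON; reruns with
the same inputs, config and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .edf import load_recording
from .preprocess import bandpass_filter, reject_artifacts
from .score import score_recording, state_proportions
from .spectral import fit_spectral_model, state_psd, subject_state_exponents
from .stats import masking_analysis

__all__ = ["run_pipeline", "process_recording"]

log = logging.getLogger("vigispec")


def process_recording(recording, config: PipelineConfig) -> dict:
    """Run the single-subject stages and return hypnogram, mask and fits."""
    if config.species_mode == "human":
        keep = int(min(recording.duration_s, config.human_truncate_s) * recording.fs)
        for ch in recording.channels:
            ch.data = ch.data[:keep]
    filtered = bandpass_filter(
        recording, config.filter_low_hz, config.filter_high_hz, config.filter_order
    )
    mask = reject_artifacts(filtered, config.artifact_sd)
    hyp = score_recording(filtered, mask, config.species_mode)
    fit_rows = []
    spectra = []
    states = sorted(set(hyp.labels.astype(str)) - {"noise"})
    for state in states:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            specs = state_psd(filtered, hyp, state, config.min_state_epochs,
                              config.psd_fmin, config.psd_fmax)
        for spec in specs:
            fit = fit_spectral_model(spec, config.max_peaks,
                                     config.peak_threshold_sd,
                                     config.peak_width_limits)
            spectra.append(spec)
            fit_rows.append({
                "subject": recording.subject, "group": recording.group,
                "sex": recording.sex, "state": state, "channel": spec.channel,
                "offset": fit.offset, "exponent": fit.exponent,
                "r2": fit.r_squared, "mae": fit.mae, "n_peaks": fit.n_peaks,
                "n_epochs": spec.n_epochs,
            })
    return {"mask": mask, "hypnogram": hyp, "fits": pd.DataFrame(fit_rows),
            "spectra": spectra}


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, input_dir: str | Path,
                 out_dir: str | Path) -> dict:
    """Process every recording under ``input_dir`` and write results.

    Per subject: hypnogram CSV, artifact-mask CSV, per-state spectra CSV
    and a fits CSV.  Cohort level: pooled subject × state exponent table,
    state-proportion summary and (for ≥ 2 groups) the masking report.
    A subject whose stage fails is logged and skipped; if every subject
    fails (or the input directory is empty) a ``RuntimeError`` is raised.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("vigispec %s  config=%s  seed=%d",
                 __version__, _config_hash(config), config.seed)
        paths = sorted(input_dir.glob("*.edf")) + sorted(
            p for p in input_dir.glob("*.json") if p.with_suffix(".bin").exists()
        )
        if not paths:
            raise RuntimeError(f"no recordings found in {input_dir}")
        all_fits, hyps, failures = [], [], 0
        for path in paths:
            try:
                rec = load_recording(path)
                res = process_recording(rec, config)
            except Exception as exc:  # noqa: BLE001 - subject-level isolation
                log.error("subject file %s failed: %s", path.name, exc)
                failures += 1
                continue
            stem = out_dir / rec.subject
            res["hypnogram"].to_frame().to_csv(f"{stem}_hypnogram.csv", index=False)
            pd.DataFrame({
                "epoch": range(res["mask"].n_epochs),
                "flag": res["mask"].epoch_flags.astype(int),
            }).to_csv(f"{stem}_mask.csv", index=False)
            for spec in res["spectra"]:
                spec.to_frame().to_csv(
                    f"{stem}_{spec.state}_{spec.channel}_psd.csv", index=False)
            res["fits"].to_csv(f"{stem}_fits.csv", index=False)
            all_fits.append(res["fits"])
            hyps.append(res["hypnogram"])
            log.info("subject %s: %d epochs, %d fits",
                     rec.subject, res["hypnogram"].n_epochs, len(res["fits"]))
        if not all_fits:
            raise RuntimeError("all subjects failed")

        fits = pd.concat(all_fits, ignore_index=True)
        fits.to_csv(out_dir / "fits_all_channels.csv", index=False)
        pooled = subject_state_exponents(fits)
        pooled.to_csv(out_dir / "subject_state_exponents.csv", index=False)
        state_proportions(hyps).to_csv(out_dir / "state_proportions.csv")

        report = {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "n_subjects": len(all_fits),
            "n_failed": failures,
        }
        if pooled["group"].nunique() >= 2 and pooled["state"].nunique() >= 2:
            res = masking_analysis(pooled, n_boot=config.n_boot,
                                   alpha=config.alpha, seed=config.seed)
            res.to_json(out_dir / "masking_report.json")
            with open(out_dir / "masking_report.txt", "w") as fh:
                fh.write(res.summary() + "\n")
            report["masking_demonstrated"] = res.masking_demonstrated
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
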