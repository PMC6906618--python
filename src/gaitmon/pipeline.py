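"""End-to-end processing: raw files in, derived delimited tables out.

Stages run in order io -> detect -> param -> bouts -> weartime -> dailies
-> epochs -> threshold -> clinical; every output file is listed in a
manifest with a content hash, so re-running with identical inputs and
config reproduces identical derived outputs.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import bouts as bouts_mod
from . import clinical, compliance, weartime
from .config import PipelineConfig
from .detect import analyze_recording
from .gait import load_default_model, load_model, parameterize_windows
from .io import merge_recordings, read_accel_hdf5, read_assessments

__all__ = ["run_pipeline", "process_subject"]

log = logging.getLogger("gaitmon")


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def process_subject(period, model, cfg: PipelineConfig):
    """Windows -> gait parameters -> bouts -> wear -> dailies for one subject.

    Bout times are converted to absolute timestamps via each recording's
    start time; returns ``(bouts_with_abs_times, wear_intervals, dailies)``
    where bouts are ``(bout, start_timestamp)`` pairs.
    """
    all_bouts = []
    t0 = period.start_time
    for rec in period.recordings:
        windows, filtered = analyze_recording(rec, cfg.plausibility)
        gws = parameterize_windows(rec, windows, filtered, cfg.plausibility, model=model)
        bts, _ = bouts_mod.segment_bouts(
            gws,
            merge_factor=cfg.bouts.merge_factor,
            max_gap_s=cfg.bouts.max_gap_s,
            min_steps=cfg.bouts.min_steps,
            running_mean=cfg.bouts.running_mean,
        )
        offset = (rec.start_time - t0).total_seconds()
        for b in bts:
            b.start_time_s += offset
            b.end_time_s += offset
        all_bouts.extend(bts)
    bouts_mod.bin_bouts(all_bouts, cfg.bouts.bin_edges)
    wear = weartime.detect_weartime(period, cfg.weartime)
    dailies = weartime.daily_summaries(
        period, all_bouts, wear, tz_offset_hours=cfg.tz_offset_hours
    )
    return all_bouts, wear, dailies


def run_pipeline(cfg: PipelineConfig, input_dir, output_dir) -> dict:
    """Process a canonical-format input directory and write derived tables.

    Expects per-subject HDF5 recordings (``<subject>_*.h5``) and an
    ``assessments.csv`` table.  Writes bout, daily, epoch, exclusion,
    assessment-speed, agreement and validity-pair tables plus the echoed
    config and a manifest of output hashes.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    model = load_model(cfg.model_path) if cfg.model_path else load_default_model()

    h5s = sorted(input_dir.glob("*.h5"))
    if not h5s:
        raise FileNotFoundError(f"no .h5 recordings in {input_dir}")
    by_subject: dict[str, list] = {}
    for p in h5s:
        rec = read_accel_hdf5(p)
        by_subject.setdefault(rec.subject_id, []).append(rec)

    assessments_path = input_dir / "assessments.csv"
    assessments = read_assessments(assessments_path) if assessments_path.exists() else []

    bout_frames, daily_frames, epoch_frames, excl_frames = [], [], [], []
    speed_rows = []
    all_pairs = []

    for sid, recs in sorted(by_subject.items()):
        period = merge_recordings(recs)
        bts, wear, dailies = process_subject(period, model, cfg)
        bout_frames.append(bouts_mod.bouts_to_frame(bts, sid, period.start_time))
        daily_frames.append(weartime.dailies_to_frame(dailies))

        subj_assessments = [a for a in assessments if a.subject_id == sid]
        visits = sorted(
            {
                (a.visit_id, (a.start_time + pd.Timedelta(hours=cfg.tz_offset_hours)).date())
                for a in subj_assessments
            }
        )
        epochs = compliance.build_epochs(dailies, visits, cfg.compliance)
        kept, report = compliance.apply_threshold(
            epochs, cfg.compliance.h_min, cfg.compliance.d_min
        )
        epoch_frames.append(compliance.epochs_to_frame(epochs))
        excl_frames.append(report)

        off = pd.Timedelta(hours=cfg.tz_offset_hours)
        bouts_by_day: dict[_dt.date, list] = {}
        for b in bts:
            d = (period.start_time + pd.Timedelta(seconds=b.start_time_s) + off).date()
            bouts_by_day.setdefault(d, []).append(b)
        all_pairs.extend(
            clinical.build_validity_pairs(
                kept, bouts_by_day, subj_assessments,
                tz_offset_hours=cfg.tz_offset_hours,
            )
        )

        for a in subj_assessments:
            try:
                sl = clinical.extract_assessment_window(period, a)
            except clinical.GapError as e:
                log.warning("%s", e)
                continue
            est = clinical.assessment_speed(sl, model, cfg.plausibility)
            speed_rows.append(
                {
                    "subject_id": sid,
                    "visit_id": a.visit_id,
                    "assessment_type": a.assessment_type,
                    "reference_speed_mps": a.reference_speed_mps,
                    "estimated_speed_mps": est,
                }
            )

    outputs = {
        "bouts.csv": pd.concat(bout_frames, ignore_index=True) if bout_frames else pd.DataFrame(),
        "daily_summaries.csv": pd.concat(daily_frames, ignore_index=True) if daily_frames else pd.DataFrame(),
        "epochs.csv": pd.concat(epoch_frames, ignore_index=True) if epoch_frames else pd.DataFrame(),
        "exclusions.csv": pd.concat(excl_frames, ignore_index=True) if excl_frames else pd.DataFrame(),
        "assessment_speeds.csv": pd.DataFrame(speed_rows),
        "validity_pairs.csv": clinical.pairs_to_frame(all_pairs),
    }

    speeds = pd.DataFrame(speed_rows)
    if len(speeds) >= 3 and speeds["estimated_speed_mps"].notna().sum() >= 3:
        ok = speeds.dropna(subset=["estimated_speed_mps"])
        try:
            st = clinical.agreement(
                list(zip(ok["reference_speed_mps"], ok["estimated_speed_mps"]))
            )
            outputs["agreement.csv"] = pd.DataFrame(
                [
                    {
                        "n": st.n,
                        "slope": st.slope,
                        "intercept": st.intercept,
                        "pearson_r": st.pearson_r,
                        "residual_standard_error": st.residual_standard_error,
                    }
                ]
            )
        except ValueError as e:
            log.warning("agreement skipped: %s", e)

    manifest = {"outputs": {}}
    for name, df in outputs.items():
        path = output_dir / name
        df.to_csv(path, index=False)
        manifest["outputs"][name] = _file_hash(path)
    cfg_path = output_dir / "config.yaml"
    cfg.to_yaml(cfg_path)
    manifest["outputs"]["config.yaml"] = _file_hash(cfg_path)
    with open(output_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest
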