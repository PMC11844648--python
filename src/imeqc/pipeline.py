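"""End-to-end pipeline: simulate/load -> reference -> filter -> detect ->
screen artifacts -> sort -> metrics -> yield.

Every output file is stamped (in ``provenance.json``) with the config hash
and global seed; re-running with an identical config reproduces
byte-identical result files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qcio
from .metrics import aggregate_channel_phase, channel_noise_rms, \
    compute_unit_metrics
from .preproc import bandpass, common_median_reference, detect_spikes, \
    reject_artifacts, robust_sigma
from .sorting import sort_events
from .synth import AmplitudeOutlierSpec, EphysSimConfig, MotionArtifactSpec, \
    UnitSpec, biphasic_template, simulate_recording
from .yields import make_activity_table, weekly_aey

__all__ = ["build_scene", "run_pipeline"]


def build_scene(scene: dict, seed: int) -> EphysSimConfig:
    """Instantiate the synthetic-recording config described by a flat
    scene dict (the YAML-friendly form used in RunConfig)."""
    n_ch = int(scene["n_channels"])
    fs = float(scene["fs_hz"])
    vpps = list(scene["unit_vpp_uv"])
    rates = list(scene["unit_rate_hz"])
    units = [UnitSpec(channel=c,
                      template=biphasic_template(fs, vpps[c % len(vpps)]),
                      rate_hz=rates[c % len(rates)])
             for c in range(n_ch)]
    dur = float(scene["duration_s"])
    n_art = int(scene.get("n_motion_artifacts", 0))
    arts = [MotionArtifactSpec(time_s=(i + 1) * dur / (n_art + 1),
                               amplitude_uv=float(
                                   scene.get("motion_amplitude_uv", 300.0)),
                               n_channels_hit=int(
                                   scene.get("motion_channels_hit", 15)),
                               channel_delay_ms=float(
                                   scene.get("motion_delay_ms", 0.25)))
            for i in range(n_art)]
    n_out = int(scene.get("n_amplitude_outliers", 0))
    outs = [AmplitudeOutlierSpec(channel=i % n_ch,
                                 time_s=(2 * i + 1) * dur / (2 * n_out + 1),
                                 peak_uv=float(
                                     scene.get("outlier_peak_uv", 800.0)))
            for i in range(n_out)]
    return EphysSimConfig(n_channels=n_ch, duration_s=dur, fs_hz=fs,
                          noise_sd_uv=float(scene["noise_sd_uv"]),
                          units=units, motion_artifacts=arts,
                          amplitude_outliers=outs, seed=seed)


def run_pipeline(cfg: qcio.RunConfig, out_dir) -> dict:
    """Run detect -> sort -> metrics -> yield on the configured synthetic
    scene and write all result tables under ``out_dir``.

    Returns a bundle with the in-memory intermediates. Any stage failure
    surfaces as an exception naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": cfg}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    def _simulate():
        sim_cfg = build_scene(cfg.ephys,
                              qcio.stage_seed(cfg.seed, "simulate"))
        return simulate_recording(sim_cfg)

    rec, gt = _stage("simulate", _simulate)
    bundle["ground_truth"] = gt

    det_cfg = cfg.detection_config()
    ref = _stage("reference", lambda: common_median_reference(rec))
    filt = _stage("filter", lambda: bandpass(ref, det_cfg.band_hz))
    events = _stage("detect", lambda: detect_spikes(filt, det_cfg))
    kept, rem_amp, rem_mot = _stage(
        "screen", lambda: reject_artifacts(events, det_cfg, rec.fs_hz))
    bundle.update(events=events, kept=kept, removed_amplitude=rem_amp,
                  removed_motion=rem_mot)

    flags = {}
    for e in rem_amp:
        flags[id(e)] = "amplitude"
    for e in rem_mot:
        flags[id(e)] = "motion"
    qcio.write_events(sorted(events, key=lambda e: (e.peak_sample, e.channel)),
                      rec.fs_hz, out / "events.csv", flags)

    sort_cfg = cfg.sort_config(seed=qcio.stage_seed(cfg.seed, "sort"))
    sigma = {c: robust_sigma(filt.voltages[i])
             for i, c in enumerate(rec.channel_ids)}
    units = _stage("sort", lambda: sort_events(kept, rec.fs_hz, sort_cfg,
                                               sigma))
    for u in units:
        u.week = 1
        u.animal = "A1"
        u.group = "SIM"
    qcio.write_units(units, out / "units.json")

    peaks_by_chan: dict[int, list[int]] = {}
    for e in kept:
        peaks_by_chan.setdefault(e.channel, []).append(e.peak_sample)
    noise = {c: channel_noise_rms(filt.voltages[i], peaks_by_chan.get(c, []),
                                  rec.fs_hz, det_cfg.snippet_pre_ms,
                                  det_cfg.snippet_post_ms)
             for i, c in enumerate(rec.channel_ids)}
    metrics = _stage("metrics", lambda: compute_unit_metrics(
        units, noise, rout_q=cfg.rout_q))
    metrics.to_csv(out / "unit_metrics.csv", index=False, float_format="%.9g")
    summaries = _stage("aggregate", lambda: aggregate_channel_phase(metrics))
    summaries.to_csv(out / "channel_phase_summary.csv", index=False,
                     float_format="%.9g")
    bundle.update(unit_metrics=metrics, summaries=summaries, noise=noise)

    qual = metrics[metrics["putative"] & metrics["verified"]
                   & ~metrics["snr_outlier"]]
    act = (qual.groupby("channel").size()
           .reindex(rec.channel_ids, fill_value=0))
    table = make_activity_table(pd.DataFrame({
        "group": "SIM", "animal": "A1", "week": 1,
        "channel": act.index, "n_units": act.to_numpy()}))
    yields = _stage("yield", lambda: weekly_aey(table))
    ydf = pd.DataFrame([{"group": y.group, "scope": y.scope,
                         "n_active": y.n_active, "n_total": y.n_total,
                         "proportion": y.proportion} for y in yields])
    ydf.to_csv(out / "yields.csv", index=False, float_format="%.9g")
    bundle["yields"] = yields

    prov = {"config_hash": qcio.config_hash(cfg), "seed": cfg.seed,
            "stages": ["simulate", "reference", "filter", "detect", "screen",
                       "sort", "metrics", "aggregate", "yield"]}
    (out / "provenance.json").write_text(json.dumps(prov, indent=1))
    return bundle
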