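"""File formats, run configuration, and seeded-run provenance.

Formats are deliberately flat and diffable: recordings as channel-major
little-endian float32 raw binary with a JSON sidecar, images as 16-bit
single-channel TIFF, masks as 8-bit 0/255 TIFF, tables as CSV, unit sets
as JSON. All randomness in a run flows from one global seed through
per-stage children of a numpy SeedSequence; no stage reads OS entropy.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .preproc import Recording, SpikeEvent, DetectionConfig
from .sorting import SortConfig, Unit

__all__ = [
    "RunConfig", "stage_seed", "config_hash",
    "write_recording", "read_recording",
    "write_image", "read_image", "write_mask", "read_mask",
    "write_centroids", "read_centroids",
    "write_events", "read_events", "write_units", "read_units",
    "write_release_series", "read_release_series",
]


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

DEFAULT_EPHYS_SCENE = {
    "n_channels": 16,
    "duration_s": 600.0,
    "fs_hz": 24414.0,
    "noise_sd_uv": 10.0,
    # one planted unit per channel; vpp cycles through the listed values
    "unit_vpp_uv": [100.0, 150.0, 200.0, 250.0, 300.0],
    "unit_rate_hz": [2.0, 4.0, 6.0, 8.0, 10.0],
    "n_motion_artifacts": 0,
    # trough depth: large against the 10 uV noise floor yet below the
    # +/-500 uV amplitude rule, so motion transients exercise the
    # >14-channel coincidence rule
    "motion_amplitude_uv": 300.0,
    "motion_delay_ms": 0.25,
    "motion_channels_hit": 15,
    "n_amplitude_outliers": 0,
    "outlier_peak_uv": 800.0,
}


@dataclasses.dataclass
class RunConfig:
    """Parameters for every pipeline stage plus the global seed.

    Stage blocks omitted from a config file fall back to the documented
    defaults. The whole object round-trips through YAML unchanged.
    """

    seed: int = 0
    ephys: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EPHYS_SCENE))
    detection: dict = dataclasses.field(default_factory=dict)
    sorting: dict = dataclasses.field(default_factory=dict)
    rout_q: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        scene = dict(DEFAULT_EPHYS_SCENE)
        scene.update(self.ephys or {})
        self.ephys = scene

    def detection_config(self) -> DetectionConfig:
        return DetectionConfig(**self.detection)

    def sort_config(self, seed: int | None = None) -> SortConfig:
        kw = dict(self.sorting)
        if seed is not None:
            kw.setdefault("seed", seed)
        return SortConfig(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)  # __post_init__ merges the ephys scene

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the canonical config serialization."""
    blob = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage integer seed (< 2**31) from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


# --------------------------------------------------------------------------
# Recordings: raw float32 + JSON sidecar
# --------------------------------------------------------------------------

def write_recording(rec: Recording, path) -> None:
    """``path`` is the binary file; ``path + '.json'`` holds the sidecar."""
    path = Path(path)
    rec.voltages.astype("<f4").tofile(path)
    sidecar = {
        "fs_hz": rec.fs_hz,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "unit": "uV",
        "duration_s": rec.duration_s,
        "channel_ids": list(rec.channel_ids),
        "dtype": "<f4",
        "order": "channel_major",
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_recording(path) -> Recording:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs_hz", "n_channels", "n_samples"):
        if key not in meta:
            raise ValueError(f"sidecar missing required field {key!r}")
    if meta["fs_hz"] <= 0:
        raise ValueError("sidecar fs_hz must be positive")
    raw = np.fromfile(path, dtype="<f4")
    expected = meta["n_channels"] * meta["n_samples"]
    if raw.size != expected:
        raise ValueError(
            f"binary length mismatch: expected {expected} samples "
            f"({meta['n_channels']} ch x {meta['n_samples']}), got {raw.size}")
    V = raw.reshape(meta["n_channels"], meta["n_samples"])
    return Recording(voltages=V, fs_hz=meta["fs_hz"],
                     channel_ids=meta.get("channel_ids") or [])


# --------------------------------------------------------------------------
# Images, masks, centroids
# --------------------------------------------------------------------------

def write_image(img: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(img, dtype=np.uint16))


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.where(np.asarray(mask, bool), 255, 0
                                    ).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_centroids(centroids: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(centroids).reshape(-1, 2),
                 columns=["x_px", "y_px"]).to_csv(path, index=False)


def read_centroids(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x_px", "y_px"]].to_numpy(dtype=np.float64)


# --------------------------------------------------------------------------
# Events, units, release series
# --------------------------------------------------------------------------

def write_events(events: list[SpikeEvent], fs_hz: float, path,
                 flags: dict[int, str] | None = None) -> None:
    rows = [{
        "channel": e.channel, "peak_sample": e.peak_sample,
        "time_s": e.time_s(fs_hz), "amplitude_uv": e.peak_amplitude_uv,
        "flag": (flags or {}).get(id(e), "kept"),
    } for e in events]
    pd.DataFrame(rows, columns=["channel", "peak_sample", "time_s",
                                "amplitude_uv", "flag"]).to_csv(path,
                                                                index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_units(units: list[Unit], path) -> None:
    payload = [{
        "channel": int(u.channel),
        "spike_times_s": [float(t) for t in u.spike_times_s],
        "verified": bool(u.verified),
        "week": u.week, "animal": u.animal, "group": u.group,
        "mean_waveform_uv": [float(v) for v in u.mean_waveform],
    } for u in units]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_units(path) -> list[Unit]:
    payload = json.loads(Path(path).read_text())
    units = []
    for p in payload:
        wf = np.asarray(p["mean_waveform_uv"])[None, :]
        u = Unit(channel=p["channel"],
                 spike_times_s=np.asarray(p["spike_times_s"]),
                 waveforms=np.repeat(wf, max(len(p["spike_times_s"]), 1),
                                     axis=0),
                 verified=p["verified"], week=p.get("week"),
                 animal=p.get("animal"), group=p.get("group"))
        units.append(u)
    return units


def write_release_series(series, path) -> None:
    pd.DataFrame({"time_h": series.times_h,
                  "conc_mg_per_ml": series.conc_mg_per_ml}).to_csv(
        path, index=False)


def read_release_series(path, v_reservoir_ml: float = 14.0,
                        v_aliquot_ml: float = 1.0,
                        loaded_mass_mg: float | None = None):
    from .release import ReleaseSeries

    df = pd.read_csv(path)
    return ReleaseSeries(times_h=df["time_h"].to_numpy(),
                         conc_mg_per_ml=df["conc_mg_per_ml"].to_numpy(),
                         v_reservoir_ml=v_reservoir_ml,
                         v_aliquot_ml=v_aliquot_ml,
                         loaded_mass_mg=loaded_mass_mg)
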