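"""Synthetic data with known ground truth for every pipeline stage.

Emulates the experimental readouts of a zebrafish cardioprotection screen:

* fluorescence time-lapse stacks of a GFP-labelled larval heart — a bright
  ellipse on dark background whose area pulses at the beat frequency,
  with optional inter-beat-interval jitter and dropped (AV-block-like)
  contraction cycles;
* adult-fish ECG traces — a periodic PQRST-like template at jittered beat
  times plus Gaussian noise;
* fraction x compound peak-area matrices with planted active compounds
  concentrated in high-recovery fractions;
* MTT viability plates (optical densities per treatment group).

All generators draw exclusively from a ``numpy.random.default_rng`` seeded
from the config, so identical configs give bitwise-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "VideoConfig",
    "GroundTruth",
    "EcgConfig",
    "EcgTrace",
    "AssaySimConfig",
    "VIDEO_PRESETS",
    "ECG_PRESETS",
    "generate_heart_video",
    "generate_ecg",
    "generate_fraction_assay",
    "generate_mtt",
    "save_stack",
    "load_stack",
]


@dataclass(frozen=True)
class VideoConfig:
    """Parameters of a synthetic fluorescence heart recording.

    Defaults mirror the recording protocol of the screen: 100 continuous
    frames at 20 fps (10 fps also supported), 8-bit 128x128 frames.
    ``pulsation_fraction`` is the relative area swing about the baseline;
    ``dropped_beat_prob`` is the per-cycle probability that the ventricle
    skips a contraction and holds the diastolic (maximal-area) state.
    """

    n_frames: int = 100
    fps: float = 20.0
    beat_hz: float = 3.0
    area_baseline: float = 600.0
    pulsation_fraction: float = 0.35
    frame_shape: tuple[int, int] = (128, 128)
    noise_sd: float = 6.0
    dropped_beat_prob: float = 0.0
    ibi_jitter_cv: float = 0.0
    seed: int = 0
    background: float = 10.0
    foreground: float = 200.0
    aspect_ratio: float = 1.4

    def validate(self) -> None:
        duration = self.n_frames / self.fps
        if self.n_frames < 2 or self.fps <= 0:
            raise ValueError("need >= 2 frames and positive fps")
        if duration <= 2.0 / self.beat_hz:
            raise ValueError(
                f"duration {duration:.2f}s must exceed two beat cycles "
                f"({2.0 / self.beat_hz:.2f}s)")
        if not self.beat_hz < self.fps / 2:
            raise ValueError(f"beat_hz {self.beat_hz} must be < fps/2 = {self.fps / 2}")
        if not 0 <= self.dropped_beat_prob < 1:
            raise ValueError("dropped_beat_prob must be in [0, 1)")
        if not 0 <= self.pulsation_fraction <= 1:
            raise ValueError("pulsation_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually produced, for parameter-recovery tests."""

    true_bpm: float
    true_beat_times: tuple[float, ...]
    dropped_cycles: tuple[int, ...]
    true_area_series: tuple[float, ...]


#: Group presets encoding the rates reported for the screen: control larvae
#: beat at ~3 Hz (~180 bpm); terfenadine-treated larvae slow to ~1.5 Hz with
#: irregular rhythm and occasional skipped (AV-block-like) beats; adult fish
#: beat near 100 bpm, slowing and destabilising under terfenadine.
VIDEO_PRESETS: dict[str, dict] = {
    "control-larva": dict(beat_hz=3.0, ibi_jitter_cv=0.0, dropped_beat_prob=0.0),
    "model-larva": dict(beat_hz=1.5, ibi_jitter_cv=0.2, dropped_beat_prob=0.05),
}

ECG_PRESETS: dict[str, dict] = {
    "adult-normal": dict(beat_hz=100.0 / 60.0, ibi_jitter_cv=0.02),
    "adult-terfenadine": dict(beat_hz=1.2, ibi_jitter_cv=0.25),
}


def _draw_cycles(rng: np.random.Generator, cfg_period: float, jitter_cv: float,
                 dropped_prob: float, duration: float):
    """Cycle boundaries covering [0, duration), starting mid-cycle.

    The recording opens halfway through a cycle so that the first diastolic
    maximum falls strictly inside the trace.
    """
    intervals: list[float] = []
    dropped: list[bool] = []
    boundaries: list[float] = []
    t = None
    while t is None or t < duration + 2 * cfg_period:
        period = cfg_period
        if jitter_cv > 0:
            period = cfg_period * max(0.2, 1.0 + jitter_cv * rng.standard_normal())
        if t is None:
            t = -0.5 * period
        boundaries.append(t)
        intervals.append(period)
        dropped.append(bool(rng.random() < dropped_prob))
        t += period
    return np.array(boundaries), np.array(intervals), np.array(dropped)


def _analytic_area(times: np.ndarray, boundaries: np.ndarray,
                   intervals: np.ndarray, dropped: np.ndarray,
                   baseline: float, pf: float) -> np.ndarray:
    idx = np.searchsorted(boundaries, times, side="right") - 1
    idx = np.clip(idx, 0, len(intervals) - 1)
    phase = 2 * np.pi * (times - boundaries[idx]) / intervals[idx]
    area = baseline * (1.0 + pf * np.cos(phase))
    area[dropped[idx]] = baseline * (1.0 + pf)
    return area


def generate_heart_video(cfg: VideoConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render a pulsating-ellipse stack; returns (frames uint8, ground truth).

    Frame area follows ``area_baseline * (1 + pulsation_fraction *
    cos(phase))`` with diastole (maximal area) at cycle boundaries; a
    dropped cycle holds diastole for its full duration. Ground-truth beat
    times are the diastolic onsets of non-dropped cycles; ``true_bpm`` is
    the nominal ``60 * beat_hz``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    duration = cfg.n_frames / cfg.fps
    boundaries, intervals, dropped = _draw_cycles(
        rng, 1.0 / cfg.beat_hz, cfg.ibi_jitter_cv, cfg.dropped_beat_prob, duration)
    times = np.arange(cfg.n_frames) / cfg.fps
    areas = _analytic_area(times, boundaries, intervals, dropped,
                           cfg.area_baseline, cfg.pulsation_fraction)

    rows, cols = cfg.frame_shape
    center = (rows / 2.0, cols / 2.0)
    frames = np.empty((cfg.n_frames, rows, cols), dtype=np.uint8)
    for k, area in enumerate(areas):
        img = np.full((rows, cols), cfg.background, dtype=float)
        # ellipse with fixed aspect ratio whose rasterised area tracks `area`
        minor = np.sqrt(area / (np.pi * cfg.aspect_ratio))
        rr, cc = draw_ellipse(center[0], center[1],
                              cfg.aspect_ratio * minor, minor, shape=(rows, cols))
        img[rr, cc] = cfg.foreground
        if cfg.noise_sd > 0:
            img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
        frames[k] = np.clip(img, 0, 255).astype(np.uint8)

    in_window = (boundaries >= 0) & (boundaries < duration)
    beat_times = boundaries[in_window & ~dropped]
    dropped_idx = np.nonzero(in_window & dropped)[0]
    truth = GroundTruth(
        true_bpm=60.0 * cfg.beat_hz,
        true_beat_times=tuple(float(t) for t in beat_times),
        dropped_cycles=tuple(int(i) for i in dropped_idx),
        true_area_series=tuple(float(a) for a in areas),
    )
    return frames, truth


@dataclass(frozen=True)
class EcgConfig:
    """Synthetic adult-zebrafish surface-ECG parameters."""

    duration: float = 10.0
    sample_rate: float = 500.0
    beat_hz: float = 100.0 / 60.0
    qrs_amplitude: float = 1.0
    noise_sd: float = 0.03
    ibi_jitter_cv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if not self.sample_rate >= 50 * self.beat_hz:
            raise ValueError(
                f"sample_rate {self.sample_rate} must be >= 50 x beat_hz "
                f"({50 * self.beat_hz})")


@dataclass(frozen=True)
class EcgTrace:
    times: np.ndarray
    voltage: np.ndarray
    true_beat_times: tuple[float, ...]
    true_bpm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "voltage": self.voltage})


def _pqrst(t: np.ndarray, amplitude: float) -> np.ndarray:
    """Stylised PQRST complex centred on the R peak at t = 0 (seconds)."""
    def g(mu, sigma, a):
        return a * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return (g(-0.15, 0.025, 0.12 * amplitude)      # P
            + g(-0.025, 0.010, -0.10 * amplitude)  # Q
            + g(0.0, 0.012, amplitude)             # R
            + g(0.030, 0.012, -0.22 * amplitude)   # S
            + g(0.22, 0.045, 0.28 * amplitude))    # T


def generate_ecg(cfg: EcgConfig) -> EcgTrace:
    """Baseline + periodic QRS-like template at jittered beat times + noise."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    period = 1.0 / cfg.beat_hz
    beat_times = []
    t = 0.4 * period
    while t < cfg.duration - 0.1 * period:
        beat_times.append(t)
        step = period
        if cfg.ibi_jitter_cv > 0:
            step = period * max(0.2, 1.0 + cfg.ibi_jitter_cv * rng.standard_normal())
        t += step
    times = np.arange(int(round(cfg.duration * cfg.sample_rate))) / cfg.sample_rate
    voltage = np.zeros_like(times)
    for bt in beat_times:
        near = np.abs(times - bt) < 0.45  # template support
        voltage[near] += _pqrst(times[near] - bt, cfg.qrs_amplitude)
    if cfg.noise_sd > 0:
        voltage += rng.normal(0.0, cfg.noise_sd, size=voltage.shape)
    return EcgTrace(
        times=times,
        voltage=voltage,
        true_beat_times=tuple(beat_times),
        true_bpm=60.0 * cfg.beat_hz,
    )


@dataclass(frozen=True)
class AssaySimConfig:
    """Fraction x compound peak-area simulation with planted actives.

    Inactive compounds receive independent log-normal areas in every
    fraction; each active compound has ``active_mass_frac`` of its total
    area concentrated in its assigned high-recovery fraction(s). The
    default recovery profile mimics a separation where the first fractions
    rescue heart rate and the late ones depress it further.
    """

    n_fractions: int = 10
    n_compounds: int = 71
    n_active: int = 1
    recovery_rates: tuple[float, ...] | None = None
    active_placement: Mapping[str, Sequence[str]] | None = None
    area_lognorm_sigma: float = 0.5
    area_scale: float = 1e5
    active_mass_frac: float = 0.9
    seed: int = 0

    def resolved_recovery(self) -> tuple[float, ...]:
        if self.recovery_rates is not None:
            return tuple(self.recovery_rates)
        # smooth decline from strongly protective to rate-depressing
        return tuple(np.round(np.linspace(75.0, -25.0, self.n_fractions), 2))

    def validate(self) -> None:
        if self.n_active > self.n_compounds:
            raise ValueError("n_active cannot exceed n_compounds")
        if len(self.resolved_recovery()) != self.n_fractions:
            raise ValueError("recovery_rates length must equal n_fractions")
        if not 0 < self.active_mass_frac <= 1:
            raise ValueError("active_mass_frac must be in (0, 1]")


def generate_fraction_assay(
    cfg: AssaySimConfig,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Return (areas fractions x compounds, recovery %, active -> fractions)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fractions = [f"F{i + 1}" for i in range(cfg.n_fractions)]
    compounds = [f"C{j + 1}" for j in range(cfg.n_compounds)]
    recovery = pd.Series(cfg.resolved_recovery(), index=fractions, name="R_percent")

    areas = cfg.area_scale * rng.lognormal(
        mean=0.0, sigma=cfg.area_lognorm_sigma,
        size=(cfg.n_fractions, cfg.n_compounds))
    df = pd.DataFrame(areas, index=fractions, columns=compounds)

    if cfg.active_placement is not None:
        placement = {c: list(fr) for c, fr in cfg.active_placement.items()}
    else:
        top = recovery.idxmax()
        placement = {compounds[j]: [top] for j in range(cfg.n_active)}

    for comp, assigned in placement.items():
        total = df[comp].sum()
        others = [f for f in fractions if f not in assigned]
        w_in = rng.lognormal(0.0, cfg.area_lognorm_sigma, size=len(assigned))
        w_out = rng.lognormal(0.0, cfg.area_lognorm_sigma, size=len(others))
        col = pd.Series(0.0, index=fractions)
        col[assigned] = cfg.active_mass_frac * total * w_in / w_in.sum()
        if others:
            col[others] = (1 - cfg.active_mass_frac) * total * w_out / w_out.sum()
        df[comp] = col
    return df, recovery, placement


def generate_mtt(
    n_wells: int,
    od_control_mean: float,
    od_model_mean: float,
    od_tested_mean: float | Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Gaussian OD replicates per group, truncated at zero.

    ``od_tested_mean`` may be a single mean or a mapping of fraction id ->
    mean; the returned dict has keys ``control``, ``model`` and one per
    tested condition.
    """
    for name, mean in (("control", od_control_mean), ("model", od_model_mean)):
        if mean <= 0:
            raise ValueError(f"{name} OD mean must be positive")
    rng = np.random.default_rng(seed)

    def draw(mean: float) -> np.ndarray:
        return np.clip(rng.normal(mean, noise_sd, size=n_wells), 0.0, None)

    plate = {"control": draw(od_control_mean), "model": draw(od_model_mean)}
    if isinstance(od_tested_mean, Mapping):
        for fid, mean in od_tested_mean.items():
            plate[fid] = draw(mean)
    else:
        plate["tested"] = draw(od_tested_mean)
    return plate


def save_stack(path: str | Path, frames: np.ndarray, cfg: VideoConfig,
               truth: GroundTruth | None = None) -> None:
    """Write a multi-page TIFF plus a JSON sidecar with config/ground truth."""
    path = Path(path)
    tifffile.imwrite(path, frames)
    sidecar = {"config": asdict(cfg)}
    if truth is not None:
        sidecar["ground_truth"] = asdict(truth)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_stack(path: str | Path) -> tuple[np.ndarray, dict | None]:
    """Read a multi-page TIFF stack and its JSON sidecar if present."""
    path = Path(path)
    frames = tifffile.imread(path)
    sidecar = None
    sc_path = path.with_suffix(".json")
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
    return frames, sidecar
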