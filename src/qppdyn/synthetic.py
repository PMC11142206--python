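"""Synthetic resting-state BOLD data with planted spatiotemporal structure.

The generator produces scans that contain, with known ground truth, the
three kinds of structure the analysis arms look for:

* a shared global fluctuation ``g(t)`` (band-limited, z-scored) entering
  each region through a nonnegative coupling weight — elevated by default
  on a designated cingulate/midline region set;
* a recurring quasi-periodic pattern (QPP): a ``W``-frame waveform planted
  at quasi-regular event onsets, carried with opposite sign by two
  anticorrelated region groups and with small per-region integer frame
  lags (regions outside both groups are uninvolved);
* additive Gaussian noise band-limited to the analysis band
  (0.01–0.1 Hz by default), independently per region and per voxel.

Defaults follow the acquisition emulated here: 10-minute scans at
TR = 1.25 s (480 frames). The default cohort layout is an unbalanced
2 (virus) × 4 (stimulation) design totalling 74 scans.
"""
from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import (
    STIM_LEVELS,
    VIRUS_LEVELS,
    InvalidConfigError,
    ParcellatedScan,
    VoxelScan,
)

logger = logging.getLogger(__name__)

#: Scan counts per (virus, stimulation) cell of the default cohort.
DEFAULT_CELL_COUNTS: dict[tuple[str, str], int] = {
    ("mCherry", "baseline"): 15,
    ("ChR2", "baseline"): 13,
    ("mCherry", "2Hz"): 8,
    ("ChR2", "2Hz"): 4,
    ("mCherry", "5Hz"): 7,
    ("ChR2", "5Hz"): 5,
    ("mCherry", "15Hz-phasic"): 12,
    ("ChR2", "15Hz-phasic"): 10,
}


@dataclass
class SimulationConfig:
    """Parameters of a single synthetic scan.

    Amplitudes are in arbitrary BOLD units; the global trace and the noise
    are normalized to unit sample SD before scaling, so ``gs_amplitude``,
    ``qpp_amplitude`` and ``noise_sd`` are directly comparable.
    """

    n_regions: int = 30
    grid_shape: tuple[int, int, int] = (10, 6, 5)
    tr_seconds: float = 1.25
    n_frames: int = 480
    gs_amplitude: float = 1.0
    gs_weights: np.ndarray | None = None  # default: 0.5, cingulate 1.0
    qpp_amplitude: float = 1.0
    qpp_window_frames: int = 8
    qpp_waveform: np.ndarray | None = None  # default: one raised-cosine cycle
    qpp_lags: np.ndarray | None = None  # default: 0,1,2 cycling over involved regions
    mean_event_interval_frames: float = 24.0
    interval_jitter_frames: float = 4.0
    noise_sd: float = 0.5
    voxel_noise_sd: float = 0.1
    noise_band_hz: tuple[float, float] = (0.01, 0.1)
    # Butterworth order per pass of the zero-phase noise-shaping filter;
    # order 5 keeps >95% of the noise power inside the nominal band, which
    # is what "band-limited" is taken to mean here.
    filter_order: int = 5
    cingulate_region_ids: tuple[int, ...] = (0, 1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived structure ------------------------------------------------
    def resolved_gs_weights(self) -> np.ndarray:
        if self.gs_weights is not None:
            w = np.asarray(self.gs_weights, dtype=float)
        else:
            w = np.full(self.n_regions, 0.5)
            w[list(self.cingulate_region_ids)] = 1.0
        return w

    def resolved_waveform(self) -> np.ndarray:
        """Base event waveform (group A); one raised-cosine cycle by default."""
        if self.qpp_waveform is not None:
            return np.asarray(self.qpp_waveform, dtype=float)
        t = np.arange(self.qpp_window_frames)
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * t / self.qpp_window_frames))

    def region_group_labels(self) -> np.ndarray:
        """Per-region QPP involvement: 'A', 'B' (sign-inverted), or 'none'.

        The first third of regions (which contains the default cingulate
        set) forms group A, the second third the anticorrelated group B,
        and the remainder is uninvolved.
        """
        n = self.n_regions
        labels = np.full(n, "none", dtype=object)
        third = max(1, n // 3)
        labels[:third] = "A"
        labels[third : 2 * third] = "B"
        return labels

    def resolved_lags(self) -> np.ndarray:
        """Integer frame lags (0–2, cycling) for involved regions; 0 elsewhere."""
        if self.qpp_lags is not None:
            lags = np.asarray(self.qpp_lags, dtype=int)
            if lags.shape != (self.n_regions,):
                raise InvalidConfigError("qpp_lags must have one entry per region")
            return lags
        labels = self.region_group_labels()
        lags = np.zeros(self.n_regions, dtype=int)
        k = 0
        for r in range(self.n_regions):
            if labels[r] != "none":
                lags[r] = k % 3
                k += 1
        return lags

    def validate(self) -> None:
        if self.n_regions < 1:
            raise InvalidConfigError("n_regions must be positive")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise InvalidConfigError("grid_shape must be 3 positive integers")
        if int(np.prod(self.grid_shape)) < self.n_regions:
            raise InvalidConfigError("grid volume must be >= n_regions")
        if not self.tr_seconds > 0:
            raise InvalidConfigError("tr_seconds must be positive")
        if self.qpp_window_frames < 2:
            raise InvalidConfigError("qpp_window_frames must be >= 2")
        if self.n_frames < 2 * self.qpp_window_frames:
            raise InvalidConfigError("n_frames must be >= 2 * qpp_window_frames")
        for name in ("gs_amplitude", "qpp_amplitude", "noise_sd", "voxel_noise_sd",
                     "interval_jitter_frames"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be nonnegative")
        if self.mean_event_interval_frames < self.qpp_window_frames:
            raise InvalidConfigError(
                "mean_event_interval_frames must be >= qpp_window_frames "
                "(events must not overlap)"
            )
        lo, hi = self.noise_band_hz
        nyq = 0.5 / self.tr_seconds
        if not (0 < lo < hi < nyq):
            raise InvalidConfigError(
                f"noise_band_hz must satisfy 0 < low < high < Nyquist ({nyq:g} Hz)"
            )
        ids = list(self.cingulate_region_ids)
        if any(i < 0 or i >= self.n_regions for i in ids):
            raise InvalidConfigError("cingulate_region_ids out of range")
        w = self.resolved_gs_weights()
        if w.shape != (self.n_regions,):
            raise InvalidConfigError("gs_weights must have one entry per region")
        if np.any(w < 0):
            raise InvalidConfigError("gs_weights must be nonnegative")
        if self.qpp_waveform is not None and len(
                np.asarray(self.qpp_waveform)) != self.qpp_window_frames:
            raise InvalidConfigError("qpp_waveform must have W entries")


@dataclass
class GroundTruth:
    """Exactly what was planted in one synthetic scan."""

    event_onsets: np.ndarray  # strictly increasing frame indices
    gs_trace: np.ndarray  # length n_frames, z-scored
    planted_template: np.ndarray  # region × W (includes amplitude, signs, lags)
    region_group_labels: np.ndarray  # 'A' / 'B' / 'none' per region


def default_region_names(config: SimulationConfig) -> list[str]:
    names = [f"Region {r:02d}" for r in range(config.n_regions)]
    for j, rid in enumerate(config.cingulate_region_ids, start=1):
        names[rid] = f"Cingulate Cortex {j}"
    return names


def generate_event_train(
    n_frames: int,
    window_frames: int,
    mean_interval: float,
    jitter: float,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> np.ndarray:
    """Quasi-periodic, non-overlapping event onsets.

    A renewal process: the first onset is at frame 0 and successive
    intervals are ``mean_interval`` plus uniform jitter in ``±jitter``
    (rounded to integer frames, clipped to ``window_frames`` so events
    never overlap). Events are kept while the full window fits in the scan.
    """
    if mean_interval < window_frames:
        raise InvalidConfigError("mean_interval must be >= window_frames")
    if jitter < 0:
        raise InvalidConfigError("jitter must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    onsets = []
    t = 0
    while t + window_frames <= n_frames:
        onsets.append(t)
        interval = mean_interval + rng.uniform(-jitter, jitter)
        t += max(window_frames, int(round(interval)))
    return np.asarray(onsets, dtype=int)


def _band_limited_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fs: float,
    band: tuple[float, float],
    order: int,
) -> np.ndarray:
    """White Gaussian rows band-pass filtered (zero-phase) and re-normalized
    to unit sample SD per row."""
    x = rng.standard_normal(shape)
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    default_pad = 3 * (2 * len(sos) + 1)
    y = sps.sosfiltfilt(sos, x, axis=-1,
                        padlen=min(default_pad, shape[-1] - 1))
    sd = y.std(axis=-1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def planted_template(config: SimulationConfig) -> np.ndarray:
    """Region × W pattern inserted at each event (amplitude included)."""
    W = config.qpp_window_frames
    wave = config.resolved_waveform()
    labels = config.region_group_labels()
    lags = config.resolved_lags()
    tpl = np.zeros((config.n_regions, W))
    for r in range(config.n_regions):
        if labels[r] == "none":
            continue
        sign = 1.0 if labels[r] == "A" else -1.0
        tpl[r] = sign * np.roll(wave, lags[r])
    return config.qpp_amplitude * tpl


def _region_timecourses(
    config: SimulationConfig,
) -> tuple[np.ndarray, GroundTruth, np.random.Generator]:
    """Assemble region × time signals and the matching ground truth.

    Returns the voxel-noise RNG stream so that voxel rendering (when
    requested) is deterministic given the config alone.
    """
    ss = np.random.SeedSequence(config.seed)
    s_gs, s_noise, s_ev, s_vox = ss.spawn(4)
    fs = 1.0 / config.tr_seconds
    T, R, W = config.n_frames, config.n_regions, config.qpp_window_frames

    g = _band_limited_noise(
        np.random.default_rng(s_gs), (T,), fs, config.noise_band_hz,
        config.filter_order,
    )
    g = (g - g.mean()) / g.std(ddof=1)

    onsets = generate_event_train(
        T, W, config.mean_event_interval_frames,
        config.interval_jitter_frames, np.random.default_rng(s_ev),
    )
    tpl = planted_template(config)

    tc = config.gs_amplitude * config.resolved_gs_weights()[:, None] * g[None, :]
    for onset in onsets:
        tc[:, onset : onset + W] += tpl
    if config.noise_sd > 0:
        tc = tc + config.noise_sd * _band_limited_noise(
            np.random.default_rng(s_noise), (R, T), fs, config.noise_band_hz,
            config.filter_order,
        )

    truth = GroundTruth(
        event_onsets=onsets,
        gs_trace=g,
        planted_template=tpl,
        region_group_labels=config.region_group_labels(),
    )
    return tc, truth, np.random.default_rng(s_vox)


def make_parcellation(config: SimulationConfig) -> np.ndarray:
    """Integer label volume: regions are contiguous equal-size blocks of the
    flattened grid; any leftover voxels are background (label 0)."""
    vol = int(np.prod(config.grid_shape))
    per_region = vol // config.n_regions
    flat = np.zeros(vol, dtype=np.int32)
    for r in range(config.n_regions):
        flat[r * per_region : (r + 1) * per_region] = r + 1
    return flat.reshape(config.grid_shape)


def generate_parcellated(
    config: SimulationConfig,
    scan_id: str = "",
    virus: str | None = None,
    stimulation: str | None = None,
) -> tuple[ParcellatedScan, GroundTruth]:
    """Generate one scan as region timecourses only (no voxel rendering)."""
    tc, truth, _ = _region_timecourses(config)
    scan = ParcellatedScan(
        values=tc,
        region_names=default_region_names(config),
        tr_seconds=config.tr_seconds,
        scan_id=scan_id,
        virus=virus,
        stimulation=stimulation,
    )
    return scan, truth


def generate_scan(
    config: SimulationConfig,
) -> tuple[VoxelScan, ParcellatedScan, GroundTruth]:
    """Generate one scan at voxel and region level with ground truth.

    Every voxel of region ``r`` carries the region timecourse plus
    independent white voxel noise (``voxel_noise_sd``); the returned
    :class:`ParcellatedScan` holds the noise-free region timecourses.
    """
    tc, truth, vox_rng = _region_timecourses(config)
    labels = make_parcellation(config)
    mask = labels > 0
    T = config.n_frames
    data = np.zeros(config.grid_shape + (T,))
    flat = data.reshape(-1, T)
    lab_flat = labels.ravel()
    for r in range(config.n_regions):
        idx = np.flatnonzero(lab_flat == r + 1)
        flat[idx] = tc[r]
        if config.voxel_noise_sd > 0:
            flat[idx] += config.voxel_noise_sd * vox_rng.standard_normal((idx.size, T))
    vol = VoxelScan(
        data=data, brain_mask=mask, labels=labels, tr_seconds=config.tr_seconds,
    )
    scan = ParcellatedScan(
        values=tc,
        region_names=default_region_names(config),
        tr_seconds=config.tr_seconds,
    )
    return vol, scan, truth


def generate_cohort(
    config: SimulationConfig,
    cell_counts: dict[tuple[str, str], int] | None = None,
    overrides: dict[tuple[str, str], dict] | None = None,
    return_truth: bool = False,
):
    """Generate a full cohort of parcellated scans.

    Parameters
    ----------
    config
        Template configuration; ``config.seed`` is the master seed from
        which distinct per-scan sub-seeds are derived deterministically.
    cell_counts
        Scans per (virus, stimulation) cell; defaults to the unbalanced
        2 × 4 layout totalling 74 scans.
    overrides
        Optional per-cell config-field overrides, e.g. a larger
        ``qpp_amplitude`` for a stimulated cell.
    """
    if cell_counts is None:
        cell_counts = DEFAULT_CELL_COUNTS
    overrides = overrides or {}
    valid = set(itertools.product(VIRUS_LEVELS, STIM_LEVELS))
    for key in list(cell_counts) + list(overrides):
        if tuple(key) not in valid:
            raise InvalidConfigError(f"unknown group key {key!r}")
    for key, count in cell_counts.items():
        if count < 0:
            raise InvalidConfigError(f"negative count for {key!r}")

    total = sum(cell_counts.values())
    children = np.random.SeedSequence(config.seed).spawn(max(total, 1))
    scans, truths = [], []
    i = 0
    for virus, stim in itertools.product(VIRUS_LEVELS, STIM_LEVELS):
        count = cell_counts.get((virus, stim), 0)
        for j in range(count):
            sub_seed = int(children[i].generate_state(1)[0] & 0x7FFFFFFF)
            cfg = dataclasses.replace(
                config, seed=sub_seed, **overrides.get((virus, stim), {})
            )
            scan, truth = generate_parcellated(
                cfg,
                scan_id=f"{virus}_{stim}_{j:02d}",
                virus=virus,
                stimulation=stim,
            )
            scans.append(scan)
            truths.append(truth)
            i += 1
    logger.info("generated cohort of %d scans", len(scans))
    if return_truth:
        return scans, truths
    return scans
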