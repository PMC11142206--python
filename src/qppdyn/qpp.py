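"""Iterative sliding-template detection of quasi-periodic patterns (QPPs).

The detector starts from an observed window of the data as a seed
template, correlates the template with every window of the scan (the
sliding template correlation, STC), averages the windows at
supra-threshold STC peaks into a new template, and repeats until the
template stops changing (correlation between successive templates above
``convergence_cc`` for two consecutive iterations). Multiple seed windows
are tried and the converged run with the largest sum of supra-threshold
STC peaks is returned.

For group-level detection the scans of a group are temporally
concatenated; windows spanning scan boundaries are masked and never
averaged or counted. By default the global signal is regressed from each
scan before detection so that the anticorrelated (QPP2-like) pattern is
found rather than the global one.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import DegenerateInputError, InvalidConfigError, ParcellatedScan

logger = logging.getLogger(__name__)

_EPS = 1e-30


@dataclass
class QppParams:
    """Detection parameters.

    The window length ``window_frames`` sets the temporal extent of the
    pattern (default 8 frames = 10 s at TR 1.25 s). Early iterations use a
    permissive threshold (``threshold_initial`` for the first
    ``initial_threshold_iters`` iterations) and later iterations the
    standard event threshold (``threshold_final`` = 0.2).
    """

    window_frames: int = 8
    threshold_final: float = 0.2
    threshold_initial: float = 0.1
    initial_threshold_iters: int = 3
    convergence_cc: float = 0.9999
    max_iters: int = 50
    n_starts: int = 20
    start_seed: int = 0
    regress_gs_first: bool = True
    phase_align: bool = True

    def __post_init__(self) -> None:
        if self.window_frames < 2:
            raise InvalidConfigError("window_frames must be >= 2")
        for name in ("threshold_final", "threshold_initial"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise InvalidConfigError(f"{name} must be in (0, 1)")
        if not (0 < self.convergence_cc < 1):
            raise InvalidConfigError("convergence_cc must be in (0, 1)")
        if self.n_starts < 1 or self.max_iters < 1:
            raise InvalidConfigError("n_starts and max_iters must be positive")


@dataclass
class QppResult:
    """Converged template with its STC trace and detected events.

    ``boundary_mask[t]`` is True where the window starting at frame ``t``
    lies within a single scan of the concatenation; only those STC entries
    are meaningful. ``scan_offsets`` holds the start frame of each input
    scan in the concatenation (plus the total length as a sentinel).
    """

    template: np.ndarray | None
    stc: np.ndarray | None
    event_onsets: np.ndarray
    n_iterations: int
    converged: bool
    boundary_mask: np.ndarray | None
    window_frames: int
    scan_offsets: np.ndarray
    scan_ids: list[str]
    data: np.ndarray | None = None  # concatenated matrix the detector ran on
    start_frame: int | None = None

    def events_for_scan(self, scan: int | str) -> np.ndarray:
        """Detected onsets falling entirely within one scan, in local frames."""
        idx = self.scan_ids.index(scan) if isinstance(scan, str) else scan
        lo, hi = self.scan_offsets[idx], self.scan_offsets[idx + 1]
        ev = self.event_onsets
        sel = ev[(ev >= lo) & (ev + self.window_frames <= hi)]
        return sel - lo

    def stc_for_scan(self, scan: int | str) -> tuple[np.ndarray, np.ndarray]:
        """(stc slice, validity mask) for the windows starting inside one scan."""
        idx = self.scan_ids.index(scan) if isinstance(scan, str) else scan
        lo, hi = self.scan_offsets[idx], self.scan_offsets[idx + 1]
        hi = min(hi, len(self.stc))
        return self.stc[lo:hi], self.boundary_mask[lo:hi]


def regress_global_signal(mat: np.ndarray) -> np.ndarray:
    """Least-squares removal of the (z-scored) mean timecourse, with an
    intercept, from every region of a region × time matrix."""
    mat = np.asarray(mat, dtype=float)
    g = mat.mean(axis=0)
    sd = g.std(ddof=1)
    if sd <= 1e-12 * max(np.abs(mat).max(), 1e-300):
        raise DegenerateInputError("global signal has zero variance; cannot regress")
    g = (g - g.mean()) / sd
    X = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(X, mat.T, rcond=None)
    return (mat.T - X @ beta).T


def _window_sums(data: np.ndarray, W: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-window sums Σx and Σx² (template-independent, cacheable)."""
    win = sliding_window_view(data, W, axis=1)  # (R, L, W)
    return win.sum(axis=(0, 2)), (win**2).sum(axis=(0, 2))


def compute_stc(
    template: np.ndarray,
    scan_matrix: np.ndarray,
    _sums: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Sliding template correlation.

    ``stc[t]`` is the Pearson correlation between the flattened template
    (region × W) and the flattened window ``[t, t+W)`` of the scan matrix,
    over all regions. Zero-variance windows or a zero-variance template
    yield 0 (flagged via a warning).
    """
    template = np.asarray(template, dtype=float)
    data = np.asarray(scan_matrix, dtype=float)
    R, W = template.shape
    if data.shape[0] != R:
        raise InvalidConfigError("template and scan region counts differ")
    T = data.shape[1]
    if T < W:
        raise InvalidConfigError("scan shorter than template window")
    n = R * W
    tm = template.mean()
    tss = ((template - tm) ** 2).sum()
    L = T - W + 1
    if tss <= _EPS:
        warnings.warn("zero-variance template: STC set to 0")
        return np.zeros(L)
    win = sliding_window_view(data, W, axis=1)  # (R, L, W)
    s1, s2 = _sums if _sums is not None else _window_sums(data, W)
    cross = np.tensordot(template, win, axes=((0, 1), (0, 2)))
    cov = cross - tm * s1
    wvar = s2 - s1**2 / n
    wvar = np.maximum(wvar, 0.0)
    denom = np.sqrt(tss * wvar)
    bad = denom <= _EPS
    if np.any(bad):
        logger.debug("STC: %d zero-variance windows set to 0", int(bad.sum()))
    stc = np.where(bad, 0.0, cov / np.where(bad, 1.0, denom))
    return np.clip(stc, -1.0, 1.0)


def _pick_peaks(stc: np.ndarray, threshold: float, valid: np.ndarray,
                min_sep: int) -> np.ndarray:
    """Supra-threshold STC peaks with a minimum separation.

    Greedy selection by descending STC (stable, so earlier frames win
    ties); an accepted peak excludes frames closer than ``min_sep``. This
    realizes 'local maxima above threshold, at least a window apart'.
    """
    cand = np.flatnonzero(valid & (stc > threshold))
    if cand.size == 0:
        return np.empty(0, dtype=int)
    order = cand[np.argsort(-stc[cand], kind="stable")]
    blocked = np.zeros(stc.size, dtype=bool)
    taken: list[int] = []
    for t in order:
        if not blocked[t]:
            taken.append(int(t))
            blocked[max(0, t - min_sep + 1) : t + min_sep] = True
    return np.array(sorted(taken), dtype=int)


def _template_cc(a: np.ndarray, b: np.ndarray) -> float:
    x = a.ravel() - a.mean()
    y = b.ravel() - b.mean()
    d = np.linalg.norm(x) * np.linalg.norm(y)
    if d <= _EPS:
        return 0.0
    return float(np.dot(x, y) / d)


def _average_windows(data: np.ndarray, onsets: np.ndarray, W: int) -> np.ndarray:
    return np.mean([data[:, t : t + W] for t in onsets], axis=0)


def _phase_align(data: np.ndarray, onsets: np.ndarray, W: int,
                 valid: np.ndarray) -> int:
    """Shift (in frames) of the detected event alignment that maximizes the
    energy of the averaged template.

    The iteration's fixed points are indexed by an arbitrary time offset of
    the template within its window; among the shifted alignments of the
    same events, the one whose averaged template carries the most energy
    centers the pattern (coherent structure adds; noise cancels). Ties
    prefer the smaller absolute shift.
    """
    best_s, best_e = 0, -np.inf
    for s in sorted(range(-(W - 1), W), key=lambda v: (abs(v), v)):
        shifted = onsets + s
        keep = shifted[(shifted >= 0) & (shifted < len(valid))]
        keep = keep[valid[keep]]
        if keep.size == 0:
            continue
        tpl = _average_windows(data, keep, W)
        e = float((tpl**2).sum())
        if e > best_e * (1.0 + 1e-12) + 1e-300:
            best_s, best_e = s, e
    return best_s


def detect_qpp(scans: list, params: QppParams) -> QppResult:
    """Run the iterative template algorithm on a (group of) scan(s).

    Accepts :class:`ParcellatedScan` objects or bare region × time arrays.
    Returns an explicit no-pattern result (``converged=False``, empty
    events) if every start aborts without supra-threshold peaks.
    """
    W = params.window_frames
    mats, ids = [], []
    for i, s in enumerate(scans):
        if isinstance(s, ParcellatedScan):
            mats.append(np.asarray(s.values, dtype=float))
            ids.append(s.scan_id or f"scan{i:02d}")
        else:
            mats.append(np.asarray(s, dtype=float))
            ids.append(f"scan{i:02d}")
    if not mats:
        raise InvalidConfigError("empty scan list")
    R = mats[0].shape[0]
    if any(m.shape[0] != R for m in mats):
        raise InvalidConfigError("scans have different region counts")
    if sum(m.shape[1] for m in mats) < 2 * W:
        raise InvalidConfigError("total frames must be >= 2 * window_frames")
    if params.regress_gs_first:
        mats = [regress_global_signal(m) for m in mats]

    data = np.concatenate(mats, axis=1)
    T = data.shape[1]
    L = T - W + 1
    offsets = np.concatenate([[0], np.cumsum([m.shape[1] for m in mats])])
    valid = np.zeros(L, dtype=bool)
    for lo, hi in zip(offsets[:-1], offsets[1:]):
        if hi - lo >= W:
            valid[lo : hi - W + 1] = True

    sums = _window_sums(data, W)
    rng = np.random.default_rng(params.start_seed)
    valid_starts = np.flatnonzero(valid)
    n_starts = min(params.n_starts, valid_starts.size)
    starts = np.sort(rng.choice(valid_starts, size=n_starts, replace=False))

    best: dict | None = None
    for s0 in starts:
        tpl = data[:, s0 : s0 + W].copy()
        if ((tpl - tpl.mean()) ** 2).sum() <= _EPS:
            continue  # flat seed segment
        streak = 0
        converged = False
        n_it = 0
        for it in range(params.max_iters):
            thr = (
                params.threshold_initial
                if it < params.initial_threshold_iters
                else params.threshold_final
            )
            stc = compute_stc(tpl, data, _sums=sums)
            peaks = _pick_peaks(stc, thr, valid, W)
            if peaks.size == 0:
                break  # start aborts: no supra-threshold peaks
            new = _average_windows(data, peaks, W)
            cc = _template_cc(tpl, new)
            tpl = new
            n_it = it + 1
            streak = streak + 1 if cc > params.convergence_cc else 0
            if streak >= 2:
                converged = True
                break
        if not converged:
            continue
        stc = compute_stc(tpl, data, _sums=sums)
        peaks = _pick_peaks(stc, params.threshold_final, valid, W)
        score = float(stc[peaks].sum())
        if best is None or score > best["score"]:
            best = {
                "tpl": tpl, "peaks": peaks, "score": score,
                "n_it": n_it, "start": int(s0),
            }

    if best is None:
        logger.info("QPP detection: all %d starts aborted (no pattern)", n_starts)
        return QppResult(
            template=None, stc=None, event_onsets=np.empty(0, dtype=int),
            n_iterations=0, converged=False, boundary_mask=valid,
            window_frames=W, scan_offsets=offsets, scan_ids=ids, data=data,
        )

    tpl, peaks = best["tpl"], best["peaks"]
    if params.phase_align and peaks.size:
        shift = _phase_align(data, peaks, W, valid)
        if shift != 0:
            shifted = peaks + shift
            keep = shifted[(shifted >= 0) & (shifted < L)]
            keep = keep[valid[keep]]
            if keep.size:
                tpl = _average_windows(data, keep, W)
    stc = compute_stc(tpl, data, _sums=sums)
    events = _pick_peaks(stc, params.threshold_final, valid, W)
    return QppResult(
        template=tpl, stc=stc, event_onsets=events,
        n_iterations=best["n_it"], converged=True, boundary_mask=valid,
        window_frames=W, scan_offsets=offsets, scan_ids=ids, data=data,
        start_frame=best["start"],
    )


def fraction_above_threshold(
    stc: np.ndarray, thr: float = 0.2, mode: str = "signed",
    valid: np.ndarray | None = None,
) -> float:
    """Proportion of unmasked STC entries beyond the event threshold.

    ``mode='signed'`` counts stc > thr; ``mode='absolute'`` counts
    |stc| > thr.
    """
    stc = np.asarray(stc, dtype=float)
    if stc.size == 0:
        raise InvalidConfigError("stc is empty")
    if valid is not None:
        stc = stc[np.asarray(valid, dtype=bool)]
        if stc.size == 0:
            raise InvalidConfigError("no unmasked stc entries")
    if mode == "signed":
        return float(np.mean(stc > thr))
    if mode == "absolute":
        return float(np.mean(np.abs(stc) > thr))
    raise InvalidConfigError(f"unknown mode {mode!r}")


def stc_histogram(
    stc: np.ndarray, bin_width: float = 0.05,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of STC values over [-1, 1].

    Returns (bin_edges, counts); counts sum to the number of unmasked
    entries (the last bin includes its right edge, per numpy convention).
    """
    stc = np.asarray(stc, dtype=float)
    if valid is not None:
        stc = stc[np.asarray(valid, dtype=bool)]
    if stc.size == 0:
        raise InvalidConfigError("no unmasked stc entries to histogram")
    n_bins = int(round(2.0 / bin_width))
    if not np.isclose(n_bins * bin_width, 2.0):
        raise InvalidConfigError("bin_width must divide the interval [-1, 1]")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(stc, bins=edges)
    return edges, counts


def cingulate_qpp_range(
    result: QppResult, scan: int | str, cingulate_ids: tuple[int, ...]
) -> float:
    """Max − min of the event-averaged cingulate waveform for one scan.

    The cingulate trace is the mean of the designated regions in the data
    the detector ran on (i.e. after any global-signal regression); its
    W-frame segments at the scan's detected events are averaged into one
    waveform whose peak-to-trough range is returned. Scans with zero
    detected events yield NaN (undefined; excluded from downstream ANOVA).
    """
    if result.data is None or not result.converged:
        raise InvalidConfigError("result carries no converged pattern")
    ids = list(cingulate_ids)
    if any(i < 0 or i >= result.data.shape[0] for i in ids):
        raise InvalidConfigError("cingulate region id out of range")
    idx = result.scan_ids.index(scan) if isinstance(scan, str) else scan
    lo = result.scan_offsets[idx]
    local = result.events_for_scan(idx)
    if local.size == 0:
        logger.info("scan %s: zero QPP events; range undefined", result.scan_ids[idx])
        return float("nan")
    W = result.window_frames
    cing = result.data[ids].mean(axis=0)
    wave = np.mean([cing[lo + t : lo + t + W] for t in local], axis=0)
    return float(wave.max() - wave.min())
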