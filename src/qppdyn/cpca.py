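"""Complex PCA of analytic-signal BOLD timecourses.

Each region's z-scored timecourse is lifted to its analytic signal
(signal + i · Hilbert transform), computed per scan so that phase never
leaks across concatenation boundaries. PCA of the complex time × region
matrix then yields components whose loadings carry both a magnitude and a
relative phase per region — a traveling wave appears as a phase ramp
across the loading of a single component.

The first component of resting-state data typically captures the global
signal and the second the anticorrelated network pattern; the incidence
statistic asks, frame by frame, which of the first K components
contributes the most reconstructed power.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .core import InvalidConfigError, ParcellatedScan

logger = logging.getLogger(__name__)


@dataclass
class CpcaResult:
    """Complex decomposition ``data ≈ scores @ loadings.conj().T``.

    ``loadings`` (region × K) has unit-norm columns; ``scores`` (time × K)
    carries the amplitude, so |scores[t, k]|² is component k's share of
    reconstructed power at frame t. ``eigenvalues`` are the per-component
    variances (descending); ``variance_fraction`` is relative to the total
    variance of the complex data (all components, so it sums to 1 only
    when K is the full rank).
    """

    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    total_variance: float
    scan_offsets: np.ndarray
    scan_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.conj().T


def analytic_signal(scan, normalize: bool = True) -> np.ndarray:
    """Region × time complex analytic signal of one scan.

    With ``normalize=True`` (the default) timecourses are z-scored first
    (sample SD), enforcing the unit-variance convention the decomposition
    assumes; the real part of each output row then equals the z-scored
    input exactly — which is the input itself when it is already z-scored.
    The imaginary part is the Hilbert transform, computed within the scan
    only (never across concatenation boundaries). Constant rows become
    zero rows (flagged).
    """
    mat = scan.values if isinstance(scan, ParcellatedScan) else np.asarray(scan, float)
    mat = np.atleast_2d(mat).astype(float)
    if normalize:
        mean = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, ddof=1, keepdims=True)
        flat = sd[:, 0] == 0
        if np.any(flat):
            warnings.warn(f"{int(flat.sum())} constant timecourse(s) set to zero")
        sd = np.where(sd == 0, 1.0, sd)
        z = (mat - mean) / sd
        z[flat] = 0.0
    else:
        z = mat
    return z + 1j * np.imag(hilbert(z, axis=1))


def complex_pca(data, K: int = 3) -> CpcaResult:
    """PCA of complex analytic-signal data.

    Parameters
    ----------
    data
        One region × time complex matrix, or a list of them (one per
        scan; they are concatenated along time — Hilbert transforms must
        already have been taken per scan).
    K
        Number of components to retain. Requests beyond the numerical rank
        are truncated with a warning.
    """
    mats = data if isinstance(data, (list, tuple)) else [data]
    arrs, ids = [], []
    for i, m in enumerate(mats):
        a = np.asarray(m)
        if isinstance(m, tuple):
            raise InvalidConfigError("pass matrices, not tuples")
        arrs.append(a)
        ids.append(f"scan{i:02d}")
    R = arrs[0].shape[0]
    if any(a.shape[0] != R for a in arrs):
        raise InvalidConfigError("scans have different region counts")
    Z = np.concatenate([a.T for a in arrs], axis=0)  # time × region
    T = Z.shape[0]
    if K < 1 or K > min(T, R):
        raise InvalidConfigError("K must satisfy 1 <= K <= min(time, regions)")
    offsets = np.concatenate([[0], np.cumsum([a.shape[1] for a in arrs])])

    U, S, Vh = np.linalg.svd(Z, full_matrices=False)
    tol = S[0] * max(Z.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int(np.sum(S > tol))
    if K > rank:
        warnings.warn(f"K={K} exceeds numerical rank {rank}; truncating")
        K = max(rank, 1)
    loadings = Vh.conj().T[:, :K]
    scores = U[:, :K] * S[:K]
    eigenvalues = S[:K] ** 2 / T
    total_var = float(np.sum(np.abs(Z) ** 2) / T)
    var_frac = S[:K] ** 2 / np.sum(S**2)
    return CpcaResult(
        loadings=loadings,
        scores=scores,
        eigenvalues=eigenvalues,
        variance_fraction=var_frac,
        total_variance=total_var,
        scan_offsets=offsets,
        scan_ids=ids,
    )


def component_incidence(
    result: CpcaResult,
    K: int = 3,
    edge_exclude: int = 5,
    scan_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Fraction of each scan's frames dominated by each of the first K
    components.

    A frame is dominated by the component with the largest |score|²
    (its share of reconstructed power at that frame); exact ties go to the
    lower-index component and are logged. The first and last
    ``edge_exclude`` frames of each scan are excluded to avoid Hilbert
    edge artifacts. Per scan the K fractions sum to 1.
    """
    if K < 1:
        raise InvalidConfigError("K must be positive")
    if result.n_components < K:
        # upstream rank truncation can leave fewer components; the missing
        # ones dominate no frames, so clamp rather than fail
        logger.info("incidence: clamping K=%d to %d components", K,
                    result.n_components)
        K = result.n_components
    power = np.abs(result.scores[:, :K]) ** 2
    ids = scan_ids if scan_ids is not None else result.scan_ids
    rows = []
    n_ties = 0
    for i, (lo, hi) in enumerate(zip(result.scan_offsets[:-1],
                                     result.scan_offsets[1:])):
        a, b = lo + edge_exclude, hi - edge_exclude
        if b <= a:
            raise InvalidConfigError("edge_exclude leaves no frames in a scan")
        p = power[a:b]
        dom = np.argmax(p, axis=1)  # argmax takes the lowest index on ties
        sorted_p = np.sort(p, axis=1)
        n_ties += int(np.sum((sorted_p[:, -1] == sorted_p[:, -2])
                             & (sorted_p[:, -1] > 0))) if K > 1 else 0
        row = {"scan_id": ids[i]}
        for k in range(K):
            row[f"component_{k + 1}"] = float(np.mean(dom == k))
        rows.append(row)
    if n_ties:
        logger.info("incidence: %d exact dominance ties (lowest component wins)",
                    n_ties)
    return pd.DataFrame(rows)


def reconstruct_component_pattern(
    result: CpcaResult, k: int, n_phase_bins: int = 8
) -> np.ndarray:
    """Real-part snapshots of component ``k`` (1-based) across one cycle of
    its score phase.

    Column ``j`` is Re(a · e^{iθ_j} · conj(loadings[:, k])) with
    θ_j = 2πj / n_phase_bins and amplitude a = RMS |score|, matching the
    reconstruction convention ``scores @ loadings.conj().T``. For a
    traveling-wave component, adjacent columns are shifted versions of the
    same spatial profile.
    """
    if not (1 <= k <= result.n_components):
        raise InvalidConfigError(f"component {k} not in result")
    if n_phase_bins < 1:
        raise InvalidConfigError("n_phase_bins must be positive")
    load = result.loadings[:, k - 1]
    amp = float(np.sqrt(np.mean(np.abs(result.scores[:, k - 1]) ** 2)))
    thetas = 2.0 * np.pi * np.arange(n_phase_bins) / n_phase_bins
    return np.real(amp * np.exp(1j * thetas)[None, :] * np.conj(load)[:, None])
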