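"""Global signal computation and its spatial correlation distribution.

The global signal (GS) of a scan is the average of all in-brain
timecourses, z-scored. Its spatial "distribution" is the Pearson
correlation of every voxel (or region) with the GS; computed either on
the temporal concatenation of all scans in a group (one map per group) or
per scan (one r per region per scan, the substrate of the group ANOVA).
The cingulate metric averages the correlation values of the designated
cingulate regions for each scan.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .core import (
    DegenerateInputError,
    InvalidConfigError,
    ParcellatedScan,
    VoxelScan,
    check_same_parcellation,
)

logger = logging.getLogger(__name__)

_ZERO_VAR_RTOL = 1e-12


def _in_brain_matrix(scan) -> np.ndarray:
    if isinstance(scan, ParcellatedScan):
        return scan.values
    if isinstance(scan, VoxelScan):
        return scan.data[scan.brain_mask]
    raise TypeError(f"unsupported scan type {type(scan).__name__}")


def compute_global_signal(scan) -> np.ndarray:
    """Mean in-brain timecourse, z-scored (sample SD).

    Raises
    ------
    DegenerateInputError
        If the averaged trace has (numerically) zero variance, e.g. when
        regions cancel perfectly.
    """
    mat = _in_brain_matrix(scan)
    if mat.shape[0] < 1:
        raise InvalidConfigError("need at least one in-brain timecourse")
    g = mat.mean(axis=0)
    sd = g.std(ddof=1)
    scale = np.abs(mat).max()
    if sd <= _ZERO_VAR_RTOL * max(scale, 1e-300):
        raise DegenerateInputError("global signal has zero variance")
    return (g - g.mean()) / sd


def pearson_to_trace(mat: np.ndarray, trace: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``mat`` with ``trace``; zero-variance rows
    get r = 0 with a warning (flagged)."""
    mat = np.asarray(mat, dtype=float)
    t = trace - trace.mean()
    tn = np.linalg.norm(t)
    xc = mat - mat.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    flat = xn <= _ZERO_VAR_RTOL * max(np.abs(mat).max(), 1e-300)
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} zero-variance timecourse(s): r set to 0")
    denom = np.where(flat, 1.0, xn) * tn
    r = (xc @ t) / denom
    r[flat] = 0.0
    return np.clip(r, -1.0, 1.0)


def gs_correlation_map(scans: list, per_scan: bool = False):
    """Spatial distribution of the global signal.

    Parameters
    ----------
    scans
        Parcellated scans sharing one parcellation and TR. Scans are
        grouped by their (virus, stimulation) labels.
    per_scan
        If False (concatenated mode): temporally concatenate the scans and
        the per-scan z-scored global signals of each group, and correlate
        each region's concatenated timecourse with the concatenated GS —
        one map per group. If True: one r per region per scan, returned as
        a long-format table (the ANOVA substrate).

    Returns
    -------
    dict[(virus, stimulation) -> np.ndarray] in concatenated mode, or a
    :class:`pandas.DataFrame` with columns scan_id, virus, stimulation,
    region, region_name, r in per-scan mode.
    """
    check_same_parcellation(scans)
    if per_scan:
        rows = []
        for scan in scans:
            g = compute_global_signal(scan)
            r = pearson_to_trace(scan.values, g)
            for i, name in enumerate(scan.region_names):
                rows.append(
                    {
                        "scan_id": scan.scan_id,
                        "virus": scan.virus,
                        "stimulation": scan.stimulation,
                        "region": i,
                        "region_name": name,
                        "r": r[i],
                    }
                )
        return pd.DataFrame(rows)

    groups: dict[tuple, list[ParcellatedScan]] = {}
    for scan in scans:
        groups.setdefault(scan.group, []).append(scan)
    maps = {}
    for group, members in groups.items():
        data = np.concatenate([s.values for s in members], axis=1)
        gs = np.concatenate([compute_global_signal(s) for s in members])
        maps[group] = pearson_to_trace(data, gs)
    return maps


def cingulate_gs_metric(
    per_scan_table: pd.DataFrame, cingulate_ids: tuple[int, ...]
) -> pd.DataFrame:
    """Mean GS-correlation over the cingulate regions, one value per scan.

    Returns a table with columns scan_id, virus, stimulation, value.
    """
    ids = list(cingulate_ids)
    if not ids:
        raise InvalidConfigError("cingulate_ids must be nonempty")
    present = set(per_scan_table["region"].unique())
    missing = [i for i in ids if i not in present]
    if missing:
        raise InvalidConfigError(f"cingulate region ids {missing} not in table")
    sub = per_scan_table[per_scan_table["region"].isin(ids)]
    out = (
        sub.groupby(["scan_id", "virus", "stimulation"], sort=False, dropna=False)["r"]
        .mean()
        .reset_index()
        .rename(columns={"r": "value"})
    )
    return out
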