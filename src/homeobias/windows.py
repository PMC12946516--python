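"""Window-based read-depth analyses.

Two consumers: chromosome assignment of disomic-addition (DA) lines from
skim-seq depth in 50 Mb windows (normalised to the genome-wide median), and
centromere-midpoint detection from CENH3 ChIP depth in 1 Mb windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import logger


def window_means(depth_table: pd.DataFrame, window_bp: int) -> pd.DataFrame:
    """Mean depth in fixed windows tiled from position 0.

    ``depth_table`` holds per-bin depths (chrom, pos_bin = bin start, depth);
    the last window of each chromosome is truncated at the last covered bin.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    df = depth_table.copy()
    df["window_index"] = df["pos_bin"] // window_bp
    out = (
        df.groupby(["chrom", "window_index"], sort=True)
        .agg(mean_depth=("depth", "mean"), last_bin=("pos_bin", "max"))
        .reset_index()
    )
    # infer the bin width to place the truncated end of the last window
    bin_bp = _infer_bin(depth_table)
    out["start"] = out["window_index"] * window_bp
    out["end"] = np.minimum((out["window_index"] + 1) * window_bp, out["last_bin"] + bin_bp)
    return out[["chrom", "window_index", "start", "end", "mean_depth"]]


def _infer_bin(depth_table: pd.DataFrame) -> int:
    pos = np.sort(depth_table["pos_bin"].unique())
    if len(pos) < 2:
        return 1
    return int(np.min(np.diff(pos)))


def normalize_to_median(coverage: pd.DataFrame) -> pd.DataFrame:
    """Divide every window mean by the genome-wide median of window means."""
    if len(coverage) == 0:
        raise ValueError("empty window set")
    med = float(np.median(coverage["mean_depth"]))
    if med == 0:
        raise ValueError("genome-wide median depth is zero")
    out = coverage.copy()
    out["norm_depth"] = out["mean_depth"] / med
    return out


def assign_addition_line(coverage: pd.DataFrame, fold_threshold: float = 1.5) -> str | None:
    """Chromosome with the highest median normalised depth, if elevated.

    Returns None (with a warning) when no chromosome reaches
    ``fold_threshold``; an added chromosome pair roughly doubles coverage.
    """
    if "norm_depth" not in coverage:
        coverage = normalize_to_median(coverage)
    med = coverage.groupby("chrom")["norm_depth"].median()
    best = med.idxmax()
    if med[best] < fold_threshold:
        logger.warning(
            "no chromosome reaches fold threshold %.2f (best %s at %.2f)",
            fold_threshold,
            best,
            med[best],
        )
        return None
    return str(best)


@dataclass
class CentromereCall:
    chrom: str
    midpoints: list  # bp positions (window centers), sorted
    peak_heights: list
    n_peaks: int
    flagged: bool = False  # True when no peak qualified


def centromere_midpoints(
    depth_table: pd.DataFrame,
    window_bp: int = 1_000_000,
    min_prominence: float | None = None,
    min_height: float | None = None,
    midpoint_mode: str = "summit",
) -> dict[str, CentromereCall]:
    """Local maxima of the per-chromosome window-depth profile.

    A window qualifies as a centromere peak when its normalised depth
    reaches ``min_height`` (default: chromosome median + 5 robust standard
    deviations, the MAD scaled by 1.4826) and its prominence reaches
    ``min_prominence`` (default: 3 robust standard deviations).  The height
    floor rejects noise excursions of a flat background; the prominence
    floor separates closely spaced double centromeres into distinct calls.
    Terminal windows are ineligible.  The reported midpoint is the center
    of the summit window, or the depth-weighted centroid of the peak's
    neighbourhood with ``midpoint_mode='centroid'``.
    """
    if midpoint_mode not in ("summit", "centroid"):
        raise ValueError("midpoint_mode must be 'summit' or 'centroid'")
    cov = normalize_to_median(window_means(depth_table, window_bp))
    calls: dict[str, CentromereCall] = {}
    for chrom, sub in cov.groupby("chrom", sort=True):
        sub = sub.sort_values("window_index")
        prof = sub["norm_depth"].to_numpy()
        med = float(np.median(prof))
        rsd = 1.4826 * float(np.median(np.abs(prof - med)))
        span = float(prof.max() - prof.min())
        # noiseless background makes the MAD collapse; fall back to a
        # fraction of the profile's dynamic range
        floor = 0.1 * span
        prom = min_prominence if min_prominence is not None else max(3.0 * rsd, floor)
        height = min_height if min_height is not None else med + max(5.0 * rsd, floor)
        if span == 0:
            idx = np.array([], dtype=int)  # flat profile: nothing to call
        else:
            idx, _ = find_peaks(prof, height=height, prominence=prom or None)
        centers = sub["start"].to_numpy() + window_bp // 2
        if midpoint_mode == "summit":
            mids = [int(centers[i]) for i in idx]
        else:
            mids = []
            for i in idx:
                lo, hi = max(0, i - 3), min(len(prof), i + 4)
                w = np.clip(prof[lo:hi] - np.median(prof), 0, None)
                mids.append(int(np.average(centers[lo:hi], weights=w + 1e-12)))
        heights = [float(prof[i]) for i in idx]
        calls[chrom] = CentromereCall(
            chrom=chrom,
            midpoints=mids,
            peak_heights=heights,
            n_peaks=len(mids),
            flagged=len(mids) == 0,
        )
        if len(mids) == 0:
            logger.warning("no centromere peak found on %s", chrom)
    return calls
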