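"""Repair of centimorgan positions on a SNP annotation.

Array-vendor annotation files routinely carry unusable genetic positions:
empty cells, zeros, and values that break monotonicity with physical order.
Those are flagged and replaced by linear interpolation in physical coordinates
between the nearest valid flanking markers, so that every downstream genetic
length (HH cutoffs, region sizes in cM) is well defined.

"Inconsistent" is operationalised as: not on the longest non-decreasing
subsequence of the otherwise-valid cM values — the minimal set of repairs that
restores monotonicity.  A zero at a chromosome's first marker is kept as a
valid chromosome-start anchor.  Beyond the outermost valid markers the repair
is constant (no linear extrapolation), which keeps cM non-negative.
"""

from __future__ import annotations

from bisect import bisect_right

import numpy as np
import pandas as pd

from .genotypes import natural_chrom_key


class MapOrderError(ValueError):
    pass


class InterpolationError(ValueError):
    pass


def _longest_nondecreasing(values: np.ndarray) -> np.ndarray:
    """Indices (into ``values``) of one longest non-decreasing subsequence.

    Ties are resolved in favour of the earliest indices, so that when a later
    value contradicts an already-accepted one it is the later value that gets
    flagged (first-seen wins).
    """
    n = len(values)
    if n == 0:
        return np.empty(0, dtype=np.intp)
    tails: list[float] = []     # smallest tail value of a subsequence of each length
    by_len_idx: list[list[int]] = []
    by_len_val: list[list[float]] = []   # strictly decreasing within each length
    for i, v in enumerate(values):
        j = bisect_right(tails, v)
        if j == len(tails):
            tails.append(v)
            by_len_idx.append([])
            by_len_val.append([])
        else:
            tails[j] = v
        by_len_idx[j].append(i)
        by_len_val[j].append(v)
    # walk lengths downward, at each step the earliest index whose value fits
    cur = by_len_idx[-1][0]
    cur_val = values[cur]
    out = [cur]
    for k in range(len(tails) - 2, -1, -1):
        vals = by_len_val[k]
        lo, hi = 0, len(vals)
        while lo < hi:                       # leftmost value <= cur_val
            mid = (lo + hi) // 2
            if vals[mid] <= cur_val:
                hi = mid
            else:
                lo = mid + 1
        cur = by_len_idx[k][lo]
        cur_val = values[cur]
        out.append(cur)
    return np.array(out[::-1], dtype=np.intp)


def classify_invalid(
    pos_bp: np.ndarray, cm: np.ndarray, *, keep_zero_anchor: bool = True
) -> np.ndarray:
    """Boolean mask of *valid* cM values for one chromosome sorted by position.

    Invalid: NaN, exactly zero (except, optionally, at the chromosome's first
    marker), or off the longest non-decreasing subsequence of the remaining
    candidates.
    """
    pos_bp = np.asarray(pos_bp)
    cm = np.asarray(cm, dtype=float)
    if np.any(np.diff(pos_bp) <= 0):
        raise MapOrderError("positions must be strictly increasing within a chromosome")
    candidate = ~np.isnan(cm)
    zero = candidate & (cm == 0.0)
    if keep_zero_anchor and len(cm) and zero[0]:
        zero[0] = False
    candidate &= ~zero
    idx = np.flatnonzero(candidate)
    valid = np.zeros(len(cm), dtype=bool)
    if len(idx):
        keep = idx[_longest_nondecreasing(cm[idx])]
        valid[keep] = True
    return valid


def interpolate_cm(
    pos_bp: np.ndarray, cm: np.ndarray, valid: np.ndarray | None = None
) -> np.ndarray:
    """Fill invalid cM by linear interpolation in bp between valid flanks.

    Points outside the outermost valid markers take the nearest valid value
    (constant extrapolation).  Requires >= 2 valid points.
    """
    pos_bp = np.asarray(pos_bp, dtype=float)
    cm = np.asarray(cm, dtype=float)
    if valid is None:
        valid = classify_invalid(pos_bp, cm)
    valid = np.asarray(valid, dtype=bool)
    if valid.sum() < 2:
        raise InterpolationError("need at least two valid cM anchors to interpolate")
    out = cm.copy()
    bad = ~valid
    # np.interp clamps to end values outside the anchor range
    out[bad] = np.interp(pos_bp[bad], pos_bp[valid], cm[valid])
    return out


def repair_map(markers: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Repair the cM column of a marker annotation, chromosome by chromosome.

    Returns the repaired table and a boolean mask of repaired rows.
    """
    out = markers.copy().reset_index(drop=True)
    repaired = np.zeros(len(out), dtype=bool)
    for chrom in sorted(out["chrom"].unique(), key=natural_chrom_key):
        rows = np.flatnonzero((out["chrom"] == chrom).to_numpy())
        pos = out.loc[rows, "pos_bp"].to_numpy()
        cm = out.loc[rows, "cm"].to_numpy(dtype=float)
        valid = classify_invalid(pos, cm)
        if valid.all():
            continue
        if valid.sum() < 2:
            raise InterpolationError(
                f"chromosome {chrom}: fewer than two valid cM anchors"
            )
        out.loc[rows, "cm"] = interpolate_cm(pos, cm, valid)
        repaired[rows] = ~valid
    return out, repaired
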