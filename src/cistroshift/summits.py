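"""Summit-to-nearest-summit distance geometry between two cistromes.

Peak summits of one factor are mapped to the nearest summit of the other
factor on the same chromosome.  Short-range (<= 400 bp by default) pairings
are summarized by their empirical CDF, median, and modal (binned) distance;
the modal separation in bp converts to a linear nm distance at 0.33 nm/bp,
the canonical rise per base of B-form DNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NM_PER_BP = 0.33


@dataclass
class SummitDistanceSet:
    """Per-query nearest-target summit distances (bp, same chromosome)."""

    distances: pd.DataFrame        # columns: window_id, chrom, pos, distance
    n_excluded: int                # queries on chromosomes with no target
    query_label: str = ""
    target_label: str = ""


def nearest_summit_distances(query: pd.DataFrame, target: pd.DataFrame,
                             query_label: str = "",
                             target_label: str = "") -> SummitDistanceSet:
    """Distance from each query summit to the nearest target summit.

    ``query`` / ``target`` carry columns (window_id, chrom, pos) as produced
    by :meth:`CistromeMatrix.summits`.  Queries on chromosomes with no
    target summit are excluded and counted.
    """
    if not len(target):
        warnings.warn("empty target summit set: all queries excluded")
        empty = query.iloc[0:0].assign(distance=np.array([], int))
        return SummitDistanceSet(empty, n_excluded=len(query),
                                 query_label=query_label,
                                 target_label=target_label)
    by_chrom = {c: np.sort(g["pos"].to_numpy(np.int64))
                for c, g in target.groupby("chrom")}
    out, excluded = [], 0
    for c, g in query.groupby("chrom", sort=False):
        t = by_chrom.get(c)
        if t is None:
            excluded += len(g)
            continue
        q = g["pos"].to_numpy(np.int64)
        idx = np.searchsorted(t, q)
        left = np.abs(q - t[np.clip(idx - 1, 0, len(t) - 1)])
        right = np.abs(t[np.clip(idx, 0, len(t) - 1)] - q)
        d = np.where(idx == 0, right, np.where(idx == len(t), left,
                                               np.minimum(left, right)))
        out.append(g.assign(distance=d))
    dist = (pd.concat(out, ignore_index=True) if out
            else query.iloc[0:0].assign(distance=np.array([], int)))
    return SummitDistanceSet(dist, n_excluded=excluded,
                             query_label=query_label,
                             target_label=target_label)


def summit_pair_summary(dset: SummitDistanceSet, short_cutoff: int = 400,
                        bin_width: int = 8) -> dict:
    """Summary of a summit-distance set.

    Emits the empirical CDF, the fraction of pairings at most ``short_cutoff``
    bp apart, medians of the short-range subset and the full set, and the
    modal distance: the center of the most populated histogram bin over
    (0, short_cutoff] at ``bin_width`` bp resolution (ties -> smallest bin).
    """
    d = np.sort(dset.distances["distance"].to_numpy())
    if len(d) == 0:
        raise ValueError("empty distance set")
    cdf = pd.DataFrame({"distance": d,
                        "cdf": np.arange(1, len(d) + 1) / len(d)})
    short = d[d <= short_cutoff]
    edges = np.arange(0, short_cutoff + bin_width, bin_width)
    counts, _ = np.histogram(short[short > 0], bins=edges)
    if counts.sum():
        k = int(np.argmax(counts))
        mode = float((edges[k] + edges[k + 1]) / 2)
    else:
        mode = None
    return {
        "n": int(len(d)),
        "n_excluded": dset.n_excluded,
        "short_cutoff_bp": short_cutoff,
        "bin_width_bp": bin_width,
        "fraction_short": float(len(short) / len(d)),
        "median_short_bp": float(np.median(short)) if len(short) else None,
        "median_all_bp": float(np.median(d)),
        "modal_short_bp": mode,
        "modal_short_nm": None if mode is None else bp_to_nm(mode),
        "cdf": cdf,
    }


def bp_to_nm(bp: float, nm_per_bp: float = NM_PER_BP) -> float:
    """Linear DNA contour length for a bp separation (0.33 nm per base)."""
    if bp < 0:
        raise ValueError("bp must be non-negative")
    return bp * nm_per_bp
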