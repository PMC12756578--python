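"""TSS-to-nearest-region distances with random-region nulls, and the
proximity-protection analysis.

Distances follow the reference interval tool's default convention
(`bedtools closest -d`-style): 0 when the TSS lies within a region, 1 for
bookended features, otherwise the bp separation + 1 on the upstream side /
the start - position gap on the downstream side; i.e. the number of bases
separating the features plus one, with overlap reported as zero.

The protection test asks whether genes whose TSS is within ``cutoff``
(default 30 kb) of a partner region show a different co-treatment
expression delta than more distant genes (two-sided Mann-Whitney U), after
optional exclusion of independently co-regulated genes and optional nesting
within proximity to a second region set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DistanceProfile:
    """Per-gene distance from TSS to the nearest region of a named set."""

    df: pd.DataFrame   # gene_id, chrom, pos, distance (NaN when undefined)
    label: str = ""

    def summary(self) -> dict:
        d = self.df["distance"]
        defined = d.dropna()
        return {"label": self.label, "n": len(d),
                "n_undefined": int(d.isna().sum()),
                "mean": float(defined.mean()) if len(defined) else None,
                "median": float(defined.median()) if len(defined) else None}


def nearest_region_distance(tss: pd.DataFrame, regions: pd.DataFrame,
                            label: str = "") -> DistanceProfile:
    """Distance from each TSS (gene_id, chrom, pos) to the nearest region
    (chrom, start, end).  Genes on chromosomes without regions get NaN."""
    if not len(regions) or not len(tss):
        if not len(regions):
            warnings.warn("empty region set: all distances undefined")
        return DistanceProfile(tss.assign(distance=np.nan), label)
    by_chrom = {}
    for c, g in regions.groupby("chrom"):
        g = g.sort_values("start", kind="stable")
        starts = g["start"].to_numpy(np.int64)
        ends_cummax = np.maximum.accumulate(g["end"].to_numpy(np.int64))
        by_chrom[c] = (starts, ends_cummax)
    out = []
    for c, g in tss.groupby("chrom", sort=False):
        pos = g["pos"].to_numpy(np.int64)
        if c not in by_chrom:
            out.append(g.assign(distance=np.nan))
            continue
        starts, ends = by_chrom[c]
        idx = np.searchsorted(starts, pos, side="right") - 1
        has_left = idx >= 0
        left_end = ends[np.clip(idx, 0, None)]
        inside = has_left & (left_end > pos)
        dist_left = np.where(has_left, pos - left_end + 1, np.iinfo(np.int64).max)
        has_right = idx + 1 < len(starts)
        dist_right = np.where(has_right,
                              starts[np.clip(idx + 1, 0, len(starts) - 1)] - pos,
                              np.iinfo(np.int64).max)
        d = np.minimum(dist_left, dist_right).astype(float)
        d[inside] = 0.0
        out.append(g.assign(distance=d))
    df = pd.concat(out, ignore_index=True)
    return DistanceProfile(df, label)


def generate_random_regions(n: int, chrom_sizes: dict[str, int], width: int,
                            seed: int | np.random.Generator) -> pd.DataFrame:
    """n random fixed-width regions, chromosome chosen proportional to its
    number of valid start positions, start uniform; reproducible under seed.
    Chromosomes shorter than ``width`` are excluded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    chroms = [(c, L - width + 1) for c, L in sorted(chrom_sizes.items())
              if L >= width]
    if not chroms:
        raise ValueError("no chromosome can hold a region of this width")
    weights = np.array([v for _, v in chroms], float)
    picks = rng.choice(len(chroms), size=n, p=weights / weights.sum())
    starts = np.array([rng.integers(0, chroms[i][1]) for i in picks])
    return pd.DataFrame({
        "window_id": [f"rand{i:05d}" for i in range(n)],
        "chrom": [chroms[i][0] for i in picks],
        "start": starts,
        "end": starts + width,
    })


def distance_profile_compare(real: dict[str, DistanceProfile],
                             random_profile: DistanceProfile) -> pd.DataFrame:
    """Per gene class, distance summary and a two-sample KS test of the real
    distance distribution against the random-region null."""
    rnd = random_profile.df["distance"].dropna().to_numpy()
    rows = []
    for cls, prof in real.items():
        d = prof.df["distance"].dropna().to_numpy()
        if len(d) == 0:
            rows.append({"gene_class": cls, "n": 0, "note": "no genes"})
            continue
        ks, p = (stats.ks_2samp(d, rnd) if len(rnd) else (np.nan, np.nan))
        rows.append({"gene_class": cls, "n": len(d),
                     "mean": float(np.mean(d)), "median": float(np.median(d)),
                     "random_mean": float(np.mean(rnd)) if len(rnd) else None,
                     "ks_stat": float(ks), "ks_p": float(p), "note": ""})
    return pd.DataFrame(rows)


@dataclass
class ProtectionResult:
    cutoff: int
    n_near: int
    n_far: int
    n_excluded: int
    n_outside_nest: int
    median_near: float | None
    median_far: float | None
    median_difference: float | None   # near - far; positive = near less reduced
    statistic: float | None
    p_value: float | None
    deltas_near: np.ndarray | None = None
    deltas_far: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "cutoff", "n_near", "n_far", "n_excluded", "n_outside_nest",
            "median_near", "median_far", "median_difference", "statistic",
            "p_value")}


def protection_test(deltas: pd.DataFrame, profile: DistanceProfile,
                    cutoff: int = 30_000,
                    exclude: set[str] | None = None,
                    nest_within: tuple[DistanceProfile, int] | None = None,
                    keep_deltas: bool = False) -> ProtectionResult:
    """Two-sided Mann-Whitney U comparison of co-treatment deltas between
    genes with TSS <= cutoff of the profile's regions and more distant genes.

    Genes with undefined distance cannot be "close" and join the far group.
    ``exclude`` removes genes first (e.g. independently co-regulated DEGs);
    ``nest_within`` restricts the analysis to genes within a second
    profile's cutoff before splitting on the main profile.
    """
    d = deltas.set_index("gene_id")["delta"]
    dist = profile.df.set_index("gene_id")["distance"].reindex(d.index)
    n_excluded = 0
    if exclude:
        keep = ~d.index.isin(exclude)
        n_excluded = int((~keep).sum())
        d, dist = d[keep], dist[keep]
    n_outside_nest = 0
    if nest_within is not None:
        nest_prof, nest_cut = nest_within
        nd = nest_prof.df.set_index("gene_id")["distance"].reindex(d.index)
        inside = (nd <= nest_cut).fillna(False)
        n_outside_nest = int((~inside).sum())
        d, dist = d[inside], dist[inside]
    near_mask = (dist <= cutoff).fillna(False)
    near, far = d[near_mask].to_numpy(), d[~near_mask].to_numpy()
    res = ProtectionResult(
        cutoff=cutoff, n_near=len(near), n_far=len(far),
        n_excluded=n_excluded, n_outside_nest=n_outside_nest,
        median_near=float(np.median(near)) if len(near) else None,
        median_far=float(np.median(far)) if len(far) else None,
        median_difference=None, statistic=None, p_value=None,
        deltas_near=near if keep_deltas else None,
        deltas_far=far if keep_deltas else None)
    if len(near) and len(far):
        res.median_difference = res.median_near - res.median_far
        u, p = stats.mannwhitneyu(near, far, alternative="two-sided")
        res.statistic, res.p_value = float(u), float(p)
    return res


def distance_trend(deltas: pd.DataFrame, profile: DistanceProfile,
                   bins: np.ndarray | list) -> tuple[pd.DataFrame, dict]:
    """Median co-treatment delta per distance bin plus the gene-level
    Spearman correlation between distance and delta."""
    merged = deltas.set_index("gene_id").join(
        profile.df.set_index("gene_id")["distance"]).dropna(
        subset=["distance"])
    bins = np.asarray(bins, float)
    if len(bins) < 3:
        raise ValueError("need >= 2 bins")
    merged["bin"] = pd.cut(merged["distance"], bins=bins)
    per_bin = (merged.groupby("bin", observed=True)["delta"]
               .agg(["count", "median"]).reset_index()
               .rename(columns={"count": "n"}))
    if merged["delta"].nunique() <= 1 or merged["distance"].nunique() <= 1:
        corr = {"spearman_rho": 0.0, "p": 1.0, "n": len(merged)}
    else:
        rho, p = stats.spearmanr(merged["distance"], merged["delta"])
        corr = {"spearman_rho": float(rho), "p": float(p), "n": len(merged)}
    return per_bin, corr
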