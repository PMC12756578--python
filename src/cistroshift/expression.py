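"""Expression dynamics: DEG calling, peak-time assignment, co-treatment
deltas, co-regulation enrichment, and per-group coupling.

A gene is differentially expressed (DEG) for a treatment at a time point
when its log2 fold ``b`` versus unstimulated satisfies |b| >= 1 at
FDR <= 0.05 (inclusive, configurable); it is a treatment-level DEG when
called at any time.  The co-treatment delta is b(co) - b(mono) evaluated at
the gene's mono-treatment peak time; >= +1 is "enhanced", <= -1 "reduced".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionTable


@dataclass(frozen=True)
class DegThresholds:
    min_abs_b: float = 1.0
    max_fdr: float = 0.05


def call_degs(table: ExpressionTable,
              thresholds: DegThresholds = DegThresholds()
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-record up/down/none calls plus per-(treatment, time) and
    treatment-level totals."""
    df = table.df.copy()
    sig = df["fdr"] <= thresholds.max_fdr
    df["direction"] = np.where(sig & (df["b"] >= thresholds.min_abs_b), "up",
                               np.where(sig & (df["b"] <= -thresholds.min_abs_b),
                                        "down", "none"))
    per_time = (df[df["direction"] != "none"]
                .groupby(["treatment", "time", "direction"])
                .size().rename("n").reset_index())
    called = df[df["direction"] != "none"]
    totals = (called.groupby(["treatment", "direction"])["gene"]
              .nunique().rename("n_genes").reset_index())
    counts = pd.concat([per_time.assign(level="per_time"),
                        totals.rename(columns={"n_genes": "n"})
                        .assign(time=np.nan, level="treatment")],
                       ignore_index=True)
    return df, counts


def deg_gene_set(calls: pd.DataFrame, treatment: str,
                 direction: str = "up") -> set[str]:
    """Genes called in the given direction at any time for a treatment."""
    m = (calls["treatment"] == treatment) & (calls["direction"] == direction)
    return set(calls.loc[m, "gene"])


def assign_peak_time(calls: pd.DataFrame, treatment: str,
                     direction: str = "up") -> pd.Series:
    """Peak time per gene: the significant time with maximal b (ties ->
    earliest time).  Genes with no significant time are omitted."""
    sub = calls[(calls["treatment"] == treatment)
                & (calls["direction"] == direction)]
    sub = sub.sort_values(["gene", "time"], kind="stable")
    idx = sub.groupby("gene")["b"].idxmax()  # first occurrence wins ties
    return sub.loc[idx].set_index("gene")["time"]


def cotreatment_delta(table: ExpressionTable, mono: str,
                      co: str = "co",
                      peak_times: pd.Series | None = None,
                      at_time: float | None = None,
                      enhanced_bound: float = 1.0) -> pd.DataFrame:
    """Per-gene co-treatment delta = b(co) - b(mono).

    Evaluated at each gene's mono-treatment peak time (``peak_times``), or at
    a fixed ``at_time``.  Genes lacking a co-treatment record at the chosen
    time are skipped and counted in ``df.attrs['n_skipped']``.
    """
    df = table.df
    piv = df.pivot_table(index=["gene", "time"], columns="treatment",
                        values="b", aggfunc="first")
    rows, skipped = [], 0
    if at_time is not None:
        genes = piv.index.get_level_values("gene").unique()
        times = pd.Series(at_time, index=genes)
    elif peak_times is not None:
        times = peak_times
    else:
        raise ValueError("provide peak_times or at_time")
    for gene, t in times.items():
        try:
            b_mono = piv.loc[(gene, t), mono]
            b_co = piv.loc[(gene, t), co]
        except KeyError:
            skipped += 1
            continue
        if pd.isna(b_mono) or pd.isna(b_co):
            skipped += 1
            continue
        delta = b_co - b_mono
        cat = ("enhanced" if delta >= enhanced_bound
               else "reduced" if delta <= -enhanced_bound else "unchanged")
        rows.append((gene, mono, t, float(b_mono), float(b_co),
                     float(delta), cat))
    out = pd.DataFrame(rows, columns=["gene_id", "mono", "time", "b_mono",
                                      "b_co", "delta", "category"])
    out.attrs["n_skipped"] = skipped
    return out


def coregulation_enrichment(set_a: set, set_b: set, universe: set) -> dict:
    """Exact hypergeometric enrichment of the overlap of two gene sets
    within a shared universe (both over- and under-enrichment tails)."""
    if not universe:
        raise ValueError("empty universe")
    a, b = set_a & universe, set_b & universe
    n_u, n_a, n_b = len(universe), len(a), len(b)
    k = len(a & b)
    expected = n_a * n_b / n_u
    hg = stats.hypergeom(n_u, n_a, n_b)
    p_over = float(hg.sf(k - 1))
    p_under = float(hg.cdf(k))
    return {"universe": n_u, "n_a": n_a, "n_b": n_b, "overlap": k,
            "expected": expected,
            "fold_enrichment": (k / expected) if expected > 0 else np.inf,
            "p_over": p_over, "p_under": p_under}


def group_coupling(deltas: pd.DataFrame, other_mono_b: pd.Series,
                   groups: pd.Series) -> pd.DataFrame:
    """Per peak-time group, Pearson r^2 between the other mono-treatment's b
    and the co-treatment delta (predictiveness of independent regulation)."""
    merged = deltas.set_index("gene_id").join(
        other_mono_b.rename("b_other")).join(groups.rename("group"))
    rows = []
    for g, sub in merged.groupby("group"):
        ok = sub[["b_other", "delta"]].dropna()
        if len(ok) < 3 or ok["b_other"].std() == 0 or ok["delta"].std() == 0:
            rows.append((g, len(ok), None, None))
            continue
        r, p = stats.pearsonr(ok["b_other"], ok["delta"])
        rows.append((g, len(ok), float(r ** 2), float(p)))
    return pd.DataFrame(rows, columns=["group", "n", "r2", "p"])
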