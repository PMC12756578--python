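"""Cistrome dynamics: significance calling, loss/gain/maintenance and
trend classification, overlap partitioning, and factor-coupling statistics.

A window is significantly bound by a factor under a condition when its
log2-normalized read count (binding intensity) is >= 4, its log2 fold change
versus unstimulated is >= 1, and its FDR is <= 0.05 (all bounds inclusive;
thresholds configurable).  Comparing a mono-treatment cistrome to the
co-treatment cistrome on the shared window set classifies each window as
lost (mono only), gained (co only), maintained (both) or never significant,
and the log2 intensity ratio co/mono yields a decreasing / unchanged /
increasing trend with inclusive +-0.5 bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CistromeMatrix, ValidationError


@dataclass(frozen=True)
class SignificanceThresholds:
    min_intensity: float = 4.0
    min_log2fc: float = 1.0
    max_fdr: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.max_fdr <= 1):
            raise ValidationError("max_fdr must be in (0, 1]")


DEFAULT_THRESHOLDS = SignificanceThresholds()


def call_significant(matrix: CistromeMatrix, factor: str, condition: str,
                     thresholds: SignificanceThresholds = DEFAULT_THRESHOLDS
                     ) -> set[str]:
    """Window ids meeting the occupancy-significance rule (all inclusive):
    intensity >= min_intensity, log2fc vs NS >= min_log2fc, fdr <= max_fdr."""
    df = matrix.df
    cols = [CistromeMatrix.col(factor, condition, f)
            for f in ("intensity", "log2fc", "fdr")]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"matrix lacks columns {missing}")
    m = ((df[cols[0]] >= thresholds.min_intensity)
         & (df[cols[1]] >= thresholds.min_log2fc)
         & (df[cols[2]] <= thresholds.max_fdr))
    return set(df.loc[m.fillna(False), "window_id"])


def classify_mono_vs_co(sig_mono: set[str], sig_co: set[str]) -> pd.DataFrame:
    """Lost / maintained / gained status per window of the mono-co union.

    lost = significant in mono only, gained = co only, maintained = both.
    """
    rows = [(w, "lost") for w in sig_mono - sig_co]
    rows += [(w, "maintained") for w in sig_mono & sig_co]
    rows += [(w, "gained") for w in sig_co - sig_mono]
    out = pd.DataFrame(rows, columns=["window_id", "status"])
    return out.sort_values("window_id", kind="stable").reset_index(drop=True)


def status_counts(classification: pd.DataFrame) -> dict[str, int]:
    c = classification["status"].value_counts()
    lost = int(c.get("lost", 0))
    maint = int(c.get("maintained", 0))
    gained = int(c.get("gained", 0))
    return {"mono": lost + maint, "co": maint + gained, "lost": lost,
            "maintained": maint, "gained": gained,
            "union": lost + maint + gained}


def classify_trend(matrix: CistromeMatrix, factor: str,
                   mono_condition: str, co_condition: str,
                   lo: float = -0.5, hi: float = 0.5,
                   thresholds: SignificanceThresholds = DEFAULT_THRESHOLDS
                   ) -> pd.DataFrame:
    """Trend over the union of mono- and co-significant windows.

    delta = co intensity - mono intensity (log2 scale, i.e. the log2 ratio of
    co to mono binding); decreasing if delta <= lo, increasing if delta >= hi,
    else unchanged.
    """
    sig_m = call_significant(matrix, factor, mono_condition, thresholds)
    sig_c = call_significant(matrix, factor, co_condition, thresholds)
    union = sig_m | sig_c
    df = matrix.df[matrix.df["window_id"].isin(union)]
    delta = (df[CistromeMatrix.col(factor, co_condition, "intensity")]
             - df[CistromeMatrix.col(factor, mono_condition, "intensity")])
    trend = np.where(delta <= lo, "decreasing",
                     np.where(delta >= hi, "increasing", "unchanged"))
    status = classify_mono_vs_co(sig_m, sig_c).set_index("window_id")["status"]
    out = pd.DataFrame({
        "window_id": df["window_id"].to_numpy(),
        "factor": factor,
        "status": status.reindex(df["window_id"]).to_numpy(),
        "trend": trend,
        "delta": delta.to_numpy(),
    })
    return out.sort_values("window_id", kind="stable").reset_index(drop=True)


def _pct(part: int, whole: int) -> float | None:
    """Percentage rounded to 1 decimal; None when the parent set is empty."""
    return None if whole == 0 else round(100.0 * part / whole, 1)


def overlap_partition(gbr: pd.DataFrame, rbr: pd.DataFrame) -> dict:
    """Partition each factor's mono and co cistrome by overlap with the other
    factor's cistrome in the same condition, with loss/gain rates per cell.

    ``gbr`` / ``rbr`` are status classifications from
    :func:`classify_mono_vs_co` (or :func:`classify_trend`) computed on one
    shared window universe; overlap is identity of window_id.  For each
    factor the report carries: the mono set split into windows overlapping /
    not overlapping the other factor's mono set, with the number and
    percentage lost in each split; and the co set split by the other factor's
    co set, with the number and percentage gained.  Percentages of empty
    parents are reported as None.
    """
    ids_g = set(gbr["window_id"])
    ids_r = set(rbr["window_id"])
    sets = {}
    for name, cls in (("G", gbr), ("R", rbr)):
        st = cls.set_index("window_id")["status"]
        mono = set(st[st.isin(["lost", "maintained"])].index)
        co = set(st[st.isin(["maintained", "gained"])].index)
        lost = set(st[st == "lost"].index)
        gained = set(st[st == "gained"].index)
        sets[name] = {"mono": mono, "co": co, "lost": lost, "gained": gained}

    if ids_g & ids_r != ids_g & ids_r:  # pragma: no cover - identity check
        raise ValidationError("classifications must share a window universe")

    mono_overlap = sets["G"]["mono"] & sets["R"]["mono"]
    co_overlap = sets["G"]["co"] & sets["R"]["co"]

    def _split(own: str, other: str, which: str) -> dict:
        """Split own-factor `which` set ('mono'/'co') by overlap with the
        other factor's same-condition set; rate of loss (mono) / gain (co)."""
        own_set = sets[own][which]
        other_set = sets[other][which]
        event = sets[own]["lost" if which == "mono" else "gained"]
        inside = own_set & other_set
        outside = own_set - other_set
        ev_in, ev_out = len(event & inside), len(event & outside)
        return {
            "parent": len(own_set),
            "overlapping": len(inside),
            "non_overlapping": len(outside),
            "event_overlapping": ev_in,
            "event_non_overlapping": ev_out,
            "pct_overlapping": _pct(ev_in, len(inside)),
            "pct_non_overlapping": _pct(ev_out, len(outside)),
        }

    report = {
        "mono_overlap": len(mono_overlap),
        "co_overlap": len(co_overlap),
        "co_overlap_share_of_G": _pct(len(co_overlap), len(sets["G"]["co"])),
        "co_overlap_share_of_R": _pct(len(co_overlap), len(sets["R"]["co"])),
        "G": {"loss": _split("G", "R", "mono"),
              "gain": _split("G", "R", "co"),
              **status_counts(gbr)},
        "R": {"loss": _split("R", "G", "mono"),
              "gain": _split("R", "G", "co"),
              **status_counts(rbr)},
    }
    # events in the overlap, expressed against both candidate denominators
    # (the mono-overlap parent and the co-overlap parent), since either can
    # be the relevant reference set depending on the question asked
    for name in ("G", "R"):
        ev = report[name]["loss"]["event_overlapping"]
        report[name]["loss"]["pct_overlapping_alt_co_denominator"] = _pct(
            ev, len(co_overlap))
    # consistency: split cells must sum to the parent cistromes
    for name in ("G", "R"):
        for which, ev in (("loss", "lost"), ("gain", "gained")):
            cell = report[name][which]
            assert cell["overlapping"] + cell["non_overlapping"] == cell["parent"]
            assert (cell["event_overlapping"] + cell["event_non_overlapping"]
                    == len(sets[name][ev]))
    return report


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def factor_coupling_stats(matrix: CistromeMatrix, trends: pd.DataFrame,
                          own_factor: str, other_factor: str,
                          co_condition: str = "co",
                          rnap2_factor: str | None = None) -> dict:
    """Coupling between one factor's co-treatment intensity shift and the
    other factor's binding at the same windows.

    Returns a dict with three tidy tables:

    ``group_tests`` — per trend group, the other factor's co-treatment
    intensity distribution, all pairwise two-sided Mann-Whitney tests between
    groups, and within-group paired Wilcoxon tests of the other factor's
    mono vs co intensity.
    ``correlation`` — Spearman rho between the own-factor delta and the other
    factor's co-treatment intensity across all trend windows.
    ``rnap2`` — when an RNAP2 block is present, per trend group the RNAP2
    intensity per condition with a Kruskal-Wallis omnibus and pairwise
    Mann-Whitney post hoc tests (BH-adjusted), Dunn-style.
    """
    df = matrix.df.set_index("window_id")
    t = trends.set_index("window_id")
    other_co = df.loc[t.index, CistromeMatrix.col(other_factor, co_condition,
                                                  "intensity")]
    groups = {g: sub.index for g, sub in t.groupby("trend")}

    rows = []
    names = sorted(groups)
    for g in names:
        v = other_co.loc[groups[g]].dropna()
        rows.append({"comparison": f"{g}:summary", "group": g,
                     "n": len(v), "median": float(v.median()) if len(v) else None,
                     "stat": None, "p": None})
    pvals, prows = [], []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            v1 = other_co.loc[groups[g1]].dropna()
            v2 = other_co.loc[groups[g2]].dropna()
            if len(v1) < 2 or len(v2) < 2:
                prows.append({"comparison": f"{g1} vs {g2}", "group": None,
                              "n": len(v1) + len(v2), "median": None,
                              "stat": None, "p": None})
                continue
            u, p = stats.mannwhitneyu(v1, v2, alternative="two-sided")
            prows.append({"comparison": f"{g1} vs {g2}", "group": None,
                          "n": len(v1) + len(v2), "median": None,
                          "stat": float(u), "p": float(p)})
            pvals.append(p)
    adj = iter(_bh(np.array(pvals)))
    for r in prows:
        r["p_bh"] = float(next(adj)) if r["p"] is not None else None
    rows += prows
    # within-group paired mono-vs-co shift of the other factor
    mono_cond = {"GR": "bud", "RELA": "il1b"}.get(other_factor, "ns")
    c_mono = CistromeMatrix.col(other_factor, mono_cond, "intensity")
    if c_mono in df.columns:
        for g in names:
            sub = df.loc[groups[g]]
            a = sub[c_mono].to_numpy(float)
            b = sub[CistromeMatrix.col(other_factor, co_condition,
                                       "intensity")].to_numpy(float)
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 2 or np.allclose(a[ok], b[ok]):
                rows.append({"comparison": f"{g}:paired mono vs co",
                             "group": g, "n": int(ok.sum()), "median": None,
                             "stat": None, "p": None})
                continue
            w, p = stats.wilcoxon(a[ok], b[ok])
            rows.append({"comparison": f"{g}:paired mono vs co", "group": g,
                         "n": int(ok.sum()), "median": None,
                         "stat": float(w), "p": float(p)})
    group_tests = pd.DataFrame(rows)

    ok = ~(t["delta"].isna() | other_co.isna())
    if ok.sum() >= 3:
        rho, p = stats.spearmanr(t.loc[ok, "delta"], other_co[ok])
        correlation = {"spearman_rho": float(rho), "p": float(p),
                       "n": int(ok.sum())}
    else:
        correlation = {"spearman_rho": None, "p": None, "n": int(ok.sum())}

    rnap2 = None
    if rnap2_factor is not None:
        rnap2_rows, pv = [], []
        for cond in ("ns", "bud", "il1b", co_condition):
            col = CistromeMatrix.col(rnap2_factor, cond, "intensity")
            if col not in df.columns:
                continue
            samples = [df.loc[groups[g], col].dropna() for g in names]
            for g, v in zip(names, samples):
                rnap2_rows.append({"condition": cond, "group": g, "n": len(v),
                                   "median": float(v.median()) if len(v) else None,
                                   "test": "summary", "p": None})
            usable = [v for v in samples if len(v) >= 2]
            if len(usable) >= 2:
                h, p_kw = stats.kruskal(*usable)
                rnap2_rows.append({"condition": cond, "group": "all",
                                   "n": sum(len(v) for v in usable),
                                   "median": None, "test": "kruskal",
                                   "p": float(p_kw)})
                for i, g1 in enumerate(names):
                    for g2 in names[i + 1:]:
                        v1, v2 = samples[i], samples[names.index(g2)]
                        if len(v1) < 2 or len(v2) < 2:
                            continue
                        _, p = stats.mannwhitneyu(v1, v2,
                                                  alternative="two-sided")
                        rnap2_rows.append({"condition": cond,
                                           "group": f"{g1} vs {g2}",
                                           "n": len(v1) + len(v2),
                                           "median": None,
                                           "test": "pairwise", "p": float(p)})
                        pv.append(len(rnap2_rows) - 1)
        tab = pd.DataFrame(rnap2_rows)
        if pv:
            tab.loc[pv, "p_bh"] = _bh(tab.loc[pv, "p"].to_numpy())
        rnap2 = tab

    return {"group_tests": group_tests, "correlation": correlation,
            "rnap2": rnap2}
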