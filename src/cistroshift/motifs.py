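"""PWM scanning with exact p-value calibrated track scores, and GRE / NF-κB
co-occurrence categorization of binding regions.

A motif hit's track score is ``min(1000, round(-100 * log10 p))`` where p is
the exact probability, under the i.i.d. background, that a random word
scores at least as high as the observed log-odds score.  A threshold of 400
is therefore exactly "p <= 1e-4".  Tail probabilities come from dynamic
programming over a discretized score lattice; for short motifs this is
verified against exhaustive enumeration of all 4^w words.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ValidationError

BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}

DEFAULT_FAMILIES = {"GRE": ("NR3C1", "NR3C2"),
                    "NFKB": ("REL", "RELA", "RELB")}


@dataclass
class PWM:
    """Position probability matrix over ACGT with background and pseudocount."""

    motif_id: str
    matrix: np.ndarray               # (w, 4) probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01
    family: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.background = np.asarray(self.background, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 \
                or self.matrix.shape[0] < 1:
            raise ValidationError("PWM matrix must be (w>=1, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1, atol=1e-9):
            raise ValidationError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """(w, 4) log2-odds after pseudocount regularization."""
        p = self.matrix + self.pseudocount * self.background
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background)

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1],
                   self.background[::-1], self.pseudocount, self.family)


def read_jaspar(path) -> list[PWM]:
    """Read PWMs from a JASPAR-format matrix file (counts -> probabilities)."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], float).T
            probs = counts / counts.sum(axis=1, keepdims=True)
            out.append(PWM(m.name or m.matrix_id, probs))
    return out


def _consensus_pwm(motif_id: str, consensus: str, family: str,
                   strong: float = 0.97) -> PWM:
    """Synthetic PWM from a consensus string.

    'N' positions are uniform; IUPAC two-base codes split the strong
    probability evenly.  Off-consensus bases get unequal probabilities
    (rotated per position) so mismatch penalties differ across positions and
    bases, giving a fine-grained score distribution like an empirical matrix
    rather than a degenerate consensus filter.
    """
    iupac = {"R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC"}
    off_weights = np.array([0.5, 0.3, 0.2])
    rows = []
    for j, c in enumerate(consensus):
        if c == "N":
            row = np.full(4, 0.25)
        elif c in iupac:
            hi = [_B2I[b] for b in iupac[c]]
            lo = [i for i in range(4) if i not in hi]
            row = np.empty(4)
            row[hi] = strong / 2
            row[lo] = (1 - strong) * np.roll([0.6, 0.4], j)[:2]
        else:
            hi = _B2I[c]
            lo = [i for i in range(4) if i != hi]
            row = np.empty(4)
            row[hi] = strong
            row[lo] = (1 - strong) * np.roll(off_weights, j)
        rows.append(row / row.sum())
    return PWM(motif_id, np.array(rows), family=family)


def default_pwms() -> list[PWM]:
    """Synthetic GRE-like and κB-like motif models.

    These are synthetic stand-ins built from the canonical consensus of each
    family — the palindromic GR half-sites AGAACAnnnTGTTCT and the κB
    element GGGACTTTCC — not database matrices.
    """
    return [
        _consensus_pwm("GRE_synthetic", "AGAACANNNTGTTCT", "GRE"),
        _consensus_pwm("NFKB_synthetic", "GGGACTTTCC", "NFKB"),
    ]


# ---------------------------------------------------------------------------
# exact score distribution
# ---------------------------------------------------------------------------

class ExactScoreDistribution:
    """Exact tail probabilities of PWM log-odds scores under the background.

    Dynamic programming over a lattice of scores discretized at ``step``
    bits: position score distributions are convolved, giving the full pmf of
    the total score of a random background word, from which the survival
    function P(score >= s) follows.
    """

    def __init__(self, pwm: PWM, step: float = 1e-3):
        import warnings

        if pwm.width > 30 and step > 1e-2:
            warnings.warn("coarse step for a wide motif; p-values may lose "
                          "precision")
        self.step = step
        lo = pwm.log_odds()
        # scanning uses this same integer lattice matrix, so scanned scores
        # coincide exactly with the DP support
        self.scaled_matrix = np.round(lo / step).astype(np.int64)
        scaled = self.scaled_matrix
        offset = scaled.min(axis=1)
        spans = scaled.max(axis=1) - offset
        pmf = np.array([1.0])
        for j in range(pwm.width):
            col = np.zeros(spans[j] + 1)
            for b in range(4):
                col[scaled[j, b] - offset[j]] += pwm.background[b]
            pmf = np.convolve(pmf, col)
        self._min_scaled = int(offset.sum())
        self._pmf = pmf
        sf = np.cumsum(pmf[::-1])[::-1]
        self._sf = np.minimum(sf, 1.0)

    def pvalue_scaled(self, k: int) -> float:
        """P(lattice score >= k) for a random background word."""
        i = k - self._min_scaled
        if i <= 0:
            return 1.0
        if i >= len(self._sf):
            return 0.0
        return float(self._sf[i])

    def pvalue(self, score: float) -> float:
        """P(log-odds >= score); ``score`` in bits, resolved to the lattice."""
        return self.pvalue_scaled(int(np.ceil(score / self.step - 1e-9)))

    def track_score(self, score: float) -> int:
        p = self.pvalue(score)
        if p <= 0:
            return 1000
        return int(min(1000, round(-100 * np.log10(p))))

    def min_scaled_for_track(self, track: int) -> int | None:
        """Smallest lattice score whose track score reaches ``track``."""
        target = 10 ** (-(track - 0.5) / 100)
        idx = np.nonzero(self._sf <= target)[0]
        if len(idx) == 0:
            return None
        return int(idx[0] + self._min_scaled)


def pwm_score_distribution(pwm: PWM, step: float = 1e-3
                           ) -> ExactScoreDistribution:
    return ExactScoreDistribution(pwm, step=step)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), np.uint8)
    out = np.full(arr.shape, -1, np.int8)
    for b, i in _B2I.items():
        out[arr == ord(b)] = i
    return out


_BAD = np.iinfo(np.int64).min // 4


def _position_scores(enc: np.ndarray, scaled: np.ndarray) -> np.ndarray:
    """Lattice score at every offset; sentinel where the word overlaps
    non-ACGT bases."""
    w = scaled.shape[0]
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0, np.int64)
    scores = np.zeros(n, np.int64)
    bad = np.zeros(n, bool)
    for j in range(w):
        col = enc[j:j + n]
        ok = col >= 0
        bad |= ~ok
        scores += np.where(ok, scaled[j, np.clip(col, 0, 3)], 0)
    scores[bad] = _BAD
    return scores


def window_sequences(fasta_path, windows: pd.DataFrame) -> dict[str, str]:
    """Sequences for windows from FASTA — either per-window records keyed by
    window_id, or genomic records addressed by (chrom, start, end)."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    out = {}
    for r in windows.itertuples(index=False):
        if r.window_id in fa:
            out[r.window_id] = str(fa[r.window_id][:])
        elif r.chrom in fa:
            out[r.window_id] = str(fa[r.chrom][r.start:r.end])
        else:
            raise KeyError(f"no FASTA record for {r.window_id} / {r.chrom}")
    return out


def scan_regions(seqs: dict[str, str], pwms: list[PWM],
                 min_track_score: int = 400,
                 step: float = 1e-3) -> tuple[pd.DataFrame, dict]:
    """Scan window sequences with PWMs on both strands.

    Returns (hits, stats): one best hit per (window, motif) with track score
    >= ``min_track_score``, and per-motif scan statistics — positions
    scanned (both strands), positions meeting the threshold, and positions
    skipped for non-ACGT bases — for calibration checks.
    """
    hits = []
    scan_stats = {}
    for pwm in pwms:
        dists = {"+": pwm_score_distribution(pwm, step=step),
                 "-": pwm_score_distribution(pwm.reverse_complement(),
                                             step=step)}
        s_min = {s: d.min_scaled_for_track(min_track_score)
                 for s, d in dists.items()}
        n_pos = n_hit = n_skip = 0
        for wid, seq in seqs.items():
            enc = _encode(seq)
            best: tuple = (None, None, None)
            best_p = 1.1
            for strand, dist in dists.items():
                sc = _position_scores(enc, dist.scaled_matrix)
                valid = sc > _BAD // 2
                n_pos += int(valid.sum())
                n_skip += int((~valid).sum())
                if s_min[strand] is None:
                    continue
                passing = valid & (sc >= s_min[strand])
                n_hit += int(passing.sum())
                if passing.any():
                    k = int(np.argmax(sc))
                    p = dist.pvalue_scaled(int(sc[k]))
                    if p < best_p:
                        best_p = p
                        best = (int(sc[k]) * step, strand, k, dist)
            if best[1] is not None:
                score, strand, k, dist = best
                hits.append((wid, pwm.motif_id, pwm.family, int(k),
                             strand, float(score),
                             dist.track_score(score)))
        scan_stats[pwm.motif_id] = {"positions_scanned": n_pos,
                                    "position_hits": n_hit,
                                    "positions_skipped_n": n_skip}
    df = pd.DataFrame(hits, columns=["window_id", "motif_id", "family",
                                     "offset", "strand", "log_odds",
                                     "track_score"])
    return df, scan_stats


def categorize_by_motif(window_ids, hits: pd.DataFrame,
                        families: dict[str, tuple[str, ...]] | None = None,
                        trends: pd.DataFrame | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Assign each window one of four co-occurrence categories.

    A window is "GRE only" when any GRE-family motif hit is present and no
    NF-κB-family hit, etc.  Hits may carry a ``family`` column; otherwise
    ``families`` maps family name -> motif_ids.  When ``trends`` (window_id,
    trend) is given, a cross-tabulation with per-trend percentages is also
    returned.
    """
    if "family" in hits.columns and hits["family"].notna().any():
        fam = hits.set_index("motif_id")["family"].to_dict()
    else:
        families = families or DEFAULT_FAMILIES
        fam = {m: f for f, ms in families.items() for m in ms}
    h = hits.assign(fam=hits["motif_id"].map(fam))
    by_win = h.groupby("window_id")["fam"].agg(set)
    cats = []
    for wid in window_ids:
        fams = by_win.get(wid, set())
        has_gre, has_nfkb = "GRE" in fams, "NFKB" in fams
        if has_gre and has_nfkb:
            cat = "GRE and NF-κB"
        elif has_gre:
            cat = "GRE only"
        elif has_nfkb:
            cat = "NF-κB only"
        else:
            cat = "neither"
        cats.append((wid, cat))
    categories = pd.DataFrame(cats, columns=["window_id", "category"])
    xtab = None
    if trends is not None:
        merged = categories.merge(trends[["window_id", "trend"]], on="window_id")
        xtab = pd.crosstab(merged["trend"], merged["category"])
        pct = xtab.div(xtab.sum(axis=1), axis=0) * 100
        xtab = pd.concat({"n": xtab, "pct": pct.round(1)}, axis=1)
    return categories, xtab
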