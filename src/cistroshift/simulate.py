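"""Synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure of a paired GR/RELA
ChIP-seq + RNA-seq study of glucocorticoid / IL1B co-treatment:

* a shared set of fixed-width consensus windows on which both factors are
  quantified, with planted lost / maintained / gained windows realized by
  shifting log2 intensity across the significance threshold;
* a planted coupling between one factor's co-treatment intensity shift and
  the other factor's co-treatment intensity at the same window;
* gene expression whose co-treatment delta carries a planted "protection"
  term for genes whose TSS lies within ``d_protect`` of a partner region;
* window sequences with planted GRE / kB motif instances; and
* dual-channel nanoscale spot fields, either completely spatially random
  (CSR) or with a planted fraction of co-localized pairs.

Everything is deterministic under (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets
from .cistrome import DEFAULT_THRESHOLDS, SignificanceThresholds
from .io import CistromeMatrix, ExpressionTable, SpotField

STATUSES = ("lost", "maintained", "gained", "none")


@dataclass
class SimConfig:
    """Study-level simulation parameters (defaults are the study conditions).

    Counts and noise scales were chosen to mirror the structure of the
    emulated study: ~3,000 consensus windows whose joint status table is a
    scaled copy of the worked-example counts, log2 binding intensities with
    unit spread around a mean of 6 for occupied windows against a
    significance floor of 4, 600 planted mono-upregulated DEGs whose
    co-treatment delta is -1.5 at baseline with +1 protection within 30 kb
    of a partner region and 0.5 noise, and nuclear spot densities of
    5e-5 spots/nm^2.
    """

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 150_000_000), ("chr2", 150_000_000),
        ("chr3", 150_000_000), ("chr4", 150_000_000))
    window_width: int = 400
    n_windows: int = 3000
    joint_counts: dict[tuple[str, str], int] | None = None
    margin: int = 250_000
    thresholds: SignificanceThresholds = DEFAULT_THRESHOLDS
    # intensity model (log2 scale)
    mu_sig: float = 6.0
    sd_sig: float = 1.0
    mu_insig: float = 2.5
    sd_insig: float = 0.6
    coupling_slope_gr: float = 0.3    # dGR on co-treatment ~ RELA co intensity
    coupling_slope_rela: float = 0.3  # dRELA on co-treatment ~ GR co intensity
    delta_sd: float = 0.35            # noise on maintained-window deltas
    summit_jitter_sd: float = 15.0
    summit_offset_scale: float = 40.0  # Laplace scale of RELA-GR summit offset
    include_rnap2: bool = True
    rnap2_slope: float = 0.5
    rnap2_sd: float = 0.8
    # expression model
    n_genes: int = 800
    n_deg_up: int = 600
    times: tuple[float, ...] = (1, 2, 6, 12, 24)
    mono_treatment: str = "bud"
    partner_condition: str = "il1b"   # partner regions: RELA under IL1B
    b_up_mean: float = 2.0
    b_up_sd: float = 0.5
    baseline_delta: float = -1.5
    protection_delta: float = 1.0
    delta_noise_sd: float = 0.5
    d_protect: int = 30_000
    frac_near: float = 0.5
    frac_il1b_up: float = 0.15
    # sequences / motifs
    base_composition: tuple[float, float, float, float] = (.25, .25, .25, .25)
    category_mix: tuple[float, float, float, float] = (.4, .3, .2, .1)
    # spot fields
    mask_nm: float = 4000.0
    spot_density: float = 5e-5        # spots per nm^2 per channel
    paired_fraction: float = 0.0
    paired_offset_nm: float = 20.0
    paired_offset_sd: float = 10.0
    n_null_iterations: int = 10

    def __post_init__(self) -> None:
        for f in (self.frac_near, self.frac_il1b_up, self.paired_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_windows <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-local deterministic generator."""
        return np.random.default_rng([self.seed, stage])


def _scaled_joint_counts(n: int) -> dict[tuple[str, str], int]:
    """Scale the worked-example joint status table to ~n windows."""
    base = datasets.GR_RELA_STATUS_COUNTS
    total = sum(base.values())
    out = {k: max(1, round(v * n / total)) if v else 0 for k, v in base.items()}
    return out


def _trunc(rng: np.random.Generator, n: int, mean: float, sd: float,
           lo: float = -np.inf, hi: float = np.inf) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                               random_state=rng)


def _sig_fdr(rng: np.random.Generator, n: int, max_fdr: float) -> np.ndarray:
    return 10 ** -rng.uniform(-np.log10(max_fdr) + 0.01, 6, n)


def place_windows(config: SimConfig, n: int,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Place n non-overlapping fixed-width windows uniformly on the genome."""
    w = config.window_width
    lengths = np.array([l for _, l in config.genome], float)
    usable = lengths - 2 * config.margin
    if (usable < w).all() or n * w > usable.sum():
        raise ValueError("requested window count exceeds genome capacity")
    per = rng.multinomial(n, usable / usable.sum())
    rows = []
    for (chrom, length), k in zip(config.genome, per):
        if k == 0:
            continue
        space = length - 2 * config.margin - k * w
        if space < 0:
            raise ValueError("requested window count exceeds genome capacity")
        gaps = np.sort(rng.integers(0, space + 1, size=k))
        starts = config.margin + gaps + np.arange(k) * w
        for s in starts:
            rows.append((chrom, int(s), int(s) + w))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    df.insert(0, "window_id", [f"win{i:05d}" for i in range(len(df))])
    return df


def cistrome_from_status_counts(
        counts: dict[tuple[str, str], int],
        config: SimConfig | None = None,
        rng: np.random.Generator | None = None) -> CistromeMatrix:
    """Realize a CistromeMatrix whose GR and RELA mono/co significance
    statuses reproduce a joint (GR status x RELA status) count table exactly.

    Statuses are realized by drawing intensities from truncated normals on
    the appropriate side of the significance floor ("shifting across the
    threshold"), with matching log2 fold changes and FDRs.  Maintained
    windows additionally carry the configured coupling between each factor's
    co-treatment intensity shift and the other factor's co-treatment
    intensity.
    """
    config = config or SimConfig()
    rng = rng or config.rng(1)
    thr = config.thresholds
    n = sum(counts.values())
    windows = place_windows(config, n, rng)

    gs = np.empty(n, object)
    rs = np.empty(n, object)
    i = 0
    for (g, r) in sorted(counts):
        k = counts[(g, r)]
        gs[i:i + k] = g
        rs[i:i + k] = r
        i += k
    perm = rng.permutation(n)
    gs, rs = gs[perm], rs[perm]

    df = windows.copy()
    df["gr_status"], df["rela_status"] = gs, rs

    def _intensity(sig_mask: np.ndarray) -> np.ndarray:
        out = np.empty(n)
        k = int(sig_mask.sum())
        out[sig_mask] = _trunc(rng, k, config.mu_sig, config.sd_sig,
                               lo=thr.min_intensity + 0.05)
        out[~sig_mask] = _trunc(rng, n - k, config.mu_insig, config.sd_insig,
                                hi=thr.min_intensity - 0.05)
        return out

    def _log2fc(sig_mask: np.ndarray) -> np.ndarray:
        out = rng.normal(0.2, 0.6, n)
        k = int(sig_mask.sum())
        out[sig_mask] = _trunc(rng, k, 2.0, 0.8, lo=thr.min_log2fc + 0.01)
        return out

    def _fdr(sig_mask: np.ndarray) -> np.ndarray:
        out = rng.uniform(0, 1, n)
        k = int(sig_mask.sum())
        out[sig_mask] = _sig_fdr(rng, k, thr.max_fdr)
        return out

    mono_of = {"GR": "bud", "RELA": "il1b"}
    status_of = {"GR": gs, "RELA": rs}
    sig = {}
    for fac in ("GR", "RELA"):
        st = status_of[fac]
        sig[(fac, mono_of[fac])] = np.isin(st, ["lost", "maintained"])
        sig[(fac, "co")] = np.isin(st, ["maintained", "gained"])

    centers = windows["start"].to_numpy() + config.window_width // 2
    gr_anchor = np.clip(
        centers + rng.normal(0, config.summit_jitter_sd, n).round().astype(int),
        windows["start"] + 2, windows["end"] - 3)
    rela_anchor = np.clip(
        gr_anchor + rng.laplace(0, config.summit_offset_scale, n)
        .round().astype(int),
        windows["start"] + 2, windows["end"] - 3)
    anchor = {"GR": gr_anchor, "RELA": rela_anchor}

    intens: dict[tuple[str, str], np.ndarray] = {}
    for fac in ("GR", "RELA"):
        for cond in (mono_of[fac], "co"):
            m = sig[(fac, cond)]
            intens[(fac, cond)] = _intensity(m)
            df[CistromeMatrix.col(fac, cond, "log2fc")] = _log2fc(m)
            df[CistromeMatrix.col(fac, cond, "fdr")] = _fdr(m)
            jit = rng.normal(0, 3, n).round().astype(int)
            smt = np.clip(anchor[fac] + jit, windows["start"] + 1,
                          windows["end"] - 2).astype(float)
            smt[~m] = np.nan
            df[CistromeMatrix.col(fac, cond, "summit")] = smt
        # unstimulated block: background occupancy, no fold change
        df[CistromeMatrix.col(fac, "ns", "intensity")] = _trunc(
            rng, n, config.mu_insig, config.sd_insig, hi=thr.min_intensity - 0.05)
        df[CistromeMatrix.col(fac, "ns", "log2fc")] = 0.0
        df[CistromeMatrix.col(fac, "ns", "fdr")] = 1.0
        df[CistromeMatrix.col(fac, "ns", "summit")] = np.nan

    # planted coupling on maintained windows: co = mono + noise +
    # slope * (other factor's co intensity, centered).  GR is conditioned on
    # the uncoupled RELA draw, RELA then on the realized GR co intensities.
    for fac, other, slope in (("GR", "RELA", config.coupling_slope_gr),
                              ("RELA", "GR", config.coupling_slope_rela)):
        maint = status_of[fac] == "maintained"
        o = intens[(other, "co")]
        delta = (rng.normal(0, config.delta_sd, n)
                 + slope * (o - o.mean()))
        coupled = np.clip(intens[(fac, mono_of[fac])] + delta,
                          thr.min_intensity + 0.05, None)
        intens[(fac, "co")] = np.where(maint, coupled, intens[(fac, "co")])
    for fac in ("GR", "RELA"):
        for cond in (mono_of[fac], "co"):
            df[CistromeMatrix.col(fac, cond, "intensity")] = intens[(fac, cond)]

    if config.include_rnap2:
        drive = (intens[("GR", "co")] + intens[("RELA", "co")]) / 2
        for cond in ("ns", "bud", "il1b", "co"):
            scale = {"ns": 0.0, "bud": 0.6, "il1b": 0.6, "co": 1.0}[cond]
            v = (3.0 + scale * config.rnap2_slope * (drive - drive.mean())
                 + rng.normal(0, config.rnap2_sd, n))
            df[CistromeMatrix.col("RNAP2", cond, "intensity")] = v
            df[CistromeMatrix.col("RNAP2", cond, "log2fc")] = 0.0
            df[CistromeMatrix.col("RNAP2", cond, "fdr")] = 1.0
            df[CistromeMatrix.col("RNAP2", cond, "summit")] = np.nan

    order = ["window_id", "chrom", "start", "end", "gr_status", "rela_status"]
    order += [c for c in df.columns if c not in order]
    return CistromeMatrix(df[order], width=config.window_width)


def simulate_cistromes(config: SimConfig) -> CistromeMatrix:
    """Simulate a consensus-window cistrome matrix for GR and RELA (and
    RNAP2) whose joint status table is a scaled copy of the worked-example
    counts (or ``config.joint_counts`` when given)."""
    counts = config.joint_counts or _scaled_joint_counts(config.n_windows)
    return cistrome_from_status_counts(counts, config, config.rng(1))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def partner_regions(config: SimConfig, cistromes: CistromeMatrix,
                    factor: str = "RELA") -> pd.DataFrame:
    """Partner-factor regions (windows significant for ``factor`` under the
    configured partner condition) used for the protection structure."""
    from .cistrome import call_significant

    ids = call_significant(cistromes, factor, config.partner_condition,
                           config.thresholds)
    df = cistromes.df
    return df.loc[df["window_id"].isin(ids),
                  ["window_id", "chrom", "start", "end"]].reset_index(drop=True)


def simulate_tss(config: SimConfig, cistromes: CistromeMatrix) -> pd.DataFrame:
    """Place gene TSSs: planted DEGs are aimed near to / far from partner
    regions in configured proportion; remaining genes are uniform."""
    rng = config.rng(2)
    regions = partner_regions(config, cistromes)
    lengths = dict(config.genome)
    n_near = round(config.n_deg_up * config.frac_near)
    rows = []
    for i in range(config.n_genes):
        gid = f"gene{i:05d}"
        if i < config.n_deg_up and len(regions):
            r = regions.iloc[rng.integers(len(regions))]
            if i < n_near:
                off = int(rng.integers(0, int(config.d_protect * 0.8)))
            else:
                off = int(rng.integers(int(config.d_protect * 1.5),
                                       config.d_protect * 5))
            side = 1 if rng.random() < 0.5 else -1
            pos = (r["end"] + off) if side > 0 else (r["start"] - 1 - off)
            pos = int(np.clip(pos, 0, lengths[r["chrom"]] - 1))
            rows.append((gid, r["chrom"], pos))
        else:
            ci = rng.integers(len(config.genome))
            chrom, length = config.genome[ci]
            rows.append((gid, chrom, int(rng.integers(0, length))))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos"])


def simulate_expression(config: SimConfig, cistromes: CistromeMatrix,
                        tss: pd.DataFrame
                        ) -> tuple[ExpressionTable, pd.DataFrame]:
    """Simulate the gene x treatment x time expression table.

    Planted mono-upregulated DEGs get a peak-time b >= 1 at FDR <= 0.05 under
    the mono treatment; the co-treatment b is mono b + baseline_delta +
    protection_delta for genes whose TSS is actually within ``d_protect`` of
    a partner region (the indicator is computed with the pipeline's own
    nearest-distance routine) + Gaussian noise.  Returns the table and a
    manifest with per-gene planted truth.
    """
    from .proximity import nearest_region_distance

    rng = config.rng(3)
    regions = partner_regions(config, cistromes)
    profile = nearest_region_distance(tss, regions, label="partner")
    dist = profile.df.set_index("gene_id")["distance"]
    near = (dist <= config.d_protect).fillna(False)

    genes = tss["gene_id"].to_numpy()
    n = len(genes)
    is_deg = np.arange(n) < config.n_deg_up
    il1b_up = rng.random(n) < config.frac_il1b_up
    peak_idx = rng.integers(0, len(config.times), n)

    mono = config.mono_treatment
    other = "il1b" if mono == "bud" else "bud"
    rows = []
    manifest = []
    for i, g in enumerate(genes):
        near_i = bool(near.get(g, False))
        b_peak = _trunc(rng, 1, config.b_up_mean, config.b_up_sd, lo=1.1)[0]
        prot = (config.baseline_delta
                + config.protection_delta * near_i)
        b_il1b_peak = (_trunc(rng, 1, config.b_up_mean, config.b_up_sd,
                              lo=1.1)[0] if il1b_up[i] else np.nan)
        for j, t in enumerate(config.times):
            if is_deg[i]:
                b_mono = b_peak if j == peak_idx[i] else (
                    b_peak * rng.uniform(0.2, 0.9))
                fdr_mono = (_sig_fdr(rng, 1, 0.05)[0] if j == peak_idx[i]
                            else rng.uniform(0, 1))
            else:
                b_mono = rng.normal(0, 0.3)
                fdr_mono = rng.uniform(0.1, 1)
            b_co = b_mono + prot + rng.normal(0, config.delta_noise_sd) \
                if is_deg[i] else b_mono + rng.normal(0, 0.3)
            fdr_co = (_sig_fdr(rng, 1, 0.05)[0] if abs(b_co) >= 1
                      else rng.uniform(0.06, 1))
            if il1b_up[i]:
                b_oth = b_il1b_peak if j == peak_idx[i] else (
                    b_il1b_peak * rng.uniform(0.2, 0.9))
                fdr_oth = (_sig_fdr(rng, 1, 0.05)[0] if j == peak_idx[i]
                           else rng.uniform(0, 1))
            else:
                b_oth = rng.normal(0, 0.3)
                fdr_oth = rng.uniform(0.1, 1)
            rows.append((g, mono, t, b_mono, fdr_mono))
            rows.append((g, other, t, b_oth, fdr_oth))
            rows.append((g, "co", t, b_co, fdr_co))
        manifest.append((g, bool(is_deg[i]), bool(il1b_up[i]), near_i,
                         config.times[peak_idx[i]],
                         float(dist.get(g, np.nan))))
    table = ExpressionTable(pd.DataFrame(
        rows, columns=["gene", "treatment", "time", "b", "fdr"]))
    man = pd.DataFrame(manifest, columns=[
        "gene_id", "planted_up", "il1b_up", "near_partner", "peak_time",
        "partner_distance"])
    return table, man


# ---------------------------------------------------------------------------
# sequences with planted motifs
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def _sample_instance(pwm, rng: np.random.Generator) -> str:
    idx = np.array([rng.choice(4, p=row) for row in pwm.matrix])
    return "".join(_BASES[idx])


def simulate_sequences(config: SimConfig, cistromes: CistromeMatrix,
                       pwms: list | None = None
                       ) -> tuple[dict[str, str], pd.DataFrame]:
    """Per-window sequences with planted motif instances.

    Returns ({window_id: sequence}, manifest).  Each window is assigned a
    category from ``config.category_mix`` (GRE only / NF-kB only / both /
    neither); for each planted family one instance sampled from the family's
    first PWM is embedded at a recorded offset and strand.  The manifest
    lists (window_id, category, motif_id, offset, strand), one row per
    planted instance (category-only rows for "neither").
    """
    from .motifs import default_pwms

    if pwms is None:
        pwms = default_pwms()
    gre = next(p for p in pwms if p.family == "GRE")
    nfkb = next(p for p in pwms if p.family == "NFKB")
    w = config.window_width
    for p in (gre, nfkb):
        if len(p.matrix) > w:
            raise ValueError(f"motif {p.motif_id} longer than window")
    rng = config.rng(4)
    comp = np.asarray(config.base_composition, float)
    comp = comp / comp.sum()
    cats = np.array(["GRE only", "NF-κB only", "GRE and NF-κB",
                     "neither"])
    ids = cistromes.df["window_id"].to_numpy()
    chosen = cats[rng.choice(4, size=len(ids), p=np.asarray(config.category_mix))]

    seqs: dict[str, str] = {}
    manifest = []
    for wid, cat in zip(ids, chosen):
        s = list("".join(_BASES[rng.choice(4, size=w, p=comp)]))
        plant = []
        if cat in ("GRE only", "GRE and NF-κB"):
            plant.append(gre)
        if cat in ("NF-κB only", "GRE and NF-κB"):
            plant.append(nfkb)
        used: list[tuple[int, int]] = []
        for pwm in plant:
            m = len(pwm.matrix)
            for _ in range(100):
                off = int(rng.integers(0, w - m + 1))
                if all(off + m <= a or off >= a + b for a, b in used):
                    break
            used.append((off, m))
            inst = _sample_instance(pwm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                inst = inst.translate(_COMP)[::-1]
            s[off:off + m] = list(inst)
            manifest.append((wid, cat, pwm.motif_id, off, strand))
        if not plant:
            manifest.append((wid, cat, None, None, None))
        seqs[wid] = "".join(s)
    man = pd.DataFrame(manifest, columns=["window_id", "category", "motif_id",
                                          "offset", "strand"])
    return seqs, man


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, s in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(s), 60):
                fh.write(s[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# spot fields
# ---------------------------------------------------------------------------

def square_mask(side_nm: float):
    from shapely.geometry import Polygon

    return Polygon([(0, 0), (side_nm, 0), (side_nm, side_nm), (0, side_nm)])


def uniform_in_mask(mask, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n uniform points inside a polygon mask."""
    from shapely import contains_xy

    minx, miny, maxx, maxy = mask.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        k = max(32, int((n - len(pts)) * 2))
        cand = np.column_stack([rng.uniform(minx, maxx, k),
                                rng.uniform(miny, maxy, k)])
        cand = cand[contains_xy(mask, cand[:, 0], cand[:, 1])]
        pts = np.vstack([pts, cand])
    return pts[:n]


def simulate_spots(config: SimConfig, rng: np.random.Generator | None = None
                   ) -> SpotField:
    """Simulate a dual-channel spot field in a square nuclear mask.

    With ``paired_fraction`` 0 both channels are homogeneous Poisson (CSR);
    otherwise that fraction of B spots is planted near a random A spot at a
    folded-normal center offset (planted co-localization), remainder CSR.
    """
    import warnings

    rng = rng if rng is not None else config.rng(5)
    mask = square_mask(config.mask_nm)
    lam = config.spot_density
    area = mask.area
    if lam * area < 1:
        warnings.warn("expected spot count below 1")
    n_a = rng.poisson(lam * area)
    n_b = rng.poisson(lam * area)
    a = uniform_in_mask(mask, n_a, rng)
    n_paired = round(config.paired_fraction * n_b) if n_a else 0
    parts = []
    if n_paired:
        anchors = a[rng.integers(0, n_a, n_paired)]
        r = np.abs(rng.normal(config.paired_offset_nm,
                              config.paired_offset_sd, n_paired))
        th = rng.uniform(0, 2 * np.pi, n_paired)
        b_pair = anchors + np.column_stack([r * np.cos(th), r * np.sin(th)])
        from shapely import contains_xy
        inside = contains_xy(mask, b_pair[:, 0], b_pair[:, 1])
        b_pair[~inside] = anchors[~inside]  # keep planted pairs in-mask
        parts.append(b_pair)
    parts.append(uniform_in_mask(mask, n_b - n_paired, rng))
    b = np.vstack(parts) if parts else np.empty((0, 2))
    return SpotField(a, b, mask, pixel_nm=20.0)
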