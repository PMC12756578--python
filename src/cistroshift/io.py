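"""Domain types and file I/O for cistrome, expression, TSS and spot data.

Coordinate convention is 0-based half-open everywhere in memory; BED-family
dialects are honored on disk.  The canonical exchange format for consensus
windows is a wide "region TSV": one row per window with columns

    window_id  chrom  start  end
    {factor}_{condition}_intensity   log2-normalized read count
    {factor}_{condition}_log2fc      log2 fold vs unstimulated
    {factor}_{condition}_fdr         false-discovery rate
    {factor}_{condition}_summit      absolute bp position, empty if absent

for factor in {GR, RELA, RNAP2} and condition in {ns, bud, il1b, co}
(``co`` denotes the IL1B-plus-budesonide co-treatment).  Only the
(factor, condition) blocks present in a file are loaded; missing blocks are
permitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FACTORS = ("GR", "RELA", "RNAP2")
CONDITIONS = ("ns", "bud", "il1b", "co")
_FIELDS = ("intensity", "log2fc", "fdr", "summit")


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class CistromeMatrix:
    """Consensus windows x (factor, condition) occupancy statistics.

    ``df`` holds one row per fixed-width window.  All windows share the same
    width; overlap between cistromes is window identity.
    """

    df: pd.DataFrame
    width: int = 400

    def __post_init__(self) -> None:
        required = ["window_id", "chrom", "start", "end"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"CistromeMatrix missing columns: {missing}")
        w = self.df["end"] - self.df["start"]
        if len(self.df) and not (w == self.width).all():
            raise ValidationError(f"all windows must have width {self.width}")
        if self.df["window_id"].duplicated().any():
            raise ValidationError("duplicate window_id")
        for f, c in self.blocks():
            s = self.df[self.col(f, c, "summit")]
            ok = s.isna() | ((s >= self.df["start"]) & (s < self.df["end"]))
            if not ok.all():
                raise ValidationError(f"summit outside window for {f}/{c}")
            fdr = self.df[self.col(f, c, "fdr")]
            if ((fdr < 0) | (fdr > 1)).any():
                raise ValidationError(f"fdr outside [0,1] for {f}/{c}")

    @staticmethod
    def col(factor: str, condition: str, fld: str) -> str:
        return f"{factor}_{condition}_{fld}"

    def blocks(self) -> list[tuple[str, str]]:
        """(factor, condition) pairs present in the matrix."""
        out = []
        for f in FACTORS:
            for c in CONDITIONS:
                if self.col(f, c, "intensity") in self.df.columns:
                    out.append((f, c))
        return out

    def summits(self, factor: str, condition: str,
                window_ids: Iterable[str] | None = None) -> pd.DataFrame:
        """Non-null summit positions as a (window_id, chrom, pos) frame."""
        cols = ["window_id", "chrom", self.col(factor, condition, "summit")]
        sub = self.df[cols].rename(columns={cols[2]: "pos"})
        if window_ids is not None:
            sub = sub[sub["window_id"].isin(set(window_ids))]
        sub = sub.dropna(subset=["pos"])
        return sub.assign(pos=sub["pos"].astype(int)).reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        df = self.df.copy()
        for f, c in self.blocks():
            sc = self.col(f, c, "summit")
            df[sc] = df[sc].map(lambda v: "" if pd.isna(v) else str(int(v)))
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, width: int | None = None) -> "CistromeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"window_id": str, "chrom": str})
        for col in df.columns:
            if col.endswith("_summit"):
                df[col] = pd.to_numeric(df[col], errors="coerce")
        if width is None:
            if not len(df):
                raise ParseError(f"{path}: empty region table needs explicit width")
            width = int(df["end"].iloc[0] - df["start"].iloc[0])
        return cls(df, width=width)


@dataclass
class ExpressionTable:
    """Per-gene expression statistics: log2 fold ``b`` and FDR per
    (treatment, time) versus the unstimulated control."""

    df: pd.DataFrame  # columns: gene, treatment, time, b, fdr

    def __post_init__(self) -> None:
        required = ["gene", "treatment", "time", "b", "fdr"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"ExpressionTable missing columns: {missing}")
        if self.df.duplicated(subset=["gene", "treatment", "time"]).any():
            raise ValidationError("duplicate (gene, treatment, time)")
        fdr = self.df["fdr"]
        if ((fdr < 0) | (fdr > 1)).any():
            raise ValidationError("fdr outside [0,1]")

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class SpotField:
    """Dual-channel point pattern (nm) within a nuclear analysis mask."""

    spots_a: np.ndarray  # (n, 2) centers in nm
    spots_b: np.ndarray
    mask: "object"       # shapely Polygon / MultiPolygon, nm units
    pixel_nm: float = 20.0
    radii_a: np.ndarray | None = None
    radii_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spots_a = np.asarray(self.spots_a, float).reshape(-1, 2)
        self.spots_b = np.asarray(self.spots_b, float).reshape(-1, 2)
        if self.pixel_nm <= 0:
            raise ValidationError("pixel_nm must be positive")


# ---------------------------------------------------------------------------
# region readers / writers
# ---------------------------------------------------------------------------

def _parse_bedlike(path: str | Path, n_min: int, kind: str) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < n_min:
                raise ParseError(f"{path}:{i}: {kind} needs >= {n_min} columns, "
                                 f"got {len(parts)}")
            try:
                int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
            parts.insert(0, str(i))
            rows.append(parts)
    return rows


def read_regions(path: str | Path, format: str = "region-TSV") -> pd.DataFrame | CistromeMatrix:
    """Read genomic regions.

    BED6 / narrowPeak inputs yield a plain frame with columns
    (window_id, chrom, start, end[, summit]); for narrowPeak the 10th-column
    peak offset is converted to an absolute summit position (offset -1 means
    absent).  ``region-TSV`` yields a full :class:`CistromeMatrix`.
    """
    if format == "region-TSV":
        return CistromeMatrix.from_tsv(path)
    if format == "BED6":
        rows = _parse_bedlike(path, 3, "BED6")
        recs = []
        for lineno, chrom, start, end, *rest in rows:
            start, end = int(start), int(end)
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: empty interval "
                                      f"[{start}, {end})")
            name = rest[0] if rest else f"region_{lineno}"
            recs.append((name, chrom, start, end))
        return pd.DataFrame(recs, columns=["window_id", "chrom", "start", "end"])
    if format == "narrowPeak":
        rows = _parse_bedlike(path, 10, "narrowPeak")
        recs = []
        for lineno, chrom, start, end, name, _score, _strand, _sv, _pv, _qv, peak in rows:
            start, end = int(start), int(end)
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: empty interval")
            offset = int(peak)
            summit = np.nan if offset == -1 else start + offset
            if not np.isnan(summit) and not (start <= summit < end):
                raise ValidationError(
                    f"{path}:{lineno}: summit {int(summit)} outside "
                    f"[{start}, {end})")
            recs.append((name, chrom, start, end, summit))
        return pd.DataFrame(
            recs, columns=["window_id", "chrom", "start", "end", "summit"])
    raise ValueError(f"unknown region format {format!r}")


def write_bed6(df: pd.DataFrame, path: str | Path, score: int = 0) -> None:
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.window_id}\t{score}\t.\n")


def write_narrowpeak(df: pd.DataFrame, path: str | Path) -> None:
    """Write an ENCODE 10-column narrowPeak; summit NaN -> offset -1."""
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            summit = getattr(r, "summit", np.nan)
            off = -1 if pd.isna(summit) else int(summit) - r.start
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.window_id}"
                     f"\t0\t.\t0\t-1\t-1\t{off}\n")


# ---------------------------------------------------------------------------
# expression / TSS / spots
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "treatment": str})
    return ExpressionTable(df)


def read_tss(path: str | Path) -> pd.DataFrame:
    """Read gene TSS positions from BED.

    Intervals wider than 1 bp are collapsed to the strand-aware 5' end
    (start for '+', end-1 for '-').  Returns a frame with columns
    (gene_id, chrom, pos); ``pos`` is the 0-based TSS base.
    """
    rows = _parse_bedlike(path, 4, "BED")
    recs = []
    for lineno, chrom, start, end, name, *rest in rows:
        if not name:
            raise ParseError(f"{path}:{lineno}: missing gene name")
        start, end = int(start), int(end)
        if start >= end:
            raise ValidationError(f"{path}:{lineno}: empty interval")
        strand = rest[1] if len(rest) >= 2 else "+"
        if end - start == 1:
            pos = start
        else:
            pos = start if strand != "-" else end - 1
        recs.append((name, chrom, pos))
    return pd.DataFrame(recs, columns=["gene_id", "chrom", "pos"])


def write_tss_bed(tss: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in tss.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.gene_id}\t0\t+\n")


def read_mask(path: str | Path):
    """Read an analysis mask as one or more polygons.

    Format: TSV with columns ``polygon_id, x_nm, y_nm``, vertices in order.
    """
    from shapely.geometry import MultiPolygon, Polygon
    from shapely.ops import unary_union

    df = pd.read_csv(path, sep="\t")
    polys = [Polygon(g[["x_nm", "y_nm"]].to_numpy())
             for _, g in df.groupby("polygon_id", sort=True)]
    return unary_union(polys) if len(polys) > 1 else polys[0]


def write_mask(mask, path: str | Path) -> None:
    from shapely.geometry import MultiPolygon

    polys = list(mask.geoms) if isinstance(mask, MultiPolygon) else [mask]
    rows = []
    for i, p in enumerate(polys):
        for x, y in np.asarray(p.exterior.coords)[:-1]:
            rows.append((i, x, y))
    pd.DataFrame(rows, columns=["polygon_id", "x_nm", "y_nm"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def read_spots(path: str | Path, mask_path: str | Path,
               pixel_nm: float = 20.0) -> SpotField:
    """Read a dual-channel spot CSV (columns x_nm, y_nm, channel[, radius_nm])
    restricted to the mask; spots outside the mask are dropped and counted."""
    from shapely import points as shp_points

    mask = read_mask(mask_path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["x_nm", "y_nm", "channel"])
    if len(df):
        bad = set(df["channel"].unique()) - {"A", "B"}
        if bad:
            raise ParseError(f"{path}: unknown channel labels {sorted(bad)}")
    out: dict[str, np.ndarray] = {}
    radii: dict[str, np.ndarray | None] = {}
    for ch in ("A", "B"):
        sub = df[df["channel"] == ch] if len(df) else df
        xy = sub[["x_nm", "y_nm"]].to_numpy(float).reshape(-1, 2)
        if len(xy):
            inside = np.array([mask.covers(p) for p in shp_points(xy)])
            n_drop = int((~inside).sum())
            if n_drop:
                logger.info("read_spots: dropped %d channel-%s spots outside "
                            "mask", n_drop, ch)
            sub = sub[inside]
            xy = xy[inside]
        out[ch] = xy
        radii[ch] = (sub["radius_nm"].to_numpy(float)
                     if "radius_nm" in sub.columns and len(sub) else None)
    return SpotField(out["A"], out["B"], mask, pixel_nm=pixel_nm,
                     radii_a=radii["A"], radii_b=radii["B"])


def write_spots(field: SpotField, path: str | Path) -> None:
    rows = []
    for ch, xy, rr in (("A", field.spots_a, field.radii_a),
                       ("B", field.spots_b, field.radii_b)):
        for i, (x, y) in enumerate(xy):
            row = {"x_nm": x, "y_nm": y, "channel": ch}
            if rr is not None:
                row["radius_nm"] = rr[i]
            rows.append(row)
    pd.DataFrame(rows, columns=["x_nm", "y_nm", "channel"]
                 + (["radius_nm"] if rows and "radius_nm" in rows[0] else [])
                 ).to_csv(path, index=False, float_format="%.6g")
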