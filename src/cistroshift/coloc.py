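"""Nanoscale dual-channel spot co-localization statistics.

Per direction (A->B and B->A), nearest-neighbor center-center distances are
computed; spots whose NN distance is at most the touching threshold
(default 69 nm, the empirically calibrated center-distance equivalent of
edge contact) are counted as co-localized.  The observed field is compared
against a configurable number of complete-spatial-randomness (CSR)
re-placements of the same spot counts inside the same mask (default 10),
with a two-sided Wilcoxon rank-sum comparison of the distance
distributions.  The analytic CSR nearest-neighbor CDF 1 - exp(-lambda pi
r^2) serves as an independent oracle for the randomization null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .io import SpotField


@dataclass
class ColocResult:
    touching_nm: float
    pixel_nm: float
    nn_ab: np.ndarray                 # per A-spot NN distance to B (nm)
    nn_ba: np.ndarray
    touching_fraction_ab: float
    touching_fraction_ba: float
    pixel_overlap_fraction_ab: float
    pixel_overlap_fraction_ba: float
    pixel_rule: str                   # "radii" or "center-fallback"
    null_touching_ab: list[float] = field(default_factory=list)
    null_touching_ba: list[float] = field(default_factory=list)
    null_nn_ab: np.ndarray | None = None
    null_nn_ba: np.ndarray | None = None
    statistic: float | None = None
    p_value: float | None = None

    def as_dict(self) -> dict:
        return {
            "touching_nm": self.touching_nm, "pixel_nm": self.pixel_nm,
            "n_a": len(self.nn_ab), "n_b": len(self.nn_ba),
            "touching_fraction_ab": self.touching_fraction_ab,
            "touching_fraction_ba": self.touching_fraction_ba,
            "pixel_overlap_fraction_ab": self.pixel_overlap_fraction_ab,
            "pixel_overlap_fraction_ba": self.pixel_overlap_fraction_ba,
            "pixel_rule": self.pixel_rule,
            "null_touching_ab": self.null_touching_ab,
            "null_touching_ba": self.null_touching_ba,
            "statistic": self.statistic, "p_value": self.p_value,
        }


def _nn(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tree = cKDTree(dst)
    d, idx = tree.query(src, k=1)
    return np.asarray(d, float), np.asarray(idx, int)


def nn_colocalization(f: SpotField, touching_nm: float = 69.0,
                      pixel_nm: float | None = None) -> ColocResult:
    """Nearest-neighbor distances and touching fractions, both directions.

    The pixel-overlap fraction uses supplied radii when present (NN center
    distance <= r_self + r_other - pixel) and otherwise falls back to the
    center-distance rule NN <= pixel; the rule used is labeled.
    """
    if len(f.spots_a) == 0 or len(f.spots_b) == 0:
        raise ValueError("both channels must be non-empty")
    pixel_nm = f.pixel_nm if pixel_nm is None else pixel_nm
    d_ab, i_ab = _nn(f.spots_a, f.spots_b)
    d_ba, i_ba = _nn(f.spots_b, f.spots_a)
    have_radii = f.radii_a is not None and f.radii_b is not None
    if have_radii:
        lim_ab = f.radii_a + f.radii_b[i_ab] - pixel_nm
        lim_ba = f.radii_b + f.radii_a[i_ba] - pixel_nm
        rule = "radii"
    else:
        lim_ab = np.full_like(d_ab, pixel_nm)
        lim_ba = np.full_like(d_ba, pixel_nm)
        rule = "center-fallback"
    return ColocResult(
        touching_nm=touching_nm, pixel_nm=pixel_nm,
        nn_ab=d_ab, nn_ba=d_ba,
        touching_fraction_ab=float((d_ab <= touching_nm).mean()),
        touching_fraction_ba=float((d_ba <= touching_nm).mean()),
        pixel_overlap_fraction_ab=float((d_ab <= lim_ab).mean()),
        pixel_overlap_fraction_ba=float((d_ba <= lim_ba).mean()),
        pixel_rule=rule)


def randomized_null(f: SpotField, n_iter: int = 10,
                    seed: int | np.random.Generator = 0,
                    touching_nm: float = 69.0) -> ColocResult:
    """Observed co-localization versus CSR re-placements of the same spot
    counts inside the mask; two-sided rank-sum test on pooled NN distances."""
    from .simulate import uniform_in_mask

    if f.mask.area <= 0:
        raise ValueError("mask area must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    res = nn_colocalization(f, touching_nm=touching_nm)
    null_ab, null_ba = [], []
    frac_ab, frac_ba = [], []
    for _ in range(n_iter):
        a = uniform_in_mask(f.mask, len(f.spots_a), rng)
        b = uniform_in_mask(f.mask, len(f.spots_b), rng)
        d_ab, _ = _nn(a, b)
        d_ba, _ = _nn(b, a)
        null_ab.append(d_ab)
        null_ba.append(d_ba)
        frac_ab.append(float((d_ab <= touching_nm).mean()))
        frac_ba.append(float((d_ba <= touching_nm).mean()))
    res.null_nn_ab = np.concatenate(null_ab)
    res.null_nn_ba = np.concatenate(null_ba)
    res.null_touching_ab = frac_ab
    res.null_touching_ba = frac_ba
    actual = np.concatenate([res.nn_ab, res.nn_ba])
    null = np.concatenate([res.null_nn_ab, res.null_nn_ba])
    s, p = stats.ranksums(actual, null)
    res.statistic, res.p_value = float(s), float(p)
    return res


def csr_expectation(lam: float, r: float) -> float:
    """CSR nearest-neighbor distance CDF at r: 1 - exp(-lambda pi r^2)."""
    if lam < 0 or r < 0:
        raise ValueError("lambda and r must be non-negative")
    return float(1.0 - np.exp(-lam * np.pi * r * r))


def pla_density(spots: np.ndarray, nuclei_mask,
                area_unit_nm2: float = 1e6) -> dict:
    """Counts of spots inside vs outside nuclei, normalized to nuclear area.

    ``area_unit_nm2`` sets the density unit (default 1e6 nm^2 = 1 um^2).
    """
    from shapely import contains_xy

    area = nuclei_mask.area
    if area <= 0:
        raise ValueError("zero nuclear area")
    spots = np.asarray(spots, float).reshape(-1, 2)
    if len(spots):
        inside = contains_xy(nuclei_mask, spots[:, 0], spots[:, 1])
    else:
        inside = np.zeros(0, bool)
    n_in, n_out = int(inside.sum()), int((~inside).sum())
    units = area / area_unit_nm2
    return {"n_inside": n_in, "n_outside": n_out,
            "nuclear_area_units": units,
            "density_inside": n_in / units,
            "density_outside": n_out / units}
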