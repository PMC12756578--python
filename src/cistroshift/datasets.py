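"""Worked-example data: published-scale cistrome status counts.

``GR_RELA_STATUS_COUNTS`` is the joint allocation of consensus windows over
(GR status x RELA status) cells for a GR/RELA ChIP-seq comparison of
budesonide, IL1B and combined treatment in A549 cells, used throughout the
docs and the acceptance checks as a worked example.  Statuses refer to the
mono-treatment vs co-treatment comparison: lost / maintained / gained /
never-significant ("none").

The marginal and overlap counts implied by this table:

* GR:   mono 6,479; co 7,005; union 8,221; lost 1,216; gained 1,742.
* RELA: mono 4,738; co 4,870; union 5,883; lost 1,013; gained 1,145.
* mono-treatment overlap 1,163 windows; co-treatment overlap 3,106.
* GR loss rate 22.3% outside the mono overlap vs 2.6% inside; RELA loss
  24.4% outside; GR gain 11.5% outside the co overlap vs 41.7% inside;
  RELA gain 5.3% outside vs 33.8% inside.

The joint table is the minimal completion of those published marginals
(cells unconstrained by them set to zero).
"""

from __future__ import annotations

# {(gr_status, rela_status): n_windows}
GR_RELA_STATUS_COUNTS: dict[tuple[str, str], int] = {
    ("lost", "lost"): 0,
    ("lost", "maintained"): 30,
    ("lost", "gained"): 0,
    ("lost", "none"): 1186,
    ("maintained", "lost"): 141,
    ("maintained", "maintained"): 992,
    ("maintained", "gained"): 819,
    ("maintained", "none"): 3311,
    ("gained", "lost"): 0,
    ("gained", "maintained"): 1064,
    ("gained", "gained"): 231,
    ("gained", "none"): 447,
    ("none", "lost"): 872,
    ("none", "maintained"): 1639,
    ("none", "gained"): 95,
    ("none", "none"): 0,
}

#: modal summit separations (bp) between GR and RELA short-range peak pairs
#: in the same study: mono-treatments vs the co-treatment
MODAL_SUMMIT_SEPARATION_BP = {"mono": 56, "co": 32}
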