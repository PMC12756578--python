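"""End-to-end pipeline orchestration over synthetic or user-supplied data.

``run`` executes the enabled stages in dependency order — simulate,
classify, overlap, summits, motifs, degs, proximity, protect, coloc — and
writes per-stage tables plus one machine-readable JSON report aggregating
all counts and statistics.  Percentages appear both as raw fractions and
1-decimal roundings.  A stage failure aborts its dependents and the report
marks partial completion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import cistrome, coloc, expression, motifs, proximity, simulate, summits
from .io import CistromeMatrix
from .simulate import SimConfig

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

ALL_STAGES = ("simulate", "classify", "overlap", "summits", "motifs",
              "degs", "proximity", "protect", "coloc")


@dataclass
class PipelineConfig:
    outdir: str = "cistroshift_out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = ALL_STAGES
    thresholds: cistrome.SignificanceThresholds = cistrome.DEFAULT_THRESHOLDS
    trend_lo: float = -0.5
    trend_hi: float = 0.5
    protect_cutoff: int = 30_000
    touching_nm: float = 69.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "genome" in sim_raw:
            sim_raw["genome"] = tuple((c, int(L)) for c, L in sim_raw["genome"])
        known = {f.name for f in fields(SimConfig)}
        bad = set(sim_raw) - known
        if bad:
            raise ValueError(f"unknown sim config keys: {sorted(bad)}")
        sim = SimConfig(**sim_raw)
        thr_raw = raw.pop("thresholds", None)
        cfg = cls(sim=sim, **{k: v for k, v in raw.items()
                              if k in {f.name for f in fields(cls)}})
        if thr_raw:
            cfg.thresholds = cistrome.SignificanceThresholds(**thr_raw)
        if "seed" in raw:
            cfg.sim = _with_seed(cfg.sim, raw["seed"])
        return cfg


def _with_seed(sim: SimConfig, seed: int) -> SimConfig:
    from dataclasses import replace

    return replace(sim, seed=seed)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    return obj


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the JSON report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = _with_seed(config.sim, config.seed)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "seed": config.seed, "stages_run": [], "status": "ok"}
    state: dict = {}

    def enabled(stage: str) -> bool:
        return stage in config.stages

    deps = {"classify": ["simulate"], "overlap": ["classify"],
            "summits": ["simulate"], "motifs": ["classify"],
            "degs": ["simulate"], "proximity": ["degs"],
            "protect": ["proximity"], "coloc": []}

    failed: set[str] = set()
    for stage in ALL_STAGES:
        if not enabled(stage):
            continue
        if any(d in failed or (d not in report["stages_run"] and enabled(d))
               and d in failed for d in deps.get(stage, [])):
            continue
        if any(d in failed for d in deps.get(stage, [])):
            report["status"] = "partial"
            continue
        try:
            _run_stage(stage, sim, config, state, report, out)
            report["stages_run"].append(stage)
        except Exception as exc:  # stage failure aborts dependents
            logger.exception("stage %s failed", stage)
            failed.add(stage)
            report["status"] = "partial"
            report.setdefault("errors", {})[stage] = str(exc)
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report


def _run_stage(stage: str, sim: SimConfig, config: PipelineConfig,
               state: dict, report: dict, out: Path) -> None:
    if stage == "simulate":
        mat = simulate.simulate_cistromes(sim)
        mat.to_tsv(out / "cistromes.tsv")
        state["matrix"] = mat
        report["simulate"] = {"n_windows": len(mat.df), "seed": sim.seed}
    elif stage == "classify":
        mat = state["matrix"]
        res = {}
        for fac, mono in (("GR", "bud"), ("RELA", "il1b")):
            tr = cistrome.classify_trend(mat, fac, mono, "co",
                                         config.trend_lo, config.trend_hi,
                                         config.thresholds)
            tr.to_csv(out / f"classification_{fac}.tsv", sep="\t", index=False)
            res[fac] = tr
        state["trends"] = res
        report["classify"] = {
            fac: {**cistrome.status_counts(tr),
                  "trend_counts": tr["trend"].value_counts().to_dict()}
            for fac, tr in res.items()}
    elif stage == "overlap":
        part = cistrome.overlap_partition(state["trends"]["GR"],
                                          state["trends"]["RELA"])
        coupling = cistrome.factor_coupling_stats(
            state["matrix"], state["trends"]["GR"], "GR", "RELA",
            rnap2_factor="RNAP2" if sim.include_rnap2 else None)
        coupling["group_tests"].to_csv(out / "coupling_GR.tsv", sep="\t",
                                       index=False)
        report["overlap"] = part
        report["coupling"] = {"GR": coupling["correlation"]}
    elif stage == "summits":
        mat = state["matrix"]
        q = mat.summits("GR", "co")
        t = mat.summits("RELA", "co")
        dset = summits.nearest_summit_distances(q, t, "GR/co", "RELA/co")
        summ = summits.summit_pair_summary(dset)
        summ.pop("cdf").to_csv(out / "summit_cdf.tsv", sep="\t", index=False)
        report["summits"] = summ
    elif stage == "motifs":
        mat = state["matrix"]
        seqs, manifest = simulate.simulate_sequences(sim, mat)
        hits, scan_stats = motifs.scan_regions(seqs, motifs.default_pwms())
        cats, xtab = motifs.categorize_by_motif(
            mat.df["window_id"], hits, trends=state["trends"]["GR"])
        cats.to_csv(out / "motif_categories.tsv", sep="\t", index=False)
        hits.to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        report["motifs"] = {
            "categories": cats["category"].value_counts().to_dict(),
            "scan_stats": scan_stats}
    elif stage == "degs":
        mat = state["matrix"]
        tss = simulate.simulate_tss(sim, mat)
        table, manifest = simulate.simulate_expression(sim, mat, tss)
        table.to_tsv(out / "expression.tsv")
        calls, counts = expression.call_degs(table)
        counts.to_csv(out / "deg_counts.tsv", sep="\t", index=False)
        peak = expression.assign_peak_time(calls, sim.mono_treatment)
        deltas = expression.cotreatment_delta(table, sim.mono_treatment,
                                              peak_times=peak)
        deltas.to_csv(out / "cotreatment_deltas.tsv", sep="\t", index=False)
        up_mono = expression.deg_gene_set(calls, sim.mono_treatment, "up")
        other = "il1b" if sim.mono_treatment == "bud" else "bud"
        up_other = expression.deg_gene_set(calls, other, "up")
        universe = set(table.df["gene"])
        enrich = expression.coregulation_enrichment(up_mono, up_other,
                                                    universe)
        state.update(tss=tss, table=table, calls=calls, deltas=deltas,
                     up_mono=up_mono, up_other=up_other)
        report["degs"] = {
            "n_up_mono": len(up_mono), "n_up_other": len(up_other),
            "n_deltas": len(deltas), "coregulation": enrich,
            "delta_categories": deltas["category"].value_counts().to_dict()}
    elif stage == "proximity":
        mat = state["matrix"]
        regions = simulate.partner_regions(sim, mat)
        prof = proximity.nearest_region_distance(state["tss"], regions,
                                                 label="partner")
        chrom_sizes = dict(sim.genome)
        rnd = proximity.generate_random_regions(
            max(1, len(regions)), chrom_sizes, sim.window_width,
            np.random.default_rng([config.seed, 90]))
        rnd_prof = proximity.nearest_region_distance(state["tss"], rnd,
                                                     label="random")
        deg_ids = state["up_mono"]
        classes = {
            "up": proximity.DistanceProfile(
                prof.df[prof.df["gene_id"].isin(deg_ids)], "up"),
            "other": proximity.DistanceProfile(
                prof.df[~prof.df["gene_id"].isin(deg_ids)], "other")}
        cmp_tab = proximity.distance_profile_compare(classes, rnd_prof)
        cmp_tab.to_csv(out / "distance_compare.tsv", sep="\t", index=False)
        prof.df.to_csv(out / "distances.tsv", sep="\t", index=False)
        state["profile"] = prof
        report["proximity"] = {"partner": prof.summary(),
                               "random": rnd_prof.summary(),
                               "classes": _jsonable(cmp_tab)}
    elif stage == "protect":
        res = proximity.protection_test(state["deltas"], state["profile"],
                                        cutoff=config.protect_cutoff)
        res_excl = proximity.protection_test(
            state["deltas"], state["profile"], cutoff=config.protect_cutoff,
            exclude=state["up_other"])
        report["protect"] = {"all": res.as_dict(),
                             "excluding_coregulated": res_excl.as_dict()}
    elif stage == "coloc":
        f = simulate.simulate_spots(sim)
        res = coloc.randomized_null(f, n_iter=sim.n_null_iterations,
                                    seed=np.random.default_rng(
                                        [config.seed, 91]),
                                    touching_nm=config.touching_nm)
        report["coloc"] = res.as_dict()
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage}")
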