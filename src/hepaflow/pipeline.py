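"""End-to-end simulated study orchestration.

Runs the full experiment the analysis chain was built for: simulate a
sham/BDL cohort, acquire baseline FAIR ASL (global + slice-selective) and
the two caval phase-contrast cines, apply the LPS parameter shift, acquire
post-LPS FAIR, then fit T1 maps, compute perfusion and TLBF, and produce
the statistics report (baseline group comparisons, FAIR-vs-PCMRI
agreement, and the group x time mixed ANOVA of the LPS response).

Every stage persists its outputs (NIfTI series/maps, CSV tables, JSON
report) under one directory per animal per time point, so stages can be
re-run individually; re-running only the stats stage on persisted
measurements reproduces the report exactly.  All randomness derives from
the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .gating import simulate_motion_study  # noqa: F401  (re-export for stage users)
from .pcflow import caval_subtraction_from_cines
from .perfusion import PerfusionParams, ROISet, perfusion_map, roi_mean
from .phantom import (CohortConfig, PCProtocol, build_cohort, make_phantom,
                      simulate_fair_series, simulate_pc_cine)
from .stats import (bland_altman, forkman_from_samples, ks_normality,
                    mann_whitney_u, mixed_anova_2x2, welch_t)
from .t1fit import fit_t1_map

log = logging.getLogger("hepaflow")

STAGES = ("simulate", "fit_t1", "perfusion", "pcflow", "stats")
TIMEPOINTS = ("baseline", "post_lps")
MODES = ("global", "slice_selective")


@dataclass
class RunConfig:
    """Study configuration: cohort, acquisition, quantification and seeds."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    perfusion: PerfusionParams = field(default_factory=PerfusionParams)
    matrix: int = 64
    fov_mm: float = 60.0
    noise_sd: float = 10.0
    phase_noise_sd: float = 0.02
    noise_model: str = "gaussian"
    smooth: bool = True
    roi_radius_px: float | None = None
    seed: int = 0
    outdir: str = "study_out"
    stages: tuple = STAGES

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.cohort.validate()
        self.perfusion.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        perf = PerfusionParams(**raw.pop("perfusion", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(cohort=cohort, perfusion=perf, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


@dataclass
class StudyReport:
    """Statistics report plus the tidy measurement table behind it."""

    report: dict
    measurements: pd.DataFrame
    outdir: Path


# --------------------------------------------------------------------------
# Stage: simulate
# --------------------------------------------------------------------------

def _animal_seed(config: RunConfig, index: int, n: int = 8) -> np.ndarray:
    ss = np.random.SeedSequence([config.seed, index])
    return ss.generate_state(n) % (2 ** 31)


def stage_simulate(config: RunConfig) -> None:
    """Simulate the cohort and all raw acquisitions; persist everything."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    phantoms = build_cohort(config.cohort, seed=config.cohort.seed,
                            matrix=config.matrix, fov_mm=config.fov_mm)
    rows = []
    for idx, ph in enumerate(phantoms):
        seeds = _animal_seed(config, idx)
        adir = out / "animals" / ph.animal_id
        rois = ROISet.for_phantom(ph, radius=config.roi_radius_px)
        (adir / "baseline").mkdir(parents=True, exist_ok=True)
        hio.save_map(ph.liver_mask.astype(float), ph.pixel_size_mm,
                     adir / "liver_mask.nii.gz", units="mask")
        (adir / "rois.json").write_text(json.dumps(
            [{"label": r.label, "centre": list(r.centre), "radius": r.radius}
             for r in rois.rois], sort_keys=True))

        states = {"baseline": ph}
        if not ph.lost_post_lps:
            states["post_lps"] = ph.apply_lps()
        for tp, state in states.items():
            tdir = adir / tp
            tdir.mkdir(parents=True, exist_ok=True)
            for m, mode in enumerate(MODES):
                series = simulate_fair_series(
                    state, mode, noise_sd=config.noise_sd,
                    seed=int(seeds[2 * (tp == "post_lps") + m]),
                    noise_model=config.noise_model)
                hio.save_series(series, tdir / f"fair_{mode}.nii.gz")

        pdir = adir / "pcmri"
        pdir.mkdir(parents=True, exist_ok=True)
        for v, vessel in enumerate(("infra_IVC", "supra_IVC")):
            cine = simulate_pc_cine(ph, vessel,
                                    noise_sd_rad=config.phase_noise_sd,
                                    seed=int(seeds[4 + v]))
            hio.save_cine(cine, pdir / f"{vessel}.nii.gz")

        rows.append({
            "animal": ph.animal_id, "cohort": ph.cohort,
            "liver_weight_g": ph.liver_weight_g,
            "perfusion_true": ph.mean_perfusion_true,
            "t1_true_ms": ph.tissue_t1_ms["liver"],
            "tlbf_true": ph.tlbf_ground_truth(),
            "perfusion_shift": ph.perfusion_shift,
            "t1_shift_ms": ph.t1_shift_ms,
            "heart_rate_bpm": ph.heart_rate_bpm,
            "lost_post_lps": ph.lost_post_lps,
        })
        log.info("simulated %s (%s)", ph.animal_id, ph.cohort)
    pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1,
                                                sort_keys=True))


# --------------------------------------------------------------------------
# Stage: fit_t1
# --------------------------------------------------------------------------

def _cohort_table(config: RunConfig) -> pd.DataFrame:
    path = Path(config.outdir) / "cohort.csv"
    if not path.exists():
        raise FileNotFoundError("run the 'simulate' stage first")
    return pd.read_csv(path)


def stage_fit_t1(config: RunConfig) -> None:
    """Fit T1 maps for every animal, time point and inversion mode."""
    out = Path(config.outdir)
    for _, row in _cohort_table(config).iterrows():
        adir = out / "animals" / row["animal"]
        mask = hio.load_map(adir / "liver_mask.nii.gz") > 0.5
        for tp in TIMEPOINTS:
            tdir = adir / tp
            if not tdir.exists():
                continue
            for mode in MODES:
                series = hio.load_series(tdir / f"fair_{mode}.nii.gz")
                maps = fit_t1_map(series, smooth=config.smooth, mask=mask)
                px = series.protocol.pixel_mm
                hio.save_map(maps.t1, px, tdir / f"t1_{mode}.nii.gz", units="ms")
                hio.save_map(maps.alpha, px, tdir / f"alpha_{mode}.nii.gz")
                hio.save_map(maps.m0, px, tdir / f"m0_{mode}.nii.gz")
                hio.save_map(maps.valid.astype(float), px,
                             tdir / f"valid_{mode}.nii.gz", units="mask")
            log.info("fitted T1 maps for %s/%s", row["animal"], tp)


# --------------------------------------------------------------------------
# Stage: perfusion
# --------------------------------------------------------------------------

def _load_rois(adir: Path) -> ROISet:
    from .perfusion import CircleROI

    spec = json.loads((adir / "rois.json").read_text())
    return ROISet(tuple(CircleROI(r["label"], tuple(r["centre"]), r["radius"])
                        for r in spec))


def _load_mapset(tdir: Path, mode: str):
    from .t1fit import T1MapSet

    return T1MapSet(t1=hio.load_map(tdir / f"t1_{mode}.nii.gz"),
                    t1_star=None, alpha=hio.load_map(tdir / f"alpha_{mode}.nii.gz"),
                    m0=hio.load_map(tdir / f"m0_{mode}.nii.gz"),
                    valid=hio.load_map(tdir / f"valid_{mode}.nii.gz") > 0.5,
                    inversion_mode=mode)


def stage_perfusion(config: RunConfig) -> None:
    """Perfusion maps and three-ROI parenchymal means per animal/time point."""
    out = Path(config.outdir)
    rows = []
    for _, arow in _cohort_table(config).iterrows():
        adir = out / "animals" / arow["animal"]
        rois = _load_rois(adir)
        for tp in TIMEPOINTS:
            tdir = adir / tp
            if not (tdir / "t1_global.nii.gz").exists():
                continue
            g = _load_mapset(tdir, "global")
            s = _load_mapset(tdir, "slice_selective")
            pmap = perfusion_map(g, s, config.perfusion)
            px = config.fov_mm / config.matrix
            hio.save_map(pmap.values, px, tdir / "perfusion.nii.gz",
                         units="ml/min/100g")
            rows.append({"animal": arow["animal"], "cohort": arow["cohort"],
                         "timepoint": tp, "metric": "perfusion",
                         "value": roi_mean(pmap, rois)})
            rows.append({"animal": arow["animal"], "cohort": arow["cohort"],
                         "timepoint": tp, "metric": "t1",
                         "value": roi_mean(g, rois)})
    pd.DataFrame(rows).to_csv(out / "fair_measurements.csv", index=False)


# --------------------------------------------------------------------------
# Stage: pcflow
# --------------------------------------------------------------------------

def stage_pcflow(config: RunConfig) -> None:
    """Caval-subtraction TLBF per animal from the persisted cine studies."""
    out = Path(config.outdir)
    rows = []
    for _, arow in _cohort_table(config).iterrows():
        pdir = out / "animals" / arow["animal"] / "pcmri"
        infra = hio.load_cine(pdir / "infra_IVC.nii.gz")
        supra = hio.load_cine(pdir / "supra_IVC.nii.gz")
        result = caval_subtraction_from_cines(infra, supra,
                                              arow["liver_weight_g"])
        rows.append({"animal": arow["animal"], "cohort": arow["cohort"],
                     "timepoint": "baseline", "metric": "tlbf",
                     "value": result.tlbf_ml_min_100g})
    pd.DataFrame(rows).to_csv(out / "flow_measurements.csv", index=False)


# --------------------------------------------------------------------------
# Stage: stats
# --------------------------------------------------------------------------

def _group_summary(x: np.ndarray) -> dict:
    return {"mean": float(np.mean(x)), "se": float(np.std(x, ddof=1) / np.sqrt(len(x)))
            if len(x) > 1 else 0.0, "n": int(len(x))}


def _baseline_comparison(sham: np.ndarray, bdl: np.ndarray, seed: int) -> dict:
    entry = {"sham": _group_summary(sham), "bdl": _group_summary(bdl)}
    normal = True
    if min(len(sham), len(bdl)) >= 4:
        for i, x in enumerate((sham, bdl)):
            _, p = ks_normality(x, seed=seed + i)
            normal = normal and p >= 0.05
    if normal:
        t, df, p = welch_t(sham, bdl)
        entry.update(test="welch_t", statistic=t, df=df, p=p)
    else:
        u, p = mann_whitney_u(sham, bdl)
        entry.update(test="mann_whitney_u", statistic=u, df=None, p=p)
    return entry


def _anova_dict(res) -> dict:
    return {
        "F": res.f_interaction, "df": [res.df1, res.df2], "p": res.p_interaction,
        "group_changes": {g: {"mean": m, "se": se, "n": n}
                          for g, (m, se, n) in res.group_changes.items()},
        "posthoc": {g: {"t": t, "df": df, "p_raw": p, "p_bonferroni": padj}
                    for g, (t, df, p, padj) in res.posthoc.items()},
        "dropped_subjects": list(res.dropped_subjects),
    }


def stage_stats(config: RunConfig) -> StudyReport:
    """Compose the tidy measurement table and compute the statistics report."""
    out = Path(config.outdir)
    cohort = _cohort_table(config)
    fair = pd.read_csv(out / "fair_measurements.csv")
    parts = [fair]
    flow_path = out / "flow_measurements.csv"
    if flow_path.exists():
        parts.append(pd.read_csv(flow_path))
    weight_rows = cohort.rename(columns={"liver_weight_g": "value"})[
        ["animal", "cohort", "value"]]
    weight_rows = weight_rows.assign(timepoint="baseline", metric="liver_weight")
    meas = pd.concat(parts + [weight_rows], ignore_index=True)[
        ["animal", "cohort", "timepoint", "metric", "value"]]
    meas = meas.sort_values(["metric", "timepoint", "animal"],
                            kind="stable").reset_index(drop=True)
    meas.to_csv(out / "measurements.csv", index=False)

    base = meas[meas["timepoint"] == "baseline"]

    def group_vals(metric, group):
        sel = base[(base["metric"] == metric) & (base["cohort"] == group)]
        return sel.sort_values("animal")["value"].to_numpy()

    report: dict = {"meta": {
        "seed": config.seed, "matrix": config.matrix,
        "n_sham": int((cohort["cohort"] == "sham").sum()),
        "n_bdl": int((cohort["cohort"] == "bdl").sum()),
        "n_bdl_post_lps": int(((cohort["cohort"] == "bdl")
                               & ~cohort["lost_post_lps"]).sum()),
    }}

    report["baseline"] = {}
    for metric in ("perfusion", "t1", "liver_weight"):
        report["baseline"][metric] = _baseline_comparison(
            group_vals(metric, "sham"), group_vals(metric, "bdl"),
            seed=config.seed)

    # agreement between FAIR perfusion and caval-subtraction TLBF
    if "tlbf" in set(meas["metric"]):
        per = base[base["metric"] == "perfusion"].set_index("animal")["value"]
        tlbf = base[base["metric"] == "tlbf"].set_index("animal")["value"]
        common = sorted(set(per.index) & set(tlbf.index))
        a = per.loc[common].to_numpy()
        b = tlbf.loc[common].to_numpy()
        agreement = {"overall": dataclasses.asdict(bland_altman(a, b))}
        grp = base[base["metric"] == "perfusion"].set_index("animal")["cohort"]
        for g in ("sham", "bdl"):
            ids = [i for i in common if grp.loc[i] == g]
            if len(ids) >= 3:
                agreement[g] = dataclasses.asdict(
                    bland_altman(per.loc[ids].to_numpy(),
                                 tlbf.loc[ids].to_numpy()))
        cov = forkman_from_samples(a, b)
        agreement["cov"] = {"fair_pct": cov.cov1_pct, "tlbf_pct": cov.cov2_pct,
                            "F": cov.F, "df": [cov.df1, cov.df2],
                            "p": cov.p_two_sided}
        report["agreement"] = agreement

    report["lps_response"] = {}
    for metric in ("perfusion", "t1"):
        sub = meas[meas["metric"] == metric]
        records = sub.rename(columns={"animal": "subject", "cohort": "group",
                                      "timepoint": "time"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mixed_anova_2x2(records[["subject", "group", "time", "value"]])
        report["lps_response"][metric] = _anova_dict(res)

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return StudyReport(report=report, measurements=meas, outdir=out)


# --------------------------------------------------------------------------
# Orchestration and rendering
# --------------------------------------------------------------------------

_STAGE_FUNCS = {"simulate": stage_simulate, "fit_t1": stage_fit_t1,
                "perfusion": stage_perfusion, "pcflow": stage_pcflow,
                "stats": stage_stats}


def run_study(config: RunConfig) -> StudyReport | None:
    """Execute the configured stages in order; halt on the first failure."""
    config.validate()
    result = None
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        try:
            out = _STAGE_FUNCS[stage](config)
        except Exception as exc:
            log.error("stage %s failed: %s", stage, exc)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        if stage == "stats":
            result = out
    return result


def lps_interaction_power(cohort_config: CohortConfig | None = None,
                          n_reps: int = 50, base_seed: int = 0,
                          alpha: float = 0.05,
                          metric: str = "perfusion") -> float:
    """Detection rate of the group x time interaction over simulated studies.

    Each replicate draws a fresh cohort from the configured distributions
    (replicate ``r`` uses seed ``base_seed + r``), forms the per-animal
    baseline and post-LPS values at measurement level, and runs the 2x2
    mixed ANOVA; the returned fraction is the share of replicates with an
    interaction p below ``alpha``.  Animals lost to attrition contribute a
    baseline value only and are dropped by the ANOVA, as in the study.
    """
    if cohort_config is None:
        cohort_config = CohortConfig()
    detections = 0
    for rep in range(n_reps):
        cohort = build_cohort(cohort_config, seed=base_seed + rep, matrix=16)
        rows = []
        for ph in cohort:
            value = ph.mean_perfusion_true if metric == "perfusion" \
                else ph.tissue_t1_ms["liver"]
            rows.append((ph.animal_id, ph.cohort, "baseline", value))
            if not ph.lost_post_lps:
                post = ph.apply_lps()
                value = post.mean_perfusion_true if metric == "perfusion" \
                    else post.tissue_t1_ms["liver"]
                rows.append((ph.animal_id, ph.cohort, "post_lps", value))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mixed_anova_2x2(pd.DataFrame(
                rows, columns=["subject", "group", "time", "value"]))
        detections += res.p_interaction < alpha
    return detections / n_reps


def report_render(report: dict) -> str:
    """Render the statistics report as a human-readable text summary.

    Values are printed exactly as stored (no recomputation), with units for
    every quantity.
    """
    required = ("meta", "baseline", "lps_response")
    missing = [k for k in required if k not in report]
    if missing:
        raise ValueError(f"report is missing sections: {missing}")
    units = {"perfusion": "ml/min/100 g", "t1": "ms", "liver_weight": "g",
             "tlbf": "ml/min/100 g"}
    lines = []
    meta = report["meta"]
    lines.append(f"Simulated study (seed {meta['seed']}): "
                 f"{meta['n_sham']} sham, {meta['n_bdl']} BDL "
                 f"({meta['n_bdl_post_lps']} BDL completed post-LPS)")
    lines.append("")
    lines.append("Baseline group comparison (mean ± SE)")
    for metric, entry in report["baseline"].items():
        u = units.get(metric, "")
        s, b = entry["sham"], entry["bdl"]
        lines.append(f"  {metric:<13} sham {s['mean']:8.1f} ± {s['se']:5.1f} {u}"
                     f" | BDL {b['mean']:8.1f} ± {b['se']:5.1f} {u}"
                     f" | {entry['test']} p = {entry['p']:.4f}")
    if "agreement" in report:
        ag = report["agreement"]
        lines.append("")
        lines.append("Agreement: FAIR ASL perfusion vs caval-subtraction TLBF")
        for key in ("overall", "sham", "bdl"):
            if key in ag:
                e = ag[key]
                lines.append(f"  {key:<8} bias {e['bias']:7.1f} ml/min/100 g, "
                             f"95% LoA [{e['loa_low']:7.1f}, {e['loa_high']:7.1f}]"
                             f" (n = {e['n']})")
        cov = ag["cov"]
        lines.append(f"  CoV: FAIR {cov['fair_pct']:.1f}% vs TLBF "
                     f"{cov['tlbf_pct']:.1f}%, F({cov['df'][0]}, {cov['df'][1]})"
                     f" = {cov['F']:.2f}, p = {cov['p']:.4f}")
    lines.append("")
    lines.append("LPS response (change from baseline, mean ± SE)")
    for metric, entry in report["lps_response"].items():
        u = units.get(metric, "")
        lines.append(f"  {metric}: interaction F({entry['df'][0]}, "
                     f"{entry['df'][1]}) = {entry['F']:.3f}, p = {entry['p']:.4f}")
        for g, ch in entry["group_changes"].items():
            ph = entry["posthoc"][g]
            lines.append(f"    {g:<5} {ch['mean']:+7.1f} ± {ch['se']:5.1f} {u}"
                         f" (n = {ch['n']}, post hoc p = {ph['p_bonferroni']:.4f})")
    return "\n".join(lines)
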