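"""Cohort-level orchestration: fits, reference methods, group statistics.

``run_pipeline`` walks a cohort manifest (one CSV row per subject/region
pointing at TAC tables), converts everything to SUV, fits the 1TCM and 2TCM
per region against the left-ventricle input, runs SRTM + Logan DVR with the
cerebellum reference for thalamus and midbrain, pairs BP_ND + 1 against the
Logan DVR, and produces group ANOVA/Tukey tables plus blood-curve
summaries. The report carries every number needed to recompute its
statistics (group n, means, SDs) and echoes the full configuration, so a
rerun with the same config and seed is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import LV_REGION
from .exceptions import PetkinError
from .fitting import FitOptions, compare_models
from .models import TissueSimulator
from .reference import dvr_from_bp, fit_srtm, logan_reference_dvr
from .reported_values import LATE_WINDOW_MIN
from .stats import anova_with_tukey, paired_compare
from .tac import SUV, SubjectMeta, late_window_summary, read_tac_table, to_suv

logger = logging.getLogger(__name__)

TARGET_REGIONS = ("thalamus", "midbrain")
REFERENCE_REGION = "cerebellum"


@dataclass(frozen=True)
class PipelineConfig:
    fit_options: FitOptions = field(default_factory=FitOptions)
    t_star: float | None = None  # None = automatic Logan start-time selection
    late_window_min: float = LATE_WINDOW_MIN
    pooled_k2_ref: bool = False  # median k2' across regions instead of per-region


def _load_subject(rows: pd.DataFrame, base: Path) -> dict:
    tacs = {}
    meta = None
    for _, row in rows.iterrows():
        tac = read_tac_table(base / row["path"])
        meta = SubjectMeta(
            injected_dose_mbq=float(row["injected_dose_mbq"]),
            body_weight_g=float(row["body_weight_g"]),
        )
        if tac.unit != SUV:
            tac = to_suv(tac, meta)
        tacs[row["region"]] = tac
    return {"tacs": tacs, "meta": meta}


def run_pipeline(manifest_path, config: PipelineConfig | None = None) -> dict:
    """Full analysis over a cohort manifest; returns the report bundle."""
    config = config or PipelineConfig()
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise PetkinError(f"{manifest_path}: empty manifest")
    base = manifest_path.parent

    fit_rows, dvr_rows, lv_rows, errors = [], [], [], []
    for (subject,), rows in manifest.groupby(["subject"], sort=True):
        try:
            data = _load_subject(rows, base)
            tacs = data["tacs"]
            if LV_REGION not in tacs:
                raise PetkinError(f"subject {subject}: no {LV_REGION} TAC")
            blood = tacs[LV_REGION]
            ligand = str(rows["ligand"].iloc[0])
            group = str(rows["group"].iloc[0])

            peak, late = late_window_summary(blood, config.late_window_min)
            lv_rows.append({"subject": subject, "ligand": ligand, "group": group,
                            "peak_suv": peak, "late_mean_suv": late})

            regions = {r: t for r, t in tacs.items() if r != LV_REGION}
            simulator = None
            fits2 = {}
            for region, tac in sorted(regions.items()):
                if simulator is None:
                    simulator = TissueSimulator(blood, tac.schedule,
                                                config.fit_options.grid_step)
                f1, f2, preferred = compare_models(tac, blood, config.fit_options)
                fits2[region] = f2
                fit_rows.append({
                    "subject": subject, "ligand": ligand, "group": group,
                    "region": region, "model": "2TCM",
                    "K1": f2.params.K1, "k2": f2.params.k2, "k3": f2.params.k3,
                    "k4": f2.params.k4, "vp": f2.params.vp, "bp_nd": f2.bp_nd,
                    "bp_reliable": f2.bp_reliable, "wss": f2.wss, "aic": f2.aic,
                    "aic_1tc": f1.aic, "preferred_model": preferred,
                    "seed": config.fit_options.seed,
                })

            if REFERENCE_REGION in regions:
                ref = regions[REFERENCE_REGION]
                srtm = {r: fit_srtm(regions[r], ref, config.fit_options)
                        for r in TARGET_REGIONS if r in regions}
                pooled = float(np.median([s.k2_ref for s in srtm.values()])) if srtm else None
                for region, s in srtm.items():
                    k2_ref = pooled if config.pooled_k2_ref else s.k2_ref
                    logan = logan_reference_dvr(regions[region], ref, k2_ref,
                                                t_star=config.t_star)
                    dvr_rows.append({
                        "subject": subject, "ligand": ligand, "group": group,
                        "region": region, "dvr": logan.dvr,
                        "intercept_min": logan.intercept, "t_star": logan.t_star,
                        "n_points": logan.n_points_used, "r_squared": logan.r_squared,
                        "k2_ref": k2_ref, "srtm_R1": s.R1, "srtm_k2": s.k2,
                        "srtm_BP": s.BP,
                        "bp_plus_one": dvr_from_bp(fits2[region].bp_nd),
                    })
        except Exception as exc:
            logger.warning("subject %s quarantined: %s", subject, exc)
            errors.append({"subject": str(subject), "error": str(exc)})

    fits = pd.DataFrame(fit_rows)
    dvr = pd.DataFrame(dvr_rows)
    lv = pd.DataFrame(lv_rows)

    report = {
        "config": _config_dict(config),
        "fits": fits,
        "reference": dvr,
        "lv_summary": lv,
        "errors": errors,
        "group_stats": _group_statistics(fits),
        "paired_bp_dvr": _paired_bp_vs_dvr(dvr),
        "lv_group_stats": _lv_group_statistics(lv),
    }
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


def _group_statistics(fits: pd.DataFrame) -> list[dict]:
    """ANOVA with Tukey HSD per (ligand, region, parameter) across groups."""
    out = []
    if fits.empty:
        return out
    for (ligand, region), sub in fits.groupby(["ligand", "region"], sort=True):
        for param in ("K1", "k2", "k3", "k4", "bp_nd"):
            groups = {g: grp[param].to_numpy() for g, grp in sub.groupby("group")}
            sizes = {g: int(v.size) for g, v in groups.items()}
            if len(groups) < 2 or min(sizes.values()) < 2:
                continue
            cmp_res = anova_with_tukey(groups)
            out.append({
                "ligand": ligand, "region": region, "parameter": param,
                "n": sizes,
                "means": {g: float(v.mean()) for g, v in groups.items()},
                "sds": {g: float(v.std(ddof=1)) for g, v in groups.items()},
                "F": cmp_res.f_statistic, "df": list(cmp_res.df),
                "p": cmp_res.p_value, "eta_squared": cmp_res.eta_squared,
                "eta_squared_ci": list(cmp_res.eta_squared_ci),
                "tukey": cmp_res.tukey.to_dict(orient="records"),
            })
    return out


def _paired_bp_vs_dvr(dvr: pd.DataFrame) -> list[dict]:
    out = []
    if dvr.empty:
        return out
    for (ligand, group, region), sub in dvr.groupby(
        ["ligand", "group", "region"], sort=True
    ):
        if len(sub) < 2:
            continue
        res = paired_compare(sub["bp_plus_one"].to_numpy(), sub["dvr"].to_numpy())
        out.append({
            "ligand": ligand, "group": group, "region": region, "n": int(len(sub)),
            "bp_plus_one_mean": float(sub["bp_plus_one"].mean()),
            "bp_plus_one_sd": float(sub["bp_plus_one"].std(ddof=1)),
            "dvr_mean": float(sub["dvr"].mean()),
            "dvr_sd": float(sub["dvr"].std(ddof=1)),
            "t": res.t_statistic, "df": res.df, "p": res.p_value,
        })
    return out


def _lv_group_statistics(lv: pd.DataFrame) -> list[dict]:
    out = []
    if lv.empty:
        return out
    for ligand, sub in lv.groupby("ligand", sort=True):
        for param in ("peak_suv", "late_mean_suv"):
            groups = {g: grp[param].to_numpy() for g, grp in sub.groupby("group")}
            if len(groups) < 2 or min(v.size for v in groups.values()) < 2:
                continue
            cmp_res = anova_with_tukey(groups)
            out.append({
                "ligand": ligand, "parameter": param,
                "n": {g: int(v.size) for g, v in groups.items()},
                "means": {g: float(v.mean()) for g, v in groups.items()},
                "sds": {g: float(v.std(ddof=1)) for g, v in groups.items()},
                "F": cmp_res.f_statistic, "p": cmp_res.p_value,
                "eta_squared": cmp_res.eta_squared,
            })
    return out


def write_report(report: dict, out_dir) -> Path:
    """Serialize the report bundle: CSV tables plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("fits", "reference", "lv_summary"):
        df = report[name]
        df.to_csv(out / f"{name}.csv", index=False)
    summary = {k: report[k] for k in
               ("config", "errors", "group_stats", "paired_bp_dvr", "lv_group_stats")}
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return path
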