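"""End-to-end orchestration: phantoms -> fits -> geometry -> profiles -> stats.

One :class:`RunConfig` drives the whole chain.  A run writes, under its
output directory: a manifest (config, versions, warning counts), the
expansion Z-profile table with cohort means and 95% CIs, overall
group-comparison tables, the per-tract Cohen's d / ANCOVA / FDR table and
the per-tract regression table.  Everything is deterministic given the
seed; per-stage randomness uses fixed offsets of the run seed.

Patient tract rows are keyed by (bundle, side): each patient's tracts are
relabeled affected/unaffected relative to that patient's lesion, and
controls (left/right averaged) serve as the comparator for both sides.
Scalar maps can come from the full bi-tensor fit (``maps_source =
"fitted"``) or analytically from the phantom ground truth
(``"ground_truth"``), which exercises the identical downstream chain at a
fraction of the cost.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cognition import DOMAINS, classify_vcd
from .datasets import DiffusionDataset
from .geometry import DEFAULT_DISTANCES, build_geometry
from .phantom import (PhantomSpec, default_spec, generate_cohort_table,
                      generate_control_cohort, generate_phantom)
from .profiles import (aggregate_profiles, cohort_profile, ring_means,
                       tract_means, zscore_profile)
from .registry import load_registry
from .stats import (ancova, anova_tukey, cohens_d, fdr_by_family,
                    impute_mode, tract_regression)
from .tensor import D_WATER, ScalarMaps, fit_dti, fit_free_water

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips losslessly to YAML."""

    out_dir: str = "perilesion_run"
    seed: int = 0
    n_patients: int = 66
    n_controls: int = 23
    grid_shape: tuple = (30, 30, 30)
    voxel_size_mm: float = 2.0
    noise_sigma: float = 0.02
    distances: tuple = DEFAULT_DISTANCES
    d_water: float = D_WATER
    reg_weight: float = 0.0
    ring_mode: str = "shell"            # shell | cumulative
    fdr_alpha: float = 0.05
    maps_source: str = "fitted"         # fitted | ground_truth
    effect_spec: dict = field(default_factory=lambda: {
        "processing_speed": (25.0, 0.6), "executive_functioning": (20.0, 0.8)})
    max_days_to_mri: float | None = None
    exclude_any_svd: bool = False

    def __post_init__(self):
        if self.ring_mode not in ("shell", "cumulative"):
            raise ValueError("ring_mode must be 'shell' or 'cumulative'")
        if self.maps_source not in ("fitted", "ground_truth"):
            raise ValueError("maps_source must be 'fitted' or 'ground_truth'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        d["distances"] = list(d["distances"])
        d["effect_spec"] = {k: list(v) for k, v in d["effect_spec"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "distances" in d:
            d["distances"] = tuple(d["distances"])
        if "effect_spec" in d:
            d["effect_spec"] = {k: tuple(v) for k, v in d["effect_spec"].items()}
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _patient_spec(base: PhantomSpec, i: int, run_seed: int) -> PhantomSpec:
    """Per-patient phantom: jittered lesion position, perturbed tissue."""
    rng = np.random.default_rng([run_seed, 1009, i])
    ext = np.asarray(base.grid_shape) * base.voxel_size_mm
    ld = base.lesion_def
    jitter = rng.uniform(-1.5 * base.voxel_size_mm, 1.5 * base.voxel_size_mm, 3)
    center = np.clip(np.asarray(ld.center_mm) + jitter,
                     ld.radius_mm + base.voxel_size_mm,
                     ext - ld.radius_mm - base.voxel_size_mm)
    bundles = []
    for b in base.bundle_defs:
        factors = 1.0 + base.control_cv * rng.standard_normal(3)
        lam = tuple(sorted(np.clip(np.asarray(b.eigenvalues) * factors,
                                   1e-5, None), reverse=True))
        bundles.append(replace(b, eigenvalues=lam))
    return replace(base, bundle_defs=tuple(bundles),
                   lesion_def=replace(ld, center_mm=tuple(center)),
                   seed=int(rng.integers(0, 2 ** 31 - 1)))


def _analysis_mask(truth, geometry) -> np.ndarray:
    """Voxels that any downstream statistic reads: tracts, lesion, rings."""
    mask = geometry.lesion_mask.copy()
    for m in geometry.tract_masks.values():
        mask |= m
    for m in geometry.ring_masks.values():
        mask |= m
    return mask


def _maps_for(data: DiffusionDataset, truth, cfg: RunConfig,
              mask=None) -> ScalarMaps:
    if cfg.maps_source == "ground_truth":
        maps = truth.to_scalar_maps(subject_id=data.subject_id)
        return maps
    if mask is not None:
        data = DiffusionDataset(data.signal, data.bvals, data.bvecs,
                                data.affine, brain_mask=mask,
                                subject_id=data.subject_id)
    init = fit_dti(data)
    return fit_free_water(data, init, d_water=cfg.d_water,
                          reg_weight=cfg.reg_weight)


def _base_and_side(tract: str, side_labels: dict, registry) -> tuple[str, str]:
    return registry.homologue_base(tract), side_labels.get(tract, "unaffected")


def run_pipeline(config: RunConfig) -> str:
    """Execute the full analysis; returns the run directory path."""
    cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    registry = load_registry()
    caught: list[str] = []

    base = default_spec(grid_shape=cfg.grid_shape,
                        voxel_size_mm=cfg.voxel_size_mm,
                        noise_sigma=cfg.noise_sigma,
                        n_controls=cfg.n_controls, seed=cfg.seed)

    with warnings.catch_warnings(record=True) as wlog:
        warnings.simplefilter("always")

        # ---- controls: shared geometry, analytic or fitted maps
        controls = generate_control_cohort(base, cfg.n_controls,
                                           return_truth=True)
        control_maps = []
        for cdata, ctruth in controls:
            # downstream statistics only read bundle voxels for controls
            cmask = None
            if cfg.maps_source == "fitted":
                cmask = np.zeros(cfg.grid_shape, dtype=bool)
                for m in ctruth.bundle_masks.values():
                    cmask |= m
            control_maps.append(_maps_for(cdata, ctruth, cfg, mask=cmask))

        # ---- patients
        patient_rows = []        # tract metric rows keyed (bundle, side)
        per_patient_profiles = []
        lesion_volumes = []
        overall_fa_t = []
        for i in range(cfg.n_patients):
            spec = _patient_spec(base, i, cfg.seed)
            data, truth = generate_phantom(spec)
            data.subject_id = f"patient-{i:02d}"
            geometry = build_geometry(truth.lesion_mask, truth.bundle_masks,
                                      registry, truth.affine,
                                      distances=cfg.distances,
                                      cumulative=(cfg.ring_mode == "cumulative"))
            mask = _analysis_mask(truth, geometry) if cfg.maps_source == "fitted" else None
            maps = _maps_for(data, truth, cfg, mask=mask)
            maps.subject_id = data.subject_id
            lesion_volumes.append(geometry.lesion_volume_mL)

            # expansion profile, controls evaluated at this patient's rings
            pmeans = ring_means(maps, geometry)
            cmeans = [ring_means(cm, geometry) for cm in control_maps]
            if not pmeans.empty:
                prof = zscore_profile(pmeans, cmeans)
                per_patient_profiles.append(aggregate_profiles(prof))

            tm = tract_means(maps, geometry.tract_masks, geometry.lesion_mask,
                             registry, side_labels=geometry.side_labels)
            tm["group_subject"] = data.subject_id
            for _, r in tm.iterrows():
                if r["tract"] == "OVERALL":
                    if r["measure"] == "FA_T":
                        overall_fa_t.append(r["value"])
                    patient_rows.append({"subject": data.subject_id,
                                         "bundle": "OVERALL", "side": "overall",
                                         "measure": r["measure"],
                                         "value": r["value"]})
                else:
                    b, s = _base_and_side(r["tract"], geometry.side_labels,
                                          registry)
                    patient_rows.append({"subject": data.subject_id,
                                         "bundle": b, "side": s,
                                         "measure": r["measure"],
                                         "value": r["value"]})
        patient_tract = pd.DataFrame(patient_rows)

        # control tract table (left/right averaged; no lesion)
        control_rows = []
        for cm, (cdata, ctruth) in zip(control_maps, controls):
            tm = tract_means(cm, ctruth.bundle_masks, None, registry,
                             is_control=True)
            for _, r in tm.iterrows():
                control_rows.append({"subject": cm.subject_id,
                                     "bundle": r["tract"],
                                     "side": r["side"],
                                     "measure": r["measure"],
                                     "value": r["value"]})
        control_tract = pd.DataFrame(control_rows)

        # ---- cohort table: cognition linked to overall FA_T
        cohort = generate_cohort_table(
            cfg.n_patients, cfg.effect_spec, seed=cfg.seed,
            tract_metric=np.asarray(overall_fa_t),
            lesion_volumes_mL=lesion_volumes)
        cohort["vcd_status"] = [
            classify_vcd({d: row[d] for d in DOMAINS})
            for _, row in cohort.iterrows()]
        cohort["group"] = np.where(cohort["vcd_status"] == "major",
                                   "major VCD", "no/mild VCD")

        # cohort filters (post-hoc subgroup capability)
        if cfg.max_days_to_mri is not None:
            cohort = cohort[cohort["days_to_mri"] <= cfg.max_days_to_mri]
        if cfg.exclude_any_svd:
            cohort = cohort[cohort["svd_score"] == 0]
        if cohort.empty:
            raise RuntimeError("cohort is empty after applying filters; "
                               "relax max_days_to_mri / exclude_any_svd")
        cohort = cohort.reset_index(drop=True)
        cohort["depression"] = impute_mode(cohort["depression"])
        keep = set(cohort["subject"])
        patient_tract = patient_tract[patient_tract["subject"].isin(keep)]
        per_patient_profiles = [p for p in per_patient_profiles
                                if p["subject"].iloc[0] in keep]

        rng_ctrl = np.random.default_rng([cfg.seed, 53])
        control_depression = pd.Series(
            rng_ctrl.binomial(1, 0.05, cfg.n_controls).astype(float))

        # ---- outputs -----------------------------------------------------
        # Expansion-profile table with cohort CI + ANOVA across distances
        profile_tbl = cohort_profile(per_patient_profiles)
        allprof = pd.concat(per_patient_profiles, ignore_index=True)
        anova_rows = []
        for m, sub in allprof.groupby("measure"):
            groups = {f"{d:g}mm": g["z"].dropna().to_numpy()
                      for d, g in sub.groupby("distance_mm")}
            groups = {k: v for k, v in groups.items() if len(v) >= 2}
            if len(groups) >= 3:
                res = anova_tukey(groups)
                anova_rows.append({"measure": m, "F": res.f_stat,
                                   "p": res.p_value})
        expansion_anova = pd.DataFrame(anova_rows)

        # Overall comparisons (control vs no/mild vs major)
        overall_rows = []
        for m in ScalarMaps.MEASURES:
            ctrl_vals = control_tract.query(
                "bundle == 'OVERALL' and measure == @m")["value"].dropna()
            pat = patient_tract.query(
                "bundle == 'OVERALL' and measure == @m").merge(
                cohort[["subject", "group"]], on="subject")
            groups = {"control": ctrl_vals.to_numpy()}
            for gname, g in pat.groupby("group"):
                groups[gname] = g["value"].dropna().to_numpy()
            groups = {k: v for k, v in groups.items() if len(v) >= 2}
            if len(groups) >= 3:
                res = anova_tukey(groups)
                overall_rows.append({"measure": m, "F": res.f_stat,
                                     "p": res.p_value})
        overall_anova = pd.DataFrame(overall_rows)

        # Per-tract group stats: Cohen's d + ANCOVA, FDR per family
        tract_stats = _per_tract_stats(patient_tract, control_tract, cohort,
                                       control_depression)
        if not tract_stats.empty:
            tract_stats = fdr_by_family(tract_stats, p_col="p",
                                        family_cols=("analysis", "measure",
                                                     "side"))

        # Per-tract regressions on domain Z-scores, FDR per family
        regress = _per_tract_regressions(patient_tract, cohort, cfg)
        if not regress.empty:
            regress = fdr_by_family(regress, p_col="p",
                                    family_cols=("domain", "measure", "side"))

        caught = [str(w.message) for w in wlog]

    # ---- write run directory
    tables = {
        "profile_cohort.tsv": profile_tbl,
        "profile_patients.tsv": allprof,
        "expansion_anova.tsv": expansion_anova,
        "overall_anova.tsv": overall_anova,
        "tract_stats.tsv": tract_stats,
        "tract_regressions.tsv": regress,
        "cohort.tsv": cohort,
        "patient_tract_metrics.tsv": patient_tract,
        "control_tract_metrics.tsv": control_tract,
    }
    for name, tbl in tables.items():
        tbl.to_csv(os.path.join(cfg.out_dir, name), sep="\t", index=False,
                   float_format="%.10g")
    cfg.save(os.path.join(cfg.out_dir, "config.yaml"))

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_patients_analyzed": int(cohort.shape[0]),
        "n_controls": int(cfg.n_controls),
        "warning_counts": _count_warnings(caught),
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return cfg.out_dir


def _count_warnings(messages) -> dict:
    counts: dict[str, int] = {}
    for m in messages:
        key = m.split(":")[0][:60]
        counts[key] = counts.get(key, 0) + 1
    return counts


def _per_tract_stats(patient_tract, control_tract, cohort,
                     control_depression) -> pd.DataFrame:
    """Cohen's d (control minus patient) and covariate-adjusted group test
    per (bundle, side, measure)."""
    rows = []
    pat = patient_tract.query("bundle != 'OVERALL'").merge(
        cohort[["subject", "group", "depression", "lesion_volume_mL"]],
        on="subject")
    for (bundle, side, measure), sub in pat.groupby(
            ["bundle", "side", "measure"]):
        ctrl = control_tract.query(
            "bundle == @bundle and measure == @measure")["value"].dropna()
        vals = sub["value"].dropna()
        if len(ctrl) < 2 or len(vals) < 2:
            continue
        d = cohens_d(ctrl.to_numpy(), vals.to_numpy())
        # three-group ANCOVA controlling for depression
        y = np.concatenate([ctrl.to_numpy(), sub["value"].to_numpy()])
        grp = np.concatenate([["control"] * len(ctrl), sub["group"].to_numpy()])
        dep = np.concatenate([control_depression.iloc[:len(ctrl)].to_numpy(),
                              sub["depression"].to_numpy()])
        p = np.nan
        if len(np.unique(grp)) >= 2 and np.isfinite(y).all():
            try:
                p, _ = ancova(y, grp, {"depression": dep})
            except ValueError:
                pass
        rows.append({"analysis": "groups", "bundle": bundle, "side": side,
                     "measure": measure, "cohens_d": d, "p": p,
                     "n_patients": len(vals), "n_controls": len(ctrl)})
        # patient-only contrast additionally controls lesion volume
        if sub["group"].nunique() == 2:
            try:
                p2, _ = ancova(sub["value"].to_numpy(), sub["group"],
                               sub[["depression", "lesion_volume_mL"]])
                rows.append({"analysis": "no/mild-vs-major", "bundle": bundle,
                             "side": side, "measure": measure,
                             "cohens_d": np.nan, "p": p2,
                             "n_patients": len(vals), "n_controls": 0})
            except ValueError:
                pass
    return pd.DataFrame(rows)


def _per_tract_regressions(patient_tract, cohort, cfg) -> pd.DataFrame:
    """Domain Z ~ tract measure + lesion volume + depression, per tract."""
    rows = []
    pat = patient_tract.query("bundle != 'OVERALL'").merge(
        cohort, on="subject")
    for (bundle, side, measure), sub in pat.groupby(
            ["bundle", "side", "measure"]):
        sub = sub.dropna(subset=["value"])
        for domain in DOMAINS:
            if len(sub) <= 4:
                continue
            try:
                res = tract_regression(
                    sub[domain], sub["value"],
                    sub[["lesion_volume_mL", "depression"]])
            except ValueError:
                continue
            rows.append({"domain": domain, "bundle": bundle, "side": side,
                         "measure": measure, "slope": res.slope,
                         "adjusted_r2": res.adjusted_r2, "p": res.p_value,
                         "n": res.n})
    return pd.DataFrame(rows)
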