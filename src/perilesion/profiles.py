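"""Control-referenced Z-score profiles and tract-mean tables.

Diffusion measures are evaluated per lesioned tract within each expansion
ring (ring voxels intersected with the tract mask, lesion voxels always
excluded).  Controls — on the same grid — are evaluated at exactly the
patient's locations, and the patient's value is Z-scored against the
control mean and sample standard deviation (n-1 denominator; with 23
controls the distinction is material).  Per-tract profiles are then
averaged across lesioned tracts into a single Z per expansion distance
and measure, and cohort-level curves carry a normal-theory 95% CI.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry import LesionTractGeometry
from .registry import TractRegistry
from .tensor import ScalarMaps

__all__ = [
    "ring_means", "zscore_profile", "aggregate_profiles", "cohort_profile",
    "tract_means", "ZProfile",
]

MEASURES = ScalarMaps.MEASURES


class ZProfile(pd.DataFrame):
    """Long-format profile table: columns (tract, measure, distance_mm, z,
    control_mean, control_sd, n_controls, defined)."""

    @property
    def _constructor(self):
        return ZProfile


def _masked_mean(values, mask):
    vals = values[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return np.nan, 0
    return float(vals.mean()), int(vals.size)


def ring_means(maps: ScalarMaps, geometry: LesionTractGeometry,
               measures=MEASURES, per_tract: bool = True,
               restrict_to_tracts: bool = True) -> pd.DataFrame:
    """Mean of each measure per expansion distance (and lesioned tract).

    Evaluation is restricted to ring ∩ tract-mask \\ lesion voxels by
    default; ``restrict_to_tracts=False`` evaluates whole rings (sensitivity
    mode).  Empty intersections yield NaN with a warning.  With no lesioned
    tract the result is an empty frame (the Z-profile stage is skipped).
    """
    lesion = geometry.lesion_mask
    rows = []
    if restrict_to_tracts:
        tract_items = sorted(geometry.lesioned_tracts)
        if not tract_items:
            warnings.warn("no lesioned tracts: Z-profile will be empty")
            return pd.DataFrame(columns=["subject", "tract", "measure",
                                         "distance_mm", "value", "n_voxels"])
        if not per_tract:
            union = np.zeros_like(lesion, dtype=bool)
            for t in tract_items:
                union |= geometry.tract_masks[t]
            tract_sets = [("all_lesioned", union)]
        else:
            tract_sets = [(t, geometry.tract_masks[t]) for t in tract_items]
    else:
        tract_sets = [("whole_ring", np.ones_like(lesion, dtype=bool))]

    for tract, tmask in tract_sets:
        for d, ring in sorted(geometry.ring_masks.items()):
            region = ring & tmask & ~lesion
            for m in measures:
                val, n = _masked_mean(maps[m], region)
                if n == 0:
                    warnings.warn(
                        f"empty ring: tract={tract} d={d} mm has no voxels")
                rows.append({"subject": maps.subject_id, "tract": tract,
                             "measure": m, "distance_mm": d,
                             "value": val, "n_voxels": n})
    return pd.DataFrame(rows)


def zscore_profile(patient_means: pd.DataFrame,
                   control_means: list[pd.DataFrame]) -> ZProfile:
    """Z-score patient ring means against matched control ring means.

    ``control_means`` holds one frame per control, produced by
    :func:`ring_means` with the *patient's* geometry (shared grid stands in
    for control-to-patient registration).  Z = (patient - mean) / sd with
    the sample (n-1) SD across controls; cells with sd = 0 or fewer than
    two finite control values are flagged undefined.
    """
    if len(control_means) < 2:
        raise ValueError("need >= 2 controls to compute a standard deviation")
    ctrl = pd.concat(control_means, ignore_index=True)
    key = ["tract", "measure", "distance_mm"]
    stats = (ctrl.groupby(key)["value"]
             .agg(control_mean="mean",
                  control_sd=lambda v: v.std(ddof=1),
                  n_controls=lambda v: v.notna().sum())
             .reset_index())
    out = patient_means.merge(stats, on=key, how="left")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (out["value"] - out["control_mean"]) / out["control_sd"]
    defined = (out["control_sd"] > 0) & (out["n_controls"] >= 2) & out["value"].notna()
    out["z"] = np.where(defined, z, np.nan)
    out["defined"] = defined
    return ZProfile(out)


def aggregate_profiles(profile: ZProfile) -> pd.DataFrame:
    """Average per-tract Z-scores across lesioned tracts.

    Returns one row per (measure, distance) with the unweighted mean Z over
    tracts (missing values excluded pairwise); all-missing cells stay NaN.
    """
    if profile.empty:
        raise ValueError("no lesioned-tract profiles to aggregate")
    agg = (profile.groupby(["measure", "distance_mm"])["z"]
           .agg(z="mean", n_tracts=lambda v: v.notna().sum())
           .reset_index())
    if "subject" in profile.columns and profile["subject"].nunique() == 1:
        agg.insert(0, "subject", profile["subject"].iloc[0])
    return pd.DataFrame(agg)


def cohort_profile(per_patient: list[pd.DataFrame]) -> pd.DataFrame:
    """Cohort mean Z per (measure, distance) with a 95% CI (mean ± 1.96·SE)."""
    allp = pd.concat(per_patient, ignore_index=True)

    def _summ(v):
        v = v.dropna()
        n = len(v)
        mean = v.mean() if n else np.nan
        se = v.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        return pd.Series({"z_mean": mean, "ci_low": mean - 1.96 * se,
                          "ci_high": mean + 1.96 * se, "n_patients": n})

    out = (allp.groupby(["measure", "distance_mm"])["z"]
           .apply(_summ).unstack().reset_index())
    return out


def tract_means(maps: ScalarMaps, tract_masks: dict, lesion_mask,
                registry: TractRegistry, is_control: bool = False,
                side_labels: dict | None = None,
                measures=MEASURES) -> pd.DataFrame:
    """Per-tract mean of each measure outside the lesion.

    Excluded registry tracts (fornix, striatal projections) are dropped.
    For controls the left/right homologues are averaged into a single row
    per bundle (side = ``both``).  Rows carry the affected/unaffected side
    label when ``side_labels`` is given.  The per-subject overall mean
    across tracts is appended as tract = ``OVERALL``.
    """
    lesion = (np.zeros(next(iter(tract_masks.values())).shape, dtype=bool)
              if lesion_mask is None else np.asarray(lesion_mask).astype(bool))
    excluded = registry.excluded
    rows = []
    for name, mask in sorted(tract_masks.items()):
        if name in excluded:
            continue
        region = np.asarray(mask).astype(bool) & ~lesion
        for m in measures:
            val, n = _masked_mean(maps[m], region)
            if n == 0:
                warnings.warn(f"tract {name} empty after lesion removal")
            rows.append({"subject": maps.subject_id, "tract": name,
                         "measure": m, "value": val, "n_voxels": n})
    df = pd.DataFrame(rows)
    if df.empty:
        return df

    if is_control:
        df["base"] = [registry.homologue_base(t) if t in registry.names else t
                      for t in df["tract"]]
        df = (df.groupby(["subject", "base", "measure"], as_index=False)
              .agg(value=("value", "mean"), n_voxels=("n_voxels", "sum")))
        df = df.rename(columns={"base": "tract"})
        df["side"] = "both"
    elif side_labels is not None:
        df["side"] = [side_labels.get(t, "unaffected") for t in df["tract"]]
    else:
        df["side"] = "unknown"

    overall = (df.groupby(["subject", "measure"], as_index=False)
               .agg(value=("value", "mean")))
    overall["tract"] = "OVERALL"
    overall["side"] = "overall"
    overall["n_voxels"] = np.nan
    return pd.concat([df, overall], ignore_index=True)
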