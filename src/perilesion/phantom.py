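"""Synthetic diffusion phantoms with bundles, crossings, lesions and cohorts.

The generator produces co-registered patient and control datasets so the
whole analysis chain (bi-tensor fitting, perilesional rings, control
referenced Z-profiles, tract statistics) can run without external data.
Each phantom is a grid of bi-tensor voxels: white-matter bundles are
geometric tubes (straight or circular-arc) carrying an anisotropic tissue
tensor oriented along the local tangent; where two bundles overlap the
tissue signal is the equal-weight sum of both bundles' attenuations
(a crossing-fiber region); everywhere a free-water compartment with fixed
diffusivity adds isotropic signal.  A spherical lesion imposes a radial
damage gradient: anisotropy is depressed and the free-water fraction
elevated by amounts that decay exponentially with distance from the lesion,
mimicking perilesional degeneration.  Noise is Rician, the magnitude-MRI
convention.  All randomness derives from a single seed; per-subject streams
use fixed offsets, so outputs are bit-reproducible.

The default acquisition scheme is multi-shell with 3 b=0 volumes and 100
diffusion-weighted volumes at b = 50(3), 150(7), 350(30), 1000(60) s/mm^2
on 2 mm isotropic voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .datasets import DiffusionDataset, make_affine
from .tensor import D_WATER, ScalarMaps, scalars_from_eigenvalues

__all__ = [
    "BundleDef", "LesionDef", "PhantomSpec", "GroundTruth",
    "generate_phantom", "generate_control_cohort", "generate_cohort_table",
    "DEFAULT_SHELL_SCHEME", "default_spec",
]

#: (b-value s/mm^2, volume count): 3 b0 + 100 diffusion-weighted volumes
DEFAULT_SHELL_SCHEME = ((0, 3), (50, 3), (150, 7), (350, 30), (1000, 60))

#: background (non-bundle) tissue: isotropic, grey-matter-like diffusivity
_BG_DIFFUSIVITY = 0.7e-3


@dataclass(frozen=True)
class BundleDef:
    """A tube-shaped bundle with its tissue tensor.

    ``axis`` is the tube direction; with nonzero ``curvature_per_mm`` the
    centerline is a circular arc of radius 1/curvature bending toward
    ``bend`` (default: +z, or +y for z-aligned bundles).  ``eigenvalues``
    are the tissue tensor eigenvalues in mm^2/s, principal axis along the
    local tangent.
    """

    name: str
    axis: tuple[float, float, float]
    center_mm: tuple[float, float, float]
    radius_mm: float = 4.0
    eigenvalues: tuple[float, float, float] = (1.5e-3, 0.3e-3, 0.3e-3)
    curvature_per_mm: float = 0.0


@dataclass(frozen=True)
class LesionDef:
    """Spherical lesion with an exponentially decaying damage gradient.

    At distance d (mm) from the lesion surface the anisotropy of each
    bundle tensor is depressed by ``fa_depression_amp * exp(-d/decay)`` —
    non-decreasing toward baseline with distance — and the free-water
    fraction elevated by ``fw_elevation_amp * exp(-d/decay)`` —
    non-increasing with distance.  Inside the lesion the depression applies
    in full and f is raised to at least ``fw_inside``.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float = 5.0
    fa_depression_amp: float = 0.6
    fw_elevation_amp: float = 0.4
    decay_scale_mm: float = 4.0
    fw_inside: float = 0.8


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic acquisition."""

    grid_shape: tuple[int, int, int] = (30, 30, 30)
    voxel_size_mm: float = 2.0
    shell_scheme: tuple = DEFAULT_SHELL_SCHEME
    bundle_defs: tuple[BundleDef, ...] = ()
    lesion_def: LesionDef | None = None
    n_controls: int = 23
    noise_sigma: float = 0.0
    s0: float = 1000.0
    fw_background: float = 0.05
    control_cv: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        bvals = [b for b, _ in self.shell_scheme]
        if 0 not in bvals:
            raise ValueError("shell scheme must include at least one b=0 volume")
        if any(c < 1 for _, c in self.shell_scheme):
            raise ValueError("shell counts must be >= 1")
        names = [b.name for b in self.bundle_defs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate bundle names")
        if self.lesion_def is not None:
            extent = np.asarray(self.grid_shape) * self.voxel_size_mm
            c = np.asarray(self.lesion_def.center_mm)
            r = self.lesion_def.radius_mm
            if np.any(c - r < 0) or np.any(c + r > extent):
                raise ValueError("lesion extends outside the grid")

    @property
    def n_volumes(self) -> int:
        return sum(c for _, c in self.shell_scheme)

    @property
    def n_dw_volumes(self) -> int:
        """Diffusion-weighted (b > 0) volume count."""
        return sum(c for b, c in self.shell_scheme if b > 0)


def default_spec(**overrides) -> PhantomSpec:
    """Default phantom: two crossing bundles with a lesion on one of them.

    Bundle geometry is named after real bundles only so that downstream
    registry lookups work; the shapes are simple tubes, not anatomy.
    """
    grid = overrides.pop("grid_shape", (30, 30, 30))
    vs = overrides.pop("voxel_size_mm", 2.0)
    ext = np.asarray(grid) * vs
    cx, cy, cz = ext / 2
    bundles = overrides.pop("bundle_defs", (
        BundleDef("CC_4", axis=(1, 0, 0), center_mm=(cx, cy, cz),
                  radius_mm=2.2 * vs),
        BundleDef("CST_right", axis=(0, 1, 0), center_mm=(cx, cy, cz),
                  radius_mm=2.2 * vs,
                  eigenvalues=(1.4e-3, 0.35e-3, 0.35e-3)),
    ))
    lesion_radius = min(2.2 * vs, float(ext.min()) / 6.0)
    lesion = overrides.pop("lesion_def", LesionDef(
        center_mm=(cx - 0.2 * ext[0], cy, cz), radius_mm=lesion_radius))
    return PhantomSpec(grid_shape=tuple(grid), voxel_size_mm=vs,
                       bundle_defs=tuple(bundles), lesion_def=lesion,
                       **overrides)


# ---------------------------------------------------------------------------
# geometry helpers


def _voxel_centers_mm(grid_shape, voxel_size_mm):
    axes = [(np.arange(n) + 0.5) * voxel_size_mm for n in grid_shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.stack([X, Y, Z], axis=-1)          # (X, Y, Z, 3)


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length axis")
    return v / n


def _bundle_geometry(bundle: BundleDef, centers):
    """Mask and per-voxel tangent of a (possibly curved) tube."""
    axis = _unit(bundle.axis)
    c = np.asarray(bundle.center_mm, dtype=float)
    if bundle.curvature_per_mm == 0.0:
        rel = centers - c
        along = rel @ axis
        perp = rel - along[..., None] * axis
        dist = np.linalg.norm(perp, axis=-1)
        mask = dist <= bundle.radius_mm
        tang = np.broadcast_to(axis, centers.shape).copy()
        return mask, tang
    # circular arc: sample the centerline densely, take nearest point
    bend = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    bend = _unit(bend - (bend @ axis) * axis)
    R = 1.0 / bundle.curvature_per_mm
    half_len = 1.5 * float(np.max(centers[..., 0]))   # generous arc length
    t = np.linspace(-half_len, half_len, 512)
    theta = t / R
    pts = c + R * np.sin(theta)[:, None] * axis + R * (1 - np.cos(theta))[:, None] * bend
    tangents = np.cos(theta)[:, None] * axis + np.sin(theta)[:, None] * bend
    flat = centers.reshape(-1, 3)
    d2 = ((flat[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    nearest = d2.argmin(axis=1)
    dist = np.sqrt(d2[np.arange(len(flat)), nearest]).reshape(centers.shape[:3])
    mask = dist <= bundle.radius_mm
    tang = tangents[nearest].reshape(centers.shape)
    return mask, tang


def _tensor_field(tangent, eigenvalues):
    """Axisymmetric tensors with principal axis along ``tangent``."""
    l1, l2, l3 = eigenvalues
    lperp = 0.5 * (l2 + l3)
    t = tangent / np.linalg.norm(tangent, axis=-1, keepdims=True)
    outer = np.einsum("...i,...j->...ij", t, t)
    return lperp * np.eye(3) + (l1 - lperp) * outer


# ---------------------------------------------------------------------------
# ground truth container


@dataclass
class GroundTruth:
    """Per-voxel truth underlying a phantom, for recovery tests."""

    tissue_tensor_field: np.ndarray      # (X, Y, Z, 3, 3), mm^2/s
    fw_fraction_field: np.ndarray        # (X, Y, Z) in [0, 1]
    bundle_masks: dict                   # name -> bool grid
    lesion_mask: np.ndarray              # bool grid
    affine: np.ndarray

    def __post_init__(self):
        w = np.linalg.eigvalsh(self.tissue_tensor_field)
        if np.any(w < -1e-10):
            raise ValueError("tissue tensors must be positive semidefinite")
        f = self.fw_fraction_field
        if np.any((f < 0) | (f > 1)):
            raise ValueError("free-water fraction must lie in [0, 1]")
        shape = self.fw_fraction_field.shape
        for name, m in self.bundle_masks.items():
            if m.shape != shape:
                raise ValueError(f"bundle mask {name!r} shape mismatch")
        if self.lesion_mask.shape != shape:
            raise ValueError("lesion mask shape mismatch")

    def to_scalar_maps(self, subject_id="truth") -> ScalarMaps:
        """Analytic scalar maps from the true tissue tensors and f field.

        The uncorrected maps are set equal to the tissue maps (ground truth
        has no fitting step); FW is the true fraction.
        """
        w = np.linalg.eigvalsh(self.tissue_tensor_field)[..., ::-1]
        w = np.clip(w, 0.0, None)
        fa, md, mo = scalars_from_eigenvalues(w[..., 0], w[..., 1], w[..., 2])
        return ScalarMaps(fa=fa.copy(), md=md.copy(), mo=mo.copy(),
                          fa_t=fa, md_t=md, mo_t=mo,
                          fw=self.fw_fraction_field.copy(),
                          affine=self.affine, subject_id=subject_id)


# ---------------------------------------------------------------------------
# forward simulation


def _gradient_table(shell_scheme):
    """Deterministic multi-shell gradient table (Fibonacci-sphere points)."""
    bvals, bvecs = [], []
    golden = (1 + 5 ** 0.5) / 2
    for shell_idx, (b, count) in enumerate(shell_scheme):
        if b == 0:
            bvals.extend([0.0] * count)
            bvecs.extend([[0.0, 0.0, 0.0]] * count)
            continue
        for i in range(count):
            # offset per shell so shells do not share directions
            u = ((i + 0.5) / count + 0.1 * shell_idx) % 1.0
            z = 1 - 2 * u
            r = np.sqrt(max(0.0, 1 - z * z))
            phi = 2 * np.pi * ((i / golden + 0.37 * shell_idx) % 1.0)
            bvecs.append([r * np.cos(phi), r * np.sin(phi), z])
            bvals.append(float(b))
    return np.asarray(bvals), np.asarray(bvecs)


def _damage_fields(spec: PhantomSpec):
    """Lesion mask, surface distance (mm), FA depression and FW elevation."""
    shape = spec.grid_shape
    if spec.lesion_def is None:
        zeros = np.zeros(shape)
        return np.zeros(shape, dtype=bool), zeros, zeros, zeros
    ld = spec.lesion_def
    centers = _voxel_centers_mm(shape, spec.voxel_size_mm)
    lesion = np.linalg.norm(centers - np.asarray(ld.center_mm), axis=-1) <= ld.radius_mm
    if not lesion.any():
        raise ValueError("lesion mask is empty at this resolution")
    dist = distance_transform_edt(~lesion, sampling=[spec.voxel_size_mm] * 3)
    dep = ld.fa_depression_amp * np.exp(-dist / ld.decay_scale_mm)
    fw_elev = ld.fw_elevation_amp * np.exp(-dist / ld.decay_scale_mm)
    return lesion, dist, dep, fw_elev


def _build_truth(spec: PhantomSpec):
    shape = spec.grid_shape
    centers = _voxel_centers_mm(shape, spec.voxel_size_mm)
    lesion, _, dep, fw_elev = _damage_fields(spec)

    bundle_masks, bundle_tensors = {}, {}
    overlap = np.zeros(shape, dtype=int)
    for b in spec.bundle_defs:
        mask, tang = _bundle_geometry(b, centers)
        D = _tensor_field(tang, b.eigenvalues)
        # radial damage: shrink the deviatoric part toward isotropy
        md = np.trace(D, axis1=-2, axis2=-1)[..., None, None] / 3.0
        D = md * np.eye(3) + (1.0 - dep)[..., None, None] * (D - md * np.eye(3))
        bundle_masks[b.name] = mask
        bundle_tensors[b.name] = D
        overlap += mask
    if np.any(overlap > 2):
        raise ValueError("incompatible bundle definitions: more than two "
                         "bundles overlap in at least one voxel")
    if spec.lesion_def is not None:
        if spec.bundle_defs and not any(
                (m & lesion).any() for m in bundle_masks.values()):
            raise ValueError("lesion does not intersect any bundle")

    fw = np.full(shape, spec.fw_background, dtype=float) + fw_elev
    if spec.lesion_def is not None:
        fw[lesion] = np.maximum(fw[lesion], spec.lesion_def.fw_inside)
    fw = np.clip(fw, 0.0, 1.0)

    # mean tissue tensor (background isotropic outside bundles)
    mean_D = np.zeros(shape + (3, 3))
    for name, m in bundle_masks.items():
        mean_D[m] += bundle_tensors[name][m]
    in_bundle = overlap > 0
    mean_D[in_bundle] /= overlap[in_bundle][..., None, None]
    mean_D[~in_bundle] = _BG_DIFFUSIVITY * np.eye(3)
    truth = GroundTruth(mean_D, fw, bundle_masks, lesion,
                        make_affine(spec.voxel_size_mm))
    return truth, bundle_tensors, overlap


def generate_phantom(spec: PhantomSpec, rng=None):
    """Simulate one acquisition from ``spec``.

    Returns ``(DiffusionDataset, GroundTruth)``.  The signal follows the
    bi-tensor forward model with the free-water diffusivity fixed at
    3.0e-3 mm^2/s; crossing voxels mix the two bundles' tissue attenuations
    with equal weight; Rician noise of scale ``noise_sigma * s0`` is applied
    to the magnitude.  Deterministic given ``spec.seed``.
    """
    truth, bundle_tensors, overlap = _build_truth(spec)
    bvals, bvecs = _gradient_table(spec.shell_scheme)
    shape = spec.grid_shape
    n = len(bvals)

    att = np.zeros(shape + (n,))
    in_bundle = overlap > 0
    for name, mask in truth.bundle_masks.items():
        D = bundle_tensors[name][mask]                       # (V, 3, 3)
        q = np.einsum("vab,na,nb->vn", D, bvecs, bvecs)      # (V, N)
        att[mask] += np.exp(-bvals[None, :] * q)
    att[in_bundle] /= overlap[in_bundle][:, None]
    Dbg = truth.tissue_tensor_field[~in_bundle]
    qbg = np.einsum("vab,na,nb->vn", Dbg, bvecs, bvecs)
    att[~in_bundle] = np.exp(-bvals[None, :] * qbg)

    f = truth.fw_fraction_field[..., None]
    ew = np.exp(-bvals * D_WATER)
    signal = spec.s0 * (f * ew + (1.0 - f) * att)

    if spec.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        scale = spec.noise_sigma * spec.s0
        n1 = rng.normal(0.0, scale, signal.shape)
        n2 = rng.normal(0.0, scale, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)

    data = DiffusionDataset(signal, bvals, bvecs,
                            make_affine(spec.voxel_size_mm),
                            subject_id=f"phantom-{spec.seed}")
    return data, truth


def generate_control_cohort(spec: PhantomSpec, n: int | None = None,
                            return_truth: bool = False):
    """Generate ``n`` lesion-free datasets on the same grid as ``spec``.

    Each control perturbs the bundle eigenvalues and background free-water
    fraction multiplicatively with coefficient of variation
    ``spec.control_cv`` (per-subject streams at fixed seed offsets).  At
    least two controls are required — Z-scoring needs a standard deviation.
    Shared geometry stands in for control-to-patient registration.
    """
    if n is None:
        n = spec.n_controls
    if n < 2:
        raise ValueError("need >= 2 controls to define a standard deviation")
    out = []
    for i in range(n):
        rng = np.random.default_rng([spec.seed, 7919 + i])
        bundles = []
        for b in spec.bundle_defs:
            factors = 1.0 + spec.control_cv * rng.standard_normal(3)
            lam = tuple(np.clip(np.asarray(b.eigenvalues) * factors, 1e-5, None))
            lam = tuple(sorted(lam, reverse=True))
            bundles.append(replace(b, eigenvalues=lam))
        fw_bg = float(np.clip(
            spec.fw_background * (1.0 + spec.control_cv * rng.standard_normal()),
            0.0, 0.5))
        cspec = replace(spec, bundle_defs=tuple(bundles), lesion_def=None,
                        fw_background=fw_bg)
        data, truth = generate_phantom(cspec, rng=rng)
        data.subject_id = f"control-{i:02d}"
        if return_truth:
            out.append((data, truth))
        else:
            out.append(data)
    return out


# ---------------------------------------------------------------------------
# cohort tables


def generate_cohort_table(n_patients: int, effect_spec: dict, seed: int = 0,
                          metric_name: str = "FA_T", metric_mean: float = 0.45,
                          metric_sd: float = 0.04,
                          depression_rate: float = 0.15,
                          depression_missing_rate: float = 0.05,
                          lesion_volumes_mL=None,
                          tract_metric=None) -> pd.DataFrame:
    """Simulate a per-subject table with known metric-to-cognition effects.

    ``effect_spec`` maps cognitive-domain names to ``(slope, noise_sd)``:
    the domain Z-score is ``slope * (metric - mean(metric)) + noise``.
    Unknown domain names raise KeyError.  The depression indicator is
    Bernoulli with configurable missingness; lesion volumes default to a
    log-normal distribution with median near 1 mL (use
    ``lesion_volumes_mL`` to supply volumes measured from actual masks).
    """
    from .cognition import DOMAINS

    unknown = set(effect_spec) - set(DOMAINS)
    if unknown:
        raise KeyError(f"unknown cognitive domain(s): {sorted(unknown)}")
    for d, (slope, noise_sd) in effect_spec.items():
        if not np.isfinite(slope):
            raise ValueError(f"non-finite slope for domain {d!r}")
        if noise_sd < 0:
            raise ValueError(f"negative noise SD for domain {d!r}")

    rng = np.random.default_rng([seed, 104729])
    if tract_metric is not None:
        metric = np.asarray(tract_metric, dtype=float)
        if len(metric) != n_patients:
            raise ValueError("tract_metric length must equal n_patients")
    else:
        metric = rng.normal(metric_mean, metric_sd, n_patients)

    table = pd.DataFrame({
        "subject": [f"patient-{i:02d}" for i in range(n_patients)],
        metric_name: metric,
    })
    centered = metric - metric.mean()
    for d in DOMAINS:
        slope, noise_sd = effect_spec.get(d, (0.0, 1.0))
        table[d] = slope * centered + rng.normal(0.0, noise_sd, n_patients)

    dep = rng.binomial(1, depression_rate, n_patients).astype(float)
    missing = rng.random(n_patients) < depression_missing_rate
    dep[missing] = np.nan
    table["depression"] = dep

    if lesion_volumes_mL is not None:
        table["lesion_volume_mL"] = np.asarray(lesion_volumes_mL, dtype=float)
    else:
        table["lesion_volume_mL"] = np.exp(rng.normal(0.0, 1.2, n_patients))
    table["days_to_mri"] = np.round(np.exp(rng.normal(np.log(30.0), 1.0, n_patients)))
    table["svd_score"] = rng.choice([0, 0, 0, 1, 2], size=n_patients)
    return table
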