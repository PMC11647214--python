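"""Single-tensor and free-water-eliminated (bi-tensor) diffusion models.

The single-tensor model is fitted by weighted least squares on the
log-signal.  The free-water model separates each voxel's signal into an
isotropic compartment with fixed diffusivity ``d_water`` (3.0e-3 mm^2/s,
body-temperature free water) and a tissue tensor:

    S_k = S0 * [ f * exp(-b_k * d_water) + (1 - f) * exp(-b_k * g_k' D g_k) ]

with volume fraction f in [0, 1] and D symmetric positive semidefinite.
The tissue tensor is parameterized by its log-Cholesky factor so that
positive semidefiniteness is guaranteed during unconstrained optimization,
and the fit is solved per voxel with a trust-region nonlinear least-squares
solver using an analytic Jacobian.  An optional spatial regularization term
penalizes the squared difference of the tensor parameters to their
6-neighborhood mean; with ``reg_weight=0`` the fit is purely voxelwise.

Scalar maps: MD is the eigenvalue mean, FA the normalized eigenvalue
dispersion, and MO the mode of anisotropy (the normalized third invariant
of the deviatoric tensor, +1 prolate / -1 oblate).  Free-water-corrected
maps (FA_T, MD_T, MO_T) come from the fitted tissue tensor; FW is the
fitted fraction f.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .datasets import DiffusionDataset, save_nifti, load_nifti

__all__ = [
    "TensorFit",
    "ScalarMaps",
    "fit_dti",
    "fit_free_water",
    "scalars_from_eigenvalues",
    "D_WATER",
]

#: free-water diffusivity at body temperature, mm^2/s
D_WATER = 3.0e-3

# internal unit scaling: b in ms/um^2, diffusivities in um^2/ms
_B_SCALE = 1e-3
_D_SCALE = 1e3


# ---------------------------------------------------------------------------
# scalar invariants


def scalars_from_eigenvalues(lam1, lam2, lam3):
    """FA, MD and MO from sorted tensor eigenvalues (lam1 >= lam2 >= lam3 >= 0).

    MD = (l1+l2+l3)/3;  FA = sqrt(3/2) * ||l - MD|| / ||l||;
    MO = 3*sqrt(6) * det(deviatoric tensor normalized to unit Frobenius norm),
    which for eigenvalues reduces to the product of the normalized deviatoric
    eigenvalues.  All-zero eigenvalues return (0, 0, 0) by convention.
    """
    lam = np.stack(np.broadcast_arrays(
        np.asarray(lam1, dtype=float),
        np.asarray(lam2, dtype=float),
        np.asarray(lam3, dtype=float)), axis=-1)
    if np.any(np.diff(lam, axis=-1) > 1e-12) or np.any(lam[..., 2] < -1e-12):
        raise ValueError("eigenvalues must satisfy lam1 >= lam2 >= lam3 >= 0")
    md = lam.mean(axis=-1)
    dev = lam - md[..., None]
    dev_norm = np.linalg.norm(dev, axis=-1)
    lam_norm = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * dev_norm / lam_norm
        mo = 3.0 * np.sqrt(6.0) * np.prod(dev / np.where(
            dev_norm[..., None] > 0, dev_norm[..., None], 1.0), axis=-1)
    fa = np.where(lam_norm > 0, fa, 0.0)
    mo = np.where(dev_norm > 0, mo, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    mo = np.clip(mo, -1.0, 1.0)
    if fa.ndim == 0:
        return float(fa), float(md), float(mo)
    return fa, md, mo


def _eigs_descending(D):
    """Batched eigendecomposition, eigenvalues descending."""
    w, v = np.linalg.eigh(D)
    return w[..., ::-1], v[..., :, ::-1]


# ---------------------------------------------------------------------------
# containers


@dataclass
class TensorFit:
    """Per-voxel single-tensor fit on the acquisition grid.

    ``eigenvalues`` are sorted descending (mm^2/s) and clipped at zero;
    ``v1`` is the principal eigenvector.  ``valid`` marks voxels inside the
    brain mask with usable signal.
    """

    eigenvalues: np.ndarray      # (X, Y, Z, 3)
    eigenvectors: np.ndarray     # (X, Y, Z, 3, 3), columns are eigenvectors
    s0: np.ndarray               # (X, Y, Z)
    valid: np.ndarray            # (X, Y, Z) bool
    affine: np.ndarray

    @property
    def v1(self) -> np.ndarray:
        return self.eigenvectors[..., :, 0]

    def tensors(self) -> np.ndarray:
        """Reassembled (X, Y, Z, 3, 3) diffusion tensors, mm^2/s."""
        lam = self.eigenvalues
        vec = self.eigenvectors
        return np.einsum("...ij,...j,...kj->...ik", vec, lam, vec)


_MAP_NAMES = ("fa", "md", "mo", "fa_t", "md_t", "mo_t", "fw")


@dataclass
class ScalarMaps:
    """Uncorrected and free-water-corrected scalar maps on one grid."""

    fa: np.ndarray
    md: np.ndarray
    mo: np.ndarray
    fa_t: np.ndarray
    md_t: np.ndarray
    mo_t: np.ndarray
    fw: np.ndarray
    affine: np.ndarray
    valid: np.ndarray | None = None
    converged: np.ndarray | None = None
    identifiable: np.ndarray | None = None
    subject_id: str = "subject"

    #: canonical measure names used in tables downstream
    MEASURES = ("FA_T", "MD_T", "MO_T", "FW")

    def __getitem__(self, measure: str) -> np.ndarray:
        key = measure.lower()
        if key not in _MAP_NAMES:
            raise KeyError(f"unknown measure {measure!r}; expected one of "
                           f"{[m.upper() for m in _MAP_NAMES]}")
        return getattr(self, key)

    def save(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name in _MAP_NAMES:
            save_nifti(getattr(self, name), self.affine,
                       os.path.join(out_dir, f"{name}.nii.gz"))
        flags = np.zeros(self.fa.shape, dtype=np.uint8)
        if self.valid is not None:
            flags |= self.valid.astype(np.uint8)
        if self.converged is not None:
            flags |= (self.converged.astype(np.uint8) << 1)
        if self.identifiable is not None:
            flags |= (self.identifiable.astype(np.uint8) << 2)
        save_nifti(flags, self.affine, os.path.join(out_dir, "flags.nii.gz"))

    @classmethod
    def load(cls, in_dir, subject_id="subject") -> "ScalarMaps":
        arrays = {}
        affine = None
        for name in _MAP_NAMES:
            arrays[name], affine = load_nifti(os.path.join(in_dir, f"{name}.nii.gz"))
        flags_path = os.path.join(in_dir, "flags.nii.gz")
        valid = converged = identifiable = None
        if os.path.exists(flags_path):
            flags = load_nifti(flags_path)[0].astype(np.uint8)
            valid = (flags & 1) > 0
            converged = (flags & 2) > 0
            identifiable = (flags & 4) > 0
        return cls(affine=affine, valid=valid, converged=converged,
                   identifiable=identifiable, subject_id=subject_id, **arrays)


# ---------------------------------------------------------------------------
# single-tensor WLS fit


def _design_matrix(bvals_ms, bvecs):
    g = bvecs
    b = bvals_ms
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def _tensors_from_coeffs(beta):
    """(V, 7) log-linear coefficients -> (V, 3, 3) tensors (scaled units)."""
    V = beta.shape[0]
    D = np.empty((V, 3, 3))
    D[:, 0, 0] = beta[:, 1]
    D[:, 1, 1] = beta[:, 2]
    D[:, 2, 2] = beta[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = beta[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = beta[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = beta[:, 6]
    return D


def fit_dti(data: DiffusionDataset) -> TensorFit:
    """Weighted-least-squares single-tensor fit per masked voxel.

    Fits ln S = ln S0 - b g'Dg with weights equal to the squared predicted
    signal (the standard WLS correction for log-transformed noise), then
    eigendecomposes D.  Negative eigenvalues are clipped to zero.  Voxels
    with non-positive signal throughout are flagged invalid.
    """
    if data.n_volumes < 7:
        raise ValueError("single-tensor fit needs >= 7 volumes "
                         "(6 directions + b0); got %d" % data.n_volumes)
    shape = data.grid_shape
    mask = data.brain_mask
    S = data.signal[mask]                     # (V, N)
    usable = S.max(axis=1) > 0
    X = _design_matrix(data.bvals * _B_SCALE, data.bvecs)   # (N, 7)
    y = np.log(np.maximum(S, 1e-12))

    beta = np.linalg.pinv(X) @ y.T            # OLS init, (7, V)
    w = np.exp(2.0 * (X @ beta)).T            # (V, N) predicted-signal^2
    w = np.clip(w, 1e-12, None)
    A = np.einsum("ni,vn,nj->vij", X, w, X)
    rhs = np.einsum("ni,vn,vn->vi", X, w, y)
    A += 1e-12 * np.eye(7)[None]
    beta_wls = np.linalg.solve(A, rhs[..., None])[..., 0]   # (V, 7)

    D = _tensors_from_coeffs(beta_wls)
    evals, evecs = _eigs_descending(D)
    evals = np.clip(evals, 0.0, None)

    full_evals = np.full(shape + (3,), np.nan)
    full_evecs = np.full(shape + (3, 3), np.nan)
    full_s0 = np.zeros(shape)
    full_valid = np.zeros(shape, dtype=bool)
    full_evals[mask] = evals / _D_SCALE
    full_evecs[mask] = evecs
    full_s0[mask] = np.exp(beta_wls[:, 0])
    full_valid[mask] = usable
    return TensorFit(full_evals, full_evecs, full_s0, full_valid, data.affine)


# ---------------------------------------------------------------------------
# free-water bi-tensor fit


def _chol_params(D):
    """Lower Cholesky factor of a (3,3) SPD matrix as a 6-vector
    [log L00, log L11, log L22, L10, L20, L21]."""
    L = np.linalg.cholesky(D + 1e-8 * np.eye(3))
    return np.array([np.log(L[0, 0]), np.log(L[1, 1]), np.log(L[2, 2]),
                     L[1, 0], L[2, 0], L[2, 1]])


def _tensor_from_chol(p):
    L = np.array([[np.exp(p[0]), 0.0, 0.0],
                  [p[3], np.exp(p[1]), 0.0],
                  [p[4], p[5], np.exp(p[2])]])
    return L @ L.T


def _fw_residual_jac(params, b, g, sn, ew, prior, sqrt_w):
    """Residuals and analytic Jacobian of the bi-tensor model in one voxel.

    params = [log L00, log L11, log L22, L10, L20, L21, f];
    residuals are model-minus-observed normalized signal, optionally
    followed by sqrt(reg_weight) * (tensor params - neighborhood prior).
    """
    p, f = params[:6], params[6]
    L = np.array([[np.exp(p[0]), 0.0, 0.0],
                  [p[3], np.exp(p[1]), 0.0],
                  [p[4], p[5], np.exp(p[2])]])
    M = g @ L                                   # (N, 3) = (L' g)'
    q = np.einsum("nj,nj->n", M, M)             # g' D g
    et = np.exp(-b * q)
    r = f * ew + (1.0 - f) * et - sn

    dq = np.empty((len(b), 6))
    dq[:, 0] = 2.0 * g[:, 0] * M[:, 0] * L[0, 0]
    dq[:, 1] = 2.0 * g[:, 1] * M[:, 1] * L[1, 1]
    dq[:, 2] = 2.0 * g[:, 2] * M[:, 2] * L[2, 2]
    dq[:, 3] = 2.0 * g[:, 1] * M[:, 0]
    dq[:, 4] = 2.0 * g[:, 2] * M[:, 0]
    dq[:, 5] = 2.0 * g[:, 2] * M[:, 1]
    J = np.empty((len(b), 7))
    J[:, :6] = (-(1.0 - f) * b * et)[:, None] * dq
    J[:, 6] = ew - et

    if sqrt_w > 0.0:
        r_reg = sqrt_w * (p - prior)
        J_reg = np.zeros((6, 7))
        J_reg[:, :6] = sqrt_w * np.eye(6)
        r = np.concatenate([r, r_reg])
        J = np.vstack([J, J_reg])
    return r, J


_LB = np.array([-10.0, -10.0, -10.0, -4.0, -4.0, -4.0, 0.0])
_UB = np.array([2.0, 2.0, 2.0, 4.0, 4.0, 4.0, 1.0])


def _fit_voxel(x0, b, g, sn, ew, prior, sqrt_w, max_iter, tol):
    res = least_squares(
        lambda x: _fw_residual_jac(x, b, g, sn, ew, prior, sqrt_w)[0],
        np.clip(x0, _LB + 1e-9, _UB - 1e-9),
        jac=lambda x: _fw_residual_jac(x, b, g, sn, ew, prior, sqrt_w)[1],
        bounds=(_LB, _UB), method="trf", ftol=tol, xtol=1e-12, gtol=1e-12,
        max_nfev=max_iter,
    )
    return res


def fit_free_water(data: DiffusionDataset, init: TensorFit | None = None,
                   d_water: float = D_WATER, reg_weight: float = 0.0,
                   max_iter: int = 100, tol: float = 1e-6) -> ScalarMaps:
    """Fit the bi-tensor free-water model and derive all scalar maps.

    Requires multi-shell data (>= 2 distinct nonzero shells): with a single
    shell the trade-off between f and tissue mean diffusivity is ill-posed.
    The tissue tensor is initialized from the single-tensor fit (``init``,
    computed here if omitted) and f from the b0-normalized mean signal of
    the highest shell; a second start at low f guards against local minima.
    When ``reg_weight > 0`` the field is refined by outer sweeps in which
    each voxel is penalized toward the 6-neighborhood mean of its tensor
    parameters from the previous sweep.

    Returns uncorrected FA/MD/MO (from ``init``) alongside FA_T/MD_T/MO_T
    (from the fitted tissue tensor) and FW = f.  Voxels with f > 0.99 are
    flagged unidentifiable: a pure-water voxel carries no tissue signal to
    constrain the tensor; their values are still returned.
    """
    if len(data.shells) < 2:
        raise ValueError(
            "free-water fit is ill-posed on single-shell data: the isotropic "
            "fraction and tissue mean diffusivity are not separable; provide "
            ">= 2 distinct nonzero b-values")
    if init is None:
        init = fit_dti(data)

    mask = data.brain_mask & init.valid
    shape = data.grid_shape
    idx = np.argwhere(mask)
    b = data.bvals * _B_SCALE
    g = data.bvecs
    dw = d_water * _D_SCALE
    ew = np.exp(-b * dw)
    s0 = data.b0_mean()
    bmax = b.max()
    hi = b == bmax

    # normalized signal; voxels with unusable S0 are dropped from the fit
    good_s0 = s0 > 0
    fit_mask = mask & good_s0

    # tissue tensors from init (scaled units), for starts
    D_init = init.tensors() * _D_SCALE

    # f0 heuristic: compare observed high-shell attenuation with a typical
    # tissue attenuation (MD 0.6 um^2/ms) against free water
    at_ref = np.exp(-bmax * 0.6)
    aw = np.exp(-bmax * dw)

    n_sweeps = 1 if reg_weight <= 0 else 10
    sqrt_w = np.sqrt(max(reg_weight, 0.0) * len(b) / 6.0) if reg_weight > 0 else 0.0

    P = np.full(shape + (6,), np.nan)     # chol params field
    F = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)

    vox_list = np.argwhere(fit_mask)
    # per-voxel precomputation
    sn_all = data.signal[fit_mask] / s0[fit_mask][:, None]

    def neighbor_prior():
        """6-neighborhood mean of the current parameter field (NaN-aware)."""
        pr = np.zeros(shape + (6,))
        cnt = np.zeros(shape)
        filled = np.nan_to_num(P, nan=0.0)
        has = ~np.isnan(P[..., 0])
        for ax in range(3):
            for sh in (1, -1):
                pr += np.roll(filled, sh, axis=ax)
                cnt += np.roll(has.astype(float), sh, axis=ax)
        with np.errstate(invalid="ignore", divide="ignore"):
            pr = pr / cnt[..., None]
        return pr, cnt > 0

    prior_field = None
    for sweep in range(n_sweeps):
        if sqrt_w > 0 and sweep > 0:
            prior_field, prior_ok = neighbor_prior()
        max_delta = 0.0
        for k, (i, j, l) in enumerate(vox_list):
            sn = sn_all[k]
            D0 = D_init[i, j, l]
            a_obs = sn[hi].mean()
            f0 = float(np.clip((at_ref - a_obs) / (at_ref - aw), 0.05, 0.9))
            use_w = sqrt_w if sweep > 0 else 0.0
            if prior_field is not None and prior_ok[i, j, l]:
                prior = prior_field[i, j, l]
            else:
                prior = np.zeros(6)
                use_w = 0.0

            if sweep == 0 or np.isnan(P[i, j, l, 0]):
                # start A: water-corrected tissue tensor + heuristic f0
                Dc = (D0 - f0 * dw * np.eye(3)) / (1.0 - f0)
                wA, vA = np.linalg.eigh(Dc)
                wA = np.clip(wA, 0.05, 2.8)
                Dc = (vA * wA) @ vA.T
                xA = np.concatenate([_chol_params(Dc), [f0]])
                resA = _fit_voxel(xA, b, g, sn, ew, prior, use_w, max_iter, tol)
                best = resA
                if resA.cost > 1e-10 * len(b):
                    # start B: raw single-tensor + low f
                    wB, vB = np.linalg.eigh(D0)
                    wB = np.clip(wB, 0.05, 2.8)
                    DB = (vB * wB) @ vB.T
                    xB = np.concatenate([_chol_params(DB), [0.05]])
                    resB = _fit_voxel(xB, b, g, sn, ew, prior, use_w, max_iter, tol)
                    if resB.cost < best.cost:
                        best = resB
            else:
                x0 = np.concatenate([P[i, j, l], [F[i, j, l]]])
                best = _fit_voxel(x0, b, g, sn, ew, prior, use_w, max_iter, tol)

            old = P[i, j, l].copy()
            P[i, j, l] = best.x[:6]
            F[i, j, l] = best.x[6]
            conv[i, j, l] = best.status > 0
            if not np.isnan(old[0]):
                max_delta = max(max_delta, float(np.abs(best.x[:6] - old).max()))
        if sweep > 0 and max_delta < 1e-4:
            break

    # assemble tissue tensors and scalar maps
    fa_t = np.full(shape, np.nan)
    md_t = np.full(shape, np.nan)
    mo_t = np.full(shape, np.nan)
    fw = np.full(shape, np.nan)
    for (i, j, l) in vox_list:
        D = _tensor_from_chol(P[i, j, l]) / _D_SCALE
        w, _ = np.linalg.eigh(D)
        lam = np.clip(w[::-1], 0.0, None)
        fa_t[i, j, l], md_t[i, j, l], mo_t[i, j, l] = scalars_from_eigenvalues(*lam)
        fw[i, j, l] = F[i, j, l]

    lam_init = np.where(np.isnan(init.eigenvalues), 0.0, init.eigenvalues)
    fa, md, mo = scalars_from_eigenvalues(
        lam_init[..., 0], lam_init[..., 1], lam_init[..., 2])
    outside = ~init.valid
    for arr in (fa, md, mo):
        arr[outside] = np.nan

    # degenerate voxels: the fitted "tissue" tensor is itself water-like
    # (MD near d_water), so tissue and free water are indistinguishable —
    # the voxel is effectively pure free water; report FW=1 and flag it.
    degenerate = fit_mask & (md_t > 0.9 * d_water)
    fw[degenerate] = 1.0
    identifiable = fit_mask & ~degenerate & (fw < 0.99)
    return ScalarMaps(fa=fa, md=md, mo=mo, fa_t=fa_t, md_t=md_t, mo_t=mo_t,
                      fw=fw, affine=data.affine, valid=fit_mask,
                      converged=conv, identifiable=identifiable,
                      subject_id=data.subject_id)
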