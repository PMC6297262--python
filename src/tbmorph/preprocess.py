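"""Scan preprocessing: denoising, bias-field correction, skull stripping via
template mask propagation, rigid alignment, and intensity matching.

The stages mirror a standard small-animal structural pipeline. Denoising is
non-local means tuned from a background noise estimate; inhomogeneity is
modelled as a smooth multiplicative field fitted as a low-order polynomial in
the log domain (robustly, so anatomy does not masquerade as bias); skull
stripping propagates a template brain mask through a diffeomorphic
registration; rigid alignment maximises normalised correlation over 6 degrees
of freedom; intensity matching is a monotone quantile map of the earlier scan
onto the later one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.restoration import denoise_nl_means

from .core import ImageVolume
from .register import RegistrationParams, RegistrationError, register_nonrigid, warp

__all__ = [
    "RigidTransform",
    "BiasField",
    "denoise",
    "correct_bias",
    "skull_strip",
    "rigid_align",
    "match_intensity",
    "estimate_noise_sigma",
    "preprocess_scan",
]


@dataclass
class RigidTransform:
    """6-DOF transform mapping moving-frame world coordinates into the fixed
    frame: x_fixed = R @ (x_moving - center) + center + t."""

    rotation: np.ndarray      # 3x3, det = +1
    translation: np.ndarray   # mm
    center: np.ndarray        # rotation centre, mm

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        self.center = np.asarray(self.center, float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper orthonormal (det = +1)")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, float) - self.center) @ self.rotation.T \
            + self.center + self.translation

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.center + self.translation - self.rotation @ self.center
        return m


@dataclass
class BiasField:
    """Smooth multiplicative inhomogeneity field, unit mean over the mask."""

    field: np.ndarray
    order: int

    def __post_init__(self):
        if np.any(self.field <= 0):
            raise ValueError("bias field must be strictly positive")


def estimate_noise_sigma(vol: ImageVolume) -> float:
    """Noise level from the background (outside the brain mask), using a
    MAD-based robust standard deviation; falls back to a wavelet-free
    pseudo-residual estimate when no mask is present."""
    if vol.mask is not None and (~vol.mask).sum() > 100:
        bg = vol.data[~vol.mask]
        return float(1.4826 * np.median(np.abs(bg - np.median(bg))))
    lap = ndimage.laplace(vol.data.astype(np.float64))
    return float(np.sqrt(np.mean(lap ** 2) / 20.0))


def denoise(vol: ImageVolume, strength: float = 1.0) -> ImageVolume:
    """Edge-preserving non-local-means denoising (patch radius 1, search
    radius 2); ``strength`` scales the filtering relative to the estimated
    background noise level. strength 0 returns the input unchanged."""
    if strength < 0:
        raise ValueError("strength must be >= 0")
    if strength == 0:
        return vol.with_data(vol.data.copy())
    sigma = estimate_noise_sigma(vol)
    if sigma <= 0:
        return vol.with_data(vol.data.copy())
    out = denoise_nl_means(vol.data.astype(np.float64), patch_size=3, patch_distance=2,
                           h=0.8 * strength * sigma, sigma=sigma, fast_mode=True)
    return vol.with_data(out)


from functools import lru_cache


@lru_cache(maxsize=4)
def _poly_design(shape, order: int) -> np.ndarray:
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((gx ** i) * (gy ** j) * (gz ** k))
    return np.stack([c.ravel() for c in cols], axis=1)


def correct_bias(vol: ImageVolume, order: int = 3, n_irls: int = 12
                 ) -> tuple[ImageVolume, BiasField]:
    """Estimate and remove a smooth multiplicative bias field.

    Fits log-intensity within the brain mask with an order-``order`` polynomial
    using iteratively reweighted least squares (Tukey biweight), so that
    anatomical structure is treated as outliers and only the smooth
    inhomogeneity is captured. Returns the divided image and the field;
    corrected * field reconstructs the input exactly.
    """
    if vol.mask is not None:
        mask = vol.mask
    else:
        # no brain mask yet (pre-stripping pass): fit over a rough foreground,
        # never over background noise whose log-intensity is unbounded below
        from skimage.filters import threshold_otsu
        mask = vol.data > threshold_otsu(vol.data)
    if mask.sum() < 100:
        raise ValueError("mask has fewer than 100 usable voxels: bias fit underdetermined")
    # fit away from the mask boundary: partial-volume shell voxels are dim and
    # would masquerade as low bias
    core = ndimage.binary_erosion(mask, iterations=2)
    if core.sum() < 100:
        core = mask
    valid = core & (vol.data > 1e-6)
    if valid.sum() < 100:
        raise ValueError("mask has fewer than 100 usable voxels: bias fit underdetermined")
    X_full = _poly_design(vol.shape, order)
    sel = valid.ravel()
    X = X_full[sel]
    y = np.log(vol.data.astype(np.float64).ravel()[sel])
    w = np.ones_like(y)
    beta = None
    for _ in range(n_irls):
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        resid = y - X @ beta
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid))) + 1e-12
        r = resid / (3.0 * scale)
        w = np.where(np.abs(r) < 1.0, (1 - r ** 2) ** 2, 0.0)
    logf = (X_full @ beta).reshape(vol.shape)
    # the polynomial is only supported inside the fitted core; extend it into
    # the boundary rind by nearest neighbour instead of extrapolating
    near = ndimage.distance_transform_edt(~core, return_distances=False,
                                          return_indices=True)
    logf = np.where(core, logf, logf[tuple(near)])
    logf -= logf[mask].mean()
    field = np.exp(logf)
    field /= field[mask].mean()
    corrected = vol.data.astype(np.float64) / field
    return vol.with_data(corrected), BiasField(field=field, order=order)


def skull_strip(vol: ImageVolume, template: ImageVolume,
                template_mask: np.ndarray | None = None,
                params: RegistrationParams | None = None) -> ImageVolume:
    """Strip non-brain voxels by aligning the template to the scan with
    diffeomorphic registration and warping the template brain mask through the
    resulting deformation (nearest neighbour)."""
    mask = template_mask if template_mask is not None else template.mask
    if mask is None:
        raise ValueError("template must carry a brain mask")
    if float(vol.data.std()) < 1e-9:
        raise RegistrationError("scan has no contrast to register")
    scan = ImageVolume(data=vol.data, spacing=vol.spacing, affine=vol.affine, mask=None)
    field = register_nonrigid(scan, template.with_data(template.data, mask=None), params)
    mask_img = ImageVolume(data=mask.astype(np.float32), spacing=template.spacing,
                           affine=template.affine)
    warped = warp(mask_img, field, "nearest")
    new_mask = warped.data > 0.5
    # idempotence: an already-stripped scan (exact-zero background agreeing
    # with the propagated mask) keeps its support instead of being re-cut at
    # the mask boundary
    support = vol.data != 0
    if (vol.data == 0).mean() > 0.3:
        dice = 2 * np.count_nonzero(new_mask & support) / max(
            new_mask.sum() + support.sum(), 1)
        if dice > 0.99:
            new_mask = support
    out = np.where(new_mask, vol.data, 0.0)
    return ImageVolume(data=out, spacing=vol.spacing.copy(), affine=vol.affine.copy(),
                       mask=new_mask)


def _euler_to_matrix(angles) -> np.ndarray:
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _resample_rigid(moving: ImageVolume, fixed: ImageVolume, theta, center) -> np.ndarray:
    """Resample moving into the fixed grid under x_f = R(x_m - c) + c + t."""
    R = _euler_to_matrix(theta[:3])
    t = np.asarray(theta[3:], float)
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = center + t - R @ center
    M = np.linalg.inv(moving.affine) @ np.linalg.inv(T) @ fixed.affine
    return ndimage.affine_transform(moving.data, M[:3, :3], offset=M[:3, 3],
                                    order=1, mode="grid-constant", cval=0.0,
                                    output_shape=fixed.shape)


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None) -> float:
    if mask is not None:
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    if den < 1e-12:
        return 0.0
    return float(a @ b / den)


def rigid_align(moving: ImageVolume, fixed: ImageVolume
                ) -> tuple[ImageVolume, RigidTransform]:
    """6-DOF alignment of ``moving`` onto ``fixed`` by maximising normalised
    correlation with multi-resolution Powell descent and 4 multi-start
    orientations."""
    center = fixed.index_to_world((np.asarray(fixed.shape, float) - 1) / 2.0)

    def downsample(vol: ImageVolume, f: int) -> ImageVolume:
        if f == 1:
            return vol
        data = ndimage.gaussian_filter(vol.data, 0.5 * f)[::f, ::f, ::f]
        aff = vol.affine.copy()
        aff[:3, :3] *= f
        m = vol.mask[::f, ::f, ::f] if vol.mask is not None else None
        return ImageVolume(data=data, spacing=vol.spacing * f, affine=aff, mask=m)

    starts = [np.zeros(6)]
    for axis in range(3):
        s = np.zeros(6)
        s[axis] = np.pi
        starts.append(s)

    def neg_ncc(theta, mov, fix):
        res = _resample_rigid(mov, fix, theta, center)
        return -_ncc(res, fix.data, fix.mask)

    # the metric stops refining at half resolution: positioning precision is
    # ~0.1 voxel there, and the output is always resampled at full resolution
    factors = [f for f in (4, 2) if min(fixed.shape) // f >= 8] or [1]
    mov_c, fix_c = downsample(moving, factors[0]), downsample(fixed, factors[0])

    def settle(start):
        # rank each candidate orientation after a quick translation-only fit,
        # otherwise near-symmetric anatomy can make a flipped start look best
        t_scale = float(np.mean(fixed.spacing) * factors[0])
        res = optimize.minimize(
            lambda p: neg_ncc(np.concatenate([start[:3], p * t_scale]), mov_c, fix_c),
            start[3:] / t_scale, method="Powell",
            options={"xtol": 1e-2, "maxiter": 40})
        theta = np.concatenate([start[:3], res.x * t_scale])
        return theta, res.fun

    settled = [settle(np.asarray(s, float)) for s in starts]
    theta = min(settled, key=lambda x: x[1])[0]
    for f in factors:
        mov_l, fix_l = downsample(moving, f), downsample(fixed, f)
        scale = np.concatenate([np.full(3, 0.05), np.full(3, float(np.mean(fixed.spacing) * f))])
        # coarse levels localise quickly; only the final level needs tight tolerances
        opts = ({"xtol": 1e-3, "ftol": 3e-7, "maxiter": 120} if f == factors[-1]
                else {"xtol": 5e-3, "ftol": 1e-5, "maxiter": 80})
        res = optimize.minimize(
            lambda p: neg_ncc(theta + p * scale, mov_l, fix_l),
            np.zeros(6), method="Powell", options=opts)
        theta = theta + res.x * scale
    score = -neg_ncc(theta, moving, fixed)
    base = _ncc(moving.data, fixed.data, fixed.mask)
    if score < base - 1e-6 and score < 0.1:
        raise RegistrationError(
            f"rigid alignment diverged (ncc {score:.3f} < initial {base:.3f})")
    transform = RigidTransform(rotation=_euler_to_matrix(theta[:3]),
                               translation=np.asarray(theta[3:], float), center=center)
    # below the optimiser's precision (peripheral displacement under a tenth
    # of a voxel): avoid a pointless resampling pass
    radius = 0.35 * float(np.max(np.asarray(fixed.shape) * fixed.spacing))
    if (moving.same_grid(fixed)
            and np.abs(theta[:3]).max() * radius < 0.1 * float(np.min(fixed.spacing))
            and np.all(np.abs(theta[3:]) < 0.1 * fixed.spacing)):
        return ImageVolume(data=moving.data.copy(), spacing=fixed.spacing.copy(),
                           affine=fixed.affine.copy(), mask=moving.mask), transform
    resampled = _resample_rigid(moving, fixed, theta, center)
    out_mask = None
    if moving.mask is not None:
        mask_vol = ImageVolume(data=moving.mask.astype(np.float32),
                               spacing=moving.spacing, affine=moving.affine)
        M = ImageVolume(data=_resample_rigid(mask_vol, fixed, theta, center),
                        spacing=fixed.spacing, affine=fixed.affine)
        out_mask = M.data > 0.5
    return ImageVolume(data=resampled, spacing=fixed.spacing.copy(),
                       affine=fixed.affine.copy(), mask=out_mask), transform


def match_intensity(source: ImageVolume, reference: ImageVolume,
                    n_quantiles: int = 256) -> ImageVolume:
    """Monotone histogram matching of ``source`` onto ``reference`` within
    their brain masks: source quantiles are mapped to reference quantiles,
    preserving rank order of source voxels."""
    smask = source.mask if source.mask is not None else np.ones(source.shape, bool)
    rmask = reference.mask if reference.mask is not None else np.ones(reference.shape, bool)
    svals = source.data[smask].astype(np.float64)
    rvals = reference.data[rmask].astype(np.float64)
    if svals.std() < 1e-12:
        raise ValueError("constant source image: quantile map undefined")
    q = np.linspace(0.0, 1.0, n_quantiles)
    sq = np.quantile(svals, q)
    rq = np.quantile(rvals, q)
    # enforce strictly increasing source knots for interpolation
    sq_u, idx = np.unique(sq, return_index=True)
    rq_u = rq[idx]
    out = source.data.astype(np.float64).copy()
    out[smask] = np.interp(source.data[smask], sq_u, rq_u)
    return source.with_data(out)


def preprocess_scan(vol: ImageVolume, template: ImageVolume,
                    denoise_strength: float = 1.0,
                    params: RegistrationParams | None = None,
                    do_rigid: bool = True) -> ImageVolume:
    """Full preprocessing chain: denoise, bias-correct, skull-strip, repeat
    bias correction on the stripped image, then rigidly align to the template."""
    out = denoise(vol, denoise_strength)
    out, _ = correct_bias(out.with_data(out.data, mask=None))
    out = skull_strip(out, template, params=params)
    out, _ = correct_bias(out)
    if do_rigid:
        out, _ = rigid_align(out, template)
    return out
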