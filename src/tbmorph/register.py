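"""Dense non-rigid registration and displacement-field algebra.

A :class:`DisplacementField` stores a per-voxel 3-vector displacement ``u`` in
world millimetres on the *fixed* image grid; the associated spatial transform is
``phi(x) = x + u(x)``. ``warp`` pulls an image back through ``phi`` (the output
at grid point ``x`` samples the input at ``phi(x)``), so composing warps
corresponds to composing transforms right-to-left.

Non-rigid registration is diffeomorphic demons: at each multi-resolution level
the intensity-driven demons force is smoothed (fluid regularisation),
exponentiated by scaling-and-squaring so each update is itself a small
diffeomorphism, composed onto the running field, and the total field is smoothed
again (elastic regularisation). Every emitted field is checked for a strictly
positive Jacobian determinant.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .core import ImageVolume, LabelVolume

__all__ = [
    "DisplacementField",
    "RegistrationParams",
    "GroupwiseResult",
    "RegistrationError",
    "identity_field",
    "warp",
    "compose",
    "invert",
    "jacobian_determinant",
    "register_nonrigid",
    "build_groupwise_template",
    "save_field",
    "load_field",
]


class RegistrationError(RuntimeError):
    """Raised when registration diverges or would emit a folded field."""


@dataclass
class DisplacementField:
    """Per-voxel displacement (mm, world frame) on the fixed image grid."""

    u: np.ndarray               # (X, Y, Z, 3)
    spacing: np.ndarray         # mm / voxel of the fixed grid
    affine: np.ndarray          # fixed grid-index -> world-mm

    def __post_init__(self):
        self.u = np.asarray(self.u)
        if self.u.dtype != np.float64:   # keep float64 oracles exact
            self.u = self.u.astype(np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError(f"displacement must have shape (X,Y,Z,3), got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.affine, other.affine))

    def magnitude_voxels(self) -> np.ndarray:
        """Per-voxel displacement magnitude in voxel units (mean spacing)."""
        return np.linalg.norm(self.u / self.spacing, axis=-1)


def identity_field(like) -> DisplacementField:
    """Zero displacement on the grid of an ImageVolume/LabelVolume/DisplacementField."""
    shape = like.shape if not isinstance(like, DisplacementField) else like.shape
    return DisplacementField(u=np.zeros(shape + (3,), dtype=np.float32),
                             spacing=np.asarray(like.spacing, float).copy(),
                             affine=np.asarray(like.affine, float).copy())


def _index_displacement(field: DisplacementField) -> np.ndarray:
    """World-mm displacements converted to grid-index displacements."""
    inv_lin = np.linalg.inv(field.affine[:3, :3])
    return field.u @ inv_lin.T


def _sample_coords(field: DisplacementField) -> np.ndarray:
    """(3, X, Y, Z) fractional index coordinates of phi(x) for every grid point."""
    shape = field.shape
    base = np.stack(np.meshgrid(*[np.arange(n, dtype=np.float32) for n in shape],
                                indexing="ij"), axis=-1)
    coords = base + _index_displacement(field).astype(np.float32)
    return np.moveaxis(coords, -1, 0)


def warp(vol, field: DisplacementField, interpolation: str = "linear"):
    """Resample an image (or label map) through phi(x) = x + u(x).

    Intensities use linear interpolation, labels and masks require nearest
    neighbour. Samples falling outside the input domain become 0 / background.
    """
    if isinstance(vol, LabelVolume):
        if interpolation != "nearest":
            raise ValueError("label volumes must be warped with nearest-neighbour interpolation")
        coords = _sample_coords(field)
        out = ndimage.map_coordinates(vol.labels, coords, order=0, mode="grid-constant", cval=0)
        return LabelVolume(labels=out, lut=dict(vol.lut),
                           spacing=field.spacing.copy(), affine=field.affine.copy())
    if not isinstance(vol, ImageVolume):
        raise TypeError(f"cannot warp object of type {type(vol)}")
    if vol.shape != field.shape:
        raise ValueError(f"geometry mismatch: image {vol.shape} vs field {field.shape}")
    order = {"linear": 1, "nearest": 0}[interpolation]
    coords = _sample_coords(field)
    out = ndimage.map_coordinates(vol.data, coords, order=order, mode="grid-constant", cval=0.0)
    new_mask = None
    if vol.mask is not None:
        new_mask = ndimage.map_coordinates(vol.mask.astype(np.uint8), coords, order=0,
                                           mode="grid-constant", cval=0).astype(bool)
    return ImageVolume(data=out, spacing=field.spacing.copy(),
                       affine=field.affine.copy(), mask=new_mask)


def _sample_field_at(field: DisplacementField, coords: np.ndarray) -> np.ndarray:
    """Interpolate a displacement field (mm) at fractional index coords (3,X,Y,Z)."""
    out = np.empty(coords.shape[1:] + (3,), dtype=np.float32)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(field.u[..., c], coords, order=1,
                                              mode="nearest")
    return out


def compose(f: DisplacementField, g: DisplacementField) -> DisplacementField:
    """Field of phi_f o phi_g, i.e. u(x) = u_g(x) + u_f(x + u_g(x)).

    ``warp(warp(vol, f), g) == warp(vol, compose(f, g))`` up to interpolation.
    """
    if not f.same_grid(g):
        raise ValueError("compose requires fields on the same grid")
    coords = _sample_coords(g)
    u = g.u + _sample_field_at(f, coords)
    return DisplacementField(u=u, spacing=f.spacing.copy(), affine=f.affine.copy())


def invert(field: DisplacementField, tol: float = 0.05, max_iter: int = 50) -> DisplacementField:
    """Fixed-point inverse: iterate u_inv <- -u(x + u_inv(x)).

    ``tol`` is the mean residual |phi o phi^-1 - id| in voxel units.
    """
    inv = identity_field(field)
    mean_sp = float(np.mean(field.spacing))
    for _ in range(max_iter):
        coords = _sample_coords(inv)
        inv = DisplacementField(u=-_sample_field_at(field, coords),
                                spacing=field.spacing.copy(), affine=field.affine.copy())
        residual = compose(field, inv)
        res_vox = float(np.mean(np.linalg.norm(residual.u, axis=-1))) / mean_sp
        if res_vox <= tol:
            return inv
    raise RegistrationError(f"field inversion did not reach tol={tol} voxels "
                            f"(residual {res_vox:.4f} voxels after {max_iter} iterations)")


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """det of the spatial gradient of phi = id + u, spacing-aware central differences."""
    shape = field.shape
    J = np.zeros(shape + (3, 3), dtype=np.float64)
    for i in range(3):
        grads = np.gradient(field.u[..., i].astype(np.float64),
                            *field.spacing, edge_order=1)
        for j in range(3):
            J[..., i, j] = grads[j]
        J[..., i, i] += 1.0
    return np.linalg.det(J)


# ---------------------------------------------------------------------------
# Diffeomorphic demons

@dataclass
class RegistrationParams:
    """Tunable contract of the demons registration.

    sigma_update_mm : fluid regularisation of each incremental update (mm).
    sigma_total_mm  : elastic regularisation of the accumulated field (mm).
    step            : scale on the demons force (1.0 = classic normalisation).
    tol             : relative MSE improvement below which a level stops.
    """

    levels: int = 3
    iterations: tuple[int, ...] = (100, 60, 40)
    sigma_update_mm: float = 0.6
    sigma_total_mm: float = 0.1
    step: float = 1.3
    tol: float = 1e-4

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.sigma_update_mm < 0 or self.sigma_total_mm < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if len(self.iterations) < self.levels:
            self.iterations = tuple(self.iterations) + (self.iterations[-1],) * (
                self.levels - len(self.iterations))


def _normalise(data: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    sel = data[mask] if mask is not None and mask.any() else data
    sd = float(sel.std())
    if sd < 1e-12:
        raise RegistrationError("image has no contrast to register")
    return ((data - float(sel.mean())) / sd).astype(np.float32)


def _downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    sm = ndimage.gaussian_filter(arr.astype(np.float32), sigma=0.5 * factor)
    return sm[::factor, ::factor, ::factor]


def _smooth_field(u: np.ndarray, sigma_mm: float, spacing: np.ndarray,
                  min_sigma_vox: float = 0.0) -> np.ndarray:
    """Gaussian-smooth a field; sigma is physical (mm) but floored per axis in
    voxel units so coarse slice spacing never leaves an axis unregularised."""
    sig = np.maximum(sigma_mm / spacing, min_sigma_vox)
    if np.all(sig <= 0):
        return u
    for c in range(3):
        u[..., c] = ndimage.gaussian_filter(u[..., c], sigma=sig)
    return u


def _exp_field(u: np.ndarray, spacing: np.ndarray, affine: np.ndarray) -> DisplacementField:
    """Exponentiate a velocity field by scaling and squaring."""
    max_vox = float(np.max(np.linalg.norm(u / spacing, axis=-1)))
    n = max(0, int(np.ceil(np.log2(max(max_vox, 1e-9) / 0.4))))
    e = DisplacementField(u=u / (2 ** n), spacing=spacing, affine=affine)
    for _ in range(n):
        e = compose(e, e)
    return e


def register_nonrigid(fixed: ImageVolume, moving: ImageVolume,
                      params: RegistrationParams | None = None) -> DisplacementField:
    """Diffeomorphic demons registration of ``moving`` onto ``fixed``.

    Returns the field on the fixed grid such that ``warp(moving, field)``
    matches ``fixed``. With fixed = earlier scan and moving = later scan,
    ``det grad(phi)`` is the local (later volume)/(earlier volume) ratio, so a
    positive log-Jacobian means expansion over the interval.
    """
    params = params or RegistrationParams()
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must share a grid after rigid alignment")
    mask = fixed.mask
    if mask is not None and moving.mask is not None and not (mask & moving.mask).any():
        raise RegistrationError("non-overlapping brain masks")
    fdat = _normalise(fixed.data, mask)
    mdat = _normalise(moving.data, moving.mask)

    factors = [2 ** (params.levels - 1 - l) for l in range(params.levels)]
    u = None
    for level, factor in enumerate(factors):
        f_l = _downsample(fdat, factor)
        m_l = _downsample(mdat, factor)
        sp_l = fixed.spacing * factor
        aff_l = fixed.affine.copy()
        aff_l[:3, :3] = aff_l[:3, :3] * factor
        msk_l = None
        if mask is not None:
            msk_l = _downsample(mask.astype(np.float32), factor) > 0.25
        if u is None:
            u = np.zeros(f_l.shape + (3,), dtype=np.float32)
        else:
            up = np.empty(f_l.shape + (3,), dtype=np.float32)
            zoom = [t / s for t, s in zip(f_l.shape, u.shape[:3])]
            for c in range(3):
                up[..., c] = ndimage.zoom(u[..., c], zoom, order=1)
            u = up
        field = DisplacementField(u=u, spacing=sp_l, affine=aff_l)
        kappa2 = float(np.mean(sp_l)) ** 2
        prev_mse = None
        for _ in range(params.iterations[level]):
            warped = ndimage.map_coordinates(m_l, _sample_coords(field), order=1,
                                             mode="grid-constant", cval=0.0)
            diff = f_l - warped
            if msk_l is not None:
                diff = np.where(msk_l, diff, 0.0)
            mse = float(np.mean(diff ** 2))
            if prev_mse is not None and prev_mse - mse < params.tol * max(prev_mse, 1e-12):
                break
            prev_mse = mse
            grads = np.gradient(warped, *sp_l)
            gnorm2 = grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2
            denom = gnorm2 + diff ** 2 / kappa2
            scale = np.where(denom > 1e-9, params.step * diff / np.maximum(denom, 1e-9), 0.0)
            upd = np.stack([scale * g for g in grads], axis=-1).astype(np.float32)
            upd = _smooth_field(upd, params.sigma_update_mm, sp_l, min_sigma_vox=0.8)
            exp_upd = _exp_field(upd, sp_l, aff_l)
            field = compose(field, exp_upd)
            field.u = _smooth_field(field.u, params.sigma_total_mm, sp_l,
                                    min_sigma_vox=0.5)
        u = field.u

    out = DisplacementField(u=u, spacing=fixed.spacing.copy(), affine=fixed.affine.copy())
    det = jacobian_determinant(out)
    interior = det[1:-1, 1:-1, 1:-1]
    if interior.size and interior.min() <= 0:
        bad = np.argwhere(det <= 0)
        raise RegistrationError(
            f"registration produced {bad.shape[0]} non-positive-Jacobian voxels, "
            f"first at {bad[0].tolist()}")
    return out


# ---------------------------------------------------------------------------
# Group-wise template construction

@dataclass
class GroupwiseResult:
    """Unbiased population template and per-subject subject->template fields."""

    template: ImageVolume
    fields: list = dc_field(default_factory=list)
    convergence: list = dc_field(default_factory=list)


def build_groupwise_template(volumes: list[ImageVolume],
                             params: RegistrationParams | None = None,
                             n_outer_iter: int = 5) -> GroupwiseResult:
    """Iterative unbiased template: register all to the evolving mean, subtract
    the mean displacement field from every subject field each outer iteration,
    and rebuild the template from the warped images.
    """
    if len(volumes) < 2:
        raise ValueError("group-wise template needs at least 2 volumes")
    geom = volumes[0]
    for v in volumes[1:]:
        if not geom.same_grid(v):
            raise ValueError("all volumes must share one grid")
    mask = None
    if all(v.mask is not None for v in volumes):
        stack = np.stack([v.mask for v in volumes])
        mask = stack.mean(axis=0) >= 0.5
    template = ImageVolume(data=np.mean([v.data for v in volumes], axis=0),
                           spacing=geom.spacing.copy(), affine=geom.affine.copy(), mask=mask)
    fields: list[DisplacementField] = []
    trace = []
    for outer in range(n_outer_iter):
        fields = []
        for i, vol in enumerate(volumes):
            try:
                fields.append(register_nonrigid(template, vol, params))
            except RegistrationError as err:
                raise RegistrationError(f"group-wise registration failed for subject {i}: {err}")
        mean_u = np.mean([f.u for f in fields], axis=0)
        fields = [DisplacementField(u=f.u - mean_u, spacing=f.spacing, affine=f.affine)
                  for f in fields]
        warped = [warp(vol, f) for vol, f in zip(volumes, fields)]
        template = ImageVolume(data=np.mean([w.data for w in warped], axis=0),
                               spacing=geom.spacing.copy(), affine=geom.affine.copy(),
                               mask=mask)
        mean_mag = float(np.mean(np.linalg.norm(np.mean([f.u for f in fields], axis=0),
                                                axis=-1))) / float(np.mean(geom.spacing))
        trace.append({"outer_iter": outer, "mean_field_voxels": mean_mag})
    return GroupwiseResult(template=template, fields=fields, convergence=trace)


# ---------------------------------------------------------------------------
# Serialization: 4D NIfTI, 3 displacement components in the 4th dimension (mm)

def save_field(field: DisplacementField, path) -> None:
    import nibabel as nib
    img = nib.Nifti1Image(field.u.astype(np.float32), field.affine)
    img.header.set_zooms(tuple(field.spacing) + (1.0,))
    nib.save(img, str(path))


def load_field(path) -> DisplacementField:
    import nibabel as nib
    img = nib.load(str(path))
    u = np.asanyarray(img.dataobj).astype(np.float32)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DisplacementField(u=u, spacing=spacing, affine=np.asarray(img.affine))
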