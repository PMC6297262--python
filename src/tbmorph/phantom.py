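"""Synthetic longitudinal cohorts with analytically known volume changes.

The phantom emulates a T2-weighted rodent acquisition: a ~160x160x32 grid of
0.2 mm in-plane voxels containing a brain envelope with labelled compartments
(lateral ventricles, central thalamus, colliculi, pretectal nuclei,
prelimbic/infralimbic cortex, CSF pools). Regional volume changes are applied
through compactly supported radial warps whose Jacobian determinant is known in
closed form inside an inner ball, giving exact ground truth for every
downstream stage; smooth bias fields and additive noise emulate acquisition
artifacts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import ImageVolume, LabelVolume, default_affine, save_volume, save_labels
from .register import DisplacementField, compose, warp
from .register import _sample_coords  # shared grid/coordinate helper

__all__ = [
    "PhantomGeometry",
    "RoiDef",
    "EffectSpec",
    "AnalyticWarp",
    "SubjectRecord",
    "CohortManifest",
    "CohortConfig",
    "ArtifactParams",
    "roi_tissue_classes",
    "default_layout",
    "make_base_phantom",
    "make_analytic_warp",
    "add_acquisition_artifacts",
    "simulate_cohort",
    "write_manifest",
    "load_manifest",
]

GROUPS = ("EtOH", "Con")

# baseline T2-like class intensities (arbitrary units)
INTENSITY = {"background": 0.0, "tissue": 100.0, "roi_tissue": 135.0, "csf": 220.0}


@dataclass
class PhantomGeometry:
    """Grid shape and voxel spacing of the simulated acquisition.

    Default matches a 160x160 matrix of 0.2 mm in-plane voxels and 32 slices;
    through-plane spacing is a knob (default 1.0 mm = slice plus gap).
    """

    shape: tuple[int, int, int] = (160, 160, 32)
    spacing: tuple[float, float, float] = (0.2, 0.2, 1.0)

    def __post_init__(self):
        if any(n <= 0 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("shape and spacing must be positive")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape, float) * np.asarray(self.spacing, float)

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.spacing)


@dataclass
class RoiDef:
    """An ellipsoidal compartment inside the brain envelope.

    center_frac is expressed as a fraction (in [-1, 1]) of the envelope
    semi-axes; bilateral ROIs are instantiated at +/- the lateral offset and
    midline ROIs straddle the central sagittal plane.
    """

    name: str
    tissue_class: str               # "tissue" or "csf"
    center_frac: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    bilateral: bool = True


@dataclass
class EffectSpec:
    """Prescribed local volume change for one ROI, interval, and group."""

    roi: str
    interval: int                   # 1 (scan1->scan2) or 2 (scan2->scan3)
    group: str
    volume_ratio: float             # local volume multiplier; 1.0 = no change

    def __post_init__(self):
        if self.interval not in (1, 2):
            raise ValueError("interval must be 1 or 2")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.volume_ratio <= 0:
            raise ValueError("volume_ratio must be > 0")


@dataclass
class AnalyticWarp:
    """Compactly supported radial warp with closed-form Jacobian.

    Inside the inner ball the transform is uniform scaling by
    volume_ratio^(1/3), so det(grad phi) = volume_ratio exactly; a cubic
    Hermite radial profile blends C1-smoothly to the identity at the outer
    radius. Monotonicity of the profile (fold-freeness) is verified on 1024
    samples before a field is emitted.
    """

    center: tuple[float, float, float]   # world mm
    inner_radius: float                  # mm
    outer_radius: float                  # mm
    volume_ratio: float
    profile: str = "hermite"             # "hermite" or "incompressible"

    def __post_init__(self):
        if self.volume_ratio <= 0:
            raise ValueError("volume_ratio must be > 0")
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")
        if self.profile not in ("hermite", "incompressible"):
            raise ValueError(f"unknown profile {self.profile!r}")

    def radial_map(self, r: np.ndarray) -> np.ndarray:
        """R(r): radius in the deformed configuration.

        hermite: cubic blend from the scaled inner ball straight to the
        identity at the outer radius; all compensating strain lives in the
        shell [inner, outer].

        incompressible: exactly volume-preserving between the inner ball and
        the outer radius (R = (r^3 + delta)^(1/3), det grad phi = 1), then a
        cubic blend to the identity beyond the outer radius over half an
        outer radius; displacement decays like 1/r^2 so remote structures
        translate sub-voxel amounts without any volume change.
        """
        s = self.volume_ratio ** (1.0 / 3.0)
        a, b = self.inner_radius, self.outer_radius
        r = np.asarray(r, dtype=float)
        if self.profile == "incompressible":
            delta = (self.volume_ratio - 1.0) * a ** 3
            c = 1.5 * b
            out = np.where(r <= a, s * r, r)
            mid = (r > a) & (r <= b)
            out = np.where(mid, np.cbrt(np.maximum(r ** 3 + delta, 0.0)), out)
            tail = (r > b) & (r < c)
            if np.any(tail):
                rb = np.cbrt(b ** 3 + delta)
                drb = b ** 2 / rb ** 2
                t = (r[tail] - b) / (c - b)
                h00 = 2 * t ** 3 - 3 * t ** 2 + 1
                h10 = t ** 3 - 2 * t ** 2 + t
                h01 = -2 * t ** 3 + 3 * t ** 2
                h11 = t ** 3 - t ** 2
                out[tail] = (h00 * rb + h10 * (c - b) * drb
                             + h01 * c + h11 * (c - b) * 1.0)
            return out
        out = np.where(r >= b, r, s * r)
        mid = (r > a) & (r < b)
        if np.any(mid):
            t = (r[mid] - a) / (b - a)
            h00 = 2 * t ** 3 - 3 * t ** 2 + 1
            h10 = t ** 3 - 2 * t ** 2 + t
            h01 = -2 * t ** 3 + 3 * t ** 2
            h11 = t ** 3 - t ** 2
            out[mid] = (h00 * (s * a) + h10 * (b - a) * s
                        + h01 * b + h11 * (b - a) * 1.0)
        return out

    @property
    def support_radius(self) -> float:
        """Radius beyond which the displacement is exactly zero."""
        return self.outer_radius * (1.5 if self.profile == "incompressible" else 1.0)

    def check_monotone(self, n: int = 1024) -> None:
        r = np.linspace(0.0, self.outer_radius * 1.05, n)
        R = self.radial_map(r)
        if np.any(np.diff(R) <= 0):
            raise ValueError(
                f"radial profile folds for volume_ratio={self.volume_ratio}: "
                "transform would not be invertible")


def default_layout() -> list[RoiDef]:
    """The study-like compartments: the nine highlighted ROIs plus the lateral
    ventricles and the CSF pool above frontal cortex."""
    return [
        RoiDef("csf_above_frontal", "csf", (0.0, 0.45, 0.62), (1.2, 0.8, 1.4), bilateral=False),
        RoiDef("prelimbic_cortex", "tissue", (0.0, 0.05, 0.80), (1.4, 1.1, 1.6), bilateral=False),
        RoiDef("infralimbic_cortex", "tissue", (0.0, -0.42, 0.62), (1.2, 0.9, 1.4), bilateral=False),
        RoiDef("nucleus_accumbens", "tissue", (0.45, -0.38, 0.42), (0.9, 0.9, 1.4), bilateral=True),
        RoiDef("lateral_ventricles", "csf", (0.40, 0.25, 0.22), (1.0, 1.0, 1.2), bilateral=True),
        RoiDef("central_thalamus", "tissue", (0.0, 0.05, -0.06), (1.6, 1.3, 2.0), bilateral=False),
        RoiDef("vplvpm_thalamus", "tissue", (0.55, -0.18, -0.06), (0.9, 0.9, 1.3), bilateral=True),
        RoiDef("anterior_pretectal", "tissue", (0.30, 0.38, -0.30), (0.8, 0.8, 1.1), bilateral=True),
        # both colliculi sit on the dorsal tectal plate, superior rostral to
        # inferior
        RoiDef("superior_colliculus", "tissue", (0.32, 0.35, -0.54), (1.1, 1.0, 1.4), bilateral=True),
        RoiDef("inferior_colliculus", "tissue", (0.26, 0.18, -0.75), (0.9, 0.9, 1.2), bilateral=True),
    ]


def _world_grid(geom: PhantomGeometry) -> np.ndarray:
    """(X,Y,Z,3) world-mm coordinates of every voxel centre."""
    axes = [np.arange(n, dtype=np.float64) * s for n, s in zip(geom.shape, geom.spacing)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _envelope(geom: PhantomGeometry, xyz: np.ndarray):
    # centred on voxel (N-1)/2 so the anatomy is exactly symmetric under the
    # grid-index mirror i -> N-1-i used for bilateral averaging
    center = (np.asarray(geom.shape, float) - 1) / 2.0 * np.asarray(geom.spacing, float)
    semi = geom.extent_mm * 0.44
    d2 = np.sum(((xyz - center) / semi) ** 2, axis=-1)
    return d2 <= 1.0, center, semi


def make_base_phantom(geometry: PhantomGeometry | None = None,
                      roi_layout: list[RoiDef] | None = None,
                      seed: int = 0,
                      texture_amplitude: float = 20.0
                      ) -> tuple[ImageVolume, LabelVolume]:
    """Build the base anatomy: brain envelope plus labelled compartments.

    The label map depends only on the layout (never on the seed); the seed
    controls only a fixed smooth intensity texture shared by the cohort.
    Overlapping compartments or compartments leaving the envelope are rejected.
    """
    geom = geometry or PhantomGeometry()
    layout = default_layout() if roi_layout is None else roi_layout
    xyz = _world_grid(geom)
    envelope, center, semi = _envelope(geom, xyz)

    labels = np.zeros(geom.shape, dtype=np.int32)
    lut: dict[int, str] = {}
    classes: dict[str, str] = {}
    next_id = 1
    for roi in layout:
        offsets = [np.asarray(roi.center_frac, float)]
        if roi.bilateral:
            mirrored = offsets[0].copy()
            mirrored[0] = -mirrored[0]
            offsets.append(mirrored)
        mask = np.zeros(geom.shape, dtype=bool)
        for off in offsets:
            c = center + off * semi
            d2 = np.sum(((xyz - c) / np.asarray(roi.radii_mm, float)) ** 2, axis=-1)
            mask |= d2 <= 1.0
        if not mask.any():
            raise ValueError(f"ROI {roi.name!r} contains no voxels at this geometry")
        if np.any(mask & ~envelope):
            raise ValueError(f"ROI {roi.name!r} exits the brain envelope")
        clash = labels[mask]
        if np.any(clash):
            other = lut[int(clash[clash > 0][0])]
            raise ValueError(f"ROI {roi.name!r} overlaps {other!r}; adjust the layout")
        labels[mask] = next_id
        lut[next_id] = roi.name
        classes[roi.name] = roi.tissue_class
        next_id += 1

    data = np.full(geom.shape, INTENSITY["background"], dtype=np.float32)
    data[envelope] = INTENSITY["tissue"]
    for lab, name in lut.items():
        value = INTENSITY["csf"] if classes[name] == "csf" else INTENSITY["roi_tissue"]
        data[labels == lab] = value

    # fixed smooth anatomical texture so group-wise templates have structure;
    # projected orthogonal to low-order polynomials so it cannot masquerade as
    # an intensity inhomogeneity field downstream
    rng = np.random.default_rng(seed)
    texture = rng.standard_normal(geom.shape).astype(np.float64)
    texture = ndimage.gaussian_filter(texture, sigma=1.2)
    from .preprocess import _poly_design
    X = _poly_design(geom.shape, 3)
    core = ndimage.binary_erosion(envelope, iterations=2) & (labels == 0)
    sel = (core if core.sum() > X.shape[1] else envelope).ravel()
    coef, *_ = np.linalg.lstsq(X[sel], texture.ravel()[sel], rcond=None)
    texture -= (X @ coef).reshape(geom.shape)
    sd = texture[envelope].std()
    if sd > 0 and texture_amplitude > 0:
        # default contrast is comparable to the tissue-class steps: interior
        # structure must carry enough evidence to pin displacements away from
        # compartment edges
        data += np.where(envelope, texture_amplitude * texture / sd,
                         0.0).astype(np.float32)
    data = ndimage.gaussian_filter(data, sigma=0.6)
    data = np.clip(data, 0, None)

    vol = ImageVolume(data=data, spacing=np.asarray(geom.spacing), affine=geom.affine,
                      mask=envelope)
    lab = LabelVolume(labels=labels, lut=lut, spacing=np.asarray(geom.spacing),
                      affine=geom.affine)
    return vol, lab


def roi_tissue_classes(layout: list[RoiDef] | None = None) -> dict[str, str]:
    layout = default_layout() if layout is None else layout
    return {r.name: r.tissue_class for r in layout}


def make_analytic_warp(spec: AnalyticWarp, like) -> DisplacementField:
    """Emit the radial warp as a displacement field on the grid of ``like``."""
    spec.check_monotone()
    spacing = np.asarray(like.spacing, float)
    affine = np.asarray(like.affine, float)
    shape = like.shape
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    idx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    xyz = idx @ affine[:3, :3].T + affine[:3, 3]
    delta = xyz - np.asarray(spec.center, float)
    r = np.linalg.norm(delta, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(r > 1e-12, spec.radial_map(r) / np.maximum(r, 1e-12) - 1.0, 0.0)
    factor = np.where(r >= spec.support_radius, 0.0, factor)
    u = (factor[..., None] * delta).astype(np.float32)
    return DisplacementField(u=u, spacing=spacing, affine=affine)


def add_acquisition_artifacts(vol: ImageVolume, noise_sigma: float = 0.0,
                              bias_amplitude: float = 0.0, seed: int = 0,
                              noise_model: str = "gaussian") -> ImageVolume:
    """Multiply by a smooth polynomial bias field (unit mean over the brain
    mask) and add zero-mean noise; deterministic given the seed."""
    if noise_sigma < 0 or bias_amplitude < 0:
        raise ValueError("noise_sigma and bias_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    data = vol.data.astype(np.float64).copy()
    mask = vol.mask if vol.mask is not None else np.ones(vol.shape, bool)
    if bias_amplitude > 0:
        coords = [np.linspace(-1, 1, n) for n in vol.shape]
        gx, gy, gz = np.meshgrid(*coords, indexing="ij")
        terms = [gx, gy, gz, gx * gy, gx * gz, gy * gz, gx ** 2, gy ** 2, gz ** 2]
        coef = rng.standard_normal(len(terms))
        q = sum(c * t for c, t in zip(coef, terms))
        q -= q[mask].mean()
        amax = np.abs(q[mask]).max()
        if amax > 0:
            q /= amax
        data *= 1.0 + bias_amplitude * q
    if noise_sigma > 0:
        if noise_model == "rician":
            n1 = rng.normal(0.0, noise_sigma, vol.shape)
            n2 = rng.normal(0.0, noise_sigma, vol.shape)
            data = np.sqrt((data + n1) ** 2 + n2 ** 2)
        else:
            data += rng.normal(0.0, noise_sigma, vol.shape)
    return vol.with_data(data.astype(np.float32))


# ---------------------------------------------------------------------------
# Cohort simulation

@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    scans: tuple[str, str, str]     # file path per timepoint 1..3


@dataclass
class CohortManifest:
    subjects: list
    seed: int
    geometry: PhantomGeometry

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError("subject ids must be unique")
        for s in self.subjects:
            if s.group not in GROUPS:
                raise ValueError(f"unknown group {s.group!r}")
            if len(s.scans) != 3:
                raise ValueError("each subject needs exactly 3 timepoints")


@dataclass
class CohortConfig:
    """Cohort structure; defaults emulate the study (13 EtOH vs 12 controls)."""

    n_etoh: int = 13
    n_con: int = 12
    geometry: PhantomGeometry = dc_field(default_factory=PhantomGeometry)
    layout: list | None = None
    jitter_voxels: float = 2.0      # max per-subject anatomical jitter
    # per-scan physiological/positioning deformation, independent at every
    # timepoint: the source of realistic between-subject variance in the
    # longitudinal change maps (~0.2 mm in-plane at default spacing, the order
    # of session-to-session non-rigid residuals after rigid alignment)
    scan_state_voxels: float = 0.9


@dataclass
class ArtifactParams:
    noise_sigma: float = 4.0        # vs tissue 100 / CSF 220 intensity units
    bias_amplitude: float = 0.2
    noise_model: str = "gaussian"


def _jitter_field(geom: PhantomGeometry, max_vox: float, rng) -> DisplacementField:
    """Smooth random per-subject anatomical variability, max |u| <= max_vox voxels."""
    coarse = tuple(max(2, n // 8) for n in geom.shape)
    u = np.empty(geom.shape + (3,), dtype=np.float32)
    for c in range(3):
        g = rng.standard_normal(coarse)
        g = ndimage.zoom(g, [t / s for t, s in zip(geom.shape, coarse)], order=3)
        u[..., c] = ndimage.gaussian_filter(g, sigma=3.0)
    spacing = np.asarray(geom.spacing)
    mag_vox = np.linalg.norm(u / spacing, axis=-1)
    peak = float(mag_vox.max())
    if peak > 0:
        u *= (max_vox * rng.uniform(0.5, 1.0)) / peak
    return DisplacementField(u=u, spacing=spacing, affine=geom.affine)


def _effect_generation_field(labels: LabelVolume, effects: list[EffectSpec],
                             margin: float = 1.25) -> DisplacementField | None:
    """Inverse-scaling field that, applied as a pull-back warp, realises the
    prescribed forward volume ratios around each affected ROI.

    The incompressible profile is used so the transform is exactly
    volume-preserving everywhere between the scaled ball and an outer radius
    placed beyond the brain envelope: remote tissue translates by sub-voxel
    amounts but carries no spurious volume change, and the compensating
    strain of the identity blend lands outside the brain.
    """
    if not effects:
        return None
    total = np.zeros(labels.shape + (3,), dtype=np.float32)
    spacing = np.asarray(labels.spacing, float)
    extent = np.asarray(labels.shape, float) * spacing
    env_center = (np.asarray(labels.shape, float) - 1) / 2.0 * spacing
    env_semi = extent * 0.44
    for eff in effects:
        mask = labels.roi_mask(eff.roi)
        if not mask.any():
            raise ValueError(f"effect ROI {eff.roi!r} missing from the label map")
        comps, n = ndimage.label(mask)
        s = eff.volume_ratio ** (1.0 / 3.0)
        for k in range(1, n + 1):
            idx = np.argwhere(comps == k)
            ctr_idx = idx.mean(axis=0)
            ctr = ctr_idx * spacing
            ext = np.linalg.norm((idx - ctr_idx) * spacing, axis=1).max()
            inner = max(ext, 0.5) * max(s, 1.0) * margin
            # outer radius beyond every point of the brain envelope
            outer = float(np.linalg.norm(ctr - env_center) + env_semi.max() + 1.0)
            spec = AnalyticWarp(center=tuple(ctr), inner_radius=inner,
                                outer_radius=outer,
                                volume_ratio=1.0 / eff.volume_ratio,
                                profile="incompressible")
            total += make_analytic_warp(spec, labels).u
    return DisplacementField(u=total, spacing=spacing,
                             affine=np.asarray(labels.affine, float))


def soft_roi_volumes(labels: LabelVolume, field: DisplacementField | None = None
                     ) -> dict[str, float]:
    """Partial-volume ROI volumes (in voxels) after warping each ROI's soft
    indicator with linear interpolation.

    Unlike nearest-neighbour label counts, the interpolated indicator integral
    tracks sub-voxel boundary motion, so it serves as the continuous
    ground-truth volume measure for simulated effects.
    """
    coords = _sample_coords(field) if field is not None else None
    out = {}
    for lab_id, name in labels.lut.items():
        ind = (labels.labels == lab_id).astype(np.float32)
        if coords is not None:
            ind = ndimage.map_coordinates(ind, coords, order=1, mode="grid-constant", cval=0.0)
        out[name] = float(ind.sum())
    return out


def simulate_cohort(config: CohortConfig, effects: list[EffectSpec],
                    artifact_params: ArtifactParams, out_dir, seed: int = 0
                    ) -> tuple[CohortManifest, "object"]:
    """Write a full synthetic cohort: three NIfTI scans per subject, a CSV
    manifest, a CSV ground-truth table of measured per-ROI volume ratios, and
    the clean base anatomy / label map / envelope for use as templates.

    Per subject: a fixed smooth jitter warp models anatomical variability;
    scan 2 composes the group's interval-1 effect warps onto the subject's
    baseline anatomy, scan 3 composes interval-2 effects onto scan 2;
    acquisition artifacts are applied independently per scan.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geom = config.geometry
    layout = config.layout if config.layout is not None else default_layout()
    roi_names = {r.name for r in layout}
    missing = sorted({e.roi for e in effects} - roi_names)
    if missing:
        raise ValueError(f"effect ROIs missing from layout: {missing}")

    base_img, base_lab = make_base_phantom(geom, layout, seed=seed)
    save_volume(base_img, out_dir / "base_image.nii")
    save_labels(base_lab, out_dir / "base_labels.nii", out_dir / "base_lut.tsv")
    save_volume(ImageVolume(data=base_img.mask.astype(np.float32), spacing=base_img.spacing,
                            affine=base_img.affine), out_dir / "base_mask.nii")

    rng = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []
    truth_rows = []
    specs = ([("EtOH", i) for i in range(config.n_etoh)]
             + [("Con", i) for i in range(config.n_con)])
    for group, i in specs:
        sid = f"{group.lower()}{i + 1:02d}"
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        jitter = _jitter_field(geom, config.jitter_voxels, sub_rng)
        img1 = warp(base_img, jitter)
        lab1 = warp(base_lab, jitter, "nearest")
        imgs, labs, totals = [img1], [lab1], [jitter]
        for interval in (1, 2):
            eff = [e for e in effects if e.group == group and e.interval == interval]
            gen = _effect_generation_field(labs[-1], eff)
            if gen is None:
                imgs.append(imgs[-1])
                labs.append(labs[-1])
                totals.append(totals[-1])
            else:
                imgs.append(warp(imgs[-1], gen))
                labs.append(warp(labs[-1], gen, "nearest"))
                totals.append(compose(totals[-1], gen))
        # each scan carries its own small physiological/positioning deformation;
        # ground truth reports the underlying anatomical change, not the
        # per-scan state fluctuation
        states = [_jitter_field(geom, config.scan_state_voxels, sub_rng)
                  if config.scan_state_voxels > 0 else None for _ in range(3)]
        volumes = [soft_roi_volumes(base_lab, t) for t in totals]
        for interval in (1, 2):
            for roi in sorted(roi_names):
                before = volumes[interval - 1][roi]
                after = volumes[interval][roi]
                ratio = after / before if before else float("nan")
                truth_rows.append({"subject": sid, "roi": roi, "interval": interval,
                                   "true_ratio": ratio})
        paths = []
        for t, img in enumerate(imgs, start=1):
            if states[t - 1] is not None:
                img = warp(img, states[t - 1])
            scan = add_acquisition_artifacts(
                img, noise_sigma=artifact_params.noise_sigma,
                bias_amplitude=artifact_params.bias_amplitude,
                seed=int(sub_rng.integers(0, 2 ** 31 - 1)),
                noise_model=artifact_params.noise_model)
            p = out_dir / f"{sid}_t{t}.nii"
            save_volume(scan, p)
            paths.append(str(p))
        subjects.append(SubjectRecord(subject_id=sid, group=group, scans=tuple(paths)))

    manifest = CohortManifest(subjects=subjects, seed=seed, geometry=geom)
    write_manifest(manifest, out_dir / "manifest.csv")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest, truth


def write_manifest(manifest: CohortManifest, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject", "group", "scan1", "scan2", "scan3"])
        for s in manifest.subjects:
            w.writerow([s.subject_id, s.group, *s.scans])


def load_manifest(path, geometry: PhantomGeometry | None = None,
                  seed: int = 0) -> CohortManifest:
    subjects = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            subjects.append(SubjectRecord(subject_id=row["subject"], group=row["group"],
                                          scans=(row["scan1"], row["scan2"], row["scan3"])))
    return CohortManifest(subjects=subjects, seed=seed,
                          geometry=geometry or PhantomGeometry())
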