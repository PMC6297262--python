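"""Log-Jacobian determinant maps: the morphometric signal.

For a deformation phi(x) = x + u(x) between the two scans of an interval, the
per-voxel value ln det(grad phi) measures local volume change: positive is
expansion over the interval, negative is shrinkage. Maps can be bilaterally
averaged about the central sagittal plane and transported (values unchanged,
no Jacobian modulation) into template space through the group-wise fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume
from .register import DisplacementField, jacobian_determinant, warp

__all__ = ["LogJacobianMap", "log_jacobian", "bilateral_average", "to_template_space"]


@dataclass
class LogJacobianMap:
    """Per-voxel natural-log local volume ratio over a scan interval."""

    values: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray
    subject: str | None = None
    interval: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log-Jacobian map contains non-finite values")

    @property
    def shape(self):
        return self.values.shape

    def as_image(self) -> ImageVolume:
        return ImageVolume(data=self.values, spacing=self.spacing.copy(),
                           affine=self.affine.copy())


def log_jacobian(field: DisplacementField, subject: str | None = None,
                 interval: int | None = None) -> LogJacobianMap:
    """ln det(grad phi) by spacing-aware central differences (one-sided at the
    boundary); exact for affine fields. Rejects fields whose determinant is
    not strictly positive anywhere."""
    det = jacobian_determinant(field)
    if det.min() <= 0:
        bad = np.argwhere(det <= 0)
        raise ValueError(f"non-positive Jacobian determinant at {bad.shape[0]} voxels "
                         f"(first at {bad[0].tolist()}): diffeomorphism contract breached")
    return LogJacobianMap(values=np.log(det), spacing=field.spacing.copy(),
                          affine=field.affine.copy(), subject=subject, interval=interval)


def bilateral_average(jmap: LogJacobianMap, midplane_axis: int = 0) -> LogJacobianMap:
    """Average each voxel with its mirror across the central plane of the
    chosen axis: v[i] <- (v[i] + v[N-1-i]) / 2. Idempotent; the central slice
    of an odd-sized axis is unchanged."""
    if not 0 <= midplane_axis < 3:
        raise ValueError(f"midplane_axis must be 0..2, got {midplane_axis}")
    mirrored = np.flip(jmap.values, axis=midplane_axis)
    return LogJacobianMap(values=0.5 * (jmap.values + mirrored),
                          spacing=jmap.spacing.copy(), affine=jmap.affine.copy(),
                          subject=jmap.subject, interval=jmap.interval)


def to_template_space(jmap: LogJacobianMap, subject_to_template: DisplacementField
                      ) -> LogJacobianMap:
    """Resample the scalar map into template geometry with linear
    interpolation; values are transported unchanged (no modulation)."""
    if jmap.shape != subject_to_template.shape:
        raise ValueError("map and field geometries do not match")
    img = warp(jmap.as_image(), subject_to_template, "linear")
    return LogJacobianMap(values=img.data, spacing=img.spacing, affine=img.affine,
                          subject=jmap.subject, interval=jmap.interval)
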