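"""Voxel-wise permutation inference with cluster-extent correction.

One-tailed Student t statistics (two-sample EtOH vs control, or one-sample
against zero) are computed per voxel on log-Jacobian maps. Significance comes
from permutation: group-label exchanges for two-sample designs, sign flips for
one-sample, exhaustive whenever the number of arrangements fits the budget.
Multiple comparisons are controlled by cluster extent: the minimum significant
cluster size is calibrated by Monte-Carlo simulation of smooth Gaussian null
fields matched to the estimated residual smoothness (FWHM), at a family-wise
false-positive rate alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from itertools import combinations

import numpy as np
from scipy import ndimage, stats as sps

__all__ = [
    "StatMap",
    "SmoothnessEstimate",
    "MCThresholdResult",
    "Cluster",
    "ClusterSet",
    "voxelwise_t",
    "permutation_p",
    "estimate_fwhm",
    "mc_cluster_threshold",
    "extract_clusters",
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class StatMap:
    """Per-voxel statistic and (permutation) p-value for one comparison."""

    t: np.ndarray
    p: np.ndarray | None
    tail: str                      # "greater" or "less"
    design: str                    # "two_sample" or "one_sample"
    df: int
    mask: np.ndarray
    inf_flag: np.ndarray | None = None   # zero-variance voxels (t = +/-inf)


@dataclass
class SmoothnessEstimate:
    fwhm_mm: np.ndarray            # per-axis Gaussian-equivalent FWHM


@dataclass
class MCThresholdResult:
    min_cluster_size: int
    voxel_p: float
    alpha: float
    n_sim: int
    seed: int
    connectivity: int
    max_sizes: np.ndarray = dc_field(default=None, repr=False)


@dataclass
class Cluster:
    mask: np.ndarray
    size: int
    direction: str                 # "expand" or "shrink"
    peak_t: float
    comparison: str = ""


@dataclass
class ClusterSet:
    clusters: list
    shape: tuple
    spacing: np.ndarray
    affine: np.ndarray

    def union_mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for c in self.clusters:
            out |= c.mask
        return out

    def mirrored(self, axis: int = 0) -> "ClusterSet":
        """Reflect every cluster across the central plane and keep both
        hemispheres (bilateral reporting)."""
        clusters = []
        for c in self.clusters:
            m = c.mask | np.flip(c.mask, axis=axis)
            clusters.append(Cluster(mask=m, size=int(m.sum()), direction=c.direction,
                                    peak_t=c.peak_t, comparison=c.comparison))
        return ClusterSet(clusters=clusters, shape=self.shape,
                          spacing=self.spacing, affine=self.affine)


def _stack(maps, mask) -> np.ndarray:
    data = np.stack([np.asarray(m.values if hasattr(m, "values") else m, float)[mask]
                     for m in maps])
    return data


def _check_geometry(maps):
    shp = maps[0].shape
    for m in maps[1:]:
        if m.shape != shp:
            raise ValueError("all maps must share one geometry")
    return shp


def _two_sample_t(data: np.ndarray, is_a: np.ndarray):
    """Pooled-variance two-sample t (group A minus group B) per voxel."""
    na, nb = int(is_a.sum()), int((~is_a).sum())
    A, B = data[is_a], data[~is_a]
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    ssa = ((A - ma) ** 2).sum(axis=0)
    ssb = ((B - mb) ** 2).sum(axis=0)
    var = (ssa + ssb) / (na + nb - 2)
    se = np.sqrt(var * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    zero = se == 0
    diff = ma - mb
    t = np.where(zero, np.where(diff > 0, np.inf, np.where(diff < 0, -np.inf, 0.0)), t)
    return t, zero


def _one_sample_t(data: np.ndarray, signs: np.ndarray | None = None):
    n = data.shape[0]
    d = data if signs is None else data * signs[:, None]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    zero = sd == 0
    t = np.where(zero, np.where(m > 0, np.inf, np.where(m < 0, -np.inf, 0.0)), t)
    return t, zero


def _as_group_bool(design) -> np.ndarray:
    arr = np.asarray(design)
    if arr.dtype.kind in "US":
        names = sorted(set(arr.tolist()))
        if "EtOH" in names:
            return arr == "EtOH"
        if len(names) != 2:
            raise ValueError(f"two-sample design needs exactly 2 groups, got {names}")
        return arr == names[0]
    return arr.astype(bool)


def voxelwise_t(maps, design, tail: str = "greater", mask: np.ndarray | None = None
                ) -> StatMap:
    """Per-voxel Student t. ``design`` is "one_sample" (test mean against 0)
    or a per-map group-label sequence (two-sample pooled variance, t oriented
    as EtOH minus control). Zero-variance voxels get t = +/-inf and are
    flagged. Parametric p is not attached; inference uses permutation_p."""
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    shp = _check_geometry(maps)
    if mask is None:
        mask = np.ones(shp, dtype=bool)
    data = _stack(maps, mask)
    if isinstance(design, str) and design == "one_sample":
        if len(maps) < 2:
            raise ValueError("one-sample design needs >= 2 maps")
        t, zero = _one_sample_t(data)
        df = len(maps) - 1
        kind = "one_sample"
    else:
        is_a = _as_group_bool(design)
        if is_a.sum() < 2 or (~is_a).sum() < 2:
            raise ValueError("each group needs >= 2 subjects")
        t, zero = _two_sample_t(data, is_a)
        df = len(maps) - 2
        kind = "two_sample"
    tfull = np.zeros(shp)
    tfull[mask] = t
    zfull = np.zeros(shp, dtype=bool)
    zfull[mask] = zero
    return StatMap(t=tfull, p=None, tail=tail, design=kind, df=df, mask=mask,
                   inf_flag=zfull)


def _two_sample_arrangements(n: int, na: int, n_perm: int, rng):
    """Index sets for group A: exhaustive if the count fits in n_perm, else
    n_perm distinct random draws that include the observed labelling first."""
    from math import comb
    total = comb(n, na)
    if total <= n_perm:
        return [np.asarray(c) for c in combinations(range(n), na)], True
    seen = {tuple(range(na))}
    draws = [np.arange(na)]
    while len(draws) < n_perm:
        c = tuple(sorted(rng.choice(n, size=na, replace=False).tolist()))
        if c not in seen:
            seen.add(c)
            draws.append(np.asarray(c))
    return draws, False


def _sign_arrangements(n: int, n_perm: int, rng):
    total = 2 ** n
    if total <= n_perm:
        signs = [np.array([1 if (k >> i) & 1 == 0 else -1 for i in range(n)])
                 for k in range(total)]
        return signs, True
    seen = {(1,) * n}
    signs = [np.ones(n, dtype=int)]
    while len(signs) < n_perm:
        s = tuple(rng.choice([-1, 1], size=n).tolist())
        if s not in seen:
            seen.add(s)
            signs.append(np.asarray(s))
    return signs, False


def permutation_p(maps, design, tail: str = "greater", n_perm: int = 5000,
                  seed: int = 0, mask: np.ndarray | None = None) -> StatMap:
    """Permutation p-values: group-label exchanges (two-sample) or sign flips
    (one-sample). Exhaustive when the number of arrangements is <= n_perm,
    otherwise n_perm distinct draws including the identity; p is the fraction
    of arranged statistics at least as extreme as the observed one (the
    identity arrangement guarantees p >= 1/m). Deterministic given the seed."""
    if n_perm < 20:
        raise ValueError("n_perm < 20 cannot resolve any useful p-value")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values", stacklevel=2)
    obs = voxelwise_t(maps, design, tail, mask)
    mask = obs.mask
    data = _stack(maps, mask)
    rng = np.random.default_rng(seed)
    t_obs = obs.t[mask]
    count = np.zeros(t_obs.shape, dtype=np.int64)
    if obs.design == "one_sample":
        arrangements, _ = _sign_arrangements(data.shape[0], n_perm, rng)
        for s in arrangements:
            t_perm, _ = _one_sample_t(data, np.asarray(s, float))
            count += _at_least_as_extreme(t_perm, t_obs, tail)
        m = len(arrangements)
    else:
        is_a = _as_group_bool(design)
        na = int(is_a.sum())
        # work on data reordered so the observed group A comes first
        order = np.concatenate([np.where(is_a)[0], np.where(~is_a)[0]])
        dat = data[order]
        arrangements, _ = _two_sample_arrangements(data.shape[0], na, n_perm, rng)
        sel = np.zeros(data.shape[0], dtype=bool)
        for idx in arrangements:
            sel[:] = False
            sel[idx] = True
            t_perm, _ = _two_sample_t(dat, sel)
            count += _at_least_as_extreme(t_perm, t_obs, tail)
        m = len(arrangements)
    p = count / m
    pfull = np.ones(obs.t.shape)
    pfull[mask] = p
    obs.p = pfull
    return obs


def _at_least_as_extreme(t_perm, t_obs, tail):
    with np.errstate(invalid="ignore"):
        if tail == "greater":
            return (t_perm >= t_obs).astype(np.int64)
        return (t_perm <= t_obs).astype(np.int64)


def estimate_fwhm(residual_maps, mask: np.ndarray, spacing) -> SmoothnessEstimate:
    """Per-axis Gaussian-equivalent FWHM from the variance of spatial first
    differences of standardized residuals (classic gradient estimator),
    averaged across maps. Scale-invariant; floored at half a voxel."""
    if mask.sum() == 0:
        raise ValueError("empty mask")
    if len(residual_maps) < 2:
        raise ValueError("need >= 2 residual maps")
    spacing = np.asarray(spacing, float)
    fwhms = []
    for m in residual_maps:
        r = np.asarray(m.values if hasattr(m, "values") else m, float)
        mu, sd = r[mask].mean(), r[mask].std()
        if sd == 0:
            continue
        r = (r - mu) / sd
        per_axis = []
        for ax in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[ax] = slice(1, None)
            sl_b[ax] = slice(None, -1)
            pair = mask[tuple(sl_a)] & mask[tuple(sl_b)]
            d = (r[tuple(sl_a)] - r[tuple(sl_b)])[pair]
            rho = np.clip(1.0 - np.mean(d ** 2) / 2.0, 1e-3, 0.999)
            sigma_vox = np.sqrt(-1.0 / (4.0 * np.log(rho)))
            per_axis.append(2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma_vox * spacing[ax])
        fwhms.append(per_axis)
    fwhm = np.mean(fwhms, axis=0)
    return SmoothnessEstimate(fwhm_mm=np.maximum(fwhm, 0.5 * spacing))


def mc_cluster_threshold(shape, spacing, mask: np.ndarray, fwhm_mm,
                         voxel_p: float = 0.01, alpha: float = 0.05,
                         connectivity: int = 6, n_sim: int = 1000,
                         seed: int = 0) -> MCThresholdResult:
    """Monte-Carlo minimum cluster size at family-wise rate ``alpha``.

    Simulates white Gaussian fields smoothed to ``fwhm_mm``, standardized
    within the mask, thresholded one-tailed at ``voxel_p``; records the
    maximum suprathreshold cluster size per simulation and returns the
    smallest size k whose exceedance fraction is <= alpha.
    """
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0,1)")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0,1]")
    if n_sim < 200:
        raise ValueError("n_sim < 200 gives an unstable cluster threshold")
    spacing = np.asarray(spacing, float)
    sigma_vox = np.asarray(fwhm_mm, float) / spacing / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if np.all(np.asarray(fwhm_mm) < spacing):
        warnings.warn("FWHM below voxel size: simulating unsmoothed noise", stacklevel=2)
        sigma_vox = np.zeros(3)
    z_crit = sps.norm.isf(voxel_p)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    rng = np.random.default_rng(seed)
    max_sizes = np.zeros(n_sim, dtype=np.int64)
    for i in range(n_sim):
        field = rng.standard_normal(shape)
        if sigma_vox.max() > 0:
            field = ndimage.gaussian_filter(field, sigma=sigma_vox)
        vals = field[mask]
        field = (field - vals.mean()) / vals.std()
        supra = (field > z_crit) & mask
        if not supra.any():
            continue
        lab, n = ndimage.label(supra, structure=structure)
        if n:
            max_sizes[i] = np.bincount(lab.ravel())[1:].max()
    ks = np.arange(1, max(int(max_sizes.max()), 1) + 2)
    exceed = np.array([(max_sizes >= k).mean() for k in ks])
    min_k = int(ks[np.argmax(exceed <= alpha)])
    return MCThresholdResult(min_cluster_size=min_k, voxel_p=voxel_p, alpha=alpha,
                             n_sim=n_sim, seed=seed, connectivity=connectivity,
                             max_sizes=max_sizes)


def extract_clusters(pmap: StatMap, voxel_p: float = 0.01, min_cluster_size: int = 1,
                     connectivity: int = 6, spacing=None, affine=None,
                     comparison: str = "") -> ClusterSet:
    """Connected components of {p < voxel_p} within the tested mask, discarding
    components smaller than min_cluster_size; direction comes from the map's
    tail (greater = expansion, less = shrinkage). An empty set is valid."""
    if pmap.p is None:
        raise ValueError("StatMap has no permutation p-values")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    supra = (pmap.p < voxel_p) & pmap.mask
    direction = "expand" if pmap.tail == "greater" else "shrink"
    clusters = []
    if supra.any():
        lab, n = ndimage.label(supra, structure=structure)
        sizes = np.bincount(lab.ravel())
        for k in range(1, n + 1):
            if sizes[k] >= min_cluster_size:
                m = lab == k
                with np.errstate(invalid="ignore"):
                    peak = float(np.nanmax(np.abs(np.where(m, pmap.t, np.nan))))
                clusters.append(Cluster(mask=m, size=int(sizes[k]), direction=direction,
                                        peak_t=peak, comparison=comparison))
    spacing = np.ones(3) if spacing is None else np.asarray(spacing, float)
    affine = np.eye(4) if affine is None else np.asarray(affine, float)
    return ClusterSet(clusters=clusters, shape=pmap.t.shape, spacing=spacing,
                      affine=affine)
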