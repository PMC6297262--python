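"""End-to-end orchestration of the morphometry analysis.

From a cohort manifest of three-timepoint scans: preprocess every scan,
compute per-subject interval log-Jacobian maps, build one group-wise template
per interval (baseline template for interval 1, post-binge template for
interval 2 — never mixed), align and bilaterally average the maps, run the six
comparisons (between-group and within-group, per interval) with one-tailed
permutation tests in both directions and Monte-Carlo cluster-extent
correction, transform surviving clusters to atlas space, and emit the ROI
overlap tables with pattern labels.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import (Atlas, build_roi_report, map_clusters_to_atlas, roi_overlap_table)
from .core import ImageVolume, load_volume, save_volume
from .jacobian import bilateral_average, log_jacobian, to_template_space
from .phantom import load_manifest
from .preprocess import match_intensity, preprocess_scan
from .register import (RegistrationParams, build_groupwise_template,
                       register_nonrigid, save_field)
from .stats import (estimate_fwhm, extract_clusters, mc_cluster_threshold,
                    permutation_p)

__all__ = ["RunConfig", "ComparisonPlan", "run_pipeline", "write_report"]

log = logging.getLogger("tbmorph")

COMPARISONS = (
    ("between", 1), ("between", 2),
    ("within_EtOH", 1), ("within_EtOH", 2),
    ("within_Con", 1), ("within_Con", 2),
)


@dataclass
class ComparisonPlan:
    """Which template backs which comparison: interval-1 analyses use the
    scans-1 (baseline) template, interval-2 analyses the scans-2 template."""

    comparisons: tuple = COMPARISONS

    def template_for(self, interval: int) -> str:
        return {1: "baseline", 2: "binge"}[interval]


@dataclass
class RunConfig:
    manifest: str
    atlas_image: str
    atlas_labels: str
    atlas_lut: str
    out_dir: str
    tissue_classes: dict | None = None
    template_image: str | None = None       # skull-strip template; default atlas image
    template_mask: str | None = None
    registration: RegistrationParams = dc_field(default_factory=RegistrationParams)
    groupwise_outer_iter: int = 5
    denoise_strength: float = 1.0
    voxel_p: float = 0.01
    alpha: float = 0.05
    n_perm: int = 5000
    n_sim: int = 500
    connectivity: int = 6
    threshold_pct: float = 10.0
    midline_axis: int = 0
    mirror_clusters: bool = True
    seed: int = 0
    write_intermediates: bool = True


def _load_strip_template(config: RunConfig) -> ImageVolume:
    path = config.template_image or config.atlas_image
    tpl = load_volume(path)
    if config.template_mask:
        mask = load_volume(config.template_mask).data > 0.5
    else:
        mask = tpl.data > 0.1 * tpl.data.max()
    return ImageVolume(data=tpl.data, spacing=tpl.spacing, affine=tpl.affine, mask=mask)


def _right_hemisphere_mask(brain: np.ndarray, axis: int) -> np.ndarray:
    n = brain.shape[axis]
    sel = np.zeros(brain.shape, dtype=bool)
    idx = [slice(None)] * 3
    idx[axis] = slice((n + 1) // 2, None)
    sel[tuple(idx)] = True
    return brain & sel


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a dict of output tables and paths."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run_log.txt")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)

    cfg_echo = {k: (v if isinstance(v, (str, int, float, bool, dict, type(None)))
                    else str(v)) for k, v in vars(config).items()}
    (out / "effective_config.yaml").write_text(yaml.safe_dump(cfg_echo))

    manifest = load_manifest(config.manifest)
    groups = {s.subject_id: s.group for s in manifest.subjects}
    n_per_group = {g: sum(1 for v in groups.values() if v == g) for g in set(groups.values())}
    if any(n < 2 for n in n_per_group.values()):
        raise ValueError(f"need >= 2 subjects per group, got {n_per_group}")
    log.info("cohort: %s", n_per_group)

    strip_tpl = _load_strip_template(config)
    from .atlas import load_atlas
    atlas = load_atlas(config.atlas_labels, config.atlas_lut)
    if config.tissue_classes:
        atlas.tissue_class.update(config.tissue_classes)

    # --- stage 1: preprocessing -------------------------------------------
    scans: dict[tuple[str, int], ImageVolume] = {}
    for s in manifest.subjects:
        for t, path in enumerate(s.scans, start=1):
            t0 = time.time()
            vol = load_volume(path)
            scans[(s.subject_id, t)] = preprocess_scan(
                vol, strip_tpl, denoise_strength=config.denoise_strength,
                params=config.registration)
            log.info("preprocess %s t%d (%.1fs)", s.subject_id, t, time.time() - t0)

    # --- stage 2: per-subject interval registrations ----------------------
    subject_maps: dict[tuple[str, int], object] = {}
    for s in manifest.subjects:
        for interval in (1, 2):
            earlier = scans[(s.subject_id, interval)]
            later = scans[(s.subject_id, interval + 1)]
            t0 = time.time()
            matched = match_intensity(earlier, later)
            field = register_nonrigid(matched, later, config.registration)
            subject_maps[(s.subject_id, interval)] = log_jacobian(
                field, subject=s.subject_id, interval=interval)
            log.info("interval map %s %d->%d (%.1fs)", s.subject_id, interval,
                     interval + 1, time.time() - t0)

    # --- stage 3: group-wise templates (one per interval, never mixed) ----
    plan = ComparisonPlan()
    templates = {}
    gw_fields = {}
    for interval, timepoint in ((1, 1), (2, 2)):
        vols = [scans[(s.subject_id, timepoint)] for s in manifest.subjects]
        t0 = time.time()
        gw = build_groupwise_template(vols, config.registration,
                                      n_outer_iter=config.groupwise_outer_iter)
        name = plan.template_for(interval)
        templates[name] = gw.template
        gw_fields[name] = {s.subject_id: f for s, f in zip(manifest.subjects, gw.fields)}
        log.info("groupwise %s template (%.1fs) %s", name, time.time() - t0,
                 gw.convergence[-1])
        if config.write_intermediates:
            save_volume(gw.template, out / f"template_{name}.nii")

    # --- stage 4: align maps to template space, bilateral average ---------
    aligned: dict[tuple[str, int], object] = {}
    for s in manifest.subjects:
        for interval in (1, 2):
            name = plan.template_for(interval)
            m = to_template_space(subject_maps[(s.subject_id, interval)],
                                  gw_fields[name][s.subject_id])
            aligned[(s.subject_id, interval)] = bilateral_average(m, config.midline_axis)
            if config.write_intermediates:
                save_volume(aligned[(s.subject_id, interval)].as_image(),
                            out / f"jacobian_{s.subject_id}_interval{interval}.nii")

    # template -> atlas fields
    atlas_img = load_volume(config.atlas_image)
    to_atlas = {}
    for name, tpl in templates.items():
        to_atlas[name] = register_nonrigid(atlas_img, tpl.with_data(tpl.data, mask=None),
                                           config.registration)
        if config.write_intermediates:
            save_field(to_atlas[name], out / f"field_{name}_to_atlas.nii")

    # --- stages 5-6: statistics, atlas overlap, report --------------------
    tables, thresholds = run_statistics(aligned, templates, to_atlas, groups,
                                        atlas, atlas_img, config, out)

    checksums = {}
    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "outputs_manifest.json":
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "outputs_manifest.json").write_text(json.dumps(checksums, indent=1))
    log.info("pipeline complete in %.1fs", time.time() - t_start)
    log.removeHandler(fh)
    fh.close()
    return {"tables": tables, "thresholds": thresholds, "out_dir": str(out)}


def run_statistics(aligned: dict, templates: dict, to_atlas: dict, groups: dict,
                   atlas: Atlas, atlas_img: ImageVolume, config: RunConfig, out: Path
                   ) -> tuple[dict, pd.DataFrame]:
    """Permutation inference, cluster-extent correction, atlas overlap and
    report emission for the six comparisons, given template-space bilaterally
    averaged maps keyed by (subject, interval)."""
    plan = ComparisonPlan()
    subject_ids = sorted({sid for sid, _ in aligned})
    rng = np.random.default_rng(config.seed)
    seeds = {c: int(rng.integers(0, 2 ** 31 - 1)) for c in COMPARISONS}
    overlap_rows = {}
    threshold_records = []
    for comp, interval in COMPARISONS:
        name = plan.template_for(interval)
        tpl = templates[name]
        brain = tpl.mask if tpl.mask is not None else tpl.data > 0.1 * tpl.data.max()
        test_mask = _right_hemisphere_mask(brain, config.midline_axis)
        if comp == "between":
            sids = subject_ids
            design = np.asarray([groups[sid] for sid in sids])
        else:
            grp = comp.split("_")[1]
            sids = [sid for sid in subject_ids if groups[sid] == grp]
            design = "one_sample"
        maps = [aligned[(sid, interval)] for sid in sids]
        comp_seed = seeds[(comp, interval)]

        data = np.stack([m.values for m in maps])
        if isinstance(design, str):
            resid = data - data.mean(axis=0)
        else:
            resid = data.copy()
            for g in np.unique(design):
                sel = design == g
                resid[sel] -= data[sel].mean(axis=0)
        fwhm = estimate_fwhm(list(resid), test_mask, tpl.spacing)
        thr = mc_cluster_threshold(tpl.shape, tpl.spacing, test_mask, fwhm.fwhm_mm,
                                   voxel_p=config.voxel_p, alpha=config.alpha,
                                   connectivity=config.connectivity,
                                   n_sim=config.n_sim, seed=comp_seed)
        threshold_records.append({
            "comparison": comp, "interval": interval, "voxel_p": config.voxel_p,
            "fwhm_mm_x": round(float(fwhm.fwhm_mm[0]), 3),
            "fwhm_mm_y": round(float(fwhm.fwhm_mm[1]), 3),
            "fwhm_mm_z": round(float(fwhm.fwhm_mm[2]), 3),
            "alpha": config.alpha, "min_cluster_size": thr.min_cluster_size,
            "n_sim": config.n_sim, "seed": comp_seed})
        log.info("%s interval %d: min cluster size %d (fwhm %s)", comp, interval,
                 thr.min_cluster_size, np.round(fwhm.fwhm_mm, 2))

        masks_by_dir = {}
        for tail, direction in (("greater", "expand"), ("less", "shrink")):
            pmap = permutation_p(maps, design, tail=tail, n_perm=config.n_perm,
                                 seed=comp_seed, mask=test_mask)
            cs = extract_clusters(pmap, voxel_p=config.voxel_p,
                                  min_cluster_size=thr.min_cluster_size,
                                  connectivity=config.connectivity,
                                  spacing=tpl.spacing, affine=tpl.affine,
                                  comparison=f"{comp}_{interval}")
            mirror = config.midline_axis if config.mirror_clusters else None
            masks_by_dir[direction] = map_clusters_to_atlas(cs, to_atlas[name], mirror)
            log.info("%s interval %d %s: %d clusters, %d voxels", comp, interval,
                     direction, len(cs.clusters), int(masks_by_dir[direction].sum()))
        overlap_rows[(comp, interval)] = roi_overlap_table(
            masks_by_dir["expand"], masks_by_dir["shrink"], atlas, interval)
        if config.write_intermediates:
            for direction, m in masks_by_dir.items():
                save_volume(ImageVolume(data=m.astype(np.float32),
                                        spacing=atlas_img.spacing, affine=atlas_img.affine),
                            out / f"clusters_{comp}_interval{interval}_{direction}.nii")

    thresholds = pd.DataFrame(threshold_records)
    thresholds.to_csv(out / "cluster_thresholds.csv", index=False)

    tables = {}
    for comp in ("between", "within_EtOH", "within_Con"):
        tables[comp] = build_roi_report(overlap_rows[(comp, 1)], overlap_rows[(comp, 2)],
                                        atlas, config.threshold_pct)
    write_report(tables, out, threshold_pct=config.threshold_pct)
    return tables, thresholds


def _display_cell(vol: int, pct: float) -> tuple[str, str]:
    """Table cells use 'n.d.' when no significant cluster touched the ROI."""
    if vol == 0:
        return "n.d.", "n.d."
    return str(vol), f"{pct:.2f}%"


def write_report(tables: dict[str, pd.DataFrame], out_dir,
                 threshold_pct: float = 10.0) -> list[str]:
    """Emit per-family CSVs (machine-readable twin with zeros plus a display
    CSV using n.d. cells) and a pattern summary of ROIs at or above the
    relevance threshold."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    summary_lines = []
    for comp, df in tables.items():
        machine = out_dir / f"roi_table_{comp}.csv"
        df.to_csv(machine, index=False)
        written.append(str(machine))
        disp_rows = []
        for _, r in df.iterrows():
            e1v, e1p = _display_cell(r.expand_vol_1, r.expand_pct_1)
            s1v, s1p = _display_cell(r.shrink_vol_1, r.shrink_pct_1)
            e2v, e2p = _display_cell(r.expand_vol_2, r.expand_pct_2)
            s2v, s2p = _display_cell(r.shrink_vol_2, r.shrink_pct_2)
            disp_rows.append({
                "ROI Name": r.roi, "ROI vol": r.roi_vol,
                "Expand vol (1-2)": e1v, "Expand % (1-2)": e1p,
                "Shrink vol (1-2)": s1v, "Shrink % (1-2)": s1p,
                "Expand vol (2-3)": e2v, "Expand % (2-3)": e2p,
                "Shrink vol (2-3)": s2v, "Shrink % (2-3)": s2p,
                "Overall": f"{r.overall_pct:.2f}%", "Pattern": r.pattern})
        display = out_dir / f"roi_table_{comp}_display.csv"
        pd.DataFrame(disp_rows).to_csv(display, index=False)
        written.append(str(display))
        summary_lines.append(f"## {comp}")
        hits = df[(df[["expand_pct_1", "shrink_pct_1", "expand_pct_2", "shrink_pct_2"]]
                   .max(axis=1) >= threshold_pct)]
        if hits.empty:
            summary_lines.append(f"  no ROI at >= {threshold_pct:.0f}% change")
        else:
            for pattern in hits.pattern.unique():
                rois = hits[hits.pattern == pattern].roi.tolist()
                summary_lines.append(f"  {pattern}: {', '.join(rois)}")
        summary_lines.append("")
    summary = out_dir / "pattern_summary.txt"
    summary.write_text("\n".join(summary_lines))
    written.append(str(summary))
    return written
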