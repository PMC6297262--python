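# tbmorph

Longitudinal tensor-based morphometry (TBM) for small-animal structural MRI,
validated end-to-end on synthetic phantoms with analytically known
deformations.

The scientific setting: a rodent cohort is scanned at three timepoints
(baseline, after an intervention such as a 4-day binge-ethanol regimen, and
after a week of recovery), and the question is *which brain regions expand or
shrink over each interval, and which of those changes reverse*. Rather than
tracing regions of interest, TBM registers each animal's scans of an interval
with a dense diffeomorphic transform φ(x) = x + u(x) and analyses the
**log-Jacobian determinant map**

    J(x) = ln det ∇φ(x)

whose value at a voxel is the local log volume ratio over the interval
(J > 0: expansion, J < 0: shrinkage). Maps are carried into a group-wise
(unbiased) template per interval, bilaterally averaged about the mid-sagittal
plane, and tested voxel-wise with one-tailed permutation tests (group-label
exchanges between groups, sign flips within a group) at p < 0.01, corrected
for multiple comparisons by a Monte-Carlo cluster-extent threshold at
family-wise α = 0.05. Surviving clusters are warped to a label atlas and each
ROI's overlap with the expansion/shrinkage masks is tabulated per interval,
together with a signed overall change and a pattern label (reversible vs
enduring expansion/shrinkage, at a 10 %-of-ROI relevance threshold).

Because raw scans for such studies are rarely available, the package ships a
first-class phantom module: labelled ellipsoidal anatomy in a T2-like
contrast, compactly supported radial warps whose Jacobian is known in closed
form (`det ∇φ = v` exactly inside an inner ball), per-subject anatomical
jitter, per-scan physiological state deformations, bias fields and noise.
Every downstream stage is validated against this analytic ground truth.

## Quick start

Simulate a study-like cohort (reversible ventricular expansion, enduring
collicular shrinkage in the ethanol group) and run the full analysis:

```bash
tbmorph simulate --outdir cohort --n-etoh 6 --n-con 6 --shape 64,64,32 \
    --preset study --seed 11
tbmorph run --config run.yaml --outdir results --seed 5
```

with `run.yaml` pointing at the simulated files:

```yaml
manifest: cohort/manifest.csv
atlas_image: cohort/base_image.nii
atlas_labels: cohort/base_labels.nii
atlas_lut: cohort/base_lut.tsv
template_image: cohort/base_image.nii
template_mask: cohort/base_mask.nii
out_dir: results
```

Or from Python:

```python
from tbmorph.phantom import (CohortConfig, EffectSpec, ArtifactParams,
                             PhantomGeometry, simulate_cohort, roi_tissue_classes)
from tbmorph.pipeline import RunConfig, run_pipeline

geom = PhantomGeometry(shape=(64, 64, 32), spacing=(0.2, 0.2, 1.0))
effects = [EffectSpec("lateral_ventricles", 1, "EtOH", 1.87),
           EffectSpec("lateral_ventricles", 2, "EtOH", 1 / 1.87),
           EffectSpec("superior_colliculus", 1, "EtOH", 0.85),
           EffectSpec("inferior_colliculus", 1, "EtOH", 0.85)]
simulate_cohort(CohortConfig(n_etoh=6, n_con=6, geometry=geom), effects,
                ArtifactParams(), "cohort", seed=11)
result = run_pipeline(RunConfig(manifest="cohort/manifest.csv",
                                atlas_image="cohort/base_image.nii",
                                atlas_labels="cohort/base_labels.nii",
                                atlas_lut="cohort/base_lut.tsv",
                                template_mask="cohort/base_mask.nii",
                                tissue_classes=roi_tissue_classes(),
                                out_dir="results", seed=5))
print(result["tables"]["between"][["roi", "expand_pct_1", "shrink_pct_1",
                                   "expand_pct_2", "shrink_pct_2", "pattern"]])
```

A between-group table from such a run looks like (abridged):

```
                 roi  expand_pct_1  shrink_pct_1  expand_pct_2  shrink_pct_2               pattern
  lateral_ventricles        100.00          0.00          0.00        100.00  reversible_expansion
 superior_colliculus          0.00         92.86          0.00          0.00    enduring_shrinkage
 inferior_colliculus          0.00         85.15          0.00          0.00    enduring_shrinkage
```

reading: the simulated ventricular expansion covers the whole ventricle ROI
during the exposure interval and fully reverses during recovery
(`reversible_expansion`), while the collicular shrinkage present in interval
1 shows no significant recovery (`enduring_shrinkage`). The within-control
tables of the same run stay empty — no ROI reaches the 10 % threshold.

Outputs per run: per-interval templates, aligned bilaterally averaged
Jacobian maps, cluster masks, a `cluster_thresholds.csv` report (estimated
FWHM, Monte-Carlo minimum cluster size per comparison), three ROI tables
(between-group, within-EtOH, within-control; machine-readable plus a display
variant using `n.d.` for empty cells), a pattern summary, a run log, and a
checksummed output manifest.

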