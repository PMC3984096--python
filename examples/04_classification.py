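"""Cross-validated classification: SOM-ROI features vs voxels-as-features.

Every fold refits class statistics, FDR, difference image, SOM, ROI map and
the SVM on its training subjects only; held-out subjects are projected onto
the trained ROIs (their own tissue map weighted by the training FDR) and
scored.  A smaller cohort than the standard study condition keeps this
example quick.
"""

from somroi import CvConfig, EffectRegion, PhantomConfig, cross_validate, generate_cohort

config = PhantomConfig(
    grid_shape=(24, 24, 24), n_per_class=15,
    effect_regions=(EffectRegion((12.0, 12.0, 12.0), 4.0, 0.4, "GM"),),
    noise_sd=0.05, seed=5,
)
gm, wm = generate_cohort(config)

n_features = {"somroi": 2 * 108, "vaf": 2 * (12 ** 3)}  # GM + WM
for method in ("somroi", "vaf"):
    report = cross_validate(
        gm, wm, CvConfig(n_folds=5, seed=5, method=method, vaf_downsample=2)
    )
    print(f"{method:>6} ({n_features[method]:>5} features): "
          f"accuracy {report.accuracy[0]:.2f}+/-{report.accuracy[1]:.2f}  "
          f"sensitivity {report.sensitivity[0]:.2f}  "
          f"specificity {report.specificity[0]:.2f}  AUC {report.auc:.2f}")
# On this clearly separable phantom both methods classify perfectly; the
# point of the ROI features is that they do so with ~16x fewer features
# (and, on the raw grid, ~100x fewer), concentrating the discriminative
# information into a handful of interpretable regions.
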