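"""Generate a synthetic two-class cohort and save it as NIfTI + manifest.

The phantom plants a spherical grey-matter "atrophy" of 0.4 probability
units in every class-1 (disease) subject; class-0 (control) subjects share
the same smooth baseline.  Output is a directory of per-subject NIfTI
volumes and a manifest CSV that every other pipeline stage consumes.
"""

from somroi import EffectRegion, PhantomConfig, generate_cohort
from somroi.io import write_cohort

config = PhantomConfig(
    grid_shape=(32, 32, 32),
    n_per_class=10,
    effect_regions=(EffectRegion(center=(16.0, 16.0, 16.0), radius=4.0,
                                 effect_size=0.4, tissue="GM"),),
    noise_sd=0.05,
    seed=0,
)
gm, wm = generate_cohort(config)
manifest = write_cohort(gm, wm, "phantom_cohort", config=config)

print(f"{gm.n_subjects} subjects per tissue on a {gm.grid_shape} grid")
print(f"GM intensity range: [{gm.volumes.min():.3f}, {gm.volumes.max():.3f}]")
d = gm.volumes[gm.labels == 0].mean(0) - gm.volumes[gm.labels == 1].mean(0)
print(f"empirical GM difference peak: {d.max():.3f}  (planted effect 0.4 + noise)")
print(f"manifest written to {manifest}")
# The difference peak sits near 0.4 because disease subjects lost exactly
# that much probability inside the planted sphere before noise.
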