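# dermaflim

Non-invasive scoring of psoriasis severity from two-photon
fluorescence-lifetime (FLIM) image stacks.

Psoriasis severity is usually graded by eye (the PASI score), which is
poorly reproducible and insensitive to local change.  Two-photon FLIM
"optical biopsies" of skin — volumetric stacks in which every pixel holds
a photon-arrival-time histogram — carry objective structural and metabolic
biomarkers instead: the lifetimes of the NAD(P)H-dominated autofluorescence
decay shift with the keratinocytes' metabolic state, the stratum
granulosum (SG) to stratum basale (SB) distance measures epidermal
thickening, and perinuclear mitochondrial clustering raises the
high-spatial-frequency content of the intensity images.  `dermaflim`
implements the full analysis pipeline from raw decay cubes to a single
severity score, for researchers analysing clinical multiphoton/FLIM data
or prototyping such analyses on simulated cohorts.

## The model

Each pixel's decay is fitted (after summing a 9×9 moving window,
binning factor n = 4) with a two-component exponential

    f(t) = a₁·e^(−t/τ₁) + a₂·e^(−t/τ₂),   τ₁ ≤ τ₂,

by Poisson-weighted least squares (weights 1/max(count, 1)), giving
per-frame lifetime statistics and component percentages
pᵢ = 100·aᵢ/(a₁+a₂).  Two texture features summarise each intensity
frame: the **Fourier parameter** (mean FFT magnitude in a
high-frequency annulus, r ∈ [24, 36) px, divided by a medium-frequency
annulus, r ∈ [14, 24) px, radii for a 512 px frame) and the **mean local
entropy** (Shannon entropy in a radius-2 px disk, averaged over the
frame).  Eight features per site (Fourier parameter and τ statistics at
SB/SG, SG depth, SG→SB distance, SG entropy) enter a standardized PCA;
the first principal component, oriented so control skin scores lowest, is
the severity score.  A five-feature variant built from lesional /
non-lesional ("pseudo-control") site ratios correlates with the clinical
PASI score.

Because clinical FLIM data of this kind is not publicly available, the
package ships a synthetic-cohort generator with a documented generative
model (group-dependent lifetimes, epidermal geometry, puncta density,
Poisson photon noise, and a tunable latent-severity coupling to PASI)
so that every stage is testable end to end.

## Worked example

```python
from dermaflim import CohortConfig, AnalysisConfig, run_study

cfg = CohortConfig(frame_size=128, n_time_bins=64, layers_only=True)
res = run_study({"control": 8, "psoriasis": 8, "eczema": 8},
                cfg, AnalysisConfig(fit_stride=8), seed=3)
print(res.pc1_group_means().round(2))
print(f"r(PC1, PASI) = {res.pasi_results.pasi_correlation():.2f}")
```

prints (one simulated cohort, 32 imaging sites):

```
group
control          -2.83
eczema            0.73
pseudo_control   -0.74
psoriasis         2.84
Name: PC1, dtype: float64
r(PC1, PASI) = 0.58
```

Severity rises along PC1 from healthy control skin through the visually
uninvolved pseudo-control skin of psoriasis patients to their lesions,
with eczema in between — and the PASI-feature model's PC1 correlates with
the simulated clinical score at roughly the coupling strength built into
the generator (target r = 0.5; the estimate is attenuated by feature
noise and n = 8 sampling error).  `res.condition_results.summary()`
prints the fitted loadings, explained variance and group separation.

The same pipeline is scriptable from a shell:

```bash
dermaflim simulate --seed 7 --out cohort/
dermaflim features cohort/ --out features/
dermaflim score features/features_condition.csv --out scores/
dermaflim plot features/features_condition.csv --out pc_plane.png
```

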