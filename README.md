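# nebfish

Quantitative analysis toolkit for zebrafish models of nebulin (*neb*)-related
nemaline myopathy. It implements, as a tested and reusable pipeline, the
bespoke measurements such studies rely on:

* **Thin-filament length from phalloidin intensity profiles.** A 1-D profile
  along a myofibril is modelled per sarcomere as a *rectangle flanked by two
  half-Gaussians*: f(x) = b + h for |x − c| ≤ W/2, and
  b + h·exp(−(|x − c| − W/2)² / 2σ²) outside (σ = σ_L or σ_R by side).
  Points at the plateau centre are *deactivated* (zero-weighted) during
  fitting because actin overlap at the Z-disk adds a bump there. Thin-filament
  length is TF = W/2 + √(2 ln 2)·σ̄ (plateau half-width plus the flank's
  half-width at half-maximum) and sarcomere length SL is the spacing of
  adjacent fitted centres. Measurements are filtered to an SL window
  (default 1.85–2.2 µm), regressed on SL (1.6–2.6 µm), and compared across
  genotypes (Welch tests vs the wild-type control, Holm-corrected).
* **Splice-event quantification.** Percent-spliced-in per exon from
  inclusion/exclusion read counts,
  IRₙ = IR/(L + r − 1), ERₙ = ER/(r − 1), PSI = 100·IRₙ/(IRₙ + ERₙ);
  relative junction-event frequencies (canonical vs alternative site(s) vs
  intron retention) as read shares; and the transcript consequence of an
  aberrant splice choice — in-frame vs frameshift by Δbp mod 3, plus
  premature-termination-codon (PTC) detection by translating the modified
  mRNA of a toy gene model (FASTA + GFF3).
* **Muscle mechanics features.** Baseline-subtracted maximum force per
  stimulation frequency (1–200 Hz force–frequency curve), single-twitch
  activation (t10→t100) and relaxation (t100→t10) times with linearly
  interpolated 10% crossings, and elliptical trunk cross-sectional area
  csa = π·(w̄/2)·(d̄/2).
* **Synthetic data generators** for all of the above, with exact ground
  truth attached, so every stage is testable end to end without microscope
  or sequencing data.

## Worked example

```python
import numpy as np
from nebfish import synthetic as syn, profile_fit as pf, filament_metrics as fm

groups = {}
for genotype, tf_true in (("wt", 1.00), ("mut", 0.94)):   # a 6% shorter mutant
    ms = []
    for seed in range(10):
        spec = syn.profile_spec_for_tf(tf_true, n_units=8, sarcomere_length=2.0,
                                       noise_sd=0.02, seed=seed)
        profile, truth, _ = syn.generate_profile_train(spec)
        fits = pf.fit_profile(profile)                     # joint train fit
        ms += fm.measurements_from_fits(fits, genotype=genotype)
    groups[genotype] = ms

comp = fm.compare_groups(groups, control="wt", sl_window=(1.85, 2.2))
for g, (mean, sem, n) in comp.group_means.items():
    print(f"{g}: TF = {mean:.4f} ± {sem:.4f} um (n={n}), "
          f"{comp.percent_of_control[g]:.1f}% of control")
print("Holm-adjusted Welch p:", f"{comp.difference_p['mut']:.2e}")
```

prints

```
wt: TF = 1.0001 ± 0.0009 um (n=80), 100.0% of control
mut: TF = 0.9402 ± 0.0003 um (n=80), 94.0% of control
Holm-adjusted Welch p: 1.93e-82
```

i.e. the pipeline recovers the simulated wild-type thin-filament length
(1.00 µm) and the mutant's 6% reduction (94% of control) from noisy
profiles, and flags the group difference as significant.

The same analyses are available from the shell:

```sh
nebfish run-demo --seed 1 --out demo_out     # full synthetic demo pipeline
nebfish fit-profiles --in profile.csv --out units.tsv
nebfish psi --counts exon_counts.tsv
nebfish splice-consequence --fasta toy.fa --gff toy.gff3 --event donor_shift:2:+5
```

Every `run-demo` output carries a header recording the package version, the
seed and a configuration hash; a repeated run with the same seed is
byte-identical.

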