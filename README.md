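# hepaflow

Liver perfusion and bulk-flow MRI analysis for small-animal studies:
FAIR ASL (flow-sensitive alternating inversion recovery arterial spin
labelling) perfusion quantification, Look-Locker inversion-recovery T1
mapping, retrospective respiratory gating, caval-subtraction phase-contrast
flow integration, and the method-agreement / group statistics that such a
study needs — all driven by a digital rodent-liver phantom with known
ground truth, so every stage of the chain can be verified without animal
data.

The package targets preclinical imaging scientists who want (a) a tested
reference implementation of the FAIR-ASL/PCMRI analysis chain for rodent
liver at high field, and (b) a simulation harness to explore protocol and
statistical choices (noise, gating, cohort sizes, attrition) before running
animals. Real data can be supplied as NIfTI stacks plus a metadata table;
the synthetic phantom is a first-class module, not a test fixture.

## The models

**T1 fitting.** Each pixel's post-inversion signal across 50 inversion
times (110 ms spacing) is fitted to the three-parameter recovery model

    Mz(TI) = M0 · (1 − α · e^(−TI/T1*)),

with M0 the equilibrium signal, α the apparent inversion efficiency (2 for
a perfect inversion) and T1\* the apparent relaxation time of the
Look-Locker readout, corrected to the true T1 by the small-angle relation
T1 = T1\*·(α − 1). Images are smoothed with a σ = 1.6 pixel Gaussian
window before fitting.

**Perfusion.** Inflowing non-inverted blood accelerates recovery after a
slice-selective inversion but not after a global one, so perfusion follows
from the paired T1 maps:

    P = (λ / T1_blood) · (T1_global / T1_slice-selective − 1),

with λ = 0.95 ml/g the blood–tissue partition coefficient and
T1_blood = 1900 ms, giving P in ml/min/100 g (conversion factor 3000 at
these defaults). Negative values are clamped to zero; values above
2000 ml/min/100 g are excluded as non-physiological. Parenchymal
measurements average three circular ROIs (right/middle/left lobes).

**Bulk flow.** Phase-contrast cines encode through-plane velocity in phase
(v = venc·φ/π). Per-frame vessel flow is Σ (voxel area × velocity) over
the vessel ROI; the cycle average uses periodic trapezoidal integration;
and total liver blood flow is estimated by caval subtraction,

    TLBF = (Q_supra-hepatic IVC − Q_infra-hepatic IVC) / liver weight × 100.

**Statistics.** Bland–Altman bias and 95% limits of agreement, Forkman's F
test for equality of inter-subject coefficients of variation, Welch's t
(from samples or printed mean ± SE summaries), Mann–Whitney U,
Lilliefors-corrected Kolmogorov–Smirnov normality (seeded Monte-Carlo
null), a 2 × 2 split-plot mixed ANOVA (sham/BDL × baseline/post-LPS) with
Bonferroni post hoc tests, and attrition-adjusted sample-size inflation.

## Worked example

`examples/02_perfusion_map.py` simulates a noisy FAIR acquisition of a
phantom with 316 ml/min/100 g liver perfusion and recovers it:

```
T1 (global)          :  1255.8 ms
T1 (slice-selective) :  1136.1 ms
perfusion measured   :   316.0 ml/min/100 g
perfusion true       :   316.0 ml/min/100 g
```

The ~120 ms gap between the two T1 maps *is* the perfusion signal. The
other examples cover the noiseless T1 round trip, caval-subtraction flow
(`TLBF measured: 316.2` vs truth `316.0` ml/min/100 g at 0.208 mm voxels),
respiratory gating (reconstruction RMS error `94.1` without gating vs
`1.3e-13` with re-acquired lines), agreement statistics on a 19-animal
cohort, and the full simulated study:

```bash
python examples/06_full_study.py      # full pipeline, prints the report
hepaflow run-all --seed 2 --outdir study_out   # same via the CLI
```

A study report lists baseline group comparisons (e.g. liver T1
`1233.7 ± 15.5` ms sham vs `1591.9 ± 86.4` ms BDL, Welch p = 0.013),
FAIR-vs-TLBF agreement, and the LPS-response interaction ANOVA.

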