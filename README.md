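# netgof

Network-template goodness-of-fit analysis of control-referenced PET
Z-score maps.

## The problem

In neurodegenerative disease imaging (the motivating application is
tau-PET in Alzheimer's disease), a cohort of patient uptake images is
compared against a control group to ask *where* pathology accumulates —
and in particular whether the brain-wide pattern respects the intrinsic
connectivity networks (ICNs) defined from resting-state fMRI.  `netgof`
implements that analysis as a reusable, tested pipeline for researchers
working with co-registered volumes in a common template space:

1. **SUVR**: each uptake volume is intensity-normalized to the mean of a
   reference-region mask (e.g. gray-matter-masked cerebellum), then
   smoothed with a Gaussian filter (default FWHM 8 mm).
2. **Z-score maps**: from the control group a voxelwise mean image μ(v)
   and sample-SD image σ(v) are built; each patient's map is
   Z(v) = (x(v) − μ(v)) / σ(v).
3. **Network scores**: against an integer-labelled ICN atlas (7 networks
   or 17 subnetworks), each subject gets per-network
   - *mean Z*  — the unweighted mean of Z over the template's voxels
     (extent of pathology), and
   - *GOF*  —  mean Z inside the template minus the mean Z of cortical
     voxels outside it (spatial preference).  A spatially uniform map has
     GOF = 0 for every network.
4. **Group inference**: one-sample t-tests (test value 0) per network and
   metric, Bonferroni-corrected for the number of networks
   (α = 0.05/7 ≈ 0.007 or 0.05/17 ≈ 0.003), plus the network ranking by
   group-mean Z.
5. **Cross-cohort correlation**: Pearson r between two cohorts' mean
   Z-maps across all cortical voxels (the reported p assumes voxel
   independence and is flagged as anti-conservative).

A synthetic-cohort generator (`netgof.simulate`) emulates the full study
design — blob-like parcellations, a disjoint reference region, and
control/patient cohorts with network-structured elevation in control-SD
units — so every stage is testable end to end without any image
downloads.

## Worked example

Simulate a cohort at the study's sample sizes (17 controls, 27 patients)
with the canonical 7-network severity profile, fit the model, and print
the group table:

```python
import netgof as ng

spec = ng.SyntheticCohortSpec(seed=0)           # 32x32x32, 2 mm voxels
zmaps, ref, atlas, _ = ng.simulate_zmaps(spec)  # SUVR -> control ref -> Z
res = ng.NetworkCorrespondenceModel(zmaps, atlas).fit(alpha_fw=0.05)
print(res.summary())
```

```
Network correspondence, 7-network level, n = 27 subjects
One-sample t-test, test value = 0; Bonferroni-corrected alpha = 0.007

metric   network       Mean       SD        t  p(2-tail)  sig
gof      DAN          0.966    1.087    4.618      0.000    *
...
mean_z   DAN          3.846    4.415    4.527      0.000    *
mean_z   VIS          3.772    4.345    4.511      0.000    *
...
mean_z   SMN          1.181    1.695    3.620      0.001    *

Ranking by mean Z: DAN > VIS > DMN > LIM > FPN > VAN > SMN
```

The per-network group means recover the injected effect profile
(3.2, 3.1, 2.9, 2.7, 2.2, 2.1, 0.9 control-SD units for
DAN, VIS, DMN, LIM, FPN, VAN, SMN) within sampling error, and the
severity ranking is reproduced exactly.  A milder replication cohort
(severity scale 0.3, n = 19 controls / 16 patients) shows no network
surviving the corrected threshold, yet its mean Z-map still correlates
strongly with the severe cohort's across cortex:

```python
out = ng.two_cohort_experiment(
    spec, ng.SyntheticCohortSpec(n_controls=19, n_patients=16,
                                 severity=0.3, seed=1000))
print(f"r = {out.cross.r:.3f} over {out.cross.n_voxels} cortical voxels")
# r = 0.909 over 7208 cortical voxels
print(out.results_b.significant_networks("mean_z"))
# []
```

## Command line

Every stage is also a `netgof` subcommand over files:
`simulate`, `preprocess`, `zmap`, `network-scores`, `group-stats`,
`correlate`, and `run --config config.yaml` for the whole pipeline
(scores + summary TSVs, mean Z-map NIfTIs, and a JSON run report with a
config hash for provenance; reruns produce byte-identical tables).

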