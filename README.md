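# tractwise

Node-wise tractometry statistics for developmental brain-behavior
studies: partial-correlation mapping of behavioral scores onto
white-matter tract FA profiles, with max-cluster-size permutation
family-wise error (FWE) correction, partially overlapping samples
t-tests for cohorts that share subjects, and a synthetic cohort
generator for validating the whole procedure.

## Who this is for

Researchers running AFQ-style along-tract analyses ("tract profiles"):
fractional anisotropy (FA) sampled at N equidistant nodes along a
white-matter tract, correlated node-by-node with a behavioral measure
while controlling covariates. The package implements the full
statistical chain downstream of tractography — it consumes long-format
node tables (subjectID, tractID, nodeID, FA), not raw diffusion data.

## The statistics

**Node-wise partial correlation.** For tract *t* and node *j*, the
association between a score *y* and FA is the Pearson correlation of
the residuals of *y* and FA(t, j) after regressing both on covariates
*Z* (e.g. the complementary language score, age, nonverbal IQ):
r_j = corr(resid(y|Z), resid(FA_j|Z)), tested with
t = r√((n−2−k)/(1−r²)) on n−2−k df, two-tailed. Subjects with any
missing value are dropped once (listwise), so every node uses the same
sample.

**Cluster-size FWE correction.** Nodes with p < α (default 0.05,
two-tailed) and consistent correlation sign are merged into clusters.
Under the null, the score is permuted across subjects (one shuffle per
permutation, shared by every tract in the comparison family), the maps
recomputed, and the maximum cluster size anywhere in the family
recorded. The critical size is the smallest observed null maximum whose
exceedance proportion is ≤ α_FWE; observed clusters at least that large
are FWE-significant with no further p-value adjustment. A lenient
uncorrected rule (≥ 9 adjacent nodes at 100-node resolution, ≥ 3 at
30-node) is reported alongside for exploratory use.

**Partially overlapping samples t-tests** (Derrick et al., 2017)
compare cohort means when n_c subjects appear in both cohorts:
t = (x̄₁−x̄₂) / (s_p √(1/n₁ + 1/n₂ − 2 r n_c/(n₁n₂))) with interpolated
df ν = (n_c−1) + ((n_a+n_b+n_c−1)/(n_a+n_b+2n_c))(n_a+n_b); a
Welch-type variant handles unequal variances. Both collapse exactly to
the ordinary independent tests when n_c = 0.

**Rank-sum test** for ordinal demographics (maternal education):
mid-ranks, tie-corrected variance, 0.5 continuity correction.

**Mahalanobis-weighted profiles.** Given a bundle of streamlines,
each is resampled to N equal-arc nodes; the tract core is the per-node
mean and covariance of positions, and the profile value at a node is
the FA of all streamlines weighted by the Gaussian density of their
Mahalanobis distance from the core.

## Worked example

```python
import tractwise as tw

# a synthetic two-cohort study with an embedded dorsal-tract effect:
# partial correlation 0.35 between the phonology score and FA in
# nodes 60-80 of the left arcuate, controlling semantics, age, NVIQ
controls = ("wordclasses_raw", "age", "nviq")
eff = tw.EffectSpec("Left Arcuate", "elision_raw", (60, 80), 0.35,
                    controls=controls, cohorts=("old",))
spec = tw.CohortSpec(tracts=("Left Arcuate", "Left SLF"), effects=(eff,))
dataset, subjects = tw.generate_cohort(spec, seed=1000)

old = subjects[subjects.cohort == "old"]
comparison = tw.ComparisonSpec("dorsal_elision", "old",
                               ("Left Arcuate", "Left SLF"),
                               "elision_raw", controls)
res = tw.run_comparison(dataset, old, comparison,
                        tw.PermutationConfig(n_perm=500, seed=2000))
print("critical cluster size:", res.critical_size)
for d in res.decisions:
    c = d.cluster
    print(f"{c.tract} nodes {c.node_start}-{c.node_end} "
          f"(size {c.size}, {c.sign}, mean r={c.mean_r:.2f}) "
          f"FWE={'yes' if d.fwe_significant else 'no'}")
```

prints

```
critical cluster size: 15
Left Arcuate nodes 60-80 (size 21, positive, mean r=0.29) FWE=yes
```

i.e. the permutation null says only clusters of ≥ 15 adjacent nodes are
family-wise significant at α = 0.05, and the embedded 21-node effect is
recovered exactly where it was planted.

The same analysis is available from the shell:

```bash
tractwise simulate cohort.yaml --seed 1 --out cohort/
tractwise analyze study.yaml --seed 1 --n-perm 1000 --out study_out/
tractwise report study_out/
```

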