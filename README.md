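# plp — point–line–plane analysis of brain FDG-PET

`plp` implements a three-level analysis of resting-state
¹⁸F-fluorodeoxyglucose PET in a two-group (patient vs. control) design,
as used to characterise glucose-metabolic remapping in cerebral small
vessel disease (CSVD):

* **point** — regional metabolism: globally normalized SUVmean per atlas
  region, compared between groups with pooled two-sample *t* tests,
  Cohen's *D* effect sizes, and Benjamini–Hochberg FDR within each
  network's family of regions; optionally voxelwise within network
  masks, with connected-component cluster reporting (size, MNI centroid,
  peak *t*);
* **line** — metabolic connectivity: the edge between two ROIs is the
  Pearson correlation of their SUVmean across the subjects of a group
  (an inter-subject covariance network — no per-subject connectome
  exists).  Edges are compared between groups with a subject re-split
  permutation test on Δr = r₁ − r₂ (default B = 10000), FDR per network;
* **plane** — whole-network metabolism: SUVmean over each of the seven
  canonical resting-state networks (visual, somatomotor, dorsal
  attention, ventral attention, limbic, frontoparietal, default),
  with inter-network correlations and network-vs-member-region
  correlations over the pooled cohort.

It is aimed at neuroimaging researchers who have MNI-space PET volumes
(or pre-extracted subject×region SUV tables) plus an integer atlas
parcellation with a region→network assignment.  Because subject-level
data from the motivating study are not public, the package ships a
synthetic cohort generator that reproduces the study's statistical
structure (group sizes 174/206, published regional means/SDs, a
within-network inter-subject correlation, injected point and edge
effects, published covariate prevalences), so every stage is testable
end-to-end.

## Core quantities

For subject *s* with volume *V_s* and whole-brain mask *M*, the
normalized image is *V_s / mean(V_s[M])*; region SUVmean is the voxel
average over the region, and network SUVmean the voxel-count-weighted
average of member regions (equal to the mean over the network mask).
Group comparison of a region uses the pooled-variance *t* and

    D = (m₁ − m₂) / s_p,   s_p² = ((n₁−1)s₁² + (n₂−1)s₂²) / (n₁+n₂−2).

An edge's permutation p is (#{|Δr*| ≥ |Δr|} + 1)/(B + 1) over B random
re-splits of the pooled subjects into the original group sizes.
Correlation p-values use the exact transform
t = r·√((n−2)/(1−r²)) on n−2 df.

## Worked example

```python
from plp import make_fixture_atlas, simulate_cohort, region_comparison, cohens_d
from plp.cohort import default_design

atlas = make_fixture_atlas(seed=7)           # 14 regions, 7 networks
cohort = simulate_cohort(default_design(atlas, seed=21))
table = region_comparison(cohort, atlas)
print(table.loc[table.label == "SM_1", ["mean1", "mean2", "p", "q", "cohens_d"]])
```

prints (the injected +0.048 SUV somatomotor effect, recovered):

```
      mean1    mean2         p        q  cohens_d
4  0.858307  0.81962  0.000005  0.00001  0.476445
```

and the published worked example reproduces from its printed summaries:

```python
>>> round(cohens_d(0.862, 0.079, 174, 0.814, 0.083, 206), 2)
0.59
```

The full analysis sequence lives under `analysis/` as numbered drivers
(`01_build_atlas.py` … `07_network_correlations.py`); run them in order
from `analysis/` and they write their tables under `results/`.  The same
pipeline is available as a CLI (`plp run --config cfg.yaml`,
`plp simulate`, `plp atlas-fixture`) for configuration-driven runs with
a provenance manifest.

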