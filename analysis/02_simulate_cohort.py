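"""Simulate the study-conditions cohort: 174 patients + 206 controls with
published regional baselines, one somatomotor point effect (+0.048 SUV in
patients), one dorsal-attention edge effect (rho 0.6 vs 0.0), and the
published covariate prevalences."""

import yaml

from _paths import ATLAS_LABELS, ATLAS_TABLE, COHORT, DESIGN, SEED

from plp.atlas import load_atlas
from plp.cohort import default_design, simulate_cohort

atlas = load_atlas(ATLAS_LABELS, ATLAS_TABLE)
design = default_design(atlas, seed=SEED)
cohort = simulate_cohort(design)

cohort.to_tsv(COHORT)
with open(DESIGN, "w") as fh:
    yaml.safe_dump(design.to_dict(), fh, sort_keys=True)

sizes = cohort.group.value_counts().to_dict()
print(f"cohort: {len(cohort.subjects)} subjects {sizes}")
print(f"point effects: {design.point_effects}")
print(f"edge effects:  {design.edge_effects}")
print(f"wrote {COHORT}")
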