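"""Shared locations for the analysis drivers (all relative to repo root)."""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
ATLAS_LABELS = RESULTS / "atlas" / "atlas_labels.nii.gz"
ATLAS_TABLE = RESULTS / "atlas" / "atlas_regions.tsv"
COHORT = RESULTS / "cohort.tsv"
DESIGN = RESULTS / "design.yaml"

SEED = 21
PERMUTATIONS = 2000


def load_atlas_and_cohort():
    from plp.atlas import load_atlas
    from plp.cohort import CohortTable

    atlas = load_atlas(ATLAS_LABELS, ATLAS_TABLE)
    cohort = CohortTable.from_tsv(COHORT, region_columns=atlas.abbreviations)
    return atlas, cohort
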