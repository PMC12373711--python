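"""Build the fixture parcellation: 14 regions (2 per canonical network)
on a 24^3 grid with an MNI-like 2 mm affine, written as NIfTI + TSV."""

from _paths import ATLAS_LABELS, ATLAS_TABLE

from plp.atlas import make_fixture_atlas, save_atlas

atlas = make_fixture_atlas(grid_shape=(24, 24, 24), regions_per_network=2, seed=7)
ATLAS_LABELS.parent.mkdir(parents=True, exist_ok=True)
save_atlas(atlas, ATLAS_LABELS, ATLAS_TABLE)

print(f"atlas: {len(atlas.regions)} regions over {sum(atlas.voxel_counts.values())} voxels")
for net in dict.fromkeys(r.network for r in atlas.regions):
    members = atlas.regions_in_network(net)
    voxels = sum(atlas.voxel_counts[r.id] for r in members)
    print(f"  {net:<18} {len(members)} regions, {voxels} voxels")
print(f"wrote {ATLAS_LABELS} and {ATLAS_TABLE}")
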