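"""Line level: inter-subject metabolic connectivity.  Within each network,
every region pair's Pearson correlation is compared between groups by a
subject re-split permutation test (B permutations, FDR per network); the
21 network-level edges are tested the same way."""

from _paths import PERMUTATIONS, RESULTS, SEED, load_atlas_and_cohort

from plp.connectivity import derive_seed, internetwork_connectivity, intranetwork_edge_tests
from plp.suv import network_table

atlas, cohort = load_atlas_and_cohort()
g1, g2 = cohort.group_labels

edge_tables = intranetwork_edge_tests(cohort, atlas, B=PERMUTATIONS, seed=SEED)
for net, table in edge_tables.items():
    table.to_csv(RESULTS / f"edges_{net}.tsv", sep="\t", index=False, float_format="%.6f")
    sig = table[table.q < 0.05]
    flag = "  <-- significant edge(s)" if len(sig) else ""
    print(f"{net:<18} {len(table)} edge(s), min q = {table.q.min():.4f}{flag}")
    for row in sig.itertuples(index=False):
        print(f"    {row.node_i} -- {row.node_j}: r({g1})={row.r1:.3f} r({g2})={row.r2:.3f} q={row.q:.4f}")

nets = network_table(cohort, atlas)
inter = internetwork_connectivity(
    nets.group_values(g1), nets.group_values(g2),
    B=PERMUTATIONS, seed=derive_seed(SEED, "internetwork"),
)
inter.to_csv(RESULTS / "edges_internetwork.tsv", sep="\t", index=False, float_format="%.6f")
print(f"\ninter-network: {len(inter)} edges, min q = {inter.q.min():.3f} "
      f"({'no' if (inter.q >= 0.05).all() else 'some'} significant change, "
      f"matching the expected negative finding)")
print(f"wrote edge tables under {RESULTS}")
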