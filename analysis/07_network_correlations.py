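"""Plane level: correlation structure of whole-network SUVmean — all 21
inter-network correlations over the pooled cohort, and each network's
SUVmean against its member regions (raw p, part-whole coupling left in)."""

import numpy as np
import pandas as pd

from _paths import RESULTS, load_atlas_and_cohort

from plp.atlas import NETWORKS
from plp.correlations import internetwork_corr, intranetwork_region_corr
from plp.suv import network_table

atlas, cohort = load_atlas_and_cohort()
nets = network_table(cohort, atlas)

icorr = internetwork_corr(nets, pooling="pooled")
icorr.to_csv(RESULTS / "internetwork_corr.tsv", sep="\t", index=False, float_format="%.6f")
rmat = np.eye(7)
for row in icorr.itertuples(index=False):
    a, b = NETWORKS.index(row.network_a), NETWORKS.index(row.network_b)
    rmat[a, b] = rmat[b, a] = row.r
pd.DataFrame(rmat, index=NETWORKS, columns=NETWORKS).to_csv(
    RESULTS / "internetwork_corr_matrix.tsv", sep="\t", float_format="%.6f"
)
print(f"inter-network correlations: r in [{icorr.r.min():.3f}, {icorr.r.max():.3f}], "
      f"max p = {icorr.p.max():.2e} ({(icorr.p < 0.001).sum()}/21 at p<0.001)")

rcorr = intranetwork_region_corr(cohort, nets, atlas)
rcorr.to_csv(RESULTS / "network_region_corr.tsv", sep="\t", index=False, float_format="%.6f")
sig = rcorr[rcorr.significant]
print(f"network-vs-member-region correlations: {len(rcorr)} pairs, "
      f"{len(sig)} at p<0.05, median r = {rcorr.r.median():.3f}")
print(f"wrote correlation tables under {RESULTS}")
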