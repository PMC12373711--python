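"""Network-level correlation structure ("plane" level).

Pearson correlations among whole-network SUVmeans, and between each
network's SUVmean and its member regions, over the pooled cohort by
default.  p-values come from the exact t transform
t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom, two-tailed.
No multiple-testing correction is applied by default (FDR on request).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from plp.atlas import NETWORKS, UNASSIGNED, AtlasDefinition
from plp.stats import fdr_bh

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two labelled variables."""

    label_x: str
    label_y: str
    r: float
    n: int
    p: float


def corr_with_p(x, y, label_x: str = "x", label_y: str = "y") -> CorrelationResult:
    """Pearson r with its exact two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(label_x, label_y, float(res.statistic), n, float(res.pvalue))


def p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r at sample size n (t transform)."""
    if not -1 < r < 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def internetwork_corr(networks, pooling: str = "pooled") -> pd.DataFrame:
    """All 21 pairwise correlations among the 7 network SUVmeans.

    ``pooling='pooled'`` (default) correlates over all subjects;
    ``'per-group'`` returns one block of 21 rows per group.
    """
    if pooling not in ("pooled", "per-group"):
        raise ValueError(f"pooling must be pooled|per-group, got {pooling!r}")
    frames = []
    if pooling == "pooled":
        frames.append(("pooled", networks.network_suv))
    else:
        for g in dict.fromkeys(networks.groups):
            frames.append((g, networks.group_values(g)))
    rows = []
    for tag, df in frames:
        for a, b in itertools.combinations(NETWORKS, 2):
            res = corr_with_p(df[a], df[b], a, b)
            rows.append(
                {"group": tag, "network_a": a, "network_b": b, "r": res.r, "n": res.n, "p": res.p}
            )
    return pd.DataFrame(rows)


def intranetwork_region_corr(
    cohort,
    networks,
    atlas: AtlasDefinition,
    leave_one_out: bool = False,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Correlate each network's SUVmean with each member region's SUVmean.

    By default the region is left in the network mean (part-whole
    coupling included, as reported); ``leave_one_out=True`` removes the
    region's voxel-weighted contribution before correlating.
    """
    rows = []
    for net in NETWORKS:
        members = atlas.regions_in_network(net)
        if not members:
            continue
        net_vals = networks.network_suv[net].to_numpy()
        weights = np.array([atlas.voxel_counts.get(r.id, 0) for r in members], dtype=float)
        total_w = weights.sum()
        for r, w in zip(members, weights):
            if r.network == UNASSIGNED:
                logger.warning("region %s unassigned; skipped", r.abbreviation)
                continue
            x = cohort.suv[r.abbreviation].to_numpy()
            y = net_vals
            if leave_one_out:
                if total_w - w <= 0:
                    logger.warning(
                        "network %s has a single region; leave-one-out undefined for %s",
                        net,
                        r.abbreviation,
                    )
                    continue
                y = (net_vals * total_w - x * w) / (total_w - w)
            res = corr_with_p(x, y, r.abbreviation, net)
            rows.append(
                {
                    "network": net,
                    "region": r.abbreviation,
                    "r": res.r,
                    "n": res.n,
                    "p": res.p,
                    "significant": res.p < alpha,
                }
            )
    table = pd.DataFrame(rows)
    if fdr and not table.empty:
        table["q"] = fdr_bh(table["p"])
        table["significant"] = table["q"] < alpha
    return table
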