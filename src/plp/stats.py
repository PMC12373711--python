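"""Region-wise and voxel-wise two-group inference ("point" level).

Two-sample t tests (pooled by default), Cohen's D on the pooled SD,
chi-square tests for categorical covariates, Benjamini-Hochberg FDR, and
connected-component cluster reporting of voxelwise statistical maps.

Sign convention throughout: group 1 = patients, group 2 = controls;
positive t or D means higher metabolism in patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

from plp.atlas import NETWORKS, AtlasDefinition, network_mask

logger = logging.getLogger(__name__)

#: 26-connectivity in 3D (vertices, edges, faces all connect).
_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


def two_sample_t(x, y, variant: str = "pooled") -> tuple[float, float, float]:
    """Two-sample t test; returns (t, df, two-tailed p).

    ``variant`` is ``pooled`` (Student, the default) or ``welch``.
    The statistic is mean(x) - mean(y) over its standard error, so a
    positive t means the first sample is larger.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be pooled|welch, got {variant!r}")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both samples have zero variance; t test undefined")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def cohens_d(mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int) -> float:
    """Signed standardized mean difference on the pooled SD.

    d = (mean1 - mean2) / s_p with
    s_p = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2)).
    """
    if sd1 <= 0 and sd2 <= 0:
        raise ValueError("pooled SD is zero; Cohen's D undefined")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("non-positive pooled variance")
    return (mean1 - mean2) / np.sqrt(sp2)


def chi_square_2x2(table, correction: str = "none") -> tuple[float, float]:
    """2x2 test of independent proportions; returns (statistic, p).

    ``correction``: ``none`` (Pearson, default), ``yates`` (continuity
    correction), or ``exact`` (Fisher's exact test; the statistic slot
    is then NaN since no chi-square statistic exists).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin; test undefined")
    if correction == "exact":
        res = sps.fisher_exact(t.astype(int))
        return float("nan"), float(res.pvalue)
    if correction not in ("none", "yates"):
        raise ValueError(f"correction must be none|yates|exact, got {correction!r}")
    res = sps.chi2_contingency(t, correction=(correction == "yates"))
    return float(res.statistic), float(res.pvalue)


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


# ---------------------------------------------------------------------------
# Region-level comparison


def region_comparison(
    cohort,
    atlas: AtlasDefinition,
    t_variant: str = "pooled",
    network_table_=None,
) -> pd.DataFrame:
    """Whole-network and per-region two-group comparison.

    One row per network (the network compared as a single ROI) and one
    row per member region.  FDR q-values are computed within each
    network's family of member regions; the seven whole-network rows
    form their own family.

    Returns a table with columns: scope (network), label, is_network_row,
    mean1, sd1, n1, mean2, sd2, n2, t, df, p, q, cohens_d.
    """
    from plp.suv import network_table as _network_table

    g1, g2 = cohort.group_labels
    if network_table_ is None:
        network_table_ = _network_table(cohort, atlas)
    net1 = network_table_.group_values(g1)
    net2 = network_table_.group_values(g2)

    rows = []
    for net in NETWORKS:
        members = atlas.regions_in_network(net)
        if not members:
            continue
        rows.append(_compare_one(net, f"{net} (whole network)", True, net1[net], net2[net], t_variant))
        for r in members:
            x = cohort.group_suv(g1)[r.abbreviation]
            y = cohort.group_suv(g2)[r.abbreviation]
            if x.isna().any() or y.isna().any():
                logger.warning("region %s has missing values; excluded", r.abbreviation)
                continue
            rows.append(_compare_one(net, r.abbreviation, False, x, y, t_variant))

    table = pd.DataFrame(rows)
    table["q"] = np.nan
    net_rows = table.is_network_row
    table.loc[net_rows, "q"] = fdr_bh(table.loc[net_rows, "p"])
    for net in NETWORKS:
        fam = (~table.is_network_row) & (table.scope == net)
        if fam.any():
            table.loc[fam, "q"] = fdr_bh(table.loc[fam, "p"])
    return table


def _compare_one(scope, label, is_network_row, x, y, t_variant) -> dict:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, df, p = two_sample_t(x, y, variant=t_variant)
    m1, s1 = x.mean(), x.std(ddof=1)
    m2, s2 = y.mean(), y.std(ddof=1)
    return {
        "scope": scope,
        "label": label,
        "is_network_row": is_network_row,
        "mean1": m1,
        "sd1": s1,
        "n1": len(x),
        "mean2": m2,
        "sd2": s2,
        "n2": len(y),
        "t": t,
        "df": df,
        "p": p,
        "cohens_d": cohens_d(m1, s1, len(x), m2, s2, len(y)),
    }


# ---------------------------------------------------------------------------
# Voxel-level comparison


@dataclass
class StatMap:
    """Voxelwise t map restricted to an analysis mask."""

    t: np.ndarray
    mask: np.ndarray
    df: float

    def pvalues(self) -> np.ndarray:
        """Two-tailed p per masked voxel (NaN outside the mask)."""
        p = np.full(self.t.shape, np.nan)
        tm = self.t[self.mask]
        p[self.mask] = 2.0 * sps.t.sf(np.abs(tm), self.df)
        return p

    def significance_masks(self, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """FDR over masked voxels; returns (positive, negative) masks at
        q < alpha, split by the sign of t."""
        p = self.pvalues()
        q = np.full(self.t.shape, np.nan)
        q[self.mask] = fdr_bh(p[self.mask])
        sig = self.mask & (q < alpha)
        return sig & (self.t > 0), sig & (self.t < 0)


def voxelwise_comparison(volumes, group_labels, mask) -> StatMap:
    """Pooled-variance t test per voxel within a mask.

    ``volumes`` is an array (subjects, x, y, z) or a sequence of 3D
    grids; ``group_labels`` assigns each subject to one of two groups
    (first label encountered = group 1 = patients).
    """
    V = np.asarray(volumes, dtype=float)
    labels = np.asarray(group_labels)
    mask = np.asarray(mask, dtype=bool)
    if V.ndim != 4:
        raise ValueError(f"expected (subjects, x, y, z), got shape {V.shape}")
    if V.shape[1:] != mask.shape:
        raise ValueError("volume grid does not match mask grid")
    if not mask.any():
        raise ValueError("analysis mask is empty")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    i1 = labels == uniq[0]
    i2 = labels == uniq[1]
    n1, n2 = int(i1.sum()), int(i2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")

    X = V[i1][:, mask]
    Y = V[i2][:, mask]
    m1, m2 = X.mean(axis=0), Y.mean(axis=0)
    v1, v2 = X.var(axis=0, ddof=1), Y.var(axis=0, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = np.zeros(mask.shape)
    t[mask] = tvals
    return StatMap(t=t, mask=mask, df=float(df))


@dataclass(frozen=True)
class ClusterRecord:
    """One suprathreshold connected component of a statistical map."""

    size: int
    centroid_mm: tuple[float, float, float]
    peak_t: float


def extract_clusters(statmap: StatMap, significance_mask: np.ndarray, affine: np.ndarray) -> list[ClusterRecord]:
    """Connected components (26-connectivity) of a significance mask.

    Positive-t and negative-t voxels are clustered separately.  The
    centroid is the unweighted mean of member voxel centers mapped
    through the affine to mm; peak t is the signed extreme value.
    Sorted by size, largest first.
    """
    sig = np.asarray(significance_mask, dtype=bool)
    if sig.shape != statmap.t.shape:
        raise ValueError("significance mask grid does not match the stat map")
    if (sig & ~statmap.mask).any():
        raise ValueError("significance mask extends outside the analysis mask")
    records: list[ClusterRecord] = []
    for sign_mask, take_peak in (
        (sig & (statmap.t > 0), np.max),
        (sig & (statmap.t < 0), np.min),
    ):
        labeled, n = ndimage.label(sign_mask, structure=_CONNECTIVITY_26)
        for c in range(1, n + 1):
            idx = np.argwhere(labeled == c)
            centroid_vox = idx.mean(axis=0)
            centroid_mm = (np.asarray(affine) @ np.append(centroid_vox, 1.0))[:3]
            peak = float(take_peak(statmap.t[labeled == c]))
            records.append(
                ClusterRecord(
                    size=int(len(idx)),
                    centroid_mm=tuple(float(v) for v in centroid_mm),
                    peak_t=peak,
                )
            )
    return sorted(records, key=lambda r: r.size, reverse=True)


def clusters_to_frame(records: list[ClusterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_size": [r.size for r in records],
            "x": [r.centroid_mm[0] for r in records],
            "y": [r.centroid_mm[1] for r in records],
            "z": [r.centroid_mm[2] for r in records],
            "t": [r.peak_t for r in records],
        }
    )
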