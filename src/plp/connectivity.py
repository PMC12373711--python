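"""Inter-subject metabolic connectivity ("line" level).

An edge between two ROIs is the Pearson correlation of their SUVmean
values across the subjects of a group — an inter-subject covariance
network, so connectivity exists only at the group level and group
comparison must permute subjects.  The group difference per edge is the
raw correlation difference delta = r1 - r2, tested by re-splitting the
pooled subjects into the original group sizes B times; the two-tailed
permutation p is (#{|delta*| >= |delta_obs|} + 1) / (B + 1), followed by
Benjamini-Hochberg FDR across the edges of the analysis family.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from plp.atlas import NETWORKS
from plp.stats import fdr_bh


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix over ROIs or networks."""

    nodes: list[str]
    r: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        k = len(self.nodes)
        if self.r.shape != (k, k):
            raise ValueError(f"matrix shape {self.r.shape} != ({k}, {k})")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("correlation entries outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.nodes, columns=self.nodes)


@dataclass
class EdgeStats:
    """Permutation comparison of one edge between two groups."""

    node_i: str
    node_j: str
    r1: float
    r2: float
    delta: float
    p: float
    q: float
    n_permutations: int


def _as_matrix(suv) -> tuple[np.ndarray, list[str]]:
    if isinstance(suv, pd.DataFrame):
        return suv.to_numpy(dtype=float), [str(c) for c in suv.columns]
    arr = np.asarray(suv, dtype=float)
    return arr, [f"node_{i}" for i in range(arr.shape[1])]


def _check_columns(X: np.ndarray, nodes: list[str]) -> None:
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects to correlate across subjects")
    sd = X.std(axis=0, ddof=1)
    bad = [nodes[i] for i in np.flatnonzero(sd == 0)]
    if bad:
        raise ValueError(f"zero-variance node(s): {bad}")


def connectivity_matrix(suv) -> ConnectivityMatrix:
    """Pairwise Pearson correlation across subjects (rows) between all
    node columns of a subjects x nodes matrix."""
    X, nodes = _as_matrix(suv)
    _check_columns(X, nodes)
    r = np.corrcoef(X, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(nodes=nodes, r=r, n_subjects=X.shape[0])


def _corr(X: np.ndarray) -> np.ndarray:
    """Correlation matrix of columns; assumes positive column variance."""
    Z = X - X.mean(axis=0)
    Z /= np.sqrt((Z**2).sum(axis=0))
    return Z.T @ Z


def derive_seed(master_seed: int, name: str) -> np.random.SeedSequence:
    """Stable per-analysis RNG stream: hashing the analysis name into the
    entropy keeps each family's permutations independent of the others."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])


def edge_permutation_test(
    suv1,
    suv2,
    B: int = 10000,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Permutation comparison of all edges between two groups.

    Returns a DataFrame with one row per node pair (upper triangle):
    node_i, node_j, r1, r2, delta, p, q, n_permutations.
    """
    X1, nodes1 = _as_matrix(suv1)
    X2, nodes2 = _as_matrix(suv2)
    if nodes1 != nodes2:
        raise ValueError(f"node sets differ: {nodes1} vs {nodes2}")
    if B < 1:
        raise ValueError("B must be >= 1")
    n1, n2 = X1.shape[0], X2.shape[0]
    if n1 < 3 or n2 < 3:
        raise ValueError("need at least 3 subjects per group")
    _check_columns(X1, nodes1)
    _check_columns(X2, nodes2)

    k = len(nodes1)
    iu, ju = np.triu_indices(k, 1)
    r1 = _corr(X1)
    r2 = _corr(X2)
    delta_obs = (r1 - r2)[iu, ju]

    pooled = np.vstack([X1, X2])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(delta_obs.shape, dtype=np.int64)
    abs_obs = np.abs(delta_obs)
    for _ in range(B):
        perm = rng.permutation(n1 + n2)
        d = _corr(pooled[perm[:n1]]) - _corr(pooled[perm[n1:]])
        exceed += np.abs(d[iu, ju]) >= abs_obs - 1e-12
    p = (exceed + 1.0) / (B + 1.0)
    q = fdr_bh(p)

    return pd.DataFrame(
        {
            "node_i": [nodes1[a] for a in iu],
            "node_j": [nodes1[b] for b in ju],
            "r1": r1[iu, ju],
            "r2": r2[iu, ju],
            "delta": delta_obs,
            "p": p,
            "q": q,
            "n_permutations": B,
        }
    )


def internetwork_connectivity(networks1, networks2, B: int = 10000, seed=0) -> pd.DataFrame:
    """Edge permutation test over the 21 pairs of the 7 networks.

    Inputs are the per-group network tables (subjects x 7), either
    :class:`plp.suv.NetworkTable` or plain DataFrames with the canonical
    network columns.
    """
    df1 = networks1.network_suv if hasattr(networks1, "network_suv") else networks1
    df2 = networks2.network_suv if hasattr(networks2, "network_suv") else networks2
    for df in (df1, df2):
        if list(df.columns) != list(NETWORKS):
            raise ValueError(f"expected canonical network columns {list(NETWORKS)}")
    return edge_permutation_test(df1, df2, B=B, seed=seed)


def intranetwork_edge_tests(
    cohort,
    atlas,
    B: int = 10000,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Run the edge permutation test within each network's region set.

    Each network is its own FDR family and draws permutations from its
    own seed stream (derived from the master seed and the network name),
    so adding a network never changes another network's p-values.
    """
    g1, g2 = cohort.group_labels
    out = {}
    for net in NETWORKS:
        abbrs = [r.abbreviation for r in atlas.regions_in_network(net)]
        if len(abbrs) < 2:
            continue
        out[net] = edge_permutation_test(
            cohort.group_suv(g1)[abbrs],
            cohort.group_suv(g2)[abbrs],
            B=B,
            seed=derive_seed(seed, net),
        )
    return out
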