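"""Synthetic FDG-PET cohorts with a controlled statistical structure.

The generator draws each group's subjects-by-regions SUVmean matrix from
a multivariate normal whose correlation matrix is block-structured by
network: a common within-network inter-subject correlation, an optional
weaker correlation shared across all networks (a global latent factor,
mimicking residual coupling that global normalization leaves behind),
explicit per-edge overrides, and additive group mean shifts on chosen
regions.  Covariates (binary prevalences, continuous mean/SD) are drawn
independently of SUV.

This emulates the estimands of the analysis — group mean differences,
inter-subject covariance edges, network-level correlations — not scanner
physics: there is no attenuation, partial-volume effect, or spatial
autocorrelation beyond optional rendering-time smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plp.atlas import NETWORKS, UNASSIGNED, AtlasDefinition
from plp.suv import smooth_volume
from plp import reference

logger = logging.getLogger(__name__)

_MIN_SUV = 0.01
_MAX_RESAMPLE_ROUNDS = 100


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: ``binary`` with per-group prevalence in [0, 1], or
    ``continuous`` with per-group (mean, sd)."""

    name: str
    kind: str  # "binary" | "continuous"
    group1: float | tuple[float, float]
    group2: float | tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"covariate kind must be binary|continuous, got {self.kind!r}")
        if self.kind == "binary":
            for p in (self.group1, self.group2):
                if not 0 <= float(p) <= 1:
                    raise ValueError(f"prevalence for {self.name} outside [0,1]: {p}")
        else:
            for m, s in (self.group1, self.group2):
                if s <= 0:
                    raise ValueError(f"covariate {self.name}: sd must be > 0, got {s}")


@dataclass
class CohortDesign:
    """Full specification of a synthetic two-group cohort.

    Parameters
    ----------
    regions
        Region abbreviations, in column order.
    region_network
        Abbreviation -> network label (``unassigned`` allowed).
    baseline_means, baseline_sds
        Abbreviation -> SUV mean / SD shared by both groups before
        effects are applied.
    network_correlation
        Within-network inter-subject correlation; scalar or per-network
        dict.  Default 0.3.
    global_correlation
        Inter-subject correlation between regions of different networks
        (global latent factor).  Default 0.
    point_effects
        (abbreviation, group_label, additive mean shift).
    edge_effects
        (abbr_i, abbr_j, group_label, target correlation), overriding the
        block structure for that pair in that group.
    covariate_specs
        Covariates to draw, independent of SUV.
    """

    regions: list[str]
    region_network: dict[str, str]
    baseline_means: dict[str, float]
    baseline_sds: dict[str, float]
    n_per_group: tuple[int, int] = (174, 206)
    group_labels: tuple[str, str] = ("CSVD", "HC")
    network_correlation: float | dict[str, float] = 0.3
    global_correlation: float = 0.0
    point_effects: list[tuple[str, str, float]] = field(default_factory=list)
    edge_effects: list[tuple[str, str, str, float]] = field(default_factory=list)
    covariate_specs: list[CovariateSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.regions) != len(set(self.regions)):
            raise ValueError("duplicate region abbreviations in design")
        for r in self.regions:
            if r not in self.region_network:
                raise ValueError(f"region {r!r} has no network assignment")
            sd = self.baseline_sds.get(r)
            if sd is None or sd <= 0:
                raise ValueError(f"region {r!r}: baseline SD must be > 0, got {sd}")
            if r not in self.baseline_means:
                raise ValueError(f"region {r!r} has no baseline mean")
        for rho in self._rho_by_network().values():
            if not -1 < rho < 1:
                raise ValueError(f"network correlation outside (-1, 1): {rho}")
        if not -1 < self.global_correlation < 1:
            raise ValueError(f"global correlation outside (-1, 1): {self.global_correlation}")
        for i, j, g, rho in self.edge_effects:
            if not -1 < rho < 1:
                raise ValueError(f"edge correlation outside (-1, 1): {rho}")
            if g not in self.group_labels:
                raise ValueError(f"edge effect group {g!r} not in {self.group_labels}")
            for r in (i, j):
                if r not in self.regions:
                    raise ValueError(f"edge effect names unknown region {r!r}")
        for r, g, _ in self.point_effects:
            if r not in self.regions:
                raise ValueError(f"point effect names unknown region {r!r}")
            if g not in self.group_labels:
                raise ValueError(f"point effect group {g!r} not in {self.group_labels}")
        for n in self.n_per_group:
            if n < 2:
                raise ValueError("each group needs at least 2 subjects")

    def _rho_by_network(self) -> dict[str, float]:
        nets = set(self.region_network.values())
        if isinstance(self.network_correlation, dict):
            return {n: float(self.network_correlation.get(n, 0.0)) for n in nets}
        return {n: float(self.network_correlation) for n in nets}

    # -- covariance assembly ------------------------------------------

    def correlation_matrix(self, group_label: str) -> np.ndarray:
        """Target inter-subject correlation matrix for one group."""
        k = len(self.regions)
        idx = {r: i for i, r in enumerate(self.regions)}
        rho_net = self._rho_by_network()
        R = np.full((k, k), self.global_correlation)
        for a in range(k):
            for b in range(a + 1, k):
                na = self.region_network[self.regions[a]]
                nb = self.region_network[self.regions[b]]
                if na == nb and na != UNASSIGNED:
                    R[a, b] = R[b, a] = rho_net[na]
                elif na == UNASSIGNED or nb == UNASSIGNED:
                    R[a, b] = R[b, a] = 0.0
        for i, j, g, rho in self.edge_effects:
            if g == group_label:
                R[idx[i], idx[j]] = R[idx[j], idx[i]] = rho
        np.fill_diagonal(R, 1.0)
        return R

    def covariance_matrix(self, group_label: str) -> np.ndarray:
        sds = np.array([self.baseline_sds[r] for r in self.regions])
        R = self.correlation_matrix(group_label)
        C = R * np.outer(sds, sds)
        return _ensure_positive_definite(C)

    def mean_vector(self, group_label: str) -> np.ndarray:
        mu = np.array([self.baseline_means[r] for r in self.regions], dtype=float)
        idx = {r: i for i, r in enumerate(self.regions)}
        for r, g, delta in self.point_effects:
            if g == group_label:
                mu[idx[r]] += delta
        return mu

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "region_network": dict(self.region_network),
            "baseline_means": {k: float(v) for k, v in self.baseline_means.items()},
            "baseline_sds": {k: float(v) for k, v in self.baseline_sds.items()},
            "n_per_group": list(self.n_per_group),
            "group_labels": list(self.group_labels),
            "network_correlation": self.network_correlation
            if not isinstance(self.network_correlation, dict)
            else dict(self.network_correlation),
            "global_correlation": self.global_correlation,
            "point_effects": [list(e) for e in self.point_effects],
            "edge_effects": [list(e) for e in self.edge_effects],
            "covariate_specs": [
                {
                    "name": c.name,
                    "kind": c.kind,
                    "group1": list(c.group1) if c.kind == "continuous" else c.group1,
                    "group2": list(c.group2) if c.kind == "continuous" else c.group2,
                }
                for c in self.covariate_specs
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortDesign":
        specs = [
            CovariateSpec(
                name=c["name"],
                kind=c["kind"],
                group1=tuple(c["group1"]) if c["kind"] == "continuous" else c["group1"],
                group2=tuple(c["group2"]) if c["kind"] == "continuous" else c["group2"],
            )
            for c in d.get("covariate_specs", [])
        ]
        return cls(
            regions=list(d["regions"]),
            region_network=dict(d["region_network"]),
            baseline_means=d["baseline_means"],
            baseline_sds=d["baseline_sds"],
            n_per_group=tuple(d.get("n_per_group", (174, 206))),
            group_labels=tuple(d.get("group_labels", ("CSVD", "HC"))),
            network_correlation=d.get("network_correlation", 0.3),
            global_correlation=d.get("global_correlation", 0.0),
            point_effects=[tuple(e) for e in d.get("point_effects", [])],
            edge_effects=[tuple(e) for e in d.get("edge_effects", [])],
            covariate_specs=specs,
            seed=int(d.get("seed", 0)),
        )


@dataclass
class CohortTable:
    """Subject-level cohort: group labels, covariates, and the subjects x
    regions matrix of globally normalized SUVmean."""

    subjects: list[str]
    group: pd.Series
    covariates: pd.DataFrame
    suv: pd.DataFrame

    def __post_init__(self) -> None:
        if self.suv.isna().any().any():
            raise ValueError("SUV table contains missing values")
        if (self.suv.to_numpy() <= 0).any():
            raise ValueError("SUV values must be positive")
        if list(self.suv.index) != list(self.subjects):
            raise ValueError("SUV index does not match subject list")

    @property
    def group_labels(self) -> tuple[str, str]:
        seen = list(dict.fromkeys(self.group))
        return tuple(seen)

    def group_suv(self, label: str) -> pd.DataFrame:
        return self.suv.loc[(self.group == label).values]

    def to_tsv(self, path) -> None:
        out = pd.concat(
            [self.group.rename("group"), self.covariates, self.suv], axis=1
        )
        out.index.name = "subject"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, region_columns: list[str] | None = None) -> "CohortTable":
        df = pd.read_csv(path, sep="\t", index_col="subject")
        df.index.name = None
        if region_columns is None:
            # region columns follow the covariates; everything after 'group'
            # that is not a known covariate is treated as a region only if
            # the caller gave no explicit list — require explicit list then.
            raise ValueError("region_columns must be given when reading a cohort TSV")
        covar_cols = [c for c in df.columns if c not in region_columns and c != "group"]
        return cls(
            subjects=list(df.index),
            group=df["group"],
            covariates=df[covar_cols],
            suv=df[region_columns],
        )


def _ensure_positive_definite(C: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Validate PD; repair by eigenvalue clipping if needed (with warning)."""
    C = (C + C.T) / 2.0
    w = np.linalg.eigvalsh(C)
    floor = tol * w.max()
    if w.min() > floor:
        return C
    logger.warning(
        "target covariance not positive definite (min eigenvalue %.3g); "
        "repairing by eigenvalue clipping",
        w.min(),
    )
    w_full, V = np.linalg.eigh(C)
    w_clipped = np.clip(w_full, floor, None)
    repaired = (V * w_clipped) @ V.T
    repaired = (repaired + repaired.T) / 2.0
    if np.linalg.eigvalsh(repaired).min() <= 0:
        raise ValueError("covariance repair failed; matrix remains non-positive-definite")
    return repaired


def simulate_cohort(design: CohortDesign) -> CohortTable:
    """Draw one cohort from the design; reproducible for a fixed seed."""
    rng = np.random.default_rng(design.seed)
    blocks = []
    groups = []
    subjects = []
    covar_frames = []
    for gi, (label, n) in enumerate(zip(design.group_labels, design.n_per_group)):
        mu = design.mean_vector(label)
        C = design.covariance_matrix(label)
        L = np.linalg.cholesky(C)
        X = mu + rng.standard_normal((n, len(design.regions))) @ L.T
        # SUV is positive: redraw whole subjects with any value below the
        # floor (astronomically rare at realistic parameters).
        for _ in range(_MAX_RESAMPLE_ROUNDS):
            bad = (X < _MIN_SUV).any(axis=1)
            if not bad.any():
                break
            X[bad] = mu + rng.standard_normal((int(bad.sum()), len(design.regions))) @ L.T
        else:
            raise ValueError("could not draw positive SUV values; check the design")
        blocks.append(X)
        groups.extend([label] * n)
        subjects.extend([f"{label}_{i + 1:03d}" for i in range(n)])
        cov = {}
        for spec in design.covariate_specs:
            par = spec.group1 if gi == 0 else spec.group2
            if spec.kind == "binary":
                cov[spec.name] = (rng.random(n) < float(par)).astype(int)
            else:
                m, s = par
                cov[spec.name] = rng.normal(m, s, n)
        covar_frames.append(pd.DataFrame(cov))

    suv = pd.DataFrame(np.vstack(blocks), index=subjects, columns=design.regions)
    covariates = pd.concat(covar_frames, ignore_index=True)
    covariates.index = pd.Index(subjects)
    return CohortTable(
        subjects=subjects,
        group=pd.Series(groups, index=subjects, name="group"),
        covariates=covariates,
        suv=suv,
    )


def render_volumes(
    cohort: CohortTable,
    atlas: AtlasDefinition,
    voxel_noise_sd: float = 0.0,
    fwhm_mm: float = 0.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Paint each subject's region SUVs into the atlas grid.

    Each region's voxels receive the subject's SUVmean for that region,
    plus independent Gaussian voxel noise, then isotropic Gaussian
    smoothing at the stated FWHM.  Background stays 0 (before smoothing).
    """
    if atlas.label_volume is None or atlas.affine is None:
        raise ValueError("atlas has no label volume")
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    missing = [c for c in cohort.suv.columns if c not in atlas.abbreviations]
    if missing:
        raise ValueError(f"cohort regions missing from atlas: {missing}")
    abbr_to_id = {r.abbreviation: r.id for r in atlas.regions}
    max_id = max(atlas.region_ids)
    labels = atlas.label_volume
    rng = np.random.default_rng(seed)
    out = {}
    for subject in cohort.subjects:
        lut = np.zeros(max_id + 1)
        for abbr in cohort.suv.columns:
            lut[abbr_to_id[abbr]] = cohort.suv.at[subject, abbr]
        vol = lut[labels]
        if voxel_noise_sd > 0:
            vol = vol + rng.normal(0.0, voxel_noise_sd, size=vol.shape) * (labels > 0)
        if fwhm_mm > 0:
            vol = smooth_volume(vol, fwhm_mm, atlas.affine)
        out[subject] = vol
    return out


def default_design(atlas: AtlasDefinition, seed: int = 0) -> CohortDesign:
    """Study-conditions design over a fixture atlas.

    Baselines per region are taken from the published control-group
    region summaries of the matching network (cycled in order).  The
    design carries the study's group sizes (174/206), one somatomotor
    point effect of +0.048 SUV in patients (the published trunk-region
    shift), one dorsal-attention edge whose inter-subject correlation is
    0.6 in patients versus 0.0 in controls, the published covariate
    prevalences, a within-network inter-subject correlation of 0.3, and
    a global factor of 0.2 linking all networks.
    """
    ref = reference.REGION_STATS[~reference.REGION_STATS.is_network_row]
    regions = []
    region_network = {}
    baseline_means = {}
    baseline_sds = {}
    for r in atlas.regions:
        regions.append(r.abbreviation)
        region_network[r.abbreviation] = r.network
        if r.network == UNASSIGNED:
            baseline_means[r.abbreviation] = 1.0
            baseline_sds[r.abbreviation] = 0.06
            continue
        rows = ref[ref.network == r.network].reset_index(drop=True)
        members = [x for x in atlas.regions_in_network(r.network)]
        pos = [m.abbreviation for m in members].index(r.abbreviation)
        row = rows.iloc[pos % len(rows)]
        baseline_means[r.abbreviation] = float(row.mean_hc)
        baseline_sds[r.abbreviation] = float(row.sd_hc)

    somato = [r.abbreviation for r in atlas.regions_in_network("somatomotor")]
    dorsal = [r.abbreviation for r in atlas.regions_in_network("dorsal_attention")]
    point_effects = []
    if somato:
        # the published trunk-region shift: control baseline 0.814 (0.083),
        # patients +0.048
        trunk = ref[ref.label == "Right postcentral gyrus (trunk region)"].iloc[0]
        baseline_means[somato[0]] = float(trunk.mean_hc)
        baseline_sds[somato[0]] = float(trunk.sd_hc)
        point_effects = [(somato[0], "CSVD", float(trunk.mean_csvd - trunk.mean_hc))]
    edge_effects = []
    if len(dorsal) >= 2:
        edge_effects = [
            (dorsal[0], dorsal[1], "CSVD", 0.6),
            (dorsal[0], dorsal[1], "HC", 0.0),
        ]

    n1, n2 = reference.GROUP_SIZES
    demo = reference.DEMOGRAPHICS.set_index("characteristic")
    covariate_specs = [
        CovariateSpec("age", "continuous", tuple(demo.loc["age", "csvd"]), tuple(demo.loc["age", "hc"])),
        CovariateSpec("male", "binary", demo.loc["male", "csvd"] / n1, demo.loc["male", "hc"] / n2),
        CovariateSpec("bmi", "continuous", tuple(demo.loc["bmi", "csvd"]), tuple(demo.loc["bmi", "hc"])),
        CovariateSpec("fbs", "continuous", tuple(demo.loc["fbs", "csvd"]), tuple(demo.loc["fbs", "hc"])),
        CovariateSpec("smoking", "binary", demo.loc["smoking", "csvd"] / n1, demo.loc["smoking", "hc"] / n2),
        CovariateSpec("hypertension", "binary", demo.loc["hypertension", "csvd"] / n1, demo.loc["hypertension", "hc"] / n2),
        CovariateSpec("diabetes", "binary", demo.loc["diabetes", "csvd"] / n1, demo.loc["diabetes", "hc"] / n2),
        CovariateSpec("hyperlipidemia", "binary", demo.loc["hyperlipidemia", "csvd"] / n1, demo.loc["hyperlipidemia", "hc"] / n2),
    ]

    return CohortDesign(
        regions=regions,
        region_network=region_network,
        baseline_means=baseline_means,
        baseline_sds=baseline_sds,
        n_per_group=(n1, n2),
        group_labels=reference.GROUP_LABELS,
        network_correlation=0.3,
        global_correlation=0.2,
        point_effects=point_effects,
        edge_effects=edge_effects,
        covariate_specs=covariate_specs,
        seed=seed,
    )
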