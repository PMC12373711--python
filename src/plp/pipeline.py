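"""Configuration-driven orchestration of the point-line-plane pipeline.

Stages: cohort acquisition (simulated, pre-extracted region table, or
NIfTI volumes) -> demographics -> region/network comparison ("point") ->
optional voxelwise comparison with cluster reporting -> intra- and
inter-network edge permutation tests ("line") -> network correlation
analyses ("plane").  Every run writes TSV tables plus a manifest
recording the seed, permutation count, package versions, and input
hashes, so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

import plp
from plp import reference
from plp.atlas import NETWORKS, AtlasDefinition, load_atlas, make_fixture_atlas, network_mask
from plp.cohort import CohortDesign, CohortTable, default_design, render_volumes, simulate_cohort
from plp.connectivity import derive_seed, internetwork_connectivity, intranetwork_edge_tests
from plp.correlations import internetwork_corr, intranetwork_region_corr
from plp.stats import chi_square_2x2, clusters_to_frame, extract_clusters, region_comparison, two_sample_t, voxelwise_comparison
from plp.suv import global_normalize, network_table, roi_suvmean
from plp.atlas import brain_mask

logger = logging.getLogger(__name__)

_MODES = ("simulate", "region_table", "volumes")


def format_p(p: float) -> str:
    """p to 3 dp with a '<0.001' floor, matching clinical-table style."""
    if np.isnan(p):
        return ""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def format_mean_sd(mean: float, sd: float, dp: int = 3) -> str:
    return f"{mean:.{dp}f} ({sd:.{dp}f})"


def format_count_pct(count: int, total: int) -> str:
    return f"{count} ({100.0 * count / total:.2f})"


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    mode: str
    out_dir: str
    seed: int = 0
    permutations: int = 10000
    alpha: float = 0.05
    t_variant: str = "pooled"
    fwhm_mm: float = 0.0
    voxel_noise_sd: float = 0.05
    render_voxelwise: bool = False
    atlas_volume: str | None = None
    atlas_table: str | None = None
    design_path: str | None = None
    cohort_path: str | None = None
    volume_manifest: str | None = None
    fixture_regions_per_network: int = 2
    fixture_grid: tuple[int, int, int] = (24, 24, 24)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.permutations < 1:
            raise ValueError(f"permutations must be >= 1, got {self.permutations}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.t_variant not in ("pooled", "welch"):
            raise ValueError(f"t_variant must be pooled|welch, got {self.t_variant!r}")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        if self.mode == "region_table" and not self.cohort_path:
            raise ValueError("region_table mode requires cohort_path")
        if self.mode == "volumes" and not self.volume_manifest:
            raise ValueError("volumes mode requires volume_manifest")
        if self.mode in ("region_table", "volumes") and not (self.atlas_volume and self.atlas_table):
            raise ValueError(f"{self.mode} mode requires atlas_volume and atlas_table")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "fixture_grid" in raw:
            raw["fixture_grid"] = tuple(raw["fixture_grid"])
        return cls(**raw)


def demographic_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-group demographic summary with tests, clinical-table style.

    Continuous covariates: mean (SD) per group and a pooled two-sample t
    p; binary covariates: count (%) per group and a Pearson chi-square p.
    Single-level covariates are reported without a test.
    """
    g1, g2 = cohort.group_labels
    m1 = (cohort.group == g1).to_numpy()
    m2 = (cohort.group == g2).to_numpy()
    n1, n2 = int(m1.sum()), int(m2.sum())
    rows = []
    for name in cohort.covariates.columns:
        v = cohort.covariates[name]
        x, y = v[m1], v[m2]
        is_binary = set(v.unique()) <= {0, 1}
        if is_binary:
            c1, c2 = int(x.sum()), int(y.sum())
            cell1, cell2 = format_count_pct(c1, n1), format_count_pct(c2, n2)
            table = np.array([[c1, n1 - c1], [c2, n2 - c2]])
            if v.nunique() < 2:
                logger.warning("covariate %s has a single level; no test", name)
                p, test = np.nan, ""
            else:
                _, p = chi_square_2x2(table, correction="none")
                test = "chi2"
        else:
            cell1 = format_mean_sd(x.mean(), x.std(ddof=1), dp=2)
            cell2 = format_mean_sd(y.mean(), y.std(ddof=1), dp=2)
            if v.nunique() < 2:
                logger.warning("covariate %s is constant; no test", name)
                p, test = np.nan, ""
            else:
                _, _, p = two_sample_t(x, y, variant="pooled")
                test = "t"
        rows.append(
            {
                "characteristic": name,
                f"{g1} (n={n1})": cell1,
                f"{g2} (n={n2})": cell2,
                "p": format_p(p) if test else "",
                "test": test,
            }
        )
    return pd.DataFrame(rows)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _acquire_atlas(config: PipelineConfig) -> AtlasDefinition:
    if config.atlas_volume and config.atlas_table:
        return load_atlas(config.atlas_volume, config.atlas_table)
    return make_fixture_atlas(
        grid_shape=config.fixture_grid,
        regions_per_network=config.fixture_regions_per_network,
        seed=config.seed,
    )


def _acquire_cohort(config: PipelineConfig, atlas: AtlasDefinition):
    """Returns (cohort, volumes-or-None)."""
    if config.mode == "simulate":
        if config.design_path:
            with open(config.design_path) as fh:
                design = CohortDesign.from_dict(yaml.safe_load(fh))
        else:
            design = default_design(atlas, seed=config.seed)
        cohort = simulate_cohort(design)
        volumes = None
        if config.render_voxelwise:
            volumes = render_volumes(
                cohort,
                atlas,
                voxel_noise_sd=config.voxel_noise_sd,
                fwhm_mm=config.fwhm_mm,
                seed=config.seed + 1,
            )
        return cohort, volumes
    if config.mode == "region_table":
        cohort = CohortTable.from_tsv(config.cohort_path, region_columns=atlas.abbreviations)
        return cohort, None
    # volumes mode: manifest TSV with columns subject, group, path
    manifest = pd.read_csv(config.volume_manifest, sep="\t")
    mask = brain_mask(atlas)
    suv_rows, volumes = {}, {}
    for row in manifest.itertuples(index=False):
        vol = np.asanyarray(nib.load(str(row.path)).dataobj).astype(float)
        vol = global_normalize(vol, mask)
        volumes[row.subject] = vol
        suv_rows[row.subject] = roi_suvmean(vol, atlas)
    suv = pd.DataFrame(suv_rows).T.loc[list(manifest.subject)]
    cohort = CohortTable(
        subjects=list(manifest.subject),
        group=pd.Series(list(manifest.group), index=list(manifest.subject), name="group"),
        covariates=pd.DataFrame(index=list(manifest.subject)),
        suv=suv,
    )
    return cohort, volumes


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of output paths and summaries."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        atlas = _acquire_atlas(config)
        stage = "cohort"
        cohort, volumes = _acquire_cohort(config, atlas)
        nets = network_table(cohort, atlas)
        g1, g2 = cohort.group_labels
        outputs: dict[str, object] = {}

        stage = "demographics"
        if len(cohort.covariates.columns):
            demo = demographic_table(cohort)
            demo.to_csv(out / "demographics.tsv", sep="\t", index=False)
            outputs["demographics"] = str(out / "demographics.tsv")

        stage = "region_comparison"
        comp = region_comparison(cohort, atlas, t_variant=config.t_variant, network_table_=nets)
        comp_out = comp.copy()
        for c in ("mean1", "sd1", "mean2", "sd2"):
            comp_out[c] = comp_out[c].map(lambda v: f"{v:.3f}")
        comp_out["cohens_d"] = comp_out["cohens_d"].map(lambda v: f"{v:.2f}")
        comp_out["p_fmt"] = comp_out["p"].map(format_p)
        comp_out.to_csv(out / "region_comparison.tsv", sep="\t", index=False, float_format="%.6f")
        outputs["region_comparison"] = str(out / "region_comparison.tsv")
        logger.info("region comparison: %d rows tested", len(comp))

        if volumes is not None:
            stage = "voxelwise"
            V = np.stack([volumes[s] for s in cohort.subjects])
            labels = cohort.group.to_numpy()
            cluster_frames = []
            for net in NETWORKS:
                mask = network_mask(atlas, net)
                if not mask.any():
                    continue
                statmap = voxelwise_comparison(V, labels, mask)
                pos, neg = statmap.significance_masks(alpha=config.alpha)
                recs = extract_clusters(statmap, pos | neg, atlas.affine)
                frame = clusters_to_frame(recs)
                frame.insert(0, "network", net)
                cluster_frames.append(frame)
                logger.info("voxelwise %s: %d voxels, %d clusters", net, int(mask.sum()), len(recs))
            clusters = pd.concat(cluster_frames, ignore_index=True) if cluster_frames else pd.DataFrame()
            clusters.to_csv(out / "clusters.tsv", sep="\t", index=False, float_format="%.3f")
            outputs["clusters"] = str(out / "clusters.tsv")

        stage = "connectivity"
        edge_tables = intranetwork_edge_tests(cohort, atlas, B=config.permutations, seed=config.seed)
        for net, table in edge_tables.items():
            path = out / f"edges_{net}.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.6f")
            outputs[f"edges_{net}"] = str(path)
            logger.info("edges %s: %d edges, B=%d", net, len(table), config.permutations)
        inter = internetwork_connectivity(
            nets.group_values(g1),
            nets.group_values(g2),
            B=config.permutations,
            seed=derive_seed(config.seed, "internetwork"),
        )
        inter.to_csv(out / "edges_internetwork.tsv", sep="\t", index=False, float_format="%.6f")
        outputs["edges_internetwork"] = str(out / "edges_internetwork.tsv")

        stage = "correlations"
        icorr = internetwork_corr(nets, pooling="pooled")
        icorr.to_csv(out / "internetwork_corr.tsv", sep="\t", index=False, float_format="%.6f")
        outputs["internetwork_corr"] = str(out / "internetwork_corr.tsv")
        rmat = np.eye(7)
        for row in icorr.itertuples(index=False):
            a, b = NETWORKS.index(row.network_a), NETWORKS.index(row.network_b)
            rmat[a, b] = rmat[b, a] = row.r
        pd.DataFrame(rmat, index=NETWORKS, columns=NETWORKS).to_csv(
            out / "internetwork_corr_matrix.tsv", sep="\t", float_format="%.6f"
        )
        rcorr = intranetwork_region_corr(cohort, nets, atlas, alpha=config.alpha)
        rcorr.to_csv(out / "network_region_corr.tsv", sep="\t", index=False, float_format="%.6f")
        outputs["network_region_corr"] = str(out / "network_region_corr.tsv")

        stage = "manifest"
        input_hashes = {}
        for key in ("atlas_volume", "atlas_table", "design_path", "cohort_path", "volume_manifest"):
            path = getattr(config, key)
            if path:
                input_hashes[key] = _hash_file(path)
        if config.mode == "simulate" and not config.design_path:
            design = default_design(atlas, seed=config.seed)
            blob = json.dumps(design.to_dict(), sort_keys=True).encode()
            input_hashes["default_design"] = hashlib.sha256(blob).hexdigest()
        manifest = {
            "mode": config.mode,
            "seed": config.seed,
            "permutations": config.permutations,
            "alpha": config.alpha,
            "t_variant": config.t_variant,
            "fwhm_mm": config.fwhm_mm,
            "versions": {
                "plp": plp.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "n_subjects": len(cohort.subjects),
            "group_sizes": {g1: int((cohort.group == g1).sum()), g2: int((cohort.group == g2).sum())},
            "input_hashes": input_hashes,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        outputs["manifest"] = str(out / "manifest.json")
        return outputs
    except Exception as err:
        (out / "INCOMPLETE").write_text(f"stage: {stage}\nerror: {err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
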