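"""Globally normalized SUV measurements at voxel, region, and network level.

FDG uptake is expressed as SUVmean divided by the whole-brain mean
("global normalization"), which removes inter-subject dose/weight
variability.  Regions are averaged per-voxel; networks are by default
voxel-count-weighted averages of their member regions, which equals the
mean over the network's voxel mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from plp.atlas import NETWORKS, AtlasDefinition, network_mask

logger = logging.getLogger(__name__)

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class NetworkTable:
    """Subjects x 7 networks table of SUVmean with group labels.

    ``network_suv`` columns are ordered as :data:`plp.atlas.NETWORKS`.
    """

    subjects: list[str]
    groups: pd.Series
    network_suv: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.network_suv.columns) != list(NETWORKS):
            raise ValueError(
                f"network columns must be {list(NETWORKS)} in order, "
                f"got {list(self.network_suv.columns)}"
            )
        if len(self.network_suv) != len(self.subjects):
            raise ValueError("network_suv row count does not match subjects")

    def group_values(self, group: str) -> pd.DataFrame:
        return self.network_suv.loc[(self.groups == group).values]


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma (mm) for a smoothing kernel of the given FWHM (mm)."""
    if fwhm < 0:
        raise ValueError(f"FWHM must be >= 0, got {fwhm}")
    return fwhm / _FWHM_PER_SIGMA


def global_normalize(volume: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Divide a volume by its mean over the whole-brain mask.

    The masked mean of the result is exactly 1; the operation is
    idempotent and invariant to positive rescaling of the input.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    if not mask.any():
        raise ValueError("brain mask is empty")
    g = volume[mask].mean()
    if g <= 0:
        raise ValueError(f"global mean over mask is {g}; must be positive")
    return volume / g


def roi_suvmean(volume: np.ndarray, atlas: AtlasDefinition) -> pd.Series:
    """Per-region unweighted voxel mean of a (normalized) volume.

    Returns a Series indexed by region abbreviation.  Regions with no
    voxels get NaN and a logged warning.
    """
    if atlas.label_volume is None:
        raise ValueError("atlas has no label volume")
    volume = np.asarray(volume, dtype=float)
    if volume.shape != atlas.label_volume.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match atlas grid "
            f"{atlas.label_volume.shape}"
        )
    ids = np.array(atlas.region_ids)
    sums = ndimage.sum_labels(volume, labels=atlas.label_volume, index=ids)
    counts = np.array([atlas.voxel_counts[i] for i in ids], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    for rid, c in zip(ids, counts):
        if c == 0:
            logger.warning("region %d has no voxels; SUVmean is NaN", rid)
    return pd.Series(means, index=atlas.abbreviations, name="suvmean")


def network_suvmean(
    source: np.ndarray | pd.Series | dict,
    atlas: AtlasDefinition,
    weighted: bool = True,
) -> pd.Series:
    """Network-level SUVmean from a volume or a per-region vector.

    From a volume this is the mean over the network's voxel mask; from a
    region vector it is the voxel-count-weighted mean of member regions
    — the two paths agree.  ``weighted=False`` gives the unweighted mean
    of member-region means (sensitivity variant).
    """
    if isinstance(source, np.ndarray) and source.ndim == 3:
        values = {}
        for net in NETWORKS:
            mask = network_mask(atlas, net)
            if not mask.any():
                logger.warning("network %s has no voxels; SUVmean is NaN", net)
                values[net] = np.nan
            else:
                values[net] = float(np.asarray(source, dtype=float)[mask].mean())
        return pd.Series(values, name="network_suvmean").reindex(list(NETWORKS))

    vec = pd.Series(source, dtype=float)
    values = {}
    for net in NETWORKS:
        members = atlas.regions_in_network(net)
        if not members:
            logger.warning("network %s has no member regions", net)
            values[net] = np.nan
            continue
        abbrs = [r.abbreviation for r in members]
        missing = [a for a in abbrs if a not in vec.index]
        if missing:
            raise KeyError(f"region vector lacks members of {net}: {missing}")
        x = vec[abbrs].to_numpy()
        if weighted:
            if not atlas.voxel_counts:
                raise ValueError(
                    "voxel counts unavailable: cannot weight regions; "
                    "load an atlas with a label volume or use weighted=False"
                )
            w = np.array([atlas.voxel_counts[r.id] for r in members], dtype=float)
            if w.sum() == 0:
                logger.warning("network %s has zero total voxels", net)
                values[net] = np.nan
                continue
            values[net] = float(np.average(x, weights=w))
        else:
            values[net] = float(x.mean())
    return pd.Series(values, name="network_suvmean").reindex(list(NETWORKS))


def network_table(cohort, atlas: AtlasDefinition, weighted: bool = True) -> NetworkTable:
    """Aggregate a cohort's region table to the subjects x 7 network table.

    Vectorized voxel-count-weighted aggregation; equivalent to calling
    :func:`network_suvmean` on every subject's region vector.
    """
    cols = {}
    for net in NETWORKS:
        members = atlas.regions_in_network(net)
        if not members:
            cols[net] = np.full(len(cohort.suv), np.nan)
            continue
        abbrs = [r.abbreviation for r in members]
        missing = [a for a in abbrs if a not in cohort.suv.columns]
        if missing:
            raise KeyError(f"cohort lacks members of {net}: {missing}")
        X = cohort.suv[abbrs].to_numpy(dtype=float)
        if weighted:
            if not atlas.voxel_counts:
                raise ValueError("voxel counts unavailable; cannot weight regions")
            w = np.array([atlas.voxel_counts[r.id] for r in members], dtype=float)
            if w.sum() == 0:
                logger.warning("network %s has zero total voxels", net)
                cols[net] = np.full(len(X), np.nan)
                continue
            cols[net] = X @ (w / w.sum())
        else:
            cols[net] = X.mean(axis=1)
    net = pd.DataFrame(cols, index=cohort.suv.index)[list(NETWORKS)]
    return NetworkTable(
        subjects=list(cohort.suv.index),
        groups=cohort.group,
        network_suv=net,
    )


def smooth_volume(volume: np.ndarray, fwhm_mm: float, affine: np.ndarray) -> np.ndarray:
    """Gaussian-smooth a volume with an isotropic FWHM given in mm."""
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float)
    voxel_sizes = np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel_sizes
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma_vox)
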