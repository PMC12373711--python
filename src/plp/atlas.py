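"""Brain parcellation and its partition into the seven canonical networks.

The parcellation follows the Brainnetome-style convention: integer region
labels 1..N in a NIfTI label volume, a region table (id, name,
abbreviation, network), and a many-to-one assignment of regions to the
seven resting-state networks (visual, somatomotor, dorsal attention,
ventral attention, limbic, frontoparietal, default).  Regions without a
network assignment (e.g. subcortical structures) carry ``unassigned`` and
are excluded from every network-level computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical network order, used for every 7-vector and 7-column table.
NETWORKS: tuple[str, ...] = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)

UNASSIGNED = "unassigned"

_NETWORK_ABBR = {
    "visual": "VIS",
    "somatomotor": "SM",
    "dorsal_attention": "DA",
    "ventral_attention": "VA",
    "limbic": "LIM",
    "frontoparietal": "FP",
    "default": "DMN",
}

#: Maximum deviation from an integer tolerated when a label volume is
#: stored as floating point.
_LABEL_TOL = 1e-6


@dataclass(frozen=True)
class RegionRecord:
    """One parcellation region: integer label, name, short code, network."""

    id: int
    name: str
    abbreviation: str
    network: str

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ValueError(f"region id must be >= 1, got {self.id}")
        if not self.abbreviation:
            raise ValueError(f"region {self.id} has an empty abbreviation")
        if self.network not in NETWORKS and self.network != UNASSIGNED:
            raise ValueError(
                f"region {self.id} ({self.abbreviation}): unknown network "
                f"{self.network!r}; expected one of {NETWORKS + (UNASSIGNED,)}"
            )


@dataclass
class AtlasDefinition:
    """Region catalogue plus optional label volume in a reference space.

    Parameters
    ----------
    regions
        Region catalogue.  Ids must be unique.
    label_volume
        Optional 3D integer grid; 0 is background.
    affine
        Optional 4x4 voxel-to-mm transform (MNI convention).
    voxel_counts
        Region id -> number of voxels; populated iff a label volume is
        present.
    """

    regions: list[RegionRecord]
    label_volume: np.ndarray | None = None
    affine: np.ndarray | None = None
    voxel_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.regions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region ids: {dupes}")
        if self.label_volume is not None:
            self.label_volume = _as_integer_labels(self.label_volume)
            known = set(ids)
            present = set(np.unique(self.label_volume)) - {0}
            missing = sorted(present - known)
            if missing:
                raise ValueError(
                    f"label volume contains labels missing from the region "
                    f"table: {missing}"
                )
            counts = dict(zip(*np.unique(self.label_volume, return_counts=True)))
            self.voxel_counts = {int(r.id): int(counts.get(r.id, 0)) for r in self.regions}
            for r in self.regions:
                if self.voxel_counts[r.id] == 0:
                    logger.warning(
                        "region %d (%s) present in table but absent from the "
                        "label volume; voxel_count set to 0",
                        r.id,
                        r.abbreviation,
                    )

    # -- lookups -------------------------------------------------------

    @property
    def region_ids(self) -> list[int]:
        return [r.id for r in self.regions]

    @property
    def abbreviations(self) -> list[str]:
        return [r.abbreviation for r in self.regions]

    def region(self, region_id: int) -> RegionRecord:
        for r in self.regions:
            if r.id == region_id:
                return r
        raise KeyError(f"no region with id {region_id}")

    def by_abbreviation(self, abbreviation: str) -> RegionRecord:
        for r in self.regions:
            if r.abbreviation == abbreviation:
                return r
        raise KeyError(f"no region with abbreviation {abbreviation!r}")

    def regions_in_network(self, network: str) -> list[RegionRecord]:
        _check_network(network, allow_unassigned=True)
        return [r for r in self.regions if r.network == network]

    def network_of(self) -> dict[int, str]:
        """Region id -> network label (including ``unassigned``)."""
        return {r.id: r.network for r in self.regions}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.regions],
                "name": [r.name for r in self.regions],
                "abbreviation": [r.abbreviation for r in self.regions],
                "network": [r.network for r in self.regions],
            }
        )


def _check_network(network: str, allow_unassigned: bool = False) -> None:
    allowed = NETWORKS + ((UNASSIGNED,) if allow_unassigned else ())
    if network not in allowed:
        raise ValueError(f"unknown network {network!r}; expected one of {allowed}")


def _as_integer_labels(volume: np.ndarray) -> np.ndarray:
    """Coerce a label grid to integers; reject genuinely non-integer data."""
    arr = np.asarray(volume)
    if arr.ndim != 3:
        raise ValueError(f"label volume must be 3D, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.int32, copy=False)
    rounded = np.rint(arr)
    if np.max(np.abs(arr - rounded)) > _LABEL_TOL:
        raise ValueError(
            "label volume is floating point with values farther than "
            f"{_LABEL_TOL} from an integer; refusing to round"
        )
    return rounded.astype(np.int32)


# ---------------------------------------------------------------------------
# I/O


def load_atlas(label_volume_path, region_table_path) -> AtlasDefinition:
    """Load an atlas from a NIfTI label volume and a TSV region table.

    The region table must carry columns ``id``, ``name``, ``abbreviation``
    and ``network``.  Every nonzero label in the volume must appear in the
    table; table regions absent from the volume get a voxel count of 0 and
    a logged warning.
    """
    img = nib.load(str(label_volume_path))
    volume = np.asanyarray(img.dataobj)
    table = pd.read_csv(region_table_path, sep="\t", dtype={"name": str, "abbreviation": str, "network": str})
    required = {"id", "name", "abbreviation", "network"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"region table must have columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    regions = [
        RegionRecord(
            id=int(row["id"]),
            name=str(row["name"]),
            abbreviation=str(row["abbreviation"]),
            network=str(row["network"]),
        )
        for _, row in table.iterrows()
    ]
    return AtlasDefinition(regions=regions, label_volume=volume, affine=np.asarray(img.affine))


def save_atlas(atlas: AtlasDefinition, label_volume_path, region_table_path) -> None:
    """Write the label volume (NIfTI) and the region table (TSV)."""
    if atlas.label_volume is None or atlas.affine is None:
        raise ValueError("atlas has no label volume/affine to save")
    img = nib.Nifti1Image(atlas.label_volume.astype(np.int32), atlas.affine)
    nib.save(img, str(label_volume_path))
    atlas.to_frame().to_csv(region_table_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Masks


def network_mask(atlas: AtlasDefinition, network: str) -> np.ndarray:
    """Boolean grid: True where the voxel's region belongs to ``network``."""
    _check_network(network, allow_unassigned=True)
    if atlas.label_volume is None:
        raise ValueError("atlas has no label volume; cannot build voxel masks")
    member_ids = [r.id for r in atlas.regions if r.network == network]
    return np.isin(atlas.label_volume, member_ids)


def region_mask(atlas: AtlasDefinition, region_id: int) -> np.ndarray:
    if atlas.label_volume is None:
        raise ValueError("atlas has no label volume; cannot build voxel masks")
    atlas.region(region_id)  # raises KeyError if unknown
    return atlas.label_volume == region_id


def brain_mask(atlas: AtlasDefinition) -> np.ndarray:
    """Default whole-brain mask: all labelled voxels."""
    if atlas.label_volume is None:
        raise ValueError("atlas has no label volume")
    return atlas.label_volume > 0


# ---------------------------------------------------------------------------
# Fixture atlas


def make_fixture_atlas(
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    regions_per_network: int = 2,
    seed: int = 0,
) -> AtlasDefinition:
    """Build a small, valid atlas for tests and simulations.

    The grid is partitioned into rectangular blocks; ``7 *
    regions_per_network`` of them become regions (contiguous by
    construction), each network receiving ``regions_per_network`` regions.
    The block-to-region assignment is shuffled by ``seed`` so different
    seeds give different geometries over the same catalogue.  The affine
    is an MNI-like 2 mm isotropic transform centred on the grid.
    """
    if regions_per_network < 1:
        raise ValueError("regions_per_network must be >= 1")
    n_regions = 7 * regions_per_network
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"grid_shape must be three positive ints, got {grid_shape}")

    splits = _choose_splits(shape, n_regions)
    boxes = _grid_boxes(shape, splits)
    if len(boxes) < n_regions:
        raise ValueError(
            f"cannot pack {n_regions} regions into grid {shape}: "
            f"only {len(boxes)} unit blocks available"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(boxes))[:n_regions]

    labels = np.zeros(shape, dtype=np.int32)
    regions: list[RegionRecord] = []
    for region_idx, box_idx in enumerate(order, start=1):
        sl = boxes[box_idx]
        labels[sl] = region_idx
        network = NETWORKS[(region_idx - 1) // regions_per_network]
        within = (region_idx - 1) % regions_per_network + 1
        abbr = f"{_NETWORK_ABBR[network]}_{within}"
        regions.append(
            RegionRecord(
                id=region_idx,
                name=f"{network.replace('_', ' ')} region {within}",
                abbreviation=abbr,
                network=network,
            )
        )

    # 2 mm isotropic, centred: a plausible MNI-like transform.
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -np.array(shape, dtype=float)  # == -(shape/2)*2mm
    atlas = AtlasDefinition(regions=regions, label_volume=labels, affine=affine)
    if any(atlas.voxel_counts[r.id] == 0 for r in regions):
        raise ValueError("packing produced an empty region; enlarge the grid")
    return atlas


def _choose_splits(shape: tuple[int, int, int], n_blocks: int) -> tuple[int, int, int]:
    """Split counts per axis whose product is >= n_blocks, blocks nonempty."""
    splits = [1, 1, 1]
    while splits[0] * splits[1] * splits[2] < n_blocks:
        # split the axis with the largest current block extent
        extents = [shape[i] / splits[i] for i in range(3)]
        axis = int(np.argmax(extents))
        if shape[axis] // (splits[axis] + 1) < 1:
            candidates = [i for i in range(3) if shape[i] // (splits[i] + 1) >= 1]
            if not candidates:
                raise ValueError(
                    f"cannot pack {n_blocks} blocks into grid {shape}"
                )
            axis = max(candidates, key=lambda i: shape[i] / splits[i])
        splits[axis] += 1
    return tuple(splits)


def _grid_boxes(shape: tuple[int, int, int], splits: tuple[int, int, int]) -> list[tuple[slice, slice, slice]]:
    edges = [np.linspace(0, shape[i], splits[i] + 1).astype(int) for i in range(3)]
    boxes = []
    for i in range(splits[0]):
        for j in range(splits[1]):
            for k in range(splits[2]):
                boxes.append(
                    (
                        slice(edges[0][i], edges[0][i + 1]),
                        slice(edges[1][j], edges[1][j + 1]),
                        slice(edges[2][k], edges[2][k + 1]),
                    )
                )
    return boxes
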