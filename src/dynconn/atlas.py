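"""Parcellation atlas: ROI identities, network labels, and filtering.

The atlas is the coordinate frame for every downstream map: each ROI carries a
stable 1-based integer id, a resting-state network label, an anatomical label,
a hemisphere, and an MNI-millimetre centroid.  ROIs labelled ``undefined`` do
not belong to any named functional network and are removed before analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ATLAS_COLUMNS = ["roi_id", "network", "anatomy", "hemisphere", "x", "y", "z"]
UNDEFINED_NETWORK = "undefined"
HEMISPHERES = {"left", "right", "midline"}


@dataclass(frozen=True)
class ParcellationAtlas:
    """An immutable ROI table.

    ``table`` holds one row per ROI with columns ``roi_id, network, anatomy,
    hemisphere, x, y, z``, sorted by ``roi_id``.  ROI ids are 1-based and
    unique; internal array positions are 0-based but all I/O uses the ids.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        tab = self.table
        missing = [c for c in ATLAS_COLUMNS if c not in tab.columns]
        if missing:
            raise ValueError(f"atlas missing required column(s): {missing}")
        unknown = [c for c in tab.columns if c not in ATLAS_COLUMNS]
        if unknown:
            raise ValueError(f"atlas has unknown column(s): {unknown}")
        ids = tab["roi_id"].to_numpy()
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].unique()
        if dup.size:
            raise ValueError(f"duplicate roi_id value(s): {sorted(int(d) for d in dup)}")
        bad_hemi = set(tab["hemisphere"]) - HEMISPHERES
        if bad_hemi:
            raise ValueError(f"unknown hemisphere value(s): {sorted(bad_hemi)}")
        ordered = tab.sort_values("roi_id").reset_index(drop=True)[ATLAS_COLUMNS]
        object.__setattr__(self, "table", ordered)

    @property
    def n_roi(self) -> int:
        return len(self.table)

    @property
    def roi_ids(self) -> np.ndarray:
        return self.table["roi_id"].to_numpy(dtype=int)

    @property
    def networks(self) -> list[str]:
        """Distinct network labels, sorted."""
        return sorted(self.table["network"].unique())

    def network_of(self) -> pd.Series:
        """Series mapping roi_id -> network label."""
        return self.table.set_index("roi_id")["network"]

    def __len__(self) -> int:
        return len(self.table)


def load_atlas(path) -> ParcellationAtlas:
    """Read a parcellation atlas from a tab-separated table.

    The file must have the header
    ``roi_id\tnetwork\tanatomy\themisphere\tx\ty\tz``.  Rows are returned in
    roi_id order regardless of file order.  Duplicate ids, unknown columns and
    empty files are hard errors.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"roi_id": "Int64"})
    if len(tab) == 0:
        raise ValueError(f"atlas file {path} contains no ROIs")
    tab["roi_id"] = tab["roi_id"].astype(int)
    return ParcellationAtlas(tab)


def write_atlas(atlas: ParcellationAtlas, path) -> None:
    """Write the atlas back to TSV; round-trips with :func:`load_atlas`."""
    atlas.table.to_csv(path, sep="\t", index=False)


def filter_defined_networks(atlas: ParcellationAtlas) -> ParcellationAtlas:
    """Drop every ROI whose network label is ``undefined``.

    Idempotent.  Logs the number of removed ROIs; an atlas with nothing to
    remove is returned unchanged, and an all-undefined atlas yields an empty
    atlas with a warning.
    """
    keep = atlas.table["network"] != UNDEFINED_NETWORK
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_defined_networks: removed %d undefined-network ROIs, %d retained",
                    n_removed, int(keep.sum()))
    if keep.sum() == 0:
        logger.warning("filter_defined_networks: every ROI is undefined; returning empty atlas")
    if n_removed == 0:
        return atlas
    return ParcellationAtlas(atlas.table[keep].reset_index(drop=True))
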