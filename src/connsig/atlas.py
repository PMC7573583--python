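"""Region atlas: a parcellation of the brain into functional regions grouped
into canonical networks.

The default configuration mirrors a 64-region parcellation grouped into 12
functional networks, the resolution at which the connectome carries
L = 64*65/2 = 2080 connectivity values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import IntegrityError, SchemaError

ATLAS_COLUMNS = ["region_id", "region_name", "network_id", "network_name"]


@dataclass(frozen=True)
class RegionAtlas:
    """Mapping of contiguous region ids to names and networks.

    Parameters
    ----------
    table:
        DataFrame with columns ``region_id``, ``region_name``,
        ``network_id``, ``network_name``. Region ids must be the contiguous
        integers ``0..R-1`` and each region belongs to exactly one network.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ATLAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"atlas table missing columns: {missing}")
        ids = np.asarray(self.table["region_id"], dtype=int)
        if len(np.unique(ids)) != len(ids):
            raise IntegrityError("duplicate region_id in atlas")
        if not np.array_equal(np.sort(ids), np.arange(len(ids))):
            raise IntegrityError("region_ids must be contiguous 0..R-1")
        object.__setattr__(
            self, "table", self.table.sort_values("region_id").reset_index(drop=True)
        )

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def n_networks(self) -> int:
        return self.table["network_id"].nunique()

    @property
    def network_ids(self) -> np.ndarray:
        """Network id of each region, indexed by region_id."""
        return np.asarray(self.table["network_id"], dtype=int)

    def network_name(self, network_id: int) -> str:
        names = self.table.loc[self.table["network_id"] == network_id, "network_name"]
        return str(names.iloc[0])
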