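"""Tiling-array design: probe coordinates, region grouping, control flags.

An :class:`ArrayDesign` describes a CHARM-like tiling array: dense runs of
probes grouped into genomic regions, plus CpG-free control probes used as an
unmethylated reference during normalization.  Internally coordinates are
1-based inclusive; BED export converts to 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ["probe_id", "chrom", "pos", "region_id", "is_control", "quality"]


class ArrayDesign:
    """Probe design table.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``probe_id`` (unique str), ``chrom`` (str), ``pos`` (int,
        1-based), ``region_id`` (int, -1 for control probes), ``is_control``
        (bool) and ``quality`` (float in [0, 100]).
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in DESIGN_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        table = table.loc[:, DESIGN_COLUMNS].copy()
        if table["probe_id"].duplicated().any():
            dups = table.loc[table["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        q = table["quality"].to_numpy(float)
        if np.any((q < 0) | (q > 100)):
            raise ValueError("quality scores must lie in [0, 100]")
        ctrl = table["is_control"].to_numpy(bool)
        rid = table["region_id"].to_numpy(int)
        if np.any(ctrl & (rid >= 0)):
            raise ValueError("control probes must not carry a region_id")
        # probes within a region must have strictly increasing positions
        noctrl = table.loc[~ctrl]
        for region, grp in noctrl.groupby("region_id", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing in region {region}")
        self.table = table.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.table["probe_id"].to_numpy()

    @property
    def is_control(self) -> np.ndarray:
        return self.table["is_control"].to_numpy(bool)

    @property
    def n_regions(self) -> int:
        rid = self.table.loc[~self.is_control, "region_id"]
        return int(rid.nunique())

    def analysis_table(self) -> pd.DataFrame:
        """Non-control probes sorted by (chrom, region, position)."""
        t = self.table.loc[~self.is_control]
        return t.sort_values(["chrom", "region_id", "pos"], kind="mergesort").reset_index(drop=True)

    def analysis_arrays(self):
        """Numpy view used by the numeric pipeline.

        Returns
        -------
        probe_ids, chrom (object array), pos (int64), region_codes (int64,
        contiguous 0..R-1 in genomic order).
        """
        t = self.analysis_table()
        rid = t["region_id"].to_numpy()
        # contiguous codes preserving the sorted order of appearance
        _, codes = np.unique(rid, return_inverse=True)
        order_first = {}
        remap = np.empty_like(codes)
        nxt = 0
        for i, c in enumerate(codes):
            if c not in order_first:
                order_first[c] = nxt
                nxt += 1
            remap[i] = order_first[c]
        return (
            t["probe_id"].to_numpy(),
            t["chrom"].to_numpy(),
            t["pos"].to_numpy(np.int64),
            remap.astype(np.int64),
        )

    def subset(self, keep: np.ndarray) -> "ArrayDesign":
        """Row-subset by boolean mask (aligned to ``self.table``)."""
        return ArrayDesign(self.table.loc[keep].reset_index(drop=True))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ArrayDesign({len(self)} probes, {self.n_regions} regions, "
            f"{int(self.is_control.sum())} controls)"
        )
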