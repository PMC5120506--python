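"""Twin cohort sample sheet: pairs, within-pair phenotype, covariates."""

from __future__ import annotations

import numpy as np
import pandas as pd

SHEET_COLUMNS = ["sample_id", "pair_id", "phenotype", "batch"]
COVARIATE_COLUMNS = ["age", "sex", "smoking", "hla_se"]


class TwinCohort:
    """Paired monozygotic-twin cohort.

    Every ``pair_id`` must contain exactly one case (``phenotype == 1``,
    e.g. the ACPA-positive twin) and one control (``phenotype == 0``).
    Batches are never mixed inside one analysis run; mixed-batch sheets are
    rejected at model-construction time, not here, so a sheet may describe
    several batches and be split with :meth:`for_batch`.
    """

    def __init__(self, sheet: pd.DataFrame):
        missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        sheet = sheet.copy()
        if sheet["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sample sheet")
        for pair, grp in sheet.groupby("pair_id"):
            phen = sorted(grp["phenotype"].astype(int).tolist())
            if phen != [0, 1]:
                raise ValueError(
                    f"pair {pair!r} must have exactly one case and one control, "
                    f"got phenotypes {phen}"
                )
        self.sheet = sheet.reset_index(drop=True)

    @property
    def n_pairs(self) -> int:
        return int(self.sheet["pair_id"].nunique())

    @property
    def sample_ids(self) -> np.ndarray:
        return self.sheet["sample_id"].to_numpy()

    @property
    def batches(self) -> list:
        return sorted(self.sheet["batch"].unique().tolist())

    def for_batch(self, batch) -> "TwinCohort":
        return TwinCohort(self.sheet.loc[self.sheet["batch"] == batch].reset_index(drop=True))

    def pair_arrays(self, sample_order: np.ndarray):
        """Pairing arrays aligned to a given sample column order.

        Returns
        -------
        pair_codes : int64 array, 0..n_pairs-1 per sample
        phenotype : int64 array (1 = case)
        case_idx, control_idx : per-pair column indices into ``sample_order``
        """
        sheet = self.sheet.set_index("sample_id").loc[list(sample_order)]
        pair_ids = sheet["pair_id"].to_numpy()
        uniq = pd.unique(pair_ids)
        codes = np.array([np.flatnonzero(uniq == p)[0] for p in pair_ids], dtype=np.int64)
        phen = sheet["phenotype"].to_numpy(np.int64)
        n = len(uniq)
        case_idx = np.full(n, -1, dtype=np.int64)
        control_idx = np.full(n, -1, dtype=np.int64)
        for j, (c, ph) in enumerate(zip(codes, phen)):
            if ph == 1:
                case_idx[c] = j
            else:
                control_idx[c] = j
        if np.any(case_idx < 0) or np.any(control_idx < 0):
            raise ValueError("sample order does not cover every pair completely")
        return codes, phen, case_idx, control_idx

    def covariate(self, name: str) -> np.ndarray:
        if name not in self.sheet.columns:
            raise KeyError(f"covariate {name!r} not present in sample sheet")
        return self.sheet[name].to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TwinCohort({self.n_pairs} pairs, batches={self.batches})"
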