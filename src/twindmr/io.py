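"""Readers/writers for the package's tabular and genomic formats.

Conventions: tab-separated UTF-8 with mandatory headers, '.' for missing
values; internal coordinates 1-based inclusive; BED export 0-based
half-open.  Readers validate and report offending rows.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import TwinCohort
from .design import ArrayDesign, DESIGN_COLUMNS
from .matrix import MethylationMatrix

NA = "."


@dataclass
class RunConfig:
    """All pipeline thresholds and defaults; serializes losslessly to YAML."""

    quality_threshold: float = 80.0
    min_pairwise_corr: float = 0.8
    eps: float = 0.01
    probe_fdr: float = 0.20
    cutoff_quantile: float = 0.995
    min_probes: int = 3
    max_gap: int = 300
    span: float = 0.3
    smooth_method: str = "loess"
    perm_threshold: float = 0.1
    fwer_threshold: float = 0.10
    fwer_report_threshold: float = 0.20
    B: int = 2000
    scheme: str = "residual"
    k_markers: int = 300
    marker_cutoff_abs: float = 0.1
    marker_min_probes: int = 2
    perm_cap: int = 4096
    seed: int = 0

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def read_design(path) -> ArrayDesign:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["region_id"] = df["region_id"].fillna(-1).astype(int)
    df["is_control"] = df["is_control"].astype(bool)
    return ArrayDesign(df)


def write_design(design: ArrayDesign, path):
    out = design.table.copy()
    out["region_id"] = out["region_id"].astype(object).where(out["region_id"] >= 0, NA)
    out["is_control"] = out["is_control"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_matrix(path, design: ArrayDesign | None = None) -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    vals = df.to_numpy(float)
    bad = np.argwhere(~np.isnan(vals) & ((vals < 0) | (vals > 1)))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"{path}: value {vals[i, j]} outside [0,1] at row {i + 2} "
            f"(probe {df.index[i]!r}, sample {df.columns[j]!r})"
        )
    mat = MethylationMatrix(df)
    if design is not None:
        design_ids = set(design.probe_ids)
        extra = [p for p in mat.probe_ids if p not in design_ids]
        if extra:
            raise ValueError(
                f"{path}: {len(extra)} probes not in design, e.g. {extra[:3]}"
            )
    return mat


def write_matrix(meth: MethylationMatrix, path):
    meth.data.to_csv(path, sep="\t", index_label="probe_id", na_rep=NA)


def read_samplesheet(path) -> TwinCohort:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    try:
        return TwinCohort(df)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_samplesheet(cohort: TwinCohort, path):
    cohort.sheet.to_csv(path, sep="\t", index=False, na_rep=NA)


def write_calls(summary: pd.DataFrame, path):
    """Call table TSV (see :meth:`TwinDMRResults.summary`)."""
    summary.to_csv(path, sep="\t", index=False, na_rep=NA)


def write_bed(calls, path, min_fwer_floor: float | None = None):
    """BED of DMR calls: 0-based half-open, score = -10*log10(best FWER).

    ``calls`` is a list of :class:`~twindmr.significance.DMRCall` sorted as
    returned by ``call_dmrs``; a FWER of 0 is floored at ``min_fwer_floor``
    (default 1/B) before the log transform.
    """
    lines = ["#chrom\tstart\tend\tname\tscore\tstrand"]
    for i, call in enumerate(calls):
        c = call.candidate
        best = min(c.fwer.fwer.values())
        floor = min_fwer_floor if min_fwer_floor is not None else 1.0 / c.fwer.B
        score = -10.0 * np.log10(max(best, floor))
        lines.append(f"{c.chrom}\t{c.start - 1}\t{c.end}\tDMR{i + 1}\t{score:.4g}\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """BED intervals back to internal 1-based inclusive coordinates."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        out.append((fields[0], int(fields[1]) + 1, int(fields[2])))
    return out


def write_truth(truth, path):
    """Ground-truth JSON for a simulated cohort."""
    payload = {
        "planted": truth.planted.to_dict(orient="records"),
        "proportions": {k: list(map(float, v)) for k, v in truth.proportions.iterrows()},
        "cell_types": list(truth.proportions.columns),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
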