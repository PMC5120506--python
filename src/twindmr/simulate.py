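"""Synthetic CHARM-like data: array designs, sorted-cell panels, twin cohorts.

The generator emulates the study design this package targets: a tiling array
with ~10-probe genomic regions plus CpG-free control probes, a sorted-cell
reference panel over four leukocyte types (neutrophils, CD4+ T, CD8+ T,
CD56+ NK), and small cohorts of monozygotic twin pairs discordant for a
binary phenotype.  Bulk methylation is a cell-type mixture
``sum_k w_k mu_k(j)`` plus a planted phenotype effect inside chosen regions,
a pair-shared baseline perturbation (MZ-twin similarity), and Gaussian noise,
clipped to [0, 1].  Full ground truth is returned so downstream stages can be
tested against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import TwinCohort
from .design import ArrayDesign
from .matrix import MethylationMatrix

DEFAULT_CELL_TYPES = ("neutrophil", "CD4T", "CD8T", "CD56NK")

#: sd of the per-probe baseline perturbation shared by both twins of a pair
PAIR_BASELINE_SD = 0.02


@dataclass
class PlantedDMR:
    """A phenotype effect planted in one design region.

    ``delta`` is signed, on the proportion scale: case twins get
    methylation ``+delta`` at every probe of the region.
    """

    region_id: int
    delta: float

    def __post_init__(self):
        if abs(self.delta) > 0.5:
            raise ValueError("|delta| must be <= 0.5 on the proportion scale")


@dataclass
class SimulationConfig:
    n_pairs: int = 5
    n_regions: int = 500
    probes_per_region: tuple[int, int] = (8, 12)
    control_fraction: float = 0.05
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    dirichlet_alpha: tuple[float, ...] | None = (8.0, 5.0, 3.0, 2.0)
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    noise_sd: float = 0.05
    proportion_shift: tuple[float, ...] | None = None
    batch: str = "B1"
    batch_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dirichlet_alpha is not None:
            alpha = np.asarray(self.dirichlet_alpha, float)
            if np.any(alpha <= 0):
                raise ValueError("dirichlet_alpha must be strictly positive")
            if len(alpha) != len(self.cell_types):
                raise ValueError("dirichlet_alpha length must match cell_types")
        self.planted_dmrs = [
            p if isinstance(p, PlantedDMR) else PlantedDMR(*p) for p in self.planted_dmrs
        ]


@dataclass
class CellReferenceTruth:
    """Ground truth for a generated sorted-cell panel."""

    profiles: pd.DataFrame  # cell types x probes, true methylation
    marker_region_ids: np.ndarray
    designated_type: dict[int, str]  # region id -> outlier cell type


@dataclass
class GroundTruth:
    """Ground truth for a simulated twin cohort."""

    planted: pd.DataFrame  # chrom, start, end, region_id, delta
    proportions: pd.DataFrame  # samples x cell types, simplex rows
    reference: pd.DataFrame | None  # cell types x probes


def generate_array_design(
    n_regions: int,
    probes_per_region: tuple[int, int] = (8, 12),
    control_fraction: float = 0.05,
    seed: int = 0,
    chrom: str = "chr1",
    n_control: int | None = None,
) -> ArrayDesign:
    """Generate a CHARM-like probe design.

    Probes within a region are spaced by uniform random gaps in [30, 100] bp;
    regions are separated by >= 1 kb.  Control (non-CpG) probes carry no
    region membership and are appended downstream of the tiled regions.
    Quality scores are Uniform[60, 100] so a quality-80 filter has work to do.

    ``n_control`` overrides the control count; otherwise it is derived from
    ``control_fraction`` (the proportion of control probes in the full
    design), with a default of 100 when there are no regions.
    """
    lo, hi = probes_per_region
    if lo > hi:
        raise ValueError(f"invalid probes_per_region range: min {lo} > max {hi}")
    if lo < 1:
        raise ValueError("probes_per_region bounds must be >= 1")
    if not 0 <= control_fraction < 1:
        raise ValueError("control_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    rows = []
    pos = 10_000
    for region in range(n_regions):
        n_probes = int(rng.integers(lo, hi + 1))
        for _ in range(n_probes):
            rows.append((f"p{len(rows):06d}", chrom, pos, region, False, float(rng.uniform(60, 100))))
            pos += int(rng.integers(30, 101))
        pos += 1000 + int(rng.integers(0, 500))  # >= 1 kb between regions

    n_noncontrol = len(rows)
    if n_control is None:
        if control_fraction == 0:
            n_control = 0
        elif n_noncontrol == 0:
            n_control = 100
        else:
            n_control = int(round(control_fraction / (1 - control_fraction) * n_noncontrol))
    pos += 5000
    for i in range(n_control):
        rows.append((f"ctrl{i:05d}", chrom, pos, -1, True, float(rng.uniform(60, 100))))
        pos += 500

    table = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "region_id", "is_control", "quality"])
    return ArrayDesign(table)


def generate_cell_reference(
    design: ArrayDesign,
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES,
    n_marker_regions: int = 40,
    n_replicates: int = 3,
    noise_sd: float = 0.02,
    baseline_range: tuple[float, float] = (0.15, 0.85),
    marker_effect_range: tuple[float, float] = (0.2, 0.4),
    seed: int = 0,
) -> tuple[MethylationMatrix, list[str], CellReferenceTruth]:
    """Generate a sorted-cell methylation panel with planted cell-type markers.

    In each of ``n_marker_regions`` randomly chosen regions, one designated
    cell type (chosen uniformly, a multinomial split across types) deviates
    from the shared baseline by an effect drawn from ``marker_effect_range``
    (>= 0.2 by default), directed away from the nearer [0, 1] boundary.
    Elsewhere all cell types share a common per-probe baseline.  Replicates
    add independent Normal(0, noise_sd) noise, clipped to [0, 1].

    Returns the replicate matrix, the per-column cell-type labels, and the
    ground truth (true profiles plus marker assignments).
    """
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    probe_ids, _, _, region_codes = design.analysis_arrays()
    n_probes = len(probe_ids)
    region_ids_sorted = design.analysis_table()["region_id"].to_numpy()
    uniq_regions = pd.unique(region_ids_sorted)
    if n_marker_regions > len(uniq_regions):
        raise ValueError("n_marker_regions exceeds the number of design regions")

    baseline = rng.uniform(*baseline_range, size=n_probes)
    profiles = np.tile(baseline, (len(cell_types), 1))

    marker_regions = rng.choice(uniq_regions, size=n_marker_regions, replace=False)
    designated = {}
    for region in marker_regions:
        k = int(rng.integers(len(cell_types)))
        designated[int(region)] = cell_types[k]
        mask = region_ids_sorted == region
        effect = rng.uniform(*marker_effect_range)
        # aim away from the nearer boundary so the contrast survives clipping
        direction = np.where(baseline[mask] < 0.5, 1.0, -1.0)
        profiles[k, mask] = np.clip(baseline[mask] + direction * effect, 0.0, 1.0)

    labels, columns = [], {}
    for k, ct in enumerate(cell_types):
        for r in range(n_replicates):
            noise = rng.normal(0.0, noise_sd, size=n_probes) if noise_sd > 0 else 0.0
            columns[f"{ct}_rep{r + 1}"] = np.clip(profiles[k] + noise, 0.0, 1.0)
            labels.append(ct)
    data = pd.DataFrame(columns, index=probe_ids)
    truth = CellReferenceTruth(
        profiles=pd.DataFrame(profiles, index=list(cell_types), columns=probe_ids),
        marker_region_ids=np.sort(np.asarray(marker_regions)),
        designated_type=designated,
    )
    return MethylationMatrix(data), labels, truth


def simulate_twin_cohort(
    design: ArrayDesign,
    reference: pd.DataFrame | None,
    config: SimulationConfig,
) -> tuple[MethylationMatrix, TwinCohort, GroundTruth]:
    """Simulate a paired twin cohort on a given design.

    ``reference`` is a cell-types x probes DataFrame of true sorted-cell
    profiles (e.g. ``CellReferenceTruth.profiles``); pass None for a
    mixture-free cohort where every sample shares one baseline profile.

    Each sample's methylation at probe j is
    ``sum_k w_k mu_k(j) + phenotype * delta * 1[j in planted DMR]``
    plus a per-probe pair-shared Normal(0, 0.02^2) baseline perturbation and
    Normal(0, noise_sd^2) noise, clipped to [0, 1].  Control probes are drawn
    near zero methylation (unmethylated reference regions).
    """
    rng = np.random.default_rng(config.seed)
    table = design.analysis_table()
    probe_ids = table["probe_id"].to_numpy()
    region_ids = table["region_id"].to_numpy()
    n_probes = len(probe_ids)
    cell_types = list(config.cell_types)

    design_regions = set(int(r) for r in pd.unique(region_ids))
    for p in config.planted_dmrs:
        if int(p.region_id) not in design_regions:
            raise ValueError(f"planted region id {p.region_id} absent from design")

    if reference is not None:
        ref = reference.loc[list(cell_types), list(probe_ids)].to_numpy(float)
    else:
        baseline = rng.uniform(0.2, 0.8, size=n_probes)
        ref = np.tile(baseline, (len(cell_types), 1))

    # planted effect vector over analysis probes
    effect = np.zeros(n_probes)
    for p in config.planted_dmrs:
        effect[region_ids == p.region_id] += p.delta

    # per-sample mixing weights
    n_samples = 2 * config.n_pairs
    if config.dirichlet_alpha is not None:
        w = rng.dirichlet(np.asarray(config.dirichlet_alpha, float), size=n_samples)
    else:
        w = np.full((n_samples, len(cell_types)), 1.0 / len(cell_types))

    sample_ids, rows_sheet = [], []
    columns = {}
    ages = rng.integers(50, 81, size=config.n_pairs)
    sexes = rng.choice(["F", "M"], size=config.n_pairs)
    truth_w = {}
    si = 0
    for pair in range(config.n_pairs):
        pair_id = f"P{pair + 1:02d}"
        pair_baseline = rng.normal(0.0, PAIR_BASELINE_SD, size=n_probes)
        for phen, tag in ((1, "case"), (0, "ctrl")):
            wk = w[si].copy()
            if phen == 1 and config.proportion_shift is not None:
                wk = np.clip(wk + np.asarray(config.proportion_shift, float), 0.0, None)
                wk /= wk.sum()
            mix = wk @ ref
            vals = mix + phen * effect + pair_baseline + config.batch_effect
            if config.noise_sd > 0:
                vals = vals + rng.normal(0.0, config.noise_sd, size=n_probes)
            sid = f"{pair_id}_{tag}"
            columns[sid] = np.clip(vals, 0.0, 1.0)
            truth_w[sid] = wk
            sample_ids.append(sid)
            rows_sheet.append(
                dict(
                    sample_id=sid,
                    pair_id=pair_id,
                    phenotype=phen,
                    batch=config.batch,
                    age=int(ages[pair]),
                    sex=str(sexes[pair]),
                    smoking=int(rng.random() < 0.3),
                    hla_se=int(rng.random() < 0.5),
                )
            )
            si += 1

    data = pd.DataFrame(columns, index=probe_ids)

    # control probes: unmethylated reference, shared truth + noise
    ctrl_table = design.table.loc[design.is_control]
    if len(ctrl_table):
        ctrl_truth = rng.uniform(0.02, 0.10, size=len(ctrl_table))
        ctrl = {}
        for sid in sample_ids:
            v = ctrl_truth + (
                rng.normal(0.0, config.noise_sd, size=len(ctrl_table)) if config.noise_sd > 0 else 0.0
            )
            ctrl[sid] = np.clip(v, 0.0, 1.0)
        ctrl_df = pd.DataFrame(ctrl, index=ctrl_table["probe_id"].to_numpy())
        data = pd.concat([data, ctrl_df])

    planted_rows = []
    for p in config.planted_dmrs:
        grp = table.loc[table["region_id"] == p.region_id]
        planted_rows.append(
            dict(
                chrom=grp["chrom"].iloc[0],
                start=int(grp["pos"].min()),
                end=int(grp["pos"].max()),
                region_id=int(p.region_id),
                delta=float(p.delta),
            )
        )
    planted = pd.DataFrame(planted_rows, columns=["chrom", "start", "end", "region_id", "delta"])
    proportions = pd.DataFrame.from_dict(truth_w, orient="index", columns=cell_types)
    truth = GroundTruth(
        planted=planted,
        proportions=proportions,
        reference=pd.DataFrame(ref, index=cell_types, columns=probe_ids) if reference is not None else None,
    )
    return MethylationMatrix(data), TwinCohort(pd.DataFrame(rows_sheet)), truth


def emit_two_channels(
    meth: MethylationMatrix, seed: int = 0, log_mean: float = np.log(1000.0), log_sd: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stylized two-channel intensity emission.

    Per probe and sample a total intensity S ~ LogNormal(log_mean, log_sd)
    is split as treated = p * S and untreated = (1 - p) * S, so the
    downstream estimator treated / (treated + untreated) recovers p exactly.
    A stylized model meant only to exercise normalization, not array
    chemistry.
    """
    rng = np.random.default_rng(seed)
    p = meth.values
    s = rng.lognormal(log_mean, log_sd, size=p.shape)
    treated = pd.DataFrame(p * s, index=meth.probe_ids, columns=meth.sample_ids)
    untreated = pd.DataFrame((1.0 - p) * s, index=meth.probe_ids, columns=meth.sample_ids)
    return treated, untreated
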