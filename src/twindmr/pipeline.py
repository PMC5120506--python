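"""End-to-end orchestration: preprocess -> deconvolution -> DMR calling.

Batches are analyzed strictly separately (the batch contract is enforced
structurally by :class:`TwinDMRModel`); the pipeline loops over batches and
produces, per batch, an uncorrected run and - when a sorted-cell panel is
supplied - a cell-proportion-corrected run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .cohort import TwinCohort
from .design import ArrayDesign
from .io import RunConfig, write_bed, write_calls
from .matrix import MethylationMatrix
from .model import CellMixtureModel, TwinDMRModel
from .preprocess import normalize_between_samples, qc_probes, qc_samples

logger = logging.getLogger("twindmr")


def run_pipeline(
    config: RunConfig,
    design: ArrayDesign,
    meth: MethylationMatrix,
    cohort: TwinCohort,
    sorted_meth: MethylationMatrix | None = None,
    cell_labels: list[str] | None = None,
    outdir: str | Path | None = None,
    normalize: bool = True,
) -> dict:
    """Run the full analysis; returns a per-batch result bundle.

    Any stage failure aborts with the stage name; artifacts produced so
    far remain on disk when ``outdir`` is given.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    stage = "probe-qc"
    try:
        design_qc, probe_report = qc_probes(design, config.quality_threshold)
        logger.info("probe QC: %d probes discarded", len(probe_report.probe_discards))

        stage = "normalization"
        if normalize:
            meth = normalize_between_samples(meth, design_qc)

        stage = "sample-qc"
        sample_report = qc_samples(meth, design_qc, min_pairwise_corr=config.min_pairwise_corr)
        if sample_report.flagged_samples:
            logger.warning("flagged samples: %s", sample_report.flagged_samples)

        mixture = None
        if sorted_meth is not None:
            stage = "deconvolution-reference"
            if cell_labels is None:
                raise ValueError("cell_labels required with a sorted-cell panel")
            mixture = CellMixtureModel(sorted_meth, cell_labels, design_qc).fit(
                k_markers=config.k_markers,
                cutoff_abs=config.marker_cutoff_abs,
                min_probes=config.marker_min_probes,
            )

        bundle = {"qc": {"probes": probe_report, "samples": sample_report}, "batches": {}}
        fit_kwargs = dict(
            cutoff_quantile=config.cutoff_quantile,
            min_probes=config.min_probes,
            max_gap=config.max_gap,
            span=config.span,
            smooth_method=config.smooth_method,
            B=config.B,
            scheme=config.scheme,
            perm_threshold=config.perm_threshold,
            fwer_threshold=config.fwer_threshold,
            perm_cap=config.perm_cap,
            seed=config.seed,
        )
        for batch in cohort.batches:
            sub = cohort.for_batch(batch)
            stage = f"dmr-uncorrected[{batch}]"
            uncorrected = TwinDMRModel(meth, sub, design_qc, eps=config.eps).fit(**fit_kwargs)
            corrected = proportions = None
            if mixture is not None:
                stage = f"deconvolve[{batch}]"
                proportions = mixture.estimate(meth)
                covars = mixture.covariates(meth)
                stage = f"dmr-corrected[{batch}]"
                corrected = TwinDMRModel(
                    meth, sub, design_qc, covariates=covars, eps=config.eps
                ).fit(**fit_kwargs)
            bundle["batches"][batch] = {
                "uncorrected": uncorrected,
                "corrected": corrected,
                "proportions": proportions,
            }
            if out is not None:
                _write_batch(out, batch, bundle["batches"][batch], config)
        if out is not None:
            (out / "run.json").write_text(
                json.dumps({"seed": config.seed, "batches": list(bundle["batches"])}, indent=1)
            )
        return bundle
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def _write_batch(out: Path, batch, results: dict, config: RunConfig):
    for label in ("uncorrected", "corrected"):
        res = results[label]
        if res is None:
            continue
        summary = res.summary(fwer_report_threshold=config.fwer_report_threshold)
        write_calls(summary, out / f"{batch}_{label}_calls.tsv")
        write_bed([c for c in res.calls if c.passed], out / f"{batch}_{label}_calls.bed")
    if results["proportions"] is not None:
        results["proportions"].w.to_csv(out / f"{batch}_proportions.tsv", sep="\t", index_label="sample_id")
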