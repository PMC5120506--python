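"""Model/Results interface for twin DMR analysis and cell deconvolution.

Two model classes front the pipeline, in the style of statsmodels:

``TwinDMRModel``
    Built from a methylation matrix, a twin cohort sheet and an array
    design (plus optional cell-proportion covariates); ``fit()`` runs the
    probe-level paired model, coefficient smoothing, bump hunting, the
    within-pair permutation filter, the stratified bootstrap FWER and the
    dual-criterion call, returning a :class:`TwinDMRResults`.

``CellMixtureModel``
    Built from a sorted-cell panel; ``fit()`` performs marker discovery,
    profile averaging and informative-marker selection, returning a
    :class:`CellMixtureResults` whose ``estimate()`` solves the per-sample
    simplex QP on new bulk samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import deconvolution as dec
from . import significance as sig
from .cohort import TwinCohort
from .design import ArrayDesign
from .dmr import (
    fit_probe_model,
    find_candidates,
    single_probe_fdr,
    smooth_coefficients,
    resolve_cutoff,
)
from .matrix import DEFAULT_EPS, MethylationMatrix


class TwinDMRModel:
    """Paired DMR-detection model for one discordant twin cohort.

    Parameters
    ----------
    meth : MethylationMatrix
        Proportion-scale methylation; must cover every cohort sample.
    cohort : TwinCohort
        One batch only - mixed-batch cohorts are rejected, batches are
        analyzed separately by construction.
    design : ArrayDesign
        QC-filtered design; only its non-control probes present in
        ``meth`` (complete cases) enter the model.
    covariates : pandas.DataFrame, optional
        Per-sample cell-proportion covariates (columns neutrophil/NK/T,
        from :meth:`CellMixtureResults.covariates`), indexed by sample id.
    eps : float
        M-value clamp.
    """

    def __init__(
        self,
        meth: MethylationMatrix,
        cohort: TwinCohort,
        design: ArrayDesign,
        covariates: pd.DataFrame | None = None,
        eps: float = DEFAULT_EPS,
    ):
        if len(cohort.batches) > 1:
            raise ValueError(
                f"cohort mixes batches {cohort.batches}; analyze each batch separately"
            )
        self.cohort = cohort
        self.design = design
        self.eps = eps

        sample_order = cohort.sample_ids
        missing = set(sample_order) - set(meth.sample_ids)
        if missing:
            raise ValueError(f"samples absent from matrix: {sorted(missing)}")

        probe_ids, chroms, positions, region_codes = design.analysis_arrays()
        present = np.isin(probe_ids, meth.data.index.to_numpy())
        data = meth.data.loc[probe_ids[present], list(sample_order)]
        complete = ~data.isna().any(axis=1).to_numpy()
        keep = np.flatnonzero(present)[complete]

        self.probe_ids = probe_ids[keep]
        self.chroms = chroms[keep]
        self.positions = positions[keep]
        self.region_codes = region_codes[keep]
        self.region_ids = design.analysis_table()["region_id"].to_numpy()[keep]
        self.prop_values = data.to_numpy()[complete]
        self.meth = MethylationMatrix(data.loc[complete])
        self.m_values = self.meth.m_values(eps=eps)

        self.pair_codes, self.phenotype, self.case_idx, self.control_idx = cohort.pair_arrays(
            sample_order
        )
        if covariates is not None:
            cov = covariates.loc[list(sample_order)]
            vals = cov.to_numpy(float)
            if vals.shape[1] >= 2 and np.allclose(vals.sum(axis=1), 1.0, atol=1e-6):
                # simplex covariates (e.g. the neutrophil/NK/T triple) are
                # collinear with the pair-block intercept; drop the last
                # column - the fit is identical, the encoding identifiable
                cov = cov.iloc[:, :-1]
            self.covariates = cov.to_numpy(float)
            self.covariate_names = list(cov.columns)
        else:
            self.covariates = None
            self.covariate_names = []

    @classmethod
    def from_dataframes(
        cls,
        meth: pd.DataFrame,
        sample_sheet: pd.DataFrame,
        design: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        **kwargs,
    ) -> "TwinDMRModel":
        return cls(
            MethylationMatrix(meth), TwinCohort(sample_sheet), ArrayDesign(design),
            covariates=covariates, **kwargs,
        )

    def fit(
        self,
        cutoff_quantile: float | None = 0.995,
        cutoff_abs: float | None = None,
        min_probes: int = 3,
        max_gap: int = 300,
        span: float = 0.3,
        smooth_method: str = "loess",
        window: int = 3,
        B: int = 2000,
        scheme: str = "residual",
        perm_threshold: float = 0.1,
        fwer_threshold: float = 0.10,
        perm_cap: int = 4096,
        strata_edges=None,
        seed: int = 0,
    ) -> "TwinDMRResults":
        """Run the full discovery pipeline and return results.

        ``B`` bootstrap iterations feed the stratified FWER (2000 for
        production runs; smaller values trade resolution for speed).  All
        randomness flows through ``seed``.
        """
        probe_fit = fit_probe_model(self.m_values, self.pair_codes, self.phenotype, self.covariates)
        smoothed = smooth_coefficients(
            probe_fit.coef, self.positions, self.region_codes,
            span=span, method=smooth_method, window=window,
        )
        cutoff_value = resolve_cutoff(smoothed, cutoff_quantile, cutoff_abs)
        candidates = find_candidates(
            smoothed, self.prop_values, self.positions, self.region_codes,
            self.chroms, self.region_ids, self.case_idx, self.control_idx,
            cutoff_quantile=None, cutoff_abs=cutoff_value,
            min_probes=min_probes, max_gap=max_gap,
        )
        rng = np.random.default_rng(seed)
        for cand in candidates:
            cand.perm = sig.within_pair_permutation_p(
                cand.probe_index, self.prop_values, self.case_idx, self.control_idx,
                cap=perm_cap, rng=rng,
            )
        retained, excluded, reasons = sig.permutation_filter(candidates, threshold=perm_threshold)
        null_pool = sig.bootstrap_null(
            probe_fit, self.positions, self.region_codes, self.case_idx, self.control_idx,
            B=B, scheme=scheme, seed=seed + 1,
            span=span, smooth_method=smooth_method, window=window,
            cutoff_quantile=cutoff_quantile, cutoff_abs=cutoff_abs,
            min_probes=min_probes, max_gap=max_gap,
            perm_threshold=perm_threshold, perm_cap=perm_cap,
        )
        sig.stratified_fwer(retained, null_pool, strata_edges=strata_edges)
        calls = sig.call_dmrs(retained, fwer_threshold=fwer_threshold, perm_threshold=perm_threshold)
        params = dict(
            cutoff_quantile=cutoff_quantile, cutoff_abs=cutoff_abs, min_probes=min_probes,
            max_gap=max_gap, span=span, smooth_method=smooth_method, window=window,
            B=B, scheme=scheme, perm_threshold=perm_threshold, fwer_threshold=fwer_threshold,
            perm_cap=perm_cap, seed=seed,
        )
        return TwinDMRResults(
            model=self, probe_fit=probe_fit, smoothed=smoothed, cutoff_value=cutoff_value,
            candidates=candidates, retained=retained, excluded=excluded,
            exclusion_reasons=reasons, null_pool=null_pool, calls=calls, params=params,
        )


class TwinDMRResults:
    """Fitted results: probe statistics, candidates, FWERs and calls."""

    def __init__(self, model, probe_fit, smoothed, cutoff_value, candidates, retained,
                 excluded, exclusion_reasons, null_pool, calls, params):
        self.model = model
        self.probe_fit = probe_fit
        self.smoothed = smoothed
        self.cutoff_value = cutoff_value
        self.candidates = candidates
        self.retained = retained
        self.excluded = excluded
        self.exclusion_reasons = exclusion_reasons
        self.null_pool = null_pool
        self.calls = calls
        self.params = params

    @property
    def significant(self) -> list:
        return [c for c in self.calls if c.passed]

    def probe_table(self) -> pd.DataFrame:
        """Per-probe coefficients, p-values and BH q-values."""
        qvals, _ = single_probe_fdr(self.probe_fit.pvalues)
        return pd.DataFrame(
            {
                "probe_id": self.model.probe_ids,
                "chrom": self.model.chroms,
                "pos": self.model.positions,
                "coef": self.probe_fit.coef,
                "se": self.probe_fit.se,
                "p": self.probe_fit.pvalues,
                "q": qvals,
                "smoothed": self.smoothed,
            }
        )

    def summary(self, fwer_report_threshold: float = 0.20) -> pd.DataFrame:
        """Call table: one row per retained candidate, sorted as called.

        Columns mirror the conventional DMR report: coordinates, probe
        count, the three statistics, per-statistic FWER (with ``<1/B``
        rendered when below resolution), the permuted p and the pass flag.
        ``fwer_report_threshold`` adds a report-level column at the looser
        0.20 level alongside the primary call.
        """
        rows = []
        for call in self.calls:
            c = call.candidate
            f = c.fwer.fwer
            rows.append(
                dict(
                    chrom=c.chrom, start=c.start, end=c.end, nprobes=c.nprobes,
                    avg=c.avg, max=c.max, area_raw=c.area_raw,
                    fwer_avg=f["avg"], fwer_max=f["max"], fwer_area=f["area_raw"],
                    perm_p=min(c.perm.p_avg, c.perm.p_max),
                    passed=call.passed,
                    passed_report=(min(f.values()) < fwer_report_threshold)
                    and (min(c.perm.p_avg, c.perm.p_max) < self.params["perm_threshold"]),
                )
            )
        cols = ["chrom", "start", "end", "nprobes", "avg", "max", "area_raw",
                "fwer_avg", "fwer_max", "fwer_area", "perm_p", "passed", "passed_report"]
        return pd.DataFrame(rows, columns=cols)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TwinDMRResults({len(self.candidates)} candidates, "
            f"{len(self.retained)} retained, {len(self.significant)} significant)"
        )


class CellMixtureModel:
    """Reference construction from a sorted-cell methylation panel."""

    def __init__(self, sorted_meth: MethylationMatrix, cell_labels: list[str], design: ArrayDesign):
        if len(cell_labels) != sorted_meth.data.shape[1]:
            raise ValueError("one label per panel column required")
        self.sorted_meth = sorted_meth
        self.cell_labels = list(cell_labels)
        self.design = design

    def fit(
        self,
        k_markers: int = 300,
        cutoff_abs: float = 0.1,
        min_probes: int = 2,
        max_gap: int = 300,
    ) -> "CellMixtureResults":
        markers = dec.find_cell_type_dmrs(
            self.sorted_meth, self.cell_labels, self.design,
            cutoff_abs=cutoff_abs, min_probes=min_probes, max_gap=max_gap,
        )
        if not markers:
            raise ValueError("no cell-type marker DMRs found in the panel")
        reference = dec.build_reference(self.sorted_meth, markers, self.cell_labels)
        reference = dec.select_informative(reference, self.sorted_meth, self.cell_labels, k=k_markers)
        return CellMixtureResults(model=self, reference=reference)


class CellMixtureResults:
    """A fitted cell reference; estimates proportions for bulk samples."""

    def __init__(self, model: CellMixtureModel, reference: dec.CellReferenceProfile):
        self.model = model
        self.reference = reference

    @property
    def n_markers(self) -> int:
        return len(self.reference.markers)

    def estimate(self, meth: MethylationMatrix) -> dec.ProportionEstimate:
        """Simplex-QP proportion estimates for each sample of ``meth``."""
        means = dec.marker_means(meth, self.reference.markers)
        return dec.estimate_proportions(means, self.reference)

    def covariates(self, meth: MethylationMatrix, mapping: dict | None = None) -> pd.DataFrame:
        """The (neutrophil, NK, CD4+CD8) covariate triple per sample."""
        est = self.estimate(meth)
        return dec.proportion_covariates(est.w, mapping=mapping)

    def summary(self) -> pd.DataFrame:
        rows = [
            dict(marker=f"m{i}", chrom=mk.chrom, start=mk.start, end=mk.end,
                 n_probes=len(mk.probe_ids),
                 score=float(self.reference.scores[i]) if self.reference.scores is not None else np.nan)
            for i, mk in enumerate(self.reference.markers)
        ]
        return pd.DataFrame(rows)
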