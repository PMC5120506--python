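"""Probe-level paired linear model, bump hunting, and region statistics.

The probe model regresses M-values on a pair fixed-effect block plus a
phenotype indicator (and optionally the three cell-proportion covariates:
neutrophil %, NK %, CD4+CD8 %).  With no covariates the phenotype
coefficient reduces algebraically to the mean within-pair M difference.
Candidate DMRs are maximal runs of consecutive same-sign probes whose
smoothed coefficient clears a cutoff; each candidate carries the three
region statistics (avg, max, area_raw) computed on the proportion scale:

* ``avg``      - mean over probes of the per-probe case-control difference
* ``max``      - the signed per-probe difference of largest magnitude
* ``area_raw`` - nprobes x avg

The model runs on M-values while the statistics are reported as
percentage-methylation differences, mirroring standard CHARM-style output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .smoothing import smooth_within_regions


@dataclass
class ProbeModelFit:
    """Per-probe OLS results of the paired model on M-values."""

    coef: np.ndarray  # phenotype coefficient per probe ("logFC" on the M scale)
    se: np.ndarray
    pvalues: np.ndarray
    residuals: np.ndarray  # probes x samples
    fitted_null: np.ndarray  # probes x samples, fit without the phenotype term
    residuals_null: np.ndarray
    df_resid: int
    covariates_used: bool
    extract_vector: np.ndarray  # c with coef = M @ c, reused by the bootstrap
    sigma2_scale: float  # coef variance = sigma2 * sigma2_scale


@dataclass
class CandidateDMR:
    """A candidate region: contiguous probe run with its three statistics.

    Coordinates are 1-based inclusive; ``probe_index`` indexes into the
    analysis (non-control, sorted) probe order.
    """

    chrom: str
    start: int
    end: int
    region_id: int
    probe_index: np.ndarray
    nprobes: int
    avg: float
    max: float
    area_raw: float
    perm: "object | None" = None  # PermutationResult, attached later
    fwer: "object | None" = None  # FWERResult, attached later

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if abs(self.area_raw - self.nprobes * self.avg) > 1e-9 * max(1.0, abs(self.area_raw)):
            raise ValueError("area_raw must equal nprobes * avg")


def build_design_matrix(pair_codes: np.ndarray, phenotype: np.ndarray, covariates: np.ndarray | None):
    """Design matrix: one indicator per pair, phenotype, optional covariates.

    Returns (X, phenotype_column_index).
    """
    n = len(pair_codes)
    n_pairs = int(pair_codes.max()) + 1
    cols = [np.zeros(n) for _ in range(n_pairs)]
    for j, c in enumerate(pair_codes):
        cols[c][j] = 1.0
    X = np.column_stack(cols + [phenotype.astype(float)])
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariates must cover all samples")
        X = np.column_stack([X, cov])
    return X, n_pairs


def fit_probe_model(
    m_values: np.ndarray,
    pair_codes: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> ProbeModelFit:
    """OLS of every probe's M-values on {pair block, phenotype, covariates}.

    All probes share one design matrix, so the fit is a single matrix
    product: coef = M @ c with c the phenotype row of the pseudo-inverse.
    Two-sided p-values use the t distribution with n - rank residual df.

    Raises
    ------
    ValueError
        If the design matrix is rank deficient (e.g. a covariate collinear
        with the pair block), since then no probe has an identifiable
        phenotype coefficient.
    """
    M = np.asarray(m_values, float)
    X, n_pairs = build_design_matrix(pair_codes, phenotype, covariates)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient; phenotype coefficient not identifiable")
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T  # p x n
    phen_col = n_pairs
    c = pinv[phen_col]  # coef = M @ c
    coef = M @ c
    H = X @ pinv
    resid = M - M @ H.T
    df = n - p
    sigma2_scale = float(xtx_inv[phen_col, phen_col])
    if df > 0:
        sigma2 = (resid**2).sum(axis=1) / df
        se = np.sqrt(sigma2 * sigma2_scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, coef / se, np.inf * np.sign(coef))
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        pvals = np.where(se > 0, pvals, np.where(coef == 0, 1.0, 0.0))
    else:
        se = np.zeros_like(coef)
        pvals = np.full_like(coef, np.nan)

    # null model (no phenotype term) for residual-bootstrap null generation
    X0 = X[:, [j for j in range(p) if j != phen_col]]
    pinv0 = np.linalg.pinv(X0)
    H0 = X0 @ pinv0
    fitted0 = M @ H0.T
    resid0 = M - fitted0
    return ProbeModelFit(
        coef=coef,
        se=se,
        pvalues=pvals,
        residuals=resid,
        fitted_null=fitted0,
        residuals_null=resid0,
        df_resid=df,
        covariates_used=covariates is not None,
        extract_vector=c,
        sigma2_scale=sigma2_scale,
    )


def smooth_coefficients(
    coef: np.ndarray,
    positions: np.ndarray,
    region_codes: np.ndarray,
    span: float = 0.3,
    method: str = "loess",
    window: int = 3,
) -> np.ndarray:
    """Smooth per-probe coefficients within regions (see :mod:`.smoothing`)."""
    return smooth_within_regions(coef, positions, region_codes, span=span, method=method, window=window)


def resolve_cutoff(smoothed: np.ndarray, cutoff_quantile: float | None, cutoff_abs: float | None) -> float:
    """Absolute threshold from either a quantile of |smoothed| or a constant."""
    if (cutoff_quantile is None) == (cutoff_abs is None):
        raise ValueError("give exactly one of cutoff_quantile / cutoff_abs")
    if cutoff_abs is not None:
        return float(cutoff_abs)
    return float(np.quantile(np.abs(smoothed), cutoff_quantile))


def _candidate_runs(smoothed, positions, region_codes, cutoff, min_probes, max_gap):
    """Maximal same-sign above-cutoff runs; yields index arrays."""
    above = np.abs(smoothed) >= cutoff
    sign = np.sign(smoothed)
    n = len(smoothed)
    i = 0
    while i < n:
        if not above[i] or sign[i] == 0:
            i += 1
            continue
        j = i + 1
        while (
            j < n
            and above[j]
            and sign[j] == sign[i]
            and region_codes[j] == region_codes[i]
            and positions[j] - positions[j - 1] <= max_gap
        ):
            j += 1
        if j - i >= min_probes:
            yield np.arange(i, j)
        i = j


def compute_statistics(
    probe_index: np.ndarray,
    prop_values: np.ndarray,
    case_idx: np.ndarray,
    control_idx: np.ndarray,
) -> tuple[float, float, float]:
    """The three region statistics on the proportion scale.

    Per-probe difference = mean over pairs of (case - control) methylation;
    avg = mean over probes, max = signed difference of largest magnitude,
    area_raw = nprobes * avg.
    """
    block = prop_values[probe_index]
    diff = block[:, case_idx].mean(axis=1) - block[:, control_idx].mean(axis=1)
    avg = float(diff.mean())
    mx = float(diff[np.argmax(np.abs(diff))])
    return avg, mx, float(len(probe_index) * avg)


def find_candidates(
    smoothed: np.ndarray,
    prop_values: np.ndarray,
    positions: np.ndarray,
    region_codes: np.ndarray,
    chroms: np.ndarray,
    region_ids: np.ndarray,
    case_idx: np.ndarray,
    control_idx: np.ndarray,
    cutoff_quantile: float | None = 0.995,
    cutoff_abs: float | None = None,
    min_probes: int = 3,
    max_gap: int = 300,
) -> list[CandidateDMR]:
    """Bump-hunting candidate discovery.

    Maximal runs of consecutive probes with |smoothed| >= cutoff (inclusive),
    constant sign, inter-probe gaps <= ``max_gap`` bp, never crossing design
    regions, of length >= ``min_probes``.  Candidates are returned sorted and
    disjoint by construction, with statistics attached.
    """
    cutoff = resolve_cutoff(smoothed, cutoff_quantile, cutoff_abs)
    out = []
    for idx in _candidate_runs(smoothed, positions, region_codes, cutoff, min_probes, max_gap):
        avg, mx, area = compute_statistics(idx, prop_values, case_idx, control_idx)
        out.append(
            CandidateDMR(
                chrom=str(chroms[idx[0]]),
                start=int(positions[idx[0]]),
                end=int(positions[idx[-1]]),
                region_id=int(region_ids[idx[0]]),
                probe_index=idx,
                nprobes=len(idx),
                avg=avg,
                max=mx,
                area_raw=area,
            )
        )
    return out


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, via statsmodels)."""
    p = np.asarray(pvalues, float)
    if np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def single_probe_fdr(pvalues: np.ndarray, q: float = 0.20):
    """BH q-values plus the discovery set {q-value <= q}.

    The probe-level screen: at the cohort sizes this package targets it is
    expected to return no discoveries, motivating the region-level approach.
    """
    qvals = bh_qvalues(pvalues)
    return qvals, np.flatnonzero(qvals <= q)
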