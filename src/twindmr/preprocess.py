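"""Quality control, normalization, and methylation estimation.

QC applies four rules: background (control) probe signal level is reported;
samples with a high untreated-channel standard deviation are flagged; the
median of control (CpG-free) probes must sit below the median of non-control
probes; and probes with quality strictly below the threshold (default 80)
are discarded.  After normalization, samples must correlate highly with each
other; a sample whose minimum pairwise correlation falls below the threshold
is flagged.

Normalization is three-step: (1) within-sample LOESS normalization using the
control (non-CpG) probes as an unmethylated reference - a smooth
intensity-dependent baseline fitted to the control probes' log-ratios is
subtracted from all probes; (2) between-sample subset quantile
normalization anchored on the control probes; (3) methylation estimation
p = treated / (treated + untreated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .design import ArrayDesign
from .matrix import MethylationMatrix

MIN_CONTROL_PROBES = 20


@dataclass
class QCReport:
    """Per-sample metrics/flags and per-probe discard decisions.

    Each discarded probe and each flagged sample cites exactly one
    triggering rule.
    """

    sample_metrics: pd.DataFrame | None = None
    sample_flags: dict = field(default_factory=dict)  # sample_id -> rule name
    probe_discards: pd.DataFrame | None = None  # probe_id, reason

    @property
    def flagged_samples(self) -> list:
        return sorted(self.sample_flags)


def qc_probes(design: ArrayDesign, quality_threshold: float = 80.0):
    """Discard probes with quality strictly below the threshold.

    Region membership is preserved for survivors; regions emptied of probes
    simply no longer appear.  Returns (filtered design, QCReport).
    """
    q = design.table["quality"].to_numpy(float)
    keep = q >= quality_threshold
    discards = pd.DataFrame(
        {
            "probe_id": design.table.loc[~keep, "probe_id"].to_numpy(),
            "reason": f"quality < {quality_threshold:g}",
        }
    )
    return design.subset(keep), QCReport(probe_discards=discards)


def qc_samples(
    meth: MethylationMatrix,
    design: ArrayDesign,
    min_pairwise_corr: float = 0.8,
    untreated: pd.DataFrame | None = None,
    untreated_sd_z: float = 3.0,
) -> QCReport:
    """Sample-level QC.

    Flags a sample under exactly one (the first triggering) rule:

    ``untreated_sd``  - untreated-channel log-intensity sd is an outlier
        across samples (z-score above ``untreated_sd_z``); skipped when no
        untreated channel is supplied.
    ``control_median`` - median(control) - median(non-control) >= 0.
    ``low_correlation`` - the sample's correlation with every other sample
        falls below ``min_pairwise_corr`` (no other sample vouches for it);
        skipped with a warning when only a single sample is present.
    """
    common = [p for p in design.probe_ids if p in meth.data.index]
    data = meth.data.loc[common]
    ctrl_mask = pd.Series(design.is_control, index=design.probe_ids).loc[common].to_numpy()
    vals = data.to_numpy()
    samples = list(data.columns)
    n = len(samples)

    metrics = pd.DataFrame(index=samples)
    metrics["background_level"] = np.nanmedian(vals[ctrl_mask], axis=0) if ctrl_mask.any() else np.nan
    metrics["control_minus_noncontrol_median"] = (
        np.nanmedian(vals[ctrl_mask], axis=0) - np.nanmedian(vals[~ctrl_mask], axis=0)
        if ctrl_mask.any()
        else np.nan
    )
    if untreated is not None:
        u = untreated.loc[common].to_numpy(float)
        with np.errstate(divide="ignore"):
            metrics["untreated_sd"] = np.nanstd(np.log2(np.where(u > 0, u, np.nan)), axis=0)
    if n >= 2:
        corr = np.corrcoef(vals.T)
        np.fill_diagonal(corr, np.nan)
        metrics["min_pairwise_corr"] = np.nanmin(corr, axis=1)
        metrics["max_pairwise_corr"] = np.nanmax(corr, axis=1)
    else:
        warnings.warn("single sample: pairwise-correlation rule skipped", RuntimeWarning)
        metrics["min_pairwise_corr"] = np.nan
        metrics["max_pairwise_corr"] = np.nan

    flags = {}
    if untreated is not None and n >= 2:
        sd = metrics["untreated_sd"].to_numpy()
        z = (sd - np.nanmean(sd)) / (np.nanstd(sd) if np.nanstd(sd) > 0 else 1.0)
        for s, zi in zip(samples, z):
            if zi > untreated_sd_z:
                flags.setdefault(s, "untreated_sd")
    if ctrl_mask.any():
        for s in samples:
            if s not in flags and metrics.loc[s, "control_minus_noncontrol_median"] >= 0:
                flags.setdefault(s, "control_median")
    if n >= 2:
        for s in samples:
            if s not in flags and metrics.loc[s, "max_pairwise_corr"] < min_pairwise_corr:
                flags.setdefault(s, "low_correlation")
    return QCReport(sample_metrics=metrics, sample_flags=flags)


def normalize_within_sample(
    treated: pd.DataFrame,
    untreated: pd.DataFrame,
    design: ArrayDesign,
    span: float = 0.3,
    iterations: int = 2,
):
    """Within-sample LOESS normalization against the control probes.

    Per sample, the log-ratio M = log2(T/U) is regressed on the average
    log-intensity A = (log2 T + log2 U)/2 over the control probes with a
    tricube-weighted local linear fit (``span``, ``iterations`` robustness
    passes), the fitted baseline is interpolated to all probes and
    subtracted, and the control residuals are re-centered so their mean is
    exactly zero.  Channels are reconstructed keeping A fixed.
    """
    ctrl_ids = design.table.loc[design.is_control, "probe_id"]
    ctrl_ids = [p for p in ctrl_ids if p in treated.index]
    if len(ctrl_ids) < MIN_CONTROL_PROBES:
        raise ValueError(
            f"need >= {MIN_CONTROL_PROBES} control probes for within-sample "
            f"normalization, got {len(ctrl_ids)}"
        )
    T = treated.to_numpy(float)
    U = untreated.to_numpy(float)
    if np.any(T <= 0) or np.any(U <= 0):
        raise ValueError("channels must be positive")
    M = np.log2(T / U)
    A = 0.5 * (np.log2(T) + np.log2(U))
    is_ctrl = treated.index.isin(ctrl_ids)

    M_adj = np.empty_like(M)
    for j in range(M.shape[1]):
        a_c, m_c = A[is_ctrl, j], M[is_ctrl, j]
        if np.ptp(a_c) == 0:
            baseline = np.full(M.shape[0], m_c.mean())
        else:
            fit = lowess(m_c, a_c, frac=span, it=iterations, return_sorted=True)
            baseline = np.interp(A[:, j], fit[:, 0], fit[:, 1])
        adj = M[:, j] - baseline
        adj -= adj[is_ctrl].mean()  # exact zero control mean
        M_adj[:, j] = adj

    T_adj = np.exp2(A + M_adj / 2.0)
    U_adj = np.exp2(A - M_adj / 2.0)
    return (
        pd.DataFrame(T_adj, index=treated.index, columns=treated.columns),
        pd.DataFrame(U_adj, index=treated.index, columns=treated.columns),
    )


def normalize_between_samples(meth: MethylationMatrix, design: ArrayDesign) -> MethylationMatrix:
    """Between-sample subset quantile normalization on control probes.

    The reference is the cross-sample mean of the sorted control-probe
    values.  Control probes are mapped by rank (stable order within ties),
    so every sample's sorted control vector equals the reference exactly
    and the step is idempotent; non-control probes are mapped through the
    monotone interpolant (sample control values -> reference, anchored at
    (0,0) and (1,1), tied values collapsed by the average-rank convention).
    Within-sample order is never reversed.
    """
    if meth.data.shape[1] < 2:
        raise ValueError("between-sample normalization needs >= 2 samples")
    is_ctrl = meth.data.index.isin(design.table.loc[design.is_control, "probe_id"])
    if not is_ctrl.any():
        raise ValueError("no control probes present in the matrix")
    vals = meth.values
    ctrl = vals[is_ctrl]
    ref = np.sort(ctrl, axis=0).mean(axis=1)

    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        if np.ptp(col[np.isfinite(col)]) == 0:
            warnings.warn(
                f"sample {meth.data.columns[j]!r} is constant; mapped to reference median",
                RuntimeWarning,
            )
            out[:, j] = np.median(ref)
            continue
        xs = np.sort(ctrl[:, j])
        # interpolant for non-control probes; ties averaged per unique value
        ux, inv = np.unique(xs, return_inverse=True)
        uy = np.bincount(inv, weights=ref) / np.bincount(inv)
        knots_x, knots_y = ux, uy
        if knots_x[0] > 0:
            knots_x = np.concatenate(([0.0], knots_x))
            knots_y = np.concatenate(([0.0], knots_y))
        if knots_x[-1] < 1:
            knots_x = np.concatenate((knots_x, [1.0]))
            knots_y = np.concatenate((knots_y, [1.0]))
        out[:, j] = np.interp(col, knots_x, knots_y)
        # control probes: exact rank mapping onto the reference curve
        order = np.argsort(ctrl[:, j], kind="mergesort")
        mapped_ctrl = np.empty_like(ref)
        mapped_ctrl[order] = ref
        out[np.flatnonzero(is_ctrl), j] = mapped_ctrl
    return MethylationMatrix(
        pd.DataFrame(np.clip(out, 0.0, 1.0), index=meth.data.index, columns=meth.data.columns)
    )


def estimate_methylation(treated: pd.DataFrame, untreated: pd.DataFrame):
    """Methylation proportions p = treated / (treated + untreated).

    Probes with zero total intensity in some sample get a missing value
    there and are reported in the QCReport.  Returns (MethylationMatrix,
    QCReport).
    """
    T = treated.to_numpy(float)
    U = untreated.to_numpy(float)
    total = T + U
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, T / total, np.nan)
    flagged = treated.index[np.any(total <= 0, axis=1)]
    report = QCReport(
        probe_discards=pd.DataFrame({"probe_id": flagged, "reason": "zero total intensity"})
    )
    mat = MethylationMatrix(
        pd.DataFrame(np.clip(p, 0.0, 1.0), index=treated.index, columns=treated.columns)
    )
    return mat, report
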