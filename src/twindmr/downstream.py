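"""Cross-cohort projection, meta-analysis, and covariate association.

Projection takes DMR intervals discovered in one cohort and asks whether
they show within-pair signal in an independent cohort, by recomputing the
sign-flip permutation p-values (avg and max summaries) on the target
cohort's own data; the exhaustive granularity is 1/2^n of the *target*
cohort's pair count.  Replication data are combined by (1) Edgington's
summation-of-p method, whose null distribution of the sum of k p-values is
Irwin-Hall, and (2) inverse-variance fixed-effect meta-analysis with
Cochran's Q homogeneity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .significance import within_pair_permutation_p, PermutationResult


@dataclass
class ProjectionResult:
    chrom: str
    start: int
    end: int
    testable: bool
    n_probes: int
    perm: PermutationResult | None  # None when untestable


@dataclass
class MetaResult:
    effect: float
    se: float
    z: float
    p: float
    q_stat: float
    q_p: float
    k: int


@dataclass
class CovariateResult:
    dmr_id: str
    covariate: str
    slope: float
    p: float


def project_dmrs(
    intervals,
    target_prop_values: np.ndarray,
    target_positions: np.ndarray,
    target_chroms: np.ndarray,
    case_idx: np.ndarray,
    control_idx: np.ndarray,
    cap: int = 4096,
    seed: int = 0,
) -> list[ProjectionResult]:
    """Permutation p-values for foreign intervals on a target cohort.

    ``intervals`` is an iterable of (chrom, start, end), 1-based inclusive.
    Intervals overlapping no probe of the target design are reported as
    untestable rather than assigned a p-value.
    """
    rng = np.random.default_rng(seed)
    out = []
    for chrom, start, end in intervals:
        idx = np.flatnonzero(
            (target_chroms == chrom) & (target_positions >= start) & (target_positions <= end)
        )
        if len(idx) == 0:
            out.append(ProjectionResult(chrom, int(start), int(end), False, 0, None))
            continue
        perm = within_pair_permutation_p(
            idx, target_prop_values, case_idx, control_idx, cap=cap, rng=rng
        )
        out.append(ProjectionResult(chrom, int(start), int(end), True, len(idx), perm))
    return out


def directional_consistency(delta_a, delta_b) -> float:
    """Sign-agreement ratio between two aligned difference vectors.

    ratio = #(sign(a) == sign(b), both nonzero) / #(both nonzero); pairs
    where either difference is exactly zero are excluded from the
    denominator.  Raises on an empty denominator.
    """
    a = np.asarray(delta_a, float)
    b = np.asarray(delta_b, float)
    if a.shape != b.shape:
        raise ValueError("difference vectors must align")
    both = (a != 0) & (b != 0)
    if not both.any():
        raise ValueError("no pairs with both differences nonzero; ratio undefined")
    return float(np.mean(np.sign(a[both]) == np.sign(b[both])))


def irwin_hall_cdf(s: float, k: int) -> float:
    """P(U_1 + ... + U_k <= s) for iid Uniform(0,1), inclusion-exclusion form.

    Valid for all s in [0, k]; exact for the small k used in p-value
    combination.
    """
    if s <= 0:
        return 0.0
    if s >= k:
        return 1.0
    total = 0.0
    for j in range(int(math.floor(s)) + 1):
        total += (-1) ** j * math.comb(k, j) * (s - j) ** k
    return total / math.factorial(k)


def meta_sum_p(p_values) -> float:
    """Edgington's summation-of-p combined p-value.

    combined p = P(sum of k iid Uniform(0,1) <= sum(p_i)), the Irwin-Hall
    CDF at S = sum(p_i).  Monotone in every input.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1 or len(p) < 1:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return float(irwin_hall_cdf(float(p.sum()), len(p)))


def meta_fixed_effect(effects, ses) -> MetaResult:
    """Inverse-variance fixed-effect meta-analysis with Cochran's Q.

    weights w_i = 1/se_i^2; combined effect = sum(w e)/sum(w);
    se = sum(w)^(-1/2); two-sided normal p; Q = sum w_i (e_i - e_bar)^2
    with a chi-square(k-1) homogeneity p-value.
    """
    e = np.asarray(effects, float)
    s = np.asarray(ses, float)
    if len(e) != len(s) or len(e) < 2:
        raise ValueError("need >= 2 studies with matching effects and ses")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    combined = float(np.sum(w * e) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = combined / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (e - combined) ** 2))
    q_p = float(stats.chi2.sf(q, len(e) - 1))
    return MetaResult(effect=combined, se=se, z=float(z), p=p, q_stat=q, q_p=q_p, k=len(e))


def covariate_association(dmr_values, covariate, dmr_id: str = "", name: str = "") -> CovariateResult:
    """Simple linear regression of DMR methylation summaries on a covariate.

    Tests H0: slope = 0 with the two-sided t-test.  Binary covariates must
    be encoded 0/1 by the caller; constant covariates are rejected.
    """
    y = np.asarray(dmr_values, float)
    x = np.asarray(covariate, float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need n >= 3 aligned observations")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: slope not identifiable")
    fit = stats.linregress(x, y)
    return CovariateResult(dmr_id=dmr_id, covariate=name, slope=float(fit.slope), p=float(fit.pvalue))


def ks_compare_differences(diffs_a, diffs_b):
    """Two-sample Kolmogorov-Smirnov comparison of difference distributions.

    Used to check whether within-pair methylation differences distribute
    differently between sample subgroups (e.g. female vs male pairs).
    Returns (statistic, asymptotic p).
    """
    a = np.asarray(diffs_a, float)
    b = np.asarray(diffs_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
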