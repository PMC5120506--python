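"""Within-pair sign-flip permutation p-values and stratified bootstrap FWER.

Small discordant-twin cohorts are vulnerable to two failure modes this
module addresses:

1. *Outlier-driven candidates*: a single twin pair with an extreme local
   difference can dominate a region statistic.  Each candidate therefore
   gets a within-pair sign-flip permutation p-value: per sample the average
   (or maximum) methylation over the candidate's probes is summarized, the
   statistic is the mean over pairs of (case - control) summaries, and the
   null enumerates all 2^n within-pair label assignments (n pairs; 32 for 5
   pairs, 128 for 7).  Candidates with permuted p > 0.1 for BOTH statistics
   are excluded - in the discovery run and inside every bootstrap iteration,
   so the null distribution is filtered the same way as the observed one.

2. *Probe-count selection bias*: raw area-based ranking favors long
   regions.  The family-wise error rate is therefore estimated per
   statistic (avg, max, area_raw) against per-iteration maxima of null
   candidates with a *similar number of probes* (probe-count strata).

The null is generated by a residual bootstrap under the no-phenotype model
(default) or by within-pair label permutation, and the full candidate
pipeline - smoothing, cutoff, permutation filter - is re-run per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dmr import CandidateDMR, ProbeModelFit, resolve_cutoff, _candidate_runs
from .matrix import inverse_m_transform
from .smoothing import smooth_within_regions

STATISTICS = ("avg", "max", "area_raw")


@dataclass
class PermutationResult:
    p_avg: float
    p_max: float
    n_permutations: int
    exhaustive: bool

    def __post_init__(self):
        for p in (self.p_avg, self.p_max):
            if not 0 < p <= 1:
                raise ValueError("permutation p must lie in (0, 1]")


@dataclass
class FWERResult:
    fwer: dict  # statistic name -> FWER estimate in [0, 1]
    below_resolution: dict  # statistic name -> True when FWER = 0 (< 1/B)
    stratum: int
    B: int


@dataclass
class DMRCall:
    candidate: CandidateDMR
    passed: bool
    reasons: list = field(default_factory=list)

    @property
    def best_fwer(self) -> float:
        return min(self.candidate.fwer.fwer.values())


def pair_differences(
    probe_index: np.ndarray,
    prop_values: np.ndarray,
    case_idx: np.ndarray,
    control_idx: np.ndarray,
    summary: str,
) -> np.ndarray:
    """Per-pair difference of the sample-level summary over a candidate.

    ``summary`` is ``"avg"`` (per-sample mean over the candidate's probes)
    or ``"max"`` (per-sample maximum).
    """
    block = prop_values[probe_index]
    if summary == "avg":
        s = block.mean(axis=0)
    elif summary == "max":
        s = block.max(axis=0)
    else:
        raise ValueError(f"unknown summary {summary!r}")
    return s[case_idx] - s[control_idx]


def sign_flip_pvalue(
    d: np.ndarray, cap: int = 4096, rng: np.random.Generator | None = None
) -> tuple[float, int, bool]:
    """Two-sided sign-flip p-value for the mean of per-pair differences.

    All 2^n sign assignments are enumerated when 2^n <= cap (identity
    included, denominator 2^n); otherwise ``cap`` Monte-Carlo assignments
    are drawn (identity included), requiring ``rng``.

    Returns (p, n_assignments, exhaustive).
    """
    d = np.asarray(d, float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    obs = abs(d.mean())
    if 2**n <= cap:
        bits = np.arange(2**n, dtype=np.int64)
        signs = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)) & 1)
        stats = signs @ d / n
        count = int(np.sum(np.abs(stats) >= obs * (1 - 1e-12)))
        return count / 2**n, 2**n, True
    if rng is None:
        raise ValueError("Monte-Carlo permutation requires an rng")
    signs = rng.integers(0, 2, size=(cap - 1, n)) * 2.0 - 1.0
    stats = signs @ d / n
    count = 1 + int(np.sum(np.abs(stats) >= obs * (1 - 1e-12)))  # identity included
    return count / cap, cap, False


def within_pair_permutation_p(
    probe_index: np.ndarray,
    prop_values: np.ndarray,
    case_idx: np.ndarray,
    control_idx: np.ndarray,
    cap: int = 4096,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Permutation p-values (avg- and max-summary) for one candidate."""
    if len(probe_index) == 0:
        raise ValueError("candidate has no probes")
    d_avg = pair_differences(probe_index, prop_values, case_idx, control_idx, "avg")
    d_max = pair_differences(probe_index, prop_values, case_idx, control_idx, "max")
    p_avg, n_perm, exhaustive = sign_flip_pvalue(d_avg, cap=cap, rng=rng)
    p_max, _, _ = sign_flip_pvalue(d_max, cap=cap, rng=rng)
    return PermutationResult(p_avg=p_avg, p_max=p_max, n_permutations=n_perm, exhaustive=exhaustive)


def permutation_filter(candidates: list[CandidateDMR], threshold: float = 0.1):
    """Split candidates into (retained, excluded, reasons).

    A candidate is excluded iff its permuted p exceeds the threshold for
    BOTH statistics (average and maximum) - the conjunction rule.
    """
    retained, excluded, reasons = [], [], {}
    for cand in candidates:
        if cand.perm is None:
            raise ValueError("permutation results must be attached before filtering")
        if cand.perm.p_avg > threshold and cand.perm.p_max > threshold:
            excluded.append(cand)
            reasons[id(cand)] = (
                f"permuted p > {threshold} for both statistics "
                f"(p_avg={cand.perm.p_avg:.4g}, p_max={cand.perm.p_max:.4g})"
            )
        else:
            retained.append(cand)
    return retained, excluded, reasons


def _null_candidate_stats(
    m_null: np.ndarray,
    extract_vector: np.ndarray,
    positions: np.ndarray,
    region_codes: np.ndarray,
    case_idx: np.ndarray,
    control_idx: np.ndarray,
    *,
    span: float,
    smooth_method: str,
    window: int,
    cutoff_quantile: float | None,
    cutoff_abs: float | None,
    min_probes: int,
    max_gap: int,
    perm_threshold: float,
    perm_cap: int,
    rng: np.random.Generator,
) -> list[tuple[int, float, float, float]]:
    """One null iteration: re-run the candidate pipeline, return survivors."""
    coef = m_null @ extract_vector
    smoothed = smooth_within_regions(
        coef, positions, region_codes, span=span, method=smooth_method, window=window
    )
    cutoff = resolve_cutoff(smoothed, cutoff_quantile, cutoff_abs)
    out = []
    for idx in _candidate_runs(smoothed, positions, region_codes, cutoff, min_probes, max_gap):
        prop_block = inverse_m_transform(m_null[idx])
        diff = prop_block[:, case_idx].mean(axis=1) - prop_block[:, control_idx].mean(axis=1)
        avg = float(diff.mean())
        mx = float(diff[np.argmax(np.abs(diff))])
        # permutation filter inside the iteration (anti-inflation)
        d_avg = prop_block.mean(axis=0)[case_idx] - prop_block.mean(axis=0)[control_idx]
        d_max = prop_block.max(axis=0)[case_idx] - prop_block.max(axis=0)[control_idx]
        p_avg, _, _ = sign_flip_pvalue(d_avg, cap=perm_cap, rng=rng)
        p_max, _, _ = sign_flip_pvalue(d_max, cap=perm_cap, rng=rng)
        if p_avg > perm_threshold and p_max > perm_threshold:
            continue
        out.append((len(idx), avg, mx, len(idx) * avg))
    return out


def bootstrap_null(
    fit: ProbeModelFit,
    positions: np.ndarray,
    region_codes: np.ndarray,
    case_idx: np.ndarray,
    control_idx: np.ndarray,
    B: int = 2000,
    scheme: str = "residual",
    seed: int = 0,
    *,
    span: float = 0.3,
    smooth_method: str = "loess",
    window: int = 3,
    cutoff_quantile: float | None = 0.995,
    cutoff_abs: float | None = None,
    min_probes: int = 3,
    max_gap: int = 300,
    perm_threshold: float = 0.1,
    perm_cap: int = 4096,
    apply_perm_filter: bool = True,
) -> list[list[tuple[int, float, float, float]]]:
    """Null statistic pool: per iteration, the filter-surviving candidates.

    Schemes
    -------
    ``residual`` (default)
        Fit the null model (no phenotype term), resample residual *columns*
        with replacement, add to the null fitted values.
    ``pairflip``
        Swap case/control columns within a random subset of pairs.

    Returns a list of B iterations, each a list of
    ``(nprobes, avg, max, area_raw)`` tuples.  ``apply_perm_filter=False``
    disables the in-iteration permutation filter (for studying its effect
    on FWER inflation); the default matches the discovery pipeline.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if scheme not in ("residual", "pairflip"):
        raise ValueError(f"unknown null scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    n_samples = fit.residuals_null.shape[1]
    m_obs = fit.fitted_null + fit.residuals_null
    pool = []
    kwargs = dict(
        span=span,
        smooth_method=smooth_method,
        window=window,
        cutoff_quantile=cutoff_quantile,
        cutoff_abs=cutoff_abs,
        min_probes=min_probes,
        max_gap=max_gap,
        perm_threshold=perm_threshold if apply_perm_filter else np.inf,
        perm_cap=perm_cap,
        rng=rng,
    )
    for _ in range(B):
        if scheme == "residual":
            cols = rng.integers(0, n_samples, size=n_samples)
            m_null = fit.fitted_null + fit.residuals_null[:, cols]
        else:
            order = np.arange(n_samples)
            for c, k in zip(case_idx, control_idx):
                if rng.integers(0, 2):
                    order[c], order[k] = order[k], order[c]
            m_null = m_obs[:, order]
        try:
            stats = _null_candidate_stats(
                m_null, fit.extract_vector, positions, region_codes, case_idx, control_idx, **kwargs
            )
        except Exception:  # a failed iteration counts toward B as empty
            import warnings

            warnings.warn("null iteration failed; recorded as empty", RuntimeWarning)
            stats = []
        pool.append(stats)
    return pool


def _quartile_strata(null_nprobes: np.ndarray, min_per_bin: int = 20) -> np.ndarray:
    """Stratum edges from quartiles of null probe counts, merging thin bins.

    Returns interior edges e (bins: nprobes <= e[0], e[0] < nprobes <= e[1],
    ...); an empty array means a single stratum.
    """
    if len(null_nprobes) == 0:
        return np.array([])
    edges = np.unique(np.quantile(null_nprobes, [0.25, 0.5, 0.75])).astype(float)
    while len(edges):
        bins = np.searchsorted(edges, null_nprobes, side="left")
        counts = np.bincount(bins, minlength=len(edges) + 1)
        thin = np.flatnonzero(counts < min_per_bin)
        if len(thin) == 0:
            break
        b = thin[0]
        # merge the thin bin into its nearest neighbour by dropping an edge
        drop = b - 1 if b == len(edges) else b
        edges = np.delete(edges, drop)
    return edges


def stratified_fwer(
    candidates: list[CandidateDMR],
    null_pool: list[list[tuple[int, float, float, float]]],
    strata_edges: np.ndarray | None = None,
) -> list[FWERResult]:
    """Probe-count-stratified FWER per candidate and per statistic.

    For candidate statistic s in its stratum:
    ``FWER_s = #{iterations whose max |s| over in-stratum null candidates
    >= |s_obs|} / B``; iterations with no in-stratum null candidate
    contribute a maximum of 0.  Results are attached to each candidate
    (``cand.fwer``) and returned in candidate order.

    ``strata_edges`` overrides the default quartile binning of the null
    candidates' probe counts (bins with < 20 null observations are merged
    into their nearest neighbor).
    """
    B = len(null_pool)
    if B == 0:
        raise ValueError("empty null pool")
    flat = [(it, n, a, m, ar) for it, stats in enumerate(null_pool) for (n, a, m, ar) in stats]
    null_np = np.array([f[1] for f in flat], dtype=float)
    if strata_edges is None:
        edges = _quartile_strata(null_np)
    else:
        edges = np.asarray(strata_edges, float)
    n_strata = len(edges) + 1

    # per-stratum, per-iteration maxima of |avg|, |max|, |area|
    maxima = np.zeros((n_strata, B, 3))
    if flat:
        bins = np.searchsorted(edges, null_np, side="left")
        iters = np.array([f[0] for f in flat])
        vals = np.abs(np.array([[f[2], f[3], f[4]] for f in flat]))
        for s in range(3):
            np.maximum.at(maxima[:, :, s], (bins, iters), vals[:, s])

    results = []
    for cand in candidates:
        stratum = int(np.searchsorted(edges, cand.nprobes, side="left"))
        fwer, below = {}, {}
        for s, name in enumerate(STATISTICS):
            obs = abs(getattr(cand, name if name != "area_raw" else "area_raw"))
            f = float(np.mean(maxima[stratum, :, s] >= obs))
            fwer[name] = f
            below[name] = f == 0.0
        res = FWERResult(fwer=fwer, below_resolution=below, stratum=stratum, B=B)
        cand.fwer = res
        results.append(res)
    return results


def call_dmrs(
    candidates: list[CandidateDMR],
    fwer_threshold: float = 0.10,
    perm_threshold: float = 0.1,
) -> list[DMRCall]:
    """The dual-criterion DMR call.

    A candidate passes iff (a) its FWER is <= ``fwer_threshold`` for at
    least one of the three statistics, and (b) its permutation criterion
    holds: min(p_avg, p_max) < ``perm_threshold``.  Calls are sorted by best
    FWER, then genomic position.
    """
    calls = []
    for cand in candidates:
        if cand.fwer is None or cand.perm is None:
            raise ValueError("candidates need FWER and permutation results attached")
        reasons = []
        best = min(cand.fwer.fwer.values())
        fwer_ok = best <= fwer_threshold
        perm_ok = min(cand.perm.p_avg, cand.perm.p_max) < perm_threshold
        if not fwer_ok:
            reasons.append(f"min FWER {best:.4g} > {fwer_threshold}")
        if not perm_ok:
            reasons.append(
                f"min permuted p {min(cand.perm.p_avg, cand.perm.p_max):.4g} >= {perm_threshold}"
            )
        calls.append(DMRCall(candidate=cand, passed=fwer_ok and perm_ok, reasons=reasons))
    calls.sort(key=lambda c: (c.best_fwer, c.candidate.chrom, c.candidate.start))
    return calls
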