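"""Reference-based cell-type deconvolution for whole-blood methylation.

Bulk blood methylation mixes cell-type-specific profiles, so phenotype
contrasts confound with composition shifts.  Following the
reference-based approach of Houseman-style deconvolution adapted to a
tiling array, the stages are:

1. marker discovery - one-vs-rest candidate DMRs per sorted cell type,
   pooled and deduplicated (interval union);
2. profile averaging - reference matrix B[k, m] = mean methylation of cell
   type k over marker m's probes (averaged over replicates);
3. informative-marker selection - per-marker one-way F statistic on
   cell-type indicators, keep the top k (default 300);
4. per-sample quadratic program - w = argmin ||x - B'w||^2 subject to
   w >= 0 and sum(w) = 1, solved exactly by active-set enumeration.

The derived model covariates are (neutrophil %, NK %, CD4 + CD8 %): three
of the four proportions, avoiding collinearity with the model intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .design import ArrayDesign
from .dmr import find_candidates, smooth_coefficients
from .matrix import MethylationMatrix


@dataclass
class MarkerInterval:
    chrom: str
    start: int
    end: int
    region_id: int
    probe_ids: np.ndarray


@dataclass
class CellReferenceProfile:
    markers: list[MarkerInterval]
    B: pd.DataFrame  # cell types x markers, entries in [0, 1]
    scores: np.ndarray | None = None  # per-marker informativeness (F statistic)

    def __post_init__(self):
        vals = self.B.to_numpy(float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("reference entries must lie in [0, 1]")


@dataclass
class ProportionEstimate:
    w: pd.DataFrame  # samples x cell types, simplex rows
    residual_norm: pd.Series

    def __post_init__(self):
        vals = self.w.to_numpy(float)
        if np.any(vals < -1e-8) or np.any(np.abs(vals.sum(axis=1) - 1) > 1e-8):
            raise ValueError("proportions must be non-negative and sum to 1")


def find_cell_type_dmrs(
    sorted_meth: MethylationMatrix,
    cell_labels: list[str],
    design: ArrayDesign,
    cutoff_abs: float = 0.1,
    min_probes: int = 2,
    max_gap: int = 300,
    span: float = 0.3,
    cell_types: list[str] | None = None,
) -> list[MarkerInterval]:
    """One-vs-rest marker discovery over all cell types, pooled.

    For each cell type the per-probe mean difference (that type vs the rest,
    proportion scale) is smoothed within regions and thresholded at
    ``cutoff_abs`` - a lowered absolute cutoff, since sorted-cell contrasts
    are large.  Overlapping candidates from different contrasts are merged
    into their interval union.  ``cell_types`` restricts/validates the
    contrast set; by default every distinct label is contrasted.
    """
    labels = np.asarray(cell_labels)
    types = list(dict.fromkeys(cell_types if cell_types is not None else cell_labels))
    missing = [ct for ct in types if ct not in labels]
    if missing:
        raise ValueError(f"cell types absent from labels: {missing}")
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    probe_ids, chroms, positions, region_codes = design.analysis_arrays()
    region_ids = design.analysis_table()["region_id"].to_numpy()
    meth = sorted_meth.reindex(probe_ids)
    vals = meth.values

    intervals = []
    for ct in types:
        in_type = labels == ct
        if in_type.sum() < 2:
            import warnings

            warnings.warn(f"fewer than 2 replicates for cell type {ct!r}", RuntimeWarning)
        if not in_type.any():
            raise ValueError(f"cell type {ct!r} absent from labels")
        diff = vals[:, in_type].mean(axis=1) - vals[:, ~in_type].mean(axis=1)
        smoothed = smooth_coefficients(diff, positions, region_codes, span=span)
        case_idx = np.flatnonzero(in_type)
        control_idx = np.flatnonzero(~in_type)
        cands = find_candidates(
            smoothed,
            vals,
            positions,
            region_codes,
            chroms,
            region_ids,
            case_idx,
            control_idx,
            cutoff_quantile=None,
            cutoff_abs=cutoff_abs,
            min_probes=min_probes,
            max_gap=max_gap,
        )
        for c in cands:
            intervals.append((c.chrom, c.start, c.end, c.region_id))

    # pool + deduplicate: union of overlapping intervals per chromosome
    merged = []
    for chrom in sorted({iv[0] for iv in intervals}):
        ivs = sorted((s, e, r) for c, s, e, r in intervals if c == chrom)
        cur = None
        for s, e, r in ivs:
            if cur is None or s > cur[1]:
                if cur is not None:
                    merged.append((chrom, *cur))
                cur = [s, e, r]
            else:
                cur[1] = max(cur[1], e)
        if cur is not None:
            merged.append((chrom, *cur))

    probe_pos = dict(zip(probe_ids, positions))
    probe_chrom = dict(zip(probe_ids, chroms))
    out = []
    for chrom, s, e, r in merged:
        pids = np.array(
            [p for p in probe_ids if probe_chrom[p] == chrom and s <= probe_pos[p] <= e]
        )
        if len(pids) >= 2:
            out.append(MarkerInterval(chrom=chrom, start=s, end=e, region_id=r, probe_ids=pids))
    return out


def build_reference(
    sorted_meth: MethylationMatrix, markers: list[MarkerInterval], cell_labels: list[str]
) -> CellReferenceProfile:
    """Average methylation per cell type over each marker's probes."""
    if not markers:
        raise ValueError("markers must be non-empty")
    labels = np.asarray(cell_labels)
    types = list(dict.fromkeys(cell_labels))
    kept, cols = [], []
    for i, mk in enumerate(markers):
        present = [p for p in mk.probe_ids if p in sorted_meth.data.index]
        if not present:
            import warnings

            warnings.warn(f"marker {i} has no surviving probes; dropped", RuntimeWarning)
            continue
        block = sorted_meth.data.loc[present]
        col = [float(block.loc[:, labels == ct].to_numpy().mean()) for ct in types]
        kept.append(mk)
        cols.append(col)
    B = pd.DataFrame(
        np.array(cols).T, index=types, columns=[f"m{i}" for i in range(len(kept))]
    )
    return CellReferenceProfile(markers=kept, B=B)


def select_informative(
    reference: CellReferenceProfile,
    sorted_meth: MethylationMatrix,
    cell_labels: list[str],
    k: int = 300,
) -> CellReferenceProfile:
    """Keep the k most informative markers by one-way F statistic.

    Each marker's per-sample mean methylation is regressed on cell-type
    indicators; markers are ranked by the resulting F statistic (one-way
    ANOVA across cell types), ties broken by genomic order.
    """
    labels = np.asarray(cell_labels)
    types = list(dict.fromkeys(cell_labels))
    scores = []
    for mk in reference.markers:
        present = [p for p in mk.probe_ids if p in sorted_meth.data.index]
        x = sorted_meth.data.loc[present].to_numpy().mean(axis=0)
        groups = [x[labels == ct] for ct in types]
        if all(len(g) for g in groups) and np.ptp(x) > 0:
            f, _ = stats.f_oneway(*groups)
            scores.append(float(f) if np.isfinite(f) else np.inf)
        else:
            scores.append(0.0)
    scores = np.asarray(scores)
    if k >= len(reference.markers):
        if k > len(reference.markers):
            import warnings

            warnings.warn("k exceeds marker count; keeping all markers", RuntimeWarning)
        return CellReferenceProfile(
            markers=reference.markers, B=reference.B.copy(), scores=scores
        )
    # sort by descending score, ties by genomic order (stable sort on -score)
    order = np.argsort(-scores, kind="mergesort")[:k]
    order = np.sort(order)  # restore genomic order among the selected
    markers = [reference.markers[i] for i in order]
    B = reference.B.iloc[:, order]
    B.columns = [f"m{i}" for i in range(len(markers))]
    return CellReferenceProfile(markers=markers, B=B, scores=scores[order])


def marker_means(meth: MethylationMatrix, markers: list[MarkerInterval]) -> pd.DataFrame:
    """Samples x markers matrix of mean methylation over each marker's probes.

    Markers whose probes are all absent from the matrix yield NaN columns
    (dropped pairwise during the QP fit).
    """
    cols = {}
    for i, mk in enumerate(markers):
        present = [p for p in mk.probe_ids if p in meth.data.index]
        cols[f"m{i}"] = (
            meth.data.loc[present].mean(axis=0) if present else pd.Series(np.nan, index=meth.data.columns)
        )
    return pd.DataFrame(cols)


def solve_simplex_qp(B: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact simplex-constrained least squares by active-set enumeration.

    Minimizes ||x - B'w||^2 over w >= 0, sum(w) = 1.  For each non-empty
    support S the equality-constrained KKT system is solved; the feasible
    solution with the smallest objective is the global optimum (the true
    active set is among the enumerated supports).  Deterministic; intended
    for small numbers of cell types (K <= ~10).
    """
    K = B.shape[0]
    best_w, best_obj = None, np.inf
    G = B @ B.T  # K x K Gram
    b = B @ x
    for size in range(1, K + 1):
        for S in combinations(range(K), size):
            S = list(S)
            A = np.zeros((size + 1, size + 1))
            A[:size, :size] = 2.0 * G[np.ix_(S, S)]
            A[:size, size] = 1.0
            A[size, :size] = 1.0
            rhs = np.concatenate([2.0 * b[S], [1.0]])
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            ws = sol[:size]
            if np.any(ws < -1e-10):
                continue
            w = np.zeros(K)
            w[S] = np.clip(ws, 0.0, None)
            w /= w.sum()
            obj = float(np.sum((x - B.T @ w) ** 2))
            if obj < best_obj - 1e-15:
                best_obj, best_w = obj, w
    return best_w, float(np.sqrt(best_obj))


def estimate_proportions(
    sample_means: pd.DataFrame, reference: CellReferenceProfile
) -> ProportionEstimate:
    """Per-sample cell proportions via the simplex-constrained QP.

    ``sample_means`` is samples x markers (see :func:`marker_means`), aligned
    to ``reference.B``'s columns; markers missing (NaN) in a sample are
    dropped pairwise.  Requires at least as many usable markers as cell
    types, else the fit is underdetermined and rejected.
    """
    Bfull = reference.B.to_numpy(float)
    K = Bfull.shape[0]
    rows, resid = {}, {}
    for sid, x in sample_means.iterrows():
        xv = x.to_numpy(float)
        ok = np.isfinite(xv)
        if ok.sum() < K:
            raise ValueError(
                f"sample {sid!r}: only {int(ok.sum())} usable markers for {K} cell types"
            )
        w, r = solve_simplex_qp(Bfull[:, ok], xv[ok])
        rows[sid] = w
        resid[sid] = r
    w_df = pd.DataFrame.from_dict(rows, orient="index", columns=list(reference.B.index))
    return ProportionEstimate(w=w_df, residual_norm=pd.Series(resid))


def proportion_covariates(
    w: pd.DataFrame,
    mapping: dict[str, str] | None = None,
) -> pd.DataFrame:
    """The three model covariates: (neutrophil, NK, CD4 + CD8 T).

    ``mapping`` maps the reference's cell-type names onto the roles
    ``neutrophil``, ``NK``, ``CD4``, ``CD8`` when nonstandard names are
    used; with the default panel names it is inferred.
    """
    if mapping is None:
        mapping = {}
        for col in w.columns:
            c = col.lower()
            if "neut" in c:
                mapping[col] = "neutrophil"
            elif "nk" in c or "cd56" in c:
                mapping[col] = "NK"
            elif "cd4" in c:
                mapping[col] = "CD4"
            elif "cd8" in c:
                mapping[col] = "CD8"
        if set(mapping.values()) != {"neutrophil", "NK", "CD4", "CD8"}:
            raise ValueError(
                "cannot infer cell-type roles from column names; supply a mapping"
            )
    roles = {role: col for col, role in mapping.items()}
    out = pd.DataFrame(
        {
            "neutrophil": w[roles["neutrophil"]],
            "NK": w[roles["NK"]],
            "T": w[roles["CD4"]] + w[roles["CD8"]],
        }
    )
    return out


def compare_proportions(
    w: pd.DataFrame, case_ids: list[str], control_ids: list[str]
) -> pd.DataFrame:
    """Paired t-test of within-pair proportion differences per cell type.

    ``case_ids[i]`` and ``control_ids[i]`` are the twins of pair i.  Returns
    per cell type the mean difference, t statistic and two-sided p; for
    zero-variance differences (degenerate t) the policy is p = 1.
    """
    if len(case_ids) != len(control_ids) or len(case_ids) < 2:
        raise ValueError("need >= 2 complete pairs")
    rows = []
    for ct in w.columns:
        d = w.loc[case_ids, ct].to_numpy() - w.loc[control_ids, ct].to_numpy()
        if d.std(ddof=1) == 0.0:
            # degenerate t: all differences identical
            if d[0] == 0.0:
                t, p = 0.0, 1.0
            else:
                t, p = float(np.sign(d[0])) * np.inf, 0.0
        else:
            t, p = stats.ttest_rel(
                w.loc[case_ids, ct].to_numpy(), w.loc[control_ids, ct].to_numpy()
            )
        rows.append(dict(cell_type=ct, mean_diff=float(np.mean(d)), t=float(t), p=float(p)))
    return pd.DataFrame(rows).set_index("cell_type")
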