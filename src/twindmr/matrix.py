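"""Methylation matrix container and the M-value transform.

Methylation proportions (beta values) live in [0, 1]; linear modeling runs on
M-values, the log2-odds transform M = log2(p / (1 - p)), which is closer to
homoscedastic.  Proportions are clamped to [eps, 1 - eps] before the
transform so M stays finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_EPS = 0.01


def m_transform(p, eps: float = DEFAULT_EPS):
    """M-value transform: log2(clamp(p)/(1 - clamp(p))).

    Parameters
    ----------
    p : array-like of proportions in [0, 1]
    eps : clamp in (0, 0.5); p is clipped to [eps, 1 - eps]
    """
    if not 0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    pc = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return np.log2(pc / (1.0 - pc))


def inverse_m_transform(m):
    """Inverse of :func:`m_transform` (no clamping): p = 2^M / (1 + 2^M)."""
    x = np.exp2(np.asarray(m, dtype=float))
    return x / (1.0 + x)


class MethylationMatrix:
    """Probe x sample matrix of methylation proportions.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by probe_id, columns by sample_id, values in [0, 1].
        NaN marks missing probe measurements.
    """

    def __init__(self, data: pd.DataFrame):
        vals = data.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            bad = np.argwhere(~np.isnan(vals) & ((vals < 0) | (vals > 1)))[0]
            raise ValueError(
                f"methylation proportions outside [0,1] at probe "
                f"{data.index[bad[0]]!r}, sample {data.columns[bad[1]]!r}"
            )
        if data.index.duplicated().any():
            raise ValueError("duplicate probe ids in methylation matrix")
        self.data = data.astype(float)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data.columns.to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def m_values(self, eps: float = DEFAULT_EPS) -> np.ndarray:
        return m_transform(self.values, eps=eps)

    def reindex(self, probe_ids) -> "MethylationMatrix":
        missing = set(probe_ids) - set(self.data.index)
        if missing:
            raise KeyError(f"{len(missing)} probes absent from matrix, e.g. {sorted(missing)[:3]}")
        return MethylationMatrix(self.data.loc[list(probe_ids)])

    def drop_incomplete(self) -> "MethylationMatrix":
        """Drop probes missing in any sample (complete-case modeling policy)."""
        keep = ~self.data.isna().any(axis=1)
        return MethylationMatrix(self.data.loc[keep])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MethylationMatrix({self.data.shape[0]} probes x {self.data.shape[1]} samples)"
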