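"""Functional network connectivity: Pearson FNC, proportional thresholding,
group summaries and cell-wise group comparison.

The FNC matrix is the C x C Pearson correlation of component time courses.
Proportional thresholding (PT) keeps a fixed fraction ``pt`` of the
strongest edges: the ``round(pt * C*(C-1)/2)`` upper-triangle entries with
largest |r|, signed weights preserved. Ranking by magnitude (rather than
signed value) retains strong negative coupling; ties at the cut are broken
by (row, column) index so the retained edge set is deterministic.

Cell-wise group tests are run on Fisher-z-transformed correlations
(variance stabilization) with Benjamini-Hochberg FDR over the upper
triangle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyGraphError, UndefinedCorrelationError

_ATANH_CLIP = 1.0 - 1e-7


def _as_matrix(x) -> np.ndarray:
    return x.to_numpy() if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)


def pearson_fnc(tc) -> np.ndarray:
    """Pearson correlation matrix of a T x C time-course table.

    Raises
    ------
    UndefinedCorrelationError
        If any column is constant, naming the offending component.
    """
    if isinstance(tc, pd.DataFrame):
        cols = list(tc.columns)
        x = tc.to_numpy(dtype=float)
    else:
        x = np.asarray(tc, dtype=float)
        cols = list(range(x.shape[1]))
    if x.ndim != 2 or x.shape[0] < 10:
        raise ValueError("time-course table must be T x C with T >= 10")
    if np.isnan(x).any():
        raise ValueError("time-course table contains missing values")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [cols[i] for i in np.flatnonzero(sd == 0)]
        raise UndefinedCorrelationError(f"constant time course for component(s) {bad}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def n_retained_edges(n_components: int, pt: float) -> int:
    """Number of upper-triangle edges kept at retention fraction ``pt``."""
    return int(round(pt * n_components * (n_components - 1) / 2))


def proportional_threshold(fnc, pt: float) -> np.ndarray:
    """Keep the strongest-|r| fraction ``pt`` of edges, zero the rest.

    Returns the symmetric signed weight matrix with zero diagonal whose
    upper triangle has exactly ``n_retained_edges(C, pt)`` nonzeros.
    """
    if not 0 < pt <= 1:
        raise ValueError(f"retention fraction must lie in (0, 1], got {pt}")
    r = _as_matrix(fnc)
    c = r.shape[0]
    m = n_retained_edges(c, pt)
    if m == 0:
        raise EmptyGraphError(f"pt={pt} retains zero of {c*(c-1)//2} edges")

    rows, cols = np.triu_indices(c, k=1)
    vals = r[rows, cols]
    # primary key |r| descending; ties broken by (row, col) ascending
    order = np.lexsort((cols, rows, -np.abs(vals)))
    keep = order[:m]
    w = np.zeros_like(r)
    w[rows[keep], cols[keep]] = vals[keep]
    w = w + w.T
    return w


def group_mean_fnc(fncs: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean over a stack of equally sized FNC matrices."""
    if len(fncs) == 0:
        raise ValueError("need at least one FNC matrix")
    mats = [_as_matrix(f) for f in fncs]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("FNC matrices differ in shape")
    return np.mean(mats, axis=0)


@dataclass
class CellwiseComparison:
    """Upper-triangle two-sample comparison of FNC cells between groups."""

    t: np.ndarray            # C x C symmetric, nan on diagonal/excluded cells
    p: np.ndarray
    significant: np.ndarray  # boolean mask after BH-FDR
    excluded: np.ndarray     # cells with zero variance in both groups
    fdr_q: float

    def to_frame(self, component_ids: Optional[Sequence] = None) -> pd.DataFrame:
        c = self.t.shape[0]
        ids = list(component_ids) if component_ids is not None else list(range(c))
        rows, cols = np.triu_indices(c, k=1)
        return pd.DataFrame({
            "component_a": [ids[i] for i in rows],
            "component_b": [ids[j] for j in cols],
            "t": self.t[rows, cols],
            "p": self.p[rows, cols],
            "significant": self.significant[rows, cols],
        })


def cellwise_group_ttest(group_a: Sequence[np.ndarray],
                         group_b: Sequence[np.ndarray],
                         fdr_q: float = 0.05) -> CellwiseComparison:
    """Two-sample t-test per FNC cell, on Fisher-z values, BH-corrected.

    Cells with zero variance in both groups are flagged and excluded from
    the FDR family rather than silently reported.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    a = np.stack([_as_matrix(f) for f in group_a])
    b = np.stack([_as_matrix(f) for f in group_b])
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("FNC matrices differ in shape between groups")
    c = a.shape[1]
    rows, cols = np.triu_indices(c, k=1)
    za = np.arctanh(np.clip(a[:, rows, cols], -_ATANH_CLIP, _ATANH_CLIP))
    zb = np.arctanh(np.clip(b[:, rows, cols], -_ATANH_CLIP, _ATANH_CLIP))

    degenerate = (za.std(axis=0) == 0) & (zb.std(axis=0) == 0)
    identical_means = degenerate & (za.mean(axis=0) == zb.mean(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_flat, p_flat = stats.ttest_ind(za, zb, axis=0)
    t_flat = np.where(identical_means, 0.0, t_flat)
    p_flat = np.where(identical_means, 1.0, p_flat)
    excluded_flat = degenerate & ~identical_means  # undefined t

    sig_flat = np.zeros(rows.size, dtype=bool)
    valid = ~excluded_flat & np.isfinite(p_flat)
    if valid.any():
        sig_flat[valid] = multipletests(p_flat[valid], alpha=fdr_q,
                                        method="fdr_bh")[0]

    def _square(flat):
        m = (np.zeros((c, c), dtype=bool) if flat.dtype == bool
             else np.full((c, c), np.nan))
        m[rows, cols] = flat
        m[cols, rows] = flat
        return m

    return CellwiseComparison(
        t=_square(np.where(excluded_flat, np.nan, t_flat)),
        p=_square(np.where(excluded_flat, np.nan, p_flat)),
        significant=_square(sig_flat),
        excluded=_square(excluded_flat),
        fdr_q=fdr_q,
    )
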