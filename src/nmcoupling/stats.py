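"""Node-metric coupling (NMC) statistics.

NMC is the Pearson correlation, taken **across subjects within a group**,
between a component's node size and a graph metric. For the three nodal
metrics the pairing is (size of component c, metric at component c); for
the three global metrics it is (size of component c, subject-level global
value). The result is a metrics x components grid per group.

Significance of a single NMC cell uses the t-transform of r
(t = r * sqrt((n-2)/(1-r^2)), df = n-2, two-tailed) with Bonferroni
correction over the whole grid (alpha / (n_metrics * n_components);
0.05/318 for 6 metrics x 53 components). Group differences in NMC use the
Fisher z-test for two independent correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, UndefinedCorrelationError
from .metrics import ALL_METRICS, GLOBAL_METRICS, NODAL_METRICS

DEFAULT_ALPHA = 0.05


def pearson_r(x, y) -> float:
    """Pearson correlation by the textbook formula.

    r = sum((x - xbar)(y - ybar)) / sqrt(sum((x - xbar)^2) sum((y - ybar)^2))

    Requires equal length >= 4 (downstream Fisher-z machinery needs n > 3)
    and two non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    dx = x - x.mean()
    dy = y - y.mean()
    den = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if den == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(np.clip((dx * dy).sum() / den, -1.0, 1.0))


@dataclass
class NMCMatrix:
    """Metrics x components grid of size-metric correlations for one group.

    Undefined cells (a constant size or metric column) are NaN and tracked
    in ``undefined``; they are never silently imputed as zero.
    """

    r: pd.DataFrame          # index = metric names, columns = component ids
    n: int                   # subjects in the group
    group: str
    undefined: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.undefined is None:
            self.undefined = self.r.isna()


def nmc_matrix(sizes: pd.DataFrame, nodal: Mapping[str, pd.DataFrame],
               global_m: pd.DataFrame, group: str,
               subjects: Optional[Sequence[str]] = None) -> NMCMatrix:
    """Correlate node size with each metric across a group's subjects.

    Parameters
    ----------
    sizes
        Subjects x components node-size table (the group's subjects, or a
        superset restricted via ``subjects``).
    nodal
        metric name -> subjects x components table for the nodal metrics.
    global_m
        Subjects x global-metric table.
    subjects
        Restrict all tables to these subject ids (the group membership).
    """
    if subjects is not None:
        subjects = list(subjects)
        for name, tab in [("sizes", sizes), ("global metrics", global_m)]:
            missing = set(subjects) - set(tab.index)
            if missing:
                raise AlignmentError(f"{name} table missing subjects {sorted(missing)}")
        sizes = sizes.loc[subjects]
        global_m = global_m.loc[subjects]
        nodal = {m: t.loc[subjects] for m, t in nodal.items()}
    n = len(sizes)
    if n < 4:
        raise AlignmentError(f"group {group!r} has {n} subjects; need >= 4")

    comps = list(sizes.columns)
    grid = pd.DataFrame(np.nan, index=pd.Index(ALL_METRICS, name="metric"),
                        columns=pd.Index(comps, name="component_id"))
    for metric in NODAL_METRICS:
        tab = nodal[metric]
        if list(tab.columns) != comps or not tab.index.equals(sizes.index):
            raise AlignmentError(f"nodal metric {metric!r} table misaligned with sizes")
        for c in comps:
            grid.loc[metric, c] = _safe_r(sizes[c], tab[c])
    if not global_m.index.equals(sizes.index):
        raise AlignmentError("global metrics table misaligned with sizes")
    for metric in GLOBAL_METRICS:
        gcol = global_m[metric]
        for c in comps:
            grid.loc[metric, c] = _safe_r(sizes[c], gcol)
    return NMCMatrix(r=grid, n=n, group=group)


def _safe_r(x, y) -> float:
    try:
        return pearson_r(np.asarray(x), np.asarray(y))
    except UndefinedCorrelationError:
        return np.nan


def bonferroni_critical_r(n: int, alpha: float = DEFAULT_ALPHA,
                          n_tests: int = 318) -> float:
    """Smallest |r| significant at alpha/n_tests (two-tailed, t-transform).

    Inverts t = r * sqrt((n-2)/(1-r^2)) at the Bonferroni-corrected
    two-tailed t quantile with df = n - 2.
    """
    if n < 4:
        raise ValueError(f"need n >= 4 subjects, got {n}")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    df = n - 2
    t_crit = sps.t.ppf(1.0 - alpha / (2.0 * n_tests), df)
    return float(t_crit / np.sqrt(df + t_crit ** 2))


@dataclass
class SignificanceReport:
    """Bonferroni-calibrated significance of one group's NMC grid."""

    group: str
    n: int
    alpha: float
    n_tests: int
    critical_r: float
    significant: pd.DataFrame        # boolean grid, metrics x components
    counts: pd.Series                # significant components per metric
    n_undefined: int


def significance_counts(nmc: NMCMatrix, alpha: float = DEFAULT_ALPHA,
                        n_tests: Optional[int] = None) -> SignificanceReport:
    """Flag |r| >= critical r and count significant components per metric.

    ``n_tests`` defaults to the grid size (metrics x components).
    """
    if n_tests is None:
        n_tests = int(nmc.r.shape[0] * nmc.r.shape[1])
    crit = bonferroni_critical_r(nmc.n, alpha=alpha, n_tests=n_tests)
    sig = (nmc.r.abs() >= crit) & ~nmc.undefined
    return SignificanceReport(
        group=nmc.group, n=nmc.n, alpha=alpha, n_tests=n_tests,
        critical_r=crit, significant=sig, counts=sig.sum(axis=1),
        n_undefined=int(nmc.undefined.to_numpy().sum()))


def fisher_z_difference(r1: float, n1: int, r2: float, n2: int):
    """Fisher z-test for two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); returns
    (z, two-tailed p).
    """
    if min(n1, n2) < 4:
        raise ValueError("both samples need n >= 4")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| = 1 has an infinite Fisher transform")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class GroupComparison:
    """Cell-wise NMC difference between two groups (Fisher z, Bonferroni)."""

    pair: tuple
    delta_r: pd.DataFrame
    z: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    n_tests: int


def nmc_group_difference(a: NMCMatrix, b: NMCMatrix,
                         alpha: float = DEFAULT_ALPHA,
                         n_tests: Optional[int] = None) -> GroupComparison:
    """Per-cell delta r, Fisher z statistic and Bonferroni-corrected mask."""
    if a.r.shape != b.r.shape:
        raise AlignmentError("NMC grids differ in shape")
    if n_tests is None:
        n_tests = int(a.r.shape[0] * a.r.shape[1])
    ra, rb = a.r.to_numpy(), b.r.to_numpy()
    defined = ~(np.isnan(ra) | np.isnan(rb))
    clip = 1.0 - 1e-12
    se = np.sqrt(1.0 / (a.n - 3) + 1.0 / (b.n - 3))
    with np.errstate(invalid="ignore"):
        z = (np.arctanh(np.clip(ra, -clip, clip))
             - np.arctanh(np.clip(rb, -clip, clip))) / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    sig = defined & (p <= alpha / n_tests)
    wrap = lambda m: pd.DataFrame(m, index=a.r.index, columns=a.r.columns)
    return GroupComparison(
        pair=(a.group, b.group),
        delta_r=wrap(np.where(defined, ra - rb, np.nan)),
        z=wrap(np.where(defined, z, np.nan)),
        p=wrap(np.where(defined, p, np.nan)),
        significant=wrap(sig), alpha=alpha, n_tests=n_tests)


def global_metric_ttest(a: pd.DataFrame, b: pd.DataFrame,
                        fdr_q: float = 0.05,
                        metrics: Sequence[str] = GLOBAL_METRICS) -> pd.DataFrame:
    """Welch two-sample t per global metric with BH-FDR across the family.

    Also reports the mean difference +/- its standard error. Metrics with
    zero variance in both groups are flagged undefined and excluded from
    the FDR family.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    rows = []
    for m in metrics:
        xa, xb = a[m].to_numpy(dtype=float), b[m].to_numpy(dtype=float)
        if xa.std() == 0 and xb.std() == 0:
            if xa.mean() == xb.mean():
                t, p = 0.0, 1.0
            else:
                t, p = np.nan, np.nan
        else:
            t, p = sps.ttest_ind(xa, xb, equal_var=False)
        se = np.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb))
        rows.append({"metric": m, "t": float(t) if np.isfinite(t) else np.nan,
                     "p": float(p) if np.isfinite(p) else np.nan,
                     "mean_diff": float(xa.mean() - xb.mean()),
                     "se": float(se)})
    out = pd.DataFrame(rows).set_index("metric")
    valid = out["p"].notna()
    out["significant"] = False
    if valid.any():
        out.loc[valid, "significant"] = multipletests(
            out.loc[valid, "p"], alpha=fdr_q, method="fdr_bh")[0]
    return out


def global_metric_ttests_all_pairs(tables: Mapping[str, pd.DataFrame],
                                   fdr_q: float = 0.05) -> pd.DataFrame:
    """Welch t-tests over every group pair, BH-FDR across the whole
    metrics x pairs family (the correction the per-pair helper applies
    only within one pair)."""
    groups = list(tables)
    frames = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            f = global_metric_ttest(tables[ga], tables[gb], fdr_q=fdr_q)
            f = f.drop(columns="significant").reset_index()
            f.insert(0, "pair", f"{ga}-{gb}")
            frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    valid = out["p"].notna()
    out["significant"] = False
    if valid.any():
        out.loc[valid, "significant"] = multipletests(
            out.loc[valid, "p"], alpha=fdr_q, method="fdr_bh")[0]
    return out
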