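"""Replicate studies on synthetic cohorts.

These routines run the full analysis chain over many simulated cohorts to
characterize the NMC statistic itself: its false-positive rate when no
size-connectivity coupling exists (null calibration) and its response to a
planted coupling of increasing strength (recovery). They are used both by
the test suite and by the reproduction script.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .config import desk_preset
from .connectivity import n_retained_edges, proportional_threshold
from .pipeline import analyze_cohort
from .synthetic import generate_cohort, generate_spatial_map
from .nodesize import suprathreshold_count


@dataclass
class NullCalibration:
    """Family-wise calibration of NMC significance under no coupling."""

    n_cohorts: int
    n_cells: int            # total (cohort, group, metric, component) cells
    n_exceedances: int      # cells with |r| >= the Bonferroni critical r
    alpha: float
    n_tests: int

    @property
    def observed_rate(self) -> float:
        return self.n_exceedances / self.n_cells

    @property
    def nominal_rate(self) -> float:
        """Per-cell corrected level alpha / n_tests."""
        return self.alpha / self.n_tests


def null_calibration(n_cohorts: int = 50, seed: int = 0,
                     alpha: float = 0.05, pt: float = 0.30) -> NullCalibration:
    """Fraction of null-cohort NMC cells exceeding the critical r.

    Generates ``n_cohorts`` desk-preset cohorts with ``coupling_beta = 0``
    and counts grid cells flagged significant at the Bonferroni-corrected
    level. A calibrated procedure keeps the observed fraction near
    ``alpha / n_tests``.
    """
    exceed = 0
    cells = 0
    n_tests = None
    for i in range(n_cohorts):
        cohort = generate_cohort(desk_preset(seed=seed + i, coupling_beta=0.0))
        an = analyze_cohort(cohort, pt=pt, alpha=alpha, use_truth_sizes=True)
        n_tests = an.n_tests
        for rep in an.significance.values():
            exceed += int(rep.significant.to_numpy().sum())
            cells += rep.significant.size
    return NullCalibration(n_cohorts=n_cohorts, n_cells=cells,
                           n_exceedances=exceed, alpha=alpha, n_tests=n_tests)


def coupling_curve(betas: Sequence[float] = (0.0, 0.2, 0.5),
                   n_replicates: int = 20, seed: int = 0,
                   pt: float = 0.30) -> Dict[float, np.ndarray]:
    """Mean degree-NMC per replicate at each coupling strength.

    Replicates are paired: replicate ``i`` uses the same cohort seed at
    every beta, so the curves differ only through the planted coupling.
    Returns ``{beta: array of n_replicates mean degree-NMC values}``.
    """
    out = {float(b): np.empty(n_replicates) for b in betas}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PD shrinkage notes at high beta
        for i in range(n_replicates):
            for b in betas:
                cohort = generate_cohort(
                    desk_preset(seed=seed + i, coupling_beta=float(b)))
                an = analyze_cohort(cohort, pt=pt, use_truth_sizes=True)
                out[float(b)][i] = np.mean(
                    [an.nmc[g].r.loc["degree"].mean() for g in an.nmc])
    return out


def density_sweep_error(components: Sequence[int] = tuple(range(5, 61, 5)),
                        pts: Sequence[float] = tuple(np.round(
                            np.arange(0.1, 1.01, 0.1), 2)),
                        seed: int = 0) -> int:
    """Max |retained edges - round(pt * C(C-1)/2)| over a pt x C sweep.

    Zero when proportional thresholding honours its density contract
    exactly everywhere.
    """
    rng = np.random.default_rng(seed)
    worst = 0
    for c in components:
        x = rng.standard_normal((60, c))
        r = np.corrcoef(x, rowvar=False)
        for pt in pts:
            w = proportional_threshold(r, float(pt))
            got = int(np.count_nonzero(np.triu(w, k=1)))
            worst = max(worst, abs(got - n_retained_edges(c, float(pt))))
    return worst


def size_recovery_errors(seed: int = 0) -> int:
    """Mismatches between planted and quantified node sizes on a desk cohort.

    Regenerates every subject/component spatial map and counts cells where
    the 3.5-SD voxel tally differs from the planted size. Exact-count
    construction makes the expected value zero.
    """
    cohort = generate_cohort(desk_preset(seed=seed))
    errors = 0
    for s in cohort.subjects:
        for j in range(cohort.config.n_components):
            m = cohort.component_map(s, j)
            if suprathreshold_count(m) != s.sizes[j]:
                errors += 1
    return errors
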