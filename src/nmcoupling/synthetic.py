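"""Synthetic multi-group cohort generator with known node-size coupling.

Every downstream stage of the pipeline (node-size quantification, FNC,
thresholding, graph metrics, node-metric coupling) can be validated against
this generator because its ground truth is exact by construction:

* **Spatial maps.** Background voxels are drawn from a standard normal
  clipped to [-3, 3]; ``target_size`` implant voxels are set to a common
  value solved to exceed 3.5 x the SD of the finished map. The finished
  map's SD never falls below ~0.99 (clipping a standard normal at 3 SD
  removes almost no variance, and the implant only adds variance), so the
  3.5-SD threshold sits above 3.4: no clipped background voxel can cross it
  and the suprathreshold count equals ``target_size`` exactly.

* **Time courses.** T rows are drawn from a multivariate normal whose
  correlation matrix has within-domain blocks at the configured base level,
  off-block entries at the between-domain level, a per-group attenuation
  multiplier, and — the planted effect — row/column ``c`` scaled by
  ``1 + coupling_beta * z(size_c)`` where ``z`` standardizes the subject's
  size for component ``c`` against the generator's own component mean and
  spread. Larger nodes therefore carry stronger edges, so weighted degree
  (and, through it, the other metrics) correlates with node size across
  subjects. With ``coupling_beta = 0`` the coupling vanishes and the
  node-metric-coupling grid is null-calibrated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import CovarianceError, SizingError
from .nodesize import suprathreshold_count

logger = logging.getLogger(__name__)

_CLIP = 3.0            # background clip, in background-SD units
_MARGIN = 1.1          # implant value sits 10% above the threshold
_FACTOR_BOUNDS = (0.25, 2.0)   # bounds on the 1 + beta*z edge factor
_MAX_OFFDIAG = 0.95    # cap on target correlations after coupling


def _solve_implant_value(bg: np.ndarray, n_implant: int, k: float) -> float:
    """Fixed-point solve for an implant value exceeding k*SD of the map."""
    n_total = bg.size + n_implant
    s_b = float(bg.sum())
    q_b = float(np.square(bg).sum())
    v = _MARGIN * k  # start near the expected threshold for SD ~ 1
    for _ in range(200):
        mean = (s_b + n_implant * v) / n_total
        var = (q_b + n_implant * v * v) / n_total - mean * mean
        v_new = _MARGIN * k * float(np.sqrt(var))
        if abs(v_new - v) < 1e-12:
            v = v_new
            break
        v = v_new
    mean = (s_b + n_implant * v) / n_total
    var = (q_b + n_implant * v * v) / n_total - mean * mean
    if not v > k * float(np.sqrt(var)):
        raise SizingError(
            f"cannot implant {n_implant} voxels above {k}x SD in a map of "
            f"{n_total} voxels: implant fraction too large")
    return v


def generate_spatial_map(target_size: int, map_shape: Tuple[int, ...],
                         rng: np.random.Generator,
                         k: float = 3.5) -> np.ndarray:
    """Generate a 3D map whose suprathreshold count at factor ``k`` is exact.

    Raises
    ------
    SizingError
        If ``target_size`` is below 1 or above 1% of the voxel count (the
        regime in which the implant is guaranteed to clear the threshold).
    """
    n_vox = int(np.prod(map_shape))
    if target_size < 1:
        raise SizingError(f"target_size must be >= 1, got {target_size}")
    if target_size > 0.01 * n_vox:
        raise SizingError(
            f"target_size {target_size} exceeds 1% of {n_vox} voxels")

    flat = np.clip(rng.standard_normal(n_vox), -_CLIP, _CLIP)
    implant_idx = rng.choice(n_vox, size=target_size, replace=False)
    bg_mask = np.ones(n_vox, dtype=bool)
    bg_mask[implant_idx] = False
    v = _solve_implant_value(flat[bg_mask], target_size, k)
    flat[implant_idx] = v

    vol = flat.reshape(map_shape)
    got = suprathreshold_count(vol, k=k)
    if got != target_size:  # construction guarantee; never expected to fire
        raise SizingError(
            f"implant failed: planted {target_size}, recovered {got}")
    return vol


def _base_correlation(config: SimulationConfig, group: str) -> np.ndarray:
    """Block correlation matrix: within/between domain levels, attenuated."""
    labels = config.domain_labels()
    same = labels[:, None] == labels[None, :]
    c0 = np.where(same, config.within_connectivity, config.between_connectivity)
    att = config.group_attenuation.get(group, 1.0)
    c0 = c0 * att
    np.fill_diagonal(c0, 1.0)
    return c0


def _nearest_pd(sigma: np.ndarray, max_shrink: float = 0.9) -> np.ndarray:
    """Shrink toward the identity until Cholesky succeeds."""
    lam = 0.0
    while lam <= max_shrink:
        cand = (1 - lam) * sigma + lam * np.eye(sigma.shape[0])
        try:
            np.linalg.cholesky(cand)
            if lam > 0:
                warnings.warn(
                    f"target correlation shrunk toward identity (lambda={lam:.2f}) "
                    "to restore positive definiteness", stacklevel=3)
            return cand
        except np.linalg.LinAlgError:
            lam = lam + 0.05 if lam else 0.05
    raise CovarianceError("covariance not positive definite after max shrinkage")


def coupling_factors(sizes: np.ndarray, base_sizes: np.ndarray,
                     size_sd: float, beta: float) -> np.ndarray:
    """Per-component edge scaling 1 + beta*z, z the standardized size."""
    z = (np.asarray(sizes, dtype=float) - base_sizes) / size_sd
    return np.clip(1.0 + beta * z, *_FACTOR_BOUNDS)


def target_correlation(config: SimulationConfig, group: str,
                       sizes: np.ndarray, base_sizes: np.ndarray) -> np.ndarray:
    """Subject-level target correlation with the coupling plant applied."""
    c0 = _base_correlation(config, group)
    f = coupling_factors(sizes, base_sizes, config.size_sd, config.coupling_beta)
    sigma = c0 * np.outer(f, f)
    np.fill_diagonal(sigma, 1.0)
    off = ~np.eye(sigma.shape[0], dtype=bool)
    sigma[off] = np.clip(sigma[off], -_MAX_OFFDIAG, _MAX_OFFDIAG)
    return _nearest_pd(sigma)


def generate_timecourses(subject_sizes: np.ndarray, config: SimulationConfig,
                         group: str, rng: np.random.Generator,
                         base_sizes: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Draw a T x C time-course table for one subject.

    ``base_sizes`` defaults to the generator's per-component mean sizes;
    passing them explicitly allows standalone use.
    """
    if base_sizes is None:
        base_sizes = component_base_sizes(config)
    sigma = target_correlation(config, group, subject_sizes, base_sizes)
    chol = np.linalg.cholesky(sigma)
    draws = rng.standard_normal((config.n_timepoints, config.n_components))
    tc = draws @ chol.T
    return pd.DataFrame(tc, columns=config.component_ids)


def component_base_sizes(config: SimulationConfig) -> np.ndarray:
    """Deterministic per-component mean voxel counts, spread over
    [0.5, 1.5] x size_mean so the cohort has a nontrivial volume ratio."""
    lo, hi = 0.5 * config.size_mean, 1.5 * config.size_mean
    base = np.linspace(lo, hi, config.n_components)
    return np.maximum(np.round(base), 1.0)


@dataclass
class SubjectRecord:
    """One simulated subject: identity, labels, truth sizes, time courses."""

    subject_id: str
    group: str
    index: int                      # cohort-wide position, drives map seeds
    sizes: np.ndarray               # planted voxel counts, one per component
    timecourses: pd.DataFrame       # T x C


@dataclass
class SyntheticCohort:
    """A simulated multi-group cohort with exact ground truth.

    Spatial maps are not stored: they are regenerated deterministically on
    demand from (seed, subject index, component index), which keeps even the
    full-size cohort in memory while guaranteeing byte-identical maps across
    calls and runs.
    """

    config: SimulationConfig
    subjects: List[SubjectRecord]
    truth: Dict = field(default_factory=dict)

    @property
    def subject_ids(self) -> List[str]:
        return [s.subject_id for s in self.subjects]

    def groups(self) -> pd.Series:
        return pd.Series({s.subject_id: s.group for s in self.subjects},
                         name="group")

    def size_table(self) -> pd.DataFrame:
        """Planted node sizes as a subjects x components table."""
        data = np.vstack([s.sizes for s in self.subjects])
        return pd.DataFrame(data, index=pd.Index(self.subject_ids, name="subject_id"),
                            columns=pd.Index(self.config.component_ids,
                                             name="component_id"))

    def _map_rng(self, subject_index: int, comp_index: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence((self.config.seed, 211, subject_index, comp_index)))

    def component_map(self, subject: SubjectRecord, comp_index: int) -> np.ndarray:
        """Regenerate one subject/component spatial map."""
        return generate_spatial_map(
            int(subject.sizes[comp_index]), self.config.map_shape,
            self._map_rng(subject.index, comp_index))

    def subject_maps(self, subject: SubjectRecord) -> Iterator[Tuple[str, np.ndarray]]:
        for j, cid in enumerate(self.config.component_ids):
            yield cid, self.component_map(subject, j)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full cohort: sizes, time courses, truth record."""
    base_sizes = component_base_sizes(config)
    n_vox = int(np.prod(config.map_shape))
    max_size = int(0.01 * n_vox)

    size_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    subjects: List[SubjectRecord] = []
    index = 0
    for group, n_sub in config.group_sizes.items():
        for g_idx in range(n_sub):
            sizes = np.round(base_sizes + config.size_sd
                             * size_rng.standard_normal(config.n_components))
            sizes = np.clip(sizes, 1, max_size).astype(int)
            tc_rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, 307, index)))
            tc = generate_timecourses(sizes, config, group, tc_rng,
                                      base_sizes=base_sizes)
            subjects.append(SubjectRecord(
                subject_id=f"{group}_{g_idx + 1:04d}", group=group,
                index=index, sizes=sizes, timecourses=tc))
            index += 1

    truth = {
        "coupling_beta": config.coupling_beta,
        "component_base_sizes": base_sizes.tolist(),
        "sizes": {s.subject_id: s.sizes.tolist() for s in subjects},
    }
    logger.info("generated cohort: %d subjects, %d components, groups %s",
                len(subjects), config.n_components, dict(config.group_sizes))
    return SyntheticCohort(config=config, subjects=subjects, truth=truth)
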