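"""Simulation configuration: cohort structure, connectivity levels, coupling.

The default configuration mirrors the study design the package targets:
53 ICA components grouped into 7 functional domains, and three diagnostic
groups of unequal size (947 healthy controls, 368 mild cognitive impairment,
213 Alzheimer's disease). A small ``desk_preset`` (60/40/30 subjects,
20 components) is provided for fast exploratory runs and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .errors import NMCouplingError

# Component counts per functional domain for the 53-component layout
# (auditory, subcortical, sensorimotor, visual, cognitive control,
# cerebellar, default mode).
DOMAIN_LAYOUT_53 = {
    "subcortical": 5,
    "auditory": 2,
    "sensorimotor": 9,
    "visual": 9,
    "cognitive_control": 17,
    "default_mode": 7,
    "cerebellar": 4,
}


def block_domain_assignment(n_components: int, n_domains: int) -> Dict[str, str]:
    """Assign components to domains in contiguous, near-equal blocks.

    For the canonical 53-component / 7-domain case the standard functional
    domain layout is used; otherwise components are split into ``n_domains``
    contiguous blocks differing in size by at most one.
    """
    comp_ids = [f"C{i + 1:02d}" for i in range(n_components)]
    if n_components == 53 and n_domains == 7:
        out: Dict[str, str] = {}
        it = iter(comp_ids)
        for dom, count in DOMAIN_LAYOUT_53.items():
            for _ in range(count):
                out[next(it)] = dom
        return out
    sizes = np.full(n_domains, n_components // n_domains, dtype=int)
    sizes[: n_components % n_domains] += 1
    out = {}
    idx = 0
    for d, sz in enumerate(sizes):
        for _ in range(sz):
            out[comp_ids[idx]] = f"D{d + 1}"
            idx += 1
    return out


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-group cohort generator.

    Attributes
    ----------
    n_components, n_domains
        Number of graph nodes (ICA components) and functional domains.
    domain_assignment
        component_id -> domain label; derived from a block layout when None.
    group_sizes
        Subjects per diagnostic group. Each group needs at least 4 subjects
        (Pearson r and its Fisher z transform require n > 3).
    n_timepoints
        Length T of each subject's component time courses.
    within_connectivity, between_connectivity
        Baseline correlation inside / between domain blocks, in [0, 1).
    group_attenuation
        Per-group multiplier on all off-diagonal correlations; models the
        globally weaker connectivity of an impaired group.
    size_mean, size_sd
        Centre and per-subject spread of the component voxel-count
        distribution. Component base sizes are spread linearly over
        [0.5, 1.5] x size_mean so the cohort has a nontrivial volume ratio.
    coupling_beta
        Strength of the planted node-size -> edge-weight coupling
        (dimensionless; 0 disables it).
    map_shape
        3D grid of each spatial map. Planted sizes must stay below 1% of
        the voxel count so the implant remains above 3.5 x SD.
    seed
        Master seed; every random stream is derived from it.
    """

    n_components: int = 53
    n_domains: int = 7
    domain_assignment: Optional[Dict[str, str]] = None
    group_sizes: Dict[str, int] = field(
        default_factory=lambda: {"HC": 947, "MCI": 368, "AD": 213})
    n_timepoints: int = 150
    within_connectivity: float = 0.45
    between_connectivity: float = 0.15
    group_attenuation: Dict[str, float] = field(
        default_factory=lambda: {"HC": 1.0, "MCI": 0.95, "AD": 0.85})
    size_mean: float = 100.0
    size_sd: float = 15.0
    coupling_beta: float = 0.0
    map_shape: tuple = (30, 30, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.domain_assignment is None:
            self.domain_assignment = block_domain_assignment(
                self.n_components, self.n_domains)
        self.validate()

    @property
    def component_ids(self) -> list:
        return [f"C{i + 1:02d}" for i in range(self.n_components)]

    def validate(self) -> None:
        if self.n_components < 2:
            raise NMCouplingError("need at least 2 components")
        if min(self.group_sizes.values()) < 4:
            raise NMCouplingError("every group needs >= 4 subjects (n > 3 for r)")
        if not (0 <= self.between_connectivity < 1 and 0 <= self.within_connectivity < 1):
            raise NMCouplingError("connectivity levels must lie in [0, 1)")
        if self.n_timepoints < 10:
            raise NMCouplingError("need at least 10 timepoints")
        assigned = set(self.domain_assignment)
        expected = set(self.component_ids)
        if assigned != expected:
            raise NMCouplingError(
                "domain_assignment must cover every component exactly once; "
                f"missing={sorted(expected - assigned)} extra={sorted(assigned - expected)}")
        n_vox = int(np.prod(self.map_shape))
        if self.size_mean * 1.5 > 0.01 * n_vox:
            raise NMCouplingError(
                f"size_mean {self.size_mean} too large for map_shape {self.map_shape}: "
                "planted sizes must stay below 1% of voxels")

    def domain_labels(self) -> np.ndarray:
        """Domain label per component, in component order."""
        return np.array([self.domain_assignment[c] for c in self.component_ids])


def desk_preset(seed: int = 0, coupling_beta: float = 0.0,
                **overrides) -> SimulationConfig:
    """Small cohort for fast runs: 60/40/30 subjects, 20 components, T=120."""
    params = dict(
        n_components=20,
        n_domains=5,
        group_sizes={"HC": 60, "MCI": 40, "AD": 30},
        n_timepoints=120,
        size_mean=40.0,
        size_sd=6.0,
        map_shape=(20, 20, 20),
        coupling_beta=coupling_beta,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)
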