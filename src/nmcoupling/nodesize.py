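"""Node-size quantification from component spatial maps.

The "size" of a functional node (an ICA component treated as a graph node)
is the number of voxels in its spatial loading map whose value exceeds a
threshold of ``k`` times the standard deviation of the map, with ``k = 3.5``
by default. The count is a dimensionless voxel tally; no mm^3 conversion is
applied.

Conventions (documented here because the field has no single standard):

* The SD is the population standard deviation (``ddof=0``) over all voxels
  of the supplied map, or over in-mask voxels when a mask is given.
* The threshold is one-sided by default: voxels with value strictly greater
  than ``+k*SD`` are counted. ``two_sided=True`` counts ``|value| > k*SD``.
* Ties at exactly ``k*SD`` are excluded (strict inequality), which makes the
  count deterministic across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateMapError, StructuralError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_FACTOR = 3.5


@dataclass
class ComponentMap:
    """One component's 3D spatial loading field for one subject.

    Parameters
    ----------
    values
        3D array of loading values (arbitrary units). Must be finite.
    component_id, subject_id
        Identifiers; carried through to output tables.
    voxel_dims
        Optional (dx, dy, dz) voxel size in mm. Metadata only — node size
        is a voxel count, not a volume.
    """

    values: np.ndarray
    component_id: str = ""
    subject_id: str = ""
    voxel_dims: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty spatial map")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spatial map contains non-finite values")


@dataclass
class NodeSizeTable:
    """Subjects x components grid of non-negative integer voxel counts."""

    counts: pd.DataFrame
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR

    def __post_init__(self) -> None:
        if self.counts.isna().any().any():
            raise StructuralError("node-size table has missing cells")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("node sizes must be non-negative")


def _map_values(m, mask: Optional[np.ndarray] = None) -> np.ndarray:
    vals = m.values if isinstance(m, ComponentMap) else np.asarray(m, dtype=float)
    if vals.size == 0:
        raise ValueError("empty spatial map")
    if not np.all(np.isfinite(vals)):
        raise ValueError("spatial map contains non-finite values")
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != vals.shape:
            raise ValueError("mask shape does not match map shape")
        vals = vals[mask]
        if vals.size == 0:
            raise ValueError("mask excludes every voxel")
    return vals


def component_threshold(m, k: float = DEFAULT_THRESHOLD_FACTOR,
                        mask: Optional[np.ndarray] = None) -> float:
    """Return ``k`` times the population SD of the map's voxel values.

    Raises
    ------
    DegenerateMapError
        If the map is constant (SD = 0), so no meaningful threshold exists.
    """
    if k <= 0:
        raise ValueError(f"threshold factor must be positive, got {k}")
    vals = _map_values(m, mask)
    sd = float(vals.std())  # population (n) divisor
    if sd == 0.0:
        raise DegenerateMapError("constant map: standard deviation is zero")
    return k * sd


def suprathreshold_count(m, k: float = DEFAULT_THRESHOLD_FACTOR,
                         mask: Optional[np.ndarray] = None,
                         two_sided: bool = False) -> int:
    """Count voxels strictly exceeding the ``k*SD`` threshold.

    One-sided (positive tail) by default; ``two_sided=True`` counts
    ``|value| > k*SD``.
    """
    thr = component_threshold(m, k=k, mask=mask)
    vals = _map_values(m, mask)
    if two_sided:
        return int(np.count_nonzero(np.abs(vals) > thr))
    return int(np.count_nonzero(vals > thr))


def node_size_table(maps: Mapping[str, Mapping[str, object]],
                    k: float = DEFAULT_THRESHOLD_FACTOR,
                    mask: Optional[np.ndarray] = None,
                    two_sided: bool = False,
                    components: Optional[Sequence[str]] = None) -> NodeSizeTable:
    """Assemble the full subjects x components node-size grid.

    Parameters
    ----------
    maps
        ``{subject_id: {component_id: map}}`` where each map is a
        :class:`ComponentMap` or a 3D array.
    components
        Explicit component order; defaults to the order seen for the first
        subject. Every subject must supply every component.

    Raises
    ------
    StructuralError
        If any (subject, component) map is missing.
    """
    subjects = list(maps.keys())
    if not subjects:
        raise StructuralError("no subjects supplied")
    if components is None:
        components = list(maps[subjects[0]].keys())
    components = list(components)

    grid = np.empty((len(subjects), len(components)), dtype=int)
    for i, sid in enumerate(subjects):
        sub = maps[sid]
        for j, cid in enumerate(components):
            if cid not in sub:
                raise StructuralError(f"missing map for subject {sid!r}, component {cid!r}")
            grid[i, j] = suprathreshold_count(sub[cid], k=k, mask=mask, two_sided=two_sided)

    counts = pd.DataFrame(grid, index=pd.Index(subjects, name="subject_id"),
                          columns=pd.Index(components, name="component_id"))
    for cid in components:
        logger.info("component %s: node size mean=%.1f sd=%.1f", cid,
                    counts[cid].mean(), counts[cid].std())
    return NodeSizeTable(counts=counts, threshold_factor=k)


def volume_ratio(table) -> float:
    """Max-to-min ratio of mean component size.

    Component means are taken over subjects (a single-row table reduces to
    raw counts, the template mode). All means must be strictly positive.
    """
    counts = table.counts if isinstance(table, NodeSizeTable) else pd.DataFrame(table)
    means = counts.mean(axis=0)
    if (means <= 0).any():
        bad = means.index[means <= 0].tolist()
        raise ValueError(f"volume ratio undefined: zero mean size for components {bad}")
    return float(means.max() / means.min())
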