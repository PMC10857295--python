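"""End-to-end orchestration: simulate -> node sizes -> FNC -> threshold ->
graph metrics -> node-metric coupling -> group comparisons.

`run_pipeline` drives the full chain from a :class:`PipelineConfig` (either
a simulation block or paths to maps/time courses/labels on disk) and writes
every stage output plus a JSON run report. `analyze_cohort` is the
in-memory core used by the CLI, the tests and the acceptance script.
"""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as nio
from .config import SimulationConfig, desk_preset
from .connectivity import (cellwise_group_ttest, group_mean_fnc, pearson_fnc,
                           proportional_threshold)
from .errors import NMCouplingError
from .metrics import ALL_METRICS, GLOBAL_METRICS, NODAL_METRICS, compute_all
from .nodesize import node_size_table, suprathreshold_count
from .stats import (NMCMatrix, global_metric_ttests_all_pairs,
                    nmc_group_difference, nmc_matrix, significance_counts)
from .synthetic import SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_PT = 0.30


@dataclass
class PipelineConfig:
    """Parameters and paths for one pipeline run.

    Either ``simulation`` is set (the cohort is generated) or the four
    input paths (``maps_dir``, ``timecourses_dir``, ``partition``,
    ``groups``) must exist.
    """

    out_dir: str = "nmc_out"
    k: float = 3.5
    pt: float = DEFAULT_PT
    alpha: float = 0.05
    fdr_q: float = 0.05
    n_tests: Optional[int] = None      # None = metrics x components, from data
    maps_dir: Optional[str] = None
    timecourses_dir: Optional[str] = None
    partition: Optional[str] = None
    groups: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    write_maps: bool = False           # persist simulated maps as NIfTI

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            if sim.pop("desk_preset", False):
                cfg.simulation = desk_preset(**sim)
            else:
                cfg.simulation = SimulationConfig(**sim)
        return cfg


def validate_inputs(cfg: PipelineConfig) -> List[str]:
    """Check path existence, alignment and parameter ranges; returns a list
    of issues (empty when the configuration is runnable)."""
    issues: List[str] = []
    if not 0 < cfg.pt <= 1:
        issues.append(f"pt={cfg.pt} outside (0, 1]")
    if cfg.k <= 0:
        issues.append(f"k={cfg.k} must be positive")
    if not 0 < cfg.alpha < 1:
        issues.append(f"alpha={cfg.alpha} outside (0, 1)")
    if cfg.simulation is not None:
        return issues
    for name in ("maps_dir", "timecourses_dir", "partition", "groups"):
        p = getattr(cfg, name)
        if p is None:
            issues.append(f"missing required path: {name}")
        elif not Path(p).exists():
            issues.append(f"{name} does not exist: {p}")
    if issues:
        return issues
    groups = nio.read_groups(cfg.groups)
    partition = nio.read_partition(cfg.partition)
    comp_ids = list(partition)
    tdir = Path(cfg.timecourses_dir)
    mdir = Path(cfg.maps_dir)
    for sid in groups.index:
        if not (tdir / f"{sid}.tsv").exists():
            issues.append(f"subject {sid} in groups but missing time courses")
        has_4d = (mdir / f"{sid}.nii").exists()
        has_3d = (mdir / f"{sid}_{comp_ids[0]}.nii").exists()
        if not (has_4d or has_3d):
            issues.append(f"subject {sid} in groups but missing maps")
    return issues


# -- in-memory analysis core --------------------------------------------------

def subject_metrics(tc: pd.DataFrame, pt: float,
                    domain_labels: np.ndarray) -> Tuple[np.ndarray, dict]:
    """FNC -> proportional threshold -> six metrics for one subject.

    Returns (thresholded weight matrix, GraphMetrics-as-dicts).
    """
    fnc = pearson_fnc(tc)
    w = proportional_threshold(fnc, pt)
    gm = compute_all(w, domain_labels)
    return w, {"nodal": gm.nodal, "global": gm.global_}


def metrics_tables(timecourses: Mapping[str, pd.DataFrame], pt: float,
                   domain_labels: np.ndarray, component_ids: Sequence[str]
                   ) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame,
                              Dict[str, np.ndarray]]:
    """Per-subject metrics over a cohort.

    Returns (nodal metric -> subjects x components table,
    subjects x global-metrics table, subject -> FNC matrix).
    """
    sids = list(timecourses)
    nodal = {m: np.empty((len(sids), len(component_ids))) for m in NODAL_METRICS}
    glob = np.empty((len(sids), len(GLOBAL_METRICS)))
    fncs: Dict[str, np.ndarray] = {}
    for i, sid in enumerate(sids):
        fnc = pearson_fnc(timecourses[sid])
        fncs[sid] = fnc
        w = proportional_threshold(fnc, pt)
        gm = compute_all(w, domain_labels)
        for m in NODAL_METRICS:
            nodal[m][i] = gm.nodal[m]
        glob[i] = [gm.global_[m] for m in GLOBAL_METRICS]
    idx = pd.Index(sids, name="subject_id")
    cols = pd.Index(component_ids, name="component_id")
    nodal_df = {m: pd.DataFrame(v, index=idx, columns=cols)
                for m, v in nodal.items()}
    glob_df = pd.DataFrame(glob, index=idx, columns=list(GLOBAL_METRICS))
    return nodal_df, glob_df, fncs


@dataclass
class CohortAnalysis:
    """All stage outputs of one in-memory run."""

    sizes: pd.DataFrame
    nodal: Dict[str, pd.DataFrame]
    global_metrics: pd.DataFrame
    fncs: Dict[str, np.ndarray]
    groups: pd.Series
    nmc: Dict[str, NMCMatrix]
    significance: Dict[str, object]
    n_tests: int


def quantify_cohort_sizes(cohort: SyntheticCohort, k: float = 3.5) -> pd.DataFrame:
    """Run the voxel-counting quantifier over every generated map."""
    rows = []
    for s in cohort.subjects:
        rows.append([suprathreshold_count(m, k=k)
                     for _, m in cohort.subject_maps(s)])
    return pd.DataFrame(rows,
                        index=pd.Index(cohort.subject_ids, name="subject_id"),
                        columns=pd.Index(cohort.config.component_ids,
                                         name="component_id"))


def analyze_cohort(cohort: SyntheticCohort, pt: float = DEFAULT_PT,
                   alpha: float = 0.05, k: float = 3.5,
                   use_truth_sizes: bool = False,
                   n_tests: Optional[int] = None) -> CohortAnalysis:
    """Full chain on a synthetic cohort.

    ``use_truth_sizes=True`` takes node sizes from the generator's truth
    record instead of quantifying regenerated maps; the two are identical
    by the exact-count construction, and the shortcut keeps replicate
    studies (null calibration, coupling recovery) fast.
    """
    cfg = cohort.config
    sizes = (cohort.size_table() if use_truth_sizes
             else quantify_cohort_sizes(cohort, k=k))
    tcs = {s.subject_id: s.timecourses for s in cohort.subjects}
    nodal, glob, fncs = metrics_tables(tcs, pt, cfg.domain_labels(),
                                       cfg.component_ids)
    groups = cohort.groups()
    if n_tests is None:
        n_tests = len(ALL_METRICS) * cfg.n_components
    nmc: Dict[str, NMCMatrix] = {}
    sig: Dict[str, object] = {}
    for g in cfg.group_sizes:
        members = groups.index[groups == g]
        nmc[g] = nmc_matrix(sizes, nodal, glob, g, subjects=members)
        sig[g] = significance_counts(nmc[g], alpha=alpha, n_tests=n_tests)
    return CohortAnalysis(sizes=sizes, nodal=nodal, global_metrics=glob,
                          fncs=fncs, groups=groups, nmc=nmc,
                          significance=sig, n_tests=n_tests)


# -- full run with file outputs ----------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write outputs under ``cfg.out_dir``.

    Returns the run report (also written as ``report.json``). Identical
    configuration and seed produce identical outputs.
    """
    issues = validate_inputs(cfg)
    fatal = [i for i in issues if "does not exist" in i or "missing required" in i
             or "outside" in i or "must be" in i]
    if fatal:
        raise NMCouplingError("invalid configuration: " + "; ".join(fatal))

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: List[str] = list(issues)

    if cfg.simulation is not None:
        sim = cfg.simulation
        logger.info("stage simulate: %d subjects", sum(sim.group_sizes.values()))
        cohort = generate_cohort(sim)
        assignment = sim.domain_assignment
        component_ids = sim.component_ids
        groups = cohort.groups()
        tcs = {s.subject_id: s.timecourses for s in cohort.subjects}
        for sid, tc in tcs.items():
            nio.write_tsv(tc, out / "timecourses" / f"{sid}.tsv", index=False)
        nio.write_tsv(groups.rename_axis("subject_id").reset_index(),
                      out / "groups.tsv", index=False)
        nio.write_partition(assignment, out / "partition.tsv")
        nio.write_json(cohort.truth, out / "truth.json")
        if cfg.write_maps:
            for s in cohort.subjects:
                nio.write_subject_maps_4d(out / "maps", s.subject_id,
                                          dict(cohort.subject_maps(s)))
        logger.info("stage nodesize: quantifying %d x %d maps",
                    len(cohort.subjects), sim.n_components)
        sizes = quantify_cohort_sizes(cohort, k=cfg.k)
    else:
        assignment = nio.read_partition(cfg.partition)
        component_ids = list(assignment)
        groups = nio.read_groups(cfg.groups)
        tcs = {sid: nio.read_timecourses(Path(cfg.timecourses_dir) / f"{sid}.tsv")
               for sid in groups.index}
        maps = {sid: nio.read_subject_maps(cfg.maps_dir, sid, component_ids)
                for sid in groups.index}
        tab = node_size_table(maps, k=cfg.k, components=component_ids)
        sizes = tab.counts

    nio.write_tsv(sizes, out / "sizes.tsv")
    domain_labels = np.array([assignment[c] for c in component_ids])

    logger.info("stage fnc+threshold+metrics: %d subjects, pt=%.2f",
                len(tcs), cfg.pt)
    nodal, glob, fncs = metrics_tables(tcs, cfg.pt, domain_labels, component_ids)
    for m, tabm in nodal.items():
        nio.write_tsv(tabm, out / "metrics" / f"nodal_{m}.tsv")
    nio.write_tsv(glob, out / "metrics" / "global.tsv")

    group_names = list(dict.fromkeys(groups))
    for g in group_names:
        members = groups.index[groups == g]
        mean_fnc = group_mean_fnc([fncs[s] for s in members])
        nio.write_matrix_csv(mean_fnc, component_ids, out / "fnc" / f"mean_{g}.csv")

    n_tests = cfg.n_tests or len(ALL_METRICS) * len(component_ids)
    logger.info("stage nmc: %d tests per group", n_tests)
    nmc: Dict[str, NMCMatrix] = {}
    summary: Dict[str, dict] = {}
    for g in group_names:
        members = groups.index[groups == g]
        nmc[g] = nmc_matrix(sizes, nodal, glob, g, subjects=members)
        rep = significance_counts(nmc[g], alpha=cfg.alpha, n_tests=n_tests)
        nio.write_tsv(nmc[g].r, out / "nmc" / f"nmc_{g}.tsv")
        nio.write_tsv(rep.significant, out / "nmc" / f"significant_{g}.tsv")
        summary[g] = {"n": rep.n, "critical_r": rep.critical_r,
                      "counts": rep.counts.to_dict(),
                      "n_undefined": rep.n_undefined}

    logger.info("stage group comparisons")
    for i, ga in enumerate(group_names):
        for gb in group_names[i + 1:]:
            comp = nmc_group_difference(nmc[ga], nmc[gb], alpha=cfg.alpha,
                                        n_tests=n_tests)
            nio.write_tsv(comp.delta_r, out / "nmc" / f"diff_{ga}_{gb}.tsv")
            nio.write_tsv(comp.significant,
                          out / "nmc" / f"diff_significant_{ga}_{gb}.tsv")
            summary[f"{ga}-{gb}"] = {
                "n_significant": int(comp.significant.to_numpy().sum())}
            ca = cellwise_group_ttest(
                [fncs[s] for s in groups.index[groups == ga]],
                [fncs[s] for s in groups.index[groups == gb]], fdr_q=cfg.fdr_q)
            nio.write_tsv(ca.to_frame(component_ids),
                          out / "fnc" / f"cellwise_{ga}_{gb}.tsv", index=False)

    gt = global_metric_ttests_all_pairs(
        {g: glob.loc[groups.index[groups == g]] for g in group_names},
        fdr_q=cfg.fdr_q)
    nio.write_tsv(gt, out / "metrics" / "global_group_tests.tsv", index=False)

    report = {
        "format_version": nio.FORMAT_VERSION,
        "package_version": __version__,
        "python": platform.python_version(),
        "parameters": {"k": cfg.k, "pt": cfg.pt, "alpha": cfg.alpha,
                       "fdr_q": cfg.fdr_q, "n_tests": n_tests,
                       "seed": cfg.simulation.seed if cfg.simulation else None},
        "n_subjects": int(len(groups)),
        "n_components": len(component_ids),
        "groups": {g: int((groups == g).sum()) for g in group_names},
        "nmc_summary": summary,
        "warnings": warnings,
    }
    nio.write_json(report, out / "report.json")
    logger.info("run complete: outputs in %s", out)
    return report
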