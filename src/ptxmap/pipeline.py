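"""End-to-end orchestration: simulate (or load) -> QC -> map -> LD -> stats.

The stages mirror the standard pseudo-testcross workflow: configuration
classification and missingness/MAF filtering, exclusion of extremely
distorted loci (p < 0.001), DH recoding of the uniparental sets, parental
bin-map construction, integration through ABxAB anchors, and the LD /
coverage summaries.

Mapping runs on pairwise-complete data: every pairwise estimate (rf, LOD,
r2) uses only gametes scored at both markers, so imputation is not required
for map construction and is exposed as its own stage (evaluated by masking
cross-validation) rather than forced into the mapping path.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import ld as ld_mod
from . import linkage, qc, stats
from .formats_io import GenotypeMatrix
from .imputation import ImputeConfig, impute
from .simulate import SimConfig, SimTruth, simulate_cross


@dataclasses.dataclass
class ParentResult:
    map_table: pd.DataFrame
    phased: linkage.PhasedGameteMatrix
    summary: pd.DataFrame
    decay: ld_mod.LDDecayCurve | None = None
    decay_cm: float | None = None


@dataclasses.dataclass
class PipelineResult:
    gm: GenotypeMatrix
    truth: SimTruth | None
    marker_stats: pd.DataFrame
    drop_report: pd.DataFrame
    impute_report: pd.DataFrame | None
    distortion: pd.DataFrame
    parents: dict[str, ParentResult]
    integrated: pd.DataFrame | None
    coverage: stats.CoverageStats | None


def run_pipeline(sim_config: SimConfig | None = None,
                 gm: GenotypeMatrix | None = None,
                 impute_config: ImputeConfig | None = None,
                 lod_min: float = linkage.LOD_MIN_DEFAULT,
                 rf_max: float = linkage.RF_MAX_DEFAULT,
                 integrate: bool = True,
                 compute_ld: bool = True,
                 genome_size_kb: float = stats.DEFAULT_GENOME_SIZE_KB,
                 ) -> PipelineResult:
    """Run the full analysis on a simulated or supplied genotype matrix."""
    truth = None
    if gm is None:
        if sim_config is None:
            sim_config = SimConfig()
        gm, truth = simulate_cross(sim_config)
    mstats = qc.marker_stats(gm)
    gm_f, drop_report = qc.filter_markers(gm, stats=mstats)
    mstats = mstats.loc[gm_f.marker_ids]
    impute_report = None
    if impute_config is not None:
        gm_f, impute_report = impute(gm_f, impute_config, stats=mstats)
        mstats = qc.marker_stats(gm_f)
    scan = qc.distortion_scan(gm_f, stats=mstats)
    excluded = qc.excluded_marker_ids(scan)
    keep = gm_f.marker_ids.difference(pd.Index(excluded), sort=False)
    gm_m = gm_f.subset(keep)
    mstats_m = mstats.loc[keep]

    sets = linkage.split_by_configuration(gm_m, stats=mstats_m)
    p1_name, p2_name = gm_m.parent_names
    parents: dict[str, ParentResult] = {}
    for pname in (p1_name, p2_name):
        map_table, phased, summary = linkage.build_parental_map(
            sets[pname], lod_min=lod_min, rf_max=rf_max)
        res = ParentResult(map_table=map_table, phased=phased, summary=summary)
        if compute_ld:
            curve = ld_mod.ld_decay_curve(phased, map_table)
            res.decay = curve
            res.decay_cm = ld_mod.decay_distance(curve)
        parents[pname] = res

    integrated = None
    coverage = None
    if integrate:
        try:
            integrated = linkage.integrate_maps(
                parents[p1_name].map_table, parents[p2_name].map_table,
                parents[p1_name].phased, parents[p2_name].phased,
                sets["ABxAB"],
            )
        except linkage.LinkageError as exc:
            import warnings

            warnings.warn(f"integration failed: {exc}", stacklevel=2)
    target = integrated if integrated is not None else parents[p1_name].map_table
    lengths, counts = [], []
    for _, grp in target.groupby("lg"):
        pos = grp["position"]
        lengths.append(float(pos.max() - pos.min()))
        counts.append(len(grp))
    if all(c >= 2 for c in counts) and lengths:
        coverage = stats.genome_coverage(lengths, counts,
                                         genome_size_kb=genome_size_kb)

    # annotate distortion with integrated positions for the genome-wide view
    if integrated is not None:
        scan = scan.drop(columns=[c for c in ("lg", "position") if c in scan],
                         errors="ignore")
        scan = scan.merge(integrated[["marker_id", "lg", "position"]],
                          on="marker_id", how="left")
    return PipelineResult(
        gm=gm, truth=truth, marker_stats=mstats, drop_report=drop_report,
        impute_report=impute_report, distortion=scan, parents=parents,
        integrated=integrated, coverage=coverage,
    )


def order_recovery_tau(map_table: pd.DataFrame, truth: SimTruth) -> pd.DataFrame:
    """|Kendall tau| between recovered and true marker order, per recovered
    LG (computed on the true cM positions; ties in either ranking are
    handled by the tau-b estimator)."""
    from scipy.stats import kendalltau

    true_cm = truth.markers["cm"]
    rows = []
    for lg, grp in map_table.groupby("lg"):
        grp = grp.sort_values(["position", "marker_id"])
        mids = [m for m in grp["marker_id"] if m in true_cm.index]
        if len(mids) < 3:
            continue
        tau = kendalltau(grp.set_index("marker_id").loc[mids, "position"],
                         true_cm.loc[mids]).statistic
        true_lgs = truth.markers.loc[mids, "lg"].value_counts()
        rows.append((int(lg), len(mids), abs(float(tau)),
                     int(true_lgs.index[0]),
                     float(true_lgs.iloc[0] / len(mids))))
    return pd.DataFrame(
        rows, columns=["lg", "n_markers", "abs_tau", "true_lg", "purity"],
    )
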