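"""Map-level genome statistics.

Implements the Chakravarti method-4 genome-length estimator — each linkage
group's observed length L is inflated by (m + 1)/(m - 1), where m is the
number of mapped markers — plus observed genome coverage G_O/G_E, the
physical-per-genetic equivalence (Kb/cM) and Table-style per-LG summaries.

The packaged reference fixture :func:`load_published_map_summary` holds the
per-LG lengths and marker counts of the published high-density cranberry
pseudo-testcross map (integrated map plus the two parental bin maps), which
is the standard worked example for these estimators.
"""

from __future__ import annotations

import dataclasses
import warnings
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

#: estimated cranberry genome size, in kilobases; configurable everywhere
DEFAULT_GENOME_SIZE_KB = 470_000.0


def load_published_map_summary() -> pd.DataFrame:
    """Per-LG summary of the published cranberry map (12 LGs).

    Columns: lg, length_i/p1/p2 (cM), markers_i/p1/p2, bins_p1/p2,
    avg_gap_p1/p2.  The integrated columns sum to 1112.1 cM and 4849 markers.
    """
    with resources.files("ptxmap.data").joinpath(
        "cranberry_map_summary.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def expected_lg_length(length_cm: float, n_markers: int) -> float:
    """Chakravarti method-4 expected length of one LG: L * (m + 1)/(m - 1)."""
    if n_markers < 2:
        raise ValueError("expected length undefined for fewer than 2 markers")
    return length_cm * (n_markers + 1) / (n_markers - 1)


@dataclasses.dataclass
class CoverageStats:
    """Observed vs expected genome length and derived equivalences."""

    per_lg: pd.DataFrame          # lg, length, n_markers, expected_length
    observed_length: float        # G_O = sum of observed LG lengths, cM
    expected_length: float        # G_E = sum of method-4 expected lengths, cM
    coverage: float               # G_O / G_E, in (0, 1]
    genome_size_kb: float
    kb_per_cm: float

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.coverage


def genome_coverage(
    lengths_cm: Sequence[float],
    marker_counts: Sequence[int],
    genome_size_kb: float = DEFAULT_GENOME_SIZE_KB,
) -> CoverageStats:
    """Observed genome coverage G_O/G_E over a set of linkage groups.

    LGs with fewer than 2 markers cannot contribute an expected length and
    are excluded with a warning.
    """
    lengths = np.asarray(lengths_cm, dtype=float)
    counts = np.asarray(marker_counts, dtype=np.int64)
    if lengths.shape != counts.shape:
        raise ValueError("lengths and marker counts differ in shape")
    usable = counts >= 2
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} LG(s) with <2 markers excluded from "
            "coverage", stacklevel=2,
        )
    lengths, counts = lengths[usable], counts[usable]
    expected = lengths * (counts + 1) / (counts - 1)
    g_o = float(lengths.sum())
    g_e = float(expected.sum())
    per_lg = pd.DataFrame(
        {
            "lg": np.arange(1, len(lengths) + 1),
            "length": lengths,
            "n_markers": counts,
            "expected_length": expected,
        }
    )
    return CoverageStats(
        per_lg=per_lg,
        observed_length=g_o,
        expected_length=g_e,
        coverage=g_o / g_e,
        genome_size_kb=genome_size_kb,
        kb_per_cm=kb_per_cm(genome_size_kb, g_o)[0],
    )


def kb_per_cm(genome_size_kb: float, total_map_cm: float) -> tuple[float, int]:
    """Physical DNA per map unit; returns (float, integer part)."""
    if genome_size_kb <= 0 or total_map_cm <= 0:
        raise ValueError("genome size and map length must be positive")
    value = genome_size_kb / total_map_cm
    return value, int(value)


def ld_extent_kb(decay_cm: float, kb_per_cm_value: float) -> float:
    """Physical extent of LD: decay distance (cM) x Kb/cM."""
    return decay_cm * kb_per_cm_value


def map_summary(
    map_table: pd.DataFrame,
    distortion: pd.DataFrame | None = None,
    recombination: pd.DataFrame | None = None,
    ld_decay: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-LG map features with a totals row (Table-style report).

    Reports per LG: length, marker count, bin count (unique positions),
    average gap = length / (unique positions - 1), and — when the matching
    per-LG frames are supplied — distorted-marker counts/percent, mean
    recombination events and LD decay distance.  The totals row sums counts
    and averages the rates.
    """
    rows = []
    for lg, grp in map_table.groupby("lg"):
        positions = np.sort(grp["position"].unique())
        length = float(positions[-1] - positions[0]) if len(positions) else 0.0
        if len(positions) < 2:
            warnings.warn(f"LG {lg} has <2 positions; excluded", stacklevel=2)
            continue
        rows.append(
            {
                "lg": int(lg),
                "length": length,
                "n_markers": len(grp),
                "n_bins": len(positions),
                "avg_gap": length / (len(positions) - 1),
            }
        )
    out = pd.DataFrame(rows)
    if distortion is not None:
        out = out.merge(
            distortion[["lg", "n_distorted", "pct_distorted"]], on="lg",
            how="left",
        )
    if recombination is not None:
        out = out.merge(recombination[["lg", "mean_events"]], on="lg", how="left")
    if ld_decay is not None:
        out = out.merge(ld_decay[["lg", "decay_cm"]], on="lg", how="left")
    totals = {"lg": 0, "length": out["length"].sum(),
              "n_markers": out["n_markers"].sum(), "n_bins": out["n_bins"].sum(),
              "avg_gap": out["avg_gap"].mean()}
    for col in ("n_distorted",):
        if col in out.columns:
            totals[col] = out[col].sum()
    for col in ("pct_distorted", "mean_events", "decay_cm"):
        if col in out.columns:
            totals[col] = out[col].mean()
    out = pd.concat([out, pd.DataFrame([totals])], ignore_index=True)
    return out
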