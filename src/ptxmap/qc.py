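"""Marker QC for pseudo-testcross genotype data.

Covers parental-configuration classification, missingness/MAF filtering and
the genome-wide segregation-distortion scan.  In an F1 cross between two
heterozygous outbred parents each marker falls into one of four informative
configurations:

========  =============================  ================  ==
config    parents                        expected ratio    df
========  =============================  ================  ==
ABxAA     P1 het, P2 hom                 1:1               1
AAxAB     P1 hom, P2 het                 1:1               1
ABxAB     both het, same two alleles     1:2:1             2
ABxCD     both het, >=3 distinct         1:1:1:1           3
========  =============================  ================  ==

hom x hom markers do not segregate and are dropped as uninformative.  The
expected class ratio of any configuration is recovered mechanically as the
multiset of sorted offspring genotypes over the four equally likely gamete
combinations, so the Pearson chi-square below needs no per-configuration
special cases.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .formats_io import MISSING, GenotypeMatrix

UNINFORMATIVE = "uninformative"
UNCLASSIFIABLE = "unclassifiable"

FLAG_OK = "ok"
FLAG_DISTORTED = "distorted"
FLAG_EXCLUDED = "excluded"


def _is_het(call: str) -> bool:
    return call[0] != call[1]


def classify_configuration(p1_call: str, p2_call: str) -> str:
    """Classify a marker from its two parental calls.

    Missing parental calls route the marker to ``"unclassifiable"`` rather
    than raising: such markers simply cannot enter the cross-specific
    analyses.
    """
    if p1_call == MISSING or p2_call == MISSING:
        return UNCLASSIFIABLE
    h1, h2 = _is_het(p1_call), _is_het(p2_call)
    if h1 and not h2:
        return "ABxAA"
    if h2 and not h1:
        return "AAxAB"
    if h1 and h2:
        alleles = set(p1_call) | set(p2_call)
        return "ABxAB" if len(alleles) == 2 else "ABxCD"
    return UNINFORMATIVE


def expected_classes(p1_call: str, p2_call: str) -> dict[str, float]:
    """Valid offspring genotypes and their Mendelian expected proportions."""
    combos = Counter(
        "".join(sorted(a + b)) for a in p1_call for b in p2_call
    )
    total = sum(combos.values())
    return {g: c / total for g, c in sorted(combos.items())}


@dataclasses.dataclass
class MarkerStats:
    marker_id: str
    configuration: str
    missing_fraction: float
    maf: float
    class_counts: dict[str, int]
    n_invalid: int


def marker_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker configuration, missingness, MAF and genotype class counts.

    MAF is computed from progeny allele counts over 2 x (non-missing calls).
    Calls outside the configuration's valid genotype set (possible only
    through genotyping error) are tallied as invalid and kept out of the
    class counts.
    """
    records = []
    calls = gm.calls.to_numpy()
    p = gm.parents.to_numpy()
    n = gm.n_samples
    for i, mid in enumerate(gm.marker_ids):
        cfg = classify_configuration(p[i, 0], p[i, 1])
        row = calls[i]
        obs = row[row != MISSING]
        miss_frac = 1.0 - len(obs) / n if n else 1.0
        allele_counts = Counter("".join(obs))
        total_alleles = sum(allele_counts.values())
        if total_alleles and len(allele_counts) > 1:
            maf = min(allele_counts.values()) / total_alleles
        elif total_alleles:
            maf = 0.0
        else:
            maf = float("nan")
        if cfg in (UNINFORMATIVE, UNCLASSIFIABLE):
            valid: dict[str, float] = {}
        else:
            valid = expected_classes(p[i, 0], p[i, 1])
        counts = Counter(obs)
        class_counts = {g: int(counts.get(g, 0)) for g in valid}
        n_invalid = len(obs) - sum(class_counts.values())
        records.append(
            MarkerStats(mid, cfg, miss_frac, maf, class_counts, n_invalid)
        )
    df = pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in records],
            "configuration": [r.configuration for r in records],
            "missing_fraction": [r.missing_fraction for r in records],
            "maf": [r.maf for r in records],
            "class_counts": [r.class_counts for r in records],
            "n_invalid": [r.n_invalid for r in records],
        },
        index=gm.marker_ids,
    )
    return df


def filter_markers(
    gm: GenotypeMatrix,
    max_missing: float = 0.20,
    min_maf: float = 0.10,
    stats: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers with excessive missing data or low MAF.

    A marker is kept iff missing_fraction <= ``max_missing`` and
    maf >= ``min_maf`` and it is informative in the cross.  Returns the kept
    matrix and a drop report listing every removed marker with its reason.
    """
    if stats is None:
        stats = marker_stats(gm)
    reasons = []
    for mid, row in stats.iterrows():
        if row["missing_fraction"] > max_missing:
            reasons.append((mid, "missing"))
        elif not np.isfinite(row["maf"]) or row["maf"] < min_maf:
            reasons.append((mid, "maf"))
        elif row["configuration"] in (UNINFORMATIVE, UNCLASSIFIABLE):
            reasons.append((mid, row["configuration"]))
    report = pd.DataFrame(reasons, columns=["marker_id", "reason"])
    kept = stats.index.difference(pd.Index(report["marker_id"]), sort=False)
    return gm.subset(kept), report


@dataclasses.dataclass
class DistortionResult:
    marker_id: str
    configuration: str
    chi2: float
    df: int
    p: float
    flag: str
    favored_class: str


def segregation_chisq(
    class_counts: dict[str, int],
    configuration: str,
    expected: dict[str, float] | None = None,
    p_distorted: float = 0.10,
    p_excluded: float = 0.001,
) -> DistortionResult:
    """Pearson chi-square of observed genotype-class counts against Mendelian
    expectation (1:1 backcross-type, 1:2:1 ABxAB, 1:1:1:1 ABxCD).

    ``expected`` overrides the uniform-by-configuration ratios when the class
    labels carry their own proportions (as produced by
    :func:`expected_classes`).  df = number of classes - 1, i.e. 1/2/3 by
    configuration.  The favored class is the one with the largest signed
    deviation from its expectation.
    """
    if expected is None:
        if configuration in ("ABxAA", "AAxAB"):
            ratios = [0.5, 0.5]
        elif configuration == "ABxAB":
            ratios = [0.25, 0.5, 0.25]
        elif configuration == "ABxCD":
            ratios = [0.25] * 4
        else:
            raise ValueError(f"no Mendelian expectation for {configuration!r}")
        keys = sorted(class_counts)
        if len(keys) != len(ratios):
            raise ValueError(
                f"{configuration}: expected {len(ratios)} classes, got {keys}"
            )
        expected = dict(zip(keys, ratios))
    keys = sorted(expected)
    obs = np.array([class_counts.get(k, 0) for k in keys], dtype=float)
    total = obs.sum()
    if total == 0:
        return DistortionResult("", configuration, float("nan"),
                                len(keys) - 1, float("nan"), "undefined", "")
    exp = np.array([expected[k] for k in keys]) * total
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(keys) - 1
    p = float(sps.chi2.sf(chi2, df))
    if p < p_excluded:
        flag = FLAG_EXCLUDED
    elif p < p_distorted:
        flag = FLAG_DISTORTED
    else:
        flag = FLAG_OK
    favored = keys[int(np.argmax(obs - exp))]
    return DistortionResult("", configuration, chi2, df, p, flag, favored)


def distortion_scan(
    gm: GenotypeMatrix,
    stats: pd.DataFrame | None = None,
    map_table: pd.DataFrame | None = None,
    p_distorted: float = 0.10,
    p_excluded: float = 0.001,
) -> pd.DataFrame:
    """Per-marker segregation-distortion test across the genome.

    Returns one row per classifiable marker: chi2, df, p, flag and favored
    class; merged with map positions when a map table is supplied, enabling
    the per-LG distortion summary of :func:`distortion_summary`.  No
    multiple-testing correction is applied: the scan reports raw p-value
    thresholds (flag at p < 0.10, exclude at p < 0.001).
    """
    if stats is None:
        stats = marker_stats(gm)
    parents = gm.parents
    rows = []
    for mid, srow in stats.iterrows():
        cfg = srow["configuration"]
        if cfg in (UNINFORMATIVE, UNCLASSIFIABLE):
            continue
        exp = expected_classes(parents.loc[mid].iloc[0], parents.loc[mid].iloc[1])
        res = segregation_chisq(srow["class_counts"], cfg, expected=exp,
                                p_distorted=p_distorted, p_excluded=p_excluded)
        rows.append((mid, cfg, res.chi2, res.df, res.p, res.flag,
                     res.favored_class))
    out = pd.DataFrame(
        rows,
        columns=["marker_id", "configuration", "chi2", "df", "p", "flag",
                 "favored_class"],
    )
    if map_table is not None:
        out = out.merge(
            map_table[["marker_id", "lg", "position"]], on="marker_id",
            how="left",
        )
    return out


def distortion_summary(scan: pd.DataFrame) -> pd.DataFrame:
    """Per-LG distorted-marker tallies (count, percent, favored classes)."""
    if "lg" not in scan.columns:
        raise ValueError("scan has no map positions; pass map_table to distortion_scan")
    rows = []
    for lg, grp in scan.groupby("lg", dropna=True):
        n = len(grp)
        dist = grp[grp["flag"].isin([FLAG_DISTORTED, FLAG_EXCLUDED])]
        het_favored = int(
            dist["favored_class"].map(lambda g: g[0] != g[1]).sum()
        ) if len(dist) else 0
        rows.append((int(lg), n, len(dist), 100.0 * len(dist) / n if n else 0.0,
                     het_favored, len(dist) - het_favored))
    return pd.DataFrame(
        rows,
        columns=["lg", "n_markers", "n_distorted", "pct_distorted",
                 "favor_het", "favor_hom"],
    )


def excluded_marker_ids(scan: pd.DataFrame) -> list[str]:
    """Markers failing the hard distortion threshold (excluded from mapping)."""
    return scan.loc[scan["flag"] == FLAG_EXCLUDED, "marker_id"].tolist()
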