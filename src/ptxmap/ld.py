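"""Gametic linkage disequilibrium in phased biparental data.

For two loci with alleles A/a and B/b, haplotype frequency pi_AB and allele
frequencies pi_A etc., the disequilibrium coefficient is
D = pi_AB - pi_A pi_B and

    r2 = D^2 / (pi_A pi_a pi_B pi_b),

which on 0/1 gamete vectors equals the squared Pearson correlation.  LD is
computed on the uniparental (DH-coded) marker sets of each parental bin map;
decay is summarised as the mean r2 in 5-cM map-separation bins pooled
genome-wide over 0–50 cM, and the decay distance is the linearly
interpolated crossing of a threshold (0.2 by convention).

In a full-sib family every pair of linked loci starts in complete
disequilibrium, so the expected r2 at recombination fraction theta is
(1 - 2 theta)^2 plus a finite-sample inflation of order 1/n.  The
:func:`simulate_decay_curve` harness draws locus pairs whose theta is the
Kosambi inverse of their map separation, giving the analytic reference the
data-driven curve is compared against.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .linkage import PhasedGameteMatrix, pairwise_rf_lod
from .simulate import simulate_locus_pair


@dataclasses.dataclass
class LDStat:
    """Haplotype/allele frequencies and r2 for one locus pair."""

    pi_ab: tuple[float, float, float, float]  # AB, Ab, aB, ab
    pi_a: float   # frequency of allele "1" at locus A
    pi_b: float
    d: float
    r2: float
    n: int


def gametic_r2(x: np.ndarray, y: np.ndarray) -> LDStat | None:
    """Gametic r2 between two 0/1 vectors over pairwise-complete entries.

    Returns None when fewer than 2 complete gametes remain or either locus
    is monomorphic in the complete subset (r2 undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 2:
        return None
    xa, ya = x[ok], y[ok]
    p_a = xa.mean()
    p_b = ya.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return None
    p_ab = float((xa * ya).mean())
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    pi = (p_ab, p_a - p_ab, p_b - p_ab, 1 - p_a - p_b + p_ab)
    return LDStat(pi_ab=pi, pi_a=p_a, pi_b=p_b, d=d, r2=r2, n=n)


def _r2_matrix(data: np.ndarray) -> np.ndarray:
    """All-pairs gametic r2 over pairwise-complete entries (NaN where
    undefined)."""
    v = np.isfinite(data).astype(float)
    a = np.where(v > 0, data, 0.0)
    n = v @ v.T
    sx = a @ v.T
    sxy = a @ a.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = sx / n
        my = mx.T
        cov = sxy / n - mx * my
        var_x = mx - mx ** 2   # x in {0,1} so E[x^2] = E[x]
        var_y = var_x.T
        r2 = np.where((var_x > 0) & (var_y > 0) & (n >= 2),
                      cov * cov / (var_x * var_y), np.nan)
    return r2


@dataclasses.dataclass
class LDMatrices:
    """Fig-style matrix pair: r2 (LD) and r (recombination), map-ordered."""

    marker_ids: pd.Index
    positions: np.ndarray
    r2: np.ndarray
    rf: np.ndarray

    def combined(self) -> np.ndarray:
        """Upper triangle r2, lower triangle recombination fraction."""
        out = np.tril(self.rf, -1) + np.triu(self.r2, 1)
        return out


def ld_matrix(pgm: PhasedGameteMatrix, map_table: pd.DataFrame) -> LDMatrices:
    """LD (r2) and recombination matrices for the mapped markers of one
    parent, sorted by map position (LG-major)."""
    mt = map_table.sort_values(["lg", "position", "marker_id"])
    id_to_row = {m: i for i, m in enumerate(pgm.marker_ids)}
    rows = [id_to_row[m] for m in mt["marker_id"] if m in id_to_row]
    ids = pd.Index([m for m in mt["marker_id"] if m in id_to_row])
    data = pgm.data[rows]
    r2 = _r2_matrix(data)
    np.fill_diagonal(r2, 1.0)
    rf = pairwise_rf_lod(data, marker_ids=ids).r
    return LDMatrices(
        marker_ids=ids,
        positions=mt.loc[mt["marker_id"].isin(ids), "position"].to_numpy(),
        r2=r2, rf=rf,
    )


@dataclasses.dataclass
class LDDecayCurve:
    """Mean gametic r2 per map-separation bin (half-open [lo, hi) cM)."""

    bin_edges: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    n_skipped: int = 0

    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "n_pairs": self.n_pairs,
            "mean_r2": self.mean_r2,
        })


#: sentinel returned when a curve never falls below the threshold
BEYOND_MAX = float("inf")


def ld_decay_curve(pgm: PhasedGameteMatrix, map_table: pd.DataFrame,
                   bin_width: float = 5.0, max_cm: float = 50.0,
                   per_lg: bool = False,
                   ) -> LDDecayCurve | dict[int, LDDecayCurve]:
    """Binned LD-decay curve over all intra-LG marker pairs.

    Pairs are pooled genome-wide (or per LG with ``per_lg``); each pair is
    assigned to a bin by cM separation.  Pairs where r2 is undefined
    (monomorphic in the complete subset) are skipped and counted.
    """
    edges = np.arange(0.0, max_cm + bin_width / 2, bin_width)
    per = {}
    id_to_row = {m: i for i, m in enumerate(pgm.marker_ids)}
    for lg, grp in map_table.groupby("lg"):
        grp = grp.sort_values(["position", "marker_id"])
        rows = [id_to_row[m] for m in grp["marker_id"] if m in id_to_row]
        pos = grp.loc[grp["marker_id"].isin(pgm.marker_ids),
                      "position"].to_numpy()
        if len(rows) < 2:
            continue
        r2 = _r2_matrix(pgm.data[rows])
        iu = np.triu_indices(len(rows), 1)
        dist = np.abs(pos[iu[0]] - pos[iu[1]])
        vals = r2[iu]
        per[int(lg)] = (dist, vals)
    if per_lg:
        return {lg: _bin_curve(d, v, edges) for lg, (d, v) in per.items()}
    if not per:
        raise ValueError("no intra-LG pairs available")
    dist = np.concatenate([d for d, _ in per.values()])
    vals = np.concatenate([v for _, v in per.values()])
    return _bin_curve(dist, vals, edges)


def _bin_curve(dist: np.ndarray, vals: np.ndarray,
               edges: np.ndarray) -> LDDecayCurve:
    in_range = dist < edges[-1]
    skipped = int((~np.isfinite(vals) & in_range).sum())
    ok = np.isfinite(vals) & in_range
    dist, vals = dist[ok], vals[ok]
    idx = np.digitize(dist, edges) - 1  # half-open [lo, hi)
    nbins = len(edges) - 1
    mean = np.full(nbins, np.nan)
    count = np.zeros(nbins, dtype=np.int64)
    for b in range(nbins):
        sel = idx == b
        count[b] = int(sel.sum())
        if count[b]:
            mean[b] = float(vals[sel].mean())
    return LDDecayCurve(bin_edges=edges, mean_r2=mean, n_pairs=count,
                        n_skipped=skipped)


def decay_distance(curve: LDDecayCurve, threshold: float = 0.2) -> float:
    """Map distance at which mean r2 first falls below ``threshold``.

    Linear interpolation between the centers of the two non-empty bins that
    straddle the first downward crossing; the first bin center when the
    curve starts at or below the threshold; :data:`BEYOND_MAX` when it never
    crosses.
    """
    centers = curve.centers()
    ok = np.isfinite(curve.mean_r2)
    c = centers[ok]
    m = curve.mean_r2[ok]
    if len(m) == 0:
        raise ValueError("empty decay curve")
    if m[0] <= threshold:
        return float(c[0])
    for i in range(len(m) - 1):
        if m[i] >= threshold > m[i + 1]:
            frac = (m[i] - threshold) / (m[i] - m[i + 1])
            return float(c[i] + (c[i + 1] - c[i]) * frac)
    return BEYOND_MAX


def simulate_decay_curve(n: int = 362, pairs_per_bin: int = 200,
                         bin_width: float = 5.0, max_cm: float = 50.0,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None,
                         ) -> LDDecayCurve:
    """Two-locus LD-decay harness at Kosambi-consistent recombination.

    For each 5-cM bin, draws ``pairs_per_bin`` locus pairs with separations
    uniform in the bin, simulates ``n`` gametes per pair at
    theta = 0.5 tanh(2d/100) and records the mean gametic r2.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    edges = np.arange(0.0, max_cm + bin_width / 2, bin_width)
    nbins = len(edges) - 1
    mean = np.full(nbins, np.nan)
    count = np.zeros(nbins, dtype=np.int64)
    skipped = 0
    for b in range(nbins):
        vals = []
        for _ in range(pairs_per_bin):
            d = rng.uniform(edges[b], edges[b + 1])
            g1, g2 = simulate_locus_pair(d, n, rng)
            stat = gametic_r2(g1, g2)
            if stat is None:
                skipped += 1
                continue
            vals.append(stat.r2)
        count[b] = len(vals)
        if vals:
            mean[b] = float(np.mean(vals))
    return LDDecayCurve(bin_edges=edges, mean_r2=mean, n_pairs=count,
                        n_skipped=skipped)


def expected_r2(theta: float | np.ndarray, n: int | None = None):
    """Expected gametic r2 at recombination fraction theta in a full-sib
    family: (1 - 2 theta)^2, plus the 1/n finite-sample inflation when n is
    given."""
    base = (1.0 - 2.0 * np.asarray(theta, dtype=float)) ** 2
    if n:
        base = base + 1.0 / n
    return base


# ---------------------------------------------------------------------------
# simple static exports

def plot_decay_curve(curve: LDDecayCurve, path, threshold: float = 0.2) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.centers(), curve.mean_r2, "o-", color="firebrick")
    ax.axhline(threshold, ls="--", color="gray", lw=0.8)
    ax.set_xlabel("map distance (cM)")
    ax.set_ylabel("mean $r^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ld_heatmap(matrices: LDMatrices, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(matrices.combined(), cmap="RdYlBu_r", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, shrink=0.8,
                 label="upper: $r^2$   lower: rec. fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
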