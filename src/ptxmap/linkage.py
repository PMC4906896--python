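"""Linkage-map construction for pseudo-testcross populations.

Uniparental markers (ABxAA for the maternal parent, AAxAB for the paternal
parent, plus one split copy of each fully informative ABxCD marker per
parent) are recoded to the 0/1 transmitted-homolog representation of a
doubled-haploid population.  From there the pipeline is:

1. pairwise recombination fraction and two-point LOD over pairwise-complete
   gametes;
2. single-linkage grouping at LOD > 10 and r < 0.35;
3. linkage-phase inference within each group (a marker's 0/1 polarity is
   arbitrary until linked neighbours orient it);
4. collapse of cosegregating markers (zero observed recombination) into bins;
5. bin ordering: minimum spanning tree of the r-weighted complete graph,
   longest tree path as backbone, SARF-minimising insertion of off-path bins
   and a windowed ripple refinement (SARF = sum of adjacent recombination
   fractions);
6. a double-recombinant scan that flags isolated singleton genotypes as
   likely genotyping errors;
7. Kosambi map distances from adjacent recombination fractions; and
8. integration of the two parental maps through shared double-heterozygous
   (ABxAB) anchor markers, parental orders held fixed.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from .formats_io import MISSING, GenotypeMatrix
from . import qc

LOD_MIN_DEFAULT = 10.0
RF_MAX_DEFAULT = 0.35


class LinkageError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# DH recoding and phasing

@dataclasses.dataclass
class PhasedGameteMatrix:
    """Per-parent transmitted-homolog matrix: rows markers, columns gametes.

    ``data`` holds 0.0/1.0/NaN.  ``phase_flags`` records, per marker, whether
    its raw coding was flipped during phase inference, so the transformation
    stays reversible.
    """

    data: np.ndarray
    marker_ids: pd.Index
    parent: str
    phase_flags: pd.Series
    configurations: pd.Series

    @property
    def n_markers(self) -> int:
        return self.data.shape[0]

    @property
    def n_gametes(self) -> int:
        return self.data.shape[1]

    def subset(self, idx: Sequence[int]) -> "PhasedGameteMatrix":
        idx = np.asarray(idx)
        return PhasedGameteMatrix(
            data=self.data[idx],
            marker_ids=self.marker_ids[idx],
            parent=self.parent,
            phase_flags=self.phase_flags.iloc[idx],
            configurations=self.configurations.iloc[idx],
        )


def _transmitted_code(parent_call: str, other_call: str,
                      progeny_call: str) -> float:
    """Which of the het parent's two (sorted) alleles a progeny call carries.

    Returns 0.0/1.0, or NaN when the call is missing, Mendelian-invalid, or
    ambiguous (both-het markers with a het progeny call).
    """
    if progeny_call == MISSING:
        return np.nan
    x, y = sorted(parent_call)
    g = list(progeny_call)
    # remove one allele attributable to the other parent, then read the rest
    for o in sorted(set(other_call)):
        if o in g:
            rest = list(g)
            rest.remove(o)
            a = rest[0]
            if a == x and (a != y):
                return 0.0
            if a == y and (a != x):
                return 1.0
            if a == x == y:
                return 0.0
    return np.nan


def recode_uniparental(gm: GenotypeMatrix, parent: str,
                       stats: pd.DataFrame | None = None) -> PhasedGameteMatrix:
    """Recode the markers heterozygous in ``parent`` to 0/1 gamete calls.

    Takes ABxAA (for P1) or AAxAB (for P2) markers plus the parent's split of
    every ABxCD marker; ABxAB markers are excluded (their het progeny do not
    reveal which parent transmitted which allele) and are used later as
    integration anchors.
    """
    if stats is None:
        stats = qc.marker_stats(gm)
    p1_name, p2_name = gm.parent_names
    own_cfg = "ABxAA" if parent == p1_name else "AAxAB"
    keep = stats["configuration"].isin([own_cfg, "ABxCD"])
    ids = stats.index[keep]
    data = np.full((len(ids), gm.n_samples), np.nan)
    calls = gm.calls.loc[ids].to_numpy()
    parents = gm.parents.loc[ids]
    own = parents[parent].to_numpy()
    other = parents[p2_name if parent == p1_name else p1_name].to_numpy()
    for i in range(len(ids)):
        lut = {}
        for g in qc.expected_classes(own[i], other[i]):
            lut[g] = _transmitted_code(own[i], other[i], g)
        row = calls[i]
        data[i] = [lut.get(c, np.nan) for c in row]
    return PhasedGameteMatrix(
        data=data,
        marker_ids=pd.Index(ids),
        parent=parent,
        phase_flags=pd.Series(False, index=ids),
        configurations=stats.loc[ids, "configuration"],
    )


def recode_abxab_for_integration(gm: GenotypeMatrix,
                                 stats: pd.DataFrame | None = None,
                                 ) -> PhasedGameteMatrix:
    """0/1 gamete codes of ABxAB markers from homozygous progeny only.

    A homozygous offspring of an ABxAB marker reveals the transmission of
    both parents simultaneously; het offspring are coded missing.  The same
    vector therefore anchors the marker in either parental framework.
    """
    if stats is None:
        stats = qc.marker_stats(gm)
    ids = stats.index[stats["configuration"] == "ABxAB"]
    data = np.full((len(ids), gm.n_samples), np.nan)
    calls = gm.calls.loc[ids].to_numpy()
    parents = gm.parents.loc[ids]
    own = parents.iloc[:, 0].to_numpy()
    for i in range(len(ids)):
        x, y = sorted(own[i])
        lut = {x + x: 0.0, y + y: 1.0}
        data[i] = [lut.get(c, np.nan) for c in calls[i]]
    return PhasedGameteMatrix(
        data=data,
        marker_ids=pd.Index(ids),
        parent="both",
        phase_flags=pd.Series(False, index=ids),
        configurations=stats.loc[ids, "configuration"],
    )


def split_by_configuration(gm: GenotypeMatrix,
                           stats: pd.DataFrame | None = None,
                           ) -> dict[str, PhasedGameteMatrix]:
    """Separate the marker set into the two parental DH sets plus anchors."""
    if stats is None:
        stats = qc.marker_stats(gm)
    p1, p2 = gm.parent_names
    return {
        p1: recode_uniparental(gm, p1, stats),
        p2: recode_uniparental(gm, p2, stats),
        "ABxAB": recode_abxab_for_integration(gm, stats),
    }


# ---------------------------------------------------------------------------
# Pairwise recombination and LOD

@dataclasses.dataclass
class RFMatrix:
    """Pairwise recombination fractions over pairwise-complete gametes.

    ``r`` is the raw fraction under the current marker polarities (may exceed
    0.5 for unphased input); ``n`` the informative gamete count.  ``r_min``
    and ``lod_min`` give the phase-invariant orientation used for grouping.
    """

    r: np.ndarray
    n: np.ndarray
    marker_ids: pd.Index

    @property
    def recombinants(self) -> np.ndarray:
        return self.r * self.n

    def r_min(self) -> np.ndarray:
        return np.minimum(self.r, 1.0 - self.r)

    def lod(self) -> np.ndarray:
        return _lod(self.n, self.recombinants)

    def lod_min(self) -> np.ndarray:
        rec = np.minimum(self.recombinants, self.n - self.recombinants)
        return _lod(self.n, rec)


def _lod(n: np.ndarray, rec: np.ndarray) -> np.ndarray:
    """Two-point backcross LOD: (N-R) log10 2(1-r) + R log10 2r.

    At r = 0 the formula reduces to N log10 2 (the R log10(2r) term has a
    zero coefficient); at r = 0.5 it is exactly 0.
    """
    n = np.asarray(n, dtype=float)
    rec = np.asarray(rec, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, rec / np.maximum(n, 1), np.nan)
        t1 = (n - rec) * np.log10(np.maximum(2.0 * (1.0 - r), 1e-300))
        t2 = np.where(rec > 0, rec * np.log10(np.maximum(2.0 * r, 1e-300)), 0.0)
    out = t1 + t2
    out = np.where(n > 0, out, np.nan)
    return out


def pairwise_rf_lod(pgm: PhasedGameteMatrix | np.ndarray,
                    marker_ids: pd.Index | None = None) -> RFMatrix:
    """All-pairs recombination fraction, informative count and LOD.

    r_ij = R/N where N counts gametes scored at both markers and R those
    scored differently.  Pairs with N = 0 are uninformative (NaN r).
    """
    if isinstance(pgm, PhasedGameteMatrix):
        data = pgm.data
        marker_ids = pgm.marker_ids
    else:
        data = np.asarray(pgm, dtype=float)
        if marker_ids is None:
            marker_ids = pd.Index(range(data.shape[0]))
    valid = np.isfinite(data)
    a = np.where(valid, data, 0.0)
    v = valid.astype(np.float64)
    n = v @ v.T
    b = v - a  # indicator of allele 0 where valid
    rec = a @ b.T + b @ a.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(n > 0, rec / np.maximum(n, 1), np.nan)
    np.fill_diagonal(r, 0.0)
    return RFMatrix(r=r, n=n, marker_ids=pd.Index(marker_ids))


def rf_between(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Recombination fraction and informative count for one marker pair."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n == 0:
        return float("nan"), 0
    rec = int((x[ok] != y[ok]).sum())
    return rec / n, n


# ---------------------------------------------------------------------------
# Grouping and phasing

def group_markers(rf: RFMatrix, lod_min: float = LOD_MIN_DEFAULT,
                  rf_max: float = RF_MAX_DEFAULT) -> list[np.ndarray]:
    """Single-linkage transitive closure over strong linkage edges.

    Edge criterion: LOD (at the phase-invariant orientation) > ``lod_min``
    and r < ``rf_max``.  Groups are returned as index arrays sorted by
    descending size; singletons come last.
    """
    lod = rf.lod_min()
    rmin = rf.r_min()
    adj = (lod > lod_min) & (rmin < rf_max) & np.isfinite(rmin)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [np.flatnonzero(labels == k) for k in range(n_comp)]
    groups.sort(key=lambda g: (-len(g), rf.marker_ids[g[0]]))
    return groups


def infer_phase(pgm: PhasedGameteMatrix, group: np.ndarray, rf: RFMatrix,
                lod_min: float = LOD_MIN_DEFAULT) -> PhasedGameteMatrix:
    """Orient marker polarities within one linkage group.

    Starting from the group's most connected marker, a breadth-first walk
    over strong-LOD edges flips every marker whose raw r to an already
    oriented neighbour exceeds 0.5, so that all within-group recombination
    fractions end up <= 0.5.  With error-free data the result matches the
    true parental phases up to one global flip per group.
    """
    sub = pgm.subset(group)
    lod = rf.lod_min()[np.ix_(group, group)]
    r = rf.r[np.ix_(group, group)]
    m = len(group)
    adj = (lod > lod_min) & np.isfinite(r)
    np.fill_diagonal(adj, False)
    degree = adj.sum(axis=1)
    seed = int(np.argmax(degree))
    flips = np.zeros(m, dtype=bool)
    seen = np.zeros(m, dtype=bool)
    seen[seed] = True
    frontier = [seed]
    while frontier:
        nxt = []
        for i in frontier:
            for j in np.flatnonzero(adj[i] & ~seen):
                flips[j] = flips[i] ^ (r[i, j] > 0.5)
                seen[j] = True
                nxt.append(j)
        frontier = nxt
    if not seen.all():
        unreached = sub.marker_ids[~seen].tolist()
        warnings.warn(
            f"{len(unreached)} marker(s) unlinked to the phasing seed; left "
            f"unphased: {unreached[:5]}...", stacklevel=2,
        )
    data = sub.data.copy()
    data[flips] = 1.0 - data[flips]
    return PhasedGameteMatrix(
        data=data,
        marker_ids=sub.marker_ids,
        parent=sub.parent,
        phase_flags=pd.Series(flips, index=sub.marker_ids),
        configurations=sub.configurations,
    )


# ---------------------------------------------------------------------------
# Bins

@dataclasses.dataclass
class Bin:
    representative: str
    members: list[str]
    rep_index: int          # row index into the group's phased matrix
    member_indices: list[int]


def collapse_bins(pgm: PhasedGameteMatrix, rf: RFMatrix | None = None) -> list[Bin]:
    """Group cosegregating markers (zero observed recombination) into bins.

    Two markers cosegregate when their gamete vectors agree on every
    pairwise-complete entry; bins are the single-linkage components of that
    relation.  The representative is the member with the least missing data
    (ties broken lexicographically on marker id).
    """
    if rf is None:
        rf = pairwise_rf_lod(pgm)
    rec = rf.recombinants
    zero = (rec < 0.5) & (rf.n >= 1)
    np.fill_diagonal(zero, True)
    n_comp, labels = connected_components(csr_matrix(zero), directed=False)
    n_missing = (~np.isfinite(pgm.data)).sum(axis=1)
    bins = []
    for k in range(n_comp):
        idx = np.flatnonzero(labels == k)
        ids = pgm.marker_ids[idx]
        order = sorted(range(len(idx)), key=lambda i: (n_missing[idx[i]], ids[i]))
        rep = order[0]
        bins.append(Bin(
            representative=str(ids[rep]),
            members=[str(x) for x in ids],
            rep_index=int(idx[rep]),
            member_indices=[int(i) for i in idx],
        ))
    bins.sort(key=lambda b: b.rep_index)
    return bins


# ---------------------------------------------------------------------------
# Ordering

def sarf(order: Sequence[int], d: np.ndarray) -> float:
    """Sum of adjacent recombination fractions for one ordering."""
    o = np.asarray(order)
    return float(d[o[:-1], o[1:]].sum())


def order_markers_mst(d: np.ndarray, ripple_window: int = 5,
                      max_passes: int = 15) -> list[int]:
    """Order bins by MST backbone + SARF-minimising insertion + ripple.

    ``d`` is the symmetric matrix of (phase-corrected) recombination
    fractions between bin representatives.  The minimum spanning tree of the
    complete r-weighted graph is computed, its weighted diameter path taken
    as the backbone, remaining bins inserted where they least increase SARF,
    and a sliding exhaustive ripple (window ``ripple_window``) applied until
    no improvement.  Orientation is canonical: the first element's index is
    smaller than the last's.
    """
    m = d.shape[0]
    if m == 0:
        return []
    if m <= 2:
        return list(range(m))
    if not np.isfinite(d[np.triu_indices(m, 1)]).all():
        raise LinkageError("recombination matrix has uninformative pairs; "
                           "cannot order a disconnected group")
    w = np.maximum(d, 1e-9)  # csgraph treats exact zeros as absent edges
    np.fill_diagonal(w, 0.0)
    mst = minimum_spanning_tree(csr_matrix(w))
    mst = mst + mst.T
    backbone = _tree_diameter_path(mst)
    order = list(backbone)
    remaining = [i for i in range(m) if i not in set(order)]
    # attach nearest-first so each insertion sees its linked neighbours
    remaining.sort(key=lambda i: d[i, order].min())
    for x in remaining:
        best_cost, best_slot = np.inf, 0
        for slot in range(len(order) + 1):
            if slot == 0:
                cost = d[x, order[0]]
            elif slot == len(order):
                cost = d[order[-1], x]
            else:
                a, b = order[slot - 1], order[slot]
                cost = d[a, x] + d[x, b] - d[a, b]
            if cost < best_cost - 1e-15:
                best_cost, best_slot = cost, slot
        order.insert(best_slot, x)
    order = _ripple(order, d, window=ripple_window, max_passes=max_passes)
    if order[0] > order[-1]:
        order.reverse()
    return order


def _tree_diameter_path(tree: csr_matrix) -> list[int]:
    import networkx as nx

    g = nx.from_scipy_sparse_array(tree)
    far = max(nx.single_source_dijkstra_path_length(g, 0).items(),
              key=lambda kv: kv[1])[0]
    lengths, paths = nx.single_source_dijkstra(g, far)
    end = max(lengths.items(), key=lambda kv: kv[1])[0]
    return paths[end]


def _ripple(order: list[int], d: np.ndarray, window: int,
            max_passes: int) -> list[int]:
    m = len(order)
    if m <= window:
        perms = itertools.permutations(range(m))
        best = min(perms, key=lambda p: sarf([order[i] for i in p], d))
        return [order[i] for i in best]
    all_perms = list(itertools.permutations(range(window)))
    for _ in range(max_passes):
        improved = False
        for start in range(m - window + 1):
            seg = order[start:start + window]
            left = order[start - 1] if start > 0 else None
            right = order[start + window] if start + window < m else None

            def seg_cost(s):
                c = sarf(s, d)
                if left is not None:
                    c += d[left, s[0]]
                if right is not None:
                    c += d[s[-1], right]
                return c

            base = seg_cost(seg)
            best_c, best_s = base, seg
            for p in all_perms[1:]:
                cand = [seg[i] for i in p]
                c = seg_cost(cand)
                if c < best_c - 1e-12:
                    best_c, best_s = c, cand
            if best_s != seg:
                order[start:start + window] = best_s
                improved = True
        if not improved:
            break
    return order


# ---------------------------------------------------------------------------
# Mapping function

def kosambi(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance in cM: d = 25 ln((1 + 2r)/(1 - 2r))."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("Kosambi distance defined for r in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Inverse Kosambi: r = 0.5 tanh(2 d / 100)."""
    d = np.asarray(d_cm, dtype=float)
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# Genotyping-error scan

def scan_double_recombinants(data: np.ndarray,
                             drop_threshold: float = 0.05,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Flag isolated double crossovers in an *ordered* gamete matrix.

    A genotype is flagged when it differs from both adjacent informative
    genotypes of the same gamete — the signature of a genotyping error on a
    dense map, where true double crossovers within a few cM are vanishingly
    rare.  Returns (flag matrix, marker drop mask); a marker is dropped when
    its flagged fraction of informative genotypes exceeds ``drop_threshold``.
    """
    m, n = data.shape
    flags = np.zeros((m, n), dtype=bool)
    for j in range(n):
        col = data[:, j]
        idx = np.flatnonzero(np.isfinite(col))
        if len(idx) < 3:
            continue
        v = col[idx]
        mid = (v[1:-1] != v[:-2]) & (v[1:-1] != v[2:])
        flags[idx[1:-1][mid], j] = True
    informative = np.isfinite(data).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(informative > 0, flags.sum(axis=1) / np.maximum(informative, 1), 0.0)
    dropped = frac > drop_threshold
    return flags, dropped


def clean_genotypes(data: np.ndarray, flags: np.ndarray) -> np.ndarray:
    out = data.copy()
    out[flags] = np.nan
    return out


# ---------------------------------------------------------------------------
# Map building

def count_sign_changes(data: np.ndarray) -> np.ndarray:
    """Observed recombination events per gamete: sign changes along each
    column of an ordered 0/1 matrix, skipping missing entries."""
    m, n = data.shape
    out = np.zeros(n, dtype=np.int64)
    for j in range(n):
        col = data[:, j]
        v = col[np.isfinite(col)]
        if len(v) > 1:
            out[j] = int(np.count_nonzero(np.diff(v)))
    return out


def build_lg_map(pgm: PhasedGameteMatrix, bins: list[Bin],
                 order: Sequence[int], lg: int) -> pd.DataFrame:
    """Positions from adjacent recombination fractions via Kosambi.

    ``order`` indexes into ``bins``.  Every bin member inherits its
    representative's cumulative position; the first bin sits at 0 cM.
    """
    reps = [bins[k].rep_index for k in order]
    pos = [0.0]
    for a, b in zip(reps[:-1], reps[1:]):
        r, n = rf_between(pgm.data[a], pgm.data[b])
        if not np.isfinite(r) or n == 0:
            warnings.warn(f"LG {lg}: uninformative adjacent pair; gap set to 0",
                          stacklevel=2)
            d = 0.0
        else:
            if r >= 0.5:
                warnings.warn(
                    f"LG {lg}: adjacent r >= 0.5 (map break); distance clamped",
                    stacklevel=2,
                )
                r = 0.4999
            d = kosambi(r)
        pos.append(pos[-1] + d)
    rows = []
    for bin_id, (k, p) in enumerate(zip(order, pos), start=1):
        b = bins[k]
        for mid in b.members:
            rows.append((mid, lg, p, bin_id))
    df = pd.DataFrame(rows, columns=["marker_id", "lg", "position", "bin_id"])
    cfg = pgm.configurations
    df["configuration"] = df["marker_id"].map(cfg).to_numpy()
    return df


def count_recombination_events(pgm: PhasedGameteMatrix,
                               map_table: pd.DataFrame) -> pd.DataFrame:
    """Per-LG observed recombination events per gamete (mean/min over LGs
    computed by the caller; one row per LG with the per-gamete mean)."""
    rows = []
    id_to_row = {mid: i for i, mid in enumerate(pgm.marker_ids)}
    for lg, grp in map_table.groupby("lg"):
        grp = grp.sort_values(["position", "marker_id"])
        idx = [id_to_row[m] for m in grp["marker_id"] if m in id_to_row]
        if len(idx) < 2:
            continue
        counts = count_sign_changes(pgm.data[idx])
        rows.append((int(lg), len(idx), float(counts.mean()),
                     int(counts.min()), int(counts.max())))
    return pd.DataFrame(
        rows, columns=["lg", "n_markers", "mean_events", "min_events",
                       "max_events"],
    )


# ---------------------------------------------------------------------------
# Integration of the two parental maps

def cross_rf(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Phase-invariant recombination fractions between two marker sets.

    Returns (r_min, n) of shape (rows of a, rows of b) over pairwise-complete
    gametes, with r folded to min(r, 1-r) because the two sets need not share
    a phase convention.
    """
    va = np.isfinite(a).astype(float)
    vb = np.isfinite(b).astype(float)
    xa = np.where(va > 0, a, 0.0)
    xb = np.where(vb > 0, b, 0.0)
    n = va @ vb.T
    rec = xa @ (vb - xb).T + (va - xa) @ xb.T
    rec = np.minimum(rec, n - rec)
    with np.errstate(invalid="ignore"):
        r = np.where(n > 0, rec / np.maximum(n, 1), np.nan)
    return r, n


def _slot_position(r_reps: np.ndarray, rep_pos: np.ndarray) -> float:
    """SARF-minimising insertion of one anchor into a fixed bin order.

    ``r_reps`` holds the anchor's phase-folded r to each ordered bin
    representative.  The insertion slot minimises the increase in the sum of
    adjacent recombination fractions (adjacent-rep r taken Kosambi-consistent
    with their map gap); the cM coordinate comes from Kosambi distances to
    the flanking representatives.
    """
    r = np.clip(np.nan_to_num(r_reps, nan=0.4999), 0.0, 0.4999)
    m = len(rep_pos)
    if m == 1:
        return float(rep_pos[0])
    gaps = kosambi_inverse(np.diff(rep_pos))
    costs = np.empty(m + 1)
    costs[0] = r[0]
    costs[m] = r[-1]
    costs[1:m] = r[:-1] + r[1:] - gaps
    s = int(np.argmin(costs))
    if s == 0:
        return float(rep_pos[0] - kosambi(r[0]))
    if s == m:
        return float(rep_pos[-1] + kosambi(r[-1]))
    pa = rep_pos[s - 1] + kosambi(r[s - 1])
    pb = rep_pos[s] - kosambi(r[s])
    return float(np.clip((pa + pb) / 2.0, rep_pos[s - 1], rep_pos[s]))


def _place_anchors(anchors: "PhasedGameteMatrix", pgm: "PhasedGameteMatrix",
                   pmap: pd.DataFrame, lod_attach: float) -> pd.DataFrame:
    """Anchor each ABxAB marker inside one parental framework (order fixed).

    Returns a frame (anchor row index -> lg, position, lod); anchors whose
    best two-point LOD is below ``lod_attach`` are omitted.
    """
    r, n = cross_rf(anchors.data, pgm.data)
    lod = _lod(n, r * n)
    id_to_row = {mid: i for i, mid in enumerate(pgm.marker_ids)}
    lg_of = dict(zip(pmap["marker_id"], pmap["lg"]))
    reps_by_lg = {}
    for lg, grp in pmap.groupby("lg"):
        reps = (grp.sort_values(["position", "marker_id"])
                .drop_duplicates("bin_id"))
        rows = [id_to_row[m] for m in reps["marker_id"] if m in id_to_row]
        reps_by_lg[lg] = (np.array(rows), reps["position"].to_numpy())
    rows_out = []
    best = np.nanmax(np.where(np.isfinite(lod), lod, -np.inf), axis=1)
    arg = np.nanargmax(np.where(np.isfinite(lod), lod, -np.inf), axis=1)
    for i in range(anchors.n_markers):
        if not np.isfinite(best[i]) or best[i] < lod_attach:
            continue
        lg = lg_of[pgm.marker_ids[arg[i]]]
        rep_rows, rep_pos = reps_by_lg[lg]
        pos = _slot_position(r[i, rep_rows], rep_pos)
        rows_out.append((i, lg, pos, best[i]))
    return pd.DataFrame(rows_out, columns=["anchor", "lg", "pos", "lod"])


def integrate_maps(p1_map: pd.DataFrame, p2_map: pd.DataFrame,
                   pgm1: PhasedGameteMatrix, pgm2: PhasedGameteMatrix,
                   anchors: PhasedGameteMatrix,
                   lod_attach: float = 10.0) -> pd.DataFrame:
    """Merge the parental maps through shared ABxAB anchor markers.

    Each anchor is positioned in both parental frameworks with the parental
    orders held fixed; LGs are paired by shared-anchor majority; the
    integrated coordinate system is the anchor-wise average of the two
    parental systems (the paternal axis flipped when anchors run in reverse),
    with uniparental markers carried over by piecewise-linear interpolation
    between anchors.  Positions are monotone within each integrated LG.
    """
    if anchors.n_markers == 0:
        raise LinkageError("no anchors: cannot integrate without shared "
                           "ABxAB markers")
    lgs1 = {lg: grp for lg, grp in p1_map.groupby("lg")}
    lgs2 = {lg: grp for lg, grp in p2_map.groupby("lg")}
    pl1 = _place_anchors(anchors, pgm1, p1_map, lod_attach)
    pl2 = _place_anchors(anchors, pgm2, p2_map, lod_attach)
    pl = pl1.merge(pl2, on="anchor", suffixes=("1", "2"))
    if pl.empty:
        raise LinkageError("no anchors could be placed in both parental maps")
    pl = pl.rename(columns={"pos1": "pos1", "pos2": "pos2"})
    pairing = (pl.groupby(["lg1", "lg2"]).size().reset_index(name="votes")
               .sort_values("votes", ascending=False))
    used1, used2, pairs = set(), set(), []
    for _, row in pairing.iterrows():
        if row["lg1"] not in used1 and row["lg2"] not in used2:
            pairs.append((row["lg1"], row["lg2"]))
            used1.add(row["lg1"])
            used2.add(row["lg2"])
    out_rows = []
    new_lg = 0
    for lg1, lg2 in sorted(pairs):
        new_lg += 1
        sub = pl[(pl["lg1"] == lg1) & (pl["lg2"] == lg2)]
        g1, g2 = lgs1[lg1], lgs2[lg2]
        if len(sub) < 2:
            warnings.warn(
                f"LG pair ({lg1},{lg2}) has <2 shared anchors; emitted "
                "unmerged", stacklevel=2,
            )
            out_rows.append(_unmerged(g1, new_lg))
            new_lg += 1
            out_rows.append(_unmerged(g2, new_lg))
            continue
        u = sub["pos1"].to_numpy()
        v = sub["pos2"].to_numpy()
        if len(u) > 1 and np.corrcoef(u, v)[0, 1] < 0:
            v = g2["position"].max() - v
            flip2 = True
        else:
            flip2 = False
        order = np.argsort(u, kind="stable")
        u, v = u[order], v[order]
        v = np.maximum.accumulate(v)  # enforce a monotone anchor scaffold
        w = (u + v) / 2.0
        w = np.maximum.accumulate(w)
        anchor_ids = anchors.marker_ids[sub["anchor"].to_numpy()[order]]
        pos1_int = _piecewise_map(g1["position"].to_numpy(), u, w)
        p2_pos = g2["position"].to_numpy()
        if flip2:
            p2_pos = g2["position"].max() - p2_pos
        pos2_int = _piecewise_map(p2_pos, v, w)
        df1 = g1.assign(position=pos1_int, lg=new_lg)
        df2 = g2.assign(position=pos2_int, lg=new_lg)
        dfa = pd.DataFrame({
            "marker_id": anchor_ids,
            "lg": new_lg,
            "position": w,
            "bin_id": -1,
            "configuration": "ABxAB",
        })
        merged = pd.concat([df1, df2, dfa], ignore_index=True)
        merged = merged.drop_duplicates("marker_id", keep="first")
        merged = merged.sort_values(["position", "marker_id"])
        merged["position"] -= merged["position"].min()
        merged["bin_id"] = (merged["position"].round(6).rank(method="dense")
                            .astype(int))
        out_rows.append(merged)
    out = pd.concat(out_rows, ignore_index=True)
    # ABxCD markers enter both parental frameworks as split copies; keep one
    out = out.drop_duplicates("marker_id", keep="first", ignore_index=True)
    return out


def concat_phased(parts: Sequence[PhasedGameteMatrix]) -> PhasedGameteMatrix:
    """Stack per-LG phased matrices back into one parent-wide matrix."""
    return PhasedGameteMatrix(
        data=np.vstack([p.data for p in parts]),
        marker_ids=pd.Index(np.concatenate([p.marker_ids for p in parts])),
        parent=parts[0].parent,
        phase_flags=pd.concat([p.phase_flags for p in parts]),
        configurations=pd.concat([p.configurations for p in parts]),
    )


def map_linkage_group(ph: PhasedGameteMatrix, lg: int,
                      drop_threshold: float = 0.05,
                      ) -> tuple[pd.DataFrame, PhasedGameteMatrix]:
    """Bin, order, error-clean and position one phased linkage group.

    Runs collapse -> MST ordering -> double-recombinant scan (flagged
    genotypes set missing, high-flag markers dropped) -> Kosambi distances.
    Returns the LG's map table and the cleaned, map-ordered phased matrix.
    """
    rf_g = pairwise_rf_lod(ph)
    bins = collapse_bins(ph, rf_g)
    reps = [b.rep_index for b in bins]
    d = np.clip(rf_g.r[np.ix_(reps, reps)], 0.0, None)
    order = order_markers_mst(d) if len(bins) > 2 else list(range(len(bins)))
    row_order, bin_sizes = [], []
    for k in order:
        members = sorted(bins[k].member_indices,
                         key=lambda i: ph.marker_ids[i])
        row_order.extend(members)
        bin_sizes.append(len(members))
    sub = ph.subset(row_order)
    flags, dropped = scan_double_recombinants(sub.data, drop_threshold)
    clean = clean_genotypes(sub.data, flags)
    keep = ~dropped
    kept_sub = PhasedGameteMatrix(
        data=clean[keep],
        marker_ids=sub.marker_ids[keep],
        parent=sub.parent,
        phase_flags=sub.phase_flags[keep],
        configurations=sub.configurations[keep],
    )
    # rebuild the ordered bin structure over the surviving markers
    new_row = np.cumsum(keep) - 1
    new_bins: list[Bin] = []
    n_missing = (~np.isfinite(kept_sub.data)).sum(axis=1)
    start = 0
    for size in bin_sizes:
        rows = [new_row[i] for i in range(start, start + size) if keep[i]]
        start += size
        if not rows:
            continue
        ids = [str(kept_sub.marker_ids[r]) for r in rows]
        rep = min(rows, key=lambda r: (n_missing[r], str(kept_sub.marker_ids[r])))
        new_bins.append(Bin(
            representative=str(kept_sub.marker_ids[rep]),
            members=ids, rep_index=int(rep),
            member_indices=[int(r) for r in rows],
        ))
    lg_map = build_lg_map(kept_sub, new_bins, list(range(len(new_bins))), lg)
    return lg_map, kept_sub


def build_parental_map(pgm_raw: PhasedGameteMatrix,
                       lod_min: float = LOD_MIN_DEFAULT,
                       rf_max: float = RF_MAX_DEFAULT,
                       drop_threshold: float = 0.05,
                       min_lg_size: int = 3,
                       ) -> tuple[pd.DataFrame, PhasedGameteMatrix, pd.DataFrame]:
    """Full parental bin map from a raw (unphased) DH-coded marker set.

    Groups at LOD > ``lod_min`` / r < ``rf_max``, phases each group, then
    orders, cleans and positions every linkage group.  LGs are numbered by
    descending marker count.  Returns (map table, cleaned phased matrix,
    per-LG summary); groups smaller than ``min_lg_size`` are reported as
    unplaced in the summary's attrs.
    """
    rf = pairwise_rf_lod(pgm_raw)
    groups = group_markers(rf, lod_min, rf_max)
    lgs = [g for g in groups if len(g) >= min_lg_size]
    unplaced = [str(pgm_raw.marker_ids[i])
                for g in groups if len(g) < min_lg_size for i in g]
    maps, cleaned = [], []
    for lg_no, g in enumerate(lgs, start=1):
        ph = infer_phase(pgm_raw, g, rf, lod_min)
        lg_map, clean = map_linkage_group(ph, lg_no, drop_threshold)
        maps.append(lg_map)
        cleaned.append(clean)
    if not maps:
        raise LinkageError("no linkage groups found")
    map_table = pd.concat(maps, ignore_index=True)
    pgm_clean = concat_phased(cleaned)
    summary_rows = []
    for lg, grp in map_table.groupby("lg"):
        pos = np.sort(grp["position"].unique())
        summary_rows.append((int(lg), len(grp), len(pos),
                             float(pos[-1] - pos[0])))
    summary = pd.DataFrame(
        summary_rows, columns=["lg", "n_markers", "n_bins", "length"],
    )
    summary.attrs["unplaced"] = unplaced
    return map_table, pgm_clean, summary


def _unmerged(grp: pd.DataFrame, new_lg: int) -> pd.DataFrame:
    g = grp.copy()
    g["lg"] = new_lg
    return g


def _piecewise_map(x: np.ndarray, knots_x: np.ndarray,
                   knots_y: np.ndarray) -> np.ndarray:
    """Piecewise-linear map with linear extension beyond the terminal knots."""
    kx, ky = np.asarray(knots_x, float), np.asarray(knots_y, float)
    uniq = np.concatenate([[True], np.diff(kx) > 1e-12])
    kx, ky = kx[uniq], ky[uniq]
    if len(kx) == 1:
        return x - kx[0] + ky[0]
    y = np.interp(x, kx, ky)
    span_ratio = (ky[-1] - ky[0]) / (kx[-1] - kx[0]) if kx[-1] > kx[0] else 1.0
    lo = x < kx[0]
    hi = x > kx[-1]
    y[lo] = ky[0] + (x[lo] - kx[0]) * span_ratio
    y[hi] = ky[-1] + (x[hi] - kx[-1]) * span_ratio
    return y
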