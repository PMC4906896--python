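"""Synthetic F1 pseudo-testcross populations with full generative truth.

Emulates the data layout of a GBS-genotyped outcross family: two highly
heterozygous parents, n full-sib progeny, 12 linkage groups, and markers in
the four informative configurations (ABxAA : AAxAB : ABxAB : ABxCD) at the
published cranberry proportions 1977 : 2370 : 1273 : 68.  Defaults follow
that study design: 362 progeny, the 12 integrated-map LG lengths, unique
marker positions at a mean 2 cM spacing with several cosegregating markers
per position (the origin of map bins), 10 % missing calls and 0.5 %
genotyping error.

Meiosis is simulated without interference (crossover count per gamete is
Poisson with mean length/100, positions uniform) — interference does not
change the mean event count, which is the quantity the recombination
summaries measure.  A separate two-locus mode draws gametes for one marker
pair at a recombination fraction equal to the Kosambi inverse of their map
separation; it exists only for the LD-decay harness, because a multilocus
crossover process exactly consistent with the Kosambi function is not well
defined.

Everything is deterministic given the configuration (including its seed),
and the returned :class:`SimTruth` carries phases, crossovers and masks so
that every simulated genotype is reconstructible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import linkage, qc
from .formats_io import MISSING, GenotypeMatrix
from .stats import load_published_map_summary

LETTERS = np.array(list("ACGT"))

#: published per-LG lengths (cM): integrated map and the two parental bin maps
_SUMMARY = load_published_map_summary()
DEFAULT_LG_LENGTHS = tuple(_SUMMARY["length_i"].tolist())
P1_LG_LENGTHS = tuple(_SUMMARY["length_p1"].tolist())
P2_LG_LENGTHS = tuple(_SUMMARY["length_p2"].tolist())

#: marker-configuration counts of the published map input (ABxAA, AAxAB,
#: ABxAB, ABxCD); used both as default proportions and default total
DEFAULT_CONFIG_COUNTS = (1977, 2370, 1273, 68)
CONFIG_NAMES = ("ABxAA", "AAxAB", "ABxAB", "ABxCD")


class SimConfigError(ValueError):
    pass


@dataclasses.dataclass
class SimConfig:
    """Study design of one simulated cross; defaults are the published
    conditions."""

    n_progeny: int = 362
    lg_lengths: tuple[float, ...] = DEFAULT_LG_LENGTHS
    marker_spacing: float = 2.0
    config_proportions: tuple[float, float, float, float] = DEFAULT_CONFIG_COUNTS
    n_markers: int | None = None          # default: sum of the count-valued proportions
    missing_rate: float = 0.10
    error_rate: float = 0.005
    distorted_loci: tuple[tuple[int, float, float], ...] = ()  # (lg, cM, s)
    crossover_model: str = "haldane_markov"
    seed: int = 0

    def validate(self) -> None:
        if any(length <= 0 for length in self.lg_lengths):
            raise SimConfigError("LG lengths must be positive")
        if self.marker_spacing > min(self.lg_lengths):
            raise SimConfigError("marker spacing exceeds the shortest LG")
        if not 0 <= self.missing_rate < 0.2:
            raise SimConfigError("missing_rate must be in [0, 0.2)")
        if not 0 <= self.error_rate <= 0.05:
            raise SimConfigError("error_rate must be in [0, 0.05]")
        if sum(self.config_proportions) <= 0:
            raise SimConfigError("configuration proportions must sum > 0")
        if self.crossover_model != "haldane_markov":
            raise SimConfigError(
                f"unknown multilocus crossover model {self.crossover_model!r}"
            )

    def total_markers(self) -> int:
        if self.n_markers is not None:
            return self.n_markers
        return int(round(sum(self.config_proportions)))


@dataclasses.dataclass
class SimTruth:
    """Generative truth of one simulated cross."""

    markers: pd.DataFrame                      # lg, cm, pos_index, configuration, parental calls
    positions_cm: dict[int, np.ndarray]        # unique marker positions per LG
    phase_flags: pd.DataFrame                  # per parent: 1 if homolog 0 carries the sorted-second allele; -1 if hom
    homologs: dict[str, dict[int, np.ndarray]]  # transmitted homolog (n x m_lg)
    crossovers: dict[str, dict[int, list[np.ndarray]]]
    error_mask: pd.DataFrame
    missing_mask: pd.DataFrame
    distorted: list[dict]
    config: SimConfig

    def true_gamete_codes(self, parent: str, marker_ids: Sequence[str]) -> np.ndarray:
        """0/1 transmitted-allele codes (sorted-first allele = 0) for markers
        heterozygous in ``parent``, before error/missing injection."""
        rows = []
        for mid in marker_ids:
            info = self.markers.loc[mid]
            h = self.homologs[parent][info["lg"]][:, info["pos_index"]]
            flag = self.phase_flags.loc[mid, parent]
            if flag < 0:
                raise ValueError(f"{mid} is homozygous in {parent}")
            rows.append(h ^ int(flag))
        return np.array(rows)


def simulate_gametes(lg_length: float, n: int, model: str = "haldane_markov",
                     seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     ) -> list[np.ndarray]:
    """Crossover position lists for ``n`` gametes on one chromosome.

    ``haldane_markov``: counts ~ Poisson(length/100), positions uniform.
    The ``kosambi_pairwise`` mode is two-locus only — use
    :func:`simulate_locus_pair`.
    """
    if lg_length <= 0:
        raise ValueError("lg_length must be positive")
    if model == "kosambi_pairwise":
        raise ValueError(
            "kosambi_pairwise is a two-locus mode; use simulate_locus_pair"
        )
    if model != "haldane_markov":
        raise ValueError(f"unknown crossover model {model!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = rng.poisson(lg_length / 100.0, size=n)
    return [np.sort(rng.uniform(0.0, lg_length, size=c)) for c in counts]


def simulate_locus_pair(distance_cm: float, n: int,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Gametes at two loci separated by ``distance_cm`` on the map.

    The pair recombines at the Kosambi inverse of the distance,
    theta = 0.5 tanh(2d/100), so simulated two-point data are exactly
    consistent with Kosambi map distances.
    """
    theta = linkage.kosambi_inverse(distance_cm)
    g1 = rng.integers(0, 2, size=n, dtype=np.int8)
    flip = rng.random(n) < theta
    return g1, g1 ^ flip


def _homologs_for_grid(rng: np.random.Generator, length: float,
                       grid: np.ndarray, n: int,
                       ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Transmitted-homolog matrix (n x len(grid)) plus crossover lists."""
    counts = rng.poisson(length / 100.0, size=n)
    starts = rng.integers(0, 2, size=n, dtype=np.int8)
    h = np.empty((n, len(grid)), dtype=np.int8)
    xovers = []
    for i in range(n):
        xs = np.sort(rng.uniform(0.0, length, size=counts[i]))
        h[i] = (starts[i] + np.searchsorted(xs, grid)) % 2
        xovers.append(xs)
    return h, xovers


def simulate_recombination_counts(lg_lengths: Sequence[float],
                                  n_gametes: int = 362,
                                  spacing: float = 2.0,
                                  seed: int | None = None,
                                  rng: np.random.Generator | None = None,
                                  ) -> pd.DataFrame:
    """Observed recombination events per gamete per LG on a regular grid.

    Gametes are simulated on each chromosome with markers every ``spacing``
    cM and events counted as sign changes along each gamete — the observable
    that per-LG recombination summaries report.  Returns one row per LG
    (length, marker count, mean/min/max events per gamete).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for lg, length in enumerate(lg_lengths, start=1):
        grid = np.arange(0.0, length + 1e-9, spacing)
        h, _ = _homologs_for_grid(rng, length, grid, n_gametes)
        events = linkage.count_sign_changes(h.T.astype(float))
        rows.append((lg, float(length), len(grid), float(events.mean()),
                     int(events.min()), int(events.max())))
    return pd.DataFrame(
        rows, columns=["lg", "length_cm", "n_markers", "mean_events",
                       "min_events", "max_events"],
    )


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _draw_marker_frame(rng: np.random.Generator, cfg: SimConfig,
                       positions: dict[int, np.ndarray]) -> pd.DataFrame:
    n_total = cfg.total_markers()
    lengths = np.asarray(cfg.lg_lengths)
    per_lg = _largest_remainder(n_total, lengths)
    cfg_counts = _largest_remainder(n_total, np.asarray(cfg.config_proportions))
    labels = np.repeat(np.array(CONFIG_NAMES, dtype=object), cfg_counts)
    rng.shuffle(labels)
    rows = []
    k = 0
    for lg, count in enumerate(per_lg, start=1):
        pos_idx = rng.integers(0, len(positions[lg]), size=count)
        for pi in np.sort(pos_idx):
            rows.append((lg, int(pi), float(positions[lg][pi]), labels[k]))
            k += 1
    df = pd.DataFrame(rows, columns=["lg", "pos_index", "cm", "configuration"])
    df["marker_id"] = [f"m{i:05d}" for i in range(1, len(df) + 1)]
    return df.set_index("marker_id", drop=False).rename_axis(None)


def _assign_alleles(rng: np.random.Generator, markers: pd.DataFrame
                    ) -> pd.DataFrame:
    """Parental genotypes, haplotype assignments and phase flags per marker.

    ``p?_hom0/p?_hom1`` are the alleles on the parent's two homologs; the
    phase flag is 1 when homolog 0 carries the sorted-second allele (so the
    true 0/1 gamete code is homolog XOR flag), and -1 for a homozygous
    parent.
    """
    out = {c: [] for c in ("p1_call", "p2_call", "p1_hom0", "p1_hom1",
                           "p2_hom0", "p2_hom1", "p1_phase", "p2_phase")}
    for cfg in markers["configuration"]:
        letters = LETTERS[rng.permutation(4)]
        if cfg == "ABxCD":
            a, b = sorted(letters[:2])
            c, d = sorted(letters[2:])
        else:
            a, b = sorted(letters[:2])
            c = d = None
        if cfg == "ABxAA":
            hom = [a, b][rng.integers(2)]
            f1 = int(rng.integers(2))
            row = (a + b, hom + hom, [a, b][f1], [a, b][1 - f1],
                   hom, hom, f1, -1)
        elif cfg == "AAxAB":
            hom = [a, b][rng.integers(2)]
            f2 = int(rng.integers(2))
            row = (hom + hom, a + b, hom, hom,
                   [a, b][f2], [a, b][1 - f2], -1, f2)
        elif cfg == "ABxAB":
            f1, f2 = int(rng.integers(2)), int(rng.integers(2))
            row = (a + b, a + b, [a, b][f1], [a, b][1 - f1],
                   [a, b][f2], [a, b][1 - f2], f1, f2)
        else:  # ABxCD: fully informative, four distinguishable progeny classes
            f1, f2 = int(rng.integers(2)), int(rng.integers(2))
            row = (a + b, c + d, [a, b][f1], [a, b][1 - f1],
                   [c, d][f2], [c, d][1 - f2], f1, f2)
        for key, val in zip(out, row):
            out[key].append(val)
    return markers.assign(**out)


def _genotypes_from_homologs(markers: pd.DataFrame,
                             hom1: dict[int, np.ndarray],
                             hom2: dict[int, np.ndarray]) -> np.ndarray:
    """(m x n) sorted two-letter genotype calls from transmitted homologs."""
    m = len(markers)
    n = next(iter(hom1.values())).shape[0]
    calls = np.empty((m, n), dtype="<U2")
    lgs = markers["lg"].to_numpy()
    pis = markers["pos_index"].to_numpy()
    a10 = markers["p1_hom0"].to_numpy()
    a11 = markers["p1_hom1"].to_numpy()
    a20 = markers["p2_hom0"].to_numpy()
    a21 = markers["p2_hom1"].to_numpy()
    for i in range(m):
        h1 = hom1[lgs[i]][:, pis[i]]
        h2 = hom2[lgs[i]][:, pis[i]]
        x = np.where(h1 == 0, a10[i], a11[i])
        y = np.where(h2 == 0, a20[i], a21[i])
        swap = x > y
        calls[i] = np.char.add(np.where(swap, y, x), np.where(swap, x, y))
    return calls


def simulate_cross(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate one F1 pseudo-testcross family.

    Returns the observed genotype matrix (after planted viability selection,
    genotyping error and missingness) and the full generative truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = {lg: float(L) for lg, L in enumerate(config.lg_lengths, start=1)}
    positions = {}
    for lg, L in lengths.items():
        pos = [0.0]
        while True:
            nxt = pos[-1] + rng.exponential(config.marker_spacing)
            if nxt > L:
                break
            pos.append(nxt)
        if len(pos) < 2:
            pos.append(L)
        positions[lg] = np.asarray(pos)
    markers = _draw_marker_frame(rng, config, positions)
    markers = _assign_alleles(rng, markers)

    # viability targets: nearest marker to each planted (lg, cM, s)
    targets = []
    for lg, cm, s in config.distorted_loci:
        if lg not in lengths:
            raise SimConfigError(f"distorted locus on unknown LG {lg}")
        on_lg = markers[markers["lg"] == lg]
        if on_lg.empty:
            raise SimConfigError(f"no markers on LG {lg} for distortion")
        mid = (on_lg["cm"] - cm).abs().idxmin()
        info = markers.loc[mid]
        classes = sorted(qc.expected_classes(info["p1_call"], info["p2_call"]))
        homs = [g for g in classes if g[0] == g[1]]
        target_class = homs[0] if homs else classes[0]
        targets.append({"lg": lg, "cm": cm, "s": float(s), "marker_id": mid,
                        "target_class": target_class,
                        "pos_index": int(info["pos_index"])})

    n = config.n_progeny
    hom = {"P1": {lg: [] for lg in lengths}, "P2": {lg: [] for lg in lengths}}
    xov = {"P1": {lg: [] for lg in lengths}, "P2": {lg: [] for lg in lengths}}
    have = 0
    while have < n:
        batch = n - have if not targets else max(2 * (n - have), 64)
        bh, bx = {}, {}
        for parent in ("P1", "P2"):
            bh[parent], bx[parent] = {}, {}
            for lg, L in lengths.items():
                h, xs = _homologs_for_grid(rng, L, positions[lg], batch)
                bh[parent][lg] = h
                bx[parent][lg] = xs
        survive = np.ones(batch, dtype=bool)
        for t in targets:
            info = markers.loc[t["marker_id"]]
            h1 = bh["P1"][t["lg"]][:, t["pos_index"]]
            h2 = bh["P2"][t["lg"]][:, t["pos_index"]]
            x = np.where(h1 == 0, info["p1_hom0"], info["p1_hom1"])
            y = np.where(h2 == 0, info["p2_hom0"], info["p2_hom1"])
            swap = x > y
            g = np.char.add(np.where(swap, y, x), np.where(swap, x, y))
            hit = g == t["target_class"]
            killed = hit & (rng.random(batch) < t["s"])
            survive &= ~killed
        idx = np.flatnonzero(survive)[: n - have]
        for parent in ("P1", "P2"):
            for lg in lengths:
                hom[parent][lg].append(bh[parent][lg][idx])
                xov[parent][lg].extend(bx[parent][lg][i] for i in idx)
        have += len(idx)
    for parent in ("P1", "P2"):
        for lg in lengths:
            hom[parent][lg] = np.vstack(hom[parent][lg])

    calls = _genotypes_from_homologs(markers, hom["P1"], hom["P2"])
    sample_names = [f"S{i:04d}" for i in range(1, n + 1)]
    calls_df = pd.DataFrame(calls, index=markers.index, columns=sample_names)

    marker_meta = pd.DataFrame(
        {
            "marker_id": markers["marker_id"],
            "alleles": [
                "/".join(sorted(set(p1 + p2)))
                for p1, p2 in zip(markers["p1_call"], markers["p2_call"])
            ],
            "chrom": [f"LG{lg}" for lg in markers["lg"]],
            "pos": (markers["cm"] * 10_000).round().astype(np.int64),
        },
        index=markers.index,
    )
    parents_df = pd.DataFrame(
        {"P1": markers["p1_call"], "P2": markers["p2_call"]},
        index=markers.index,
    )
    gm = GenotypeMatrix(markers=marker_meta, calls=calls_df, parents=parents_df)
    gm, error_mask, missing_mask = inject_missing_and_errors(
        gm, config.missing_rate, config.error_rate, rng=rng,
    )
    truth = SimTruth(
        markers=markers[["marker_id", "lg", "pos_index", "cm",
                         "configuration", "p1_call", "p2_call"]],
        positions_cm=positions,
        phase_flags=pd.DataFrame(
            {"P1": markers["p1_phase"], "P2": markers["p2_phase"]},
            index=markers.index,
        ),
        homologs=hom,
        crossovers=xov,
        error_mask=error_mask,
        missing_mask=missing_mask,
        distorted=targets,
        config=config,
    )
    return gm, truth


def inject_missing_and_errors(gm: GenotypeMatrix, missing_rate: float,
                              error_rate: float, seed: int | None = None,
                              rng: np.random.Generator | None = None,
                              ) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Plant genotyping errors and missing calls; masks are returned.

    An error replaces a call with a uniformly chosen *different* valid
    genotype class for the marker's configuration (GBS miscalls stay within
    the segregating classes); missing calls become ``NN``.  Missingness is
    applied after errors, so a cell can carry both marks.
    """
    if not (0 <= missing_rate < 1 and 0 <= error_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    calls = gm.calls.to_numpy().copy()
    m, n = calls.shape
    err = rng.random((m, n)) < error_rate
    miss = rng.random((m, n)) < missing_rate
    if err.any():
        parents = gm.parents.to_numpy()
        for i in np.flatnonzero(err.any(axis=1)):
            classes = sorted(qc.expected_classes(parents[i, 0], parents[i, 1]))
            if len(classes) < 2:
                err[i] = False
                continue
            cols = np.flatnonzero(err[i])
            offsets = rng.integers(1, len(classes), size=len(cols))
            lut = {g: k for k, g in enumerate(classes)}
            for j, off in zip(cols, offsets):
                cur = lut.get(calls[i, j], 0)
                calls[i, j] = classes[(cur + off) % len(classes)]
    calls[miss] = MISSING
    new = GenotypeMatrix(
        markers=gm.markers,
        calls=pd.DataFrame(calls, index=gm.calls.index, columns=gm.calls.columns),
        parents=gm.parents,
    )
    err_df = pd.DataFrame(err, index=gm.calls.index, columns=gm.calls.columns)
    miss_df = pd.DataFrame(miss, index=gm.calls.index, columns=gm.calls.columns)
    return new, err_df, miss_df


# ---------------------------------------------------------------------------
# Anchoring / synteny fixtures

@dataclasses.dataclass
class AnchoringFixture:
    """Mock scaffold, CDS and homology-hit tables tied to a genetic map."""

    scaffolds: pd.DataFrame       # scaffold_id, length_bp
    marker_lookup: pd.DataFrame   # marker_id, scaffold_id
    cds: pd.DataFrame             # cds_id, scaffold_id, start, end
    hits: pd.DataFrame            # BLAST outfmt-6 columns
    sequences: dict[str, str] | None
    truth_blocks: list[dict]      # planted blocks: lg, subject chr, cds ids


def simulate_anchoring_fixture(map_table: pd.DataFrame, seed: int = 0,
                               n_blocks: int = 3, block_cds: int = 4,
                               n_noise_hits: int = 0,
                               n_subthreshold_hits: int = 3,
                               mean_cds_per_scaffold: float = 0.8,
                               with_sequences: bool = False,
                               ) -> AnchoringFixture:
    """Scaffold/CDS/hit fixtures with ``n_blocks`` planted collinear blocks.

    Markers are grouped 1–4 per scaffold along the map; CDS are dropped on
    scaffolds at a Poisson rate; each planted block takes ``block_cds``
    consecutive CDS of one LG (span < 8 cM) and gives their best hits
    collinear positions 0.4 Mbp apart on a dedicated mock reference
    chromosome.  Noise hits scatter uniformly over 20 mock chromosomes of
    100 Mbp; sub-threshold hits fail one filter each.
    """
    rng = np.random.default_rng(seed)
    mt = map_table.sort_values(["lg", "position", "marker_id"])
    scaffold_rows, lookup_rows = [], []
    sid = 0
    for lg, grp in mt.groupby("lg"):
        ids = grp["marker_id"].tolist()
        i = 0
        while i < len(ids):
            take = int(rng.integers(1, 5))
            chunk = ids[i:i + take]
            i += take
            sid += 1
            name = f"scf{sid:05d}"
            length = 2000 * len(chunk) + int(rng.integers(500, 3000))
            scaffold_rows.append((name, length))
            lookup_rows.extend((mid, name) for mid in chunk)
    scaffolds = pd.DataFrame(scaffold_rows, columns=["scaffold_id", "length_bp"])
    lookup = pd.DataFrame(lookup_rows, columns=["marker_id", "scaffold_id"])

    cds_rows = []
    cid = 0
    for name, length in scaffold_rows:
        k = int(rng.poisson(mean_cds_per_scaffold))
        cursor = 1
        for _ in range(k):
            size = int(rng.integers(300, 900))
            if cursor + size > length:
                break
            cid += 1
            cds_rows.append((f"cds{cid:05d}", name, cursor, cursor + size - 1))
            cursor += size + int(rng.integers(100, 400))
    cds = pd.DataFrame(cds_rows, columns=["cds_id", "scaffold_id", "start", "end"])

    hits_rows = []
    truth_blocks: list[dict] = []
    if not cds.empty:
        scaffold_pos = (lookup.merge(mt, on="marker_id")
                        .groupby("scaffold_id")
                        .agg(lg=("lg", "first"), cm=("position", "median")))
        cds_map = cds.merge(scaffold_pos, on="scaffold_id")
        candidates = []
        for lg, grp in cds_map.sort_values("cm").groupby("lg"):
            arr = grp.reset_index(drop=True)
            for s in range(len(arr) - block_cds + 1):
                window = arr.iloc[s:s + block_cds]
                if window["cm"].iloc[-1] - window["cm"].iloc[0] < 8.0:
                    candidates.append((int(lg), window["cds_id"].tolist()))
                    break  # one candidate per LG keeps blocks disjoint
        if len(candidates) < n_blocks:
            raise ValueError(
                f"map supports only {len(candidates)} planted blocks; "
                f"asked for {n_blocks}"
            )
        picked = [candidates[i] for i in
                  rng.choice(len(candidates), size=n_blocks, replace=False)]
        for b, (lg, block_ids) in enumerate(picked):
            chrom = f"ref{b + 1:02d}"
            base = int(5e6) * (b + 1)
            for j, cds_id in enumerate(block_ids):
                start = base + j * 400_000
                hits_rows.append((cds_id, chrom, 95.0, 400, 10, 0, 1, 400,
                                  start, start + 399, 1e-50, 250.0))
            truth_blocks.append({"lg": lg, "chrom": chrom, "cds_ids": block_ids})
        planted = {c for blk in truth_blocks for c in blk["cds_ids"]}
        free = cds.loc[~cds["cds_id"].isin(planted), "cds_id"].tolist()
        for _ in range(n_noise_hits):
            if not free:
                break
            cds_id = free[rng.integers(len(free))]
            chrom = f"ref{rng.integers(1, 21):02d}"
            start = int(rng.integers(1, int(1e8)))
            e_val = 10.0 ** -float(rng.uniform(12, 20))
            hits_rows.append((cds_id, chrom, 88.0, 120, 12, 1, 1, 120,
                              start, start + 119, e_val, 110.0))
        for k in range(min(n_subthreshold_hits, len(cds))):
            cds_id = cds["cds_id"].iloc[k]
            bad = [(1e-5, 200.0, 300), (1e-30, 60.0, 300), (1e-30, 200.0, 30)]
            e_val, score, length = bad[k % 3]
            hits_rows.append((cds_id, "refXX", 80.0, length, 20, 2, 1, length,
                              1000, 1000 + length - 1, e_val, score))
    hits = pd.DataFrame(hits_rows, columns=[
        "query_id", "subject_id", "percent_identity", "alignment_length",
        "mismatches", "gap_opens", "query_start", "query_end",
        "subject_start", "subject_end", "e_value", "bit_score",
    ])
    sequences = None
    if with_sequences:
        sequences = {
            name: "".join(rng.choice(LETTERS, size=length))
            for name, length in scaffold_rows
        }
    return AnchoringFixture(
        scaffolds=scaffolds, marker_lookup=lookup, cds=cds, hits=hits,
        sequences=sequences, truth_blocks=truth_blocks,
    )
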