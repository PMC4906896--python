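"""Scaffold anchoring, pseudomolecule assembly and microsynteny detection.

Assembly scaffolds are placed on the genetic map through the mapped markers
they contain: a scaffold inherits the majority linkage group of its markers
(a tie makes it conflicted and excluded) and the median cM of its supporting
markers.  Anchored scaffolds are concatenated in map order into one
unoriented pseudomolecule per LG, joined by 100-N spacers.

Homology hits against a reference genome (BLAST outfmt-6 tables) are
filtered with e-value <= 1e-10, bit score > 80 (strict) and alignment
length >= 50 bp.  Microsynteny: two CDS less than 10 cM apart on one LG
whose best hits land on the same reference chromosome less than 10 Mbp
apart form a syntenic pair; pairs sharing a CDS chain into blocks, and a
block requires at least two pairs.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

E_VALUE_MAX = 1e-10
SCORE_MIN = 80.0
ALIGN_LEN_MIN = 50
MICRO_CM_MAX = 10.0
MICRO_BP_MAX = 10_000_000
SPACER_N = 100


@dataclasses.dataclass
class AnchoredScaffoldSet:
    """Scaffolds placed on the map, plus the conflicted/unknown remainder."""

    table: pd.DataFrame      # scaffold_id, lg, position, n_markers, length_bp
    conflicted: pd.DataFrame
    unknown_markers: list[str]

    @property
    def anchored_bp(self) -> int:
        if "length_bp" not in self.table.columns:
            raise ValueError("scaffold lengths were not provided")
        return int(self.table["length_bp"].sum())


def anchor_scaffolds(map_table: pd.DataFrame, marker_lookup: pd.DataFrame,
                     scaffolds: pd.DataFrame | None = None,
                     ) -> AnchoredScaffoldSet:
    """Assign each scaffold a linkage group and cM position.

    ``marker_lookup`` maps marker_id -> scaffold_id.  LG = majority vote of
    the scaffold's mapped markers (ties excluded as conflicted); position =
    median cM of the supporting markers on the assigned LG.
    """
    merged = marker_lookup.merge(map_table[["marker_id", "lg", "position"]],
                                 on="marker_id", how="left")
    unknown = map_table.loc[
        ~map_table["marker_id"].isin(marker_lookup["marker_id"]), "marker_id"
    ].tolist()
    rows, conflicts = [], []
    for sid, grp in merged.dropna(subset=["lg"]).groupby("scaffold_id"):
        votes = grp["lg"].value_counts()
        if len(votes) > 1 and votes.iloc[0] == votes.iloc[1]:
            conflicts.append((sid, ";".join(str(int(v)) for v in votes.index)))
            continue
        lg = int(votes.index[0])
        sup = grp[grp["lg"] == lg]
        rows.append((sid, lg, float(sup["position"].median()), len(sup),
                     ";".join(sorted(sup["marker_id"]))))
    table = pd.DataFrame(
        rows, columns=["scaffold_id", "lg", "position", "n_markers", "markers"],
    )
    if scaffolds is not None:
        table = table.merge(scaffolds[["scaffold_id", "length_bp"]],
                            on="scaffold_id", how="left")
    table = table.sort_values(["lg", "position", "scaffold_id"],
                              ignore_index=True)
    return AnchoredScaffoldSet(
        table=table,
        conflicted=pd.DataFrame(conflicts, columns=["scaffold_id", "lgs"]),
        unknown_markers=unknown,
    )


def build_pseudomolecules(anchored: AnchoredScaffoldSet,
                          sequences: dict[str, str],
                          spacer: int = SPACER_N,
                          ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Concatenate anchored scaffolds into one record per LG.

    Scaffolds are joined in cM order (ties broken lexicographically on
    scaffold id) with ``spacer`` Ns between them, in their original
    orientation — map anchoring alone cannot orient a scaffold.  Returns
    (FASTA records, coordinate table with 1-based inclusive spans).
    """
    records, coords = [], []
    gap = "N" * spacer
    for lg, grp in anchored.table.groupby("lg"):
        grp = grp.sort_values(["position", "scaffold_id"])
        parts = []
        cursor = 1
        for _, row in grp.iterrows():
            seq = sequences.get(row["scaffold_id"])
            if seq is None:
                warnings.warn(
                    f"no sequence for {row['scaffold_id']}; skipped",
                    stacklevel=2,
                )
                continue
            if parts:
                cursor += spacer
            parts.append(seq)
            coords.append((row["scaffold_id"], int(lg), cursor,
                           cursor + len(seq) - 1, row["position"]))
            cursor += len(seq)
        if not parts:
            warnings.warn(f"LG {lg}: no sequences; pseudomolecule omitted",
                          stacklevel=2)
            continue
        records.append((f"pseudomolecule_LG{int(lg)}", gap.join(parts)))
    coord_df = pd.DataFrame(
        coords,
        columns=["scaffold_id", "lg", "start", "end", "position_cm"],
    )
    return records, coord_df


def filter_hits(hits: pd.DataFrame, e_value_max: float = E_VALUE_MAX,
                score_min: float = SCORE_MIN,
                align_len_min: int = ALIGN_LEN_MIN) -> pd.DataFrame:
    """Keep hits with e <= 1e-10 AND bit score > 80 AND length >= 50 bp."""
    keep = (
        (hits["e_value"] <= e_value_max)
        & (hits["bit_score"] > score_min)
        & (hits["alignment_length"] >= align_len_min)
    )
    return hits.loc[keep].reset_index(drop=True)


def best_hits(hits: pd.DataFrame, k: int = 1) -> pd.DataFrame:
    """Top-k hits per query: lowest e-value, ties broken by higher score."""
    ordered = hits.sort_values(
        ["query_id", "e_value", "bit_score"],
        ascending=[True, True, False], kind="stable",
    )
    return ordered.groupby("query_id").head(k).reset_index(drop=True)


def cds_map_positions(anchored: AnchoredScaffoldSet,
                      cds: pd.DataFrame) -> pd.DataFrame:
    """Map positions inherited by CDS from their anchored scaffolds."""
    return cds.merge(
        anchored.table[["scaffold_id", "lg", "position"]],
        on="scaffold_id", how="inner",
    )[["cds_id", "scaffold_id", "lg", "position"]]


def detect_microsynteny(cds_positions: pd.DataFrame, hits: pd.DataFrame,
                        max_cm: float = MICRO_CM_MAX,
                        max_bp: int = MICRO_BP_MAX,
                        min_pairs: int = 2,
                        best_k: int = 1,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Chain syntenic CDS pairs into microsynteny blocks.

    ``cds_positions`` carries cds_id, lg, position (cM); ``hits`` is a
    *filtered* outfmt-6 table whose query_id is the cds_id.  Returns
    (blocks, pairs, dot-plot table).  The dot-plot table (cM vs reference
    bp for every retained best hit) supports downstream macrosynteny
    plotting; only the microsynteny rule is automated.
    """
    top = best_hits(hits, k=best_k)
    annot = cds_positions.merge(
        top[["query_id", "subject_id", "subject_start", "subject_end"]],
        left_on="cds_id", right_on="query_id", how="inner",
    )
    dotplot = annot[["cds_id", "lg", "position", "subject_id",
                     "subject_start"]].copy()
    pair_rows = []
    for lg, grp in annot.sort_values("position").groupby("lg"):
        arr = grp.reset_index(drop=True)
        for i in range(len(arr)):
            for j in range(i + 1, len(arr)):
                d_cm = arr["position"].iloc[j] - arr["position"].iloc[i]
                if d_cm >= max_cm:
                    break
                if arr["subject_id"].iloc[i] != arr["subject_id"].iloc[j]:
                    continue
                d_bp = abs(int(arr["subject_start"].iloc[j])
                           - int(arr["subject_start"].iloc[i]))
                if d_bp < max_bp:
                    pair_rows.append((
                        int(lg), arr["cds_id"].iloc[i], arr["cds_id"].iloc[j],
                        float(d_cm), arr["subject_id"].iloc[i], d_bp,
                    ))
    pairs = pd.DataFrame(
        pair_rows,
        columns=["lg", "cds_a", "cds_b", "distance_cm", "subject_id",
                 "distance_bp"],
    )
    blocks = _chain_blocks(pairs, annot, min_pairs)
    return blocks, pairs, dotplot


def _chain_blocks(pairs: pd.DataFrame, annot: pd.DataFrame,
                  min_pairs: int) -> pd.DataFrame:
    """Single-linkage chaining of pairs that share a CDS, per (lg, chrom)."""
    import networkx as nx

    rows = []
    block_id = 0
    for (lg, chrom), grp in pairs.groupby(["lg", "subject_id"]):
        g = nx.Graph()
        for _, p in grp.iterrows():
            g.add_edge(p["cds_a"], p["cds_b"])
        for comp in nx.connected_components(g):
            n_pairs = int(grp[
                grp["cds_a"].isin(comp) & grp["cds_b"].isin(comp)
            ].shape[0])
            if n_pairs < min_pairs:
                continue
            members = annot[annot["cds_id"].isin(comp)]
            block_id += 1
            rows.append((
                block_id, int(lg),
                float(members["position"].min()),
                float(members["position"].max()),
                chrom,
                int(members["subject_start"].min()),
                int(members["subject_start"].max()),
                n_pairs, len(comp),
                ";".join(sorted(comp)),
            ))
    return pd.DataFrame(
        rows,
        columns=["block_id", "lg", "cm_start", "cm_end", "chrom", "bp_start",
                 "bp_end", "n_pairs", "n_cds", "cds_ids"],
    )


def validate_blocks(blocks: pd.DataFrame, cds_positions: pd.DataFrame,
                    hits: pd.DataFrame, max_cm: float = MICRO_CM_MAX,
                    max_bp: int = MICRO_BP_MAX) -> bool:
    """Post-hoc check that every emitted block satisfies both distance rules
    between consecutive members."""
    top = best_hits(hits).set_index("query_id")
    pos = cds_positions.set_index("cds_id")
    for _, blk in blocks.iterrows():
        members = blk["cds_ids"].split(";")
        cms = sorted(pos.loc[m, "position"] for m in members)
        bps = sorted(int(top.loc[m, "subject_start"]) for m in members)
        if any(b - a >= max_cm for a, b in zip(cms, cms[1:])):
            return False
        if any(b - a >= max_bp for a, b in zip(bps, bps[1:])):
            return False
    return True
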