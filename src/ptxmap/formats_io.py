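"""Readers and writers for every on-disk representation the pipeline touches.

All other modules operate on the in-memory containers defined here:

* :class:`GenotypeMatrix` — markers x individuals diploid calls plus the two
  parental calls, parsed from a TASSEL-style HapMap table or a plain genotype
  CSV.
* map tables, BLAST tabular (outfmt-6 dialect) hit tables and scaffold/CDS
  lookup tables are plain :class:`pandas.DataFrame` objects with fixed column
  sets, documented on the reader.

Genotype calls are two-letter diploid strings over the declared alleles
(``"AG"``), normalised to sorted letter order; ``"NN"`` is the only missing
token.  This dialect is a deliberate choice: IUPAC single letters cannot
represent the het/het configurations (ABxAB, ABxCD) unambiguously.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = "NN"

#: the 11 standard HapMap header columns, in order
HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

MAP_COLUMNS = ["marker_id", "lg", "position", "bin_id", "configuration"]

BLAST_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "query_start", "query_end",
    "subject_start", "subject_end", "e_value", "bit_score",
]

CONFIGURATIONS = ("ABxAA", "AAxAB", "ABxAB", "ABxCD")


class ParseError(ValueError):
    """Malformed input file (ragged row, bad token); carries the line number."""


class ValidationError(ValueError):
    """Structurally valid file with content violating an invariant."""


def normalize_call(call: str) -> str:
    """Sort the two letters of a diploid call; ``NN`` passes through."""
    if call == MISSING:
        return MISSING
    if len(call) != 2:
        raise ValidationError(f"genotype call {call!r} is not two letters")
    a, b = sorted(call)
    return a + b


@dataclasses.dataclass
class GenotypeMatrix:
    """Diploid genotype calls for a full-sib family plus its two parents.

    Attributes
    ----------
    markers : pandas.DataFrame
        One row per marker (index = marker_id) carrying at least ``alleles``
        (e.g. ``"A/G"``), ``chrom`` and ``pos``; extra HapMap metadata columns
        are preserved for round-tripping.
    calls : pandas.DataFrame
        markers x progeny two-letter calls, ``NN`` for missing.
    parents : pandas.DataFrame
        markers x 2 parental calls; columns are the parent sample names.
    """

    markers: pd.DataFrame
    calls: pd.DataFrame
    parents: pd.DataFrame

    @property
    def marker_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def samples(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_markers(self) -> int:
        return len(self.calls.index)

    @property
    def n_samples(self) -> int:
        return len(self.calls.columns)

    @property
    def parent_names(self) -> tuple[str, str]:
        p = self.parents.columns
        return (p[0], p[1])

    def n_missing(self) -> int:
        return int((self.calls.to_numpy() == MISSING).sum())

    def subset(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = pd.Index(marker_ids)
        return GenotypeMatrix(
            markers=self.markers.loc[idx],
            calls=self.calls.loc[idx],
            parents=self.parents.loc[idx],
        )

    def validate(self) -> None:
        if not self.calls.index.is_unique:
            dup = self.calls.index[self.calls.index.duplicated()][0]
            raise ValidationError(f"duplicate marker_id {dup!r}")
        arr = self.calls.to_numpy()
        alleles = self.markers["alleles"].str.split("/")
        for i, mid in enumerate(self.calls.index):
            ok = set(alleles.iloc[i])
            for call in arr[i]:
                if call == MISSING:
                    continue
                if call[0] not in ok or call[1] not in ok:
                    raise ValidationError(
                        f"marker {mid!r}: call {call!r} uses an undeclared allele"
                    )


def _split_line(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_hapmap(path: str | Path, parents: tuple[str, str] = ("P1", "P2"),
                validate: bool = True) -> GenotypeMatrix:
    """Parse a TASSEL-style HapMap table.

    ``parents`` names the two sample columns holding the parental genotypes;
    they are split out of the progeny call matrix.  Calls are normalised to
    sorted letter order.  Raises :class:`ParseError` with a line number on
    ragged rows and :class:`ValidationError` on undeclared allele letters.
    """
    path = Path(path)
    with open(path) as fh:
        header = _split_line(fh.readline())
        if header[: len(HAPMAP_COLUMNS)] != HAPMAP_COLUMNS:
            raise ParseError(
                f"{path}: line 1: expected the {len(HAPMAP_COLUMNS)} standard "
                "HapMap header columns"
            )
        samples = header[len(HAPMAP_COLUMNS):]
        for p in parents:
            if p not in samples:
                raise ValidationError(f"designated parent {p!r} not a sample column")
        rows, meta = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = _split_line(line)
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            meta.append(fields[: len(HAPMAP_COLUMNS)])
            rows.append([normalize_call(c) for c in fields[len(HAPMAP_COLUMNS):]])

    markers = pd.DataFrame(meta, columns=HAPMAP_COLUMNS)
    markers = markers.rename(columns={"rs#": "marker_id"})
    markers["pos"] = markers["pos"].astype(np.int64)
    markers = markers.set_index("marker_id", drop=False)
    markers.index.name = None
    if not markers.index.is_unique:
        dup = markers.index[markers.index.duplicated()][0]
        raise ValidationError(f"duplicate marker_id {dup!r}")
    calls = pd.DataFrame(rows, columns=samples, index=markers.index)
    gm = GenotypeMatrix(
        markers=markers,
        calls=calls.drop(columns=list(parents)),
        parents=calls.loc[:, list(parents)],
    )
    if validate:
        gm.validate()
    return gm


def write_hapmap(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix back to a HapMap table (round-trip identical)."""
    path = Path(path)
    meta = gm.markers.copy()
    meta = meta.rename(columns={"marker_id": "rs#"})
    for col in HAPMAP_COLUMNS:
        if col not in meta.columns:
            meta[col] = "NA"
    meta = meta[HAPMAP_COLUMNS].astype(str)
    body = pd.concat([gm.parents, gm.calls], axis=1)
    # parents are emitted in their original column positions only if they were
    # first; a written file always lists parents first, which re-reads cleanly
    with open(path, "w") as fh:
        fh.write("\t".join(HAPMAP_COLUMNS + list(body.columns)) + "\n")
        for (_, m), (_, c) in zip(meta.iterrows(), body.iterrows()):
            fh.write("\t".join(m.tolist() + c.tolist()) + "\n")


def read_genotype_csv(path: str | Path, parents: tuple[str, str] = ("P1", "P2"),
                      ) -> GenotypeMatrix:
    """Plain genotype CSV: first column marker_id, remaining columns samples.

    A convenience dialect; alleles are inferred from the observed letters.
    """
    df = pd.read_csv(path, dtype=str)
    df = df.set_index(df.columns[0])
    df.index.name = None
    df = df.map(normalize_call)
    for p in parents:
        if p not in df.columns:
            raise ValidationError(f"designated parent {p!r} not a sample column")
    alleles = []
    for _, row in df.iterrows():
        letters = sorted({ch for call in row if call != MISSING for ch in call})
        alleles.append("/".join(letters) if letters else "N")
    markers = pd.DataFrame(
        {
            "marker_id": df.index,
            "alleles": alleles,
            "chrom": "NA",
            "pos": np.arange(len(df), dtype=np.int64),
        },
        index=df.index,
    )
    return GenotypeMatrix(
        markers=markers,
        calls=df.drop(columns=list(parents)),
        parents=df.loc[:, list(parents)],
    )


def write_map(map_table: pd.DataFrame, path: str | Path) -> None:
    """Write a genetic-map table (one row per marker, stable column order)."""
    missing = [c for c in MAP_COLUMNS if c not in map_table.columns]
    if missing:
        raise ValidationError(f"map table lacks columns {missing}")
    if map_table["marker_id"].duplicated().any():
        dup = map_table.loc[map_table["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValidationError(f"duplicate marker_id {dup!r}")
    out = map_table[MAP_COLUMNS].copy()
    out["position"] = out["position"].map(lambda x: format(float(x), ".6g"))
    out.to_csv(path, sep="\t", index=False)


def read_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"marker_id": str, "lg": np.int64, "position": float,
               "bin_id": np.int64, "configuration": str},
    )
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: map table lacks columns {missing}")
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValidationError(f"duplicate marker_id {dup!r}")
    return df


def read_blast_tabular(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column BLAST ``-outfmt 6`` table.

    Subject coordinates are kept 1-based inclusive as BLAST emits them.  An
    empty file yields an empty table.  Non-numeric numeric fields raise
    :class:`ParseError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", names=BLAST_COLUMNS, header=None, comment="#",
            dtype={
                "query_id": str, "subject_id": str, "percent_identity": float,
                "alignment_length": np.int64, "mismatches": np.int64,
                "gap_opens": np.int64, "query_start": np.int64,
                "query_end": np.int64, "subject_start": np.int64,
                "subject_end": np.int64, "e_value": float, "bit_score": float,
            },
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BLAST_COLUMNS)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if (df["e_value"] < 0).any():
        raise ValidationError(f"{path}: negative e-value")
    if (df["alignment_length"] < 1).any():
        raise ValidationError(f"{path}: alignment_length < 1")
    return df


def write_blast_tabular(hits: pd.DataFrame, path: str | Path) -> None:
    hits[BLAST_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Scaffold/pseudomolecule sequences as an id -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    seqio_write(recs, str(path), "fasta")


def write_manifest(out_dir: str | Path, command: str, params: dict,
                   seed: int | None) -> Path:
    """Log a run's parameters and library versions next to its outputs."""
    import ptxmap

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "params": {k: (v if _jsonable(v) else repr(v)) for k, v in params.items()},
        "versions": {
            "ptxmap": ptxmap.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / f"manifest_{command.replace(' ', '_')}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
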