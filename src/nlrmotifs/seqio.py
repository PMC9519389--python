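"""FASTA input/output, sequence records and motif annotation tables.

Coordinate convention: 0-based half-open everywhere inside the package,
1-based inclusive in every external file. Every external table carries a
``#coords=1-based-inclusive`` header line stating this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .alphabet import VALID_RESIDUES
from .errors import InputError

COORD_HEADER = "#coords=1-based-inclusive"


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence: id, free-text description, residue string.

    Residues are upper-case letters from the 20-residue alphabet plus 'X'.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise InputError(
                f"record {self.id!r}: illegal residue character(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a protein FASTA file into SequenceRecords.

    Order is preserved, residues are upper-cased and a single terminal '*'
    stop symbol is stripped. Raises InputError on an empty file, an illegal
    residue character (naming the record and the character) or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        residues = str(entry.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        if entry.id in seen:
            raise InputError(f"duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        records.append(SequenceRecord(entry.id, residues, entry.description))
    if not records:
        raise InputError(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_predictions(calls: Sequence, path, fmt: str = "tsv", registry=None) -> None:
    """Write motif calls sorted by (sequence id, position).

    TSV columns: seqid, motif, start, end (both 1-based inclusive),
    probability (4 decimals). JSON mirrors the same fields. `registry` is
    needed to turn a motif start into an end coordinate (end = start + L - 1).
    """
    from .registry import default_registry, registry_by_name

    table = registry_by_name(registry if registry is not None else default_registry())
    ordered = sorted(calls, key=lambda c: (c.seqid, c.start))
    rows = []
    for c in ordered:
        try:
            length = table[c.motif].length
        except KeyError:
            raise InputError(f"call references unknown motif {c.motif!r}") from None
        rows.append(
            {
                "seqid": c.seqid,
                "motif": c.motif,
                "start": c.start + 1,
                "end": c.start + length,
                "probability": round(float(c.probability), 4),
            }
        )
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(COORD_HEADER + "\n")
            fh.write("seqid\tmotif\tstart\tend\tprobability\n")
            for r in rows:
                fh.write(
                    f"{r['seqid']}\t{r['motif']}\t{r['start']}\t{r['end']}"
                    f"\t{r['probability']:.4f}\n"
                )
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump({"coords": "1-based-inclusive", "calls": rows}, fh, indent=1)
    else:
        raise InputError(f"unknown prediction format {fmt!r}")


@dataclass
class AnnotationTable:
    """Motif annotations: rows of (seqid, motif, start, end), 0-based half-open
    in memory, 1-based inclusive on disk."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["seqid", "motif", "start", "end"]
        )
    )

    def validate(self, registry=None, lengths: dict[str, int] | None = None) -> None:
        from .registry import default_registry, registry_by_name

        table = registry_by_name(registry if registry is not None else default_registry())
        for row in self.frame.itertuples(index=False):
            if row.motif not in table:
                raise InputError(f"annotation references unknown motif {row.motif!r}")
            if not row.start < row.end:
                raise InputError(
                    f"annotation {row.seqid}/{row.motif}: start must be < end"
                )
            if lengths is not None:
                n = lengths.get(row.seqid)
                if n is None:
                    raise InputError(f"annotation references unknown sequence {row.seqid!r}")
                if row.start < 0 or row.end > n:
                    raise InputError(
                        f"annotation {row.seqid}/{row.motif}: positions outside sequence"
                    )


def read_annotation_table(path) -> AnnotationTable:
    with open(path) as fh:
        first = fh.readline().strip()
        if first != COORD_HEADER:
            raise InputError(
                f"annotation table must declare its coordinate convention with a "
                f"leading {COORD_HEADER!r} line"
            )
        frame = pd.read_csv(fh, sep="\t")
    required = {"seqid", "motif", "start", "end"}
    if not required.issubset(frame.columns):
        raise InputError(f"annotation table missing columns {sorted(required - set(frame.columns))}")
    frame = frame.copy()
    frame["start"] = frame["start"].astype(int) - 1  # 1-based incl -> 0-based half-open
    frame["end"] = frame["end"].astype(int)
    return AnnotationTable(frame)


def write_annotation_table(table: AnnotationTable, path) -> None:
    frame = table.frame.copy()
    frame["start"] = frame["start"].astype(int) + 1
    frame["end"] = frame["end"].astype(int)
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        frame.to_csv(fh, sep="\t", index=False)
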