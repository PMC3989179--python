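"""Aligned-sequence I/O, specimen metadata, and haplotype collapsing.

The delimitation pipeline starts from an alignment of mitochondrial barcode
sequences (e.g. ~440 bp 16S or ~650 bp COI) in which every row is tied to a
specimen record carrying the morphospecies label assigned from external and
genital anatomy, the locality, and whether the specimen comes from Britain or
Ireland.  Identical sequences are collapsed to haplotypes before any distance
computation; all provenance (which specimens share a haplotype) is retained so
later stages can map delimited groups back onto individuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentError",
    "SpecimenRecord",
    "Alignment",
    "HaplotypeSet",
    "read_alignment",
    "write_alignment",
    "collapse_haplotypes",
    "METADATA_COLUMNS",
]

#: Required columns of the specimen metadata table, in canonical order.
METADATA_COLUMNS = (
    "specimen_id",
    "morphospecies_label",
    "locality",
    "in_britain_or_ireland",
    "source",
    "locus",
)

_SOURCES = frozenset({"new", "genbank"})
_LOCI = frozenset({"mt16S", "mtCOI", "nuclearITS1"})


class AlignmentError(ValueError):
    """Raised for malformed alignments or metadata (unequal lengths, duplicate
    or unmatched identifiers, empty input)."""


@dataclass(frozen=True)
class SpecimenRecord:
    """Metadata for one sequenced specimen.

    ``morphospecies_label`` may be ``"unknown"`` for juveniles identified only
    a posteriori from the DNA results.
    """

    specimen_id: str
    morphospecies_label: str = "unknown"
    locality: str = ""
    in_britain_or_ireland: bool = True
    source: str = "new"
    locus: str = "mtCOI"

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise AlignmentError("specimen_id must be non-empty")
        if self.source not in _SOURCES:
            raise AlignmentError(
                f"source must be one of {sorted(_SOURCES)}, got {self.source!r}"
            )
        if self.locus not in _LOCI:
            raise AlignmentError(
                f"locus must be one of {sorted(_LOCI)}, got {self.locus!r}"
            )


@dataclass
class Alignment:
    """An aligned set of sequences joined to specimen records.

    Rows are strings over {A, C, G, T, IUPAC ambiguity codes, '-'} and must all
    have the same length.  Specimen ids are unique and every row shares one
    locus.
    """

    records: list[SpecimenRecord]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.sequences):
            raise AlignmentError(
                f"{len(self.records)} records but {len(self.sequences)} sequences"
            )
        if not self.records:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"unaligned input: sequence lengths differ ({sorted(lengths)})"
            )
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate specimen ids: {dupes}")
        loci = {r.locus for r in self.records}
        if len(loci) != 1:
            raise AlignmentError(f"mixed loci in one alignment: {sorted(loci)}")

    @property
    def length(self) -> int:
        """Number of aligned sites."""
        return len(self.sequences[0])

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def locus(self) -> str:
        return self.records[0].locus

    def __len__(self) -> int:
        return len(self.records)

    def sequence_of(self, specimen_id: str) -> str:
        try:
            i = self.ids.index(specimen_id)
        except ValueError:
            raise KeyError(specimen_id) from None
        return self.sequences[i]

    def subset(self, specimen_ids: Iterable[str]) -> "Alignment":
        """Alignment restricted to the given specimens, in original order."""
        wanted = set(specimen_ids)
        missing = wanted - set(self.ids)
        if missing:
            raise AlignmentError(f"unknown specimen ids: {sorted(missing)}")
        keep = [i for i, r in enumerate(self.records) if r.specimen_id in wanted]
        return Alignment(
            [self.records[i] for i in keep], [self.sequences[i] for i in keep]
        )


@dataclass
class HaplotypeSet:
    """Unique sequences of an alignment with their member specimens.

    Haplotype ids are ``H1, H2, ...`` in order of first occurrence; the sum of
    multiplicities equals the number of input specimens.
    """

    ids: list[str]
    sequences: list[str]
    members: list[list[str]]
    locus: str = "mtCOI"

    @property
    def multiplicity(self) -> list[int]:
        return [len(m) for m in self.members]

    @property
    def n_specimens(self) -> int:
        return sum(self.multiplicity)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.ids)

    def haplotype_of(self, specimen_id: str) -> str:
        """Haplotype id carrying the given specimen."""
        for hid, members in zip(self.ids, self.members):
            if specimen_id in members:
                return hid
        raise KeyError(specimen_id)

    def to_alignment(self) -> Alignment:
        """One-row-per-haplotype alignment (placeholder specimen metadata),
        convenient for tree building and column-resampling bootstraps."""
        recs = [
            SpecimenRecord(
                specimen_id=hid,
                morphospecies_label="haplotype",
                locality="",
                in_britain_or_ireland=True,
                source="new",
                locus=self.locus,
            )
            for hid in self.ids
        ]
        return Alignment(recs, list(self.sequences))

    def to_json(self) -> str:
        payload = {
            "locus": self.locus,
            "haplotypes": [
                {"id": h, "sequence": s, "members": m, "multiplicity": len(m)}
                for h, s, m in zip(self.ids, self.sequences, self.members)
            ],
        }
        return json.dumps(payload, indent=2)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _coerce_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "y", "t"}:
        return True
    if text in {"false", "0", "no", "n", "f"}:
        return False
    raise AlignmentError(f"cannot interpret {value!r} as a boolean flag")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the delimited specimen metadata table (CSV or TSV, header row)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise AlignmentError(f"metadata table missing columns: {missing}")
    ids = df["specimen_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AlignmentError(f"duplicate specimen ids in metadata: {dupes}")
    return df


def read_alignment(path: str | Path, metadata_path: str | Path) -> Alignment:
    """Read an aligned FASTA plus its metadata table.

    Every FASTA identifier must appear in the metadata; an unmatched id is an
    error naming the id.  Metadata rows without a matching sequence are
    ignored (the table may describe a superset of specimens).
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise AlignmentError(f"duplicate FASTA id: {rec.id}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise AlignmentError(f"no sequences found in {path}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise AlignmentError(
            f"unaligned input: sequence lengths differ ({sorted(lengths)})"
        )
    meta = read_metadata(metadata_path).set_index("specimen_id", drop=False)
    missing = [i for i in seqs if i not in meta.index]
    if missing:
        raise AlignmentError(f"FASTA ids absent from metadata: {missing}")
    records = []
    for sid in seqs:
        row = meta.loc[sid]
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                morphospecies_label=str(row["morphospecies_label"]),
                locality="" if pd.isna(row["locality"]) else str(row["locality"]),
                in_britain_or_ireland=_coerce_bool(row["in_britain_or_ireland"]),
                source=str(row["source"]),
                locus=str(row["locus"]),
            )
        )
    return Alignment(records, list(seqs.values()))


def write_alignment(
    aln: Alignment, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write the alignment as FASTA and, optionally, its metadata as CSV."""
    seq_records = [
        SeqRecord(Seq(s), id=r.specimen_id, description="")
        for r, s in zip(aln.records, aln.sequences)
    ]
    SeqIO.write(seq_records, str(path), "fasta")
    if metadata_path is not None:
        rows = [
            {
                "specimen_id": r.specimen_id,
                "morphospecies_label": r.morphospecies_label,
                "locality": r.locality,
                "in_britain_or_ireland": r.in_britain_or_ireland,
                "source": r.source,
                "locus": r.locus,
            }
            for r in aln.records
        ]
        pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
            metadata_path, index=False
        )


def collapse_haplotypes(aln: Alignment) -> HaplotypeSet:
    """Collapse identical sequences to haplotypes.

    Identity is exact string equality after uppercasing: ambiguity codes and
    gaps are compared literally (an ``N`` never equals an ``A``).  Haplotypes
    are numbered H1, H2, ... in first-occurrence order, which makes collapsing
    deterministic and idempotent.
    """
    order: dict[str, int] = {}
    members: list[list[str]] = []
    for rec, seq in zip(aln.records, aln.sequences):
        key = seq.upper()
        if key not in order:
            order[key] = len(order)
            members.append([])
        members[order[key]].append(rec.specimen_id)
    sequences = list(order)
    ids = [f"H{i + 1}" for i in range(len(sequences))]
    return HaplotypeSet(ids=ids, sequences=sequences, members=members, locus=aln.locus)
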