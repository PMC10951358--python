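"""Alignment and taxon-map I/O, validation, and locus concatenation.

Alignments are gapped, equal-length FASTA files, one record per accession.
Columns are addressed 1-based and inclusive throughout the package, matching
the coordinate convention of published diagnostic-site tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Unambiguous nucleotide states used by all downstream analyses.
BASES = frozenset("ACGT")
#: The sole gap character. '.' is rejected at parse time.
GAP = "-"

IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")
VALID_CHARS = BASES | IUPAC_AMBIGUITY | {GAP}


class AlignmentShapeError(ValueError):
    """Sequences in one alignment have unequal lengths."""


class IdentifierError(ValueError):
    """Duplicate or missing accession identifiers."""


class FormatError(ValueError):
    """Malformed input file."""


class CompositionError(ValueError):
    """Locus concatenation could not be performed."""


@dataclass
class Alignment:
    """A multiple-sequence alignment for one locus.

    Parameters
    ----------
    name : locus label (e.g. ``"petA"``).
    accessions : ordered accession identifiers, one per row.
    sequences : equal-length uppercase strings over ``{A,C,G,T,-,N,IUPAC}``.
    """

    name: str
    accessions: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.accessions) != len(self.sequences):
            raise AlignmentShapeError(
                f"{len(self.accessions)} accessions but {len(self.sequences)} sequences"
            )
        if not self.sequences:
            raise FormatError("alignment has no records")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"unequal sequence lengths in locus {self.name!r}: {sorted(lengths)}"
            )
        if min(lengths) < 1:
            raise AlignmentShapeError("zero-length alignment")
        if len(set(self.accessions)) != len(self.accessions):
            dupes = sorted({a for a in self.accessions if self.accessions.count(a) > 1})
            raise IdentifierError(f"duplicate accession(s): {dupes}")
        self.sequences = [s.upper() for s in self.sequences]
        bad = set("".join(self.sequences)) - VALID_CHARS
        if bad:
            raise FormatError(f"invalid characters in alignment: {sorted(bad)}")

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def sequence(self, accession: str) -> str:
        return self.sequences[self.accessions.index(accession)]

    def column(self, col: int) -> str:
        """Characters of 1-based column `col`, in accession order."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        return "".join(s[col - 1] for s in self.sequences)

    def subset(self, accessions: Sequence[str]) -> "Alignment":
        """Row subset, keeping this alignment's accession order."""
        keep = [a for a in self.accessions if a in set(accessions)]
        return Alignment(
            name=self.name,
            accessions=keep,
            sequences=[self.sequence(a) for a in keep],
        )


@dataclass
class TaxonMap:
    """Accession-to-taxon assignment with a designated outgroup set."""

    assignments: dict[str, str]
    outgroup: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        missing = self.outgroup - set(self.assignments)
        if missing:
            raise IdentifierError(f"outgroup accessions not assigned: {sorted(missing)}")
        if not self.ingroup_taxa():
            raise FormatError("taxon map has no ingroup taxon")

    def taxon(self, accession: str) -> str:
        return self.assignments[accession]

    def ingroup_accessions(self) -> list[str]:
        return [a for a in self.assignments if a not in self.outgroup]

    def ingroup_taxa(self) -> list[str]:
        """Ingroup taxon labels in first-appearance order."""
        seen: dict[str, None] = {}
        for acc in self.ingroup_accessions():
            seen.setdefault(self.assignments[acc], None)
        return list(seen)

    def accessions_of(self, taxon: str) -> list[str]:
        return [a for a, t in self.assignments.items()
                if t == taxon and a not in self.outgroup]


@dataclass
class LocusPartition:
    """1-based, inclusive locus intervals on a concatenated alignment."""

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        expected_start = 1
        for name, start, end in self.intervals:
            if start != expected_start or end < start:
                raise CompositionError(
                    f"partition interval {name} [{start},{end}] does not tile the alignment"
                )
            expected_start = end + 1

    @property
    def total_length(self) -> int:
        return self.intervals[-1][2] if self.intervals else 0

    def locate(self, column: int) -> tuple[str, int]:
        """Map a concatenated column to (locus, locus-local column)."""
        for name, start, end in self.intervals:
            if start <= column <= end:
                return name, column - start + 1
        raise CompositionError(f"column {column} outside partition 1..{self.total_length}")


def read_fasta_alignment(path: str | Path, name: str | None = None) -> Alignment:
    """Read a gapped FASTA alignment.

    The accession identifier is the first whitespace-delimited token of the
    header line. Characters are uppercased; record order is preserved.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    accessions = [r.id for r in records]
    sequences = [str(r.seq) for r in records]
    if any("." in s for s in sequences):
        raise FormatError("'.' gap characters are not accepted; use '-'")
    return Alignment(name=name or path.stem, accessions=accessions, sequences=sequences)


def write_fasta_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write one record per accession in the alignment's order."""
    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in zip(alignment.accessions, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_taxon_map(path: str | Path) -> TaxonMap:
    """Read a delimited taxon map: ``accession  taxon  [outgroup]``.

    Tab- or comma-delimited; a header row naming the first column
    ``accession`` is skipped. The optional third field flags outgroup
    membership with 1/0.
    """
    path = Path(path)
    assignments: dict[str, str] = {}
    outgroup: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            fields = [f.strip() for f in fields]
            if lineno == 1 and fields[0].lower() == "accession":
                continue
            if len(fields) < 2 or not fields[1]:
                raise FormatError(f"{path}:{lineno}: missing taxon field")
            acc, taxon = fields[0], fields[1]
            if acc in assignments:
                raise IdentifierError(f"{path}:{lineno}: duplicate accession {acc!r}")
            assignments[acc] = taxon
            if len(fields) >= 3 and fields[2] in {"1", "true", "True"}:
                outgroup.add(acc)
    if not assignments:
        raise FormatError(f"empty taxon map: {path}")
    return TaxonMap(assignments=assignments, outgroup=outgroup)


def write_taxon_map(taxon_map: TaxonMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\ttaxon\toutgroup\n")
        for acc, taxon in taxon_map.assignments.items():
            flag = 1 if acc in taxon_map.outgroup else 0
            fh.write(f"{acc}\t{taxon}\t{flag}\n")


def write_partition(partition: LocusPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tstart\tend\n")
        for name, start, end in partition.intervals:
            fh.write(f"{name}\t{start}\t{end}\n")


def concatenate(
    alignments: Sequence[Alignment],
    accession_policy: str = "intersection",
) -> tuple[Alignment, LocusPartition]:
    """Join loci end-to-end into one alignment with a partition record.

    Under the default ``intersection`` policy only accessions present in
    every locus are kept (dropped accessions are logged); ``strict`` requires
    identical accession sets.
    """
    if len(alignments) < 2:
        raise CompositionError("need at least two alignments to concatenate")
    if accession_policy not in {"intersection", "strict"}:
        raise ValueError(f"unknown accession policy {accession_policy!r}")

    sets = [set(a.accessions) for a in alignments]
    if accession_policy == "strict":
        if any(s != sets[0] for s in sets[1:]):
            raise CompositionError("strict concatenation requires identical accession sets")
        shared = sets[0]
    else:
        shared = set.intersection(*sets)
        if not shared:
            raise CompositionError("no accession shared by all loci")
        dropped = set.union(*sets) - shared
        if dropped:
            logger.warning("concatenate: dropping accessions absent from some loci: %s",
                           sorted(dropped))

    order = [a for a in alignments[0].accessions if a in shared]
    sequences = ["".join(aln.sequence(acc) for aln in alignments) for acc in order]

    intervals = []
    start = 1
    for aln in alignments:
        intervals.append((aln.name, start, start + aln.length - 1))
        start += aln.length
    combined = Alignment(
        name="+".join(a.name for a in alignments),
        accessions=order,
        sequences=sequences,
    )
    return combined, LocusPartition(intervals)
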