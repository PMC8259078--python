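"""Core sequence and codon data model.

The reference frame for everything downstream is a validated in-frame coding
sequence (CDS) with optional genomic flanks.  All internal coordinates are
0-based half-open on the *sense* strand of the concatenated
``upstream_flank + cds + downstream_flank``; user-facing reports are 1-based
inclusive (c.-style), and BED output is 0-based half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")


class SequenceValidationError(ValueError):
    """A sequence record violates the CDS invariants."""


class FastaParseError(ValueError):
    """The input file is not parseable FASTA."""


@dataclass(frozen=True)
class CodonTable:
    """Mapping from each of the 64 codons to a one-letter residue, stop as '*'."""

    table_id: int
    forward: dict = field(repr=False)

    @classmethod
    def from_id(cls, table_id: int = 1) -> "CodonTable":
        bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(bio.forward_table)
        for stop in bio.stop_codons:
            mapping[stop] = "*"
        if len(mapping) != 64:
            raise ValueError(f"codon table {table_id} does not define 64 codons")
        return cls(table_id=table_id, forward=mapping)

    def aa(self, codon: str) -> str:
        try:
            return self.forward[codon]
        except KeyError:
            raise ValueError(f"invalid codon {codon!r}") from None

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, a in self.forward.items() if a == "*")


STANDARD_TABLE = CodonTable.from_id(1)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string."""
    _check_bases(seq, what="sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    if base not in VALID_BASES:
        raise ValueError(f"invalid base {base!r}")
    return base.translate(_COMPLEMENT)


def translate(cds: str, table: CodonTable = STANDARD_TABLE) -> str:
    """Translate an in-frame nucleotide string; stops rendered as ``*``."""
    if len(cds) % 3 != 0:
        raise ValueError(f"length {len(cds)} is not a multiple of 3")
    return "".join(table.aa(cds[i : i + 3]) for i in range(0, len(cds), 3))


def _check_bases(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise SequenceValidationError(
            f"{what} contains non-ACGT characters: {sorted(bad)}"
        )


@dataclass(frozen=True)
class ReferenceCoordinate:
    """Bridge between reference, CDS and codon coordinates.

    ``position`` is 1-based on the sense strand of the concatenated
    ``upstream_flank + cds + downstream_flank``.  The CDS-level fields are
    present only when the position falls inside the CDS span.
    """

    position: int
    cds_position: int | None = None
    codon_index: int | None = None
    codon_offset: int | None = None

    @property
    def in_cds(self) -> bool:
        return self.cds_position is not None


@dataclass(frozen=True)
class CodingSequence:
    """A validated in-frame CDS with optional genomic flanks (sense strand, 5'->3')."""

    id: str
    cds: str
    upstream_flank: str = ""
    downstream_flank: str = ""
    codon_table_id: int = 1

    def __post_init__(self):
        for name in ("cds", "upstream_flank", "downstream_flank"):
            object.__setattr__(self, name, getattr(self, name).upper())
        _check_bases(self.cds, what=f"{self.id}: cds")
        _check_bases(self.upstream_flank, what=f"{self.id}: upstream_flank")
        _check_bases(self.downstream_flank, what=f"{self.id}: downstream_flank")
        if len(self.cds) == 0 or len(self.cds) % 3 != 0:
            raise SequenceValidationError(
                f"{self.id}: cds length {len(self.cds)} is not a positive multiple of 3"
            )
        table = self.codon_table
        protein = translate(self.cds, table)
        if "*" in protein[:-1]:
            idx = protein.index("*") + 1
            raise SequenceValidationError(
                f"{self.id}: internal stop codon at codon {idx}"
            )

    @property
    def codon_table(self) -> CodonTable:
        if self.codon_table_id == 1:
            return STANDARD_TABLE
        return CodonTable.from_id(self.codon_table_id)

    @property
    def reference(self) -> str:
        """upstream_flank + cds + downstream_flank on the sense strand."""
        return self.upstream_flank + self.cds + self.downstream_flank

    @property
    def cds_start(self) -> int:
        """0-based start of the CDS within :attr:`reference`."""
        return len(self.upstream_flank)

    @property
    def cds_end(self) -> int:
        """0-based exclusive end of the CDS within :attr:`reference`."""
        return len(self.upstream_flank) + len(self.cds)

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def protein(self, drop_terminal_stop: bool = False) -> str:
        p = translate(self.cds, self.codon_table)
        if drop_terminal_stop and p.endswith("*"):
            p = p[:-1]
        return p

    def with_flanks(self, n: int) -> "CodingSequence":
        """Trim both flanks to at most ``n`` nucleotides nearest the CDS."""
        if n < 0:
            raise ValueError("flank length must be >= 0")
        up = self.upstream_flank[len(self.upstream_flank) - n :] if n else ""
        dn = self.downstream_flank[:n]
        return dataclasses.replace(self, upstream_flank=up, downstream_flank=dn)

    def coordinate(self, ref_index: int) -> ReferenceCoordinate:
        """Coordinate record for a 0-based index into :attr:`reference`."""
        if not 0 <= ref_index < len(self.reference):
            raise ValueError(f"reference index {ref_index} out of range")
        pos = ref_index + 1
        if self.cds_start <= ref_index < self.cds_end:
            cds_pos = ref_index - self.cds_start + 1
            return ReferenceCoordinate(
                position=pos,
                cds_position=cds_pos,
                codon_index=(cds_pos - 1) // 3 + 1,
                codon_offset=(cds_pos - 1) % 3 + 1,
            )
        return ReferenceCoordinate(position=pos)


def codon_at(cs: CodingSequence, cds_position: int) -> tuple[str, int, int]:
    """Return (codon, codon_index, codon_offset) for a 1-based CDS position."""
    if not 1 <= cds_position <= len(cs.cds):
        raise ValueError(f"cds position {cds_position} out of range 1..{len(cs.cds)}")
    codon_index = (cds_position - 1) // 3 + 1
    codon_offset = (cds_position - 1) % 3 + 1
    codon = cs.cds[(codon_index - 1) * 3 : codon_index * 3]
    return codon, codon_index, codon_offset


def _split_record(
    rec: SeqRecord,
    upstream_flank_len: int,
    downstream_flank_len: int,
    codon_table_id: int,
) -> CodingSequence:
    seq = str(rec.seq).upper()
    # per-record flank lengths may be declared in the FASTA description as
    # key=value tokens, overriding the call-level defaults
    up_len, dn_len = upstream_flank_len, downstream_flank_len
    for token in rec.description.split():
        if token.startswith("upstream_flank="):
            up_len = int(token.split("=", 1)[1])
        elif token.startswith("downstream_flank="):
            dn_len = int(token.split("=", 1)[1])
    if up_len + dn_len >= len(seq):
        raise SequenceValidationError(
            f"{rec.id}: declared flanks ({up_len}+{dn_len}) leave no CDS"
        )
    return CodingSequence(
        id=rec.id,
        cds=seq[up_len : len(seq) - dn_len] if dn_len else seq[up_len:],
        upstream_flank=seq[:up_len],
        downstream_flank=seq[len(seq) - dn_len :] if dn_len else "",
        codon_table_id=codon_table_id,
    )


def load_fasta(
    path: str | Path,
    upstream_flank_len: int = 0,
    downstream_flank_len: int = 0,
    codon_table_id: int = 1,
    errors: str = "raise",
) -> list[CodingSequence]:
    """Load coding sequences from a FASTA file.

    A single genomic record may carry flanks; their lengths are declared
    either by the ``upstream_flank_len``/``downstream_flank_len`` arguments or
    per record as ``upstream_flank=N downstream_flank=M`` tokens in the FASTA
    description line.

    With ``errors="collect"`` invalid records are skipped and returned as a
    second list of ``(record_id, reason)`` pairs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython raises ValueError
        raise FastaParseError(f"{path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    out: list[CodingSequence] = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        try:
            out.append(
                _split_record(rec, upstream_flank_len, downstream_flank_len, codon_table_id)
            )
        except (SequenceValidationError, ValueError) as exc:
            if errors == "collect":
                failures.append((rec.id, str(exc)))
            else:
                raise
    if errors == "collect":
        return out, failures  # type: ignore[return-value]
    return out


def load_plain_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Load (id, uppercased sequence) pairs without CDS validation (amplicons)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, sequences: Iterable[CodingSequence]) -> None:
    """Write coding sequences (reference with flanks) back to FASTA.

    Flank lengths are recorded in the description so that a round-trip
    through :func:`load_fasta` reproduces the same objects.
    """
    records = []
    for cs in sequences:
        desc = (
            f"upstream_flank={len(cs.upstream_flank)} "
            f"downstream_flank={len(cs.downstream_flank)}"
        )
        records.append(SeqRecord(Seq(cs.reference), id=cs.id, description=desc))
    SeqIO.write(records, str(path), "fasta")
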