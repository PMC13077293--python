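"""IUPAC sequence algebra, primer and record types, FASTA and taxonomy I/O.

Sequences are plain Python strings over the 15-letter IUPAC DNA alphabet,
stored 5'->3'.  Reference records keep the template sense strand exactly as
deposited: ITS reference databases such as UNITE are consistently oriented
(5.8S -> 28S), so no automatic re-orientation is attempted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

# IUPAC nucleotide codes and their concrete expansions.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_CODES = frozenset(IUPAC_SETS)

# Bit encoding (A=1, C=2, G=4, T=8) used by the matching engine: two codes
# are compatible iff their bit patterns intersect.
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_BITS: dict[str, int] = {
    code: sum(_BASE_BITS[b] for b in bases) for code, bases in IUPAC_SETS.items()
}
_BITS_TO_CODE = {bits: code for code, bits in IUPAC_BITS.items()}

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: Canonical seven-rank taxonomy order with their UNITE-style prefixes.
RANKS: tuple[str, ...] = (
    "kingdom", "phylum", "class", "order", "family", "genus", "species",
)
RANK_PREFIXES: dict[str, str] = {
    "k": "kingdom", "p": "phylum", "c": "class", "o": "order",
    "f": "family", "g": "genus", "s": "species",
}
UNIDENTIFIED = "unidentified"

GAP_CHARS = "-."


class SequenceError(ValueError):
    """Raised for sequences that violate the IUPAC alphabet or type invariants."""


def normalize_sequence(raw: str, *, keep_gaps: bool = False) -> str:
    """Normalize a raw sequence string to uppercase IUPAC DNA.

    Whitespace is stripped, U (RNA) is rewritten to T, and gap characters
    ('-', '.') are removed unless ``keep_gaps`` is set (aligned input).

    Raises
    ------
    SequenceError
        If the input is empty (after cleaning) or contains a character
        outside the IUPAC DNA alphabet; the message names the 1-based
        position of the first offending character.
    """
    if not raw:
        raise SequenceError("empty sequence")
    cleaned = re.sub(r"\s+", "", raw).upper().replace("U", "T")
    if not keep_gaps:
        cleaned = cleaned.translate(str.maketrans("", "", GAP_CHARS))
    for i, ch in enumerate(cleaned):
        if ch not in IUPAC_CODES and not (keep_gaps and ch in GAP_CHARS):
            raise SequenceError(
                f"invalid IUPAC code {ch!r} at position {i + 1}"
            )
    if not cleaned:
        raise SequenceError("empty sequence after normalization")
    return cleaned


def base_set(code: str) -> frozenset[str]:
    """Concrete bases denoted by one IUPAC code (e.g. R -> {A, G})."""
    try:
        return IUPAC_SETS[code]
    except KeyError:
        raise SequenceError(f"invalid IUPAC code {code!r}") from None


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H; S, W, N fixed)."""
    try:
        return "".join(_COMPLEMENT[ch] for ch in reversed(seq))
    except KeyError as exc:
        raise SequenceError(f"invalid IUPAC code {exc.args[0]!r}") from None


def degeneracy(seq: str) -> int:
    """Number of concrete sequences a degenerate sequence denotes."""
    n = 1
    for ch in seq:
        n *= len(base_set(ch))
    return n


def expansions(seq: str) -> Iterable[str]:
    """Yield every concrete realization of a degenerate sequence."""
    if not seq:
        yield ""
        return
    for rest in expansions(seq[1:]):
        for b in sorted(base_set(seq[0])):
            yield b + rest


@dataclass(frozen=True)
class Primer:
    """A named PCR primer, stored 5'->3' over the IUPAC DNA alphabet.

    ``role`` is "forward" or "reverse"; reverse primers are written as they
    would be synthesized (i.e. reverse-complementary to the sense strand).
    """

    name: str
    sequence: str
    role: str = "forward"
    min_len: int = 10
    max_len: int = 40

    def __post_init__(self) -> None:
        if self.role not in ("forward", "reverse"):
            raise SequenceError(f"primer role must be forward/reverse, got {self.role!r}")
        norm = normalize_sequence(self.sequence)
        object.__setattr__(self, "sequence", norm)
        if not self.min_len <= len(norm) <= self.max_len:
            raise SequenceError(
                f"primer {self.name!r} length {len(norm)} outside "
                f"[{self.min_len}, {self.max_len}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.sequence)


@dataclass(frozen=True)
class Lineage:
    """Ordered rank->name taxonomy assignment (kingdom .. species).

    Missing ranks are allowed; empty names are normalized to the explicit
    "unidentified" sentinel.  Rank prefixes outside the seven-rank
    convention are preserved verbatim in ``other``.
    """

    names: tuple[tuple[str, str], ...] = ()
    other: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: list[str] = []
        for rank, _name in self.names:
            if rank not in RANKS:
                raise SequenceError(f"unknown taxonomic rank {rank!r}")
            seen.append(rank)
        if len(set(seen)) != len(seen):
            raise SequenceError(f"duplicate ranks in lineage: {seen}")
        order = [RANKS.index(r) for r in seen]
        if order != sorted(order):
            raise SequenceError(f"ranks out of canonical order: {seen}")
        cleaned = tuple(
            (rank, name if name else UNIDENTIFIED) for rank, name in self.names
        )
        object.__setattr__(self, "names", cleaned)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "Lineage":
        items = tuple(
            (rank, mapping[rank]) for rank in RANKS if rank in mapping
        )
        return cls(names=items)

    def get(self, rank: str, default: str | None = None) -> str | None:
        for r, name in self.names:
            if r == rank:
                return name
        return default

    def is_empty(self) -> bool:
        return not self.names and not self.other

    def to_unite(self) -> str:
        """Render back to the semicolon-delimited rank-prefixed dialect."""
        parts = []
        prefix_of = {v: k for k, v in RANK_PREFIXES.items()}
        for rank, name in self.names:
            parts.append(f"{prefix_of[rank]}__{name}")
        parts.extend(self.other)
        return ";".join(parts)


def parse_unite_lineage(text: str) -> Lineage:
    """Parse a UNITE-style ``k__Fungi;p__Ascomycota;...`` lineage string."""
    ranks: dict[str, str] = {}
    other: list[str] = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        m = re.match(r"^([A-Za-z]+)__(.*)$", part)
        if m and m.group(1).lower() in RANK_PREFIXES:
            ranks[RANK_PREFIXES[m.group(1).lower()]] = m.group(2).strip()
        else:
            other.append(part)
    items = tuple((rank, ranks[rank]) for rank in RANKS if rank in ranks)
    return Lineage(names=items, other=tuple(other))


@dataclass(frozen=True)
class SeqRecord:
    """A reference sequence: id, sense-strand sequence, optional lineage.

    ``origin`` tags synthetic records (target/host/mock) so simulated
    libraries can be summarized per source.
    """

    id: str
    sequence: str
    lineage: Lineage = field(default_factory=Lineage)
    origin: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, taxonomy_mode: str = "none") -> list[SeqRecord]:
    """Read a multi-FASTA file into records.

    ``taxonomy_mode="unite"`` parses the header segment after the last ``|``
    as a semicolon-delimited rank-prefixed lineage; records without a
    parsable lineage get an empty one and a logged warning.  Duplicate ids
    are rejected.
    """
    if taxonomy_mode not in ("none", "unite"):
        raise ValueError(f"unknown taxonomy_mode {taxonomy_mode!r}")
    path = Path(path)
    records: list[SeqRecord] = []
    ids: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description or entry.id
        lineage = Lineage()
        rec_id = entry.id
        if taxonomy_mode == "unite":
            if "|" in header:
                head, _, tail = header.rpartition("|")
                parsed = parse_unite_lineage(tail)
                if parsed.is_empty():
                    logger.warning("record %s: unparsable lineage %r", head, tail)
                else:
                    lineage = parsed
                    rec_id = head.split()[0] if head.split() else head
            else:
                logger.warning("record %s: no lineage segment in header", rec_id)
        try:
            seq = str(entry.seq)
        except Exception:  # pragma: no cover - malformed entries
            raise SequenceError(f"unreadable sequence for record {rec_id!r}")
        if not seq:
            raise SequenceError(f"empty sequence for record {rec_id!r}")
        ids[rec_id] = ids.get(rec_id, 0) + 1
        records.append(SeqRecord(id=rec_id, sequence=seq, lineage=lineage))
    dupes = sorted(i for i, n in ids.items() if n > 1)
    if dupes:
        raise SequenceError(f"duplicate record ids: {', '.join(dupes)}")
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path,
                taxonomy_mode: str = "none", width: int = 0) -> None:
    """Write records to FASTA; in unite mode the lineage is appended after '|'.

    ``width=0`` writes single-line sequences (byte-stable round-trips).
    """
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if taxonomy_mode == "unite" and not rec.lineage.is_empty():
                header = f"{rec.id}|{rec.lineage.to_unite()}"
            fh.write(f">{header}\n")
            if width and width > 0:
                for i in range(0, len(rec.sequence), width):
                    fh.write(rec.sequence[i:i + width] + "\n")
            else:
                fh.write(rec.sequence + "\n")


def read_primers_tsv(path: str | Path) -> list[Primer]:
    """Read primers from a TSV with columns: name, sequence, role."""
    primers: list[Primer] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "name" and lineno == 1:
                continue
            if len(parts) < 3:
                raise SequenceError(
                    f"{path}:{lineno}: expected 3 tab-separated fields "
                    f"(name, sequence, role), got {len(parts)}"
                )
            primers.append(Primer(name=parts[0], sequence=parts[1], role=parts[2]))
    if not primers:
        raise SequenceError(f"no primers found in {path}")
    return primers


# The four primers evaluated in this toolkit's reference workflow.  All are
# written 5'->3' as synthesized; ITS4 is the universal reverse primer.
ITS3_CORALF = Primer("ITS3-CoralF", "GATGAAGAACGCAGCGAAA", "forward")
FITS7 = Primer("fITS7", "GTGARTCATCGAATCTTTG", "forward")
ITS86F = Primer("ITS86F", "GTGAATCATCGAATCTTTGAA", "forward")
ITS4 = Primer("ITS4", "TCCTCCGCTTATTGATATGC", "reverse")
# ITS3, the universal forward primer whose binding site ITS3-CoralF shifts
# away from; included for design-mode comparisons.
ITS3 = Primer("ITS3", "GCATCGATGAAGAACGCAGC", "forward")

PRIMER_REGISTRY: dict[str, Primer] = {
    p.name: p for p in (ITS3_CORALF, FITS7, ITS86F, ITS4, ITS3)
}
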