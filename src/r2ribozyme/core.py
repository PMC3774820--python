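"""Sequence and coordinate bedrock shared by the whole package.

R2 elements insert at a single, conserved position inside the 28S rRNA gene.
All coordinates in this package are expressed relative to that insertion
point: a *signed offset* of 0 is the boundary between the last upstream 28S
base and the first element base, negative offsets count upstream into the
28S gene (-1 is the last 28S base before the element) and positive offsets
count into the element.  Internally everything is 0-based, half-open.

DNA and RNA inputs are both accepted; sequences are stored canonically as
DNA (U -> T) and the original alphabet is remembered so output can mirror
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")


class SequenceError(ValueError):
    """Raised for malformed nucleotide input (names the offending position)."""


def normalize_sequence(seq: str) -> tuple[str, bool]:
    """Uppercase, map U->T, validate the alphabet.

    Returns ``(canonical_dna, was_rna)``.  Rejects anything outside
    A/C/G/T/U/N with the 0-based position of the first bad character.
    """
    s = seq.upper()
    was_rna = "U" in s
    s = s.replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in _VALID:
            raise SequenceError(f"illegal character {seq[i]!r} at position {i}")
    return s, was_rna


def as_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


@dataclass(frozen=True)
class TargetSiteRef:
    """The 28S rRNA target-site reference around the R2 insertion point.

    ``sequence`` is the top strand, 5'->3', spanning upstream and downstream
    28S around the insertion point.  ``insertion_index`` is the 0-based
    boundary: bases ``[0, insertion_index)`` are upstream of the element.
    """

    id: str
    sequence: str
    insertion_index: int
    was_rna: bool = field(default=False, compare=False)

    @property
    def upstream(self) -> str:
        return self.sequence[: self.insertion_index]

    @property
    def downstream(self) -> str:
        return self.sequence[self.insertion_index :]


def build_target_ref(sequence: str, insertion_index: int, id: str = "ref") -> TargetSiteRef:
    """Validate and build a :class:`TargetSiteRef`.

    T and U are treated as equivalent on input and stored canonically as T.
    """
    seq, was_rna = normalize_sequence(sequence)
    if not 0 <= insertion_index <= len(seq):
        raise ValueError(
            f"insertion_index {insertion_index} out of range [0, {len(seq)}]"
        )
    return TargetSiteRef(id=id, sequence=seq, insertion_index=insertion_index, was_rna=was_rna)


@dataclass(frozen=True)
class ElementRef:
    """Carrier for an element's 5'-terminal sequence (R2, Dong, ...)."""

    id: str
    five_prime_seq: str

    def __post_init__(self) -> None:
        seq, _ = normalize_sequence(self.five_prime_seq)
        if not seq:
            raise SequenceError("element 5' sequence must be non-empty")
        object.__setattr__(self, "five_prime_seq", seq)


def offset_to_abs(ref: TargetSiteRef, off: int) -> int:
    """Signed offset -> absolute index on ``ref.sequence``.

    0 maps to the insertion boundary itself; the result must stay within
    ``[0, len(sequence)]`` (one-past-the-end is a legal bond position).
    """
    pos = ref.insertion_index + off
    if not 0 <= pos <= len(ref.sequence):
        raise ValueError(
            f"offset {off} maps to {pos}, outside [0, {len(ref.sequence)}]"
        )
    return pos


def abs_to_offset(ref: TargetSiteRef, pos: int) -> int:
    """Inverse of :func:`offset_to_abs` (round-trip identity)."""
    if not 0 <= pos <= len(ref.sequence):
        raise ValueError(f"position {pos} outside [0, {len(ref.sequence)}]")
    return pos - ref.insertion_index


def upstream_slice(ref: TargetSiteRef, k: int) -> str:
    """The ``k`` bases immediately 5' of the insertion point, 5'->3'."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > ref.insertion_index:
        raise ValueError(
            f"k={k} exceeds upstream length {ref.insertion_index}"
        )
    return ref.sequence[ref.insertion_index - k : ref.insertion_index]


# --- pairing rules -----------------------------------------------------------

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or G.U wobble (DNA alphabet; N never pairs)."""
    return (a, b) in _PAIRS


def is_gu(a: str, b: str) -> bool:
    return (a, b) in {("G", "T"), ("T", "G")}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# --- FASTA / TSV plumbing ----------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, canonical-DNA sequence)`` pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq, _ = normalize_sequence(str(rec.seq))
        out.append((rec.id, seq))
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                descriptions: dict[str, str] | None = None) -> None:
    recs = []
    for rid, seq in records:
        desc = (descriptions or {}).get(rid, "")
        recs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(recs, str(path), "fasta")


def iter_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    """Junction reads from FASTA or two-column TSV (read_id <tab> sequence)."""
    path = Path(path)
    text_head = path.open().read(1)
    if text_head == ">":
        yield from read_fasta(path)
        return
    with path.open() as fh:
        first = True
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"expected two tab-separated columns in {path}")
            if first and fields[1].lower() in {"sequence", "seq"}:
                first = False
                continue  # header row
            first = False
            seq, _ = normalize_sequence(fields[1])
            yield fields[0], seq
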