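"""Core sequence types and I/O.

Nucleotide reads with phred qualities, transcripts, FASTA/FASTQ reading and
writing, reverse complement, translation and ORF (precursor) extraction.

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("venomxtend")

DNA_ALPHABET = frozenset("ACGTN")
PHRED_OFFSET = 33

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class NucleotideRead:
    """A sequencing read: sequence over {A,C,G,T,N} with per-base phred scores."""

    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.id!r}: negative phred quality")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Transcript:
    """A (possibly partial) transcript sequence.

    ``cds`` is an optional 0-based half-open interval on the forward strand;
    its length must be divisible by 3.  ``class_label`` carries a toxin-class
    tag such as ``CTL`` or ``SVSP`` when known.
    """

    id: str
    sequence: str
    class_label: Optional[str] = None
    cds: Optional[tuple[int, int]] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.cds is not None:
            start, end = self.cds
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"transcript {self.id!r}: cds {self.cds} out of bounds")
            if (end - start) % 3 != 0:
                raise ValueError(f"transcript {self.id!r}: cds length not divisible by 3")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_sequence(self) -> str:
        """The annotated CDS if present, else the full sequence."""
        if self.cds is None:
            return self.sequence
        return self.sequence[self.cds[0]:self.cds[1]]


@dataclass
class OpenReadingFrame:
    """An ATG→stop open reading frame.

    ``start``/``end`` are 0-based half-open on the reported strand (``end``
    includes the stop codon when one terminates the ORF).  ``strand`` is
    ``+`` for the input sequence, ``-`` for its reverse complement; ``frame``
    is the start offset modulo 3 within that strand.
    """

    start: int
    end: int
    frame: int
    protein: str
    strand: str = "+"
    has_stop: bool = True

    @property
    def precursor_length(self) -> int:
        """Precursor length in amino acids (initiator Met through last residue)."""
        return len(self.protein)


# ---------------------------------------------------------------------------
# FASTQ / FASTA I/O
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[NucleotideRead]:
    """Stream phred+33 FASTQ records in file order.

    Raises :class:`ParseError` naming the offending line for malformed 4-line
    records or sequence/quality length mismatches.
    """
    with open(path) as handle:
        lineno = 0
        while True:
            header = handle.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ParseError(f"{path}:{lineno}: expected '@' header, got {header.strip()!r}")
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not qual:
                raise ParseError(f"{path}:{lineno}: truncated record (need 4 lines)")
            lineno += 3
            seq = seq.strip().upper()
            qual = qual.strip()
            if not plus.startswith("+"):
                raise ParseError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}:{lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield NucleotideRead(
                id=header[1:].strip().split()[0] if header[1:].strip() else "",
                sequence=seq,
                qualities=[ord(c) - PHRED_OFFSET for c in qual],
            )


def write_fastq(reads: Iterable[NucleotideRead], path: str | Path) -> None:
    """Write phred+33 FASTQ."""
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(chr(min(q, 93) + PHRED_OFFSET) for q in read.qualities)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read FASTA transcripts (wrapped or unwrapped lines).

    Duplicate ids are kept but disambiguated with ``.2``, ``.3``, ... suffixes
    (a warning is logged).  Description lines may carry ``class=<TAG>``,
    ``toxin=<0|1>`` and ``cds=<start>-<end>`` key=value tags, parsed into
    ``class_label``/``cds`` (toxin flags are read back via
    :func:`parse_fasta_flags`).
    """
    transcripts: list[Transcript] = []
    seen: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        rid = record.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}.{seen[rid]}"
            logger.warning("duplicate FASTA id %r kept as %r", rid, new_id)
            rid = new_id
        else:
            seen[rid] = 1
        class_label = None
        cds = None
        for token in record.description.split()[1:]:
            if token.startswith("class="):
                class_label = token[6:]
            elif token.startswith("cds="):
                a, _, b = token[4:].partition("-")
                cds = (int(a), int(b))
        transcripts.append(
            Transcript(
                id=rid,
                sequence=str(record.seq).upper(),
                class_label=class_label,
                cds=cds,
                description=record.description,
            )
        )
    return transcripts


def parse_fasta_flags(transcripts: Sequence[Transcript]) -> dict[str, bool]:
    """Extract ``toxin=`` flags from transcript description lines (default False)."""
    flags = {}
    for t in transcripts:
        flags[t.id] = any(tok in ("toxin=1", "toxin=true") for tok in t.description.split())
    return flags


def write_fasta(
    transcripts: Iterable[Transcript],
    path: str | Path,
    width: int = 70,
    extra_tags: Optional[dict[str, str]] = None,
) -> None:
    """Write FASTA with line-wrapped sequences, preserving tag annotations.

    ``extra_tags`` maps transcript id to an extra description token (e.g.
    ``"toxin=1"``).
    """
    records = []
    for t in transcripts:
        desc_parts = []
        if t.class_label is not None:
            desc_parts.append(f"class={t.class_label}")
        if t.cds is not None:
            desc_parts.append(f"cds={t.cds[0]}-{t.cds[1]}")
        if extra_tags and t.id in extra_tags:
            desc_parts.append(extra_tags[t.id])
        records.append(SeqRecord(Seq(t.sequence), id=t.id, description=" ".join(desc_parts)))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Sequence operations
# ---------------------------------------------------------------------------

def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution (N ↔ N)."""
    invalid = set(sequence) - DNA_ALPHABET
    if invalid:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(invalid)}")
    return sequence.translate(_COMPLEMENT)[::-1]


def translate(cds_sequence: str, warn_internal_stop: bool = True) -> str:
    """Translate a CDS with the standard genetic code.

    A trailing stop codon yields no residue; an internal stop truncates the
    translation (logged unless ``warn_internal_stop`` is False).  Codons
    containing N translate to ``X``.
    """
    if len(cds_sequence) % 3 != 0:
        raise ValueError(f"CDS length {len(cds_sequence)} not divisible by 3")
    protein = str(Seq(cds_sequence).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        if warn_internal_stop:
            logger.warning("internal stop codon: translation truncated")
        protein = protein.split("*")[0]
    return protein


_STOPS = ("TAA", "TAG", "TGA")


def _scan_orfs(sequence: str, min_length_aa: int) -> list[OpenReadingFrame]:
    """All maximal ATG→stop ORFs in the three forward frames of ``sequence``."""
    orfs: list[OpenReadingFrame] = []
    n = len(sequence)
    for frame in range(3):
        start: Optional[int] = None
        for pos in range(frame, n - 2, 3):
            codon = sequence[pos:pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                end = pos + 3
                protein = translate(sequence[start:end], warn_internal_stop=False)
                if len(protein) >= min_length_aa:
                    orfs.append(OpenReadingFrame(start, end, frame, protein, has_stop=True))
                start = None
        if start is not None:
            # runs off the 3' end without a stop codon
            end = start + 3 * ((n - start) // 3)
            protein = translate(sequence[start:end], warn_internal_stop=False)
            if len(protein) >= min_length_aa:
                orfs.append(OpenReadingFrame(start, end, frame, protein, has_stop=False))
    return orfs


def longest_orf(
    transcript: Transcript | str,
    search_reverse: bool = False,
    min_length_aa: int = 30,
) -> Optional[OpenReadingFrame]:
    """Longest ATG→stop ORF across three (or six) frames.

    Returns None when no ORF reaches ``min_length_aa`` residues.  Ties are
    broken by forward strand first, then smallest start coordinate, then
    lowest frame index.  Reverse-strand coordinates refer to the reverse
    complement of the input.
    """
    sequence = transcript.sequence if isinstance(transcript, Transcript) else transcript
    if not sequence:
        raise ValueError("empty transcript")
    candidates = _scan_orfs(sequence, min_length_aa)
    if search_reverse:
        for orf in _scan_orfs(reverse_complement(sequence), min_length_aa):
            orf.strand = "-"
            candidates.append(orf)
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda o: (-len(o.protein), o.strand != "+", o.start, o.frame),
    )
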