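"""Reference sequence I/O and synthetic genome generation.

Genomes are held in memory as plain uppercase strings over {A, C, G, T, N}.
IUPAC ambiguity codes other than N carry no information for the simulator or
the built-in mapper, so they are collapsed to N on input (with a warning).
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord as _BioRecord

log = logging.getLogger(__name__)

_ALPHABET = b"ACGTN"
# translate: lowercase -> uppercase, anything outside ACGTN -> N
_NORMALIZE = bytearray(ord("N") for _ in range(256))
for _b in _ALPHABET:
    _NORMALIZE[_b] = _b
    _NORMALIZE[_b + 32] = _b  # lowercase
_NORMALIZE = bytes(_NORMALIZE)

_DELETE_VALID = bytes(_ALPHABET)


class FastaFormatError(ValueError):
    """Raised for missing, empty, or non-FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence over the alphabet {A, C, G, T, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.sequence.encode("ascii").translate(None, _DELETE_VALID):
            raise ValueError(
                f"sequence {self.id!r} contains characters outside ACGTN; "
                "normalize input with read_fasta() or normalize_sequence()"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """Ordered collection of contigs with unique ids."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate contig ids: {dupes}")
        self._by_id = {r.id: r for r in self.records}

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._by_id

    def get(self, contig_id: str) -> SequenceRecord:
        return self._by_id[contig_id]


def normalize_sequence(raw: str) -> str:
    """Uppercase and collapse non-ACGTN characters to N."""
    data = raw.encode("ascii", errors="replace")
    cleaned = data.translate(_NORMALIZE)
    upper = data.upper()
    if cleaned != upper:
        n_changed = int(
            np.count_nonzero(
                np.frombuffer(upper, dtype=np.uint8) != np.frombuffer(cleaned, dtype=np.uint8)
            )
        )
        log.warning("mapped %d ambiguity/invalid characters to N", n_changed)
    return cleaned.decode("ascii")


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> Genome:
    """Load a (optionally gzipped) FASTA file into a :class:`Genome`.

    Record order is preserved, sequences are uppercased, ambiguity codes
    other than N become N, and ids are truncated at the first whitespace.
    """
    path = Path(path)
    if not path.exists():
        raise FastaFormatError(f"no such file: {path}")
    records: list[SequenceRecord] = []
    try:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                records.append(SequenceRecord(rec.id, normalize_sequence(str(rec.seq))))
    except ValueError as exc:  # Biopython signals malformed FASTA this way
        raise FastaFormatError(f"not valid FASTA: {path}: {exc}") from exc
    if not records:
        raise FastaFormatError(f"empty or non-FASTA file: {path}")
    return Genome(records)


def write_fasta(genome: Genome, path: str | Path, line_width: int = 60) -> Path:
    """Write ``genome`` as multi-line FASTA wrapped at ``line_width`` columns."""
    if line_width < 1:
        raise ValueError(f"line_width must be positive, got {line_width}")
    if not genome.records:
        raise ValueError("refusing to write an empty genome")
    path = Path(path)
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=line_width)
        writer.write_file(
            _BioRecord(Seq(r.sequence), id=r.id, description="") for r in genome.records
        )
    return path


def generate_synthetic_genome(
    length: int,
    n_contigs: int = 1,
    gc_fraction: float = 0.5,
    seed: int = 0,
) -> Genome:
    """Generate a random genome with i.i.d. bases at a given GC content.

    ``length`` is split as evenly as possible across ``n_contigs``; each base
    is drawn independently with P(G) = P(C) = ``gc_fraction`` / 2. Identical
    seeds yield identical genomes.
    """
    if n_contigs < 1 or length < n_contigs:
        raise ValueError(f"need length >= n_contigs >= 1, got {length}, {n_contigs}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    cum = np.cumsum([at, gc, gc, at])
    cum[-1] = 1.0  # guard against round-off
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def draw(n: int) -> str:
        chunks = []
        chunk = 1 << 24
        for off in range(0, n, chunk):
            m = min(chunk, n - off)
            idx = np.searchsorted(cum, rng.random(m), side="right")
            chunks.append(bases[idx].tobytes())
        return b"".join(chunks).decode("ascii")

    base_len, extra = divmod(length, n_contigs)
    records = []
    for i in range(n_contigs):
        clen = base_len + (1 if i < extra else 0)
        records.append(SequenceRecord(f"contig{i + 1}", draw(clen)))
    return Genome(records)
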