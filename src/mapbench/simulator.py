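"""Read simulation with a truth table, gold-standard import, and read subsampling.

The simulator mutates the artificial chromosome once (a haploid sample:
SNPs, short insertions and deletions at configurable per-base rates) and
then draws reads from the mutated sequence, applying uniform per-base
substitution sequencing errors on top. Every read's leftmost base is lifted
through the mutation map back to artificial coordinates and then through
the region map back to reference coordinates, giving the gold-standard
(contig, position, strand) against which mappers are scored.

Truth is authoritative in a sidecar TSV keyed by (read id, mate); read
names additionally mirror it in the grammar
``sim:<serial>|<contig>|<pos 1-based>|<F/R>|<mate>`` as a convenience.
"""
from __future__ import annotations

import logging
import math
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .genome_io import SequenceRecord
from .subsampler import IN_PADDING, RegionMap, lift_to_reference

log = logging.getLogger(__name__)

FORWARD = "F"
REVERSE = "R"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


class GoldStandardError(ValueError):
    """Problem importing an external gold standard (FASTQ + SAM)."""


@dataclass(frozen=True)
class SimulationProfile:
    """Mutation, error, and library parameters for one simulated dataset.

    Rates are per-base probabilities. ``coverage`` is fold coverage of the
    *sampled* sequence: reads = round(coverage x sampled bp / read length).
    """

    read_length: int
    snp_rate: float = 0.0
    indel_rate: float = 0.0
    insertion_fraction: float = 0.5
    max_indel_length: int = 10
    error_rate: float = 0.0
    paired: bool = False
    insert_mean: int | None = None
    insert_sd: float = 0.0
    coverage: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "insertion_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.max_indel_length < 1:
            raise ValueError("max_indel_length must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.paired:
            if self.insert_mean is None or self.insert_mean < 2 * self.read_length:
                raise ValueError("paired mode needs insert_mean >= 2 x read_length")

    @property
    def quality_phred(self) -> int:
        """Constant per-base quality implied by the error rate (capped at 41)."""
        if self.error_rate <= 0.0:
            return 41
        return min(41, int(round(-10.0 * math.log10(self.error_rate))))


@dataclass(frozen=True)
class MutationEvent:
    position: int  # 0-based position on the original sequence
    kind: str  # "SNP" | "insertion" | "deletion"
    ref: str
    alt: str


@dataclass
class MutationMap:
    """Applied mutation events plus an exact mutated->original liftover.

    The liftover is piecewise linear: ``segments`` lists (mutated start,
    original start, length) blocks that correspond base-for-base. Mutated
    positions inside an insertion have no original image; they lift to the
    nearest preceding original position.
    """

    events: list[MutationEvent]
    segments: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        self._mut_starts = [s[0] for s in self.segments]

    def lift(self, mutated_pos: int) -> int:
        idx = bisect_right(self._mut_starts, mutated_pos) - 1
        if idx < 0:  # inside an insertion before the first matched base
            return self.segments[0][1]
        mut_start, orig_start, length = self.segments[idx]
        if mutated_pos < mut_start + length:
            return orig_start + (mutated_pos - mut_start)
        return orig_start + length - 1  # inside an insertion: preceding original base


def mutate_sequence(
    seq: SequenceRecord,
    profile: SimulationProfile,
    rng: np.random.Generator,
) -> tuple[SequenceRecord, MutationMap]:
    """Apply SNPs and indels to ``seq`` and return the mutated copy with its map.

    Each non-N base mutates to one of the three other bases with probability
    ``snp_rate``; indel events start at a non-N base with probability
    ``indel_rate``, are insertions with probability ``insertion_fraction``
    (else deletions), and have lengths uniform on [1, max_indel_length].
    Deletions are truncated so they never swallow N bases; N positions are
    never mutated.
    """
    orig = np.frombuffer(seq.sequence.encode("ascii"), dtype=np.uint8)
    n = orig.size
    mut = orig.copy()
    non_n = orig != _N
    n_positions = np.flatnonzero(~non_n)

    snp_pos = np.empty(0, dtype=np.int64)
    if profile.snp_rate > 0.0:
        snp_pos = np.flatnonzero((rng.random(n) < profile.snp_rate) & non_n)
        base_idx = _BASE_INDEX[orig[snp_pos]]
        alt_idx = (base_idx + rng.integers(1, 4, size=snp_pos.size)) % 4
        mut[snp_pos] = _BASES[alt_idx]

    indel_pos = np.empty(0, dtype=np.int64)
    indel_is_ins = np.empty(0, dtype=bool)
    indel_len = np.empty(0, dtype=np.int64)
    if profile.indel_rate > 0.0:
        indel_pos = np.flatnonzero((rng.random(n) < profile.indel_rate) & non_n)
        indel_is_ins = rng.random(indel_pos.size) < profile.insertion_fraction
        indel_len = rng.integers(1, profile.max_indel_length + 1, size=indel_pos.size)

    # merge: (pos, order) with indels applied at their position before SNP bookkeeping
    candidates: list[tuple[int, int, int]] = []  # (pos, kind_code, idx) kind: 0 indel, 1 snp
    for i, p in enumerate(indel_pos):
        candidates.append((int(p), 0, i))
    for i, p in enumerate(snp_pos):
        candidates.append((int(p), 1, i))
    candidates.sort()

    events: list[MutationEvent] = []
    pieces: list[np.ndarray] = []
    segments: list[tuple[int, int, int]] = []
    cur = 0  # cursor on the original sequence
    mut_len = 0

    def flush(upto: int) -> None:
        nonlocal cur, mut_len
        if upto > cur:
            pieces.append(mut[cur:upto])
            segments.append((mut_len, cur, upto - cur))
            mut_len += upto - cur
            cur = upto

    for pos, kind_code, i in candidates:
        if pos < cur:  # swallowed by a preceding deletion
            continue
        if kind_code == 1:  # SNP: 1:1, already applied to `mut`
            events.append(MutationEvent(pos, "SNP", chr(orig[pos]), chr(mut[pos])))
            continue
        flush(pos)
        length = int(indel_len[i])
        if indel_is_ins[i]:
            ins = _BASES[rng.integers(0, 4, size=length)]
            pieces.append(ins)
            mut_len += length
            events.append(
                MutationEvent(pos, "insertion", "", ins.tobytes().decode("ascii"))
            )
        else:
            j = bisect_right(n_positions, pos - 1)
            next_n = int(n_positions[j]) if j < n_positions.size else n
            length = min(length, next_n - pos, n - pos)
            if length <= 0:
                continue
            events.append(
                MutationEvent(pos, "deletion", orig[pos:pos + length].tobytes().decode("ascii"), "")
            )
            cur = pos + length
    flush(n)

    if not segments:  # everything deleted (degenerate); keep an empty anchor
        segments = [(0, 0, 0)]
    mutated = b"".join(p.tobytes() for p in pieces).decode("ascii")
    record = SequenceRecord(seq.id, mutated) if mutated else seq
    return record, MutationMap(events, segments)


def determine_read_count(sampled_length: int, profile: SimulationProfile) -> int:
    """Reads needed for the configured fold coverage of the sampled sequence."""
    if sampled_length < profile.read_length:
        raise ValueError("sampled_length must be >= read_length")
    count = int(round(profile.coverage * sampled_length / profile.read_length))
    if profile.paired and count % 2:
        count -= 1
    return count


@dataclass(frozen=True)
class ReadTruth:
    """Gold-standard origin of one simulated read (or one mate)."""

    read_id: str
    contig: str
    true_pos: int  # leftmost 0-based reference coordinate of the read's span
    strand: str  # FORWARD | REVERSE
    mate: int = 0  # 0 = unpaired, 1/2 = mate index


class TruthTable:
    """Association (read_id, mate) -> :class:`ReadTruth`."""

    def __init__(self) -> None:
        self._entries: dict[tuple[str, int], ReadTruth] = {}

    def add(self, truth: ReadTruth) -> None:
        key = (truth.read_id, truth.mate)
        if key in self._entries:
            raise ValueError(f"duplicate truth entry for {key}")
        self._entries[key] = truth

    def get(self, read_id: str, mate: int = 0) -> ReadTruth | None:
        hit = self._entries.get((read_id, mate))
        if hit is None and mate == 0:
            # mapper ran mates single-end: accept a unique mate-specific entry
            hit = self._entries.get((read_id, 1)) or self._entries.get((read_id, 2))
        return hit

    def items(self):
        return self._entries.items()

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def count(self) -> int:
        return len(self._entries)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("read_id\tmate\tcontig\tpos0\tstrand\n")
            for truth in self._entries.values():
                fh.write(
                    f"{truth.read_id}\t{truth.mate}\t{truth.contig}"
                    f"\t{truth.true_pos}\t{truth.strand}\n"
                )
        return path

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("read_id\t"):
                raise ValueError(f"not a truth TSV: {path}")
            for line in fh:
                read_id, mate, contig, pos0, strand = line.rstrip("\n").split("\t")
                table.add(ReadTruth(read_id, contig, int(pos0), strand, int(mate)))
        return table


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    sequence: str
    quality: str
    mate: int = 0


_NAME_RE = re.compile(r"^sim:(\d+)\|(.+)\|(\d+)\|([FR])\|(\d+)$")


def encode_truth_name(serial: int, contig: str, pos0: int, strand: str, mate: int) -> str:
    return f"sim:{serial}|{contig}|{pos0 + 1}|{strand}|{mate}"


def decode_truth_name(read_id: str) -> ReadTruth | None:
    """Recover truth fields from a simulated read name; None if unparseable."""
    m = _NAME_RE.match(read_id)
    if m is None:
        return None
    _, contig, pos1, strand, mate = m.groups()
    return ReadTruth(read_id, contig, int(pos1) - 1, strand, int(mate))


def _apply_errors(seq: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0.0:
        return seq
    hit = np.flatnonzero(rng.random(seq.size) < error_rate)
    if hit.size:
        seq = seq.copy()
        idx = _BASE_INDEX[seq[hit]]
        seq[hit] = _BASES[(idx + rng.integers(1, 4, size=hit.size)) % 4]
    return seq


def simulate_reads(
    artificial: SequenceRecord,
    region_map: RegionMap,
    profile: SimulationProfile,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[SimulatedRead], TruthTable]:
    """Simulate reads from the (mutated) artificial chromosome with known truth.

    Read starts are uniform over the mutated artificial sequence; draws whose
    span would touch an N (i.e. the inter-region padding, which is at least
    2x the read length / insert size wide) are redrawn, so no read bridges
    two regions. Strand is uniform. Paired mode emits FR-oriented mates with
    insert length ~ Normal(insert_mean, insert_sd) truncated to >= 2x read
    length. Base qualities are the constant Phred score implied by
    ``error_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)

    mutated, mmap = mutate_sequence(artificial, profile, rng)
    mseq = np.frombuffer(mutated.sequence.encode("ascii"), dtype=np.uint8)
    rl = profile.read_length
    if mseq.size < rl:
        raise ValueError("mutated artificial chromosome shorter than one read")

    sampled_length = region_map.sampled_length
    total = determine_read_count(sampled_length, profile)
    qual = chr(profile.quality_phred + 33) * rl

    reads: list[SimulatedRead] = []
    truth = TruthTable()
    max_attempts = 10_000

    def lift(mut_pos: int):
        return lift_to_reference(region_map, mmap.lift(mut_pos))

    def make_read(serial: int, span_start: int, is_reverse: bool, mate: int) -> SimulatedRead:
        window = mseq[span_start:span_start + rl]
        where = lift(span_start)
        assert where is not IN_PADDING
        contig, refpos = where
        strand = REVERSE if is_reverse else FORWARD
        if is_reverse:
            window = window[::-1]
            window = np.frombuffer(
                window.tobytes().translate(_COMPLEMENT), dtype=np.uint8
            )
        window = _apply_errors(window, profile.error_rate, rng)
        read_id = encode_truth_name(serial, contig, refpos, strand, mate)
        truth.add(ReadTruth(read_id, contig, refpos, strand, mate))
        return SimulatedRead(read_id, window.tobytes().decode("ascii"), qual, mate)

    if not profile.paired:
        for serial in range(total):
            for _ in range(max_attempts):
                start = int(rng.integers(0, mseq.size - rl + 1))
                span = mseq[start:start + rl]
                if not (span == _N).any() and lift(start) is not IN_PADDING:
                    break
            else:
                raise RuntimeError("could not place a read clear of padding/N runs")
            reads.append(make_read(serial, start, bool(rng.random() < 0.5), 0))
    else:
        for serial in range(total // 2):
            for _ in range(max_attempts):
                frag = max(2 * rl, int(round(rng.normal(profile.insert_mean, profile.insert_sd))))
                if frag > mseq.size:
                    continue
                start = int(rng.integers(0, mseq.size - frag + 1))
                span = mseq[start:start + frag]
                if ((span == _N).any()
                        or lift(start) is IN_PADDING
                        or lift(start + frag - rl) is IN_PADDING):
                    continue
                break
            else:
                raise RuntimeError("could not place a fragment clear of padding/N runs")
            flip = bool(rng.random() < 0.5)
            left, right = start, start + frag - rl
            if not flip:
                reads.append(make_read(serial, left, False, 1))
                reads.append(make_read(serial, right, True, 2))
            else:
                reads.append(make_read(serial, right, True, 1))
                reads.append(make_read(serial, left, False, 2))

    return reads, truth


def write_fastq(reads: Sequence[SimulatedRead], out_prefix: str | Path) -> list[Path]:
    """Write reads as Phred+33 FASTQ: ``<prefix>.fastq`` or ``<prefix>_1/_2.fastq``."""
    out_prefix = Path(out_prefix)
    paired = any(r.mate in (1, 2) for r in reads)
    if not paired:
        path = out_prefix.with_suffix(".fastq")
        with open(path, "w") as fh:
            for r in reads:
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
        return [path]
    paths = [Path(f"{out_prefix}_1.fastq"), Path(f"{out_prefix}_2.fastq")]
    with open(paths[0], "w") as fh1, open(paths[1], "w") as fh2:
        for r in reads:
            fh = fh1 if r.mate == 1 else fh2
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
    return paths


def _fastq_records(path: str | Path):
    return list(SeqIO.parse(str(path), "fastq"))


def import_gold_standard(
    fastq_paths: Sequence[str | Path],
    gold_sam: str | Path,
) -> TruthTable:
    """Build a truth table from user-simulated reads plus their gold SAM.

    The SAM provides contig, leftmost position (converted to 0-based) and
    strand; mate index comes from the pairing flags. Every FASTQ read id
    must appear in the SAM, and gold records must be mapped.
    """
    import pysam

    truth = TruthTable()
    with pysam.AlignmentFile(str(gold_sam), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_unmapped:
                raise GoldStandardError(
                    f"gold-standard record {aln.query_name!r} is unmapped"
                )
            mate = 1 if aln.is_read1 else 2 if aln.is_read2 else 0
            truth.add(ReadTruth(
                aln.query_name,
                aln.reference_name,
                aln.reference_start,
                REVERSE if aln.is_reverse else FORWARD,
                mate,
            ))

    missing: list[str] = []
    for file_idx, path in enumerate(fastq_paths):
        mate = 0 if len(fastq_paths) == 1 else file_idx + 1
        for rec in _fastq_records(path):
            if truth.get(rec.id, mate) is None:
                missing.append(rec.id)
    if missing:
        shown = ", ".join(missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise GoldStandardError(
            f"{len(missing)} FASTQ reads absent from the gold SAM: {shown}{more}"
        )
    return truth


def subsample_reads(
    fastq_paths: Sequence[str | Path],
    n: int,
    seed: int,
    out_paths: Sequence[str | Path],
) -> list[Path]:
    """Uniformly subsample min(n, available) reads without replacement.

    For paired input (two files), mates are kept together: the same record
    indices are taken from both files.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(fastq_paths) != len(out_paths):
        raise ValueError("need one output path per input file")
    rng = np.random.default_rng(seed)
    record_sets = [_fastq_records(p) for p in fastq_paths]
    counts = {len(rs) for rs in record_sets}
    if len(counts) != 1:
        raise ValueError(f"paired FASTQ files differ in read count: {sorted(counts)}")
    available = counts.pop()
    k = min(n, available)
    idx = np.sort(rng.choice(available, size=k, replace=False))
    written: list[Path] = []
    for records, out in zip(record_sets, out_paths):
        out = Path(out)
        with open(out, "w") as fh:
            for i in idx:
                rec = records[int(i)]
                quals = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{quals}\n")
        written.append(out)
    return written
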