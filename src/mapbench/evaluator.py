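"""Alignment correctness evaluation: the C/W/N trichotomy and summary statistics.

Each truth read is scored against its primary alignment only. A read is
*not mapped* if absent, flagged unmapped, or its mapping quality is below
the configured threshold; otherwise it is *correct* iff it is on the truth
contig, on the truth strand, and its reported leftmost position is within
X bp of the true position (X defaults to 50% of the read length); anything
else is *wrong*. From the tallies C, W, N the summary statistics are

    precision  P = C / (C + W)
    recall     R = C / (C + N)
    F-measure  F = 2PR / (P + R)

plus correctly-mapped-reads-per-second and percent mapped. Note the recall
denominator excludes wrongly mapped reads — this is the benchmark's
definition, and whenever W > 0 it exceeds the conventional C/total, which
is therefore reported alongside as ``recall_conventional``.

For genuine reads (no truth) only the overall percentage of mapped reads is
computed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pysam

from .simulator import FORWARD, REVERSE, ReadTruth, TruthTable

log = logging.getLogger(__name__)

CORRECT = "correct"
WRONG = "wrong"
NOT_MAPPED = "not_mapped"


class EvaluationError(ValueError):
    """Malformed or internally inconsistent alignment input."""


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation thresholds.

    The positional tolerance is X = floor(tolerance_fraction x read_length);
    "within X bp" is inclusive. A mapped read passes the quality check iff
    mapq >= mapq_threshold, so the default threshold of 0 excludes nothing.
    """

    read_length: int
    mapq_threshold: int = 0
    tolerance_fraction: float = 0.5
    strip_chr_prefix: bool = False

    def __post_init__(self) -> None:
        if self.mapq_threshold < 0:
            raise ValueError("mapq_threshold must be >= 0")
        if not 0.0 <= self.tolerance_fraction <= 1.0:
            raise ValueError("tolerance_fraction must be in [0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")

    @property
    def tolerance_bp(self) -> int:
        return math.floor(self.tolerance_fraction * self.read_length)


@dataclass(frozen=True)
class AlignmentObservation:
    """The evaluated subset of one primary SAM record."""

    read_id: str
    mate: int
    is_mapped: bool
    contig: str | None = None
    leftmost_pos: int | None = None
    strand: str | None = None
    mapq: int = 0


@dataclass(frozen=True)
class EvalCounts:
    correct: int
    wrong: int
    not_mapped: int

    @property
    def total(self) -> int:
        return self.correct + self.wrong + self.not_mapped

    @property
    def mapped(self) -> int:
        return self.correct + self.wrong


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f_measure: float
    correct_per_second: float | None
    percent_mapped: float
    recall_conventional: float


def load_alignments(
    sam_path: str | Path,
) -> dict[tuple[str, int], AlignmentObservation]:
    """Extract primary alignments from a SAM file, keyed by (read id, mate).

    Secondary (0x100) and supplementary (0x800) records are dropped; the
    unmapped flag (0x4) yields is_mapped = False; POS is converted to
    0-based; strand comes from flag 0x10 and mate from 0x40/0x80.
    """
    observations: dict[tuple[str, int], AlignmentObservation] = {}
    try:
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
            for aln in sam:
                if aln.is_secondary or aln.is_supplementary:
                    continue
                mate = 1 if aln.is_read1 else 2 if aln.is_read2 else 0
                key = (aln.query_name, mate)
                if key in observations:
                    raise EvaluationError(
                        f"duplicate primary records for read {aln.query_name!r} "
                        f"(mate {mate}) in {sam_path}"
                    )
                if aln.is_unmapped:
                    observations[key] = AlignmentObservation(
                        aln.query_name, mate, is_mapped=False,
                        mapq=aln.mapping_quality,
                    )
                else:
                    observations[key] = AlignmentObservation(
                        aln.query_name, mate, is_mapped=True,
                        contig=aln.reference_name,
                        leftmost_pos=aln.reference_start,
                        strand=REVERSE if aln.is_reverse else FORWARD,
                        mapq=aln.mapping_quality,
                    )
    except ValueError as exc:
        if isinstance(exc, EvaluationError):
            raise
        raise EvaluationError(f"malformed SAM {sam_path}: {exc}") from exc
    return observations


def _contig_eq(a: str, b: str, config: EvalConfig) -> bool:
    if config.strip_chr_prefix:
        a = a[3:] if a.startswith("chr") else a
        b = b[3:] if b.startswith("chr") else b
    return a == b


def classify_read(
    obs: AlignmentObservation | None,
    truth: ReadTruth,
    config: EvalConfig,
) -> str:
    """Classify one truth read as correct / wrong / not_mapped."""
    if obs is None or not obs.is_mapped:
        return NOT_MAPPED
    if obs.mapq < config.mapq_threshold:
        return NOT_MAPPED
    if (
        _contig_eq(obs.contig, truth.contig, config)
        and obs.strand == truth.strand
        and abs(obs.leftmost_pos - truth.true_pos) <= config.tolerance_bp
    ):
        return CORRECT
    return WRONG


def aggregate(classifications: Sequence[str]) -> EvalCounts:
    c = w = n = 0
    for cls in classifications:
        if cls == CORRECT:
            c += 1
        elif cls == WRONG:
            w += 1
        elif cls == NOT_MAPPED:
            n += 1
        else:
            raise ValueError(f"unknown classification {cls!r}")
    return EvalCounts(c, w, n)


def evaluate(
    observations: Mapping[tuple[str, int], AlignmentObservation],
    truth: TruthTable,
    config: EvalConfig,
) -> EvalCounts:
    """Classify every truth read against its primary alignment and tally.

    Truth entries with mate 1/2 whose mapper ran the mates single-end (no
    pairing flags in the SAM) fall back to the mate-0 observation key.
    """
    classifications = []
    for (read_id, mate), t in truth.items():
        obs = observations.get((read_id, mate))
        if obs is None and mate in (1, 2):
            obs = observations.get((read_id, 0))
        classifications.append(classify_read(obs, t, config))
    return aggregate(classifications)


def _ratio(num: int, den: int) -> float:
    if den == 0:
        log.debug("0/0 ratio defined as 0")
        return 0.0
    return num / den


def compute_metrics(counts: EvalCounts, mapping_wall_time: float | None = None) -> Metrics:
    """The six summary statistics from one C/W/N tally.

    ``correct_per_second`` is None when no (positive) wall time is supplied.
    """
    c, w, n = counts.correct, counts.wrong, counts.not_mapped
    precision = _ratio(c, c + w)
    recall = _ratio(c, c + n)
    f_measure = 0.0 if precision + recall == 0 else (
        2 * precision * recall / (precision + recall)
    )
    cps = None
    if mapping_wall_time is not None and mapping_wall_time > 0:
        cps = c / mapping_wall_time
    percent_mapped = 100.0 * _ratio(c + w, counts.total)
    recall_conventional = _ratio(c, counts.total)
    return Metrics(precision, recall, f_measure, cps, percent_mapped, recall_conventional)


def evaluate_real(
    observations: Mapping[tuple[str, int], AlignmentObservation],
    total_reads: int,
    config: EvalConfig,
) -> float:
    """Percent of reads mapped at/above the mapq threshold, out of all input reads.

    The denominator is the FASTQ read count, so reads absent from the SAM
    count as unmapped.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    mapped = sum(
        1 for obs in observations.values()
        if obs.is_mapped and obs.mapq >= config.mapq_threshold
    )
    return 100.0 * mapped / total_reads


def threshold_sweep(
    observations: Mapping[tuple[str, int], AlignmentObservation],
    truth: TruthTable,
    config: EvalConfig,
    thresholds: Sequence[int],
) -> list[tuple[int, EvalCounts, Metrics]]:
    """Re-evaluate the same observations at each mapq threshold."""
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    rows = []
    for thr in thresholds:
        counts = evaluate(observations, truth, replace(config, mapq_threshold=thr))
        rows.append((thr, counts, compute_metrics(counts)))
    return rows
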