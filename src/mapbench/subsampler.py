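"""Tiered genome subsampling and artificial-chromosome construction.

Benchmarking a mapper on a full mammalian genome is slow; mapping behaviour
can instead be estimated from reads simulated off randomly sampled regions.
The sampling budget depends on genome size: 50% of genomes below 100 Mb,
25% below 500 Mb, 1% otherwise, with a global floor of 15 Mb so small
genomes still give a robust measurement. Each region is 10x the average
read length (or insert size for paired-end libraries). Sampled regions are
concatenated into a single artificial chromosome, separated by N runs of
2x the read length / insert size so that no simulated read can bridge two
regions. Reads are later mapped back to the *full* reference, so the
:class:`RegionMap` records where each region sits in the artificial
chromosome and supports lifting artificial coordinates back to reference
coordinates.

All coordinates are 0-based half-open; conversion to SAM's 1-based
convention happens only at SAM boundaries.
"""
from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import Genome, SequenceRecord

log = logging.getLogger(__name__)

MB = 1_000_000

#: (genome-size upper bound in bp, sampled fraction); bounds are strict "<".
DEFAULT_TIERS: tuple[tuple[int | None, float], ...] = (
    (100 * MB, 0.50),
    (500 * MB, 0.25),
    (None, 0.01),
)


class ConfigurationError(ValueError):
    """Invalid sampling configuration for the given genome."""


class SamplingError(RuntimeError):
    """The sampling target could not be reached (fragmented or N-rich genome)."""


@dataclass(frozen=True)
class SamplingConfig:
    """Parameters of the subsampling stage.

    ``region_factor`` and ``pad_factor`` multiply the read length, or the
    insert size when ``insert_size`` is set (paired-end).
    """

    read_length: int
    insert_size: int | None = None
    region_factor: int = 10
    pad_factor: int = 2
    tier_table: tuple[tuple[int | None, float], ...] = DEFAULT_TIERS
    min_total: int = 15 * MB
    max_n_fraction: float = 0.10
    max_rejections: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ConfigurationError("read_length must be >= 1")
        if self.region_factor < 1 or self.pad_factor < 1:
            raise ConfigurationError("region_factor and pad_factor must be >= 1")
        if self.insert_size is not None and self.insert_size < self.read_length:
            raise ConfigurationError("insert_size must be >= read_length")
        bounds = [b for b, _ in self.tier_table if b is not None]
        if bounds != sorted(set(bounds)):
            raise ConfigurationError("tier bounds must be strictly increasing")
        for _, frac in self.tier_table:
            if not 0.0 < frac <= 1.0:
                raise ConfigurationError("tier fractions must lie in (0, 1]")

    @property
    def unit_length(self) -> int:
        """Read length, or insert size for paired-end libraries."""
        return self.insert_size if self.insert_size is not None else self.read_length

    @property
    def region_length(self) -> int:
        return self.region_factor * self.unit_length

    @property
    def pad_length(self) -> int:
        return self.pad_factor * self.unit_length


@dataclass(frozen=True)
class Region:
    """Half-open interval [start, end) on one reference contig."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid region {self.contig_id}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


class _InPadding:
    """Sentinel for artificial positions that fall inside an N separator."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "IN_PADDING"


IN_PADDING = _InPadding()


@dataclass
class RegionMap:
    """Ordered (Region, artificial offset) pairs plus the artificial length."""

    entries: list[tuple[Region, int]]
    artificial_length: int

    def __post_init__(self) -> None:
        offsets = [o for _, o in self.entries]
        if offsets != sorted(offsets):
            raise ValueError("region-map entries must be sorted by artificial offset")
        self._offsets = offsets

    @property
    def sampled_length(self) -> int:
        return sum(len(r) for r, _ in self.entries)

    def lift(self, artificial_pos: int):
        return lift_to_reference(self, artificial_pos)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# columns: contig, start, end, artificial_offset "
                     "(0-based half-open reference coordinates)\n")
            fh.write("contig\tstart\tend\tartificial_offset\n")
            for region, off in self.entries:
                fh.write(f"{region.contig_id}\t{region.start}\t{region.end}\t{off}\n")
        return path

    @classmethod
    def read_tsv(cls, path: str | Path, artificial_length: int | None = None) -> "RegionMap":
        entries: list[tuple[Region, int]] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("contig\t"):
                    continue
                contig, start, end, off = line.rstrip("\n").split("\t")
                entries.append((Region(contig, int(start), int(end)), int(off)))
        if artificial_length is None:
            last_region, last_off = entries[-1]
            artificial_length = last_off + len(last_region)
        return cls(entries, artificial_length)


def tier_fraction(genome_length: int,
                  tiers: Sequence[tuple[int | None, float]] = DEFAULT_TIERS) -> float:
    """Sampling fraction for a genome of the given size (strict upper bounds)."""
    for bound, frac in tiers:
        if bound is None or genome_length < bound:
            return frac
    raise AssertionError("tier table must end with an unbounded tier")


def compute_sampling_target(genome_length: int, config: SamplingConfig) -> int:
    """Total bp to sample: max(tier fraction x genome, 15 Mb floor), capped at the genome."""
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    frac = tier_fraction(genome_length, config.tier_table)
    target = max(int(round(frac * genome_length)), config.min_total)
    if target > genome_length:
        log.warning(
            "sampling target %d bp exceeds genome length %d bp; capping at genome length",
            target, genome_length,
        )
        target = genome_length
    return target


def sample_regions(
    genome: Genome,
    config: SamplingConfig,
    rng: np.random.Generator | int | None = None,
) -> list[Region]:
    """Sample non-overlapping fixed-length regions until the tier target is met.

    Each contig long enough for a region is tiled into region-length windows
    at a per-contig random phase; windows are then drawn uniformly without
    replacement. This keeps placement random and seeded while guaranteeing
    non-overlap at any packing density (unconstrained uniform placement jams
    near 75% occupancy, below what the 15 Mb floor demands of a 20 Mb
    genome). Windows with more than ``max_n_fraction`` N are rejected;
    ``max_rejections`` consecutive N-rejections abort with a diagnostic.
    Sampling stops at the first region whose addition meets or exceeds the
    target, so the total lies in [target, target + region length).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)
    L = config.region_length
    eligible = [rec for rec in genome.records if len(rec) >= L]
    if not eligible:
        raise ConfigurationError(
            f"no contig is >= one region length ({L} bp); longest contig is "
            f"{max((len(r) for r in genome.records), default=0)} bp"
        )
    target = compute_sampling_target(genome.total_length, config)

    pool: list[tuple[SequenceRecord, int]] = []  # (contig, window start)
    for rec in eligible:
        phase = int(rng.integers(0, L))
        n_windows = (len(rec) - phase) // L
        if n_windows == 0:  # phase pushed a short contig out; fall back to phase 0
            phase, n_windows = 0, len(rec) // L
        pool.extend((rec, phase + w * L) for w in range(n_windows))
    achievable = len(pool) * L
    if target > achievable:
        log.warning(
            "sampling target %d bp exceeds achievable length %d bp; capping",
            target, achievable,
        )
        target = achievable

    regions: list[Region] = []
    total = 0
    rejections = 0
    for idx in rng.permutation(len(pool)):
        if total >= target:
            break
        rec, start = pool[int(idx)]
        if rec.sequence.count("N", start, start + L) > config.max_n_fraction * L:
            rejections += 1
            if rejections >= config.max_rejections:
                raise SamplingError(
                    f"{config.max_rejections} consecutive candidates exceeded "
                    f"{config.max_n_fraction:.0%} N after {total} of {target} bp; "
                    "the genome is too N-rich to reach the sampling target"
                )
            continue
        rejections = 0
        regions.append(Region(rec.id, start, start + L))
        total += L
    if total < target:
        raise SamplingError(
            f"sampled {total} of {target} bp ({len(regions)} regions of {L} bp); "
            "the genome is too short, too fragmented, or too N-rich for this "
            "region length"
        )
    return regions


def build_artificial_chromosome(
    genome: Genome,
    regions: Sequence[Region],
    config: SamplingConfig,
    chrom_id: str = "artificial_chr",
) -> tuple[SequenceRecord, RegionMap]:
    """Concatenate sampled regions, separated by N-padding, into one sequence."""
    if not regions:
        raise ValueError("cannot build an artificial chromosome from zero regions")
    pad = "N" * config.pad_length
    pieces: list[str] = []
    entries: list[tuple[Region, int]] = []
    offset = 0
    for i, region in enumerate(regions):
        if i > 0:
            pieces.append(pad)
            offset += config.pad_length
        contig = genome.get(region.contig_id)
        if region.end > len(contig):
            raise ValueError(f"region {region} exceeds contig {region.contig_id}")
        pieces.append(contig.sequence[region.start:region.end])
        entries.append((region, offset))
        offset += len(region)
    sequence = "".join(pieces)
    return SequenceRecord(chrom_id, sequence), RegionMap(entries, len(sequence))


def lift_to_reference(region_map: RegionMap, artificial_pos: int):
    """Map an artificial-chromosome position back to (contig, reference position).

    Positions inside an N separator return the :data:`IN_PADDING` sentinel.
    """
    if not 0 <= artificial_pos < region_map.artificial_length:
        raise IndexError(
            f"artificial position {artificial_pos} outside "
            f"[0, {region_map.artificial_length})"
        )
    idx = bisect_right(region_map._offsets, artificial_pos) - 1
    region, offset = region_map.entries[idx]
    if artificial_pos < offset + len(region):
        return region.contig_id, region.start + artificial_pos - offset
    return IN_PADDING
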