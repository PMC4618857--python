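"""Mapper execution harness: parameter grids, adapters, baseline and oracle mappers.

External mappers are declared as command templates with ``{reference}``,
``{fastq1}``, ``{fastq2}``, ``{params}`` and ``{output}`` placeholders. The
harness times the mapping command only — indexing is run first and excluded,
matching how mapper throughput should be reported for large read sets — and
records the peak resident set of the mapper's process tree by polling
``/proc`` every 50 ms (a lower bound on the true peak).

Two built-in mappers make the whole pipeline testable without third-party
binaries: a seed-and-verify baseline (exact first k-mer match, full-read
Hamming verification) and a truth-reading oracle used as a test double.
"""
from __future__ import annotations

import itertools
import logging
import re
import shlex
import shutil
import subprocess
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pysam
from Bio import SeqIO

from .genome_io import Genome
from .simulator import FORWARD, REVERSE, TruthTable, reverse_complement

log = logging.getLogger(__name__)

_POLL_INTERVAL = 0.05


class ConfigurationError(ValueError):
    """Bad adapter, grid, or missing executable."""


class OracleError(ValueError):
    """A read has no truth entry."""


@dataclass(frozen=True)
class ParameterSet:
    """One labelled combination of command-line tokens for a mapper."""

    label: str
    tokens: tuple[tuple[str, str | None], ...] = ()

    def render(self) -> str:
        parts = []
        for flag, value in self.tokens:
            parts.append(flag if value is None else f"{flag} {value}")
        return " ".join(parts)


DEFAULT_PARAMETER_SET = ParameterSet("default", ())


def expand_grid(grid: Mapping[str, Sequence]) -> list[ParameterSet]:
    """Cartesian product of parameter value lists, in input order.

    An empty grid yields the single default (empty) parameter set. A value
    of None means the flag is passed bare.
    """
    if not grid:
        return [DEFAULT_PARAMETER_SET]
    names = list(grid)
    for name in names:
        if len(grid[name]) == 0:
            raise ConfigurationError(f"empty value list for parameter {name!r}")
    sets: list[ParameterSet] = []
    for combo in itertools.product(*(grid[name] for name in names)):
        tokens = tuple(
            (name, None if value is None else str(value))
            for name, value in zip(names, combo)
        )
        label = ",".join(
            name if value is None else f"{name}={value}"
            for name, value in zip(names, combo)
        )
        sets.append(ParameterSet(label, tokens))
    return sets


@dataclass(frozen=True)
class MapperAdapter:
    """Declarative description of how to index and run one mapper."""

    name: str
    map_command: str
    index_command: str | None = None
    output_format: str = "SAM"

    def __post_init__(self) -> None:
        for placeholder in ("{reference}", "{fastq1}", "{output}"):
            if placeholder not in self.map_command:
                raise ConfigurationError(
                    f"map_command for {self.name!r} must contain {placeholder}"
                )


@dataclass
class RunRecord:
    """Outcome of one mapper x parameter-set execution."""

    mapper: str
    parameter_label: str
    alignment_path: Path | None
    mapping_wall_time: float
    peak_memory: int
    exit_status: int
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.exit_status == 0


def _proc_descendants(pid: int) -> list[int]:
    pids = [pid]
    i = 0
    while i < len(pids):
        p = pids[i]
        i += 1
        try:
            for task in Path(f"/proc/{p}/task").iterdir():
                children = (task / "children").read_text().split()
                pids.extend(int(c) for c in children)
        except OSError:
            continue
    return pids


def _rss_bytes(pid: int) -> int:
    total = 0
    for p in _proc_descendants(pid):
        try:
            status = Path(f"/proc/{p}/status").read_text()
        except OSError:
            continue
        m = re.search(r"^VmRSS:\s+(\d+)\s+kB", status, re.MULTILINE)
        if m:
            total += int(m.group(1)) * 1024
    return total


def _render(template: str, *, reference, fastq1, fastq2, params, output) -> str:
    return template.format(
        reference=shlex.quote(str(reference)),
        fastq1=shlex.quote(str(fastq1)),
        fastq2=shlex.quote(str(fastq2)) if fastq2 else "",
        params=params,
        output=shlex.quote(str(output)),
    )


def run_mapper(
    adapter: MapperAdapter,
    params: ParameterSet,
    reference: str | Path,
    reads: Sequence[str | Path],
    out_dir: str | Path,
    timeout: float | None = None,
) -> RunRecord:
    """Run one mapper with one parameter set, timing the mapping step only.

    The index command (if any) runs first and is excluded from
    ``mapping_wall_time``. Peak memory is the maximum resident set summed
    over the mapper's process tree, sampled every 50 ms.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    safe_label = re.sub(r"[^A-Za-z0-9._=-]+", "_", params.label) or "default"
    out_sam = out_dir / f"{adapter.name}__{safe_label}.sam"
    fastq1 = reads[0]
    fastq2 = reads[1] if len(reads) > 1 else ""

    def render(tpl: str) -> list[str]:
        return shlex.split(_render(
            tpl, reference=reference, fastq1=fastq1, fastq2=fastq2,
            params=params.render(), output=out_sam,
        ))

    map_argv = render(adapter.map_command)
    if shutil.which(map_argv[0]) is None:
        raise ConfigurationError(
            f"mapper executable {map_argv[0]!r} for adapter {adapter.name!r} not found"
        )

    if adapter.index_command:
        index_argv = render(adapter.index_command)
        if shutil.which(index_argv[0]) is None:
            raise ConfigurationError(
                f"index executable {index_argv[0]!r} for adapter {adapter.name!r} not found"
            )
        idx = subprocess.run(index_argv, capture_output=True, text=True)
        if idx.returncode != 0:
            return RunRecord(
                adapter.name, params.label, None, 0.0, 0, idx.returncode,
                error=f"index command failed: {idx.stderr[-500:]}",
            )

    peak = 0
    t0 = time.perf_counter()
    proc = subprocess.Popen(
        map_argv, stdout=subprocess.PIPE, stderr=subprocess.PIPE, text=True
    )
    try:
        while proc.poll() is None:
            peak = max(peak, _rss_bytes(proc.pid))
            if timeout is not None and time.perf_counter() - t0 > timeout:
                proc.kill()
                proc.wait()
                return RunRecord(
                    adapter.name, params.label, None,
                    time.perf_counter() - t0, peak, -9,
                    error=f"timeout after {timeout}s",
                )
            time.sleep(_POLL_INTERVAL)
    finally:
        stdout, stderr = proc.communicate()
    wall = time.perf_counter() - t0

    if proc.returncode != 0:
        return RunRecord(
            adapter.name, params.label, None, wall, peak, proc.returncode,
            error=(stderr or stdout)[-500:],
        )
    if not out_sam.exists():
        return RunRecord(
            adapter.name, params.label, None, wall, peak, 1,
            error=f"mapper exited 0 but produced no output at {out_sam}",
        )
    return RunRecord(adapter.name, params.label, out_sam, wall, peak, 0)


# ---------------------------------------------------------------------------
# built-in mappers


def sam_header(genome: Genome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": rec.id, "LN": len(rec)} for rec in genome.records],
    })


def write_sam(
    records: Sequence[pysam.AlignedSegment], genome: Genome, path: str | Path
) -> Path:
    path = Path(path)
    with pysam.AlignmentFile(str(path), "w", header=sam_header(genome)) as out:
        for rec in records:
            out.write(rec)
    return path


def build_kmer_index(genome: Genome, k: int) -> dict[str, list[tuple[int, int]]]:
    """Exact k-mer -> [(contig index, position)] over all contigs (N k-mers skipped)."""
    index: dict[str, list[tuple[int, int]]] = {}
    for ci, rec in enumerate(genome.records):
        seq = rec.sequence
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos:pos + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((ci, pos))
    return index


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _read_fastq_tuples(paths: Sequence[str | Path]) -> list[tuple[str, str, str, int]]:
    out = []
    for file_idx, path in enumerate(paths):
        mate = 0 if len(paths) == 1 else file_idx + 1
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append((rec.id, str(rec.seq).upper(), quals, mate))
    return out


def baseline_map(
    reads: Sequence[str | Path],
    genome: Genome,
    k: int | None = None,
    index: dict | None = None,
) -> list[pysam.AlignedSegment]:
    """Map reads with the built-in seed-and-verify baseline mapper.

    Candidate placements come from exact matches of the read's first k-mer
    (forward and reverse complement); each candidate is verified by Hamming
    distance over the full read. The lowest-distance placement becomes the
    primary alignment with mapping quality 60 if uniquely best, 0 on ties
    (tie broken toward the leftmost coordinate); reads with no candidate are
    reported unmapped.
    """
    header = sam_header(genome)
    tuples = _read_fastq_tuples(reads)
    if not tuples:
        return []
    if k is None:
        k = min(17, len(tuples[0][1]))
    if index is None:
        index = build_kmer_index(genome, k)

    out: list[pysam.AlignedSegment] = []
    for read_id, seq, qual, mate in tuples:
        rc = reverse_complement(seq)
        candidates: list[tuple[int, int, bool]] = []  # (contig idx, pos, is_reverse)
        if len(seq) >= k:
            for ci, pos in index.get(seq[:k], ()):
                candidates.append((ci, pos, False))
            for ci, pos in index.get(rc[:k], ()):
                candidates.append((ci, pos, True))

        best: list[tuple[int, int, bool]] = []
        best_dist = None
        for ci, pos, is_rev in candidates:
            ref = genome.records[ci].sequence
            if pos + len(seq) > len(ref):
                continue
            query = rc if is_rev else seq
            dist = _hamming(query, ref[pos:pos + len(seq)])
            if best_dist is None or dist < best_dist:
                best_dist = dist
                best = [(ci, pos, is_rev)]
            elif dist == best_dist:
                best.append((ci, pos, is_rev))

        aln = pysam.AlignedSegment(header)
        aln.query_name = read_id
        if mate == 1:
            aln.flag |= 0x1 | 0x40
        elif mate == 2:
            aln.flag |= 0x1 | 0x80
        if not best:
            aln.flag |= 0x4
            aln.query_sequence = seq
            aln.query_qualities = pysam.qualitystring_to_array(qual)
            out.append(aln)
            continue
        best.sort()  # deterministic: leftmost (contig index, position, strand)
        ci, pos, is_rev = best[0]
        if is_rev:
            aln.flag |= 0x10
        aln.reference_id = ci
        aln.reference_start = pos
        aln.mapping_quality = 60 if len(best) == 1 else 0
        aln.cigartuples = [(0, len(seq))]
        aln.query_sequence = rc if is_rev else seq
        aln.query_qualities = pysam.qualitystring_to_array(
            qual[::-1] if is_rev else qual
        )
        out.append(aln)
    return out


def oracle_map(
    truth: TruthTable,
    reads: Sequence[str | Path],
    genome: Genome,
) -> list[pysam.AlignedSegment]:
    """Emit each read at exactly its truth position/strand, mapping quality 60.

    Test double: downstream evaluation of an oracle run must classify every
    read as correct.
    """
    header = sam_header(genome)
    contig_ids = {rec.id: i for i, rec in enumerate(genome.records)}
    out: list[pysam.AlignedSegment] = []
    for read_id, seq, qual, mate in _read_fastq_tuples(reads):
        t = truth.get(read_id, mate)
        if t is None:
            raise OracleError(f"no truth entry for read {read_id!r} (mate {mate})")
        aln = pysam.AlignedSegment(header)
        aln.query_name = read_id
        if t.mate == 1:
            aln.flag |= 0x1 | 0x40
        elif t.mate == 2:
            aln.flag |= 0x1 | 0x80
        if t.strand == REVERSE:
            aln.flag |= 0x10
        aln.reference_id = contig_ids[t.contig]
        aln.reference_start = t.true_pos
        aln.mapping_quality = 60
        aln.cigartuples = [(0, len(seq))]
        aln.query_sequence = seq
        aln.query_qualities = pysam.qualitystring_to_array(qual)
        out.append(aln)
    return out


def load_mapper_configs(config: Mapping) -> list[tuple[MapperAdapter, list[ParameterSet]]]:
    """Turn the ``mappers`` section of a run config into adapters + parameter sets.

    Each mapper entry carries either ``builtin: baseline`` or a
    ``map_command`` template (plus optional ``index_command``), and any
    combination of ``sets`` (explicit labelled argument strings) and ``grid``
    (value lists expanded to their cartesian product). With neither, the
    mapper runs once with defaults.
    """
    out: list[tuple[MapperAdapter, list[ParameterSet]]] = []
    for entry in config.get("mappers", []):
        name = entry.get("name")
        if not name:
            raise ConfigurationError("every mapper entry needs a name")
        if entry.get("builtin") == "baseline":
            adapter = builtin_baseline_adapter(k=entry.get("k"))
            adapter = MapperAdapter(name, adapter.map_command, adapter.index_command)
        elif "map_command" in entry:
            adapter = MapperAdapter(
                name, entry["map_command"], entry.get("index_command")
            )
        else:
            raise ConfigurationError(
                f"mapper {name!r} needs either builtin: baseline or a map_command"
            )
        sets: list[ParameterSet] = []
        for s in entry.get("sets", []):
            tokens = tuple((tok, None) for tok in shlex.split(s.get("args", "")))
            sets.append(ParameterSet(s["label"], tokens))
        if "grid" in entry:
            sets.extend(expand_grid(entry["grid"]))
        if not sets:
            sets = [DEFAULT_PARAMETER_SET]
        labels = [s.label for s in sets]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate parameter-set labels for {name!r}")
        out.append((adapter, sets))
    return out


def builtin_baseline_adapter(k: int | None = None) -> MapperAdapter:
    """Adapter that runs this package's baseline mapper as a subprocess."""
    extra = f" -k {k}" if k is not None else ""
    return MapperAdapter(
        name="baseline",
        map_command=(
            f"{shlex.quote(sys.executable)} -m mapbench baseline-map "
            "--ref {reference} --fastq {fastq1} --out {output}" + extra + " {params}"
        ),
    )
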