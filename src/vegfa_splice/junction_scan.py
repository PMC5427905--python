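"""Junction evidence counting: exact probe scanning and SJ-file quantification.

Two complementary routes mirror the dual strategy of the analysis:

1. **Probe scanning** — every read is tested for exact, contiguous,
   case-insensitive containment of each 2*flank-base junction probe (on both
   strands by default).  A read contributes at most once per probe; paired
   mates are scanned as independent reads.  Counts are normalized to hits per
   million reads scanned.
2. **SJ-file extraction** — 9-column splice-junction tables produced by
   spliced aligners are filtered to a genomic window, annotated against a
   junction catalog (unknown introns keep a ``novel:first-last`` label) and
   normalized per billion aligned bases.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ParseError, ValidationError
from .locus_model import JunctionDef, JunctionProbe
from .sequtils import is_dna, reverse_complement

logger = logging.getLogger(__name__)


def _open_maybe_gzip(path: Path) -> io.TextIOBase:
    with path.open("rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return path.open("rt")


def iter_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream (id, sequence) from FASTA or FASTQ, plain or gzipped.

    Compression is detected from magic bytes, the format from the first
    character ('>' FASTA, '@' FASTQ).  Malformed records raise ParseError
    naming the record index.
    """
    path = Path(path)
    handle = _open_maybe_gzip(path)
    try:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ParseError(f"{path}: not FASTA or FASTQ (first character {first!r})")
        index = 0
        parser = SeqIO.parse(handle, fmt)
        while True:
            try:
                record = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ParseError(f"{path}: invalid record {index}: {exc}") from exc
            yield record.id, str(record.seq).upper()
            index += 1
    finally:
        handle.close()


@dataclass(frozen=True)
class ScanResult:
    """Per-probe read counts for one sample, with optional per-million values."""

    sample_id: str
    total_reads: int
    counts: Mapping[str, int]
    per_million: Mapping[str, float] | None = None


def scan_reads(
    reads,
    probes: Sequence[JunctionProbe],
    both_strands: bool = True,
    sample_id: str = "sample",
) -> ScanResult:
    """Count reads containing each probe as an exact substring.

    ``reads`` is a FASTA/FASTQ path or an iterable of (id, sequence).  A read
    is counted for a probe iff the probe sequence occurs contiguously in the
    read or, when ``both_strands``, in its reverse complement.  Reads
    containing N never match (exact-match contract).  Reads matching several
    distinct probes are all counted once per probe; a summary warning is
    logged because the default probe set cannot produce them on a valid
    locus.
    """
    if not probes:
        raise ValidationError("at least one probe is required")
    seqs = [(p.junction_name, p.sequence.upper()) for p in probes]
    for name, seq in seqs:
        if not is_dna(seq):
            raise ValidationError(f"probe {name} contains non-ACGT characters")
    if len({s for _, s in seqs}) != len(seqs):
        raise ValidationError("probe sequences must be distinct")

    if isinstance(reads, (str, Path)):
        reads = iter_reads(reads)

    counts = {name: 0 for name, _ in seqs}
    total = 0
    multi_probe_reads = 0
    for _, read in reads:
        total += 1
        rc = reverse_complement(read) if both_strands else None
        hits = 0
        for name, probe in seqs:
            if probe in read or (rc is not None and probe in rc):
                counts[name] += 1
                hits += 1
        if hits > 1:
            multi_probe_reads += 1
    if multi_probe_reads:
        logger.warning(
            "%s: %d reads matched more than one probe (each counted per probe)",
            sample_id,
            multi_probe_reads,
        )
    return ScanResult(sample_id, total, counts)


def normalize_per_million(result: ScanResult) -> ScanResult:
    """Populate hits-per-million-reads; raw counts are preserved."""
    if result.total_reads <= 0:
        raise ValidationError("cannot normalize: total_reads is 0")
    per_million = {
        name: count / result.total_reads * 1e6
        for name, count in result.counts.items()
    }
    return dataclasses.replace(result, per_million=per_million)


def write_scan_tsv(results: Sequence[ScanResult], path: str | Path) -> None:
    rows = []
    for r in results:
        pm = r.per_million or {}
        for name in r.counts:
            rows.append(
                {
                    "sample": r.sample_id,
                    "probe": name,
                    "count": r.counts[name],
                    "per_million": pm.get(name, float("nan")),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SJRecord:
    """One row of a 9-column splice-junction table (1-based intron coords)."""

    chrom: str
    intron_first: int
    intron_last: int
    strand_code: int
    motif_code: int
    annotated: int
    unique_count: int
    multi_count: int
    max_overhang: int

    def __post_init__(self) -> None:
        if self.intron_first > self.intron_last:
            raise ValidationError(
                f"SJ record {self.chrom}:{self.intron_first}-{self.intron_last}: "
                "intron_first > intron_last"
            )
        if min(self.unique_count, self.multi_count) < 0:
            raise ValidationError("SJ counts must be >= 0")


def parse_sj_file(
    path: str | Path,
    window: tuple[str, int, int] | None = None,
) -> list[SJRecord]:
    """Parse an SJ file, keeping records whose intron lies inside ``window``.

    ``window`` is (chrom, start, end), 1-based inclusive; containment requires
    both intron coordinates inside the window.  ``None`` keeps everything.
    """
    path = Path(path)
    records = []
    with _open_maybe_gzip(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 columns, got {len(fields)}"
                )
            try:
                record = SJRecord(fields[0], *(int(x) for x in fields[1:]))
            except ValueError as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate or count"
                ) from exc
            if window is not None:
                chrom, start, end = window
                if record.chrom != chrom:
                    continue
                if record.intron_first < start or record.intron_last > end:
                    continue
            records.append(record)
    return records


def annotate_sj_records(
    records: Sequence[SJRecord], junctions: Sequence[JunctionDef]
) -> dict[str, int]:
    """Tabulate unique-read counts per junction name for one sample.

    A record whose intron matches a catalog junction gets that junction's
    name; anything else is labeled ``novel:<intron_first>-<intron_last>``.
    Records with identical introns are summed into a single entry.
    """
    by_intron = {(j.intron_first, j.intron_last): j.name for j in junctions}
    row: dict[str, int] = {}
    for record in records:
        name = by_intron.get(
            (record.intron_first, record.intron_last),
            f"novel:{record.intron_first}-{record.intron_last}",
        )
        row[name] = row.get(name, 0) + record.unique_count
    return row


@dataclass
class JunctionCountTable:
    """Samples x junctions unique-read counts with optional normalization.

    ``denominators`` holds the per-sample normalization denominator (aligned
    bases for per-billion, or total reads for per-million); ``normalized``
    holds count / denominator * scale and is recomputable from the raw
    counts, which are always preserved.
    """

    counts: pd.DataFrame
    denominators: pd.Series | None = None
    normalized: pd.DataFrame | None = None
    scale: float | None = None

    @classmethod
    def from_rows(cls, rows: Mapping[str, Mapping[str, int]]) -> "JunctionCountTable":
        frame = (
            pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
        )
        return cls(counts=frame.sort_index(axis=1))

    def denormalized(self) -> pd.DataFrame:
        """Recompute integer counts from the normalized values (round trip)."""
        if self.normalized is None or self.denominators is None or self.scale is None:
            raise ValidationError("table has not been normalized")
        back = self.normalized.mul(self.denominators, axis=0) / self.scale
        return back.round().astype(int)


def filter_junctions(
    table: JunctionCountTable, min_unique: int, max_unique: int
) -> JunctionCountTable:
    """Keep junction columns whose total count across samples is in bounds.

    Bounds are inclusive, matching a "supported by 20-200 uniquely aligned
    reads from all datasets combined" style selection.
    """
    if min_unique > max_unique:
        raise ValidationError("min_unique must be <= max_unique")
    sums = table.counts.sum(axis=0)
    keep = sums[(sums >= min_unique) & (sums <= max_unique)].index
    return JunctionCountTable(
        counts=table.counts[keep].copy(),
        denominators=table.denominators,
    )


def normalize_per_billion_bases(
    table: JunctionCountTable, bases_aligned: Mapping[str, float]
) -> JunctionCountTable:
    """Normalize counts to 'per billion aligned bases' per sample."""
    denom = pd.Series(
        {sample: bases_aligned[sample] for sample in table.counts.index},
        dtype=float,
    )
    if (denom <= 0).any():
        bad = denom[denom <= 0].index.tolist()
        raise ValidationError(f"zero/negative denominator for samples {bad}")
    normalized = table.counts.div(denom, axis=0) * 1e9
    return JunctionCountTable(
        counts=table.counts.copy(),
        denominators=denom,
        normalized=normalized,
        scale=1e9,
    )


def junction_introns_to_bed(
    junctions: Sequence[JunctionDef], chrom: str, path: str | Path
) -> None:
    """Export junction introns as BED (0-based half-open conversion)."""
    with Path(path).open("w") as handle:
        for j in junctions:
            handle.write(
                f"{chrom}\t{j.intron_first - 1}\t{j.intron_last}\t{j.name}\n"
            )
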