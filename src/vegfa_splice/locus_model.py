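"""Model of the VEGFA locus: exons, splice junctions, probes and transcripts.

VEGFA's alternative splicing is described over a catalog of named exons with
1-based inclusive genomic coordinates on the plus strand of chromosome 6
(hg19).  Splice junctions are named ``donor-acceptor`` (e.g. ``7b-8a``).  The
canonical terminal exon 8 consists of two genomically contiguous segments, 8a
and 8b: splicing into the 8a acceptor produces the canonical VEGFA_xxx
isoforms, whereas splicing directly into 8b (skipping 8a) would produce the
putative anti-angiogenic VEGFA_xxx_b isoforms.

A *junction probe* concatenates the last ``flank`` bases of the donor exon
with the first ``flank`` bases of the acceptor exon; exact containment of a
probe in a sequencing read is evidence for the junction.  Because the last
three bases of exon 7 equal the last three bases of exon 8a, spliced read
placements at the 8b acceptor with a donor overhang of three bases or fewer
are ambiguous — this module quantifies that *shared terminal ambiguity*
directly from sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError
from .sequtils import (
    is_dna,
    longest_shared_prefix,
    longest_shared_suffix,
    reverse_complement,
)

DEFAULT_FLANK = 11

#: Default donor/acceptor exon names for the ten exon-8 junctions of interest.
DEFAULT_DONORS: tuple[str, ...] = ("4", "5", "6a", "7a", "7b")
DEFAULT_ACCEPTORS: tuple[str, ...] = ("8a", "8b")

#: hg19 coordinates of the VEGFA exons (1-based inclusive, plus strand).
#: Exons 1B, 1C and 1D have no published start coordinate and are omitted;
#: they may be supplied through a user catalog.
_DEFAULT_VEGFA_EXONS: tuple[tuple[str, int, int], ...] = (
    ("1a", 43737946, 43738362),
    ("1b", 43738363, 43739049),
    ("1A", 43739722, 43739838),
    ("2", 43742078, 43742129),
    ("3", 43745206, 43745402),
    ("4", 43746197, 43746273),
    ("5", 43746626, 43746655),
    ("6a", 43748469, 43748522),
    ("6b", 43748523, 43748540),
    ("6c", 43748541, 43748591),
    ("7a", 43749693, 43749789),
    ("7b", 43749790, 43749824),
    ("8a", 43752278, 43752343),
    ("8b", 43752344, 43754223),
)

#: The hg19 window used when extracting VEGFA splice junctions from SJ files.
VEGFA_WINDOW: tuple[str, int, int] = ("chr6", 43737945, 43754224)


@dataclass(frozen=True)
class ExonDef:
    """A named exon with 1-based inclusive genomic coordinates."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("exon name must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"exon {self.name}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValidationError(
                f"exon {self.name}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class ExonCatalog(Mapping[str, ExonDef]):
    """An ordered collection of uniquely named exons."""

    def __init__(self, exons: Iterable[ExonDef]):
        self._exons: dict[str, ExonDef] = {}
        for exon in exons:
            if exon.name in self._exons:
                raise ValidationError(f"duplicate exon name {exon.name!r}")
            self._exons[exon.name] = exon

    def __getitem__(self, name: str) -> ExonDef:
        return self._exons[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._exons)

    def __len__(self) -> int:
        return len(self._exons)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._exons)

    def exons(self) -> tuple[ExonDef, ...]:
        return tuple(self._exons.values())


def default_vegfa_catalog() -> ExonCatalog:
    """The built-in hg19 VEGFA exon catalog."""
    return ExonCatalog(
        ExonDef(name, "chr6", start, end, "+")
        for name, start, end in _DEFAULT_VEGFA_EXONS
    )


_CATALOG_COLUMNS = ("name", "chrom", "start", "end", "strand")


def load_exon_catalog(path: str | Path) -> ExonCatalog:
    """Load a tab-delimited exon catalog (header: name chrom start end strand)."""
    path = Path(path)
    exons: list[ExonDef] = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty catalog file") from None
        if tuple(header) != _CATALOG_COLUMNS:
            raise ParseError(
                f"{path}: line 1: expected header {' '.join(_CATALOG_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 columns")
            name, chrom, start, end, strand = row
            try:
                exons.append(ExonDef(name, chrom, int(start), int(end), strand))
            except ValueError as exc:  # int() failure or ExonDef validation
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
    return ExonCatalog(exons)


def write_exon_catalog(catalog: ExonCatalog, path: str | Path) -> None:
    """Write a catalog in the tab-delimited format read by load_exon_catalog."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_CATALOG_COLUMNS)
        for exon in catalog.exons():
            writer.writerow([exon.name, exon.chrom, exon.start, exon.end, exon.strand])


@dataclass(frozen=True)
class JunctionDef:
    """A donor-acceptor splice junction with its intron coordinates."""

    name: str
    donor_exon: str
    acceptor_exon: str
    donor_end: int
    acceptor_start: int

    def __post_init__(self) -> None:
        if self.name != f"{self.donor_exon}-{self.acceptor_exon}":
            raise ValidationError(
                f"junction name {self.name!r} must be donor-acceptor"
            )
        if self.intron_first > self.intron_last:
            raise ValidationError(
                f"junction {self.name}: not a forward junction "
                f"(donor end {self.donor_end} >= acceptor start {self.acceptor_start})"
            )

    @property
    def intron_first(self) -> int:
        return self.donor_end + 1

    @property
    def intron_last(self) -> int:
        return self.acceptor_start - 1


def build_junction_catalog(
    catalog: ExonCatalog,
    donor_names: Sequence[str],
    acceptor_names: Sequence[str],
) -> list[JunctionDef]:
    """One junction per (donor, acceptor) pair, in donor then acceptor genomic order.

    Raises ValidationError if any pair is not a forward junction (the acceptor
    must start at least two bases after the donor ends, leaving an intron).
    """
    for name in list(donor_names) + list(acceptor_names):
        if name not in catalog:
            raise ValidationError(f"exon {name!r} not in catalog")
    donors = sorted((catalog[n] for n in donor_names), key=lambda e: e.start)
    acceptors = sorted((catalog[n] for n in acceptor_names), key=lambda e: e.start)
    junctions = []
    for donor in donors:
        for acceptor in acceptors:
            junctions.append(
                JunctionDef(
                    name=f"{donor.name}-{acceptor.name}",
                    donor_exon=donor.name,
                    acceptor_exon=acceptor.name,
                    donor_end=donor.end,
                    acceptor_start=acceptor.start,
                )
            )
    return junctions


def junctions_in_chain(catalog: ExonCatalog, exon_chain: Sequence[str]) -> list[JunctionDef]:
    """Real splice junctions between consecutive chain exons.

    Genomically contiguous neighbours (acceptor starts one base after the
    donor ends, e.g. 8a|8b) are part of one exon and yield no junction.
    """
    out = []
    for a, b in zip(exon_chain, exon_chain[1:]):
        if catalog[b].start > catalog[a].end + 1:
            out.append(
                JunctionDef(
                    name=f"{a}-{b}",
                    donor_exon=a,
                    acceptor_exon=b,
                    donor_end=catalog[a].end,
                    acceptor_start=catalog[b].start,
                )
            )
    return out


@dataclass(frozen=True)
class LocusReference:
    """A contiguous genomic window holding the exon catalog's sequence."""

    chrom: str
    region_start: int
    region_end: int
    sequence: str
    exons: ExonCatalog

    def __post_init__(self) -> None:
        if len(self.sequence) != self.region_end - self.region_start + 1:
            raise ValidationError(
                "locus sequence length does not match region coordinates"
            )
        if set(self.sequence) - set("ACGTN"):
            raise ValidationError("locus sequence must be uppercase ACGTN")
        for exon in self.exons.exons():
            if exon.start < self.region_start or exon.end > self.region_end:
                raise ValidationError(
                    f"exon {exon.name} lies outside the locus window"
                )

    def fetch(self, start: int, end: int) -> str:
        """Genomic subsequence, 1-based inclusive coordinates."""
        if start < self.region_start or end > self.region_end or start > end:
            raise ValidationError(f"fetch({start}, {end}) outside locus window")
        off = self.region_start
        return self.sequence[start - off : end - off + 1]

    def exon_sequence(self, name: str) -> str:
        exon = self.exons[name]
        return self.fetch(exon.start, exon.end)


def load_locus_reference(
    fasta_path: str | Path,
    exons: ExonCatalog,
    chrom: str,
    region_start: int,
    region_end: int,
) -> LocusReference:
    """Slice a locus window out of a genome FASTA (via pyfaidx)."""
    from pyfaidx import Fasta

    genome = Fasta(str(fasta_path))
    seq = str(genome[chrom][region_start - 1 : region_end]).upper()
    return LocusReference(chrom, region_start, region_end, seq, exons)


@dataclass(frozen=True)
class JunctionProbe:
    """A 2*flank-base junction-spanning probe: donor suffix + acceptor prefix."""

    junction_name: str
    flank: int
    donor_half: str
    acceptor_half: str

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValidationError("flank must be >= 1")
        if len(self.donor_half) != self.flank or len(self.acceptor_half) != self.flank:
            raise ValidationError(
                f"probe {self.junction_name}: halves must each be {self.flank} bases"
            )

    @property
    def sequence(self) -> str:
        return self.donor_half + self.acceptor_half


def extract_probe(
    locus: LocusReference, junction: JunctionDef, flank: int = DEFAULT_FLANK
) -> JunctionProbe:
    """Build a junction probe from the locus sequence."""
    if flank < 1:
        raise ValidationError("flank must be >= 1")
    donor = locus.exons[junction.donor_exon]
    acceptor = locus.exons[junction.acceptor_exon]
    for exon in (donor, acceptor):
        if flank > exon.length:
            raise ValidationError(
                f"flank {flank} exceeds length {exon.length} of exon {exon.name}"
            )
    donor_half = locus.fetch(donor.end - flank + 1, donor.end)
    acceptor_half = locus.fetch(acceptor.start, acceptor.start + flank - 1)
    return JunctionProbe(junction.name, flank, donor_half, acceptor_half)


def build_probes(
    locus: LocusReference,
    junctions: Sequence[JunctionDef],
    flank: int = DEFAULT_FLANK,
) -> list[JunctionProbe]:
    return [extract_probe(locus, j, flank) for j in junctions]


def write_probe_fasta(probes: Sequence[JunctionProbe], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.junction_name, description="")
        for p in probes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_probe_fasta(path: str | Path) -> list[JunctionProbe]:
    """Read probes written by write_probe_fasta (even-length records)."""
    probes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) % 2 != 0 or not is_dna(seq):
            raise ParseError(f"probe {rec.id}: expected even-length ACGT sequence")
        flank = len(seq) // 2
        probes.append(JunctionProbe(rec.id, flank, seq[:flank], seq[flank:]))
    return probes


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript assembled from an ordered exon chain.

    ``junction_offsets`` holds, for each real splice junction in the chain,
    the transcript offset of the junction boundary (number of transcript
    bases upstream of the acceptor's first base).
    """

    name: str
    exon_chain: tuple[str, ...]
    sequence: str
    junction_offsets: tuple[tuple[str, int], ...] = field(default=())

    @property
    def junctions(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.junction_offsets)

    @property
    def length(self) -> int:
        return len(self.sequence)


def assemble_transcript(
    locus: LocusReference, name: str, exon_chain: Sequence[str]
) -> TranscriptModel:
    """Concatenate exon subsequences in genomic order into a transcript."""
    if not exon_chain:
        raise ValidationError("exon chain must be non-empty")
    exons = [locus.exons[n] for n in exon_chain]
    for a, b in zip(exons, exons[1:]):
        if b.start <= a.end:
            raise ValidationError(
                f"transcript {name}: exons {a.name} and {b.name} are "
                "out of order or overlapping"
            )
    parts = [locus.exon_sequence(e.name) for e in exons]
    offsets = []
    cum = 0
    for a, b, part in zip(exons, exons[1:], parts):
        cum += len(part)
        if b.start > a.end + 1:
            offsets.append((f"{a.name}-{b.name}", cum))
    return TranscriptModel(name, tuple(exon_chain), "".join(parts), tuple(offsets))


def write_transcript_fasta(
    transcripts: Sequence[TranscriptModel], path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.name, description="") for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def shared_terminal_ambiguity(locus: LocusReference, exon_a: str, exon_b: str) -> int:
    """Longest s such that the last s bases of the two exons are identical.

    Symmetric in its arguments; 0 when the terminal bases already differ.
    This is the quantity that makes spliced placements with donor overhang
    <= s non-unique when one exon's end abuts the other junction's acceptor.
    """
    return longest_shared_suffix(
        locus.exon_sequence(exon_a), locus.exon_sequence(exon_b)
    )


def shared_initial_ambiguity(locus: LocusReference, exon_a: str, exon_b: str) -> int:
    """Longest shared prefix of two exons (acceptor-side analogue)."""
    return longest_shared_prefix(
        locus.exon_sequence(exon_a), locus.exon_sequence(exon_b)
    )


@dataclass(frozen=True)
class AmbiguityEntry:
    exon_a: str
    exon_b: str
    shared_suffix_len: int

    @property
    def min_safe_overhang(self) -> int:
        return self.shared_suffix_len + 1


@dataclass(frozen=True)
class AmbiguityReport:
    """Shared terminal suffix lengths for ordered exon pairs."""

    entries: tuple[AmbiguityEntry, ...]

    def shared_suffix(self, exon_a: str, exon_b: str) -> int:
        for e in self.entries:
            if (e.exon_a, e.exon_b) == (exon_a, exon_b):
                return e.shared_suffix_len
        raise KeyError((exon_a, exon_b))


def ambiguity_report(
    locus: LocusReference, names: Sequence[str] | None = None
) -> AmbiguityReport:
    names = list(names) if names is not None else list(locus.exons.names)
    entries = [
        AmbiguityEntry(a, b, shared_terminal_ambiguity(locus, a, b))
        for a in names
        for b in names
        if a != b
    ]
    return AmbiguityReport(tuple(entries))


@dataclass(frozen=True)
class ProbeAudit:
    junction_name: str
    containing_transcripts: tuple[str, ...]
    specific: bool


def probe_cross_match_audit(
    probes: Sequence[JunctionProbe], transcripts: Sequence[TranscriptModel]
) -> list[ProbeAudit]:
    """Which transcripts contain each probe, and whether the probe is specific.

    A probe is *non-specific* if it occurs (on either strand) in a transcript
    that does not contain its junction.  At flank sizes exceeding the shared
    terminal suffix between the donor and the exon abutting the acceptor,
    probes cannot occur in junction-free transcripts — this audit verifies
    that property on concrete sequence.
    """
    audits = []
    for probe in probes:
        seq = probe.sequence
        rc = reverse_complement(seq)
        containing = tuple(
            t.name for t in transcripts if seq in t.sequence or rc in t.sequence
        )
        specific = all(
            probe.junction_name in t.junctions
            for t in transcripts
            if t.name in containing
        )
        audits.append(ProbeAudit(probe.junction_name, containing, specific))
    return audits
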