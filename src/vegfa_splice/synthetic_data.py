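"""Synthetic locus, transcript mixtures, read simulation and SJ fixtures.

The generator stands in for the real hg19 VEGFA window so that every
downstream stage — probe scanning, SJ-file extraction, spliced assignment,
amplicon classification — can be exercised end to end with a recorded ground
truth.  The toy locus mirrors the VEGFA exon architecture at reduced scale:
the same 14 named exons in the same order, with the same contiguity structure
(exon 1 = 1a|1b, exon 6 = 6a|6b|6c, exon 7 = 7a|7b and the terminal exon
8 = 8a|8b are genomically contiguous), and an *engineered* shared terminal
suffix between exons 7b and 8a (3 bases by default, matching the real locus)
which is what makes short-overhang placements at the 8b acceptor ambiguous.

Guarantees enforced by rejection sampling (all checked on the generated
sequence, never assumed):

* ``shared_terminal_ambiguity(7b, 8a)`` equals the requested suffix exactly;
* every default junction probe occurs exactly at its cognate junction in the
  transcript set and nowhere else, on either strand, in the locus or any
  transcript — with a Hamming-distance margin of at least 2, so that a single
  substitution error can never forge a probe hit;
* no other exon pair shares a terminal suffix as long as the probe flank.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .locus_model import (
    DEFAULT_ACCEPTORS,
    DEFAULT_DONORS,
    DEFAULT_FLANK,
    ExonCatalog,
    ExonDef,
    JunctionDef,
    LocusReference,
    TranscriptModel,
    assemble_transcript,
    build_junction_catalog,
    build_probes,
    shared_terminal_ambiguity,
)
from .sequtils import DNA_BASES, random_dna, reverse_complement

logger = logging.getLogger(__name__)

#: Exon order along the toy locus (mirrors the hg19 catalog).
TOY_EXON_ORDER: tuple[str, ...] = (
    "1a", "1b", "1A", "2", "3", "4", "5",
    "6a", "6b", "6c", "7a", "7b", "8a", "8b",
)

#: Scaled-down exon lengths.  8a keeps its real length (66); 8b is shortened
#: but left long enough (120) to accommodate acceptor-side overhangs up to
#: the default read length; exon 5 keeps its real 30 bases (it caps the probe
#: flank); 6b keeps a short length as in hg19 (18 -> 24, the probe minimum).
TOY_EXON_LENGTHS: dict[str, int] = {
    "1a": 60, "1b": 60, "1A": 40, "2": 30, "3": 50, "4": 40, "5": 30,
    "6a": 40, "6b": 24, "6c": 30, "7a": 50, "7b": 35, "8a": 66, "8b": 120,
}

#: Intron length following each exon.  Exons absent from the map are
#: genomically contiguous with their successor (1a|1b, 6a|6b|6c, 7a|7b, 8a|8b).
TOY_INTRON_LENGTHS: dict[str, int] = {
    "1b": 200, "1A": 250, "2": 300, "3": 150, "4": 100, "5": 400,
    "6c": 350, "7b": 300,
}

#: Exon chains of the canonical isoform models.  All carry the contiguous
#: read-through terminal exon 8 (8a followed immediately by 8b).
CANONICAL_CHAINS: dict[str, tuple[str, ...]] = {
    "VEGFA_121": ("1a", "1b", "2", "3", "4", "5", "8a", "8b"),
    "VEGFA_145": ("1a", "1b", "2", "3", "4", "5", "6a", "8a", "8b"),
    "VEGFA_148": ("1a", "1b", "2", "3", "4", "5", "7a", "8a", "8b"),
    "VEGFA_165": ("1a", "1b", "2", "3", "4", "5", "7a", "7b", "8a", "8b"),
    "VEGFA_183": ("1a", "1b", "2", "3", "4", "5", "6a", "6b", "7a", "7b", "8a", "8b"),
    "VEGFA_189": ("1a", "1b", "2", "3", "4", "5", "6a", "6b", "6c", "7a", "7b", "8a", "8b"),
}

#: Exon chains of the putative b-isoform models (splice directly into 8b).
B_ISOFORM_CHAINS: dict[str, tuple[str, ...]] = {
    "VEGFA_121b": ("1a", "1b", "2", "3", "4", "5", "8b"),
    "VEGFA_165b": ("1a", "1b", "2", "3", "4", "5", "7a", "7b", "8b"),
}


@dataclass(frozen=True)
class ToyLocusSpec:
    """Parameters of the toy locus generator."""

    exon_lengths: Mapping[str, int] = field(default_factory=lambda: dict(TOY_EXON_LENGTHS))
    intron_lengths: Mapping[str, int] = field(default_factory=lambda: dict(TOY_INTRON_LENGTHS))
    engineered_shared_suffix: int = 3
    seed: int = 0
    flank: int = DEFAULT_FLANK
    max_attempts: int = 200

    def __post_init__(self) -> None:
        if self.engineered_shared_suffix < 0:
            raise ValidationError("engineered_shared_suffix must be >= 0")
        probe_exons = set(DEFAULT_DONORS) | set(DEFAULT_ACCEPTORS)
        for name, length in self.exon_lengths.items():
            if length < 2:
                raise ValidationError(f"exon {name}: length must be >= 2")
            if name in probe_exons and length < 2 * self.flank + 2:
                raise ValidationError(
                    f"exon {name}: probe exons need length >= {2 * self.flank + 2}"
                )
        s = self.engineered_shared_suffix
        if s >= min(self.exon_lengths["7b"], self.exon_lengths["8a"]):
            raise ValidationError("engineered suffix must be shorter than exons 7b/8a")


def _toy_catalog(spec: ToyLocusSpec) -> tuple[ExonCatalog, int]:
    pos = 1
    exons = []
    for name in TOY_EXON_ORDER:
        length = spec.exon_lengths[name]
        exons.append(ExonDef(name, "toy1", pos, pos + length - 1, "+"))
        pos += length + spec.intron_lengths.get(name, 0)
    return ExonCatalog(exons), pos - 1


def canonical_transcripts(locus: LocusReference) -> dict[str, TranscriptModel]:
    """The six canonical isoform models assembled on ``locus``."""
    return {
        name: assemble_transcript(locus, name, chain)
        for name, chain in CANONICAL_CHAINS.items()
    }


def b_isoform_transcripts(locus: LocusReference) -> dict[str, TranscriptModel]:
    """The putative 8b-spliced isoform models assembled on ``locus``."""
    return {
        name: assemble_transcript(locus, name, chain)
        for name, chain in B_ISOFORM_CHAINS.items()
    }


def _window_is_cognate(
    label: str,
    start: int,
    probe_name: str,
    flank: int,
    cognate: Mapping[str, dict[str, int]],
) -> bool:
    sites = cognate.get(label)
    return sites is not None and sites.get(probe_name) == start


def _probe_clash(
    probe_name: str,
    probe_seq: str,
    sequences: Mapping[str, str],
    cognate: Mapping[str, dict[str, int]],
) -> bool:
    """True if any non-cognate window sits within Hamming distance 1 of the probe."""
    k = len(probe_seq)
    flank = k // 2
    targets = (probe_seq, reverse_complement(probe_seq))
    for label, seq in sequences.items():
        for start in range(len(seq) - k + 1):
            window = seq[start : start + k]
            for target in targets:
                mismatches = 0
                for x, y in zip(window, target):
                    if x != y:
                        mismatches += 1
                        if mismatches > 1:
                            break
                if mismatches <= 1:
                    if (
                        target is probe_seq
                        and mismatches == 0
                        and _window_is_cognate(label, start, probe_name, flank, cognate)
                    ):
                        continue
                    return True
    return False


def make_toy_locus(spec: ToyLocusSpec | None = None) -> LocusReference:
    """Generate a toy locus satisfying the documented probe-specificity guarantees.

    Deterministic for a given ``spec.seed``.  Raises after ``max_attempts``
    failed rejection-sampling rounds (suggesting longer exons).
    """
    spec = spec or ToyLocusSpec()
    catalog, total = _toy_catalog(spec)
    rng = np.random.default_rng(spec.seed)
    s = spec.engineered_shared_suffix

    for _ in range(spec.max_attempts):
        seq = list(random_dna(rng, total))
        e7b, e8a = catalog["7b"], catalog["8a"]
        # Engineer the shared terminal suffix: copy 8a's last s bases onto 7b
        # and force the preceding base to differ so the suffix is exactly s.
        for i in range(s):
            seq[e7b.end - 1 - i] = seq[e8a.end - 1 - i]
        a_base = seq[e8a.end - 1 - s]
        alternatives = [b for b in DNA_BASES if b != a_base]
        seq[e7b.end - 1 - s] = alternatives[int(rng.integers(0, 3))]

        locus = LocusReference("toy1", 1, total, "".join(seq), catalog)
        if _toy_locus_ok(locus, spec):
            return locus

    raise ValidationError(
        f"could not generate a specific toy locus in {spec.max_attempts} attempts; "
        "try longer exons or a different seed"
    )


def _toy_locus_ok(locus: LocusReference, spec: ToyLocusSpec) -> bool:
    s = spec.engineered_shared_suffix
    if shared_terminal_ambiguity(locus, "7b", "8a") != s:
        return False
    # No other exon pair may share a terminal suffix as long as the flank.
    names = locus.exons.names
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if {a, b} == {"7b", "8a"}:
                continue
            if shared_terminal_ambiguity(locus, a, b) >= spec.flank:
                return False

    junctions = build_junction_catalog(locus.exons, DEFAULT_DONORS, DEFAULT_ACCEPTORS)
    probes = build_probes(locus, junctions, spec.flank)
    transcripts = {**canonical_transcripts(locus), **b_isoform_transcripts(locus)}
    sequences = {"locus": locus.sequence}
    cognate: dict[str, dict[str, int]] = {}
    for name, t in transcripts.items():
        sequences[name] = t.sequence
        cognate[name] = {jn: p - spec.flank for jn, p in t.junction_offsets}
    for probe in probes:
        if _probe_clash(probe.junction_name, probe.sequence, sequences, cognate):
            return False
    return True


@dataclass(frozen=True)
class SimConfig:
    """Read-simulation parameters."""

    seed: int = 0
    n_reads: int = 1000
    read_length: int = 100
    paired: bool = False
    fragment_length: int = 250
    error_rate: float = 0.0
    isoform_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValidationError("n_reads must be >= 0")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValidationError("error_rate must be in [0, 1)")
        if self.read_length < 1:
            raise ValidationError("read_length must be >= 1")
        if self.paired and self.fragment_length < self.read_length:
            raise ValidationError("fragment_length must be >= read_length")
        if self.isoform_weights:
            weights = list(self.isoform_weights.values())
            if any(w < 0 for w in weights) or sum(weights) <= 0:
                raise ValidationError("isoform weights must be >= 0 with positive sum")


@dataclass
class SimulatedReads:
    """Simulated reads plus their per-read ground truth.

    ``truth`` columns: read_id, transcript, start (0-based offset of the read
    window in the transcript), strand, junctions.  ``junctions`` encodes the
    splice junctions spanned with at least one base on each side as
    ``name:donor_overhang:acceptor_overhang`` joined by commas.
    """

    reads: list[tuple[str, str]]
    truth: pd.DataFrame
    paired: bool = False


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0.0:
        return seq
    mask = rng.random(len(seq)) < error_rate
    if not mask.any():
        return seq
    out = list(seq)
    for pos in np.flatnonzero(mask):
        base = out[pos]
        choices = [b for b in DNA_BASES if b != base]
        out[pos] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def _spanned(transcript: TranscriptModel, start: int, length: int) -> str:
    hits = []
    for name, p in transcript.junction_offsets:
        if start < p < start + length:
            hits.append(f"{name}:{p - start}:{start + length - p}")
    return ",".join(hits)


def simulate_reads(
    locus: LocusReference,
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    config: SimConfig,
) -> SimulatedReads:
    """Draw reads from a weighted isoform mixture with substitution errors.

    Reads are drawn by choosing a transcript proportional to its weight, a
    uniform start over valid positions, a random strand (reverse complement
    with probability 1/2) and i.i.d. substitutions at ``error_rate``.  Paired
    mode emits two mates from opposite ends of a ``fragment_length`` fragment,
    written as separate reads (``/1`` and ``/2``) and counted as two reads
    downstream.
    """
    if isinstance(transcripts, Mapping):
        pool = list(transcripts.values())
    else:
        pool = list(transcripts)
    if config.isoform_weights:
        by_name = {t.name: t for t in pool}
        missing = set(config.isoform_weights) - set(by_name)
        if missing:
            raise ValidationError(f"weights refer to unknown transcripts: {sorted(missing)}")
        pool = [by_name[n] for n in config.isoform_weights if config.isoform_weights[n] > 0]
        weights = np.array([config.isoform_weights[t.name] for t in pool], float)
    else:
        weights = np.ones(len(pool), float)
    if not pool:
        raise ValidationError("no transcripts with positive weight")
    weights = weights / weights.sum()

    span = config.fragment_length if config.paired else config.read_length
    min_len = min(t.length for t in pool)
    if span > min_len:
        raise ValidationError(
            f"read/fragment span {span} exceeds shortest transcript length {min_len}"
        )

    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    t_idx = rng.choice(len(pool), size=n, p=weights)
    lengths = np.array([t.length for t in pool])
    starts = np.floor(rng.random(n) * (lengths[t_idx] - span + 1)).astype(np.int64)
    reverse = rng.random(n) < 0.5

    reads: list[tuple[str, str]] = []
    rows: list[tuple[str, str, int, str, str]] = []
    L = config.read_length
    for i in range(n):
        t = pool[t_idx[i]]
        start = int(starts[i])
        strand = "-" if reverse[i] else "+"
        if not config.paired:
            read = _mutate(t.sequence[start : start + L], rng, config.error_rate)
            if strand == "-":
                read = reverse_complement(read)
            rid = f"r{i:07d}"
            reads.append((rid, read))
            rows.append((rid, t.name, start, strand, _spanned(t, start, L)))
        else:
            frag = t.sequence[start : start + span]
            if strand == "-":
                frag = reverse_complement(frag)
            mate1 = _mutate(frag[:L], rng, config.error_rate)
            mate2 = _mutate(reverse_complement(frag[span - L :]), rng, config.error_rate)
            # Transcript-coordinate windows covered by the two mates.
            if strand == "+":
                w1, w2 = start, start + span - L
            else:
                w1, w2 = start + span - L, start
            rid = f"r{i:07d}"
            reads.append((f"{rid}/1", mate1))
            reads.append((f"{rid}/2", mate2))
            rows.append((f"{rid}/1", t.name, w1, strand, _spanned(t, w1, L)))
            rows.append((f"{rid}/2", t.name, w2, strand, _spanned(t, w2, L)))

    truth = pd.DataFrame(
        rows, columns=["read_id", "transcript", "start", "strand", "junctions"]
    )
    return SimulatedReads(reads, truth, paired=config.paired)


def truth_junction_counts(
    truth: pd.DataFrame, min_overhang: int = 1
) -> dict[str, int]:
    """Per-junction counts of reads spanning with >= min_overhang on each side."""
    counts: dict[str, int] = {}
    for encoded in truth["junctions"]:
        if not encoded:
            continue
        for item in encoded.split(","):
            name, d, a = item.rsplit(":", 2)
            if int(d) >= min_overhang and int(a) >= min_overhang:
                counts[name] = counts.get(name, 0) + 1
    return counts


def write_fastq(
    reads: Iterable[tuple[str, str]] | SimulatedReads, path: str | Path
) -> int:
    """Write reads as Phred+33 FASTQ (quality 'I'); gzip if path ends in .gz."""
    if isinstance(reads, SimulatedReads):
        reads = reads.reads
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as handle:
        for rid, seq in reads:
            handle.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def write_fastq_pair(
    sim: SimulatedReads, path1: str | Path, path2: str | Path
) -> tuple[int, int]:
    """Split paired simulated reads into two mate FASTQ files."""
    if not sim.paired:
        raise ValidationError("write_fastq_pair requires paired simulated reads")
    mates1 = [(rid, seq) for rid, seq in sim.reads if rid.endswith("/1")]
    mates2 = [(rid, seq) for rid, seq in sim.reads if rid.endswith("/2")]
    return write_fastq(mates1, path1), write_fastq(mates2, path2)


def simulate_amplicon_reads(
    templates: Sequence[tuple[TranscriptModel, float]],
    primers,
    config: SimConfig,
) -> SimulatedReads:
    """Full-length amplicon reads from a weighted template mixture.

    Each template is amplified in silico with ``primers`` (every template must
    yield a unique product); read counts per template follow the weights
    exactly (largest-remainder apportionment), with substitution errors and
    random read orientation.
    """
    from .amplicon import insilico_pcr

    if not templates:
        raise ValidationError("at least one template required")
    weights = np.array([w for _, w in templates], float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValidationError("template weights must be >= 0 with positive sum")
    products = [insilico_pcr(t, primers) for t, _ in templates]

    n = config.n_reads
    exact = weights / weights.sum() * n
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for j in np.argsort(-remainder)[: n - counts.sum()]:
        counts[j] += 1

    rng = np.random.default_rng(config.seed)
    reads: list[tuple[str, str]] = []
    rows = []
    i = 0
    for (template, _), product, count in zip(templates, products, counts):
        for _ in range(count):
            seq = _mutate(product.product_sequence, rng, config.error_rate)
            strand = "-" if rng.random() < 0.5 else "+"
            if strand == "-":
                seq = reverse_complement(seq)
            rid = f"a{i:07d}"
            reads.append((rid, seq))
            rows.append((rid, template.name, 0, strand, ""))
            i += 1
    truth = pd.DataFrame(
        rows, columns=["read_id", "transcript", "start", "strand", "junctions"]
    )
    return SimulatedReads(reads, truth)


def write_sj_fixture(
    counts: Mapping[JunctionDef, tuple[int, int, int]],
    chrom: str,
    path: str | Path,
) -> None:
    """Write a 9-column SJ-dialect file from per-junction counts.

    Columns: chrom, intron first, intron last (1-based inclusive), strand
    code (1 = plus), motif code (1 = GT/AG), annotated flag, unique-read
    count, multimapping count, max overhang.  Strand/motif codes are emitted
    as defaults; the parser does not rely on them.
    """
    rows = []
    for junction, (unique, multi, max_overhang) in counts.items():
        if min(unique, multi, max_overhang) < 0:
            raise ValidationError("SJ counts must be non-negative")
        rows.append(
            (chrom, junction.intron_first, junction.intron_last, 1, 1, 0,
             unique, multi, max_overhang)
        )
    rows.sort(key=lambda r: (r[1], r[2]))
    with Path(path).open("w") as handle:
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")


def simulate_ratio_counts(
    true_ratios: Sequence[float], n_spanning: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Binomial junction-spanning counts for the 5-8a vs 7b-8a ratio analysis.

    For a tissue with true 5-8a:7b-8a ratio rho, each of ``n_spanning``
    junction-spanning reads is 5-8a with probability rho/(1+rho).  Returns a
    table with one row per tissue and columns '5-8a' and '7b-8a'.
    """
    rows = []
    for rho in true_ratios:
        if rho < 0:
            raise ValidationError("ratios must be >= 0")
        x = int(rng.binomial(n_spanning, rho / (1.0 + rho)))
        rows.append((x, n_spanning - x))
    return pd.DataFrame(
        rows,
        columns=["5-8a", "7b-8a"],
        index=[f"tissue{i + 1:02d}" for i in range(len(rows))],
    )
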