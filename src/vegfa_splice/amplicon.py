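"""In-silico PCR and junction classification of amplicon sequencing reads.

The RT-PCR experiment amplifies across the VEGFA exon 7-8 junction with a
forward primer in exon 7 and a reverse primer in exon 8a: canonical 7b-8a
templates yield a 235 bp product and 7b-8b templates a 169 bp product, while
a universal exon 4/5 primer pair yields 115 bp from either.  Deep sequencing
of the product pool then classifies each read by the exon junction whose
probe it contains.

Primer conventions: the forward primer is given on the sense strand and must
match the template as-is; the reverse primer is given 5'->3' on the antisense
strand (as primers are ordered) and must match the template as its reverse
complement, downstream of the forward site.  The predicted product spans both
primer footprints inclusively.  Matching is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .errors import NonUniquePrimingError, NoProductError, ValidationError
from .locus_model import JunctionProbe, TranscriptModel
from .sequtils import is_dna, reverse_complement

#: Primer pair spanning the exon 7-8 splice junction.
EXON7_8_PRIMERS: "PrimerPair"
#: Primer pair within exons 4 and 5, common to canonical and b-type templates.
UNIVERSAL_EXON4_5_PRIMERS: "PrimerPair"
#: Exon-8-specific oligonucleotide used to prime reverse transcription.
RT_PRIMER_EXON8 = "TTCAGGTTTCTGGATTAAGGAC"


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    forward_name: str = "fwd"
    reverse_name: str = "rev"

    def __post_init__(self) -> None:
        for name, seq in ((self.forward_name, self.forward), (self.reverse_name, self.reverse)):
            if not is_dna(seq):
                raise ValidationError(f"primer {name}: must be non-empty ACGT")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


EXON7_8_PRIMERS = PrimerPair(
    "CAAGATCCGCAGACGTGTAA", "TCTGTCGATGGTGATGGTGT",
    "VEGFA_ex7_For1", "VEGFA_ex8_Rev",
)
UNIVERSAL_EXON4_5_PRIMERS = PrimerPair(
    "TGCGGATCAAACCTCACCAA", "GGCCCACAGGGATTTTCTTG",
    "VEGF_universal_For", "VEGF_universal_Rev",
)


@dataclass(frozen=True)
class AmpliconPrediction:
    """A predicted PCR product with 1-based inclusive template coordinates."""

    template_name: str
    product_length: int
    product_sequence: str
    forward_site: tuple[int, int]
    reverse_site: tuple[int, int]

    def __post_init__(self) -> None:
        expected = self.reverse_site[1] - self.forward_site[0] + 1
        if self.product_length != expected or self.product_length != len(
            self.product_sequence
        ):
            raise ValidationError(
                f"{self.template_name}: inconsistent product length"
            )


def _unique_site(template: str, query: str, label: str, template_name: str) -> int:
    sites = []
    pos = template.find(query)
    while pos != -1:
        sites.append(pos)
        pos = template.find(query, pos + 1)
    if not sites:
        raise NoProductError(f"{template_name}: no site for {label}")
    if len(sites) > 1:
        pretty = ", ".join(str(p + 1) for p in sites)
        raise NonUniquePrimingError(
            f"{template_name}: {label} primes at multiple sites ({pretty})"
        )
    return sites[0]


def insilico_pcr(template: TranscriptModel, primers: PrimerPair) -> AmpliconPrediction:
    """Predict the amplicon of a primer pair on a transcript template."""
    seq = template.sequence.upper()
    fwd = _unique_site(seq, primers.forward, primers.forward_name, template.name)
    rev_rc = reverse_complement(primers.reverse)
    rev = _unique_site(seq, rev_rc, primers.reverse_name, template.name)
    if rev < fwd:
        raise NoProductError(
            f"{template.name}: reverse primer site upstream of forward site"
        )
    product = seq[fwd : rev + len(rev_rc)]
    return AmpliconPrediction(
        template_name=template.name,
        product_length=len(product),
        product_sequence=product,
        forward_site=(fwd + 1, fwd + len(primers.forward)),
        reverse_site=(rev + 1, rev + len(rev_rc)),
    )


def primer_trim(read: str, primers: PrimerPair) -> tuple[str, bool]:
    """Strip exact primer footprints from an amplicon read.

    Handles both read orientations; reads without recognizable primers pass
    through untrimmed with ``trimmed=False``.
    """
    seq = read.upper()
    fwd = primers.forward
    rev_rc = reverse_complement(primers.reverse)
    if seq.startswith(fwd) and seq.endswith(rev_rc) and len(seq) >= len(fwd) + len(rev_rc):
        return seq[len(fwd) : len(seq) - len(rev_rc)], True
    rev = primers.reverse
    fwd_rc = reverse_complement(primers.forward)
    if seq.startswith(rev) and seq.endswith(fwd_rc) and len(seq) >= len(rev) + len(fwd_rc):
        return seq[len(rev) : len(seq) - len(fwd_rc)], True
    return read, False


@dataclass(frozen=True)
class AmpliconClassSummary:
    """Junction classification of an amplicon read pool.

    counts/percent cover each junction plus the 'ambiguous' and
    'unclassified' classes; counts sum to ``total`` and percentages to
    100 up to two-decimal rounding.
    """

    total: int
    counts: Mapping[str, int]
    percent: Mapping[str, float]
    ambiguous: int
    unclassified: int


def classify_amplicon_reads(
    reads,
    probes: Sequence[JunctionProbe],
    primers: PrimerPair | None = None,
) -> AmpliconClassSummary:
    """Assign each read to the unique junction whose probe it contains.

    ``reads`` is a FASTA/FASTQ path or an iterable of (id, sequence).  Probes
    are matched exactly on either strand.  Reads matching no probe are
    'unclassified'; reads matching two or more distinct probes are counted
    'ambiguous' and reported separately.  When ``primers`` is given, exact
    primer footprints are trimmed first (classification is unaffected for
    probes clear of the primer sites).
    """
    from .junction_scan import iter_reads

    if len({p.sequence for p in probes}) != len(probes):
        raise ValidationError("probe sequences must be distinct")
    if isinstance(reads, (str, Path)):
        reads = iter_reads(reads)

    counts = {p.junction_name: 0 for p in probes}
    seqs = [(p.junction_name, p.sequence.upper()) for p in probes]
    total = ambiguous = unclassified = 0
    for _, seq in reads:
        total += 1
        if primers is not None:
            seq, _ = primer_trim(seq, primers)
        seq = seq.upper()
        rc = reverse_complement(seq)
        hits = [name for name, probe in seqs if probe in seq or probe in rc]
        if not hits:
            unclassified += 1
        elif len(hits) > 1:
            ambiguous += 1
        else:
            counts[hits[0]] += 1

    classes = dict(counts)
    classes["ambiguous"] = ambiguous
    classes["unclassified"] = unclassified
    percent = {
        name: (round(100.0 * n / total, 2) if total else 0.0)
        for name, n in classes.items()
    }
    return AmpliconClassSummary(
        total=total,
        counts=counts,
        percent=percent,
        ambiguous=ambiguous,
        unclassified=unclassified,
    )


def write_amplicon_summary_tsv(summary: AmpliconClassSummary, path) -> None:
    import pandas as pd

    rows = [
        {"junction": name, "count": count, "percent": summary.percent[name]}
        for name, count in summary.counts.items()
    ]
    rows.append(
        {"junction": "ambiguous", "count": summary.ambiguous,
         "percent": summary.percent["ambiguous"]}
    )
    rows.append(
        {"junction": "unclassified", "count": summary.unclassified,
         "percent": summary.percent["unclassified"]}
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
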