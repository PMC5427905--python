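"""Detection-limit arithmetic, isoform ratios, cross-dataset correlation, reports.

Zero observations of a junction among n informative reads do not prove its
absence; they bound its proportion.  Two statistics are reported, clearly
labeled: the *one-read proportion* 100/n (the proportion a single observed
read would have represented — the argument used when surveying public data),
and a proper upper confidence bound for a zero count, either the exact
solution of (1-p)^n = 1 - confidence or the rule-of-three approximation 3/n.

Tissue splicing patterns are compared through the ratio of exon 5-8a to exon
7b-8a junction reads; agreement between independent datasets is measured by
the squared Pearson correlation of per-tissue ratio pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from .errors import ValidationError, ZeroDenominatorError

logger = logging.getLogger(__name__)

#: Total read counts of the three public multi-tissue RNA-seq compendia used
#: for the junction survey (reads; mates counted separately).
REFERENCE_DATASET_READS: tuple[float, float, float] = (5.0e9, 6.9e9, 2.8e9)

#: Exact-probe hits to the canonical exon 8a junctions in the same three
#: compendia; their sum is the denominator of the headline detection limit.
REFERENCE_CANONICAL_8A_HITS: tuple[int, int, int] = (10_188, 31_614, 8_428)

#: Mean canonical 8a-junction reads per tissue across the 14 tissues shared
#: by the two principal compendia (the per-tissue detection-limit argument).
REFERENCE_MEAN_8A_READS_PER_TISSUE: int = 1_807

RATIO_NUMERATOR = "5-8a"
RATIO_DENOMINATOR = "7b-8a"


def round_to_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (headline-report presentation)."""
    if x == 0:
        return 0.0
    if sig < 1:
        raise ValidationError("sig must be >= 1")
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def one_read_proportion(n_canonical: int) -> float:
    """Percentage of n that a single read would have represented (100/n)."""
    if n_canonical < 1:
        raise ValidationError("n_canonical must be >= 1")
    return 100.0 / n_canonical


def zero_hit_upper_bound(
    n: int, confidence: float = 0.95, method: str = "exact"
) -> float:
    """Upper bound (percent) on a proportion observed 0 times in n reads.

    ``exact`` solves (1-p)^n = 1-confidence; ``rule_of_three`` returns 3/n
    (its large-n approximation at 95% confidence).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not (0.0 < confidence < 1.0):
        raise ValidationError("confidence must be in (0, 1)")
    if method == "exact":
        return 100.0 * (1.0 - (1.0 - confidence) ** (1.0 / n))
    if method == "rule_of_three":
        return 100.0 * 3.0 / n
    raise ValidationError("method must be 'exact' or 'rule_of_three'")


@dataclass(frozen=True)
class DetectionLimit:
    """Zero-observation summary for one pool of canonical-junction reads."""

    label: str
    n_canonical: int
    one_read_percent: float
    upper95_percent: float


def detection_limit(
    n_canonical: int, label: str = "", confidence: float = 0.95
) -> DetectionLimit:
    return DetectionLimit(
        label=label,
        n_canonical=n_canonical,
        one_read_percent=one_read_proportion(n_canonical),
        upper95_percent=zero_hit_upper_bound(n_canonical, confidence, "exact"),
    )


def isoform_ratio(
    counts: Mapping[str, int],
    numerator: str = RATIO_NUMERATOR,
    denominator: str = RATIO_DENOMINATOR,
) -> float:
    """Ratio of numerator-junction to denominator-junction read counts."""
    denom = counts.get(denominator, 0)
    if denom <= 0:
        raise ZeroDenominatorError(
            f"cannot form {numerator}:{denominator} ratio with zero {denominator} count"
        )
    return counts.get(numerator, 0) / denom


@dataclass(frozen=True)
class RatioPoint:
    label: str
    ratio_a: float
    ratio_b: float


def ratio_points(
    table_a: Mapping[str, Mapping[str, int]] | pd.DataFrame,
    table_b: Mapping[str, Mapping[str, int]] | pd.DataFrame,
    numerator: str = RATIO_NUMERATOR,
    denominator: str = RATIO_DENOMINATOR,
) -> list[RatioPoint]:
    """Per-sample ratio pairs across two datasets, skipping zero denominators.

    Inputs are samples-by-junction count tables (DataFrame or nested
    mapping); only samples present in both are paired.  Samples whose
    denominator count is zero in either dataset are excluded with a log
    entry.
    """
    if isinstance(table_a, pd.DataFrame):
        table_a = table_a.to_dict(orient="index")
    if isinstance(table_b, pd.DataFrame):
        table_b = table_b.to_dict(orient="index")
    points = []
    for label in sorted(set(table_a) & set(table_b)):
        try:
            ra = isoform_ratio(table_a[label], numerator, denominator)
            rb = isoform_ratio(table_b[label], numerator, denominator)
        except ZeroDenominatorError:
            logger.info("sample %s excluded from ratio analysis (zero %s count)",
                        label, denominator)
            continue
        points.append(RatioPoint(label, ra, rb))
    return points


def cross_dataset_r2(points: Sequence[RatioPoint]) -> float:
    """Squared Pearson correlation of per-sample ratios across two datasets."""
    if len(points) < 3:
        raise ValidationError("need at least 3 ratio points")
    a = [p.ratio_a for p in points]
    b = [p.ratio_b for p in points]
    if len(set(a)) == 1 or len(set(b)) == 1:
        raise ValidationError("zero variance in one dataset's ratios")
    r = sps.pearsonr(a, b).statistic
    return float(r * r)


def format_bracketed(clean: int, artifact: int) -> str:
    """Render a clean count with the artifact-flagged count in brackets.

    ``0 (24)`` means zero retained assignments and 24 short-overhang artifact
    assignments; without artifacts the plain count is shown.
    """
    if artifact:
        return f"{clean} ({artifact})"
    return str(clean)


def build_report(
    outdir: str | Path,
    scan_results: Sequence | None = None,
    count_table=None,
    detection_limits: Sequence[DetectionLimit] | None = None,
    points: Sequence[RatioPoint] | None = None,
    artifact_summary: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Assemble deterministic TSVs plus a human-readable text report.

    Sections with no input are omitted (and noted in the log).  Headline
    percentages are rounded to one significant figure; the TSVs keep full
    precision.  Running twice on the same inputs produces byte-identical
    files.
    """
    if not any(
        x is not None for x in
        (scan_results, count_table, detection_limits, points, artifact_summary)
    ):
        raise ValidationError("build_report requires at least one input")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    lines: list[str] = ["VEGFA junction evidence report", ""]

    if scan_results is not None:
        from .junction_scan import write_scan_tsv

        path = outdir / "scan_results.tsv"
        write_scan_tsv(list(scan_results), path)
        written["scan_results"] = path
        lines.append("Probe scan (per-probe read counts):")
        for r in scan_results:
            pm = r.per_million or {}
            for name in sorted(r.counts):
                extra = f"\t{pm[name]:.6g}/M" if name in pm else ""
                lines.append(f"  {r.sample_id}\t{name}\t{r.counts[name]}{extra}")
        lines.append("")
    else:
        logger.info("report: no scan results; section omitted")

    if count_table is not None:
        path = outdir / "junction_counts.tsv"
        count_table.counts.to_csv(path, sep="\t")
        written["junction_counts"] = path
        if count_table.normalized is not None:
            npath = outdir / "junction_counts_normalized.tsv"
            count_table.normalized.to_csv(npath, sep="\t")
            written["junction_counts_normalized"] = npath
    else:
        logger.info("report: no junction count table; section omitted")

    if detection_limits is not None:
        path = outdir / "detection_limits.tsv"
        pd.DataFrame(
            [
                {
                    "label": d.label,
                    "n_canonical": d.n_canonical,
                    "one_read_percent": d.one_read_percent,
                    "upper95_percent": d.upper95_percent,
                }
                for d in detection_limits
            ]
        ).to_csv(path, sep="\t", index=False)
        written["detection_limits"] = path
        lines.append("Detection limits (zero 8b-junction observations):")
        for d in detection_limits:
            one = round_to_sig(d.one_read_percent, 1)
            upper = round_to_sig(d.upper95_percent, 1)
            lines.append(
                f"  {d.label or 'pool'}: n={d.n_canonical} canonical reads; "
                f"one read = {one:g}%; exact 95% upper bound = {upper:g}%"
            )
        lines.append("")
    else:
        logger.info("report: no detection limits; section omitted")

    if points is not None:
        path = outdir / "ratios.tsv"
        pd.DataFrame(
            [
                {"sample": p.label, "ratio_a": p.ratio_a, "ratio_b": p.ratio_b}
                for p in points
            ]
        ).to_csv(path, sep="\t", index=False)
        written["ratios"] = path
        lines.append(f"{RATIO_NUMERATOR}:{RATIO_DENOMINATOR} ratios "
                     f"({len(points)} samples):")
        if len(points) >= 3:
            lines.append(f"  cross-dataset R^2 = {cross_dataset_r2(points):.2f}")
        lines.append("")
    else:
        logger.info("report: no ratio points; section omitted")

    if artifact_summary is not None:
        lines.append("Junction assignments, clean (artifact-flagged):")
        for name, row in artifact_summary.iterrows():
            lines.append(
                f"  {name}\t{format_bracketed(int(row['clean']), int(row['artifact']))}"
            )
        lines.append("")
    else:
        logger.info("report: no artifact summary; section omitted")

    report_path = outdir / "report.txt"
    report_path.write_text("\n".join(lines))
    written["report"] = report_path
    return written
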