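"""Genomic-feature annotation of CNVRs and set-level summaries.

Each CNVR receives exactly one feature category, resolved from all of its
transcript overlaps by a fixed precedence (the conventional gene-centric
variant-annotation hierarchy):

    exonic_and_splicing > exonic > splicing > ncRNA_exonic > UTR5 > UTR3 >
    ncRNA_intronic > intronic > upstream_and_downstream > upstream >
    downstream > intergenic

"exonic" means overlap with the translated part of a coding exon; UTRs are
the untranslated exon parts 5'/3' of the CDS (strand-aware); "splicing" is
an intronic overlap within ``splice_window`` bp of an exon boundary;
upstream/downstream are strand-aware flanks (default 1 kb) outside the
transcript body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import InvalidArgumentError
from .discovery import Cnvr

__all__ = [
    "Transcript",
    "GeneModel",
    "FeatureAnnotation",
    "CATEGORY_PRECEDENCE",
    "annotate_cnvr",
    "annotate_cnvrs",
    "summarize_lengths",
    "summarize_chromosomes",
    "feature_fractions",
    "DEFAULT_LENGTH_EDGES",
]

CATEGORY_PRECEDENCE = (
    "exonic_and_splicing",
    "exonic",
    "splicing",
    "ncRNA_exonic",
    "UTR5",
    "UTR3",
    "ncRNA_intronic",
    "intronic",
    "upstream_and_downstream",
    "upstream",
    "downstream",
    "intergenic",
)

DEFAULT_LENGTH_EDGES = (0, 1_000, 2_000, 5_000, 10_000, 50_000, 100_000, 500_000)


@dataclass(frozen=True)
class Transcript:
    """One transcript in 0-based half-open coordinates."""

    gene: str
    transcript_id: str
    chrom: str
    strand: str  # "+" | "-"
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None  # genomic CDS span; None = non-coding

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidArgumentError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise InvalidArgumentError("transcript end <= start")
        prev_end = None
        for s, e in self.exons:
            if e <= s or s < self.start or e > self.end:
                raise InvalidArgumentError("exon outside transcript or empty")
            if prev_end is not None and s < prev_end:
                raise InvalidArgumentError("exons overlap or are unsorted")
            prev_end = e

    @property
    def coding(self) -> bool:
        return self.cds is not None


@dataclass
class GeneModel:
    """A set of transcripts plus the flank size used for upstream/downstream."""

    transcripts: list[Transcript]
    flank_size: int = 1_000

    def __post_init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for tx in self.transcripts:
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            tree.addi(tx.start - self.flank_size, tx.end + self.flank_size, tx)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Transcript]:
        """Transcripts whose flank-extended span overlaps [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda t: (t.start, t.end, t.transcript_id))


@dataclass(frozen=True)
class FeatureAnnotation:
    cnvr_id: str
    category: str
    gene_names: tuple[str, ...]
    warning: str | None = None


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and a1 > b0


def _transcript_labels(
    start: int, end: int, tx: Transcript, splice_window: int
) -> set[str]:
    """Feature labels the interval [start, end) picks up from one transcript."""
    labels: set[str] = set()
    body = _overlaps(start, end, tx.start, tx.end)
    if body:
        for es, ee in tx.exons:
            if not _overlaps(start, end, es, ee):
                continue
            if not tx.coding:
                labels.add("ncRNA_exonic")
                continue
            cs, ce = tx.cds
            if _overlaps(start, end, max(es, cs), min(ee, ce)):
                labels.add("exonic")
            # untranslated exon parts, 5'/3' by strand
            if es < cs and _overlaps(start, end, es, min(ee, cs)):
                labels.add("UTR5" if tx.strand == "+" else "UTR3")
            if ee > ce and _overlaps(start, end, max(es, ce), ee):
                labels.add("UTR3" if tx.strand == "+" else "UTR5")
        for (_, ie_start), (ie_end, _) in zip(tx.exons, tx.exons[1:]):
            # intron = [prev exon end, next exon start)
            if not _overlaps(start, end, ie_start, ie_end):
                continue
            near_boundary = _overlaps(
                start, end, ie_start, min(ie_start + splice_window, ie_end)
            ) or _overlaps(start, end, max(ie_end - splice_window, ie_start), ie_end)
            if tx.coding:
                labels.add("splicing" if near_boundary else "intronic")
            else:
                labels.add("ncRNA_intronic")
    return labels


def _flank_labels(
    start: int, end: int, tx: Transcript, flank_size: int
) -> set[str]:
    labels: set[str] = set()
    if tx.strand == "+":
        up = (tx.start - flank_size, tx.start)
        down = (tx.end, tx.end + flank_size)
    else:
        up = (tx.end, tx.end + flank_size)
        down = (tx.start - flank_size, tx.start)
    if _overlaps(start, end, *up):
        labels.add("upstream")
    if _overlaps(start, end, *down):
        labels.add("downstream")
    return labels


def annotate_cnvr(
    cnvr: Cnvr, model: GeneModel, splice_window: int = 2
) -> FeatureAnnotation:
    """Assign the single highest-precedence feature category to a CNVR."""
    if not model.transcripts:
        raise InvalidArgumentError("gene model is empty")
    warning = None
    if cnvr.chrom not in model.chromosomes:
        warning = f"chromosome {cnvr.chrom} absent from gene model"
        return FeatureAnnotation(cnvr.id, "intergenic", (), warning)

    labels: set[str] = set()
    genes: set[str] = set()
    for tx in model.overlapping(cnvr.chrom, cnvr.start, cnvr.end):
        tx_labels = _transcript_labels(cnvr.start, cnvr.end, tx, splice_window)
        tx_labels |= _flank_labels(cnvr.start, cnvr.end, tx, model.flank_size)
        if tx_labels:
            labels |= tx_labels
            genes.add(tx.gene)

    if "exonic" in labels and "splicing" in labels:
        labels.add("exonic_and_splicing")
    if "upstream" in labels and "downstream" in labels:
        labels.add("upstream_and_downstream")

    category = "intergenic"
    for cat in CATEGORY_PRECEDENCE:
        if cat in labels:
            category = cat
            break
    return FeatureAnnotation(cnvr.id, category, tuple(sorted(genes)), warning)


def annotate_cnvrs(
    cnvrs: list[Cnvr], model: GeneModel, splice_window: int = 2
) -> list[FeatureAnnotation]:
    return [annotate_cnvr(c, model, splice_window) for c in cnvrs]


def summarize_lengths(
    cnvrs: list[Cnvr], bin_edges: tuple[int, ...] = DEFAULT_LENGTH_EDGES
) -> pd.DataFrame:
    """Count CNVRs per half-open length bin [lo, hi) per kind.

    An open-ended overflow bin beyond the last edge guarantees the counts
    partition the set.
    """
    edges = list(bin_edges)
    if edges != sorted(edges):
        raise InvalidArgumentError("bin_edges must be sorted")
    bins = [(lo, hi) for lo, hi in zip(edges, edges[1:])] + [(edges[-1], np.inf)]
    labels = [
        f"[{lo},{'inf' if np.isinf(hi) else int(hi)})" for lo, hi in bins
    ]
    kinds = ("deletion", "duplication", "both")
    table = pd.DataFrame(0, index=labels, columns=list(kinds) + ["total"])
    table.index.name = "length_bin"
    for c in cnvrs:
        for (lo, hi), lab in zip(bins, labels):
            if lo <= c.length < hi:
                if c.kind in kinds:
                    table.loc[lab, c.kind] += 1
                table.loc[lab, "total"] += 1
                break
    return table


def summarize_chromosomes(cnvrs: list[Cnvr]) -> pd.DataFrame:
    """Per-chromosome, per-kind CNVR count and total length (bp)."""
    rows: dict[tuple[str, str], list[int]] = {}
    for c in cnvrs:
        key = (c.chrom, c.kind)
        entry = rows.setdefault(key, [0, 0])
        entry[0] += 1
        entry[1] += c.length
    table = pd.DataFrame(
        [
            {"chrom": chrom, "kind": kind, "count": n, "total_bp": bp}
            for (chrom, kind), (n, bp) in sorted(rows.items())
        ],
        columns=["chrom", "kind", "count", "total_bp"],
    )
    return table


def feature_fractions(annotations: list[FeatureAnnotation]) -> dict[str, float]:
    """Fraction of CNVRs per category; fractions sum to 1."""
    if not annotations:
        raise InvalidArgumentError("no annotations")
    counts: dict[str, int] = {}
    for a in annotations:
        counts[a.category] = counts.get(a.category, 0) + 1
    n = len(annotations)
    return {cat: counts[cat] / n for cat in CATEGORY_PRECEDENCE if cat in counts}
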