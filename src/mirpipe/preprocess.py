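"""Read classification through the QC cascade.

Collapsed reads are assigned, in order, to: too_short (below the length
floor), unaligned (no exact genome match on either strand), known_mirna
(full-length exact equality with a panel mature sequence), ncrna (exact
substring of a non-miRNA ncRNA), or unannotated (genome-matched reads left
over for novel-miRNA discovery).  All cascade tallies sum collapsed read
counts, not distinct sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ValidationError
from .io_core import (
    GenomicInterval,
    MiRNAAnnotation,
    PipelineConfig,
    ReadRecord,
    percentage,
    reverse_complement,
)

logger = logging.getLogger("mirpipe")

CATEGORIES = ("too_short", "unaligned", "known_mirna", "ncrna", "unannotated")


@dataclass
class ClassifiedRead:
    record: ReadRecord
    category: str
    matched_name: Optional[str] = None
    genome_hits: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.category == "known_mirna" and self.matched_name is None:
            raise ValidationError("known_mirna read must carry matched_name")
        if self.category == "too_short" and self.genome_hits:
            raise ValidationError("too_short read must not carry genome hits")


@dataclass
class QCCascade:
    """Stage-by-stage read tallies with the derived percentages.

    Invariants: raw >= high_quality >= genome_matched >= known_mirna_matched,
    and genome_matched partitions exactly into known + ncrna + remaining.
    """

    raw_reads: int
    high_quality_reads: int
    genome_matched: int
    known_mirna_matched: int
    ncrna_matched: int
    remaining_for_discovery: int

    def __post_init__(self) -> None:
        if not (
            self.raw_reads
            >= self.high_quality_reads
            >= self.genome_matched
            >= self.known_mirna_matched
        ):
            raise ValidationError(f"QC cascade counts are not monotone: {self}")
        if self.genome_matched != (
            self.known_mirna_matched + self.ncrna_matched + self.remaining_for_discovery
        ):
            raise ValidationError(f"QC cascade does not partition: {self}")

    @property
    def high_quality_pct(self) -> float:
        """High-quality reads as a percentage of raw reads."""
        return percentage(self.high_quality_reads, self.raw_reads)

    @property
    def genome_matched_pct(self) -> float:
        """Genome-matched reads as a percentage of high-quality reads."""
        return percentage(self.genome_matched, self.high_quality_reads)

    @property
    def known_mirna_pct(self) -> float:
        """Known-miRNA reads as a percentage of genome-matched reads."""
        return percentage(self.known_mirna_matched, self.genome_matched)


def find_genome_hits(sequence: str, genome: dict[str, str]) -> list[GenomicInterval]:
    """All exact occurrences of ``sequence`` in ``genome`` on either strand.

    The genome is stored plus-strand in RNA alphabet; a minus-strand hit
    means the reverse complement of the read occurs in the plus strand.
    Coordinates always refer to the plus strand, 0-based half-open.
    """
    hits: list[GenomicInterval] = []
    rc = reverse_complement(sequence)
    for chrom in sorted(genome):
        text = genome[chrom]
        for query, strand in ((sequence, "+"), (rc, "-")):
            start = text.find(query)
            while start != -1:
                hits.append(GenomicInterval(chrom, start, start + len(query), strand))
                start = text.find(query, start + 1)
    return hits


def classify_reads(
    reads: Iterable[ReadRecord],
    genome: dict[str, str],
    known_panel: Iterable[MiRNAAnnotation],
    ncrna_set: dict[str, str],
    config: PipelineConfig | None = None,
) -> tuple[list[ClassifiedRead], QCCascade]:
    """Run the classification cascade over collapsed reads.

    ``genome`` and ``ncrna_set`` map names to RNA-alphabet sequences;
    ``known_panel`` supplies mature sequences matched by full-length exact
    equality.  Returns the per-read classifications and the count cascade.
    """
    config = config or PipelineConfig()
    if not genome or not any(genome.values()):
        raise ValidationError("empty genome")

    mature_index: dict[str, str] = {}
    for ann in known_panel:
        mature_index.setdefault(ann.mature_sequence, ann.name)
    ncrna_seqs = list(ncrna_set.values())

    classified: list[ClassifiedRead] = []
    tallies = dict.fromkeys(CATEGORIES, 0)
    for rec in reads:
        if len(rec.sequence) < config.min_read_length:
            cr = ClassifiedRead(rec, "too_short")
        else:
            hits = find_genome_hits(rec.sequence, genome)
            if not hits:
                cr = ClassifiedRead(rec, "unaligned")
            elif rec.sequence in mature_index:
                cr = ClassifiedRead(
                    rec, "known_mirna", mature_index[rec.sequence], hits
                )
            elif any(rec.sequence in nc for nc in ncrna_seqs):
                cr = ClassifiedRead(rec, "ncrna", genome_hits=hits)
            else:
                cr = ClassifiedRead(rec, "unannotated", genome_hits=hits)
        tallies[cr.category] += rec.count
        classified.append(cr)

    raw = sum(tallies.values())
    high_quality = raw - tallies["too_short"]
    genome_matched = high_quality - tallies["unaligned"]
    cascade = QCCascade(
        raw_reads=raw,
        high_quality_reads=high_quality,
        genome_matched=genome_matched,
        known_mirna_matched=tallies["known_mirna"],
        ncrna_matched=tallies["ncrna"],
        remaining_for_discovery=tallies["unannotated"],
    )
    logger.info(
        "classify_reads: raw=%d high_quality=%d genome=%d known=%d ncrna=%d "
        "remaining=%d",
        cascade.raw_reads, cascade.high_quality_reads, cascade.genome_matched,
        cascade.known_mirna_matched, cascade.ncrna_matched,
        cascade.remaining_for_discovery,
    )
    return classified, cascade


def qc_report(cascade: QCCascade) -> str:
    """Render the cascade as TSV: stage, read count, percentage of parent."""
    rows = [
        ("raw", cascade.raw_reads, ""),
        ("high_quality", cascade.high_quality_reads,
         f"{cascade.high_quality_pct:.2f}"),
        ("genome_matched", cascade.genome_matched,
         f"{cascade.genome_matched_pct:.2f}"),
        ("known_mirna", cascade.known_mirna_matched,
         f"{cascade.known_mirna_pct:.2f}"),
        ("ncrna", cascade.ncrna_matched,
         f"{percentage(cascade.ncrna_matched, cascade.genome_matched):.2f}"),
        ("remaining_for_discovery", cascade.remaining_for_discovery,
         f"{percentage(cascade.remaining_for_discovery, cascade.genome_matched):.2f}"),
    ]
    lines = ["stage\treads\tpct_of_parent"]
    for stage, count, pct in rows:
        lines.append(f"{stage}\t{count}\t{pct}")
        logger.info("qc_report: %s\t%d\t%s", stage, count, pct)
    return "\n".join(lines) + "\n"


def write_classified_tsv(classified: Iterable[ClassifiedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tsequence\tcount\tcategory\tmatched_name\tgenome_hits\n"
        )
        for cr in classified:
            hits = ";".join(
                f"{h.chrom}:{h.start}-{h.end}({h.strand})" for h in cr.genome_hits
            )
            fh.write(
                f"{cr.record.read_id}\t{cr.record.sequence}\t{cr.record.count}\t"
                f"{cr.category}\t{cr.matched_name or ''}\t{hits}\n"
            )
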