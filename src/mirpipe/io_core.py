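"""Core domain types and file I/O shared by every pipeline stage.

Sequences are held in the RNA alphabet (A/C/G/U) internally: DNA input is
converted on read (T -> U) and converted back (U -> T) when writing files
that represent genomic DNA.  Genomic coordinates are 0-based half-open
throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, fields, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Optional

import yaml
from Bio import SeqIO

from .errors import ConfigError, FormatError, ValidationError

logger = logging.getLogger("mirpipe")

_RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_COUNT_HEADER_RE = re.compile(r"^seq-(\d+)_x(\d+)$")


def normalize_sequence(seq: str) -> str:
    """Upper-case ``seq``, map T to U, and reject anything outside ACGTU.

    Idempotent: normalizing an already-normalized sequence is the identity.
    """
    out = seq.upper().replace("T", "U")
    bad = set(out) - _RNA_ALPHABET
    if bad:
        raise ValidationError(
            f"sequence contains non-ACGTU characters: {sorted(bad)!r}"
        )
    if not out:
        raise ValidationError("sequence is empty")
    return out


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA space (A<->U, C<->G)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """RNA -> DNA alphabet for writing genome-context FASTA."""
    return seq.replace("U", "T")


def percentage(part: float, whole: float, decimals: int = 2) -> float:
    """``part / whole * 100`` rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding matches how read-cascade and summary
    percentages are conventionally printed.
    """
    if whole == 0:
        raise ValidationError("percentage denominator is zero")
    q = Decimal(part) / Decimal(whole) * 100
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValidationError(f"negative coordinate in {self}")
        if self.start >= self.end:
            raise ValidationError(
                f"interval start must be < end (got {self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def gap_to(self, other: "GenomicInterval") -> int:
        """Unsigned end-to-start gap; 0 when the intervals overlap or abut."""
        if self.chrom != other.chrom:
            raise ValidationError("gap between intervals on different chromosomes")
        lo, hi = sorted((self, other), key=lambda iv: iv.start)
        return max(0, hi.start - lo.end)


@dataclass
class ReadRecord:
    """One collapsed small-RNA read: unique sequence plus its multiplicity."""

    read_id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if self.count < 1:
            raise ValidationError(
                f"read {self.read_id!r}: count must be >= 1, got {self.count}"
            )
        m = _COUNT_HEADER_RE.match(self.read_id)
        if m and int(m.group(2)) != self.count:
            raise ValidationError(
                f"read id {self.read_id!r} encodes count {m.group(2)} "
                f"but record count is {self.count}"
            )


@dataclass
class MiRNAAnnotation:
    """A named mature miRNA with species tag, sequence and optional locus."""

    name: str
    species: str
    mature_sequence: str
    locus: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        self.mature_sequence = normalize_sequence(self.mature_sequence)
        if len(self.mature_sequence) < 9:
            raise ValidationError(
                f"{self.name}: mature sequence must be >= 9 nt so a 2-8 seed "
                f"exists (got {len(self.mature_sequence)})"
            )
        prefix = self.name.split("-", 1)[0]
        if len(prefix) == 3 and prefix.isalpha() and prefix != self.species:
            raise ValidationError(
                f"{self.name}: name prefix {prefix!r} does not match species "
                f"{self.species!r}"
            )


@dataclass
class PipelineConfig:
    """All thresholds used by the analysis stages.

    Defaults are the study's operating point: reads >= 18 nt are high
    quality, novel candidates need >= 10 total counts, differential
    expression requires p < 0.05 and a fold change beyond 2.0, conservation
    requires a perfect nt 2-8 seed match plus >= 50% overall identity,
    pathway relatedness needs >= 2 targeted primary genes, and loci within
    10 kb cluster.
    """

    min_read_length: int = 18
    min_candidate_count: int = 10
    p_threshold: float = 0.05
    fold_threshold: float = 2.0
    identity_threshold: float = 0.50
    seed_start: int = 2
    seed_end: int = 8
    min_pathway_targets: int = 2
    cluster_gap: int = 10_000
    rng_seed: int = 0
    pseudocount: float = 0.0
    log2_transform: bool = False
    identity_denominator: str = "longer"  # longer | shorter | alignment

    def __post_init__(self) -> None:
        if not (1 <= self.seed_start < self.seed_end):
            raise ConfigError(
                f"seed_start/seed_end: need 1 <= start < end, got "
                f"{self.seed_start}/{self.seed_end}"
            )
        if self.fold_threshold <= 1:
            raise ConfigError(f"fold_threshold must be > 1, got {self.fold_threshold}")
        if not (0 < self.identity_threshold <= 1):
            raise ConfigError(
                f"identity_threshold must be in (0, 1], got {self.identity_threshold}"
            )
        if not (0 < self.p_threshold < 1):
            raise ConfigError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        for key in ("min_read_length", "min_candidate_count", "min_pathway_targets",
                    "cluster_gap"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be non-negative")
        if self.identity_denominator not in ("longer", "shorter", "alignment"):
            raise ConfigError(
                f"identity_denominator must be longer/shorter/alignment, "
                f"got {self.identity_denominator!r}"
            )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_count_fasta(path: str | Path) -> list[ReadRecord]:
    """Read collapsed reads from FASTA.

    Headers of the dialect ``seq-<rank>_x<count>`` carry the collapsed read
    count; any other header gets count 1.  T is normalized to U.
    """
    path = Path(path)
    _check_fasta_shape(path)
    records: list[ReadRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        m = _COUNT_HEADER_RE.match(entry.id)
        if m:
            count = int(m.group(2))
            if count <= 0:
                raise ValidationError(
                    f"{path}: header {entry.id!r} encodes non-positive count"
                )
        else:
            count = 1
        records.append(ReadRecord(entry.id, str(entry.seq), count))
    logger.info("read_count_fasta: %s -> %d records", path, len(records))
    return records


def write_count_fasta(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.read_id}\n{rec.sequence}\n")


def read_fasta_dict(path: str | Path, rna: bool = True) -> dict[str, str]:
    """FASTA -> {id: sequence}; sequences normalized to RNA unless ``rna=False``."""
    path = Path(path)
    _check_fasta_shape(path)
    out: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq)
        out[entry.id] = normalize_sequence(seq) if rna else seq.upper()
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, dna: bool = False) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{to_dna(seq) if dna else seq}\n")


def _check_fasta_shape(path: Path) -> None:
    """Reject files whose first non-blank line is not a FASTA header.

    Bio.SeqIO silently returns nothing for such files; fail loudly instead,
    naming the offending line.
    """
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}:{lineno}: expected FASTA header line, got "
                        f"{line.strip()[:40]!r}"
                    )
                return


_ANNOT_COLUMNS = ("name", "species", "mature_sequence")


def read_annotation_table(path: str | Path) -> list[MiRNAAnnotation]:
    """Read a known-miRNA panel TSV.

    Required columns: name, species, mature_sequence.  Optional locus
    columns: chrom, start, end, strand (0-based half-open).
    """
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    has_locus = all(c in df.columns for c in ("chrom", "start", "end"))
    out: list[MiRNAAnnotation] = []
    for row in df.itertuples(index=False):
        locus = None
        if has_locus and isinstance(row.chrom, str) and row.chrom:
            strand = getattr(row, "strand", "+")
            if not isinstance(strand, str) or not strand:
                strand = "+"
            locus = GenomicInterval(row.chrom, int(row.start), int(row.end), strand)
        out.append(
            MiRNAAnnotation(row.name, row.species, row.mature_sequence, locus)
        )
    logger.info("read_annotation_table: %s -> %d records", path, len(out))
    return out


def write_annotation_table(
    annotations: Iterable[MiRNAAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("name\tspecies\tmature_sequence\tchrom\tstart\tend\tstrand\n")
        for a in annotations:
            if a.locus is not None:
                loc = f"{a.locus.chrom}\t{a.locus.start}\t{a.locus.end}\t{a.locus.strand}"
            else:
                loc = "\t\t\t"
            fh.write(f"{a.name}\t{a.species}\t{a.mature_sequence}\t{loc}\n")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file; absent file/keys fall back to defaults."""
    values: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FormatError(f"no such config file: {path}")
        with open(path) as fh:
            try:
                loaded = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise FormatError(f"{path}: invalid YAML: {exc}") from exc
        if not isinstance(loaded, dict):
            raise FormatError(f"{path}: config must be a key-value mapping")
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        values.update(loaded)
    values.update(overrides)
    return PipelineConfig(**values)


def read_gene_list(path: str | Path) -> list[str]:
    """Plain one-gene-per-line text file; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


__all__ = [
    "GenomicInterval", "ReadRecord", "MiRNAAnnotation", "PipelineConfig",
    "normalize_sequence", "reverse_complement", "to_dna", "percentage",
    "read_count_fasta", "write_count_fasta", "read_fasta_dict", "write_fasta",
    "read_annotation_table", "write_annotation_table", "load_config",
    "read_gene_list", "replace",
]
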