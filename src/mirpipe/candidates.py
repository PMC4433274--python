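"""Novel-miRNA candidate discovery from unannotated genome-matched reads.

This is a transparent, rule-based discovery stage: unannotated reads are
grouped into genomic loci, a precursor window is excised around the
highest-count read, the window is folded with a weighted Nussinov dynamic
program, and a locus is retained when the fold looks like a single
stem-loop hosting the mature read on one arm and the locus carries at
least ``min_candidate_count`` collapsed reads.  It deliberately trades the
probabilistic read-signature scoring of full miRNA-discovery tools
(miRDeep-class models) and thermodynamic nearest-neighbor folding
(RNAfold-class models) for deterministic, inspectable rules; the
``energy_score`` is a pairing-weight score, not a free energy in kcal/mol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import ValidationError
from .io_core import (
    GenomicInterval,
    PipelineConfig,
    reverse_complement,
)
from .preprocess import ClassifiedRead

logger = logging.getLogger("mirpipe")

# Pairing weights: a monotone proxy for duplex stability (strong GC, then
# AU, then GU wobble).  Non-complementary combinations are unpairable.
PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}

MIN_LOOP = 3  # sterically minimal hairpin loop

# Precursor excision window around the mature read, in nt.
PRECURSOR_UPSTREAM = 20
PRECURSOR_DOWNSTREAM = 50


@dataclass
class HairpinAssessment:
    precursor_sequence: str
    pairing: list[tuple[int, int]]     # 0-based (i, j) with i < j, nested
    n_pairs: int
    energy_score: float                # -(total pair weight); lower = more stable
    mature_arm: Optional[str] = None   # 5p | 3p | None
    mature_paired_fraction: float = 0.0
    is_hairpin: bool = False

    def dot_bracket(self) -> str:
        chars = ["." for _ in self.precursor_sequence]
        for i, j in self.pairing:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)


@dataclass
class NovelCandidate:
    candidate_id: str                  # seq-<rank>_x<count>
    mature_sequence: str
    precursor_locus: GenomicInterval
    hairpin: HairpinAssessment
    total_count: int
    per_sample_counts: list[int] = field(default_factory=list)


def _pair_weight(a: str, b: str) -> int:
    return PAIR_WEIGHTS.get((a, b), 0)


def fold_nussinov(sequence: str, min_loop: int = MIN_LOOP) -> HairpinAssessment:
    """Maximum-weight nested secondary structure by dynamic programming.

    W(i, j) = max over: j unpaired, or j paired with some k (k < j -
    min_loop, w(k, j) > 0) splitting the interval.  Traceback is
    deterministic: at ties the pairing branch with the smallest 5' partner
    index wins, which also keeps helices maximally outside (fewest, longest
    helices among co-optimal structures).
    """
    n = len(sequence)
    if n < min_loop + 2:
        raise ValidationError(
            f"sequence length {n} is below the foldable minimum {min_loop + 2}"
        )
    s = sequence
    # W[i][j]: best weight on s[i..j] inclusive
    W = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i][j - 1]
            for k in range(i, j - min_loop):
                w = _pair_weight(s[k], s[j])
                if w == 0:
                    continue
                left = W[i][k - 1] if k > i else 0
                inner = W[k + 1][j - 1] if k + 1 <= j - 1 else 0
                cand = left + inner + w
                if cand > best:
                    best = cand
            W[i][j] = best

    pairing: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = W[i][j]
        chosen = None
        for k in range(i, j - min_loop):
            w = _pair_weight(s[k], s[j])
            if w == 0:
                continue
            left = W[i][k - 1] if k > i else 0
            inner = W[k + 1][j - 1] if k + 1 <= j - 1 else 0
            if left + inner + w == target:
                chosen = k
                break
        if chosen is None:
            stack.append((i, j - 1))
        else:
            pairing.append((chosen, j))
            if chosen + 1 <= j - 1:
                stack.append((chosen + 1, j - 1))
            if chosen > i:
                stack.append((i, chosen - 1))

    pairing.sort()
    total = sum(_pair_weight(s[i], s[j]) for i, j in pairing)
    return HairpinAssessment(
        precursor_sequence=sequence,
        pairing=pairing,
        n_pairs=len(pairing),
        energy_score=-float(total),
    )


def _is_single_stem_loop(
    pairing: Sequence[tuple[int, int]], min_loop: int = MIN_LOOP
) -> bool:
    """True when all base pairs form one contiguous nesting chain.

    Pairs sorted by 5' index must be strictly nested in one another
    (i1 < i2 < j2 < j1).  Two side-by-side pairs indicate a second helix:
    tolerated only when the unpaired gap separating them is shorter than a
    minimal loop on either side, in which case they cannot host an
    independent stem-loop.
    """
    pairs = sorted(pairing)
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i1 < i2 < j2 < j1:
            continue  # nested
        # side-by-side (j1 < i2 by sortedness + non-crossing)
        gap = i2 - j1 - 1
        if gap >= min_loop:
            return False
    return True


def assess_hairpin(
    precursor: str,
    mature: str,
    config: PipelineConfig | None = None,
    min_loop: int = MIN_LOOP,
    min_paired_fraction: float = 0.6,
) -> HairpinAssessment:
    """Fold ``precursor`` and judge whether it is a plausible pre-miRNA.

    ``is_hairpin`` requires (a) a single stem-loop structure, (b) the
    mature sequence lying entirely 5' or 3' of the terminal loop, and (c)
    at least ``min_paired_fraction`` of mature bases paired.
    """
    first = precursor.find(mature)
    if first == -1:
        raise ValidationError("mature sequence not found in precursor")
    if precursor.find(mature, first + 1) != -1:
        raise ValidationError("mature sequence occurs more than once in precursor")

    fold = fold_nussinov(precursor, min_loop=min_loop)
    m_start, m_end = first, first + len(mature)  # half-open

    paired_positions = {i for p in fold.pairing for i in p}
    n_paired = sum(1 for i in range(m_start, m_end) if i in paired_positions)
    fold.mature_paired_fraction = n_paired / len(mature)

    if fold.pairing and _is_single_stem_loop(fold.pairing, min_loop):
        innermost = max(fold.pairing, key=lambda p: p[0])
        loop_start, loop_end = innermost  # terminal loop is (loop_start, loop_end)
        if m_end <= loop_start + 1:
            fold.mature_arm = "5p"
        elif m_start >= loop_end:
            fold.mature_arm = "3p"
        fold.is_hairpin = (
            fold.mature_arm is not None
            and fold.mature_paired_fraction >= min_paired_fraction
        )
    return fold


def _group_loci(
    hits: Sequence[tuple[GenomicInterval, int]], merge_gap: int = 30
) -> list[list[int]]:
    """Single-linkage grouping of hit intervals within ``merge_gap`` nt.

    ``hits`` is (interval, read index); returns groups of read indices.
    """
    groups: list[list[int]] = []
    by_chrom: dict[str, list[tuple[GenomicInterval, int]]] = {}
    for iv, idx in hits:
        by_chrom.setdefault(iv.chrom, []).append((iv, idx))
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom], key=lambda e: (e[0].start, e[0].end))
        current: list[int] = [entries[0][1]]
        reach = entries[0][0].end
        for iv, idx in entries[1:]:
            if iv.start - reach <= merge_gap:
                current.append(idx)
                reach = max(reach, iv.end)
            else:
                groups.append(current)
                current = [idx]
                reach = iv.end
        groups.append(current)
    return groups


def _excise(genome: dict[str, str], locus: GenomicInterval) -> str:
    seq = genome[locus.chrom][locus.start:locus.end]
    return reverse_complement(seq) if locus.strand == "-" else seq


def _precursor_windows(
    mature_hit: GenomicInterval, chrom_len: int
) -> list[GenomicInterval]:
    """The two candidate precursor windows around a mature hit.

    On the hit's strand: 20 nt upstream to 50 nt downstream (mature on the
    5' arm) and the mirror window (mature on the 3' arm).  Upstream means
    genomic-left on '+' and genomic-right on '-'.
    """
    s, e, strand = mature_hit.start, mature_hit.end, mature_hit.strand
    if strand == "+":
        spans = [(s - PRECURSOR_UPSTREAM, e + PRECURSOR_DOWNSTREAM),
                 (s - PRECURSOR_DOWNSTREAM, e + PRECURSOR_UPSTREAM)]
    else:
        spans = [(s - PRECURSOR_DOWNSTREAM, e + PRECURSOR_UPSTREAM),
                 (s - PRECURSOR_UPSTREAM, e + PRECURSOR_DOWNSTREAM)]
    out = []
    for lo, hi in spans:
        lo, hi = max(0, lo), min(chrom_len, hi)
        if hi - lo >= len(mature_hit):
            out.append(GenomicInterval(mature_hit.chrom, lo, hi, strand))
    return out


def discover_candidates(
    classified: Iterable[ClassifiedRead],
    genome: dict[str, str],
    config: PipelineConfig | None = None,
    per_sample_counts: Optional[dict[str, list[int]]] = None,
    merge_gap: int = 30,
) -> list[NovelCandidate]:
    """Group unannotated reads into loci and retain hairpin-like candidates.

    Only reads of category ``unannotated`` are considered (others are
    ignored, so the full classification list may be passed).  Per locus the
    highest-count read is the putative mature; both precursor windows are
    folded and the better assessment (hairpin first, then lower
    energy_score) decides.  A candidate is retained iff the hairpin check
    passes and the locus total count reaches ``min_candidate_count``.
    ``per_sample_counts`` optionally maps read sequence -> per-sample count
    vector, carried through to the report.
    """
    config = config or PipelineConfig()
    reads = [cr for cr in classified if cr.category == "unannotated"]
    for cr in reads:
        if not cr.genome_hits:
            raise ValidationError(
                f"unannotated read {cr.record.read_id!r} carries no genome hits"
            )

    hit_list: list[tuple[GenomicInterval, int]] = []
    for idx, cr in enumerate(reads):
        for hit in cr.genome_hits:
            hit_list.append((hit, idx))
    if not hit_list:
        return []

    candidates: list[NovelCandidate] = []
    seen_loci: set[tuple[str, int, int, str]] = set()
    for group in _group_loci(hit_list, merge_gap):
        members = sorted(set(group))
        total = sum(reads[i].record.count for i in members)
        # mature = highest-count read; ties break on sequence for determinism
        mature_read = min(
            (reads[i] for i in members),
            key=lambda cr: (-cr.record.count, cr.record.sequence),
        )
        mature = mature_read.record.sequence
        best: Optional[tuple[HairpinAssessment, GenomicInterval]] = None
        for hit in mature_read.genome_hits:
            for window in _precursor_windows(hit, len(genome[hit.chrom])):
                precursor = _excise(genome, window)
                if mature not in precursor:
                    continue
                try:
                    fold = assess_hairpin(precursor, mature, config)
                except ValidationError:
                    continue
                key = (fold.is_hairpin, -fold.energy_score)
                if best is None or key > (best[0].is_hairpin, -best[0].energy_score):
                    best = (fold, window)
        if best is None or not best[0].is_hairpin:
            continue
        if total < config.min_candidate_count:
            logger.info(
                "discover_candidates: hairpin locus at %s dropped "
                "(count %d < %d)", best[1], total, config.min_candidate_count,
            )
            continue
        locus_key = (best[1].chrom, best[1].start, best[1].end, best[1].strand)
        if locus_key in seen_loci:
            continue
        seen_loci.add(locus_key)
        psc = list(per_sample_counts.get(mature, [])) if per_sample_counts else []
        candidates.append(NovelCandidate(
            candidate_id="",  # assigned after ranking
            mature_sequence=mature,
            precursor_locus=best[1],
            hairpin=best[0],
            total_count=total,
            per_sample_counts=psc,
        ))

    candidates.sort(key=lambda c: (-c.total_count, c.mature_sequence))
    for rank, cand in enumerate(candidates, start=1):
        cand.candidate_id = f"seq-{rank}_x{cand.total_count}"
    logger.info("discover_candidates: %d reads -> %d retained candidates",
                len(reads), len(candidates))
    return candidates


def write_candidates_tsv(candidates: Sequence[NovelCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "candidate_id\tmature_sequence\tchrom\tstart\tend\tstrand\t"
            "total_count\tn_pairs\tenergy_score\tmature_arm\t"
            "mature_paired_fraction\tper_sample_counts\n"
        )
        for c in candidates:
            loc = c.precursor_locus
            fh.write(
                f"{c.candidate_id}\t{c.mature_sequence}\t{loc.chrom}\t"
                f"{loc.start}\t{loc.end}\t{loc.strand}\t{c.total_count}\t"
                f"{c.hairpin.n_pairs}\t{c.hairpin.energy_score}\t"
                f"{c.hairpin.mature_arm}\t"
                f"{c.hairpin.mature_paired_fraction:.3f}\t"
                f"{','.join(map(str, c.per_sample_counts))}\n"
            )


def write_precursors_fasta(candidates: Sequence[NovelCandidate], path) -> None:
    """Precursor sequences with dot-bracket structure lines for inspection."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.candidate_id}\n{c.hairpin.precursor_sequence}\n"
                     f";{c.hairpin.dot_bracket()}\n")
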