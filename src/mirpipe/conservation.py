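"""Seed extraction and cross-species conservation classification.

A candidate is conserved relative to a panel miRNA when its seed
(nucleotides 2-8 of the mature, 1-based inclusive) matches the panel seed
perfectly AND the overall mature sequences are at least 50% identical.
Identity counts matched nucleotides in a gap-free-scored global alignment
(matches +1, mismatches and gaps 0) over the length of the longer sequence
by default — the most conservative of the admissible denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

from .errors import ValidationError
from .io_core import MiRNAAnnotation, PipelineConfig, percentage

logger = logging.getLogger("mirpipe")


@dataclass(frozen=True)
class SeedSequence:
    seed: str
    source_id: str


@dataclass
class ConservationHit:
    candidate_id: str
    known_name: str
    species: str
    overall_identity: float  # percentage, 2 decimals
    seed_exact: bool
    conserved: bool
    same_species_seed_share: bool = False


def extract_seed(
    mature: str, config: PipelineConfig | None = None, source_id: str = ""
) -> SeedSequence:
    """Positional seed slice [seed_start, seed_end], 1-based inclusive."""
    config = config or PipelineConfig()
    if len(mature) < config.seed_end:
        raise ValidationError(
            f"mature sequence of length {len(mature)} has no "
            f"{config.seed_start}-{config.seed_end} seed"
        )
    return SeedSequence(mature[config.seed_start - 1:config.seed_end], source_id)


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=0,
    extend_gap_score=0,
)


def max_alignment_matches(a: str, b: str) -> int:
    """Maximum number of identical aligned positions over all global
    alignments with free gaps (equivalently, the longest common
    subsequence length)."""
    return int(_aligner.score(a, b))


def overall_identity(
    a: str, b: str, denominator: str = "longer"
) -> float:
    """Percent identity between two mature sequences, 2 decimals half-up.

    ``denominator`` selects what the match count is divided by: the longer
    sequence (default, conservative), the shorter, or the alignment length
    (max of the two lengths here, since free end gaps pad to the longer).
    """
    if not a or not b:
        raise ValidationError("overall_identity requires non-empty sequences")
    matches = max_alignment_matches(a, b)
    if denominator == "shorter":
        denom = min(len(a), len(b))
    else:  # longer / alignment coincide under free-gap match counting
        denom = max(len(a), len(b))
    return percentage(matches, denom)


def classify_conservation(
    candidates: Iterable,
    panel: Sequence[MiRNAAnnotation],
    config: PipelineConfig | None = None,
    candidate_species: str = "hsa",
) -> list[ConservationHit]:
    """Score every candidate x panel pair for seed sharing and conservation.

    ``candidates`` may be NovelCandidate objects or (id, mature_sequence)
    pairs.  Output is sorted by candidate id then descending identity, and
    is therefore invariant to panel order.  ``same_species_seed_share``
    flags seed sharing with a panel member of the candidate's own species
    (the basis for assigning candidates to known miRNA families).
    """
    config = config or PipelineConfig()
    if not panel:
        raise ValidationError("conservation panel is empty")
    pairs = []
    for cand in candidates:
        if isinstance(cand, tuple):
            pairs.append(cand)
        else:
            pairs.append((cand.candidate_id, cand.mature_sequence))

    hits: list[ConservationHit] = []
    for cand_id, mature in pairs:
        cand_seed = extract_seed(mature, config, cand_id).seed
        for ann in panel:
            panel_seed = extract_seed(ann.mature_sequence, config, ann.name).seed
            seed_exact = cand_seed == panel_seed
            ident = overall_identity(
                mature, ann.mature_sequence, config.identity_denominator
            )
            conserved = seed_exact and ident >= config.identity_threshold * 100
            hits.append(ConservationHit(
                candidate_id=cand_id,
                known_name=ann.name,
                species=ann.species,
                overall_identity=ident,
                seed_exact=seed_exact,
                conserved=conserved,
                same_species_seed_share=(
                    seed_exact and ann.species == candidate_species
                ),
            ))
    hits.sort(key=lambda h: (h.candidate_id, -h.overall_identity, h.known_name))
    n_cons = sum(h.conserved for h in hits)
    logger.info("classify_conservation: %d pairs scored, %d conserved",
                len(hits), n_cons)
    return hits


def write_conservation_tsv(hits: Sequence[ConservationHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\tknown_name\tspecies\toverall_identity\t"
                 "seed_exact\tconserved\tsame_species_seed_share\n")
        for h in hits:
            fh.write(
                f"{h.candidate_id}\t{h.known_name}\t{h.species}\t"
                f"{h.overall_identity:.2f}\t{h.seed_exact}\t{h.conserved}\t"
                f"{h.same_species_seed_share}\n"
            )
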