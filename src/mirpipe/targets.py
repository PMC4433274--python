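"""Seed-complement target prediction and pathway-relatedness classification.

A gene is a predicted target of a miRNA when the reverse complement of the
miRNA's seed (nt 2-8) occurs exactly somewhere in the gene's 3'UTR.  A
miRNA is related to a pathway when it targets at least
``min_pathway_targets`` (default 2) distinct primary genes of that
pathway.  The same seed rule is applied to known miRNAs and novel
candidates alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from .conservation import extract_seed
from .errors import ValidationError
from .expression import DECall
from .io_core import PipelineConfig, percentage, reverse_complement

logger = logging.getLogger("mirpipe")


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    gene_id: str
    utr_offset: int      # 0-based start of the site within the UTR
    site_sequence: str   # reverse complement of the seed


@dataclass
class PathwayAssessment:
    mirna_id: str
    pathway_name: str
    targeted_primary_genes: set[str]
    n_targeted: int
    related: bool


def default_tgfb_pathway() -> list[str]:
    """The bundled TGF-beta primary gene set (ligands, receptors, SMADs)."""
    text = resources.files("mirpipe").joinpath("data/tgfb_primary_genes.txt")
    return [ln.strip() for ln in text.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]


def predict_targets(
    mirnas: Iterable[tuple[str, str]],
    utrs: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> list[TargetSite]:
    """All exact seed-complement occurrences of each miRNA in each UTR.

    ``mirnas`` yields (id, mature_sequence) pairs; ``utrs`` maps gene id to
    RNA-alphabet 3'UTR.  Every occurrence is reported, including
    overlapping ones.
    """
    config = config or PipelineConfig()
    if not utrs:
        logger.warning("predict_targets: empty UTR set")
        return []
    sites: list[TargetSite] = []
    for mirna_id, mature in mirnas:
        seed = extract_seed(mature, config, mirna_id).seed
        site_seq = reverse_complement(seed)
        for gene_id in sorted(utrs):
            utr = utrs[gene_id]
            pos = utr.find(site_seq)
            while pos != -1:
                sites.append(TargetSite(mirna_id, gene_id, pos, site_seq))
                pos = utr.find(site_seq, pos + 1)
    logger.info("predict_targets: %d sites found", len(sites))
    return sites


def assess_pathway(
    sites: Iterable[TargetSite],
    pathway_genes: set[str],
    config: PipelineConfig | None = None,
    pathway_name: str = "TGF-beta",
    mirna_ids: Optional[Iterable[str]] = None,
) -> list[PathwayAssessment]:
    """Count distinct targeted pathway genes per miRNA and flag relatedness.

    ``mirna_ids`` optionally forces an assessment row (n=0) for miRNAs
    without any site.
    """
    config = config or PipelineConfig()
    targeted: dict[str, set[str]] = {}
    for site in sites:
        targeted.setdefault(site.mirna_id, set())
        if site.gene_id in pathway_genes:
            targeted[site.mirna_id].add(site.gene_id)
    if mirna_ids is not None:
        for mid in mirna_ids:
            targeted.setdefault(mid, set())
    out = []
    for mirna_id in sorted(targeted):
        genes = targeted[mirna_id]
        out.append(PathwayAssessment(
            mirna_id=mirna_id,
            pathway_name=pathway_name,
            targeted_primary_genes=genes,
            n_targeted=len(genes),
            related=len(genes) >= config.min_pathway_targets,
        ))
    logger.info("assess_pathway: %d miRNAs assessed, %d related",
                len(out), sum(a.related for a in out))
    return out


@dataclass
class PathwaySummary:
    """Pathway-related miRNAs partitioned by origin and DE direction."""

    cells: dict[tuple[str, str], int]  # (origin in {known, novel}, direction)
    n_related: int
    n_de_novel: int
    related_novel_pct: float           # related novel / DE novel, 2 decimals


def pathway_summary(
    assessments: Sequence[PathwayAssessment],
    de_calls: Sequence[DECall],
    novel_ids: Optional[set[str]] = None,
) -> PathwaySummary:
    """Cross-tabulate pathway-related miRNAs by known/novel and up/down.

    ``novel_ids`` marks which miRNA ids are novel candidates; ids in the
    seq-<rank>_x<count> dialect are treated as novel when it is omitted.
    miRNAs assessed but absent from the DE calls are warned about and
    excluded.
    """
    de_by_id = {c.mirna_id: c for c in de_calls}

    def origin(mid: str) -> str:
        if novel_ids is not None:
            return "novel" if mid in novel_ids else "known"
        return "novel" if mid.startswith("seq-") else "known"

    cells: dict[tuple[str, str], int] = {
        (o, d): 0 for o in ("known", "novel") for d in ("up", "down")
    }
    n_related = 0
    for a in assessments:
        if not a.related:
            continue
        call = de_by_id.get(a.mirna_id)
        if call is None:
            logger.warning("pathway_summary: %s has no DE call; excluded",
                           a.mirna_id)
            continue
        n_related += 1
        if call.direction in ("up", "down"):
            cells[(origin(a.mirna_id), call.direction)] += 1

    related_novel = cells[("novel", "up")] + cells[("novel", "down")]
    n_de_novel = sum(
        1 for c in de_calls if c.differential and origin(c.mirna_id) == "novel"
    )
    pct = percentage(related_novel, n_de_novel) if n_de_novel else 0.0
    return PathwaySummary(
        cells=cells,
        n_related=n_related,
        n_de_novel=n_de_novel,
        related_novel_pct=pct,
    )


def write_sites_tsv(sites: Sequence[TargetSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\tutr_offset\tsite_sequence\n")
        for s in sites:
            fh.write(f"{s.mirna_id}\t{s.gene_id}\t{s.utr_offset}\t{s.site_sequence}\n")


def write_pathway_summary_tsv(summary: PathwaySummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("origin\tdirection\tn\n")
        for (o, d), n in sorted(summary.cells.items()):
            fh.write(f"{o}\t{d}\t{n}\n")
        fh.write(f"total_related\t\t{summary.n_related}\n")
        fh.write(f"related_novel_pct_of_de_novel\t\t"
                 f"{summary.related_novel_pct:.2f}\n")
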