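"""Genomic proximity clustering of miRNA loci.

Loci on one chromosome whose end-to-start gaps chain within ``cluster_gap``
(default 10 kb) form a cluster; such miRNAs are often co-transcribed and
hence co-regulated, so member DE directions are cross-checked for
concordance.  Strand is ignored for clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .expression import DECall
from .io_core import GenomicInterval

logger = logging.getLogger("mirpipe")


@dataclass
class GenomicCluster:
    chrom: str
    members: list[tuple[str, GenomicInterval]]  # sorted by start
    span: int            # first start to last end
    max_gap_used: int


@dataclass
class ClusterConcordance:
    cluster: GenomicCluster
    directions: list[str]
    concordant: bool


def cluster_loci(
    loci: Iterable[tuple[str, GenomicInterval]], gap: int = 10_000
) -> list[GenomicCluster]:
    """Single-linkage chaining per chromosome; singletons are dropped.

    Consecutive loci (sorted by start) join when
    ``max(0, next.start - prev.end) <= gap``.  Output order and membership
    are invariant to input order.
    """
    by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for name, iv in loci:
        by_chrom.setdefault(iv.chrom, []).append((name, iv))

    clusters: list[GenomicCluster] = []
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom], key=lambda e: (e[1].start, e[1].end, e[0]))
        current = [entries[0]]
        reach = entries[0][1].end
        for name, iv in entries[1:]:
            if max(0, iv.start - reach) <= gap:
                current.append((name, iv))
                reach = max(reach, iv.end)
            else:
                if len(current) >= 2:
                    clusters.append(_make_cluster(chrom, current, gap))
                current = [(name, iv)]
                reach = iv.end
        if len(current) >= 2:
            clusters.append(_make_cluster(chrom, current, gap))
    logger.info("cluster_loci: %d clusters at gap %d", len(clusters), gap)
    return clusters


def _make_cluster(
    chrom: str, members: list[tuple[str, GenomicInterval]], gap: int
) -> GenomicCluster:
    start = min(iv.start for _, iv in members)
    end = max(iv.end for _, iv in members)
    return GenomicCluster(chrom=chrom, members=members, span=end - start,
                          max_gap_used=gap)


def cluster_de_concordance(
    clusters: Sequence[GenomicCluster],
    de_calls: Sequence[DECall] | Mapping[str, DECall],
) -> list[ClusterConcordance]:
    """Per cluster: member DE directions and an all-same-direction flag.

    A member without a DE call gets direction "none" (logged); the cluster
    can still be concordant when at most one member is missing and all the
    others agree on up or down.
    """
    if not isinstance(de_calls, Mapping):
        de_calls = {c.mirna_id: c for c in de_calls}
    out = []
    for cluster in clusters:
        directions = []
        n_missing = 0
        for name, _ in cluster.members:
            call = de_calls.get(name)
            if call is None:
                logger.info("cluster_de_concordance: no DE call for %s", name)
                n_missing += 1
                directions.append("none")
            else:
                directions.append(call.direction)
        present = [d for d in directions if d != "none"]
        concordant = (
            n_missing <= 1
            and len(present) >= 1
            and len(set(present)) == 1
            and present[0] in ("up", "down")
            and len(present) == len(directions) - n_missing
        )
        if n_missing == 0:
            concordant = len(set(directions)) == 1 and directions[0] in ("up", "down")
        out.append(ClusterConcordance(cluster, directions, concordant))
    return out


def write_clusters_tsv(concordances: Sequence[ClusterConcordance], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\tchrom\tspan\tmembers\tdirections\tconcordant\n")
        for k, cc in enumerate(concordances, start=1):
            names = ";".join(name for name, _ in cc.cluster.members)
            fh.write(
                f"cluster_{k}\t{cc.cluster.chrom}\t{cc.cluster.span}\t"
                f"{names}\t{';'.join(cc.directions)}\t{cc.concordant}\n"
            )
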