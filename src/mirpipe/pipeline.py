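"""End-to-end orchestration: simulate -> classify -> DE -> discover ->
conserve -> targets -> clusters -> qPCR, plus recovery scoring against the
generator's ground truth."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np

from .candidates import NovelCandidate, discover_candidates
from .clusters import ClusterConcordance, cluster_de_concordance, cluster_loci
from .conservation import ConservationHit, classify_conservation
from .expression import CountTable, DECall, call_de
from .io_core import PipelineConfig
from .preprocess import ClassifiedRead, QCCascade, classify_reads
from .qpcr import RelativeExpression, ddct, ngs_qpcr_correlation
from .synthetic import SimulatedStudy, SimulationSpec, simulate_all
from .targets import (
    PathwayAssessment,
    PathwaySummary,
    assess_pathway,
    pathway_summary,
    predict_targets,
)

logger = logging.getLogger("mirpipe")


@dataclass
class PipelineResult:
    study: SimulatedStudy
    cascades: dict[str, QCCascade]
    count_table: CountTable              # observed, known + novel rows
    de_calls: list[DECall]
    candidates: list[NovelCandidate]
    conservation_hits: list[ConservationHit]
    target_sites: list
    pathway_assessments: list[PathwayAssessment]
    summary: PathwaySummary
    cluster_concordance: list[ClusterConcordance]
    qpcr_results: list[RelativeExpression]
    ngs_qpcr_r: float
    ngs_qpcr_p: float
    candidate_by_mature: dict[str, NovelCandidate] = field(default_factory=dict)


def run_pipeline(
    spec: SimulationSpec | None = None,
    config: PipelineConfig | None = None,
    study: SimulatedStudy | None = None,
) -> PipelineResult:
    """Run every analysis stage on a simulated study.

    Either pass a pre-generated ``study`` or a ``spec`` to generate one.
    """
    config = config or PipelineConfig()
    if study is None:
        study = simulate_all(spec or SimulationSpec())

    # --- per-sample QC classification
    sample_ids = study.count_table.sample_ids
    cascades: dict[str, QCCascade] = {}
    classified: dict[str, list[ClassifiedRead]] = {}
    for sample in sample_ids:
        cls, cascade = classify_reads(
            study.reads_per_sample[sample], study.genome,
            study.annotations, study.ncrna, config,
        )
        classified[sample] = cls
        cascades[sample] = cascade

    # --- observed count table: known miRNA counts, genome-matched denominators
    known_names = [a.name for a in study.annotations]
    known_idx = {n: i for i, n in enumerate(known_names)}
    counts = np.zeros((len(known_names), len(sample_ids)), dtype=int)
    for j, sample in enumerate(sample_ids):
        for cr in classified[sample]:
            if cr.category == "known_mirna":
                counts[known_idx[cr.matched_name], j] += cr.record.count
    denominators = np.array(
        [cascades[s].genome_matched for s in sample_ids], dtype=float
    )

    # --- pool unannotated reads across samples for discovery
    pooled: dict[str, dict] = {}
    per_sample_counts: dict[str, list[int]] = {}
    for j, sample in enumerate(sample_ids):
        for cr in classified[sample]:
            if cr.category != "unannotated":
                continue
            seq = cr.record.sequence
            if seq not in pooled:
                pooled[seq] = {"count": 0, "hits": cr.genome_hits}
                per_sample_counts[seq] = [0] * len(sample_ids)
            pooled[seq]["count"] += cr.record.count
            per_sample_counts[seq][j] += cr.record.count
    from .io_core import ReadRecord
    pooled_reads = [
        ClassifiedRead(
            ReadRecord(f"pooled-{k + 1}", seq, info["count"]),
            "unannotated", genome_hits=info["hits"],
        )
        for k, (seq, info) in enumerate(sorted(pooled.items()))
    ]
    candidates = discover_candidates(
        pooled_reads, study.genome, config, per_sample_counts
    )
    candidate_by_mature = {c.mature_sequence: c for c in candidates}

    # --- DE over known + candidate rows
    if candidates:
        cand_counts = np.array(
            [c.per_sample_counts or [c.total_count] + [0] * (len(sample_ids) - 1)
             for c in candidates], dtype=int,
        )
        all_counts = np.vstack([counts, cand_counts])
        all_ids = known_names + [c.candidate_id for c in candidates]
    else:
        all_counts, all_ids = counts, known_names
    table = CountTable(
        mirna_ids=all_ids,
        sample_ids=sample_ids,
        groups=list(study.count_table.groups),
        counts=all_counts,
        denominators=denominators,
    )
    de_calls = call_de(table, config)
    de_by_id = {c.mirna_id: c for c in de_calls}

    # --- conservation of candidates against the known panel
    conservation_hits = (
        classify_conservation(candidates, study.annotations, config)
        if candidates else []
    )

    # --- seed-complement targets and pathway relatedness for DE miRNAs
    de_ids = [c.mirna_id for c in de_calls if c.differential]
    matures = {a.name: a.mature_sequence for a in study.annotations}
    matures.update({c.candidate_id: c.mature_sequence for c in candidates})
    mirna_seqs = [(mid, matures[mid]) for mid in de_ids if mid in matures]
    sites = predict_targets(mirna_seqs, study.utrs, config)
    assessments = assess_pathway(
        sites, set(study.pathway_genes), config,
        mirna_ids=[mid for mid, _ in mirna_seqs],
    )
    summary = pathway_summary(assessments, de_calls)

    # --- genomic clustering of DE miRNA loci
    loci = []
    for a in study.annotations:
        if a.locus is not None and de_by_id.get(a.name, None) is not None \
                and de_by_id[a.name].differential:
            loci.append((a.name, a.locus))
    for c in candidates:
        if de_by_id.get(c.candidate_id) and de_by_id[c.candidate_id].differential:
            loci.append((c.candidate_id, c.precursor_locus))
    clusters = cluster_loci(loci, config.cluster_gap)
    concordance = cluster_de_concordance(clusters, de_by_id)

    # --- qPCR cross-validation
    qpcr_results = ddct(study.ct_measurements)
    qpcr_ratios = {r.mirna_id: r.ratio for r in qpcr_results}
    ngs_ratios: dict[str, float] = {}
    for truth_id in qpcr_ratios:
        if truth_id in de_by_id:
            ngs_ratios[truth_id] = de_by_id[truth_id].ratio
        elif truth_id in study.truth.hairpin_matures:
            cand = candidate_by_mature.get(study.truth.hairpin_matures[truth_id])
            if cand is not None and cand.candidate_id in de_by_id:
                ngs_ratios[truth_id] = de_by_id[cand.candidate_id].ratio
    try:
        r, p, _ = ngs_qpcr_correlation(ngs_ratios, qpcr_ratios)
    except Exception:
        r, p = float("nan"), float("nan")
        logger.warning("ngs_qpcr_correlation: insufficient shared miRNAs")

    return PipelineResult(
        study=study, cascades=cascades, count_table=table, de_calls=de_calls,
        candidates=candidates, conservation_hits=conservation_hits,
        target_sites=sites, pathway_assessments=assessments, summary=summary,
        cluster_concordance=concordance, qpcr_results=qpcr_results,
        ngs_qpcr_r=r, ngs_qpcr_p=p, candidate_by_mature=candidate_by_mature,
    )


# ---------------------------------------------------------------------------
# Recovery scoring against ground truth
# ---------------------------------------------------------------------------


@dataclass
class RecoveryMetrics:
    hairpin_recovered: int
    hairpin_eligible: int        # planted hairpins with enough reads
    decoys_rejected: int
    n_decoys: int
    de_recovered: int            # true planted DE knowns called differential
    de_planted: int
    false_positive_nulls: int    # null knowns called differential
    n_nulls: int

    @property
    def hairpin_recovery_rate(self) -> float:
        return (self.hairpin_recovered / self.hairpin_eligible
                if self.hairpin_eligible else 1.0)

    @property
    def decoy_rejection_rate(self) -> float:
        return self.decoys_rejected / self.n_decoys if self.n_decoys else 1.0

    @property
    def de_recovery_rate(self) -> float:
        return self.de_recovered / self.de_planted if self.de_planted else 1.0

    @property
    def type1_rate(self) -> float:
        return self.false_positive_nulls / self.n_nulls if self.n_nulls else 0.0


def score_recovery(
    result: PipelineResult, config: PipelineConfig | None = None
) -> RecoveryMetrics:
    """Compare pipeline output with the generator's ground truth."""
    config = config or PipelineConfig()
    truth = result.study.truth
    de_by_id = {c.mirna_id: c for c in result.de_calls}

    # hairpin recovery: planted mature recovered as a candidate, among
    # hairpins whose pooled reads reach the count filter
    pooled_counts: dict[str, int] = {}
    for sample, cls in (
        (s, result.study.reads_per_sample[s])
        for s in result.count_table.sample_ids
    ):
        for rec in cls:
            pooled_counts[rec.sequence] = pooled_counts.get(rec.sequence, 0) \
                + rec.count
    eligible = [
        m for m in truth.hairpin_matures.values()
        if pooled_counts.get(m, 0) >= config.min_candidate_count
    ]
    recovered = sum(1 for m in eligible if m in result.candidate_by_mature)

    decoy_seqs = set(truth.decoy_reads.values())
    decoys_rejected = sum(
        1 for s in decoy_seqs if s not in result.candidate_by_mature
    )

    known_names = {a.name for a in result.study.annotations}
    planted_known = truth.true_de_set & known_names
    de_recovered = sum(
        1 for name in planted_known
        if name in de_by_id and de_by_id[name].differential
    )
    nulls = [n for n in known_names if n not in truth.true_de_set]
    false_pos = sum(
        1 for name in nulls
        if name in de_by_id and de_by_id[name].differential
    )
    return RecoveryMetrics(
        hairpin_recovered=recovered,
        hairpin_eligible=len(eligible),
        decoys_rejected=decoys_rejected,
        n_decoys=len(decoy_seqs),
        de_recovered=de_recovered,
        de_planted=len(planted_known),
        false_positive_nulls=false_pos,
        n_nulls=len(nulls),
    )
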