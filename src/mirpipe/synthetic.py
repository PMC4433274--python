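"""Synthetic study generator: every input the pipeline consumes, with the
statistical structure the analysis assumes, plus the ground truth needed to
score recovery.

The emulated design is two groups of three samples (mid- vs
late-gestation), a toy multi-chromosome genome carrying embedded known
miRNA loci (six of them arranged as clustered pairs within 10 kb,
co-regulated downwards), stem-loop precursors of novel miRNAs, shuffled
decoy loci, and non-miRNA ncRNA genes.  Counts are overdispersed around
group means (negative binomial; ``dispersion == 0`` is the exact
noise-free limit where counts equal their rounded means), sequencing depth
varies by +/-10% between samples so normalization is non-trivial, planted
fold changes exceed the 2.0-fold calling threshold, and 3'UTRs carry
planted seed-complement sites against a screened background.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .candidates import assess_hairpin, _precursor_windows, _excise
from .errors import GenerationError, ValidationError
from .expression import CountTable
from .io_core import (
    GenomicInterval,
    MiRNAAnnotation,
    PipelineConfig,
    ReadRecord,
    reverse_complement,
    write_annotation_table,
    write_count_fasta,
    write_fasta,
)
from .preprocess import find_genome_hits
from .qpcr import CtMeasurement
from .targets import default_tgfb_pathway

logger = logging.getLogger("mirpipe")

_BASES = np.array(list("ACGU"))
_MAX_RETRIES = 200


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults are the scaled-down study conditions: 3 vs 3 samples, a
    per-sample genome-matched depth of 100,000 reads (the study's 12-13 M
    scaled by ~1/125), mild overdispersion, and planted late/mid ratios of
    4.0 (up), 0.25 (down) or 1.0 (null) that straddle the 2.0-fold gate.
    """

    n_chromosomes: int = 6
    chrom_length: int = 80_000
    n_known_mirnas: int = 40
    n_novel_hairpins: int = 8
    n_decoy_loci: int = 8
    n_ncrna: int = 6
    n_samples_per_group: int = 3
    depth_per_sample: int = 100_000
    planted_fold_changes: Optional[dict[str, float]] = None
    dispersion: float = 0.05
    n_utrs: int = 24
    utr_length: int = 200
    planted_sites: Optional[dict[str, list[str]]] = None
    n_cluster_pairs: int = 6
    mature_length: int = 22
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for key in ("n_chromosomes", "chrom_length", "n_known_mirnas",
                    "n_samples_per_group", "depth_per_sample", "n_utrs",
                    "utr_length", "mature_length"):
            if getattr(self, key) <= 0:
                raise ValidationError(f"{key} must be positive")
        for key in ("n_novel_hairpins", "n_decoy_loci", "n_ncrna",
                    "n_cluster_pairs"):
            if getattr(self, key) < 0:
                raise ValidationError(f"{key} must be non-negative")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.planted_fold_changes is not None:
            if any(r <= 0 for r in self.planted_fold_changes.values()):
                raise ValidationError("planted ratios must be > 0")
        if 2 * self.n_cluster_pairs > self.n_known_mirnas:
            raise ValidationError("n_cluster_pairs needs 2 loci per pair")


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring recovery downstream."""

    true_de_set: set[str] = field(default_factory=set)
    planted_ratios: dict[str, float] = field(default_factory=dict)
    true_hairpin_loci: list[GenomicInterval] = field(default_factory=list)
    hairpin_matures: dict[str, str] = field(default_factory=dict)
    decoy_loci: list[GenomicInterval] = field(default_factory=list)
    decoy_reads: dict[str, str] = field(default_factory=dict)
    cluster_pairs: list[tuple[str, str]] = field(default_factory=list)
    true_target_pairs: list[tuple[str, str]] = field(default_factory=list)
    site_offsets: dict[str, dict[str, int]] = field(default_factory=dict)
    pathway_genes: list[str] = field(default_factory=list)
    per_sample_totals: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def iv(x: GenomicInterval) -> dict:
            return {"chrom": x.chrom, "start": x.start, "end": x.end,
                    "strand": x.strand}
        payload = {
            "true_de_set": sorted(self.true_de_set),
            "planted_ratios": self.planted_ratios,
            "true_hairpin_loci": [iv(x) for x in self.true_hairpin_loci],
            "hairpin_matures": self.hairpin_matures,
            "decoy_loci": [iv(x) for x in self.decoy_loci],
            "decoy_reads": self.decoy_reads,
            "cluster_pairs": self.cluster_pairs,
            "true_target_pairs": self.true_target_pairs,
            "site_offsets": self.site_offsets,
            "pathway_genes": self.pathway_genes,
            "per_sample_totals": self.per_sample_totals,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _rng_for(spec: SimulationSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng([salt, spec.rng_seed])


class _Placer:
    """Non-overlapping locus placement with a safety margin."""

    def __init__(self, spec: SimulationSpec, rng: np.random.Generator,
                 margin: int = 120):
        self.spec = spec
        self.rng = rng
        self.margin = margin
        self.occupied: dict[str, list[tuple[int, int]]] = {
            f"chr{i + 1}": [] for i in range(spec.n_chromosomes)
        }

    def free(self, chrom: str, start: int, end: int) -> bool:
        if start < 0 or end > self.spec.chrom_length:
            return False
        for s, e in self.occupied[chrom]:
            if start < e + self.margin and s < end + self.margin:
                return False
        return True

    def claim(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].append((start, end))

    def place_random(self, length: int) -> tuple[str, int]:
        for _ in range(_MAX_RETRIES):
            chrom = f"chr{self.rng.integers(1, self.spec.n_chromosomes + 1)}"
            start = int(self.rng.integers(0, self.spec.chrom_length - length))
            if self.free(chrom, start, start + length):
                self.claim(chrom, start, start + length)
                return chrom, start
        raise GenerationError("could not place a locus without collision")


def resolve_fold_changes(
    spec: SimulationSpec, known_names: list[str], hairpin_ids: list[str]
) -> dict[str, float]:
    """Planted late/mid ratios for every expressed entity.

    When the spec supplies none, the default planting mirrors the study's
    predominantly-downward shift: clustered pairs and a block of singleton
    knowns go down 4-fold (ratio 0.25), a smaller block goes up (4.0), the
    rest are null; novel hairpins get two up, four down, the rest null.
    """
    if spec.planted_fold_changes is not None:
        fc = dict(spec.planted_fold_changes)
        for name in known_names + hairpin_ids:
            fc.setdefault(name, 1.0)
        return fc
    fc: dict[str, float] = {}
    n_pairs = 2 * spec.n_cluster_pairs
    for i, name in enumerate(known_names):
        if i < n_pairs:
            fc[name] = 0.25          # clustered pairs: co-regulated down
        elif i < n_pairs + 4:
            fc[name] = 4.0
        elif i < n_pairs + 12:
            fc[name] = 0.25
        else:
            fc[name] = 1.0
    for i, hid in enumerate(hairpin_ids):
        fc[hid] = 4.0 if i < 2 else (0.25 if i < 6 else 1.0)
    return fc


def _hairpin_recoverable(genome: dict[str, str], mature: str,
                         config: PipelineConfig) -> bool:
    """Would the discovery stage accept this embedded mature's locus?

    Runs the real excision windows and hairpin assessment on the genome as
    embedded, flanks included, so construction guarantees recovery.
    """
    hits = find_genome_hits(mature, genome)
    for hit in hits:
        for window in _precursor_windows(hit, len(genome[hit.chrom])):
            precursor = _excise(genome, window)
            if precursor.count(mature) != 1:
                continue
            if assess_hairpin(precursor, mature, config).is_hairpin:
                return True
    return False


def simulate_genome_and_annotation(
    spec: SimulationSpec,
) -> tuple[dict[str, str], list[MiRNAAnnotation], dict[str, str], GroundTruth]:
    """Random genome with embedded known-miRNA, hairpin, decoy and ncRNA loci.

    Returns (genome, known annotation, ncRNA sequences, partial truth).
    Known loci are spaced more than the clustering gap apart except for
    ``n_cluster_pairs`` deliberate pairs planted 2-8 kb apart; novel
    hairpin precursors are stem-loops (arm, 8-nt loop, near-reverse-
    complement arm) screened so the discovery stage's excision windows
    recover them; decoy loci carry shuffled, unscreened sequence.
    """
    rng = _rng_for(spec, 1)
    config = PipelineConfig()
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    genome = {c: _random_seq(rng, spec.chrom_length) for c in chroms}
    placer = _Placer(spec, rng)
    truth = GroundTruth()
    L = spec.mature_length

    # --- known miRNAs: clustered pairs first, then spaced singletons
    annotations: list[MiRNAAnnotation] = []
    known_seqs: set[str] = set()

    def fresh_mature() -> str:
        for _ in range(_MAX_RETRIES):
            seq = _random_seq(rng, L)
            if seq not in known_seqs:
                known_seqs.add(seq)
                return seq
        raise GenerationError("could not draw a fresh mature sequence")

    def embed(chrom: str, start: int, seq: str) -> None:
        genome[chrom] = genome[chrom][:start] + seq + genome[chrom][start + len(seq):]

    pair_chroms = [chroms[i % len(chroms)] for i in range(spec.n_cluster_pairs)]
    idx = 0
    for p, chrom in enumerate(pair_chroms):
        for _ in range(_MAX_RETRIES):
            a_start = int(rng.integers(0, spec.chrom_length - 10_000 - 2 * L))
            gap = int(rng.integers(2_000, 8_000))
            b_start = a_start + L + gap
            if (placer.free(chrom, a_start, a_start + L)
                    and placer.free(chrom, b_start, b_start + L)):
                break
        else:
            raise GenerationError("could not place a clustered pair")
        names = []
        for start in (a_start, b_start):
            name = f"hsa-miR-sim-{idx + 1}"
            seq = fresh_mature()
            embed(chrom, start, seq)
            placer.claim(chrom, start, start + L)
            annotations.append(MiRNAAnnotation(
                name, "hsa", seq, GenomicInterval(chrom, start, start + L, "+")
            ))
            names.append(name)
            idx += 1
        truth.cluster_pairs.append((names[0], names[1]))

    # remaining knowns: kept clear of the planted pairs (so those clusters
    # stay clean two-member groups), otherwise placed freely
    pair_loci: list[GenomicInterval] = [a.locus for a in annotations]
    while idx < spec.n_known_mirnas:
        for _ in range(_MAX_RETRIES):
            chrom = f"chr{rng.integers(1, spec.n_chromosomes + 1)}"
            start = int(rng.integers(0, spec.chrom_length - L))
            iv = GenomicInterval(chrom, start, start + L, "+")
            near_pair = any(
                k.chrom == chrom and iv.gap_to(k) <= config.cluster_gap
                for k in pair_loci
            )
            if placer.free(chrom, start, start + L) and not near_pair:
                break
        else:
            raise GenerationError("could not place an isolated known locus")
        name = f"hsa-miR-sim-{idx + 1}"
        seq = fresh_mature()
        embed(chrom, start, seq)
        placer.claim(chrom, start, start + L)
        annotations.append(MiRNAAnnotation(name, "hsa", seq, iv))
        idx += 1

    # --- novel hairpin precursors, screened for recoverability
    loop_len = 8
    for h in range(spec.n_novel_hairpins):
        hid = f"hairpin-{h + 1}"
        placed = False
        for _ in range(_MAX_RETRIES):
            chrom, start = placer.place_random(2 * L + loop_len)
            strand = "+" if rng.random() < 0.5 else "-"
            for _ in range(20):
                arm = fresh_mature()
                loop = _random_seq(rng, loop_len)
                arm2 = list(reverse_complement(arm))
                for pos in rng.choice(len(arm2), size=int(rng.integers(0, 3)),
                                      replace=False):
                    current = arm2[pos]
                    arm2[pos] = str(rng.choice(_BASES[_BASES != current]))
                precursor = arm + loop + "".join(arm2)
                if strand == "-":
                    genomic = reverse_complement(precursor)
                else:
                    genomic = precursor
                saved = genome[chrom]
                embed(chrom, start, genomic)
                if _hairpin_recoverable(genome, arm, config):
                    placed = True
                    break
                genome[chrom] = saved
                known_seqs.discard(arm)
            if placed:
                break
        if not placed:
            raise GenerationError(f"could not construct recoverable {hid}")
        truth.true_hairpin_loci.append(
            GenomicInterval(chrom, start, start + len(precursor), strand)
        )
        truth.hairpin_matures[hid] = arm

    # --- decoy loci: shuffled hairpin-composition sequence, unscreened
    for d in range(spec.n_decoy_loci):
        proto = list(_random_seq(rng, L) + _random_seq(rng, loop_len)
                     + _random_seq(rng, L))
        rng.shuffle(proto)
        seq = "".join(proto)
        chrom, start = placer.place_random(len(seq))
        embed(chrom, start, seq)
        truth.decoy_loci.append(
            GenomicInterval(chrom, start, start + len(seq), "+")
        )
        # the read emitted from this locus: its central mature-length slice
        offset = (len(seq) - L) // 2
        truth.decoy_reads[f"decoy-{d + 1}"] = seq[offset:offset + L]

    # --- non-miRNA ncRNA genes (tRNA/snoRNA-sized), embedded
    ncrna: dict[str, str] = {}
    for n in range(spec.n_ncrna):
        seq = _random_seq(rng, 80)
        chrom, start = placer.place_random(len(seq))
        embed(chrom, start, seq)
        ncrna[f"ncrna-{n + 1}"] = seq

    logger.info(
        "simulate_genome_and_annotation: %d chroms x %d nt, %d known, "
        "%d hairpins, %d decoys, %d ncRNAs",
        spec.n_chromosomes, spec.chrom_length, len(annotations),
        spec.n_novel_hairpins, spec.n_decoy_loci, spec.n_ncrna,
    )
    return genome, annotations, ncrna, truth


def simulate_counts(
    spec: SimulationSpec,
    annotations: list[MiRNAAnnotation],
    ncrna: dict[str, str],
    truth: GroundTruth,
) -> tuple[dict[str, list[ReadRecord]], CountTable]:
    """Per-sample collapsed reads plus the true known-miRNA count table.

    Baselines are log-uniform; late-group means are mid-group means times
    the planted ratio; counts are negative binomial with the spec's
    dispersion (exactly the rounded means at dispersion 0).  Per-sample
    genome-matched totals are recorded in the truth as the normalization
    denominators.  Non-genome-matched noise (too-short and unalignable
    reads) is appended so the QC cascade has all five categories.
    """
    rng = _rng_for(spec, 2)
    n = spec.n_samples_per_group
    sample_ids = [f"mid_{i + 1}" for i in range(n)] + \
                 [f"late_{i + 1}" for i in range(n)]
    groups = ["mid"] * n + ["late"] * n
    depth_factors = rng.uniform(0.9, 1.1, size=2 * n)

    known_names = [a.name for a in annotations]
    hairpin_ids = sorted(truth.hairpin_matures)
    fc = resolve_fold_changes(spec, known_names, hairpin_ids)
    truth.planted_ratios = fc
    fold_gate = math.log2(PipelineConfig().fold_threshold)
    truth.true_de_set = {
        name for name, r in fc.items() if abs(math.log2(r)) > fold_gate
    }

    entities: list[tuple[str, str, float]] = []  # (id, sequence, mid weight)
    for a in annotations:
        entities.append((a.name, a.mature_sequence,
                         float(np.exp(rng.uniform(np.log(10), np.log(1000))))))
    for hid in hairpin_ids:
        entities.append((hid, truth.hairpin_matures[hid],
                         float(np.exp(rng.uniform(np.log(20), np.log(200))))))
    for did in sorted(truth.decoy_reads):
        entities.append((did, truth.decoy_reads[did],
                         float(np.exp(rng.uniform(np.log(10), np.log(60))))))
    for nid in sorted(ncrna):
        seq = ncrna[nid]
        offset = (len(seq) - spec.mature_length) // 2
        entities.append((nid, seq[offset:offset + spec.mature_length],
                         float(np.exp(rng.uniform(np.log(50), np.log(500))))))

    weight_sum = sum(w for _, _, w in entities)

    def draw(mean: float) -> int:
        if mean <= 0:
            return 0
        if spec.dispersion == 0:
            return int(round(mean))
        size = 1.0 / spec.dispersion
        p = size / (size + mean)
        return int(rng.negative_binomial(size, p))

    counts = np.zeros((len(entities), 2 * n), dtype=int)
    for i, (eid, _, w) in enumerate(entities):
        ratio = fc.get(eid, 1.0)
        for j in range(2 * n):
            r = ratio if groups[j] == "late" else 1.0
            mean = depth_factors[j] * spec.depth_per_sample * w * r / weight_sum
            counts[i, j] = draw(mean)

    reads_per_sample: dict[str, list[ReadRecord]] = {}
    genome_totals: dict[str, int] = {}
    for j, sample in enumerate(sample_ids):
        col = [(entities[i][1], int(counts[i, j]))
               for i in range(len(entities)) if counts[i, j] > 0]
        genome_total = sum(c for _, c in col)
        # non-genome noise: unalignable reads (~12% of HQ) and short reads
        # (~14% of raw), echoing the study's cascade shape
        n_unaligned = int(round(genome_total * 0.14))
        for k in range(3):
            seq = _random_seq(rng, spec.mature_length + 2)
            col.append((seq, n_unaligned // 3 + (n_unaligned % 3 if k == 0 else 0)))
        n_short = int(round((genome_total + n_unaligned) * 0.165))
        for k in range(2):
            seq = _random_seq(rng, 14)
            col.append((seq, n_short // 2 + (n_short % 2 if k == 0 else 0)))
        col = [(s, c) for s, c in col if c > 0]
        col.sort(key=lambda sc: (-sc[1], sc[0]))
        reads_per_sample[sample] = [
            ReadRecord(f"seq-{rank + 1}_x{c}", s, c)
            for rank, (s, c) in enumerate(col)
        ]
        genome_totals[sample] = genome_total
    truth.per_sample_totals = genome_totals

    n_known = len(known_names)
    table = CountTable(
        mirna_ids=known_names,
        sample_ids=sample_ids,
        groups=groups,
        counts=counts[:n_known, :],
        denominators=np.array([genome_totals[s] for s in sample_ids], float),
    )
    logger.info("simulate_counts: %d samples, genome-matched totals %s",
                2 * n, [genome_totals[s] for s in sample_ids])
    return reads_per_sample, table


def default_planted_sites(
    spec: SimulationSpec, known_names: list[str], hairpin_ids: list[str],
    pathway_genes: list[str],
) -> dict[str, list[str]]:
    """Default seed-site planting: a multi-target hairpin, a two-gene
    hairpin, two-gene knowns, and one single-gene boundary case."""
    if spec.planted_sites is not None:
        return dict(spec.planted_sites)
    sites: dict[str, list[str]] = {}
    pg = pathway_genes
    if hairpin_ids:
        sites[hairpin_ids[0]] = pg[:4]           # heavily multi-targeted
    if len(hairpin_ids) > 1:
        sites[hairpin_ids[1]] = pg[4:6]
    n_pairs = 2 * spec.n_cluster_pairs
    if len(known_names) > n_pairs:
        sites[known_names[n_pairs]] = pg[6:8]    # an up-regulated known
    if len(known_names) > n_pairs + 4:
        sites[known_names[n_pairs + 4]] = pg[:2]  # a down-regulated known
    if len(known_names) > n_pairs + 5:
        sites[known_names[n_pairs + 5]] = pg[2:3]  # exactly one: not related
    return sites


def simulate_utrs_and_pathway(
    spec: SimulationSpec,
    annotations: list[MiRNAAnnotation],
    truth: GroundTruth,
    config: PipelineConfig | None = None,
) -> tuple[dict[str, str], list[str]]:
    """3'UTR set with planted seed-complement sites plus the pathway list.

    Background UTRs are screened to contain no seed complement of any
    annotated miRNA (known or planted hairpin); each planted (miRNA, gene)
    pair then gets exactly one reverse-complemented seed site written at a
    recorded offset.
    """
    from .conservation import extract_seed

    config = config or PipelineConfig()
    rng = _rng_for(spec, 3)
    pathway_genes = default_tgfb_pathway()
    known_names = [a.name for a in annotations]
    hairpin_ids = sorted(truth.hairpin_matures)
    matures = {a.name: a.mature_sequence for a in annotations}
    matures.update(truth.hairpin_matures)
    site_seqs = {
        mid: reverse_complement(extract_seed(m, config, mid).seed)
        for mid, m in matures.items()
    }

    gene_ids = list(pathway_genes)
    gene_ids += [f"GENE{i + 1:03d}" for i in range(spec.n_utrs - len(gene_ids))]
    gene_ids = gene_ids[:max(spec.n_utrs, len(pathway_genes))]

    planted = default_planted_sites(spec, known_names, hairpin_ids, pathway_genes)
    # invert: gene -> list of miRNAs to plant, in deterministic order
    per_gene: dict[str, list[str]] = {g: [] for g in gene_ids}
    for mid in sorted(planted):
        for gene in planted[mid]:
            if gene not in per_gene:
                raise GenerationError(f"planted site in unknown gene {gene!r}")
            per_gene[gene].append(mid)

    utrs: dict[str, str] = {}
    for gene in gene_ids:
        to_plant = per_gene[gene]
        forbidden = [s for mid, s in sorted(site_seqs.items())
                     if mid not in to_plant]
        planted_ok = False
        for _ in range(_MAX_RETRIES):
            utr = _random_seq(rng, spec.utr_length)
            if any(s in utr for s in forbidden):
                continue
            offsets = {}
            slot_width = spec.utr_length // (len(to_plant) + 1) if to_plant else 0
            ok = True
            for k, mid in enumerate(to_plant):
                site = site_seqs[mid]
                pos = (k + 1) * slot_width - len(site) // 2
                utr = utr[:pos] + site + utr[pos + len(site):]
                offsets[mid] = pos
            # planting may have created a forbidden site; re-screen
            if any(s in utr for s in forbidden):
                continue
            # each planted site must occur exactly once
            for mid in to_plant:
                if utr.count(site_seqs[mid]) != 1:
                    ok = False
            if not ok:
                continue
            utrs[gene] = utr
            for mid, off in offsets.items():
                truth.site_offsets.setdefault(mid, {})[gene] = off
                truth.true_target_pairs.append((mid, gene))
            planted_ok = True
            break
        if not planted_ok:
            raise GenerationError(f"could not screen a UTR for {gene}")
    truth.pathway_genes = pathway_genes
    logger.info("simulate_utrs_and_pathway: %d UTRs, %d planted site pairs",
                len(utrs), len(truth.true_target_pairs))
    return utrs, pathway_genes


def simulate_ct_table(
    spec: SimulationSpec,
    truth: GroundTruth,
    n_targets: int = 8,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.2,
) -> list[CtMeasurement]:
    """Synthetic validation qPCR: Ct values consistent with the planted
    ratios (plus replicate noise) for a panel of planted-DE miRNAs, with a
    U6 reference in every sample."""
    rng = _rng_for(spec, 4)
    n = spec.n_samples_per_group
    samples = [(f"mid_{i + 1}", "mid") for i in range(n)] + \
              [(f"late_{i + 1}", "late") for i in range(n)]
    # a validation panel spanning both directions: alternate the most
    # down- and most up-regulated planted miRNAs
    ordered = sorted(truth.true_de_set,
                     key=lambda m: (truth.planted_ratios[m], m))
    panel = []
    lo, hi = 0, len(ordered) - 1
    while len(panel) < min(n_targets, len(ordered)):
        panel.append(ordered[lo]); lo += 1
        if lo <= hi and len(panel) < n_targets:
            panel.append(ordered[hi]); hi -= 1
    if len(panel) < 3:
        panel = sorted(truth.planted_ratios)[:max(3, n_targets)]

    out: list[CtMeasurement] = []
    u6_ct: dict[str, float] = {}
    for sample, group in samples:
        u6 = 18.0 + float(rng.normal(0, 0.1))
        u6_ct[sample] = u6
        for rep in range(1, n_replicates + 1):
            out.append(CtMeasurement("U6", sample, group, u6
                                     + float(rng.normal(0, ct_noise_sd)), rep))
    for target in panel:
        ratio = truth.planted_ratios.get(target, 1.0)
        base_dct = float(rng.uniform(4, 10))
        for sample, group in samples:
            dct = base_dct - (math.log2(ratio) if group == "late" else 0.0)
            for rep in range(1, n_replicates + 1):
                ct = u6_ct[sample] + dct + float(rng.normal(0, ct_noise_sd))
                out.append(CtMeasurement(target, sample, group, ct, rep))
    return out


def write_ct_tsv(measurements: list[CtMeasurement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("target_id\tsample_id\tgroup\treplicate\tct\n")
        for m in measurements:
            fh.write(f"{m.target_id}\t{m.sample_id}\t{m.group}\t"
                     f"{m.replicate}\t{m.ct:.4f}\n")


@dataclass
class SimulatedStudy:
    spec: SimulationSpec
    genome: dict[str, str]
    annotations: list[MiRNAAnnotation]
    ncrna: dict[str, str]
    reads_per_sample: dict[str, list[ReadRecord]]
    count_table: CountTable
    utrs: dict[str, str]
    pathway_genes: list[str]
    ct_measurements: list[CtMeasurement]
    truth: GroundTruth


def simulate_all(
    spec: SimulationSpec, outdir: str | Path | None = None
) -> SimulatedStudy:
    """Run every generator stage; optionally write the full file set.

    Emits genome.fa (DNA alphabet), known.tsv, ncrna.fa, sample_*.fa,
    utrs.fa, pathway.txt, ct.tsv and truth.json under ``outdir``.  Output
    is byte-identical for a fixed ``rng_seed``.
    """
    genome, annotations, ncrna, truth = simulate_genome_and_annotation(spec)
    reads, table = simulate_counts(spec, annotations, ncrna, truth)
    utrs, pathway_genes = simulate_utrs_and_pathway(spec, annotations, truth)
    ct = simulate_ct_table(spec, truth)
    study = SimulatedStudy(spec, genome, annotations, ncrna, reads, table,
                           utrs, pathway_genes, ct, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "genome.fa", dna=True)
        write_annotation_table(annotations, outdir / "known.tsv")
        write_fasta(ncrna, outdir / "ncrna.fa")
        for i, sample in enumerate(sorted(reads), start=1):
            write_count_fasta(reads[sample], outdir / f"sample_{sample}.fa")
        write_fasta(utrs, outdir / "utrs.fa")
        with open(outdir / "pathway.txt", "w") as fh:
            fh.write("\n".join(pathway_genes) + "\n")
        write_ct_tsv(ct, outdir / "ct.tsv")
        table.to_tsv(outdir / "counts.tsv")
        with open(outdir / "samples.tsv", "w") as fh:
            fh.write("sample_id\tgroup\tdenominator\n")
            for sid, grp in zip(table.sample_ids, table.groups):
                fh.write(f"{sid}\t{grp}\t{int(truth.per_sample_totals[sid])}\n")
        truth.to_json(outdir / "truth.json")
    return study
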