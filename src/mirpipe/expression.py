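"""Count table, reads-per-million normalization and two-group DE calling.

Expression is compared between a mid-gestation and a late-gestation group
of three samples each.  Counts are scaled to reads per million of each
sample's genome-matched read total, group means are compared with a
pooled-variance Student's t-test (df = n_a + n_b - 2), and a miRNA is
called differentially expressed when p < 0.05 AND the late/mid ratio lies
outside (1/2, 2) — the fold gate is strict, so a ratio of exactly 2.0 does
not qualify.  No multiple-testing correction enters the call; a
Benjamini-Hochberg adjusted column is reported alongside for reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_core import PipelineConfig

logger = logging.getLogger("mirpipe")

GROUPS = ("mid", "late")


@dataclass
class CountTable:
    """miRNA-by-sample integer counts plus per-sample normalization totals.

    ``denominators[j]`` is sample j's genome-matched read total — the
    normalization denominator, which is NOT the column sum of the matrix
    (the matrix holds only panel miRNAs, the denominator all genome-matched
    reads).
    """

    mirna_ids: list[str]
    sample_ids: list[str]
    groups: list[str]
    counts: np.ndarray
    denominators: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.denominators = np.asarray(self.denominators, dtype=float)
        n_mirna, n_samp = self.counts.shape
        if n_mirna != len(self.mirna_ids) or n_samp != len(self.sample_ids):
            raise ValidationError("count matrix shape does not match id lists")
        if len(self.groups) != n_samp:
            raise ValidationError("one group label per sample required")
        if any(g not in GROUPS for g in self.groups):
            raise ValidationError(f"group labels must be in {GROUPS}")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if (self.denominators <= 0).any():
            raise ValidationError("normalization denominators must be positive")

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([j for j, g in enumerate(self.groups) if g == group])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, index=self.mirna_ids, columns=self.sample_ids)
        df.index.name = "mirna_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        groups_path: str | Path,
    ) -> "CountTable":
        """Read counts (miRNA x sample TSV) plus a sample sheet.

        The sample sheet has columns sample_id, group, denominator.
        """
        cdf = pd.read_csv(counts_path, sep="\t", index_col=0)
        sdf = pd.read_csv(groups_path, sep="\t", dtype={"sample_id": str})
        for col in ("sample_id", "group", "denominator"):
            if col not in sdf.columns:
                raise ValidationError(f"sample sheet missing column {col!r}")
        sdf = sdf.set_index("sample_id").loc[list(cdf.columns)]
        return cls(
            mirna_ids=list(cdf.index),
            sample_ids=list(cdf.columns),
            groups=list(sdf["group"]),
            counts=cdf.to_numpy(),
            denominators=sdf["denominator"].to_numpy(dtype=float),
        )


@dataclass
class DECall:
    mirna_id: str
    mean_mid: float
    mean_late: float
    ratio: float           # late / mid of normalized means; inf when mid == 0
    t_stat: float
    p_value: float
    significant: bool      # p < p_threshold
    differential: bool     # significant AND fold gate passed
    direction: str         # up | down | none
    p_adjusted: float = math.nan  # BH-adjusted, reported only


def normalize(table: CountTable) -> np.ndarray:
    """Counts -> reads per million of each sample's denominator."""
    return table.counts / table.denominators[np.newaxis, :] * 1e6


def student_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test.

    Degenerate zero-variance inputs are defined rather than NaN: equal
    means give (t=0, p=1), unequal means the (t=+/-inf, p=0) limit.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values for a t-test")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        logger.warning("t-test on zero-variance groups with unequal means")
        return (-math.inf if a.mean() < b.mean() else math.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def call_de(table: CountTable, config: PipelineConfig | None = None) -> list[DECall]:
    """Per-miRNA DE calls between the mid and late groups.

    The test is run on the normalized per-sample values (optionally log2
    with the configured pseudocount); the ratio is late over mid of the
    normalized (non-log) means.
    """
    config = config or PipelineConfig()
    mid_cols = table.group_columns("mid")
    late_cols = table.group_columns("late")
    if len(mid_cols) < 2 or len(late_cols) < 2:
        raise ValidationError("both groups need >= 2 samples")

    rpm = normalize(table)
    test_values = rpm + config.pseudocount
    if config.log2_transform:
        if (test_values <= 0).any():
            raise ValidationError("log2 transform requires a positive pseudocount")
        test_values = np.log2(test_values)

    calls: list[DECall] = []
    for i, mirna in enumerate(table.mirna_ids):
        mean_mid = float(rpm[i, mid_cols].mean())
        mean_late = float(rpm[i, late_cols].mean())
        if mean_mid > 0:
            ratio = mean_late / mean_mid
        elif mean_late > 0:
            ratio = math.inf
            logger.info("call_de: %s has zero mid-group mean; ratio = inf", mirna)
        else:
            ratio = math.nan
        t, p = student_t_test(test_values[i, mid_cols], test_values[i, late_cols])
        significant = p < config.p_threshold
        up = ratio > config.fold_threshold
        down = ratio < 1 / config.fold_threshold
        if math.isinf(ratio):
            # mid mean exactly zero: fold gate is decided by significance alone
            differential = significant
            up, down = significant, False
        else:
            differential = significant and (up or down)
        direction = "up" if (differential and up) else (
            "down" if (differential and down) else "none")
        calls.append(DECall(
            mirna_id=mirna, mean_mid=mean_mid, mean_late=mean_late, ratio=ratio,
            t_stat=t, p_value=p, significant=significant,
            differential=differential, direction=direction,
        ))

    pvals = np.array([c.p_value for c in calls])
    if len(pvals):
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        for call, padj in zip(calls, adjusted):
            call.p_adjusted = float(padj)
    n_diff = sum(c.differential for c in calls)
    logger.info(
        "call_de: %d miRNAs tested, %d significant, %d differential "
        "(%d up / %d down)",
        len(calls), sum(c.significant for c in calls), n_diff,
        sum(c.direction == "up" for c in calls),
        sum(c.direction == "down" for c in calls),
    )
    return calls


def de_calls_to_frame(calls: Sequence[DECall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


def write_de_tsv(calls: Sequence[DECall], path: str | Path) -> None:
    de_calls_to_frame(calls).to_csv(path, sep="\t", index=False)
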