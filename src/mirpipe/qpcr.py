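"""Relative qPCR quantification by the 2^-ddCt method and NGS concordance.

dCt = Ct(target) - Ct(U6 reference) per sample (replicates averaged
first); group dCt is the mean over samples; ddCt = dCt(late) - dCt(mid);
the relative expression ratio is 2^-ddCt.  A ratio strictly below 1.0 is
classified low expression in the late group, anything else high.
Cross-platform agreement with sequencing is measured as the Pearson
correlation of log2 ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger("mirpipe")

REFERENCE_ID = "U6"


@dataclass(frozen=True)
class CtMeasurement:
    target_id: str
    sample_id: str
    group: str          # mid | late
    ct: float           # cycles
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValidationError(
                f"Ct must be positive ({self.target_id}/{self.sample_id})"
            )
        if self.group not in ("mid", "late"):
            raise ValidationError(f"group must be mid or late, got {self.group!r}")


@dataclass
class RelativeExpression:
    mirna_id: str
    delta_ct_mid: float
    delta_ct_late: float
    delta_delta_ct: float
    ratio: float            # 2^-ddCt
    classification: str     # low (< 1.0) | high
    delta_ct_sd_mid: float = math.nan   # replicate-propagated, reference only
    delta_ct_sd_late: float = math.nan


def read_ct_tsv(path: str | Path) -> list[CtMeasurement]:
    """TSV columns: target_id, sample_id, group, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"target_id", "sample_id", "group", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return [
        CtMeasurement(str(r.target_id), str(r.sample_id), str(r.group),
                      float(r.ct), int(r.replicate))
        for r in df.itertuples(index=False)
    ]


def ddct(
    measurements: Sequence[CtMeasurement], reference_id: str = REFERENCE_ID
) -> list[RelativeExpression]:
    """2^-ddCt relative expression of late- versus mid-group samples.

    Every sample carrying a target measurement must also carry a reference
    (U6) measurement.  Replicates are averaged per (target, sample) before
    differencing, and the per-sample dCt values are averaged within each
    group before ddCt.
    """
    by_target: dict[str, dict[str, list[float]]] = {}
    sample_group: dict[str, str] = {}
    for m in measurements:
        by_target.setdefault(m.target_id, {}).setdefault(m.sample_id, []).append(m.ct)
        sample_group[m.sample_id] = m.group

    ref = by_target.pop(reference_id, None)
    if ref is None:
        raise ValidationError(f"no {reference_id} reference measurements")
    ref_mean = {s: float(np.mean(v)) for s, v in ref.items()}

    out: list[RelativeExpression] = []
    for target in sorted(by_target):
        per_sample = by_target[target]
        dct: dict[str, list[float]] = {"mid": [], "late": []}
        for sample, cts in per_sample.items():
            if sample not in ref_mean:
                raise ValidationError(
                    f"sample {sample!r} has no {reference_id} measurement"
                )
            dct[sample_group[sample]].append(float(np.mean(cts)) - ref_mean[sample])
        if not dct["mid"] or not dct["late"]:
            raise ValidationError(f"{target}: both groups need >= 1 sample")
        d_mid = float(np.mean(dct["mid"]))
        d_late = float(np.mean(dct["late"]))
        ddct_val = d_late - d_mid
        ratio = 2.0 ** (-ddct_val)
        out.append(RelativeExpression(
            mirna_id=target,
            delta_ct_mid=d_mid,
            delta_ct_late=d_late,
            delta_delta_ct=ddct_val,
            ratio=ratio,
            classification="low" if ratio < 1.0 else "high",
            delta_ct_sd_mid=float(np.std(dct["mid"], ddof=1))
            if len(dct["mid"]) > 1 else math.nan,
            delta_ct_sd_late=float(np.std(dct["late"], ddof=1))
            if len(dct["late"]) > 1 else math.nan,
        ))
    logger.info("ddct: %d targets quantified", len(out))
    return out


def ngs_qpcr_correlation(
    ngs_ratios: Mapping[str, float],
    qpcr_ratios: Mapping[str, float],
    method: str = "pearson",
) -> tuple[float, float, pd.DataFrame]:
    """Correlation of log2 expression ratios between platforms.

    Only miRNAs present in both maps with finite positive ratios enter;
    at least three such pairs are required.  Returns (r, two-sided p,
    paired table).
    """
    shared = sorted(
        m for m in set(ngs_ratios) & set(qpcr_ratios)
        if _finite_positive(ngs_ratios[m]) and _finite_positive(qpcr_ratios[m])
    )
    if len(shared) < 3:
        raise ValidationError(
            f"need >= 3 shared finite positive ratios, got {len(shared)}"
        )
    table = pd.DataFrame({
        "mirna_id": shared,
        "ngs_log2_ratio": [math.log2(ngs_ratios[m]) for m in shared],
        "qpcr_log2_ratio": [math.log2(qpcr_ratios[m]) for m in shared],
    })
    if method == "pearson":
        r, p = stats.pearsonr(table["ngs_log2_ratio"], table["qpcr_log2_ratio"])
    elif method == "spearman":
        r, p = stats.spearmanr(table["ngs_log2_ratio"], table["qpcr_log2_ratio"])
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    logger.info("ngs_qpcr_correlation: n=%d r=%.3f p=%.3g", len(shared), r, p)
    return float(r), float(p), table


def _finite_positive(x: float) -> bool:
    return math.isfinite(x) and x > 0


def write_relative_expression_tsv(
    results: Sequence[RelativeExpression], path: str | Path
) -> None:
    pd.DataFrame([vars(r) for r in results]).to_csv(path, sep="\t", index=False)
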