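"""Sample-level sequencing QC and exclusion.

Copy-number estimates from depth ratios are only as good as the underlying
libraries, so samples with aberrant alignment statistics are excluded before
any cohort analysis:

* uniquely mapped read count far outside the cohort (robust median/MAD rule);
* poor mapping efficiency;
* incomplete bisulfite conversion, evidenced by high non-CpG methylation;
* RRBS only: total CpG methylation far from the cohort mean (mean/SD rule),
  indicating aberrant enzyme digestion or size selection.

Thresholds are qualitative in origin; the concrete defaults live in
:class:`QCPolicy` and are echoed into output provenance so every exclusion
is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.stats import median_abs_deviation


@dataclass(frozen=True)
class SampleQCMetrics:
    sample_id: str
    uniquely_mapped_reads: int
    mapping_efficiency: float
    non_cpg_methylation: float
    total_cpg_methylation: float
    assay: str  # wgbs | rrbs

    def __post_init__(self) -> None:
        for name in ("mapping_efficiency", "non_cpg_methylation", "total_cpg_methylation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValueError(f"{self.sample_id}: {name}={v} outside [0, 1]")
        if self.uniquely_mapped_reads < 0:
            raise ValueError("negative read count")
        if self.assay not in {"wgbs", "rrbs"}:
            raise ValueError(f"unknown assay {self.assay!r}")


@dataclass(frozen=True)
class QCPolicy:
    """Exclusion thresholds.

    ``read_count_mad_k``: flag samples beyond median +/- k * MAD (normal-
    consistent MAD) of uniquely mapped reads.  ``rrbs_total_meth_sd_k``:
    flag RRBS samples beyond mean +/- k * SD of total CpG methylation.
    """

    read_count_mad_k: float = 3.0
    min_mapping_efficiency: float = 0.6
    max_non_cpg_methylation: float = 0.02
    rrbs_total_meth_sd_k: float = 3.0

    def __post_init__(self) -> None:
        if min(self.read_count_mad_k, self.min_mapping_efficiency,
               self.max_non_cpg_methylation, self.rrbs_total_meth_sd_k) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class QCVerdict:
    sample_id: str
    included: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.included != (len(self.reasons) == 0):
            raise ValueError("included must equal 'no failed rules'")


def apply_qc(metrics: Sequence[SampleQCMetrics], policy: QCPolicy = QCPolicy()
             ) -> list[QCVerdict]:
    """Evaluate every exclusion rule per sample; verdicts list all failures.

    Cohort-relative rules (read count, RRBS total methylation) are computed
    on the full input cohort, so the verdicts are order-independent and
    deterministic.  At least 3 samples are required for those rules; with
    fewer samples only the per-sample rules apply.
    """
    if not metrics:
        raise ValueError("empty cohort")
    reads = np.array([m.uniquely_mapped_reads for m in metrics], dtype=float)
    if not np.isfinite(reads).all():
        raise ValueError("non-finite read count")
    cohort_rules = len(metrics) >= 3
    if cohort_rules:
        med = float(np.median(reads))
        mad = float(median_abs_deviation(reads, scale="normal"))
    rrbs_tm = np.array([m.total_cpg_methylation for m in metrics if m.assay == "rrbs"])
    rrbs_rule = cohort_rules and len(rrbs_tm) >= 3
    if rrbs_rule:
        tm_mean = float(rrbs_tm.mean())
        tm_sd = float(rrbs_tm.std(ddof=1))
    verdicts = []
    for m in metrics:
        reasons = []
        if cohort_rules and mad > 0 and abs(m.uniquely_mapped_reads - med) > policy.read_count_mad_k * mad:
            reasons.append("read_count_outlier")
        if m.mapping_efficiency < policy.min_mapping_efficiency:
            reasons.append("mapping_efficiency")
        if m.non_cpg_methylation > policy.max_non_cpg_methylation:
            reasons.append("bisulfite_conversion")
        if (m.assay == "rrbs" and rrbs_rule and tm_sd > 0
                and abs(m.total_cpg_methylation - tm_mean) > policy.rrbs_total_meth_sd_k * tm_sd):
            reasons.append("total_methylation_outlier")
        verdicts.append(QCVerdict(sample_id=m.sample_id, included=not reasons,
                                  reasons=tuple(reasons)))
    return verdicts


def policy_provenance(policy: QCPolicy) -> dict:
    """Thresholds as a JSON-ready dict for output sidecars."""
    return asdict(policy)
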