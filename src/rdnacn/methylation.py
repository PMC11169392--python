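"""CpG methylation aggregation over the rDNA unit and genomic features.

Consumes bismark-style coverage files (per-CpG methylated/unmethylated read
counts, destranded) and aggregates them to region level.  Two conventions
matter throughout:

* On the rDNA contig only CpGs covered by at least ``min_coverage`` unique
  reads (default 50) enter a summary — the multicopy locus is deep enough
  to afford the filter and shallow CpGs there are disproportionately noisy.
  Genome-wide feature classes use all CpGs.
* The default regional mean is coverage-weighted (total methylated reads /
  total reads over retained CpGs); an unweighted per-CpG mean is available
  via ``weighting="cpg"``.

Also provides the methylation-adjusted ("active") copy number: methylated
units are presumed transcriptionally silenced, so the active copy count is
``CN * (1 - mean methylation)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cn import CopyNumberEstimate
from .reference import LoopedReference

Interval = tuple[str, int, int]

DEFAULT_MIN_COVERAGE = 50
DEFAULT_RDNA_PROMOTER_UPSTREAM = 1000


@dataclass(frozen=True)
class MethylationSummary:
    """Regional methylation with CpG and read accounting.

    ``mean_methylation`` is ``None`` when no CpG survives the coverage
    filter — an explicit empty signal, deliberately distinct from 0.
    """

    sample_id: str
    region_name: str
    mean_methylation: float | None
    n_cpgs_used: int
    n_cpgs_filtered: int
    total_coverage: int
    weighting: str = "coverage"

    def __post_init__(self) -> None:
        if self.mean_methylation is not None and not 0.0 <= self.mean_methylation <= 1.0:
            raise ValueError("mean_methylation outside [0, 1]")
        if (self.mean_methylation is None) != (self.n_cpgs_used == 0):
            raise ValueError("empty summary must have no used CpGs and vice versa")

    @property
    def is_empty(self) -> bool:
        return self.mean_methylation is None


@dataclass(frozen=True)
class ActiveCopyEstimate:
    sample_id: str
    raw_cn: float
    mean_methylation: float
    active_cn: float
    formula: str = "active = raw * (1 - mean_methylation)"

    def __post_init__(self) -> None:
        if not 0.0 <= self.active_cn <= self.raw_cn + 1e-9:
            raise ValueError("active_cn outside [0, raw_cn]")


# ---------------------------------------------------------------------------
# bismark coverage I/O

_COV_COLUMNS = ["contig", "start", "end", "pct", "meth", "unmeth"]


def read_cpg_calls(path: str | Path) -> pd.DataFrame:
    """Parse a bismark coverage file into a 0-based CpG table.

    Input columns are chrom, start (1-based), end, %methylation, methylated
    count, unmethylated count.  The percent field is redundant with the
    counts and is discarded after a consistency check (a warning names the
    first offending line).  Output columns: ``contig, pos, meth, unmeth``,
    sorted by (contig, pos).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_COV_COLUMNS,
                         dtype={"contig": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed coverage file {path}: {exc}") from exc
    if df.empty:
        return pd.DataFrame(columns=["contig", "pos", "meth", "unmeth"])
    for col in ("start", "end", "meth", "unmeth"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0] + 1
            raise ValueError(f"malformed coverage file {path}: non-numeric {col} at line {bad}")
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise ValueError(f"negative counts in {path}")
    cov = df["meth"] + df["unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_from_counts = np.where(cov > 0, 100.0 * df["meth"] / cov, np.nan)
    mism = np.abs(pct_from_counts - df["pct"].to_numpy()) > 0.51
    mism &= ~np.isnan(pct_from_counts)
    if mism.any():
        line = int(np.argmax(mism)) + 1
        warnings.warn(f"{path}: percent column inconsistent with counts "
                      f"(first at line {line}); counts take precedence")
    out = pd.DataFrame({
        "contig": df["contig"],
        "pos": df["start"].astype(np.int64) - 1,  # 1-based -> 0-based
        "meth": df["meth"].astype(np.int64),
        "unmeth": df["unmeth"].astype(np.int64),
    })
    return out.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)


def write_cpg_calls(records: pd.DataFrame, path: str | Path) -> None:
    """Write a CpG table back out in bismark coverage format (1-based)."""
    cov = records["meth"] + records["unmeth"]
    pct = np.where(cov > 0, 100.0 * records["meth"] / cov, 0.0)
    out = pd.DataFrame({
        "contig": records["contig"],
        "start": records["pos"] + 1,
        "end": records["pos"] + 1,
        "pct": pct,
        "meth": records["meth"],
        "unmeth": records["unmeth"],
    })
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# regional aggregation


def _in_intervals(records: pd.DataFrame, intervals: Sequence[Interval]) -> pd.Series:
    mask = pd.Series(False, index=records.index)
    for contig, s, e in intervals:
        if e <= s:
            raise ValueError(f"empty interval {contig}:{s}-{e}")
        mask |= (records["contig"] == contig) & (records["pos"] >= s) & (records["pos"] < e)
    return mask


def region_methylation(records: pd.DataFrame, intervals: Sequence[Interval],
                       *, sample_id: str = "sample", region_name: str = "region",
                       min_coverage: int = DEFAULT_MIN_COVERAGE,
                       weighting: str = "coverage") -> MethylationSummary:
    """Aggregate CpG counts over a (possibly split) region.

    ``weighting="coverage"`` (default): mean = sum(meth) / sum(meth+unmeth)
    over retained CpGs.  ``weighting="cpg"``: unweighted mean of per-CpG
    methylation fractions.  CpGs below ``min_coverage`` are excluded and
    counted in ``n_cpgs_filtered``.
    """
    if weighting not in {"coverage", "cpg"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    if not intervals:
        raise ValueError("empty region")
    sub = records[_in_intervals(records, intervals)]
    cov = sub["meth"] + sub["unmeth"]
    keep = cov >= min_coverage
    used = sub[keep]
    n_filtered = int((~keep).sum())
    if used.empty:
        return MethylationSummary(sample_id=sample_id, region_name=region_name,
                                  mean_methylation=None, n_cpgs_used=0,
                                  n_cpgs_filtered=n_filtered, total_coverage=0,
                                  weighting=weighting)
    total_m = int(used["meth"].sum())
    total_cov = int(used["meth"].sum() + used["unmeth"].sum())
    if weighting == "coverage":
        mean = total_m / total_cov
    else:
        fr = used["meth"] / (used["meth"] + used["unmeth"])
        mean = float(fr.mean())
    return MethylationSummary(sample_id=sample_id, region_name=region_name,
                              mean_methylation=float(mean), n_cpgs_used=int(len(used)),
                              n_cpgs_filtered=n_filtered, total_coverage=total_cov,
                              weighting=weighting)


def rdna_region_intervals(looped: LoopedReference, contig: str,
                          which: str = "promoter_and_unit",
                          promoter_upstream: int = DEFAULT_RDNA_PROMOTER_UPSTREAM
                          ) -> list[Interval]:
    """Named rDNA regions as looped-contig intervals (split-aware).

    ``promoter_and_unit`` is the window from ``promoter_upstream`` bases
    before the TSS through the end of the annotated transcribed unit; any
    other name selects that region from the looped annotation (e.g. ``18S``,
    ``UCE``, ``core_promoter``).
    """
    if which == "promoter_and_unit":
        if "transcript" not in looped.regions:
            raise KeyError("annotation lacks a 'transcript' region")
        from .reference import rotate_interval

        _, t_end = _contiguous_native_end(looped)
        tss_native = looped.looped_to_native(looped.tss_looped)
        native_start = (tss_native - promoter_upstream) % looped.unit_length
        if native_start < t_end:
            pieces = rotate_interval((native_start, t_end), looped.breakpoint, looped.unit_length)
        else:  # promoter window wraps the native unit origin
            pieces = (rotate_interval((native_start, looped.unit_length), looped.breakpoint, looped.unit_length)
                      + rotate_interval((0, t_end), looped.breakpoint, looped.unit_length))
        return [(contig, s, e) for s, e in pieces]
    if which not in looped.regions:
        raise KeyError(f"region {which!r} not in annotation")
    return [(contig, s, e) for s, e in looped.regions[which]]


def _contiguous_native_end(looped: LoopedReference) -> tuple[int, int]:
    """Native (start, end) of the annotated transcribed unit, recovered from
    its looped pieces (the transcript was annotated natively as one interval)."""
    pieces = looped.regions["transcript"]
    native_positions = []
    for s, e in pieces:
        native_positions.append(looped.looped_to_native(s))
        native_positions.append((looped.looped_to_native(e - 1) + 1))
    return min(native_positions), max(native_positions)


def rdna_promoter_and_unit_methylation(records: pd.DataFrame, looped: LoopedReference,
                                       contig: str = "rDNA",
                                       *, sample_id: str = "sample",
                                       promoter_upstream: int = DEFAULT_RDNA_PROMOTER_UPSTREAM,
                                       min_coverage: int = DEFAULT_MIN_COVERAGE,
                                       weighting: str = "coverage",
                                       subregion: str | None = None) -> MethylationSummary:
    """Mean methylation across the rDNA promoter plus transcribed unit.

    The window runs from ``promoter_upstream`` bases upstream of the TSS to
    the end of the transcribed region, expressed on the looped contig (two
    intervals when the window crosses the loop junction).  ``subregion``
    selects a named annotation region instead (``UCE``, ``core_promoter``,
    ``18S``...).
    """
    which = subregion if subregion is not None else "promoter_and_unit"
    intervals = rdna_region_intervals(looped, contig, which, promoter_upstream)
    return region_methylation(records, intervals, sample_id=sample_id,
                              region_name=which, min_coverage=min_coverage,
                              weighting=weighting)


def feature_methylation_and_coverage(records: pd.DataFrame,
                                     features: Mapping[str, Sequence[Interval]],
                                     *, sample_id: str = "sample",
                                     weighting: str = "coverage"
                                     ) -> dict[str, tuple[MethylationSummary, float]]:
    """Per-feature-class methylation and mean CpG read coverage.

    CpGs are assigned by position containment; no coverage filter is applied
    (feature classes use all CpGs).  Coverage per class is the mean over
    contained CpGs of (methylated + unmethylated reads); ``nan`` when the
    class contains no CpG.
    """
    out: dict[str, tuple[MethylationSummary, float]] = {}
    for name, intervals in features.items():
        summary = region_methylation(records, intervals, sample_id=sample_id,
                                     region_name=name, min_coverage=0,
                                     weighting=weighting)
        if summary.is_empty:
            out[name] = (summary, math.nan)
        else:
            sub = records[_in_intervals(records, intervals)]
            out[name] = (summary, float((sub["meth"] + sub["unmeth"]).mean()))
    return out


def promoter_intervals(tss_list: Sequence[tuple[str, int, str]], flank: int = 1000
                       ) -> list[Interval]:
    """Genome promoters: +/- ``flank`` bases around each TSS (strand-agnostic
    window; the strand column is accepted for interface symmetry)."""
    out = []
    for contig, tss, _strand in tss_list:
        out.append((contig, max(0, tss - flank), tss + flank))
    return out


# ---------------------------------------------------------------------------
# methylation-adjusted copy number


def methylation_adjusted_cn(cn: CopyNumberEstimate, meth: MethylationSummary) -> ActiveCopyEstimate:
    """Discount copies by the methylated (presumed silenced) fraction."""
    if meth.is_empty:
        raise ValueError(f"sample {cn.sample_id}: no methylation summary available")
    m = meth.mean_methylation
    return ActiveCopyEstimate(sample_id=cn.sample_id, raw_cn=cn.value,
                              mean_methylation=m, active_cn=cn.value * (1.0 - m))


def summaries_to_table(summaries: Sequence[MethylationSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": s.sample_id, "region": s.region_name,
        "mean_methylation": math.nan if s.is_empty else s.mean_methylation,
        "n_cpgs_used": s.n_cpgs_used, "n_cpgs_filtered": s.n_cpgs_filtered,
        "total_coverage": s.total_coverage, "weighting": s.weighting,
    } for s in summaries])
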