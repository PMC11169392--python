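"""rDNA copy-number estimation.

Three estimators, kept in deliberately distinct units:

* ``wgbs_absolute`` — absolute copies per diploid genome from WGBS-style
  depth: ``CN = 2 * mean_depth(18S) / mean_depth(exome)``, the factor 2
  anchoring the single-copy exome at diploid ploidy.
* ``rrbs_relative`` — a unitless per-sample fraction for RRBS libraries,
  whose exome coverage is too patchy for a depth denominator: reads aligned
  to the rDNA contig divided by total alignments.  Comparable across
  samples only by rank.
* ``ddpcr`` — sequencing-independent: reference ploidy times the
  FAM(target)/VIC(single-copy reference) concentration ratio, with wells
  excluded when the mean copies-per-partition (Lambda) is high enough to
  violate Poisson quantification assumptions.

Plus the cross-validation between estimators and the down-sampling
robustness analysis (split reads into equal subsamples, re-estimate CN from
merged subsets at decreasing coverage fractions).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

Interval = tuple[str, int, int]  # contig, start, end (0-based half-open)

DEFAULT_LAMBDA_THRESHOLD = 1.6


@dataclass(frozen=True)
class DepthSummary:
    sample_id: str
    mean_depth_18s: float
    mean_depth_exome: float
    n_bases_18s: int
    n_bases_exome: int

    def __post_init__(self) -> None:
        if self.mean_depth_18s < 0 or self.mean_depth_exome < 0:
            raise ValueError("depths must be non-negative")
        if self.n_bases_18s <= 0 or self.n_bases_exome <= 0:
            raise ValueError("base counts must be positive")


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    method: str  # wgbs_absolute | rrbs_relative | ddpcr
    value: float
    inputs_digest: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("copy number cannot be negative")
        if self.method not in {"wgbs_absolute", "rrbs_relative", "ddpcr"}:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class ReadCountSummary:
    sample_id: str
    rdna_aligned_reads: int
    total_alignments: int

    def __post_init__(self) -> None:
        if self.total_alignments <= 0:
            raise ValueError("total_alignments must be positive")
        if not 0 <= self.rdna_aligned_reads <= self.total_alignments:
            raise ValueError("rdna_aligned_reads outside [0, total_alignments]")


@dataclass(frozen=True)
class DdpcrWell:
    sample_id: str
    target_concentration: float  # FAM channel, copies per unit volume
    reference_concentration: float  # VIC channel
    lambda_cp_per_rxn: float
    reference_ploidy: float = 2.0

    def __post_init__(self) -> None:
        if min(self.target_concentration, self.reference_concentration, self.lambda_cp_per_rxn) < 0:
            raise ValueError("ddPCR quantities must be non-negative")


@dataclass(frozen=True)
class DdpcrExclusion:
    sample_id: str
    reason: str
    lambda_cp_per_rxn: float


# ---------------------------------------------------------------------------
# depth


def _is_unique(read, uniqueness_rule: str) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if uniqueness_rule == "nh_tag" and read.has_tag("NH"):
        return read.get_tag("NH") == 1
    return True


def _region_mean_from_cov(cov_by_contig: Mapping[str, np.ndarray], intervals: Sequence[Interval]) -> tuple[float, int]:
    total, nbases = 0.0, 0
    for contig, s, e in intervals:
        if e <= s:
            raise ValueError(f"zero-length region {contig}:{s}-{e}")
        if contig not in cov_by_contig:
            raise KeyError(f"region contig {contig!r} absent from input")
        arr = cov_by_contig[contig]
        seg = arr[s:e]
        total += float(seg.sum())
        # positions beyond the recorded array have zero depth
        nbases += e - s
    return total / nbases, nbases


def depth_from_alignments(source, regions: Mapping[str, Sequence[Interval]], sample_id: str,
                          uniqueness_rule: str = "primary") -> DepthSummary:
    """Per-base mean unique-read depth over the 18S and exome regions.

    ``source`` is either a SAM/BAM path (parsed with pysam; secondary and
    supplementary alignments excluded, ``uniqueness_rule="nh_tag"``
    additionally requires NH==1) or a per-base depth table — a DataFrame
    with columns ``contig, pos, depth`` (0-based), in which uniqueness is
    assumed to have been applied upstream.  ``regions`` maps ``"18S"`` and
    ``"exome"`` to interval lists; split looped-annotation intervals are
    averaged jointly (sum of depth over all intervals / total length).
    """
    for key in ("18S", "exome"):
        if key not in regions or not regions[key]:
            raise ValueError(f"regions must define {key!r}")
    if isinstance(source, pd.DataFrame):
        cov: dict[str, np.ndarray] = {}
        for contig, grp in source.groupby("contig"):
            size = int(grp["pos"].max()) + 1
            arr = np.zeros(size)
            arr[grp["pos"].to_numpy()] = grp["depth"].to_numpy()
            cov[contig] = arr
        needed = {c for ivs in regions.values() for c, _, _ in ivs}
        for contig in needed:
            if contig not in cov:
                raise KeyError(f"region contig {contig!r} absent from depth table")
        # extend arrays so slicing never truncates
        for contig in needed:
            maxend = max(e for ivs in regions.values() for c, _, e in ivs if c == contig)
            if len(cov[contig]) < maxend:
                cov[contig] = np.pad(cov[contig], (0, maxend - len(cov[contig])))
    else:
        import pysam

        cov = {}
        with pysam.AlignmentFile(str(source)) as af:
            needed = {c for ivs in regions.values() for c, _, _ in ivs}
            for contig in needed:
                if contig not in af.references:
                    raise KeyError(f"region contig {contig!r} absent from alignment file")
                cov[contig] = np.zeros(af.get_reference_length(contig))
            # stream all records (works for unindexed SAM) and pile up the
            # aligned reference positions of unique primary alignments
            for read in af.fetch(until_eof=True):
                if not _is_unique(read, uniqueness_rule):
                    continue
                if read.reference_name not in cov:
                    continue
                arr = cov[read.reference_name]
                for blk_start, blk_end in read.get_blocks():
                    arr[blk_start:blk_end] += 1
    d18, n18 = _region_mean_from_cov(cov, regions["18S"])
    dex, nex = _region_mean_from_cov(cov, regions["exome"])
    return DepthSummary(sample_id=sample_id, mean_depth_18s=d18, mean_depth_exome=dex,
                        n_bases_18s=n18, n_bases_exome=nex)


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """3-column TSV (contig, 0-based position, depth) -> DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "pos", "depth"],
                     dtype={"contig": str, "pos": np.int64, "depth": np.float64})
    if (df["pos"] < 0).any() or (df["depth"] < 0).any():
        raise ValueError("negative position or depth in depth table")
    return df


# ---------------------------------------------------------------------------
# estimators


def estimate_cn_wgbs(depth: DepthSummary) -> CopyNumberEstimate:
    """Absolute rDNA copies per diploid genome: ``2 * d(18S) / d(exome)``."""
    if depth.mean_depth_exome <= 0:
        raise ValueError(f"sample {depth.sample_id}: exome depth is zero; CN undefined")
    value = 2.0 * depth.mean_depth_18s / depth.mean_depth_exome
    return CopyNumberEstimate(
        sample_id=depth.sample_id, method="wgbs_absolute", value=value,
        inputs_digest={"mean_depth_18s": depth.mean_depth_18s,
                       "mean_depth_exome": depth.mean_depth_exome})


def estimate_cn_rrbs(counts: ReadCountSummary) -> CopyNumberEstimate:
    """Relative rDNA abundance: rDNA-aligned reads / total alignments."""
    value = counts.rdna_aligned_reads / counts.total_alignments
    return CopyNumberEstimate(
        sample_id=counts.sample_id, method="rrbs_relative", value=value,
        inputs_digest={"rdna_aligned_reads": counts.rdna_aligned_reads,
                       "total_alignments": counts.total_alignments})


def estimate_cn_ddpcr(well: DdpcrWell, lambda_threshold: float = DEFAULT_LAMBDA_THRESHOLD
                      ) -> CopyNumberEstimate | DdpcrExclusion:
    """ddPCR CN = reference_ploidy * FAM / VIC; high-Lambda wells excluded."""
    if well.lambda_cp_per_rxn >= lambda_threshold:
        return DdpcrExclusion(sample_id=well.sample_id,
                              reason=f"lambda >= {lambda_threshold}",
                              lambda_cp_per_rxn=well.lambda_cp_per_rxn)
    if well.reference_concentration <= 0:
        raise ValueError(f"sample {well.sample_id}: zero reference concentration")
    value = well.reference_ploidy * well.target_concentration / well.reference_concentration
    return CopyNumberEstimate(
        sample_id=well.sample_id, method="ddpcr", value=value,
        inputs_digest={"target_concentration": well.target_concentration,
                       "reference_concentration": well.reference_concentration,
                       "lambda_cp_per_rxn": well.lambda_cp_per_rxn})


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class CrossValidationReport:
    n: int
    spearman_r: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    shared_ids: tuple[str, ...]
    methods: tuple[str, str]


def cross_validate(estimates_a: Sequence[CopyNumberEstimate],
                   estimates_b: Sequence[CopyNumberEstimate]) -> CrossValidationReport:
    """Rank agreement between two estimators on their shared samples.

    Because the two methods may live on different scales (absolute copies vs
    a read fraction) the headline statistic is Spearman; Pearson is reported
    alongside for same-scale comparisons.
    """
    a = {e.sample_id: e.value for e in estimates_a}
    b = {e.sample_id: e.value for e in estimates_b}
    shared = sorted(a.keys() & b.keys())
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    xs = np.array([a[s] for s in shared])
    ys = np.array([b[s] for s in shared])
    sr = sps.spearmanr(xs, ys)
    pr = sps.pearsonr(xs, ys)
    return CrossValidationReport(
        n=len(shared), spearman_r=float(sr.statistic), spearman_p=float(sr.pvalue),
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        shared_ids=tuple(shared),
        methods=(estimates_a[0].method if estimates_a else "?",
                 estimates_b[0].method if estimates_b else "?"))


# ---------------------------------------------------------------------------
# down-sampling stability


DEFAULT_FRACTIONS = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)


def partition_reads(n_reads: int, n_subsamples: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Exhaustive disjoint split into equal subsamples (sizes differ by <= 1).

    Reads are shuffled once, then dealt round-robin, mirroring equal-size
    FASTQ splitting at desk scale.
    """
    order = rng.permutation(n_reads)
    return [order[i::n_subsamples] for i in range(n_subsamples)]


def cn_from_read_records(reads: pd.DataFrame, region_lengths: Mapping[str, int],
                         sample_id: str = "sample") -> CopyNumberEstimate:
    """WGBS CN from labelled read records (columns ``target`` in {18S, exome}
    and ``length`` in bases); depth = aligned bases / region length."""
    lens = reads.groupby("target")["length"].sum()
    d18 = float(lens.get("18S", 0)) / region_lengths["18S"]
    dex = float(lens.get("exome", 0)) / region_lengths["exome"]
    depth = DepthSummary(sample_id=sample_id, mean_depth_18s=d18, mean_depth_exome=max(dex, 1e-300),
                         n_bases_18s=region_lengths["18S"], n_bases_exome=region_lengths["exome"])
    return estimate_cn_wgbs(depth)


def downsampling_stability(reads: pd.DataFrame, region_lengths: Mapping[str, int],
                           n_subsamples: int = 10,
                           fractions: Sequence[float] = DEFAULT_FRACTIONS,
                           seed: int = 0, sample_id: str = "sample") -> pd.DataFrame:
    """Re-estimate CN from merged random subsamples at decreasing coverage.

    Reads are split into ``n_subsamples`` equal parts (exhaustive, disjoint);
    a fraction ``f`` estimate merges ``round(f * n_subsamples)`` parts chosen
    at random under ``seed``.  Returns a table of (fraction, cn,
    relative_deviation) against the full-data estimate, which is included as
    the ``fraction == 1.0`` row.  Deterministic for a fixed seed.
    """
    if len(reads) < n_subsamples:
        raise ValueError("fewer reads than subsamples")
    rng = np.random.default_rng(seed)
    parts = partition_reads(len(reads), n_subsamples, rng)
    full = cn_from_read_records(reads, region_lengths, sample_id)
    rows = [{"fraction": 1.0, "cn": full.value, "relative_deviation": 0.0}]
    for f in fractions:
        k_exact = f * n_subsamples
        k = int(round(k_exact))
        if abs(k_exact - k) > 1e-9:
            warnings.warn(f"fraction {f} is not a multiple of 1/{n_subsamples}; "
                          f"using {k}/{n_subsamples}")
        if k < 1:
            raise ValueError(f"fraction {f} leaves no subsample")
        chosen = rng.choice(n_subsamples, size=k, replace=False)
        idx = np.concatenate([parts[i] for i in chosen])
        est = cn_from_read_records(reads.iloc[idx], region_lengths, sample_id)
        rows.append({"fraction": f, "cn": est.value,
                     "relative_deviation": abs(est.value - full.value) / full.value
                     if full.value else math.nan})
    out = pd.DataFrame(rows)
    out.attrs["full_cn"] = full.value
    out.attrs["seed"] = seed
    return out


# ---------------------------------------------------------------------------
# tables


def estimates_to_table(estimates: Sequence[CopyNumberEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        row = {"sample_id": e.sample_id, "method": e.method, "value": e.value}
        row.update({f"input_{k}": v for k, v in e.inputs_digest.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def read_ddpcr_csv(path: str | Path) -> list[DdpcrWell]:
    """CSV with columns sample, fam_conc, vic_conc, lambda (header required)."""
    df = pd.read_csv(path)
    wells = []
    for _, r in df.iterrows():
        wells.append(DdpcrWell(sample_id=str(r["sample"]),
                               target_concentration=float(r["fam_conc"]),
                               reference_concentration=float(r["vic_conc"]),
                               lambda_cp_per_rxn=float(r["lambda"])))
    return wells
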