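"""Reference engineering for a multicopy rDNA locus.

The 47S ribosomal DNA repeat is absent from standard genome assemblies,
which instead contain scattered partial "pseudocopies".  Quantifying rDNA
copy number and methylation from short-read alignments therefore requires a
purpose-built reference:

* a *looped* rDNA unit — the consensus unit rotated so that the artificial
  start/end junction falls inside the intergenic spacer (IGS), far from the
  promoter, so reads spanning the natural unit boundary align contiguously;
* the genome assembly with known pseudocopies hard-masked to ``N`` and the
  looped unit appended as an extra contig;
* a single-copy exome reference (short and sex-chromosome exons removed,
  mutually similar sequences deduplicated) used as the depth denominator
  for absolute copy-number estimation.

All coordinates are 0-based half-open.  BED input is interpreted as such;
1-based inclusive ranges from annotation text are converted at the boundary
(see :func:`slice_1based_inclusive`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = tuple[int, int]

DEFAULT_UPSTREAM_OFFSET = 2120
"""Distance (bases) from the loop breakpoint to the transcription start
site: the breakpoint sits this far upstream of the TSS, inside the IGS."""


# ---------------------------------------------------------------------------
# annotation and looped unit


@dataclass(frozen=True)
class RdnaUnitAnnotation:
    """Annotation of the native (unrotated) rDNA unit.

    Parameters
    ----------
    unit_length
        Length of the consensus unit in bases.
    tss
        0-based offset of the 47S transcription start site.
    regions
        Named 0-based half-open intervals in native coordinates, e.g.
        ``{"18S": [(s, e)], "promoter": [...], "transcript": [...]}``.
    breakpoint
        0-based offset of the loop point; derived from ``tss`` via
        :func:`derive_breakpoint` when not given explicitly.
    """

    unit_length: int
    tss: int
    regions: Mapping[str, Sequence[Interval]] = field(default_factory=dict)
    breakpoint: int | None = None

    def __post_init__(self) -> None:
        if self.unit_length <= 0:
            raise ValueError("unit_length must be positive")
        if not 0 <= self.tss < self.unit_length:
            raise ValueError("tss outside unit")
        if self.breakpoint is not None and not 0 <= self.breakpoint < self.unit_length:
            raise ValueError("breakpoint outside unit")
        for name, ivs in self.regions.items():
            for s, e in ivs:
                if not (0 <= s < e <= self.unit_length):
                    raise ValueError(f"region {name!r} interval ({s},{e}) outside unit")


def derive_breakpoint(annotation: RdnaUnitAnnotation, upstream_offset: int = DEFAULT_UPSTREAM_OFFSET) -> int:
    """Loop point located ``upstream_offset`` bases upstream of the TSS.

    The offset is taken modulo the unit length, so a TSS close to the unit
    start wraps around to the far end of the unit.
    """
    if upstream_offset >= annotation.unit_length:
        raise ValueError("upstream_offset must be smaller than the unit length")
    return (annotation.tss - upstream_offset) % annotation.unit_length


def rotate_interval(interval: Interval, breakpoint: int, unit_length: int) -> list[Interval]:
    """Map a native-coordinate interval onto the rotated (looped) unit.

    Returns one interval, or two when the rotation splits the region across
    the new contig ends.
    """
    s, e = interval
    if not (0 <= s < e <= unit_length):
        raise ValueError(f"invalid interval ({s},{e})")
    s2 = (s - breakpoint) % unit_length
    length = e - s
    if s2 + length <= unit_length:
        return [(s2, s2 + length)]
    head = unit_length - s2
    return [(s2, unit_length), (0, length - head)]


@dataclass(frozen=True)
class LoopedReference:
    """A rotated rDNA unit with its coordinate map and remapped annotation."""

    sequence: str
    breakpoint: int
    unit_length: int
    tss_looped: int
    regions: Mapping[str, Sequence[Interval]] = field(default_factory=dict)

    def native_to_looped(self, pos: int) -> int:
        if not 0 <= pos < self.unit_length:
            raise ValueError("position outside unit")
        return (pos - self.breakpoint) % self.unit_length

    def looped_to_native(self, pos: int) -> int:
        if not 0 <= pos < self.unit_length:
            raise ValueError("position outside unit")
        return (pos + self.breakpoint) % self.unit_length


def build_looped_unit(unit_sequence: str, breakpoint: int,
                      annotation: RdnaUnitAnnotation | None = None) -> LoopedReference:
    """Rotate the rDNA unit so that ``breakpoint`` becomes position 0.

    The bases from the breakpoint to the unit end are prepended to the bases
    upstream of the breakpoint, i.e. ``unit[breakpoint:] + unit[:breakpoint]``.
    Annotated regions are remapped; a region split by the rotation is
    represented as two looped intervals.
    """
    n = len(unit_sequence)
    if n == 0:
        raise ValueError("empty unit sequence")
    if not 0 <= breakpoint < n:
        raise ValueError(f"breakpoint {breakpoint} out of range for unit of length {n}")
    looped_seq = unit_sequence[breakpoint:] + unit_sequence[:breakpoint]
    regions: dict[str, list[Interval]] = {}
    tss_native = breakpoint  # placeholder when no annotation supplied
    if annotation is not None:
        if annotation.unit_length != n:
            raise ValueError("annotation unit_length does not match sequence")
        tss_native = annotation.tss
        for name, ivs in annotation.regions.items():
            out: list[Interval] = []
            for iv in ivs:
                out.extend(rotate_interval(iv, breakpoint, n))
            regions[name] = out
    tss_looped = (tss_native - breakpoint) % n
    return LoopedReference(sequence=looped_seq, breakpoint=breakpoint,
                           unit_length=n, tss_looped=tss_looped, regions=regions)


# ---------------------------------------------------------------------------
# masking


@dataclass(frozen=True)
class MaskSpec:
    """Pseudocopy regions to hard-mask, as (contig, start, end) half-open."""

    regions: Sequence[tuple[str, int, int]] = ()

    def __post_init__(self) -> None:
        for contig, s, e in self.regions:
            if s >= e or s < 0:
                raise ValueError(f"invalid mask interval {contig}:{s}-{e}")


def mask_and_append(genome: Mapping[str, str], mask: MaskSpec,
                    looped: LoopedReference | str, extra_contig_name: str) -> dict[str, str]:
    """Hard-mask pseudocopy intervals and append the rDNA contig.

    Masked positions become ``N``; every other base and every contig length
    is unchanged.  ``looped`` may be a :class:`LoopedReference` or a plain
    sequence (used for the rat 18S-only reference).
    """
    if extra_contig_name in genome:
        raise ValueError(f"contig name collision: {extra_contig_name!r}")
    out = {name: seq for name, seq in genome.items()}
    for contig, s, e in mask.regions:
        if contig not in out:
            raise KeyError(f"mask interval on unknown contig {contig!r}")
        seq = out[contig]
        if e > len(seq):
            raise ValueError(f"mask interval {contig}:{s}-{e} beyond contig end")
        out[contig] = seq[:s] + "N" * (e - s) + seq[e:]
    extra = looped.sequence if isinstance(looped, LoopedReference) else looped
    out[extra_contig_name] = extra
    return out


def build_rat_reference(genome: Mapping[str, str], mask: MaskSpec,
                        unit_18s: str, contig_name: str = "rDNA_18S") -> dict[str, str]:
    """Masked assembly with only the 18S subsequence appended (no looping).

    The rat rDNA consensus spans only 18S..28S, so no IGS breakpoint exists;
    copy number is instead read from depth over this dedicated 18S contig.
    """
    if not unit_18s:
        raise ValueError("empty 18S sequence")
    return mask_and_append(genome, mask, unit_18s, contig_name)


def slice_1based_inclusive(sequence: str, start: int, end: int) -> str:
    """Extract a 1-based inclusive range, e.g. ``(1, 1874)`` -> first 1874 bases."""
    if start < 1 or end < start or end > len(sequence):
        raise ValueError(f"invalid 1-based range {start}..{end}")
    return sequence[start - 1:end]


# ---------------------------------------------------------------------------
# exome filtering


@dataclass(frozen=True)
class ExomeFilterPolicy:
    """Rules producing a deduplicated single-copy exome depth denominator."""

    min_length: int = 300
    excluded_contigs: frozenset[str] = frozenset({"chrX", "chrY", "X", "Y"})
    similarity_k: int = 31
    similarity_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if not 0 < self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ExonRecord:
    id: str
    contig: str
    sequence: str


@dataclass(frozen=True)
class RemovalEntry:
    id: str
    reason: str  # excluded_contig | too_short | similar
    partner: str | None = None


def kmer_set(sequence: str, k: int) -> frozenset[str]:
    seq = sequence.upper()
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def kmer_jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 0.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def filter_exome(exons: Iterable[ExonRecord], policy: ExomeFilterPolicy = ExomeFilterPolicy()
                 ) -> tuple[list[ExonRecord], list[RemovalEntry]]:
    """Retain single-copy autosomal exons long enough for stable depth.

    Removes exons on excluded contigs or shorter than ``min_length``, then
    resolves mutually similar pairs (shared-k-mer Jaccard above threshold) by
    dropping the shorter member, ties broken by keeping the lexicographically
    smaller identifier.  The removal log names the retained partner of every
    similarity casualty, so the decision is auditable.
    """
    records = list(exons)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate exon identifiers")
    removed: list[RemovalEntry] = []
    survivors: list[ExonRecord] = []
    for rec in records:
        if rec.contig in policy.excluded_contigs:
            removed.append(RemovalEntry(rec.id, "excluded_contig"))
        elif len(rec.sequence) < policy.min_length:
            removed.append(RemovalEntry(rec.id, "too_short"))
        else:
            survivors.append(rec)
    survivors.sort(key=lambda r: r.id)
    kmers = {r.id: kmer_set(r.sequence, policy.similarity_k) for r in survivors}
    alive = {r.id: r for r in survivors}
    for i, a in enumerate(survivors):
        for b in survivors[i + 1:]:
            if a.id not in alive or b.id not in alive:
                continue
            if kmer_jaccard(kmers[a.id], kmers[b.id]) > policy.similarity_threshold:
                # drop the shorter; tie -> drop the lexicographically greater id
                if len(a.sequence) < len(b.sequence):
                    victim, keeper = a, b
                elif len(b.sequence) < len(a.sequence):
                    victim, keeper = b, a
                else:
                    victim, keeper = (b, a) if a.id < b.id else (a, b)
                del alive[victim.id]
                removed.append(RemovalEntry(victim.id, "similar", partner=keeper.id))
    retained = [r for r in records if r.id in alive]
    return retained, removed


# ---------------------------------------------------------------------------
# file boundaries


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_mask_bed(path: str | Path) -> MaskSpec:
    """BED (0-based half-open) -> MaskSpec; extra columns ignored."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            regions.append((parts[0], int(parts[1]), int(parts[2])))
    return MaskSpec(tuple(regions))


def write_coordinate_map(looped: LoopedReference, path: str | Path) -> None:
    """JSON sidecar recording the rotation and the remapped annotation."""
    payload = {
        "unit_length": looped.unit_length,
        "breakpoint": looped.breakpoint,
        "tss_looped": looped.tss_looped,
        "mapping": "looped = (native - breakpoint) mod unit_length",
        "regions_looped": {name: [list(iv) for iv in ivs] for name, ivs in looped.regions.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def scan_kmers(contigs: Mapping[str, str], query_kmers: frozenset[str], k: int) -> dict[str, int]:
    """Count occurrences of any query k-mer per contig (pseudocopy leak check)."""
    hits: dict[str, int] = {}
    for name, seq in contigs.items():
        seq = seq.upper()
        n = sum(1 for i in range(len(seq) - k + 1) if seq[i:i + k] in query_kmers)
        if n:
            hits[name] = n
    return hits
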