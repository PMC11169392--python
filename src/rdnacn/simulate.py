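"""Ground-truthed synthetic data for every pipeline stage.

Each generator emits observations in exactly the formats the other modules
consume (per-base depth tables, bismark-style CpG coverage, alignment-count
summaries, ddPCR wells, cohort phenotype tables, long-format weekly
weights) together with the latent truth that produced them, so recovery can
be asserted instead of assumed.

The generative structure mirrors the study designs this package analyses:

* per-sample true rDNA copy number, uniform across a wide population range;
* per-base read depth Poisson around ``CN/2 * exome_depth`` on the 18S and
  around ``exome_depth`` on the single-copy exome;
* per-sample mean rDNA methylation coupled to copy number through a
  Gaussian copula with Beta marginals (higher-CN individuals carry more
  methylated copies), with fixed per-CpG site effects and binomial read
  sampling on top;
* RRBS read allocation binomial with rDNA probability proportional to CN;
* BMI linear in standardised CN with a configurable (negative) slope,
  nulled in a "medicated" stratum;
* monozygotic twin pairs sharing true CN exactly, discordant in BMI;
* weekly weights following an exponential-plateau growth curve whose gain,
  but not starting weight, decreases with CN — so the CN association is
  absent at the first week and emerges by the last;
* ddPCR wells with FAM/VIC concentrations and Poisson-loading Lambda.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cn import DdpcrWell, ReadCountSummary
from .methylation import write_cpg_calls
from .reference import (LoopedReference, MaskSpec, RdnaUnitAnnotation,
                        build_looped_unit, derive_breakpoint)


# ---------------------------------------------------------------------------
# desk-scale rDNA unit


def default_annotation(unit_length: int = 13000, tss: int = 3000) -> RdnaUnitAnnotation:
    """A desk-scale rDNA unit annotation.

    The true human unit is ~45 kb with a ~13.3 kb transcript; this compact
    stand-in keeps the same topology (promoter upstream of the TSS, 18S
    inside the transcribed region, regulatory elements in the IGS) at a
    size convenient for simulation.  The 18S keeps its real 1869 bp length
    so depth averaging operates at a realistic interval size.
    """
    return RdnaUnitAnnotation(
        unit_length=unit_length, tss=tss,
        regions={
            "transcript": [(tss, tss + 9000)],
            "18S": [(tss + 1000, tss + 1000 + 1869)],
            "promoter": [(tss - 1000, tss)],
            "UCE": [(tss - 200, tss - 107)],
            "core_promoter": [(tss - 45, tss + 20)],
        })


def default_looped(annotation: RdnaUnitAnnotation | None = None,
                   upstream_offset: int = 2120) -> LoopedReference:
    """Looped desk-scale unit (synthetic sequence, seeded independently of
    any cohort randomness)."""
    ann = annotation or default_annotation()
    rng = np.random.default_rng(19860701)
    seq = "".join(rng.choice(list("ACGT"), size=ann.unit_length))
    bp = derive_breakpoint(ann, upstream_offset)
    return build_looped_unit(seq, bp, ann)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the WGBS-style discovery cohort.

    Defaults follow the emulated study: 63 males at ~14x exome depth, true
    copy number uniform on [150, 600] per diploid genome, CN-methylation
    Spearman coupling 0.74, RRBS libraries of five million alignments, and
    a negative standardised BMI-on-CN slope that is absent in the medicated
    stratum.  The exome is represented by 20 kb of single-copy sequence —
    enough bases that the depth denominator's sampling error is well below
    the 18S term's.
    """

    n_samples: int = 63
    cn_low: float = 150.0
    cn_high: float = 600.0
    exome_depth: float = 14.0
    n_exome_bases: int = 20000
    rho_cn_meth: float = 0.74
    meth_beta_mean: float = 0.30
    meth_beta_concentration: float = 25.0
    n_cpgs: int = 100
    cpg_site_sd: float = 0.04
    cpg_coverage_mean: float = 120.0
    rrbs_total_alignments: int = 5_000_000
    rdna_read_prob_per_copy: float = 1.25e-6
    bmi_mean: float = 27.0
    bmi_sd: float = 4.0
    bmi_cn_effect: float = -0.30
    bmi_cn_effect_medicated: float = 0.0
    medicated_fraction: float = 0.41
    age_mean: float = 55.0
    age_sd: float = 6.0
    ddpcr_vic_mean: float = 50.0
    ddpcr_conc_cv: float = 0.05
    ddpcr_lambda_shape: float = 4.0
    ddpcr_lambda_scale: float = 0.2


@dataclass
class CohortSimulation:
    """Simulated inputs plus the latent truth, keyed by sample id."""

    config: SimulationConfig
    seed: int
    truth: pd.DataFrame
    phenotypes: pd.DataFrame
    depth_tables: dict[str, pd.DataFrame]
    cpg_tables: dict[str, pd.DataFrame]
    read_counts: list[ReadCountSummary]
    ddpcr_wells: list[DdpcrWell]
    looped: LoopedReference
    regions: dict[str, list[tuple[str, int, int]]]
    rdna_contig: str = "rDNA"

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(json.dumps({
            "seed": self.seed, "config": asdict(self.config)}, indent=2) + "\n")
        self.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        for sid, df in self.depth_tables.items():
            df.to_csv(out / f"{sid}.depth.tsv", sep="\t", index=False, header=False)
        for sid, df in self.cpg_tables.items():
            write_cpg_calls(df, out / f"{sid}.cov.tsv")
        pd.DataFrame([{"sample_id": r.sample_id, "rdna_aligned_reads": r.rdna_aligned_reads,
                       "total_alignments": r.total_alignments} for r in self.read_counts]
                     ).to_csv(out / "rrbs_counts.tsv", sep="\t", index=False)
        pd.DataFrame([{"sample": w.sample_id, "fam_conc": w.target_concentration,
                       "vic_conc": w.reference_concentration, "lambda": w.lambda_cp_per_rxn}
                      for w in self.ddpcr_wells]).to_csv(out / "ddpcr.csv", index=False)


def _copula_pair(rho_s: float, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Correlated uniforms via a Gaussian copula hitting a target Spearman.

    For the bivariate normal copula, Spearman's rho relates to the Gaussian
    correlation as ``rho_s = (6/pi) * arcsin(rho_z / 2)``; inverting gives
    the latent correlation to use.
    """
    if not -1.0 < rho_s < 1.0:
        raise ValueError(f"target Spearman correlation {rho_s} infeasible")
    rho_z = 2.0 * math.sin(math.pi * rho_s / 6.0)
    z1 = rng.standard_normal(n)
    z2 = rho_z * z1 + math.sqrt(1.0 - rho_z ** 2) * rng.standard_normal(n)
    return sps.norm.cdf(z1), sps.norm.cdf(z2)


def simulate_cohort(config: SimulationConfig = SimulationConfig(), seed: int = 0,
                    looped: LoopedReference | None = None) -> CohortSimulation:
    """Generate one WGBS-style cohort with full latent truth."""
    cfg = config
    rng = np.random.default_rng(seed)
    looped = looped or default_looped()
    sample_ids = [f"S{i:03d}" for i in range(cfg.n_samples)]

    u_cn, u_m = _copula_pair(cfg.rho_cn_meth, cfg.n_samples, rng)
    cn_true = cfg.cn_low + u_cn * (cfg.cn_high - cfg.cn_low)
    a = cfg.meth_beta_mean * cfg.meth_beta_concentration
    b = (1.0 - cfg.meth_beta_mean) * cfg.meth_beta_concentration
    meth_true = sps.beta.ppf(u_m, a, b)

    # regions on the looped contig (18S may be split by the rotation)
    s18 = [("rDNA", s, e) for s, e in looped.regions["18S"]]
    regions = {"18S": s18, "exome": [("exome", 0, cfg.n_exome_bases)]}

    depth_tables: dict[str, pd.DataFrame] = {}
    cpg_tables: dict[str, pd.DataFrame] = {}
    read_counts: list[ReadCountSummary] = []
    ddpcr_wells: list[DdpcrWell] = []

    # CpG sites: fixed positions across promoter + transcript with fixed
    # per-site offsets shared by the whole cohort
    tss_l = looped.tss_looped
    cpg_pos = np.linspace(tss_l - 1000, tss_l + 8999, cfg.n_cpgs).astype(int)
    site_offsets = rng.normal(0.0, cfg.cpg_site_sd, cfg.n_cpgs)

    for i, sid in enumerate(sample_ids):
        d18_mean = cn_true[i] / 2.0 * cfg.exome_depth
        rows = []
        for contig, s, e in s18:
            depth = rng.poisson(d18_mean, e - s)
            rows.append(pd.DataFrame({"contig": contig, "pos": np.arange(s, e), "depth": depth}))
        dex = rng.poisson(cfg.exome_depth, cfg.n_exome_bases)
        rows.append(pd.DataFrame({"contig": "exome", "pos": np.arange(cfg.n_exome_bases),
                                  "depth": dex}))
        depth_tables[sid] = pd.concat(rows, ignore_index=True)

        p_site = np.clip(meth_true[i] + site_offsets, 1e-3, 1 - 1e-3)
        cov = rng.poisson(cfg.cpg_coverage_mean, cfg.n_cpgs)
        meth_counts = rng.binomial(cov, p_site)
        cpg_tables[sid] = pd.DataFrame({
            "contig": "rDNA", "pos": cpg_pos,
            "meth": meth_counts, "unmeth": cov - meth_counts})

        p_rdna = min(cfg.rdna_read_prob_per_copy * cn_true[i], 1.0)
        rdna_reads = int(rng.binomial(cfg.rrbs_total_alignments, p_rdna))
        read_counts.append(ReadCountSummary(sample_id=sid, rdna_aligned_reads=rdna_reads,
                                            total_alignments=cfg.rrbs_total_alignments))

        vic = cfg.ddpcr_vic_mean * math.exp(rng.normal(0.0, cfg.ddpcr_conc_cv))
        fam = vic * cn_true[i] / 2.0 * math.exp(rng.normal(0.0, cfg.ddpcr_conc_cv))
        lam = float(rng.gamma(cfg.ddpcr_lambda_shape, cfg.ddpcr_lambda_scale))
        ddpcr_wells.append(DdpcrWell(sample_id=sid, target_concentration=fam,
                                     reference_concentration=vic, lambda_cp_per_rxn=lam))

    z_cn = (cn_true - cn_true.mean()) / cn_true.std()
    medicated = rng.random(cfg.n_samples) < cfg.medicated_fraction
    slope = np.where(medicated, cfg.bmi_cn_effect_medicated, cfg.bmi_cn_effect)
    noise_scale = np.sqrt(1.0 - slope ** 2)
    bmi = cfg.bmi_mean + cfg.bmi_sd * (slope * z_cn + noise_scale * rng.standard_normal(cfg.n_samples))
    age = rng.normal(cfg.age_mean, cfg.age_sd, cfg.n_samples)

    truth = pd.DataFrame({
        "sample_id": sample_ids, "cn_true": cn_true, "meth_true": meth_true,
        "active_cn_true": cn_true * (1.0 - meth_true)})
    phenotypes = pd.DataFrame({
        "sample_id": sample_ids, "bmi": bmi, "age": age,
        "medicated": np.where(medicated, "medicated", "non_medicated")})
    return CohortSimulation(config=cfg, seed=seed, truth=truth, phenotypes=phenotypes,
                            depth_tables=depth_tables, cpg_tables=cpg_tables,
                            read_counts=read_counts, ddpcr_wells=ddpcr_wells,
                            looped=looped, regions=regions)


# ---------------------------------------------------------------------------
# two-group (lean/obese) copy numbers


@dataclass(frozen=True)
class GroupConfig:
    """Lean/obese contrast: group sizes follow the emulated discovery
    cohort (31 lean, 32 obese); the copy-number shift is expressed in
    within-group standard deviations."""

    n_lean: int = 31
    n_obese: int = 32
    cn_mean: float = 400.0
    cn_sd: float = 80.0
    shift_sd: float = 0.8


def simulate_two_group_cn(config: GroupConfig = GroupConfig(), seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """True CN for a lean and an obese group; obese shifted downwards."""
    rng = np.random.default_rng(seed)
    lean = rng.normal(config.cn_mean, config.cn_sd, config.n_lean)
    obese = rng.normal(config.cn_mean - config.shift_sd * config.cn_sd,
                       config.cn_sd, config.n_obese)
    return lean, obese


# ---------------------------------------------------------------------------
# twins


@dataclass(frozen=True)
class TwinConfig:
    """BMI-discordant monozygotic twin design: 24 pairs, co-twins share
    true CN exactly; observed CN differs only by measurement noise."""

    n_pairs: int = 24
    cn_mean: float = 400.0
    cn_sd: float = 80.0
    cn_measurement_cv: float = 0.02
    meth_rho: float = 0.74
    meth_beta_mean: float = 0.30
    meth_beta_concentration: float = 25.0
    meth_measurement_sd: float = 0.01
    bmi_base_mean: float = 25.5
    bmi_base_sd: float = 3.0
    discordance_mean: float = 3.0
    discordance_sd: float = 1.0
    age_mean: float = 35.0
    age_sd: float = 8.0


def simulate_twins(config: TwinConfig = TwinConfig(), seed: int = 0
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Twin cohort records and truth.

    Returns ``(records, truth)``; records carry one row per individual with
    ``twin_pair_id``, observed CN/methylation (shared truth plus measurement
    noise) and BMI discordant by construction.
    """
    cfg = config
    if cfg.n_pairs < 3:
        raise ValueError("need at least 3 twin pairs")
    rng = np.random.default_rng(seed)
    u_cn, u_m = _copula_pair(cfg.meth_rho, cfg.n_pairs, rng)
    cn_pair = sps.norm.ppf(u_cn) * cfg.cn_sd + cfg.cn_mean
    cn_pair = np.clip(cn_pair, 10.0, None)
    a = cfg.meth_beta_mean * cfg.meth_beta_concentration
    b = (1.0 - cfg.meth_beta_mean) * cfg.meth_beta_concentration
    meth_pair = sps.beta.ppf(u_m, a, b)
    base_bmi = rng.normal(cfg.bmi_base_mean, cfg.bmi_base_sd, cfg.n_pairs)
    disc = np.abs(rng.normal(cfg.discordance_mean, cfg.discordance_sd, cfg.n_pairs))
    age = rng.normal(cfg.age_mean, cfg.age_sd, cfg.n_pairs)
    rows, truth_rows = [], []
    for i in range(cfg.n_pairs):
        pid = f"P{i:02d}"
        for role, bmi in (("heavier", base_bmi[i] + disc[i] / 2),
                          ("leaner", base_bmi[i] - disc[i] / 2)):
            sid = f"{pid}_{role}"
            cn_obs = cn_pair[i] * math.exp(rng.normal(0.0, cfg.cn_measurement_cv))
            m_obs = float(np.clip(meth_pair[i] + rng.normal(0.0, cfg.meth_measurement_sd),
                                  0.0, 1.0))
            rows.append({"sample_id": sid, "twin_pair_id": pid, "role": role,
                         "bmi": bmi, "age": age[i], "cn": cn_obs, "methylation": m_obs})
        truth_rows.append({"twin_pair_id": pid, "cn_true": cn_pair[i],
                           "meth_true": meth_pair[i], "bmi_discordance": disc[i],
                           "age": age[i]})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# longitudinal growth


@dataclass(frozen=True)
class GrowthConfig:
    """Post-pubertal growth in a rat cohort (44 animals, weeks 8-19).

    Weekly weight follows ``W(t) = Y0 + G * (1 - exp(-k (t - first_week)))``
    per animal with multiplicative lognormal observation noise.  Starting
    weight is independent of copy number; the growth span G carries the CN
    effect (standardised slope ``gain_cn_effect``), so the cross-sectional
    CN correlation is null at the first week and emerges towards the
    plateau.
    """

    n_animals: int = 44
    first_week: int = 8
    last_week: int = 19
    y0_mean: float = 180.0
    y0_sd: float = 12.0
    gain_mean: float = 80.0
    gain_sd: float = 18.0
    k_per_week: float = 0.35
    gain_cn_effect: float = 0.55
    obs_noise_cv: float = 0.03
    cn_mean: float = 400.0
    cn_sd: float = 80.0
    cn_measurement_cv: float = 0.03


def simulate_growth(config: GrowthConfig = GrowthConfig(), seed: int = 0
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weekly weights (long format) and per-animal truth.

    Returns ``(weights, truth)``: weights has columns ``sample_id, week,
    weight``; truth carries true/observed CN and the generative plateau
    parameters per animal.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    n = cfg.n_animals
    weeks = np.arange(cfg.first_week, cfg.last_week + 1)
    cn_true = np.clip(rng.normal(cfg.cn_mean, cfg.cn_sd, n), 10.0, None)
    z = (cn_true - cn_true.mean()) / cn_true.std()
    y0 = rng.normal(cfg.y0_mean, cfg.y0_sd, n)
    eff = cfg.gain_cn_effect
    if not -1.0 < eff < 1.0:
        raise ValueError("gain_cn_effect must be in (-1, 1)")
    gain = cfg.gain_mean - cfg.gain_sd * (eff * z + math.sqrt(1 - eff ** 2)
                                          * rng.standard_normal(n))
    gain = np.clip(gain, 1.0, None)
    cn_obs = cn_true * np.exp(rng.normal(0.0, cfg.cn_measurement_cv, n))
    rows = []
    for i in range(n):
        sid = f"R{i:02d}"
        mean_w = y0[i] + gain[i] * (1.0 - np.exp(-cfg.k_per_week * (weeks - cfg.first_week)))
        obs = mean_w * np.exp(rng.normal(0.0, cfg.obs_noise_cv, len(weeks)))
        for wk, wt in zip(weeks, obs):
            rows.append({"sample_id": sid, "week": int(wk), "weight": float(wt)})
    weights = pd.DataFrame(rows)
    truth = pd.DataFrame({
        "sample_id": [f"R{i:02d}" for i in range(n)],
        "cn_true": cn_true, "cn_obs": cn_obs, "y0": y0, "gain": gain,
        "ym": y0 + gain, "k_per_week": cfg.k_per_week})
    return weights, truth


# ---------------------------------------------------------------------------
# read records for the down-sampling analysis


def simulate_read_records(seed: int = 0, cn_true: float = 400.0,
                          exome_depth: float = 14.0, read_length: int = 100,
                          len_18s: int = 1869, n_exome_bases: int = 2_000_000
                          ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Labelled read records for one ~14x sample.

    Emits a read table (columns ``target`` in {18S, exome} and ``length``)
    whose aggregate depth matches the Poisson depth model, plus the region
    lengths needed to turn reads back into depth.  The exome denominator is
    Mb-scale, as in the libraries being emulated, so even a 10% subsample
    retains tens of thousands of reads on both sides of the depth ratio
    (at smaller denominators the subsample ratio itself, not the estimator,
    dominates the deviation).
    """
    rng = np.random.default_rng(seed)
    d18 = cn_true / 2.0 * exome_depth
    n_rdna = int(rng.poisson(d18 * len_18s / read_length))
    n_ex = int(rng.poisson(exome_depth * n_exome_bases / read_length))
    reads = pd.DataFrame({
        "target": np.concatenate([np.repeat("18S", n_rdna), np.repeat("exome", n_ex)]),
        "length": np.full(n_rdna + n_ex, read_length, dtype=np.int64)})
    return reads, {"18S": len_18s, "exome": n_exome_bases}


# ---------------------------------------------------------------------------
# toy reference with a planted pseudocopy


def simulate_reference_fixture(seed: int = 0) -> tuple[str, RdnaUnitAnnotation,
                                                       dict[str, str], MaskSpec]:
    """A toy rDNA unit, a 2-contig genome with a planted 18S pseudocopy,
    and the mask covering it — for exercising reference engineering
    end-to-end at desk scale."""
    rng = np.random.default_rng(seed)
    unit_length = 2000
    ann = RdnaUnitAnnotation(
        unit_length=unit_length, tss=600,
        regions={"transcript": [(600, 1800)], "18S": [(700, 1000)],
                 "promoter": [(500, 600)], "UCE": [(520, 560)],
                 "core_promoter": [(580, 620)]})
    unit = "".join(rng.choice(list("ACGT"), size=unit_length))
    chr1 = "".join(rng.choice(list("ACGT"), size=5000))
    chr2 = "".join(rng.choice(list("ACGT"), size=3000))
    pseudo = unit[700:1000]  # 18S pseudocopy planted on chr1
    chr1 = chr1[:2000] + pseudo + chr1[2000 + len(pseudo):]
    genome = {"chr1": chr1, "chr2": chr2}
    mask = MaskSpec(regions=(("chr1", 2000, 2000 + len(pseudo)),))
    return unit, ann, genome, mask
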