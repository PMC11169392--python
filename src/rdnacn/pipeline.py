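"""End-to-end convenience: run every estimator over a simulated cohort."""

from __future__ import annotations

import pandas as pd

from . import cn as cn_mod
from . import methylation as meth_mod
from .simulate import CohortSimulation


def estimate_cohort(sim: CohortSimulation) -> pd.DataFrame:
    """Estimate per-sample quantities from a simulated cohort's observation
    files: absolute WGBS copy number, relative RRBS copy number, rDNA
    promoter+unit methylation and the methylation-adjusted (active) copy
    number, joined with the latent truth.
    """
    rc = {r.sample_id: r for r in sim.read_counts}
    rows = []
    for sid in sim.truth["sample_id"]:
        depth = cn_mod.depth_from_alignments(sim.depth_tables[sid], sim.regions, sid)
        wgbs = cn_mod.estimate_cn_wgbs(depth)
        rrbs = cn_mod.estimate_cn_rrbs(rc[sid])
        msum = meth_mod.rdna_promoter_and_unit_methylation(
            sim.cpg_tables[sid], sim.looped, sim.rdna_contig, sample_id=sid)
        active = meth_mod.methylation_adjusted_cn(wgbs, msum)
        rows.append({"sample_id": sid, "cn_wgbs": wgbs.value, "cn_rrbs": rrbs.value,
                     "meth_hat": msum.mean_methylation, "active_cn": active.active_cn})
    return pd.DataFrame(rows).merge(sim.truth, on="sample_id")
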