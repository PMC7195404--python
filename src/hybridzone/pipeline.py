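"""End-to-end pipeline on a simulated study.

Chains every stage on one :func:`hybridzone.synthetic.simulate_study`
data set: EM allele frequencies -> AIM designation -> ancestry frequencies
in the ancient hybrid populations -> hybrid indexes and genomic clines in
the contemporary zone -> the consistency (enrichment) grid -> polarized LD
and pairwise F_ST -> window topologies and f_d. Writes one TSV per result
with a config-hash comment line.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ancestry, clines, enrichment, phylo, popgen
from .allele_freq import designate_aims, em_allele_frequencies
from .core_io import RunConfig, write_table
from .synthetic import SimulationConfig, StudyData, simulate_study

logger = logging.getLogger("hybridzone")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    data: StudyData
    tables: dict[str, pd.DataFrame]

    def table_names(self) -> list[str]:
        return sorted(self.tables)


def run_pipeline(
    cfg: SimulationConfig | None = None,
    out_dir: str | None = None,
    aim_threshold: float = 0.3,
    ancestry_cfg: ancestry.AncestryModelConfig | None = None,
    cline_cfg: clines.ClineMcmcConfig | None = None,
    n_perm_consistency: int = 10_000,
    fd_set_size: int = 49,
) -> PipelineResult:
    """Run every stage on one synthetic study and collect the result tables.

    MCMC settings default to desk-scale chains (a few thousand iterations);
    pass explicit configs to match longer production runs.
    """
    cfg = cfg or SimulationConfig()
    run_config = RunConfig(seed=cfg.seed, stage_options={"aim_threshold": aim_threshold})
    data = simulate_study(cfg)
    tables: dict[str, pd.DataFrame] = {}

    pop = data.populations
    parent0_pops = pop.populations(role="parent0")
    parent1_pops = pop.populations(role="parent1")
    ancient_pops = [p for p in pop.populations(role="hybrid") if p.startswith("ancient")]
    zone_pops = [p for p in pop.populations(role="hybrid") if p.startswith("zone")]

    # 1. allele frequencies + AIMs
    freqs = em_allele_frequencies(data.gl, pop)
    tables["allele_frequencies"] = freqs.to_frame()
    aims = designate_aims(freqs, parent0_pops, parent1_pops, threshold=aim_threshold)
    tables["aims"] = aims.to_frame()
    logger.info("%d AIMs of %d loci", aims.n_members, len(aims.loci))

    # 2. ancestry frequencies in the ancient hybrid populations
    a_cfg = ancestry_cfg or ancestry.AncestryModelConfig(
        n_iter=2_000, burn_in=1_000, thin=5, seed=cfg.seed
    )
    track = ancestry.fit_ancestry_frequencies(
        data.gl, freqs, aims, pop, populations=ancient_pops, cfg=a_cfg
    )
    tables["ancestry_frequencies"] = track.to_frame()
    tables["fixation_summary"] = ancestry.summarize_fixation(track)

    # 3. hybrid indexes and genomic clines in the contemporary zone
    zone_ids = pop.individuals(population=zone_pops)
    gl_zone = data.gl.subset_individuals(zone_ids)
    hi = clines.estimate_hybrid_index(gl_zone, freqs, aims)
    tables["hybrid_index"] = hi.to_frame()
    c_cfg = cline_cfg or clines.ClineMcmcConfig(
        n_chains=2, n_iter=3_000, burn_in=1_000, thin=5, seed=cfg.seed
    )
    est = clines.fit_genomic_clines(gl_zone, hi, freqs, aims, c_cfg)
    tables["cline_parameters"] = est.summary.merge(est.rhat, on="locus_id")
    tables["cline_classes"] = clines.classify_credible(est)

    # 4. consistency grid: cline deviations vs ancient ancestry extremes
    aim_loci = aims.member_locus_map()
    grid = enrichment.consistency_suite(
        est.summary,
        track.mean_track(),
        aim_loci.is_Z,
        n_perm=n_perm_consistency,
        seed=cfg.seed,
    )
    tables["consistency_grid"] = grid

    # Z-chromosome category enrichment of the credible classes
    classes = tables["cline_classes"]
    z_rows = []
    for label, mask in (
        ("restricted", classes["restricted"].to_numpy()),
        ("directional_parent1", classes["directional_parent1"].to_numpy()),
        ("directional_parent0", classes["directional_parent0"].to_numpy()),
    ):
        if mask.sum() == 0:
            continue
        lset = enrichment.LocusSet(
            np.flatnonzero(mask), label, np.nan, "top", len(mask)
        )
        res = enrichment.category_enrichment_test(
            lset, aim_loci.is_Z, n_perm=1_000, seed=cfg.seed
        )
        z_rows.append({"class": label, "n_set": int(mask.sum()), **res.as_dict()})
    tables["z_enrichment"] = pd.DataFrame(z_rows)

    # 5. polarized LD in the zone, F_ST across populations, IBD inputs
    ld = popgen.polarized_ld(
        data.gl, pop, aims, zone_pops[0], parental_freqs=freqs, allow_small=True
    )
    tables["ld_summary"] = pd.DataFrame(
        [{"population": ld.population, "mean_r": ld.mean_r, "n_loci": len(ld.locus_ids)}]
    )
    fst_rows = []
    pops_all = pop.populations()
    for i in range(len(pops_all)):
        for j in range(i + 1, len(pops_all)):
            res = popgen.fst_pair(freqs, pops_all[i], pops_all[j])
            fst_rows.append(
                {
                    "pop_a": res.population_a,
                    "pop_b": res.population_b,
                    "n_loci": res.n_loci,
                    "fst": res.fst,
                    "logit_fst": res.logit_fst,
                }
            )
    tables["fst_pairs"] = pd.DataFrame(fst_rows)

    # 6. window topologies, class tests, and f_d
    topo = phylo.assign_window_topologies(
        data.window_matrices, data.windows, method="parsimony"
    )
    tables["window_topologies"] = topo.table
    is_z_window = (topo.table["chromosome"] == "Z").to_numpy()
    class_rows = []
    for target in sorted(set(topo.labels)):
        for cname, cmask, direction in (
            ("Z", is_z_window, "excess"),
            ("autosomes", ~is_z_window, "excess"),
        ):
            res = phylo.topology_class_test(
                topo, target, cmask, n_perm=1_000, seed=cfg.seed
            )
            class_rows.append(
                {"topology_id": target, "class": cname, **res.as_dict()}
            )
    tables["topology_class_tests"] = pd.DataFrame(class_rows)

    fd_rows = []
    fd_per_window = np.empty(len(data.window_matrices))
    for k, mat in enumerate(data.window_matrices):
        res = phylo.fd_statistic(
            mat[:, 0], mat[:, 1], mat[:, 2], mat[:, 4],
            roles=("t0", "t1", "t2", "t4"), scope=f"window:{k}",
        )
        fd_per_window[k] = res.fd
    for chrom in dict.fromkeys(data.windows["chromosome"]):
        sel = (data.windows["chromosome"] == chrom).to_numpy()
        fd_rows.append(
            {
                "chromosome": chrom,
                "mean_fd": float(np.nanmean(fd_per_window[sel])),
                "n_windows": int(sel.sum()),
            }
        )
    tables["fd_by_chromosome"] = pd.DataFrame(fd_rows)
    k = min(fd_set_size, int(np.isfinite(fd_per_window).sum()) - 1)
    candidate = np.zeros(len(fd_per_window), dtype=bool)
    candidate[np.argsort(fd_per_window)[:k]] = True  # worked example: lowest-f_d set
    fd_test = phylo.fd_window_set_test(
        fd_per_window, candidate, n_draws=1_000, seed=cfg.seed
    )
    tables["fd_window_set_test"] = pd.DataFrame([fd_test.as_dict()])

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for name, frame in tables.items():
            write_table(frame, os.path.join(out_dir, f"{name}.tsv"), run_config)
    return PipelineResult(data=data, tables=tables)
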