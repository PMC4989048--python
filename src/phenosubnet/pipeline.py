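"""End-to-end pipeline: paired DE -> sub-network discovery -> regulon
inference, with stage toggles, a single seeded configuration and a
machine-readable run report.

Identical configurations and seeds produce identical reports: all
randomness is drawn from named sub-streams of the master seed and the report
contains no timestamps.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import paired_de as de_mod
from . import phenonet, regulon as reg_mod
from ._utils import stage_rngs
from .synthio import SimConfig, SyntheticStudy, simulate_study

log = logging.getLogger("phenosubnet")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with their conventional defaults:
    DEG calling at fold change 1.5 and BH-adjusted p <= 0.10, one
    unwanted-variation factor, initial sub-network size cap 7, empirical
    threshold 0.05 with 10,000 resampled null sub-networks, AUC recovery on
    the top 3% of rankings with a z >= 3 pass, and a text-mining q <= 0.1."""

    fdr: float = 0.10
    fc: float = 1.5
    min_mean_norm_count: float = 1.0
    n_control_exclude: int = 5000
    ruv_k: int = 1
    alpha_subnet: float = 0.05
    nulls: int = 10000
    max_size: int = 7
    top_fraction: float = 0.03
    z_cut: float = 3.0
    tm_q: float = 0.1
    run_de: bool = True
    run_subnet: bool = True
    run_regulon: bool = True
    seed: int = 0


def run_pipeline(config: PipelineConfig, study: SyntheticStudy | None = None,
                 sim_config: SimConfig | None = None) -> dict:
    """Run the toggled stages on a study (simulated if not supplied).

    Returns a machine-readable report: configuration, per-stage seeds, and
    the counts/statistics each stage produced.
    """
    rngs = stage_rngs(config.seed)
    report: dict = {"config": asdict(config), "stages": []}

    if study is None:
        t0 = time.perf_counter()
        study = simulate_study(config=sim_config, seed=config.seed)
        log.info("simulate: %.1fs", time.perf_counter() - t0)
    report["n_genes"] = int(study.counts.shape[0])
    report["n_samples"] = int(study.counts.shape[1])

    de_result = None
    up, down = [], []
    if config.run_de:
        t0 = time.perf_counter()
        counts = de_mod.filter_low_expression(study.counts, study.meta,
                                              config.min_mean_norm_count)
        sf = de_mod.size_factors_median_of_ratios(counts)
        first_pass = de_mod.nb_wald_paired_test(counts, study.meta, sf=sf)
        n_exclude = min(config.n_control_exclude, counts.shape[0] // 2)
        if n_exclude != config.n_control_exclude:
            log.info("de: clamped control exclusion to %d of %d genes",
                     n_exclude, counts.shape[0])
        controls = de_mod.select_control_genes(first_pass, n_exclude)
        uf = de_mod.estimate_unwanted_factors(counts, sf, controls, k=config.ruv_k)
        de_result = de_mod.nb_wald_paired_test(counts, study.meta, sf=sf, uf=uf)
        up, down = de_mod.call_degs(de_result, config.fc, config.fdr)
        summary = de_mod.deg_summary(up, down, counts.shape[0])
        report["de"] = {"n_filtered": int(counts.shape[0]),
                        "n_controls": len(controls), "summary": summary}
        report["stages"].append("de")
        log.info("de: %.1fs, %d up / %d down", time.perf_counter() - t0,
                 len(up), len(down))

    subnets = []
    if config.run_subnet:
        if de_result is None:
            raise ValueError("sub-network stage requires the DE stage")
        t0 = time.perf_counter()
        de_scores = phenonet.score_nodes(de_result.table)
        rwr_scores = phenonet.rwr(study.net, study.truth.seed_phenotypes)
        combined = phenonet.combined_node_scores(study.net, de_scores, rwr_scores)
        candidates = phenonet.extract_subnetworks(study.net, combined,
                                                  max_size=config.max_size)
        sampler = phenonet.PPISampler(study.net)
        rng = rngs["subnet"]
        candidates = [
            phenonet.empirical_pvalue(c, study.net, combined, config.nulls,
                                      rng=rng, sampler=sampler)
            for c in candidates
        ]
        subnets = phenonet.filter_and_merge(candidates, config.alpha_subnet)
        subnets = [phenonet.annotate_top_go(s, study.gene_sets) for s in subnets]
        report["subnet"] = {
            "n_candidates": len(candidates),
            "n_significant": len(subnets),
            "networks": [
                {"size": s.size, "empirical_p": s.empirical_p,
                 "top_go": s.top_go_term, "genes": s.sorted_nodes()}
                for s in subnets
            ],
        }
        report["stages"].append("subnet")
        log.info("subnet: %.1fs, %d significant", time.perf_counter() - t0, len(subnets))

    if config.run_regulon:
        t0 = time.perf_counter()
        bundle = study.evidence
        up_set = set(up) & set(bundle.genes)
        down_set = set(down) & set(bundle.genes)
        deg_sets = {"up": up_set or set(bundle.degs), "down": down_set}
        agg = reg_mod.motif_rankings(bundle)
        selected_union: dict[str, reg_mod.Regulon] = {}
        outcomes_by_dir = {}
        for direction, degs in deg_sets.items():
            if not degs:
                continue
            outcomes = reg_mod.evaluate_evidence(bundle, degs=degs,
                                                 top_fraction=config.top_fraction,
                                                 tm_q_cut=config.tm_q,
                                                 _motif_rankings=agg)
            outcomes_by_dir[direction] = outcomes
            for reg in reg_mod.build_regulons(outcomes, bundle, degs=degs,
                                              top_fraction=config.top_fraction,
                                              tm_q_cut=config.tm_q, agg_rankings=agg):
                if reg.tf in selected_union:
                    selected_union[reg.tf].targets |= reg.targets
                else:
                    selected_union[reg.tf] = reg
        regulons = [selected_union[tf] for tf in sorted(selected_union)]
        subnet_genes = set().union(*(set(s.nodes) for s in subnets)) if subnets else set()
        overlap_p = (
            reg_mod.tf_pathway_overlap(regulons, subnet_genes, set(bundle.genes))
            if regulons and subnet_genes else None
        )
        n_regulated = len(set().union(*(r.targets for r in regulons))) if regulons else 0
        report["regulon"] = {
            "selected_tfs": sorted(selected_union),
            "n_regulated_degs": n_regulated,
            "tf_pathway_overlap_p": overlap_p,
            "tf_tf_edges": sorted(
                [list(e) for r in regulons for e in r.tf_edges]
            ),
        }
        report["stages"].append("regulon")
        log.info("regulon: %.1fs, %d TFs selected", time.perf_counter() - t0,
                 len(selected_union))

    return report
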