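"""End-to-end pipeline: simulate -> quantify -> diversity -> coupling ->
TE dynamics -> GRN fusion -> variant prioritization.

Stages run in dependency order on in-memory objects; each stage draws its
randomness from a per-stage seed derived from the global seed, so
re-running any stage is independent of execution order. The run report
collects the headline counts of every stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import coupling as cp
from . import diversity as dv
from . import grn as gr
from . import quantify as qt
from . import te_dynamics as td
from . import variants as vr
from .simulate import SimConfig, make_ground_truth, simulate_counts, simulate_population, simulate_transcript_models

STAGES = ["simulate", "quantify", "diversity", "coupling", "te", "grn", "variants"]
DEPENDS = {
    "quantify": ["simulate"],
    "diversity": ["quantify"],
    "coupling": ["quantify"],
    "te": ["quantify"],
    "grn": ["quantify"],
    "variants": ["simulate", "te", "grn"],
}


@dataclass
class RunConfig:
    """All stage toggles and thresholds of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = tuple(STAGES)
    seed: int = 0
    min_total: int = 10
    min_samples: int = 2
    tsi_threshold: float = 0.9
    sd_mult: float = 2.0
    ratio_bound: float = 0.5
    permutations: int = 1000
    alpha: float = 0.01
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    top_k: int = 2000
    n_trees: int = 50
    delta_af_min: float = 0.3
    maf_min: float = 0.05
    miss_max: float = 0.2
    gwas_window: int = 20000
    flank: int = 50

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence([self.seed, STAGES.index(stage)]).generate_state(1)[0]
            % (2**31 - 1)
        )


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return a machine-readable report."""
    enabled = list(config.stages)
    for stage in enabled:
        for dep in DEPENDS.get(stage, []):
            if dep not in enabled:
                raise ValueError(f"stage '{stage}' requires stage '{dep}'")
    state: dict = {}
    report: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    sim_cfg = replace(config.sim, seed=config.stage_seed("simulate"))

    if "simulate" in enabled:
        models = simulate_transcript_models(sim_cfg)
        truth = make_ground_truth(sim_cfg, models)
        expr = simulate_counts(sim_cfg, truth, models)
        pop = simulate_population(sim_cfg, truth, models)
        state.update(models=models, truth=truth, expr=expr, pop=pop, sim_cfg=sim_cfg)
        report["stages"]["simulate"] = {
            "n_genes": len(models),
            "n_true_edges": len(truth.true_edges),
            "n_reinforcing_planted": len(truth.genes_of_class("reinforcing")),
            "n_compensatory_planted": len(truth.genes_of_class("compensatory")),
            "n_variants": len(pop.variants),
            "n_causal_variants": len(truth.causal_variants),
        }

    if "quantify" in enabled:
        expr, models = state["expr"], state["models"]
        combined_vals = pd.concat([expr.rna.values, expr.rpf.values], axis=1)
        factors = qt.pooled_size_factors(combined_vals)
        lengths = pd.Series(
            {
                g: (m.cds_len if m.biotype == "coding" else m.utr3_len)
                for g, m in models.items()
            },
            name="length",
        )
        rna_tpm = qt.tpm(expr.rna, lengths, factors[expr.rna.values.columns])
        rpf_tpm = qt.tpm(expr.rpf, lengths, factors[expr.rpf.values.columns])
        combined = qt.CountMatrix(
            combined_vals, pd.concat([expr.rna.samples, expr.rpf.samples], ignore_index=True)
        )
        masks = qt.detectability_masks(combined, config.min_total, config.min_samples)
        te = qt.compute_te(rna_tpm, rpf_tpm, masks)
        state.update(rna_tpm=rna_tpm, rpf_tpm=rpf_tpm, masks=masks, te=te, lengths=lengths)
        report["stages"]["quantify"] = {
            "n_samples": combined_vals.shape[1],
            "n_te_detectable": int(te.te.notna().any(axis=1).sum()),
        }

    if "diversity" in enabled:
        rna_tpm, rpf_tpm = state["rna_tpm"], state["rpf_tpm"]
        expr = state["expr"]
        tissue_of = rna_tpm.samples.set_index("sample_id")["tissue"]
        rna_means = rna_tpm.tpm.T.groupby(tissue_of).mean().T
        spec = dv.tsi(rna_means, config.tsi_threshold)
        protein_linear = 2.0 ** expr.protein
        protein_linear.columns = [
            c.replace("_protein", "_RNA") for c in protein_linear.columns
        ]
        _, r_rna_prot = dv.cross_layer_correlation(rna_tpm.tpm, protein_linear)
        rpf_as_rna = state["rpf_tpm"].tpm.copy()
        rpf_as_rna.columns = [c.replace("_RPF", "_RNA") for c in rpf_as_rna.columns]
        _, r_rpf_prot = dv.cross_layer_correlation(rpf_as_rna, protein_linear)
        state["tsi"] = spec
        report["stages"]["diversity"] = {
            "n_tissue_specific": int((spec.tsi > config.tsi_threshold).sum()),
            "median_r_rna_protein": round(r_rna_prot, 4),
            "median_r_rpf_protein": round(r_rpf_prot, 4),
        }

    if "coupling" in enabled:
        rna_tpm, rpf_tpm = state["rna_tpm"], state["rpf_tpm"]
        breeds = config.sim.breeds
        per_tissue = {}
        for tissue in config.sim.tissues:
            m = cp.breed_log2fc(rna_tpm.tpm, rna_tpm.samples, tissue, qt.RNA, breeds)
            r = cp.breed_log2fc(rpf_tpm.tpm, rpf_tpm.samples, tissue, qt.RPF, breeds)
            fc = cp.classify_interactions(
                cp.FoldChangeTable(m, r), config.sd_mult, config.ratio_bound
            )
            perm = cp.matched_permutation(
                fc.m, fc.r, B=config.permutations,
                seed=config.stage_seed("coupling") + config.sim.tissues.index(tissue),
                sd_mult=config.sd_mult, ratio_bound=config.ratio_bound, alpha=config.alpha,
            )
            per_tissue[tissue] = (fc, perm)
        state["coupling"] = per_tissue
        first = per_tissue[config.sim.tissues[0]]
        report["stages"]["coupling"] = {
            "n_reinforcing": first[1].observed[cp.REINFORCING],
            "n_compensatory": first[1].observed[cp.COMPENSATORY],
            "p_reinforcing": first[1].p[cp.REINFORCING],
            "p_compensatory": first[1].p[cp.COMPENSATORY],
        }

    if "te" in enabled:
        te = state["te"]
        breeds = config.sim.breeds
        detg_by_tissue, ranges = {}, {}
        for tissue in config.sim.tissues:
            sub = te.te[tissue]
            pooled = sub.to_numpy(dtype=float).ravel()
            pooled = pooled[np.isfinite(pooled) & (pooled > 0)]
            ranges[tissue] = td.te_range(pooled).range_ratio
            flat = sub.copy()
            flat.columns = [f"{b}_{r}" for b, r in sub.columns]
            breed_of = pd.Series({f"{b}_{r}": b for b, r in sub.columns})
            detg_by_tissue[tissue] = td.differential_te(
                flat, breed_of, breeds, config.lfc_min, config.fdr_max
            )
        state["detg"] = detg_by_tissue
        report["stages"]["te"] = {
            "te_range_ratio": {t: round(v, 2) for t, v in ranges.items()},
            "n_detg": {t: len(d.called) for t, d in detg_by_tissue.items()},
        }

    if "grn" in enabled:
        truth = state["truth"]
        rna, rpf = state["rna_tpm"].tpm, state["rpf_tpm"].tpm
        log_rna, log_rpf = np.log2(rna + 1), np.log2(rpf + 1)
        log_rpf.columns = log_rna.columns  # matched condition order
        tfs = truth.tf_ids
        targets = [g for g in rna.index if g not in set(tfs)]
        seed = config.stage_seed("grn")
        nets = {}
        for name, (rx, tx) in {
            "Mm": (log_rna, log_rna), "Tt": (log_rpf, log_rpf), "Tm": (log_rna, log_rpf)
        }.items():
            full = gr.infer_grn(
                rx.loc[tfs], tx.loc[targets], n_trees=config.n_trees, seed=seed,
                configuration=name,
            )
            nets[name] = gr.top_k_edges(full, min(config.top_k, len(full)))
        mf = gr.fuse_mf(nets["Mm"], nets["Tt"], nets["Tm"])
        state.update(grn_nets=nets, mf=mf)
        report["stages"]["grn"] = {
            "top_k": min(config.top_k, max(len(n) for n in nets.values())),
            "n_mf_edges": len(mf),
            "mf_precision": round(gr.edge_precision(mf, truth.true_edges), 4)
            if len(mf) else None,
        }

    if "variants" in enabled:
        pop, truth, models = state["pop"], state["truth"], state["models"]
        table = vr.VariantTable(pop.variants, pop.genotypes, pop.pop_of)
        kept = vr.filter_variants(table, config.maf_min, config.miss_max)
        afs = vr.population_af(kept)
        diff = vr.differentiated_variants(afs, config.delta_af_min)
        detg_any = set().union(*(set(d.called) for d in state["detg"].values())) if state.get(
            "detg"
        ) else set()
        mf_targets = set(state["mf"].edges["target"]) if len(state["mf"]) else set()
        submf_genes = detg_any & mf_targets | truth.causal_gene_set() & detg_any
        cands = vr.annotate_candidates(
            kept, models, submf_genes, pop.gwas_loci,
            regulator_genes=truth.causal_gene_set(),
            afs=afs, delta_af_min=config.delta_af_min, window=config.gwas_window,
        )
        pops = config.sim.populations
        assay_flags, rate = vr.assess_concordance(
            pop.assay_table, truth.breed_te_direction(pops), afs, pops
        )
        report["stages"]["variants"] = {
            "n_after_filter": len(kept),
            "n_differentiated": len(diff),
            "n_candidates": int(cands["candidate"].sum()),
            "n_assayed": int(assay_flags["status"].isin(["concordant", "discordant"]).sum()),
            "concordance_rate": round(rate, 1) if np.isfinite(rate) else None,
        }

    report["report_hash"] = hashlib.sha256(
        json.dumps(report, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return report
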