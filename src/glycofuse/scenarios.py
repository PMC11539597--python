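"""Canonical simulation-study configurations.

These fix, once, the synthetic conditions used throughout the test
suite and the reproduction script, so every consumer exercises the same
study design:

* the full factorial design (3 strains x 2 diets x 3 timepoints = 18
  groups, 4 mice per group = 72 samples),
* one transcript block with a single phenotype-driving module
  (beta = 2 glycemia units per eigengene SD, within-module loading
  0.8) among null modules and background genes,
* group-concentrated module eigengenes (ICC 0.8) so the group-mean
  summaries that enter the fusion model retain the planted signal,
* uniform 140 mg/dL baseline with 1.0 SD residual phenotype noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import coexpression, fusion, genescore, simulate
from .enrichment import GseaResult, gsea_preranked

DRIVER_BETA = 2.0
DRIVER_LOADING = 0.8
N_MICE = 4
GROUP_ICC = 0.8


def driver_design(seed: int) -> pd.DataFrame:
    """18-group design with exactly 4 mice per group (72 samples)."""
    spec = simulate.DesignSpec(mice_per_group=(N_MICE, N_MICE), seed=seed)
    return simulate.generate_design(spec)


def driver_plan(n_modules: int = 4, module_size: int = 25, n_background: int = 100) -> simulate.ModulePlan:
    """One driver module (index 0) among null modules and background."""
    return simulate.ModulePlan(
        n_modules=n_modules,
        module_sizes=[module_size] * n_modules,
        within_module_loading=DRIVER_LOADING,
        n_background_genes=n_background,
        driver_effects={0: DRIVER_BETA},
        noise_sd=0.4,
        group_icc=GROUP_ICC,
    )


@dataclass
class DriverDataset:
    """One realisation of the planted-driver study."""

    design: pd.DataFrame
    counts: pd.DataFrame
    truth: simulate.TruthRecord
    phenotype: pd.DataFrame
    y_groups: pd.Series  # mean glycemia per group


def driver_dataset(seed: int, block: str = "liver-rna") -> DriverDataset:
    design = driver_design(seed)
    plan = driver_plan()
    counts, truth = simulate.generate_expression_block(design, plan, seed=seed, name=block)
    phen = simulate.generate_phenotype(design, truth, baseline_by_strain_diet=140.0, noise_sd=1.0, seed=seed)
    return DriverDataset(
        design=design,
        counts=counts,
        truth=truth,
        phenotype=phen,
        y_groups=simulate.group_means(phen),
    )


@dataclass
class DriverRunResult:
    """Fitted pipeline on one planted-driver dataset."""

    module_model: coexpression.ModuleModel
    driver_label: str | None  # recovered module matching the planted driver
    fit: fusion.ConsensusOPLSResults
    perm: fusion.PermutationResult
    gene_table: pd.DataFrame | None
    gsea: GseaResult | None


def match_driver_module(
    assignment: pd.Series, truth: simulate.TruthRecord, driver_index: int = 0
) -> str | None:
    """Recovered module with the largest overlap with the planted driver.

    Returns None when no recovered module captures a majority of the
    planted members.
    """
    members = set(truth.module_members(driver_index))
    best, best_n = None, 0
    for label in assignment.unique():
        if label == coexpression.UNASSIGNED:
            continue
        overlap = len(members & set(assignment.index[assignment == label]))
        if overlap > best_n:
            best, best_n = label, overlap
    if best is not None and best_n >= len(members) / 2:
        return best
    return None


def run_driver_pipeline(
    data: DriverDataset,
    seed: int,
    n_perm: int = 99,
    with_gsea: bool = True,
    gsea_n_perm: int = 999,
) -> DriverRunResult:
    """Preprocess -> modules -> fusion (+permutations) -> scores -> GSEA."""
    from . import preprocess

    block = data.truth.block
    kept = preprocess.cpm_filter(data.counts)
    factors = preprocess.tmm_norm_factors(kept)
    logcpm = preprocess.log_cpm(kept, factors)
    model = coexpression.detect_modules(logcpm, coexpression.NetworkParams())
    driver_label = match_driver_module(model.assignment, data.truth)
    grouped = coexpression.summarize_by_group(model.eigengenes, data.design)
    blocks = {block: grouped.T}
    cop = fusion.ConsensusOPLS(blocks, data.y_groups, folds=14)
    fit = cop.fit(seed=seed)
    perm = fit.permutation_test(n_perm=n_perm, seed=seed + 1000)

    gene_table = None
    gsea_res = None
    if with_gsea:
        svip = fit.svip_for_block(block)
        svip_perm = perm.svip_perm[block]
        mm = model.membership[list(svip.index)]
        gene_table = genescore.score_tissue(mm, svip, svip_perm[list(svip.index)])
        sets = simulate.truth_gene_sets(data.truth, n_decoys=10, decoy_size=25, seed=seed)
        gsea_res = gsea_preranked(
            gene_table,
            sets,
            n_perm=gsea_n_perm,
            min_size=5,
            max_size=500,
            seed=seed + 2000,
        )
    return DriverRunResult(
        module_model=model,
        driver_label=driver_label,
        fit=fit,
        perm=perm,
        gene_table=gene_table,
        gsea=gsea_res,
    )


def driver_has_top_vip(result: DriverRunResult) -> bool:
    """Did the recovered driver module attain its block's largest VIP?"""
    if result.driver_label is None:
        return False
    vt = result.fit.vip_table
    top = vt.loc[vt["vip"].idxmax(), "module"]
    return top == result.driver_label


def driver_term_detected(result: DriverRunResult, alpha: float = 0.05) -> bool:
    """Is the planted driver gene set enriched with the right sign?"""
    if result.gsea is None:
        return False
    term = None
    for t in result.gsea.table["term"]:
        if t.endswith("_set_M1"):
            term = t
            break
    if term is None:
        return False
    row = result.gsea.table.set_index("term").loc[term]
    return bool(row["adj_p"] <= alpha and row["nes"] > 0)
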