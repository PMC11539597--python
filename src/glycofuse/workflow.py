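"""End-to-end orchestration: simulate -> preprocess -> modules -> fusion
-> gene scores -> enrichment -> term selection.

A single YAML-style config drives the whole run; every stage reads and
writes plain-text tables in the output directory, records SHA-256
checksums of its outputs in a run manifest, and is skipped on re-run
when its recorded outputs are intact (resume semantics: a corrupted or
missing intermediate forces recomputation of its stage).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd

from . import coexpression, enrichment, fusion, genescore, preprocess, simulate
from ._exceptions import ConfigurationError, DataError
from ._io import (
    ensure_dir,
    read_csv,
    read_tsv,
    sha256_file,
    sha256_text,
    write_csv,
    write_json,
    write_tsv,
)

log = logging.getLogger("glycofuse")

STAGES = ["simulate", "preprocess", "modules", "fusion", "score", "gsea", "select"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "design": {
        "strains": ["B6", "DBA", "BALB"],
        "diets": ["RC", "HFD"],
        "timepoints": [2, 10, 30],
        "mice_per_group": [2, 4],
    },
    "blocks": {},
    "phenotype": {"baseline": 140.0, "noise_sd": 1.0},
    "preprocess": {
        "cpm_threshold": 1.0,
        "min_fraction_samples": None,
        "prior_count": 0.5,
        "max_missing": 0.25,
    },
    "imputation": {"n_trees": 100, "max_iter": 10, "tol": 1e-4},
    "fusion": {"folds": 14, "n_perm": 999, "max_ortho": 3},
    "enrichment": {
        "alpha": 0.01,
        "n_perm": 1000,
        "min_size": 10,
        "max_size": 500,
        "weight": 1.0,
        "n_decoy_sets": 20,
        "decoy_size": 20,
        "gmt": None,
    },
}

_BLOCK_KEYS = {"kind", "plan", "network", "missing_rate", "library_size_range"}
_PLAN_KEYS = {
    "n_modules",
    "module_sizes",
    "within_module_loading",
    "n_background_genes",
    "driver_effects",
    "noise_sd",
    "group_icc",
    "n_total_genes",
}
_NETWORK_KEYS = {
    "power",
    "min_module_size",
    "cut_height",
    "reassign_threshold",
    "min_coherence",
    "min_membership",
}


def _merge(defaults: dict, overrides: dict) -> dict:
    out = dict(defaults)
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def validate_config(config: dict) -> list[str]:
    """Check the full config; returns ALL problems, not just the first."""
    errors: list[str] = []
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")
    seed = config.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append(f"seed must be a non-negative integer, got {seed!r}")
    design = config.get("design", {})
    try:
        spec = simulate.DesignSpec(
            strains=design.get("strains", []),
            diets=design.get("diets", []),
            timepoints=design.get("timepoints", []),
            mice_per_group=tuple(design.get("mice_per_group", (2, 4))),
        )
        spec.validate()
        n_groups = spec.n_groups
    except (ConfigurationError, TypeError) as exc:
        errors.append(f"design: {exc}")
        n_groups = None
    blocks = config.get("blocks", {})
    if not blocks:
        errors.append("at least one block must be configured")
    for name, bconf in blocks.items():
        unknown = set(bconf) - _BLOCK_KEYS
        if unknown:
            errors.append(f"block {name!r}: unknown keys {sorted(unknown)}")
        kind = bconf.get("kind")
        if kind not in ("rna", "lipid"):
            errors.append(f"block {name!r}: kind must be 'rna' or 'lipid', got {kind!r}")
        plan = bconf.get("plan", {})
        unknown = set(plan) - _PLAN_KEYS
        if unknown:
            errors.append(f"block {name!r}: unknown plan keys {sorted(unknown)}")
        else:
            try:
                _plan_from_config(plan).validate()
            except (ConfigurationError, TypeError) as exc:
                errors.append(f"block {name!r} plan: {exc}")
        network = bconf.get("network", {})
        unknown = set(network) - _NETWORK_KEYS
        if unknown:
            errors.append(f"block {name!r}: unknown network keys {sorted(unknown)}")
    fus = config.get("fusion", {})
    folds = fus.get("folds", 14)
    if n_groups is not None and not (2 <= folds <= n_groups):
        errors.append(f"fusion.folds={folds} invalid for {n_groups} groups")
    if not (0 <= fus.get("max_ortho", 3) <= 3):
        errors.append("fusion.max_ortho must be in [0, 3]")
    if fus.get("n_perm", 999) < 1:
        errors.append("fusion.n_perm must be >= 1")
    enr = config.get("enrichment", {})
    if not (0 < enr.get("alpha", 0.01) <= 1):
        errors.append("enrichment.alpha must be in (0, 1]")
    return errors


def _plan_from_config(plan: dict) -> simulate.ModulePlan:
    kwargs = dict(plan)
    if "driver_effects" in kwargs and kwargs["driver_effects"]:
        kwargs["driver_effects"] = {int(k): float(v) for k, v in kwargs["driver_effects"].items()}
    return simulate.ModulePlan(**kwargs)


def _network_from_config(network: dict) -> coexpression.NetworkParams:
    return coexpression.NetworkParams(**network)


def _is_rna(bconf: dict) -> bool:
    return bconf.get("kind") == "rna"


def tissue_of(block_name: str) -> str:
    """Tissue label of a block: the part before the first dash."""
    return block_name.split("-")[0]


@dataclass
class RunManifest:
    """Checksummed record of a pipeline run."""

    path: Path
    data: dict

    @classmethod
    def load_or_new(cls, outdir: Path, config_hash: str) -> "RunManifest":
        p = outdir / "manifest.json"
        if p.exists():
            with open(p) as fh:
                data = json.load(fh)
            if data.get("config_hash") == config_hash:
                return cls(path=p, data=data)
        return cls(path=p, data={"config_hash": config_hash, "stages": {}})

    def stage_intact(self, stage: str) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None:
            return False
        for fname, digest in rec["outputs"].items():
            f = self.path.parent / fname
            if not f.exists() or sha256_file(f) != digest:
                return False
        return True

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.data["stages"][stage] = {
            "outputs": {p.name: sha256_file(p) for p in outputs},
            "seconds": round(seconds, 3),
        }
        write_json(self.data, self.path)


class Pipeline:
    """Stage runner over one config and output directory."""

    def __init__(self, config: dict, outdir):
        errors = validate_config(config)
        if errors:
            raise ConfigurationError("invalid config:\n  " + "\n  ".join(errors))
        self.config = config
        self.outdir = ensure_dir(outdir)
        self.seed = int(config["seed"])
        chash = sha256_text(json.dumps(config, sort_keys=True, default=str))
        self.manifest = RunManifest.load_or_new(self.outdir, chash)

    # -- stage implementations ----------------------------------------------
    def _stage_simulate(self) -> list[Path]:
        cfg = self.config
        d = cfg["design"]
        spec = simulate.DesignSpec(
            strains=d["strains"],
            diets=d["diets"],
            timepoints=d["timepoints"],
            mice_per_group=tuple(d["mice_per_group"]),
            seed=self.seed,
        )
        design = simulate.generate_design(spec)
        out = [self.outdir / "design.tsv"]
        write_tsv(design, out[-1], index_label="sample")
        truths = []
        for name, bconf in cfg["blocks"].items():
            plan = _plan_from_config(bconf.get("plan", {}))
            if _is_rna(bconf):
                lsr = tuple(bconf.get("library_size_range", (5e5, 2e6)))
                counts, truth = simulate.generate_expression_block(
                    design, plan, library_size_range=lsr, seed=self.seed, name=name
                )
                out.append(self.outdir / f"{name}.counts.tsv")
                write_tsv(counts, out[-1], index_label="gene")
            else:
                counts, truth = simulate.generate_lipid_block(
                    design,
                    plan,
                    missing_rate=bconf.get("missing_rate", 0.2),
                    seed=self.seed,
                    name=name,
                )
                out.append(self.outdir / f"{name}.lipids.csv")
                write_csv(counts, out[-1], index_label="lipid")
            truths.append(truth)
            out.append(self.outdir / f"{name}.truth.tsv")
            write_tsv(truth.assignment.to_frame(), out[-1], index_label="feature")
        phen = simulate.generate_phenotype(
            design,
            truths,
            baseline_by_strain_diet=cfg["phenotype"].get("baseline", 140.0),
            noise_sd=cfg["phenotype"].get("noise_sd", 1.0),
            seed=self.seed,
        )
        out.append(self.outdir / "phenotype.tsv")
        write_tsv(phen, out[-1], index_label="sample")
        if cfg["enrichment"].get("gmt") is None:
            sets: dict[str, list[str]] = {}
            for (name, bconf), truth in zip(cfg["blocks"].items(), truths):
                if _is_rna(bconf):
                    sets.update(
                        simulate.truth_gene_sets(
                            truth,
                            n_decoys=cfg["enrichment"].get("n_decoy_sets", 20),
                            decoy_size=cfg["enrichment"].get("decoy_size", 20),
                            seed=self.seed,
                        )
                    )
            out.append(self.outdir / "genesets.gmt")
            enrichment.write_gmt(sets, out[-1])
        return out

    def _stage_preprocess(self) -> list[Path]:
        cfg = self.config
        pp = cfg["preprocess"]
        out: list[Path] = []
        for name, bconf in cfg["blocks"].items():
            if _is_rna(bconf):
                counts = read_tsv(self.outdir / f"{name}.counts.tsv")
                kept = preprocess.cpm_filter(
                    counts,
                    cpm_threshold=pp["cpm_threshold"],
                    min_fraction_samples=pp["min_fraction_samples"],
                )
                factors = preprocess.tmm_norm_factors(kept)
                logcpm = preprocess.log_cpm(kept, factors, prior_count=pp["prior_count"])
                out.append(self.outdir / f"{name}.factors.tsv")
                write_tsv(factors.to_frame(), out[-1], index_label="sample")
                out.append(self.outdir / f"{name}.logcpm.tsv")
                write_tsv(logcpm, out[-1], index_label="gene")
            else:
                lipids = read_csv(self.outdir / f"{name}.lipids.csv")
                kept = preprocess.lipid_missing_filter(lipids, max_missing=pp["max_missing"])
                imp = cfg["imputation"]
                filled = preprocess.impute_missing(
                    kept,
                    max_iter=imp["max_iter"],
                    tol=imp["tol"],
                    seed=self.seed,
                    n_trees=imp["n_trees"],
                )
                norm = preprocess.total_signal_normalize(filled)
                out.append(self.outdir / f"{name}.lipids.norm.csv")
                write_csv(norm, out[-1], index_label="lipid")
        return out

    def _stage_modules(self) -> list[Path]:
        cfg = self.config
        design = read_tsv(self.outdir / "design.tsv")
        out: list[Path] = []
        for name, bconf in cfg["blocks"].items():
            if _is_rna(bconf):
                X = read_tsv(self.outdir / f"{name}.logcpm.tsv")
            else:
                X = read_csv(self.outdir / f"{name}.lipids.norm.csv")
            params = _network_from_config(bconf.get("network", {}))
            model = coexpression.detect_modules(X, params)
            out.append(self.outdir / f"{name}.assignment.tsv")
            write_tsv(model.assignment.to_frame(), out[-1], index_label="feature")
            out.append(self.outdir / f"{name}.eigengenes.tsv")
            write_tsv(model.eigengenes, out[-1], index_label="module")
            out.append(self.outdir / f"{name}.membership.tsv")
            write_tsv(model.membership, out[-1], index_label="feature")
            grouped = coexpression.summarize_by_group(model.eigengenes, design)
            out.append(self.outdir / f"{name}.group_eigengenes.tsv")
            write_tsv(grouped, out[-1], index_label="module")
        return out

    def _load_blocks(self) -> dict[str, pd.DataFrame]:
        blocks = {}
        for name in self.config["blocks"]:
            tab = read_tsv(self.outdir / f"{name}.group_eigengenes.tsv")
            if tab.shape[0] == 0:
                log.warning("block %s produced no modules; excluded from fusion", name)
                continue
            blocks[name] = tab.T  # group x module
        if not blocks:
            raise DataError("no block produced any co-expression module")
        return blocks

    def _stage_fusion(self) -> list[Path]:
        cfg = self.config["fusion"]
        blocks = self._load_blocks()
        phen = read_tsv(self.outdir / "phenotype.tsv")
        y = simulate.group_means(phen)
        model = fusion.ConsensusOPLS(
            blocks,
            y,
            n_ortho="auto",
            max_ortho=cfg["max_ortho"],
            folds=min(cfg["folds"], len(y)),
        )
        res = model.fit(seed=self.seed)
        perm = res.permutation_test(n_perm=cfg["n_perm"], seed=self.seed + 1000)
        out = [self.outdir / "fusion_summary.json"]
        write_json(
            {
                "q2": res.q2,
                "r2y": res.r2y,
                "n_ortho": res.n_ortho_,
                "p_q2": perm.p_q2,
                "n_perm": perm.n_perm,
                "weights": {k: float(v) for k, v in res.weights.items()},
            },
            out[-1],
        )
        out.append(self.outdir / "vip.tsv")
        vt = res.vip_table.copy()
        vt.to_csv(out[-1], sep="\t", float_format="%.10g", index=False)
        out.append(self.outdir / "q2_perm.tsv")
        write_tsv(
            pd.DataFrame({"q2_perm": perm.q2_perm}), out[-1], index_label="permutation"
        )
        out.append(self.outdir / "svip_perm.tsv")
        sp = perm.svip_perm.copy()
        sp.columns = [f"{b}:{m}" for b, m in sp.columns]
        write_tsv(sp, out[-1], index_label="permutation")
        return out

    def _load_svip(self):
        vip = pd.read_csv(self.outdir / "vip.tsv", sep="\t")
        sp = read_tsv(self.outdir / "svip_perm.tsv")
        return vip, sp

    def _stage_score(self) -> list[Path]:
        vip, svip_perm = self._load_svip()
        out: list[Path] = []
        for name, bconf in self.config["blocks"].items():
            if not _is_rna(bconf):
                continue
            sub = vip[vip["block"] == name]
            if sub.empty:
                continue
            mm = read_tsv(self.outdir / f"{name}.membership.tsv")
            svip = pd.Series(sub["svip"].to_numpy(), index=list(sub["module"]))
            perm_cols = [f"{name}:{m}" for m in svip.index]
            sp = svip_perm[perm_cols].copy()
            sp.columns = list(svip.index)
            mm = mm[list(svip.index)]
            table = genescore.score_tissue(mm, svip, sp)
            out.append(self.outdir / f"{tissue_of(name)}.ranked.tsv")
            write_tsv(table, out[-1], index_label="gene")
        if not out:
            raise DataError("no transcript block with modules; nothing to score")
        return out

    def _stage_gsea(self) -> list[Path]:
        cfg = self.config["enrichment"]
        gmt = cfg.get("gmt") or (self.outdir / "genesets.gmt")
        collection = enrichment.read_gmt(gmt)
        out: list[Path] = []
        for name, bconf in self.config["blocks"].items():
            if not _is_rna(bconf):
                continue
            tissue = tissue_of(name)
            path = self.outdir / f"{tissue}.ranked.tsv"
            if not path.exists():
                continue
            ranked = read_tsv(path)
            res = enrichment.gsea_preranked(
                ranked,
                collection,
                n_perm=cfg["n_perm"],
                min_size=cfg["min_size"],
                max_size=cfg["max_size"],
                weight=cfg["weight"],
                seed=self.seed + 2000,
            )
            out.append(self.outdir / f"{tissue}.gsea.tsv")
            res.table.to_csv(out[-1], sep="\t", float_format="%.10g", index=False)
        return out

    def _stage_select(self) -> list[Path]:
        cfg = self.config["enrichment"]
        results = {}
        for name, bconf in self.config["blocks"].items():
            if not _is_rna(bconf):
                continue
            tissue = tissue_of(name)
            path = self.outdir / f"{tissue}.gsea.tsv"
            if path.exists():
                table = pd.read_csv(path, sep="\t")
                results[tissue] = enrichment.GseaResult(
                    table=table, n_perm=cfg["n_perm"], excluded=pd.DataFrame()
                )
        matrix = enrichment.select_terms(results, alpha=cfg["alpha"])
        out = [self.outdir / "term_selection.tsv"]
        write_tsv(matrix, out[-1], index_label="term")
        return out

    # -- driver --------------------------------------------------------------
    def run(self, resume: bool = True) -> dict:
        runners = {
            "simulate": self._stage_simulate,
            "preprocess": self._stage_preprocess,
            "modules": self._stage_modules,
            "fusion": self._stage_fusion,
            "score": self._stage_score,
            "gsea": self._stage_gsea,
            "select": self._stage_select,
        }
        for stage in STAGES:
            if resume and self.manifest.stage_intact(stage):
                log.info("stage %s: outputs intact, skipped", stage)
                continue
            log.info("stage %s: running", stage)
            t0 = time.perf_counter()
            try:
                outputs = runners[stage]()
            except Exception as exc:
                raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
            self.manifest.record(stage, outputs, time.perf_counter() - t0)
        return self.manifest.data


def run_pipeline(config: dict, outdir, resume: bool = True) -> dict:
    """Validate the config and execute all stages; returns the manifest."""
    return Pipeline(config, outdir).run(resume=resume)
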