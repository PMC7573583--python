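"""End-to-end pipeline: CWAS per cohort, mirror tests, similarity scans,
behavior correlations and the transcriptomics arm, wired through written
artifacts so any stage can be rerun from its inputs.
"""

from __future__ import annotations

import json
import logging
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cwas as _cwas
from . import expression as _expr
from . import io as _io
from . import similarity as _sim
from .exceptions import ConnsigError

logger = logging.getLogger("connsig")


def configure_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s",
                          datefmt="%Y-%m-%dT%H:%M:%S")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)


@dataclass
class RunConfig:
    """Inputs and parameters for one full run.

    ``cohorts`` maps a cohort name to its connectome and phenotype paths.
    Defaults follow the full-scale analysis (5000 permutations, 10,000
    random gene sets, q < 0.05); small studies should downscale explicitly.
    """

    atlas: str
    cohorts: dict[str, dict[str, str]]
    out_dir: str = "connsig_run"
    covariates: list[str] = field(default_factory=lambda: ["sex", "site", "age", "mean_fd"])
    q_threshold: float = 0.05
    n_perm: int = 5000
    n_null: int = 5000
    n_random_sets: int = 10000
    plsr_components: int = 2
    seed: int = 0
    mirror_pairs: list[list[str]] = field(default_factory=list)
    behavior_scores: list[str] = field(default_factory=list)
    expression_samples: str | None = None
    gene_sets: dict[str, str] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    """One child seed per stage, derived deterministically from the run seed."""
    states = np.random.SeedSequence(seed).generate_state(len(names)) % (2**31)
    return {name: int(s) for name, s in zip(names, states)}


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages in order; returns the report directory.

    Stages: z-scoring + CWAS per cohort (with global-shift permutation test)
    -> mirror tests for declared deletion/duplication pairs -> whole-brain
    similarity scan across all cohorts -> regional similarity scans ->
    behavior correlations -> expression alignment, PLSR and gene-set tests.
    Deterministic given the seed; on failure partial outputs are removed.
    """
    configure_logging(config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    seeds = _stage_seeds(config.seed, ["cwas", "null", "similarity", "genesets"])
    stage = "setup"
    try:
        atlas = _io.read_atlas(config.atlas)
        cohorts = {
            name: _cwas.zscore_to_controls(
                _io.read_cohort(spec["connectomes"], spec["phenotypes"], name)
            )
            for name, spec in config.cohorts.items()
        }

        stage = "cwas"
        signatures: dict[str, _cwas.SignatureMap] = {}
        nulls: dict[str, np.ndarray] = {}
        for i, (name, cohort) in enumerate(cohorts.items()):
            logger.info("CWAS: %s (n=%d)", name, cohort.n_subjects)
            sig = _cwas.run_cwas(cohort, config.covariates, config.q_threshold)
            shift, p = _cwas.global_shift_test(
                cohort, config.covariates, config.n_perm, seeds["cwas"] + i
            )
            sig.global_shift_p = p
            sig.n_perm = config.n_perm
            sig.seed = seeds["cwas"] + i
            signatures[name] = sig
            nulls[name] = _cwas.generate_null_signatures(
                cohort, config.covariates, config.n_null, seeds["null"] + i
            )
            _io.write_signature(sig, out / f"cwas_{name}.tsv")
            summary["stages"][f"cwas_{name}"] = {
                "n_significant": int(sig.sig_mask.sum()),
                "global_shift": sig.global_shift,
                "global_shift_p": p,
            }

        stage = "mirror"
        for del_name, dup_name in config.mirror_pairs:
            table = _cwas.network_mirror_test(
                signatures[del_name].beta,
                signatures[dup_name].beta,
                atlas,
                nulls[del_name],
                nulls[dup_name],
            )
            _io.write_table(table, out / f"mirror_{del_name}_{dup_name}.tsv")
            summary["stages"][f"mirror_{del_name}_{dup_name}"] = {
                "n_negative": int((table["statistic"] < 0).sum()),
                "n_groupings": len(table),
            }

        stage = "whole_brain_similarity"
        adjusted = {
            name: _sim.adjust_connectomes(cohort, config.covariates)
            for name, cohort in cohorts.items()
        }
        if len(adjusted) >= 2:
            results = _sim.whole_brain_similarity_scan(
                signatures, adjusted, config.q_threshold
            )
            _io.write_table(_sim.results_to_frame(results), out / "similarity_whole_brain.tsv")
            summary["stages"]["whole_brain_similarity"] = {
                "n_tests": len(results),
                "n_significant": int(sum(r.q < config.q_threshold for r in results)),
            }

        stage = "regional_similarity"
        n_regional_sig = 0
        for sig_name, sig in signatures.items():
            for coh_name, cohort in adjusted.items():
                if coh_name == sig_name:
                    continue
                is_case = cohort.is_case.astype(bool)
                results = _sim.regional_similarity_scan(
                    sig,
                    cohort.connectomes[is_case],
                    cohort.connectomes[~is_case],
                    config.q_threshold,
                    target_signature=sig_name,
                    cohort=coh_name,
                )
                _io.write_table(
                    _sim.results_to_frame(results),
                    out / f"similarity_regional_{sig_name}_in_{coh_name}.tsv",
                )
                n_regional_sig += int(sum(r.q < config.q_threshold for r in results))
        summary["stages"]["regional_similarity"] = {"n_significant_regions": n_regional_sig}

        stage = "behavior"
        if config.behavior_scores:
            import pandas as pd

            n_behavior = 0
            for sig_name, sig in signatures.items():
                rows = _sim.regional_signatures(sig)
                for coh_name, cohort in adjusted.items():
                    if coh_name == sig_name:
                        continue
                    scores = cohort.phenotypes[
                        [c for c in config.behavior_scores if c in cohort.phenotypes]
                    ]
                    if scores.empty:
                        continue
                    from .connectome import matrixize

                    mats = np.stack([matrixize(c) for c in cohort.connectomes])
                    sims = pd.DataFrame(
                        {
                            k: _sim.similarity_scores(rows[k], mats[:, k, :])
                            for k in range(rows.shape[0])
                        }
                    )
                    table = _sim.behavior_correlation(sims, scores, config.q_threshold)
                    _io.write_table(
                        table, out / f"behavior_{sig_name}_in_{coh_name}.tsv"
                    )
                    n_behavior += len(table)
            summary["stages"]["behavior"] = {"n_correlations": n_behavior}

        stage = "expression"
        if config.expression_samples:
            samples = _io.read_expression_samples(config.expression_samples)
            panel = _expr.normalize_expression(samples, atlas)
            _io.write_panel(panel, out / "expression_panel.tsv")
            expr_summary: dict = {"n_genes": len(panel.genes)}
            for set_name, set_path in config.gene_sets.items():
                gene_set = _io.read_gene_set(set_path)
                for sig_name, sig in signatures.items():
                    y = _expr.regional_response(sig)
                    null_y = np.stack(
                        [_expr.regional_response(b) for b in nulls[sig_name]]
                    )
                    plsr = _expr.plsr_association(
                        panel, y, config.plsr_components, null_y, gene_set=gene_set
                    )
                    correlations = _expr.genome_wide_correlation(
                        panel, y, null_y, config.q_threshold
                    )
                    p_median, p_top = _expr.gene_set_tests(
                        gene_set,
                        correlations,
                        n_random=config.n_random_sets,
                        seed=seeds["genesets"],
                    )
                    expr_summary[f"{set_name}_vs_{sig_name}"] = {
                        "plsr_r2": plsr.r2_response,
                        "plsr_p": plsr.p_perm,
                        "gene_set_p_median": p_median,
                        "gene_set_p_top_percentile": p_top,
                    }
            summary["stages"]["expression"] = expr_summary

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete: %s", out)
        return out
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise ConnsigError(f"pipeline failed at stage '{stage}': {exc}") from exc
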