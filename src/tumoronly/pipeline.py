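"""End-to-end orchestration: simulate -> filter -> enrich -> survive -> compare.

A single YAML config drives the whole analysis.  Every stage draws its
randomness from a seed derived from the root seed and the stage name,
so stages are independently reproducible and a rerun with the same
config is bit-identical.  A completed run is cached through its
manifest: rerunning over an output directory whose manifest carries the
same config hash returns the stored results without recomputation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import compare_enrichment_results, confusion_vs_truth, sum_confusions
from .enrichment import (
    build_cohort_matrix,
    domain_enrichment,
    gene_enrichment,
    pathway_enrichment,
    results_to_frame,
)
from .io import (
    read_annotation_table,
    read_gmt,
    read_survival_table,
    read_vcf,
    write_annotation_table,
    write_gmt,
    write_survival_table,
    write_vcf,
)
from .panel import (
    FitError,
    apply_panel_filter,
    fit_carrier_spectrum,
    fit_saturation_curve,
    refine_with_matched_normal,
    required_panel_size,
    sensitivity_curve,
)
from .simulate import (
    CohortConfig,
    PopulationModel,
    SurvivalConfig,
    build_germline_pool,
    simulate_cohort,
    simulate_panel,
    simulate_survival,
    synthetic_annotations,
)
from .survival import mutation_survival_screen

__all__ = ["PipelineConfig", "run_pipeline", "default_config", "stage_seed"]

logger = logging.getLogger(__name__)

_DEFAULT_K_GRID = [1, 2, 5, 10, 20, 40, 60, 96, 130, 170, 217]


def default_config() -> dict:
    """A fully populated default configuration (synthetic cohort at study scale)."""
    return {
        "seed": 1,
        "outdir": "tumoronly_run",
        "simulate": {
            "genome": {"n_genes": 17_175, "n_drivers": 11},
            "population": {"n_germline_sites": 100_000},
            "cohort": {
                "n_patients": 97,
                "somatic_per_patient": 150.0,
                "recurrent_fraction": 0.03,
                "artifact_fraction": 0.25,
                "normal_miss_rate": 0.02,
            },
            "panel": {"size": 217, "label": "JPT"},
            "survival": {
                "baseline_hazard": 0.015,
                "censoring_time": 60.0,
                "hazard_ratios": "auto",
            },
        },
        "thresholds": {
            "alpha_gene": 0.02,
            "alpha_pathway": 0.05,
            "min_gene_snvs": 5,
            "min_domain_snvs": 3,
            "max_combos": 10_000,
            "min_carriers": 3,
        },
        "powercurve": {"k_grid": list(_DEFAULT_K_GRID), "targets": [0.90, 0.95]},
        "write_vcfs": True,
    }


@dataclasses.dataclass
class PipelineConfig:
    data: dict

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data=_merge(default_config(), data))

    @classmethod
    def default(cls, **overrides) -> "PipelineConfig":
        return cls(data=_merge(default_config(), overrides))

    def __getitem__(self, key):
        return self.data[key]

    def hash(self) -> str:
        canon = json.dumps(self.data, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: root seed combined with a stage-name hash."""
    return int(
        np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31 - 1)
    )


def _auto_hazard_ratios(genome) -> dict[str, float]:
    """Two prognosis drivers: one hazard-increasing, one protective."""
    drivers = genome.driver_genes
    if len(drivers) >= 7:
        return {drivers[5]: 3.0, drivers[6]: 1.0 / 3.0}
    if len(drivers) >= 2:
        return {drivers[0]: 3.0, drivers[1]: 1.0 / 3.0}
    return {}


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Run the full analysis described by ``config``; returns the manifest.

    Writes crude and refined somatic VCFs, the sensitivity curve and its
    saturation fits, gene/domain/pathway enrichment tables for both
    datasets, survival screens, the crude-vs-refined overlap report, a
    per-patient confusion table, and a manifest echoing the seeds and
    parameters.  Reruns with an unchanged config are served from the
    manifest cache.
    """
    outdir = Path(config["outdir"])
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") == config.hash():
            logger.info("pipeline: cached run found in %s; reusing", outdir)
            return old
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    thr = config["thresholds"]
    manifest: dict[str, Any] = {
        "tool": "tumoronly",
        "version": __version__,
        "seed": seed,
        "config_hash": config.hash(),
        "config": config.data,
        "stages": {},
    }

    if config.data.get("simulate"):
        bundle_objs = _simulate_inputs(config, seed, manifest)
    else:
        bundle_objs = _load_inputs(config, manifest)
    (annotations, tumor, normal, panel, survival_df, germline_truth, genome) = bundle_objs

    # --- filtering -------------------------------------------------------
    crude = [apply_panel_filter(cs, panel) for cs in tumor] if panel else None
    refined = (
        [refine_with_matched_normal(t, n) for t, n in zip(tumor, normal)] if normal else None
    )
    n_cand = sum(len(cs) for cs in tumor)
    manifest["stages"]["filter"] = {
        "candidates": n_cand,
        "crude_kept": sum(len(cs) for cs in crude) if crude else None,
        "refined_kept": sum(len(cs) for cs in refined) if refined else None,
        "panel_size": len(panel) if panel else 0,
    }
    logger.info("filter: %s", manifest["stages"]["filter"])
    if config.data.get("write_vcfs", True):
        for name, sets in (("crude", crude), ("refined", refined)):
            if sets:
                d = outdir / name
                d.mkdir(exist_ok=True)
                for cs in sets:
                    write_vcf(cs, d / f"{cs.sample_id}.vcf")

    # --- panel power curve ----------------------------------------------
    if germline_truth and panel:
        pc = config["powercurve"]
        k_grid = [k for k in pc["k_grid"] if k <= len(panel)]
        curve = sensitivity_curve(
            germline_truth, panel, k_grid, max_combos=int(thr["max_combos"]),
            seed=stage_seed(seed, "powercurve"), exact=bool(pc.get("exact", True)),
        )
        curve.to_frame().to_csv(outdir / "sensitivity_curve.tsv", sep="\t", index=False)
        fits: dict[str, Any] = {}
        try:
            expfit = fit_saturation_curve(curve, model="exponential")
            fits["exponential"] = {
                "s_max": expfit.s_max,
                "tau": expfit.tau,
                "residual_rms": expfit.residual_rms,
            }
        except (FitError, ValueError) as exc:
            fits["exponential"] = {"error": str(exc)}
        spec_fit = fit_carrier_spectrum(germline_truth, panel)
        required = {}
        for t in pc.get("targets", []):
            try:
                required[str(t)] = required_panel_size(spec_fit, float(t))
            except ValueError as exc:
                required[str(t)] = str(exc)
        fits["carrier_spectrum"] = {
            "residual_rms": spec_fit.residual_rms,
            "required_panel_size": required,
        }
        with open(outdir / "saturation_fit.json", "w") as fh:
            json.dump(fits, fh, indent=2, sort_keys=True)
        manifest["stages"]["powercurve"] = {
            "k_grid": [int(p.k) for p in curve.points],
            "sensitivity": [round(p.mean_sensitivity, 6) for p in curve.points],
            "required_panel_size": required,
        }
        logger.info("powercurve: %s", manifest["stages"]["powercurve"])

    # --- enrichment ------------------------------------------------------
    enrich_results: dict[str, list] = {}
    for name, sets in (("crude", crude), ("refined", refined)):
        if not sets:
            continue
        matrix = build_cohort_matrix(sets, annotations)
        res = (
            gene_enrichment(matrix, annotations)
            + domain_enrichment(
                matrix,
                annotations,
                min_gene_snvs=int(thr["min_gene_snvs"]),
                min_domain_snvs=int(thr["min_domain_snvs"]),
            )
            + pathway_enrichment(matrix, annotations)
        )
        enrich_results[name] = res
        frame = results_to_frame(res)
        for kind in ("gene", "domain", "pathway"):
            sub = frame[frame["kind"] == kind].sort_values(["p_value", "unit_id"])
            sub.to_csv(outdir / f"enrichment_{kind}_{name}.tsv", sep="\t", index=False)
        alpha = {"gene": thr["alpha_gene"], "domain": thr["alpha_gene"], "pathway": thr["alpha_pathway"]}
        manifest["stages"][f"enrichment_{name}"] = {
            kind: int(((frame["kind"] == kind) & (frame["p_value"] < alpha[kind])).sum())
            for kind in ("gene", "domain", "pathway")
        }
        logger.info("enrichment[%s]: %s", name, manifest["stages"][f"enrichment_{name}"])

        if survival_df is not None:
            screen = mutation_survival_screen(
                matrix, survival_df, min_carriers=int(thr["min_carriers"])
            )
            screen.to_csv(outdir / f"survival_screen_{name}.tsv", sep="\t", index=False)
            manifest["stages"][f"survival_{name}"] = {
                "n_genes_screened": int(len(screen)),
                "n_significant": int((screen["p_value"] < 0.05).sum()),
            }

    # --- concordance -----------------------------------------------------
    if "crude" in enrich_results and "refined" in enrich_results:
        overlap = compare_enrichment_results(
            enrich_results["crude"],
            enrich_results["refined"],
            alpha_gene=float(thr["alpha_gene"]),
            alpha_pathway=float(thr["alpha_pathway"]),
        )
        overlap.to_csv(outdir / "overlap_report.tsv", sep="\t", index=False)
        manifest["stages"]["overlap"] = {
            r["kind"]: [int(r["n_crude"]), int(r["n_refined"]), int(r["n_overlap"])]
            for _, r in overlap.iterrows()
        }
        logger.info("overlap (crude/refined/both): %s", manifest["stages"]["overlap"])

    labeled = all(
        cs.attrs.get(v, {}).get("label") is not None for cs in tumor for v in cs.variants
    )
    if crude and labeled:
        confs = [confusion_vs_truth(c, t) for c, t in zip(crude, tumor)]
        total = sum_confusions(confs)
        pd.DataFrame(
            [(c.sample_id, c.tp, c.fp, c.fn, c.tn) for c in confs],
            columns=["patient_id", "tp", "fp", "fn", "tn"],
        ).to_csv(outdir / "confusion.tsv", sep="\t", index=False)
        manifest["stages"]["confusion"] = {
            "tp": total.tp,
            "fp": total.fp,
            "fn": total.fn,
            "tn": total.tn,
            "sensitivity": round(total.sensitivity, 6),
            "specificity": round(total.specificity, 6),
            "candidate_fp_fraction": round(
                (total.fp + total.tn) / total.n_input if total.n_input else float("nan"), 6
            ),
        }
        logger.info("confusion: %s", manifest["stages"]["confusion"])

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _simulate_inputs(config: PipelineConfig, seed: int, manifest: dict):
    sim = config["simulate"]
    genome = synthetic_annotations(**sim["genome"], seed=stage_seed(seed, "genome"))
    pop = PopulationModel(**sim["population"])
    pool = build_germline_pool(pop, genome, seed=stage_seed(seed, "pool"))
    panel = simulate_panel(
        pool,
        int(sim["panel"]["size"]),
        sim["panel"].get("label", "PANEL"),
        seed=stage_seed(seed, "panel"),
    )
    cohort_cfg = CohortConfig(**sim["cohort"])
    cohort = simulate_cohort(cohort_cfg, pool, genome, seed=stage_seed(seed, "cohort"))
    surv = dict(sim["survival"])
    hr = surv.pop("hazard_ratios", "auto")
    if hr == "auto":
        hr = _auto_hazard_ratios(genome)
    survival_df = simulate_survival(
        cohort, SurvivalConfig(hazard_ratio_by_gene=hr or {}, **surv),
        seed=stage_seed(seed, "survival"),
    )
    manifest["stages"]["simulate"] = {
        "n_patients": len(cohort),
        "n_genes": len(genome.gene_ids),
        "coding_space": genome.total_length,
        "pool_sites": len(pool),
        "panel_size": len(panel),
        "drivers": genome.driver_genes,
        "hazard_ratios": {g: float(v) for g, v in (hr or {}).items()},
    }
    logger.info("simulate: %s", manifest["stages"]["simulate"])
    if config.data.get("write_vcfs", True):
        outdir = Path(config["outdir"])
        for sub, sets in (("tumor", cohort.tumor), ("normal", cohort.normal)):
            d = outdir / sub
            d.mkdir(parents=True, exist_ok=True)
            for cs in sets:
                write_vcf(cs, d / f"{cs.sample_id}.vcf")
        write_vcf(panel, outdir / "panel.vcf")
        write_annotation_table(genome.annotations, outdir / "annotations.tsv")
        write_gmt(genome.annotations.pathways, outdir / "pathways.gmt")
        write_survival_table(survival_df, outdir / "survival.tsv")
    return (
        genome.annotations,
        cohort.tumor,
        cohort.normal,
        panel,
        survival_df,
        cohort.germline_truth(),
        genome,
    )


def _load_inputs(config: PipelineConfig, manifest: dict):
    paths = config.data.get("inputs") or {}
    missing = []
    if not paths.get("tumor_dir"):
        missing.append("inputs.tumor_dir")
    if not paths.get("panel_vcf") and not paths.get("normal_dir"):
        missing.append("inputs.panel_vcf or inputs.normal_dir")
    if not paths.get("annotations"):
        missing.append("inputs.annotations")
    if missing:
        raise ValueError(f"pipeline config missing inputs: {', '.join(missing)}")
    annotations = read_annotation_table(paths["annotations"])
    if paths.get("pathways"):
        annotations.pathways = read_gmt(paths["pathways"])
    tumor = [
        read_vcf(p) for p in sorted(Path(paths["tumor_dir"]).glob("*.vcf"))
    ]
    if not tumor:
        raise ValueError(f"no VCFs found in {paths['tumor_dir']}")
    normal = None
    if paths.get("normal_dir"):
        normal = [read_vcf(p) for p in sorted(Path(paths["normal_dir"]).glob("*.vcf"))]
        ids_t = [cs.sample_id for cs in tumor]
        ids_n = [cs.sample_id for cs in normal]
        if ids_t != ids_n:
            raise ValueError("tumor and normal directories do not pair up by sample id")
    panel = read_vcf(paths["panel_vcf"]) if paths.get("panel_vcf") else None
    survival_df = read_survival_table(paths["survival"]) if paths.get("survival") else None
    germline_truth = (
        {cs.sample_id: frozenset(cs.variants) for cs in normal} if normal else None
    )
    manifest["stages"]["load"] = {
        "n_patients": len(tumor),
        "panel_size": len(panel) if panel else 0,
    }
    return (annotations, tumor, normal, panel, survival_df, germline_truth, None)
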