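"""End-to-end orchestration: simulate -> traits -> ANOVA/quantgen -> GWA -> network.

A run is driven by a single :class:`PipelineConfig` (loadable from
YAML).  One explicit seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence`` with fixed spawn keys, so each stage is
independently reproducible and a rerun with the same config reproduces
every output bit-for-bit.  Each stage writes its tables under the output
directory and registers them in a JSON manifest with sha256 checksums,
row counts and the parameter values used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gwa as gwa_mod
from . import io
from . import network as net_mod
from . import quantgen
from . import synthetic
from . import traits as traits_mod
from .anova import Factor, ModelSpec, derive_ems, estimate_components, \
    fit_balanced_anova, synthesize_tests

__all__ = ["PipelineConfig", "run", "load_config"]

STAGE_SEEDS = {"simulate": 0, "gwa": 10, "network": 11}


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "cafeqg_run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    consumption_path: str | None = None              # real data instead of simulation
    genotypes_path: str | None = None
    annotation_path: str | None = None
    network_path: str | None = None
    stages: dict = field(default_factory=lambda: {
        "traits": True, "anova": True, "quantgen": True,
        "gwa": True, "network": True,
    })
    gwa_traits: list = field(default_factory=lambda: ["drug_E1"])
    maf_min: float = 0.05
    candidate_p: float = 5e-5
    gene_window: int = 1000
    alpha: float = 0.05
    n_perm: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.maf_min < 0.5 and 0 < self.candidate_p < 1
                and 0 < self.alpha < 1 and self.gene_window >= 0 and self.n_perm >= 1):
            raise ValueError("pipeline thresholds out of valid ranges")
        if not self.simulation and self.consumption_path is None:
            raise ValueError("provide either a simulation block or a consumption_path")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(manifest: dict, stage: str, path: Path, n_rows: int | None = None) -> None:
    manifest["files"].append({
        "stage": stage, "path": path.name, "sha256": _sha256(path),
        "n_rows": n_rows,
    })


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": asdict(config),
                      "stages": {}, "files": []}

    def fail(stage: str, err: Exception):
        manifest["stages"][stage] = "FAILED"
        io.write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # -- inputs ----------------------------------------------------------
    sim_seed = int(np.random.SeedSequence(
        config.seed, spawn_key=(STAGE_SEEDS["simulate"],)).generate_state(1)[0] % (2**31))
    truth = None
    sim_line_means = None
    if config.simulation or config.consumption_path is None:
        sim_cfg = synthetic.SimulationConfig(**{**config.simulation, "seed": sim_seed})
        study = synthetic.simulate_study(sim_cfg)
        fixture_paths = synthetic.write_fixtures(study, out / "inputs")
        consumption, genotypes = study.consumption, study.genotypes
        annotation, graph, truth = study.annotation, study.network, study.truth
        sim_line_means = study.line_means
        for name, p in fixture_paths.items():
            _register(manifest, "simulate", p)
        manifest["stages"]["simulate"] = "ok"
    else:
        consumption = io.read_consumption(config.consumption_path)
        genotypes = io.read_vcf(config.genotypes_path) if config.genotypes_path else None
        annotation = io.read_bed(config.annotation_path) if config.annotation_path else None
        graph = io.read_edges(config.network_path) if config.network_path else None

    # -- traits ----------------------------------------------------------
    corrected = vial_traits = lmeans = None
    if config.stages.get("traits", True):
        try:
            corrected = traits_mod.correct_evaporation(consumption)
            vial_traits = traits_mod.compute_traits(corrected)
            lmeans = traits_mod.line_means(vial_traits)
            for name, df in (("corrected_consumption", corrected),
                             ("vial_traits", vial_traits), ("line_means", lmeans)):
                p = io.write_table(df, out / f"{name}.tsv")
                _register(manifest, "traits", p, len(df))
            manifest["stages"]["traits"] = "ok"
        except Exception as e:  # noqa: BLE001 - stage boundary
            fail("traits", e)

    # -- full mixed-model ANOVA + components ----------------------------
    components = None
    if config.stages.get("anova", True) and corrected is not None:
        try:
            n_lines = corrected["line_id"].nunique()
            n_exp = corrected["exposure"].nunique()
            reps = int(len(corrected) / (n_lines * n_exp * 4))
            model = ModelSpec(
                factors=(Factor("line_id", n_lines, fixed=False),
                         Factor("exposure", n_exp, fixed=True),
                         Factor("solution", 2, fixed=True),
                         Factor("sex", 2, fixed=True)),
                n_replicates=reps,
            )
            ems = derive_ems(model)
            tab = synthesize_tests(
                fit_balanced_anova(corrected, model, "consumption_mm"), ems)
            components = estimate_components(tab, ems)
            p = io.write_table(tab.table.reset_index(), out / "anova_full.tsv")
            _register(manifest, "anova", p, len(tab.table))
            p = io.write_table(components.table.reset_index(),
                               out / "variance_components.tsv")
            _register(manifest, "anova", p, len(components.table))
            manifest["stages"]["anova"] = "ok"
        except Exception as e:  # noqa: BLE001
            fail("anova", e)

    # -- heritabilities / correlations ----------------------------------
    if config.stages.get("quantgen", True) and components is not None:
        try:
            reps = int(lmeans["n_vials"].iloc[0])
            rows = []
            for mode in ("vial", "line_means"):
                h2 = quantgen.broad_sense_h2(components, n_replicates=reps, mode=mode,
                                             line_factor="line_id")
                rows.append(("consumption_full_model", mode, h2.sum_genetic,
                             h2.residual, h2.h2))
            h2_tab = pd.DataFrame(rows, columns=["trait", "basis", "sum_genetic",
                                                 "residual", "h2"])
            p = io.write_table(h2_tab, out / "heritability.tsv")
            _register(manifest, "quantgen", p, len(h2_tab))
            corr = quantgen.correlation_matrix(
                lmeans, [c for c in traits_mod.TRAIT_COLUMNS if c in lmeans.columns])
            p = io.write_table(corr, out / "phenotypic_correlations.tsv")
            _register(manifest, "quantgen", p, len(corr))
            manifest["stages"]["quantgen"] = "ok"
        except Exception as e:  # noqa: BLE001
            fail("quantgen", e)

    # -- GWA -------------------------------------------------------------
    candidate_gene_ids: list[str] = []
    if config.stages.get("gwa", True):
        if genotypes is None or lmeans is None:
            fail("gwa", ValueError("gwa stage enabled but no genotypes/line means"))
        try:
            gwa_means = sim_line_means if sim_line_means is not None else lmeans
            filtered = gwa_mod.filter_variants(genotypes, maf_min=config.maf_min)
            all_assigned = []
            for trait in config.gwa_traits:
                for sex in ("F", "M"):
                    res = gwa_mod.associate(
                        gwa_means, filtered, trait, sex,
                        candidate_p=config.candidate_p, alpha=config.alpha)
                    if annotation is not None:
                        res = gwa_mod.assign_genes(res, annotation,
                                                   window_bp=config.gene_window)
                    all_assigned.append(res)
            assoc = pd.concat(all_assigned, ignore_index=True)
            p = io.write_table(assoc, out / "gwa_results.tsv")
            _register(manifest, "gwa", p, len(assoc))
            if annotation is not None:
                candidate_gene_ids = gwa_mod.candidate_genes(assoc)
                p = io.write_table(pd.DataFrame({"gene_id": candidate_gene_ids}),
                                   out / "candidate_genes.tsv")
                _register(manifest, "gwa", p, len(candidate_gene_ids))
            manifest["stages"]["gwa"] = "ok"
        except Exception as e:  # noqa: BLE001
            fail("gwa", e)

    # -- network ---------------------------------------------------------
    if config.stages.get("network", True) and graph is not None:
        try:
            net_seed = int(np.random.SeedSequence(
                config.seed, spawn_key=(STAGE_SEEDS["network"],)
            ).generate_state(1)[0] % (2**31))
            candidates = candidate_gene_ids or (truth or {}).get("module_genes", [])
            res = net_mod.permutation_test(candidates, graph,
                                           n_perm=config.n_perm, seed=net_seed)
            payload = {
                "n_candidates": res.n_candidates, "n_dropped": res.n_dropped,
                "statistic": res.statistic, "members": res.members,
                "p": res.p, "n_permutations": res.n_permutations,
                "n_exceedances": res.n_exceedances, "seed": res.seed,
            }
            p = io.write_json(payload, out / "network_result.json")
            _register(manifest, "network", p)
            manifest["stages"]["network"] = "ok"
        except Exception as e:  # noqa: BLE001
            fail("network", e)

    io.write_json(manifest, out / "manifest.json")
    return manifest
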