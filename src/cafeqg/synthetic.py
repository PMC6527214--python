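"""Synthetic two-choice consumption studies with known ground truth.

The generator is the generative inverse of the mixed-model ANOVA the
package fits: every vial observation is

    Y = mu + (fixed effects of exposure, solution, sex and their
    interactions) + (independent normal draws for line and every
    line-involving interaction, one per level combination, reused across
    all cells sharing those levels) + residual,

split across the vial's two same-solution capillaries and perturbed by a
shared evaporation offset that matching fly-free control vials also
record, so the evaporation-correction stage is exercised non-trivially.

It also plants genotypes (homozygous biallelic, MAF drawn uniformly over
the feasible minor-line counts, causal variants shifting line means),
evenly spaced gene annotations, and a gene-gene interaction network with
a connected module planted over the causal genes.

Defaults reproduce the design of a 46-line inbred panel assayed over
three exposures, two solutions, both sexes and ten replicate vials, with
variance components of a realistic magnitude for consumption in mm.

All randomness flows from a single integer seed; stages draw from
independently seeded child streams (consumption=0, genotypes=1,
network=2) in a fixed documented order, so any stage can be reproduced
standalone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io
from .gwa import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "ConfigurationError",
    "simulate_consumption",
    "simulate_genotypes",
    "simulate_annotation",
    "simulate_network",
    "simulate_study",
    "write_fixtures",
]

FIXED_TERMS = ("E", "S", "X", "E×S", "E×X", "S×X", "E×S×X")
RANDOM_TERMS = ("L", "L×E", "L×S", "L×X", "L×E×S", "L×E×X", "L×S×X", "L×E×S×X")


class ConfigurationError(ValueError):
    """A simulation parameter is inconsistent or infeasible."""


def _default_variance_components() -> dict[str, float]:
    # Magnitudes typical of line-panel consumption variation (mm^2):
    # line variance dominates the genetic terms, residual between-vial
    # variation dominates overall.
    return {
        "L": 63.86, "L×E": 7.71, "L×S": 4.52, "L×X": 15.24,
        "L×E×S": 13.16, "L×E×X": 0.27, "L×S×X": 4.23, "L×E×S×X": 0.25,
        "residual": 267.28,
    }


def _default_fixed_effects() -> dict[str, np.ndarray]:
    # Main effects sized so exposure, solution and sex are all detectable
    # (sex dimorphism the largest, as is typical for body-size-driven
    # intake); interaction effects default to zero.
    return {
        "E": np.array([-2.6, 0.0, 2.6]),
        "S": np.array([1.65, -1.65]),     # (drug, sucrose)
        "X": np.array([6.4, -6.4]),       # (F, M)
        "E×S": np.zeros((3, 2)),
        "E×X": np.zeros((3, 2)),
        "S×X": np.zeros((2, 2)),
        "E×S×X": np.zeros((3, 2, 2)),
    }


@dataclass
class SimulationConfig:
    """Parameters of a synthetic balanced consumption study."""

    n_lines: int = 46
    n_exposures: int = 3
    n_solutions: int = 2
    n_sexes: int = 2
    n_vials: int = 10
    grand_mean: float = 50.0  # mm per vial per solution
    fixed_effects: dict = field(default_factory=_default_fixed_effects)
    variance_components: dict = field(default_factory=_default_variance_components)
    # evaporation of the capillary column in fly-free controls
    evaporation_mean_mm: float = 1.5
    evaporation_sd_mm: float = 0.2
    n_control_vials: int = 10
    # genotypes
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 5
    causal_effect_mm: float = 2.0
    causal_trait: str = "drug_E1"
    # annotation / network
    n_genes: int = 500
    genome_length: int = 1_000_000
    chromosome: str = "2L"
    planted_module_size: int = 10
    background_edge_prob: float = 0.005
    module_extra_edge_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_exposures", "n_solutions", "n_sexes", "n_vials"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.n_solutions != 2 or self.n_sexes != 2:
            raise ConfigurationError("n_solutions and n_sexes must both be 2")
        for term, v in self.variance_components.items():
            if v < 0:
                raise ConfigurationError(f"variance component {term!r} is negative")
        unknown = set(self.variance_components) - set(RANDOM_TERMS) - {"residual"}
        if unknown:
            raise ConfigurationError(f"unknown variance component terms: {sorted(unknown)}")
        shapes = {"E": (self.n_exposures,), "S": (2,), "X": (2,),
                  "E×S": (self.n_exposures, 2), "E×X": (self.n_exposures, 2),
                  "S×X": (2, 2), "E×S×X": (self.n_exposures, 2, 2)}
        for term, arr in self.fixed_effects.items():
            arr = np.asarray(arr, dtype=float)
            if term not in shapes:
                raise ConfigurationError(f"unknown fixed-effect term {term!r}")
            if arr.shape != shapes[term]:
                raise ConfigurationError(
                    f"fixed_effects[{term!r}] has shape {arr.shape}, expected {shapes[term]}"
                )
            for axis in range(arr.ndim):
                if np.abs(arr.sum(axis=axis)).max() > 1e-8:
                    raise ConfigurationError(
                        f"fixed_effects[{term!r}] must sum to zero over each factor"
                    )
            self.fixed_effects[term] = arr
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.n_causal > self.n_variants:
            raise ConfigurationError("n_causal exceeds n_variants")
        if self.planted_module_size > self.n_genes:
            raise ConfigurationError("planted_module_size exceeds n_genes")
        if not 0 <= self.background_edge_prob <= 1:
            raise ConfigurationError("background_edge_prob must be a probability")

    # -- derived labels ---------------------------------------------------

    @property
    def line_ids(self) -> list[str]:
        return [f"L{i + 1:03d}" for i in range(self.n_lines)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class SimulatedStudy:
    """A complete synthetic study plus the ground truth that generated it."""

    config: SimulationConfig
    consumption: pd.DataFrame          # raw capillary records incl. controls
    genotypes: GenotypeMatrix | None
    annotation: pd.DataFrame | None
    network: nx.Graph | None
    truth: dict
    line_means: pd.DataFrame | None = None  # GWA-ready, incl. planted causal shifts


# ---------------------------------------------------------------------------
# consumption
# ---------------------------------------------------------------------------

_TERM_FACTORS = {
    "L": ("L",), "E": ("E",), "S": ("S",), "X": ("X",),
    "L×E": ("L", "E"), "L×S": ("L", "S"), "L×X": ("L", "X"),
    "E×S": ("E", "S"), "E×X": ("E", "X"), "S×X": ("S", "X"),
    "L×E×S": ("L", "E", "S"), "L×E×X": ("L", "E", "X"), "L×S×X": ("L", "S", "X"),
    "E×S×X": ("E", "S", "X"), "L×E×S×X": ("L", "E", "S", "X"),
}


def simulate_consumption(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate raw capillary records (with controls) and the truth record.

    Draw order (fixed for seed portability): random-effect vectors for
    L, L×E, L×S, L×X, L×E×S, L×E×X, L×S×X, L×E×S×X; residuals; capillary
    split fractions; evaporation offsets per stratum; per-capillary
    evaporation noise for experimental then control vials.
    """
    rng = rng if rng is not None else config.stage_rng(0)
    nL, nE, nS, nX, r = (config.n_lines, config.n_exposures, 2, 2, config.n_vials)
    dims = {"L": nL, "E": nE, "S": nS, "X": nX}

    vc = {**_default_variance_components(), **config.variance_components}
    draws: dict[str, np.ndarray] = {}
    for term in RANDOM_TERMS:
        shape = tuple(dims[f] for f in _TERM_FACTORS[term])
        draws[term] = rng.normal(0.0, np.sqrt(vc[term]), size=shape)

    # cell means over the L x E x S x X grid
    cell = np.full((nL, nE, nS, nX), config.grand_mean)
    fx = {**_default_fixed_effects(), **{k: np.asarray(v, float)
                                         for k, v in config.fixed_effects.items()}}
    cell += fx["E"][None, :, None, None]
    cell += fx["S"][None, None, :, None]
    cell += fx["X"][None, None, None, :]
    cell += fx["E×S"][None, :, :, None]
    cell += fx["E×X"][None, :, None, :]
    cell += fx["S×X"][None, None, :, :]
    cell += fx["E×S×X"][None, :, :, :]
    for term in RANDOM_TERMS:
        facs = _TERM_FACTORS[term]
        view = np.expand_dims(draws[term], axis=tuple(
            i for i, f in enumerate(("L", "E", "S", "X")) if f not in facs
        ))
        cell = cell + view

    resid = rng.normal(0.0, np.sqrt(vc["residual"]), size=(nL, nE, nS, nX, r))
    consumption = np.clip(cell[..., None] + resid, 0.0, None)

    split = rng.uniform(0.25, 0.75, size=consumption.shape)
    evap_offset = np.clip(
        rng.normal(config.evaporation_mean_mm, 0.2 * config.evaporation_mean_mm,
                   size=(nE, nS)),
        0.0, None,
    )
    evap_noise = rng.normal(0.0, config.evaporation_sd_mm, size=consumption.shape + (2,))
    ctrl_noise = rng.normal(0.0, config.evaporation_sd_mm,
                            size=(nE, nS, config.n_control_vials, 2))

    lines = config.line_ids
    sexes = ["F", "M"]
    solutions = ["drug", "sucrose"]
    rows_idx = pd.MultiIndex.from_product(
        [lines, range(1, nE + 1), solutions, sexes, range(1, r + 1)],
        names=["line_id", "exposure", "solution", "sex", "vial"],
    )
    cons_flat = consumption.reshape(-1)  # (L, E, S, X, r) in C order matches the product
    split_flat = split.reshape(-1)
    evap_cell = np.broadcast_to(
        evap_offset[None, :, :, None, None], consumption.shape
    ).reshape(-1)
    noise_flat = evap_noise.reshape(-1, 2)
    cap1 = np.clip(cons_flat * split_flat + evap_cell + noise_flat[:, 0], 0.0, None)
    cap2 = np.clip(cons_flat * (1 - split_flat) + evap_cell + noise_flat[:, 1], 0.0, None)

    records = pd.DataFrame(index=rows_idx).reset_index()
    records["capillary1_mm"] = cap1
    records["capillary2_mm"] = cap2
    records["is_control"] = 0

    ctrl_rows = []
    for (ei, e), (si, s) in itertools.product(enumerate(range(1, nE + 1)),
                                              enumerate(solutions)):
        for v in range(config.n_control_vials):
            c1 = max(0.0, evap_offset[ei, si] + ctrl_noise[ei, si, v, 0])
            c2 = max(0.0, evap_offset[ei, si] + ctrl_noise[ei, si, v, 1])
            ctrl_rows.append(("CTRL", e, s, "F", v + 1, c1, c2, 1))
    ctrl = pd.DataFrame(ctrl_rows, columns=["line_id", "exposure", "solution", "sex",
                                            "vial", "capillary1_mm", "capillary2_mm",
                                            "is_control"])
    out = pd.concat([records, ctrl], ignore_index=True)
    out = out[["line_id", "sex", "exposure", "solution", "vial",
               "capillary1_mm", "capillary2_mm", "is_control"]]

    truth = {
        "random_effects": {t: draws[t] for t in RANDOM_TERMS},
        "evaporation_offsets": evap_offset,
        "variance_components": dict(vc),
        "grand_mean": config.grand_mean,
    }
    return out, truth


# ---------------------------------------------------------------------------
# genotypes / annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced non-overlapping gene bodies along one chromosome arm."""
    span = config.genome_length // config.n_genes
    if span < 10:
        raise ConfigurationError("genome_length too short for n_genes")
    rows = []
    for i, gid in enumerate(config.gene_ids):
        start = i * span + span // 4 + 1
        end = start + span // 2 - 1
        rows.append((gid, gid, config.chromosome, start, end, "+" if i % 2 == 0 else "-"))
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"])


def simulate_genotypes(
    config: SimulationConfig,
    line_means: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame | None, dict]:
    """Homozygous biallelic genotypes with planted causal variants.

    The minor-line count of each variant is uniform over the counts
    achievable within ``maf_range`` (MAF in line units).  Causal
    variants are placed inside distinct gene bodies when an annotation
    is given (so the network stage can plant its module over causal
    genes) and shift ``causal_trait`` line means by +effect/2 for
    minor-allele lines and -effect/2 otherwise, in both sexes.

    Returns (genotypes, adjusted line means or None, truth record).
    """
    rng = rng if rng is not None else config.stage_rng(1)
    n = config.n_lines
    if line_means is not None:
        n_found = line_means["line_id"].nunique()
        if n_found != n:
            raise ConfigurationError(
                f"line_means has {n_found} lines but config.n_lines={n}"
            )
    lo, hi = config.maf_range
    m_lo = int(np.ceil(lo * n))
    m_hi = min(int(np.floor(hi * n)), n // 2)
    if m_lo < 1 or m_lo > m_hi:
        raise ConfigurationError(
            f"maf_range {config.maf_range} is infeasible for {n} lines"
        )

    # positions: causal variants inside distinct genes, the rest uniform
    if annotation is None:
        annotation = simulate_annotation(config)
    causal_gene_idx = rng.choice(len(annotation), size=config.n_causal, replace=False)
    causal_pos = np.array([
        int(rng.integers(annotation.iloc[g]["start"], annotation.iloc[g]["end"] + 1))
        for g in causal_gene_idx
    ], dtype=int)
    n_bg = config.n_variants - config.n_causal
    bg_pos = rng.choice(config.genome_length, size=n_bg, replace=False) + 1
    pos = np.concatenate([causal_pos, bg_pos])
    causal_flag = np.zeros(config.n_variants, dtype=bool)
    causal_flag[: config.n_causal] = True
    order = np.argsort(pos, kind="stable")
    pos, causal_flag = pos[order], causal_flag[order]

    calls = np.zeros((n, config.n_variants))
    for j in range(config.n_variants):
        m = int(rng.integers(m_lo, m_hi + 1))
        minor = rng.choice(n, size=m, replace=False)
        calls[minor, j] = 2.0

    variants = pd.DataFrame({
        "chrom": config.chromosome,
        "pos": pos,
        "id": [f"{config.chromosome}_{p}" for p in pos],
        "ref": "A",
        "alt": "T",
    })
    geno = GenotypeMatrix(variants=variants, calls=calls, line_ids=config.line_ids)

    causal_ids = variants.loc[causal_flag, "id"].tolist()
    causal_genes = sorted(annotation.iloc[causal_gene_idx]["gene_id"].tolist())
    adjusted = None
    if line_means is not None and config.n_causal > 0:
        adjusted = line_means.copy()
        order_map = {l: i for i, l in enumerate(config.line_ids)}
        for vid in causal_ids:
            j = int(np.flatnonzero(variants["id"] == vid)[0])
            shift = np.where(
                calls[[order_map[l] for l in adjusted["line_id"]], j] == 2.0,
                +config.causal_effect_mm / 2.0,
                -config.causal_effect_mm / 2.0,
            )
            adjusted[config.causal_trait] = adjusted[config.causal_trait] + shift

    truth = {"causal_variants": causal_ids, "causal_genes": causal_genes,
             "causal_trait": config.causal_trait,
             "causal_effect_mm": config.causal_effect_mm}
    return geno, adjusted, truth


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def simulate_network(
    config: SimulationConfig,
    module_genes: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[nx.Graph, dict]:
    """Erdős–Rényi background plus a connected planted module.

    The module is wired as a random recursive tree over its genes plus
    extra within-module edges at ``module_extra_edge_prob``, so it is
    connected by construction.  ``module_genes`` defaults to a random
    sample of ``planted_module_size`` genes (the study driver passes the
    causal genes, topped up to the module size).
    """
    rng = rng if rng is not None else config.stage_rng(2)
    genes = config.gene_ids
    g = nx.Graph()
    g.add_nodes_from(genes)

    p = config.background_edge_prob
    if p > 0:
        n = len(genes)
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < p
        g.add_edges_from((genes[a], genes[b]) for a, b in zip(iu[mask], ju[mask]))

    module: list[str] = []
    if config.planted_module_size > 0:
        if config.planted_module_size < 2:
            raise ConfigurationError("planted_module_size must be >= 2 when a module is requested")
        if module_genes is None:
            module = list(rng.choice(genes, size=config.planted_module_size, replace=False))
        else:
            module = list(module_genes)
            missing = [m for m in module if m not in g]
            if missing:
                raise ConfigurationError(f"module genes not in universe: {missing[:5]}")
            if len(module) < config.planted_module_size:
                pool = [x for x in genes if x not in set(module)]
                extra = rng.choice(pool, size=config.planted_module_size - len(module),
                                   replace=False)
                module = module + list(extra)
        perm = list(rng.permutation(module))
        for i in range(1, len(perm)):
            j = int(rng.integers(0, i))
            g.add_edge(perm[i], perm[j])  # random recursive tree: connected
        for a, b in itertools.combinations(sorted(module), 2):
            if not g.has_edge(a, b) and rng.random() < config.module_extra_edge_prob:
                g.add_edge(a, b)

    truth = {"module_genes": sorted(module)}
    return g, truth


# ---------------------------------------------------------------------------
# full study + fixtures
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run every generator stage and collect the ground truth."""
    from . import traits as traits_mod

    consumption, truth_c = simulate_consumption(config)
    corrected = traits_mod.correct_evaporation(consumption)
    vial_traits = traits_mod.compute_traits(corrected)
    lmeans = traits_mod.line_means(vial_traits)
    annotation = simulate_annotation(config)
    geno, adjusted, truth_g = simulate_genotypes(config, lmeans, annotation)
    network, truth_n = simulate_network(
        config, module_genes=truth_g["causal_genes"] or None
    )
    truth = {**truth_c, **truth_g, **truth_n}
    gwa_means = adjusted if adjusted is not None else lmeans
    truth["line_means"] = gwa_means.to_dict("list")
    return SimulatedStudy(
        config=config,
        consumption=consumption,
        genotypes=geno,
        annotation=annotation,
        network=network,
        truth=truth,
        line_means=gwa_means,
    )


def write_fixtures(study: SimulatedStudy, directory: str | Path) -> dict[str, Path]:
    """Write the study to plain-text files; returns the file manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "consumption": io.write_consumption(study.consumption, d / "consumption.tsv"),
        "genotypes": io.write_vcf(study.genotypes, d / "genotypes.vcf"),
        "annotation": io.write_bed(study.annotation, d / "annotation.bed"),
        "network": io.write_edges(study.network, d / "network.tsv"),
        "truth": io.write_json(study.truth, d / "truth.json"),
    }
    for name, path in manifest.items():
        if path.stat().st_size == 0:
            raise IOError(f"fixture {name} at {path} is empty")
    return manifest
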