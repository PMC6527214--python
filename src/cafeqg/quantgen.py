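"""Heritabilities and genetic/phenotypic correlations for line panels.

Inbred lines permit only broad-sense quantities: every variance
component whose term involves the line factor counts as genetic.

* H^2 (vial basis)       = sum(G) / (sum(G) + sigma^2_eps)
* H^2 (line-mean basis)  = sum(G) / (sum(G) + sigma^2_eps / r),
  r the number of replicate vials — the precision gain from averaging.
* Cross-condition genetic correlation
  r_G = sigma^2_L(joint) / (sigma_L1 * sigma_L2), where the numerator is
  the among-line variance component of the stacked two-way (line x
  condition) ANOVA — the covariance of line effects across conditions —
  and the denominators are the among-line standard deviations from the
  per-condition one-way ANOVAs.  The ratio estimator can stray outside
  [-1, 1] in finite samples; the raw value is kept alongside a clipped
  one rather than silently clipped.
* Phenotypic correlation: Pearson product-moment correlation of line
  means with a two-sided t-based P-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import (
    AnovaTable,
    Factor,
    ModelSpec,
    derive_ems,
    estimate_components,
    fit_balanced_anova,
)

__all__ = [
    "HeritabilityResult",
    "CorrelationResult",
    "broad_sense_h2",
    "genetic_correlation",
    "phenotypic_correlation",
]


@dataclass
class HeritabilityResult:
    sum_genetic: float
    residual: float
    h2: float
    mode: str           # "vial" | "line_means"
    n_replicates: int


@dataclass
class CorrelationResult:
    r: float                    # clipped to [-1, 1] for the genetic estimator
    raw: float                  # unclipped estimate
    kind: str                   # "genetic" | "phenotypic"
    p: float | None = None      # phenotypic only
    sigma2_joint: float | None = None
    sigma_1: float | None = None
    sigma_2: float | None = None
    out_of_bounds: bool = False
    undefined: bool = False


def broad_sense_h2(
    components,
    n_replicates: int = 1,
    mode: str = "vial",
    line_factor: str = "L",
) -> HeritabilityResult:
    """Broad-sense heritability from estimated variance components.

    ``components`` is a :class:`~cafeqg.anova.VarianceComponents` or a
    plain mapping from term name to sigma^2 (must include "residual").
    Genetic variance is the post-truncation sum of every random term
    containing ``line_factor``.
    """
    if hasattr(components, "genetic_sum"):
        sum_g = components.genetic_sum(line_factor)
        resid = components.residual
    else:
        sum_g = float(sum(v for k, v in components.items()
                          if line_factor in k.split("×")))
        resid = float(components["residual"])
    if mode not in ("vial", "line_means"):
        raise ValueError("mode must be 'vial' or 'line_means'")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    env = resid if mode == "vial" else resid / n_replicates
    total = sum_g + env
    if total <= 0:
        raise ValueError("total phenotypic variance is zero; heritability undefined")
    return HeritabilityResult(sum_genetic=sum_g, residual=resid, h2=sum_g / total,
                              mode=mode, n_replicates=n_replicates)


def _among_line_component(data: pd.DataFrame, value: str, n_lines: int,
                          n_reps: int, condition: str | None,
                          n_conditions: int = 2) -> float:
    """sigma^2_L from a one-way (condition None) or two-way line x condition ANOVA."""
    if condition is None:
        model = ModelSpec(factors=(Factor("line_id", n_lines, fixed=False),),
                          n_replicates=n_reps)
    else:
        model = ModelSpec(factors=(Factor("line_id", n_lines, fixed=False),
                                   Factor(condition, n_conditions, fixed=True)),
                          n_replicates=n_reps)
    ems = derive_ems(model)
    tab = fit_balanced_anova(data, model, value)
    comps = estimate_components(tab, ems)
    return float(comps.table.loc["line_id", "raw"])


def genetic_correlation(
    data: pd.DataFrame,
    condition: str,
    value: str = "value",
) -> CorrelationResult:
    """Cross-condition genetic correlation from replicated line data.

    ``data`` is long format with columns ``line_id``, ``condition`` (two
    levels: the paired sexes, exposures, solutions, or traits) and the
    trait value, balanced within condition.
    """
    levels = sorted(data[condition].unique())
    if len(levels) != 2:
        raise ValueError(f"condition {condition!r} must have exactly 2 levels, got {levels}")
    n_lines = data["line_id"].nunique()
    counts = data.groupby(["line_id", condition], observed=True).size()
    if counts.nunique() != 1:
        raise ValueError("genetic correlation requires balanced replication")
    n_reps = int(counts.iloc[0])

    sigma2_joint = _among_line_component(data, value, n_lines, n_reps, condition)
    sig2 = []
    for lev in levels:
        sub = data[data[condition] == lev]
        sig2.append(_among_line_component(sub, value, n_lines, n_reps, None))
    if sig2[0] <= 0 or sig2[1] <= 0:
        return CorrelationResult(r=np.nan, raw=np.nan, kind="genetic",
                                 sigma2_joint=sigma2_joint,
                                 sigma_1=np.nan, sigma_2=np.nan, undefined=True)
    s1, s2 = np.sqrt(sig2[0]), np.sqrt(sig2[1])
    raw = sigma2_joint / (s1 * s2)
    clipped = float(np.clip(raw, -1.0, 1.0))
    return CorrelationResult(r=clipped, raw=float(raw), kind="genetic",
                             sigma2_joint=sigma2_joint, sigma_1=float(s1),
                             sigma_2=float(s2), out_of_bounds=abs(raw) > 1.0)


def phenotypic_correlation(
    line_means: pd.DataFrame, trait_x: str, trait_y: str
) -> CorrelationResult:
    """Pearson correlation of two traits' line means, two-sided t-based P."""
    cols = [trait_x] if trait_x == trait_y else [trait_x, trait_y]
    sub = line_means[cols].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 lines with both traits")
    x, y = sub[trait_x].to_numpy(), sub[trait_y].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a trait; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), raw=float(r), kind="phenotypic", p=float(p))


def correlation_matrix(line_means: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """All pairwise phenotypic correlations of line means (long format)."""
    rows = []
    for i, tx in enumerate(traits):
        for ty in traits[i + 1:]:
            res = phenotypic_correlation(line_means, tx, ty)
            rows.append((tx, ty, res.r, res.p))
    return pd.DataFrame(rows, columns=["trait_x", "trait_y", "r", "p"])
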