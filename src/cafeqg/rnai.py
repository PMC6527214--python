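"""Fixed-effect contrasts for knockdown-vs-control validation assays.

Each assay compares one RNAi knockdown genotype with its progenitor
control in the same two-choice consumption design, separately by sex,
with every factor fixed (two specific genotypes, not a random sample of
lines).  With all factors fixed every synthesized denominator collapses
to the residual mean square, so these are classical factorial ANOVAs.

Term-to-behavior mapping for the significance calls:

    genotype main effect (L)        -> consumption
    genotype x solution (L×S)       -> preference
    genotype x exposure (L×E)       -> change of consumption
    genotype x exposure x solution  -> change of preference

Only the first and third exposures enter the models.  P-values are
per-test at alpha = 0.05 by default; a Benjamini–Hochberg adjustment
across a batch is available but off by default.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .anova import Factor, ModelSpec, derive_ems, fit_balanced_anova, synthesize_tests

__all__ = ["CATEGORY_TERMS", "fit_contrasts", "fit_batch"]

CATEGORY_TERMS = {
    "consumption": "L",
    "preference": "L×S",
    "change_of_consumption": "L×E",
    "change_of_preference": "L×E×S",
}

MODELS = {
    "full": ("L", "E", "S"),       # consumption: genotype x exposure x solution
    "change": ("L", "S"),          # change scores: genotype x solution
    "preference": ("L", "E"),      # preference: genotype x exposure
}

_FACTOR_COLS = {"L": "genotype", "E": "exposure", "S": "solution"}


def fit_contrasts(
    data: pd.DataFrame,
    response: str = "consumption_mm",
    model: str = "full",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fixed-effect ANOVA of one knockdown/control pair (one sex).

    ``data`` is long format with a two-level ``genotype`` column
    (control vs knockdown) and, depending on the model, ``exposure``
    (restricted to two exposures) and ``solution`` columns, balanced.

    Returns the ANOVA table with a ``call`` column naming the behavior
    category for each genotype-involving term significant at ``alpha``.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {sorted(MODELS)}")
    letters = MODELS[model]
    factors = []
    for letter in letters:
        col = _FACTOR_COLS[letter]
        if col not in data.columns:
            raise ValueError(f"model {model!r} needs column {col!r}")
        n_levels = data[col].nunique()
        if letter == "L" and n_levels != 2:
            raise ValueError("genotype must have exactly 2 levels (control, knockdown)")
        if letter == "E" and n_levels != 2:
            raise ValueError("restrict exposures to the first and third before fitting")
        factors.append(Factor(col, n_levels, fixed=True))
    counts = data.groupby([f.name for f in factors], observed=True).size()
    spec = ModelSpec(factors=tuple(factors), n_replicates=int(counts.iloc[0]))

    ems = derive_ems(spec)
    tab = synthesize_tests(fit_balanced_anova(data, spec, response), ems).table

    name_map = {  # engine term names use data column names
        "×".join(_FACTOR_COLS[l] for l in term_letters): "×".join(term_letters)
        for k in range(1, len(letters) + 1)
        for term_letters in itertools.combinations(letters, k)
    }
    tab = tab.rename(index=name_map)
    term_to_cat = {v: k for k, v in CATEGORY_TERMS.items()}
    tab["call"] = [
        term_to_cat.get(t, "") if (p == p and p < alpha and "L" in t.split("×")) else ""
        for t, p in zip(tab.index, tab["p"])
    ]
    return tab


def fit_batch(
    assays: pd.DataFrame,
    response: str = "consumption_mm",
    model: str = "full",
    alpha: float = 0.05,
    group_cols: tuple[str, ...] = ("gene", "driver", "drug", "sex"),
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """ANOVAs for a panel of knockdown assays, one per group.

    Returns a long table (group columns, term, df, ms, f, p [, p_adj],
    call).  ``bh_adjust`` applies Benjamini–Hochberg across all
    genotype-involving tests in the batch and re-derives the calls from
    the adjusted values.
    """
    rows = []
    for keys, grp in assays.groupby(list(group_cols), observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        tab = fit_contrasts(grp, response=response, model=model, alpha=alpha)
        tab = tab.reset_index().rename(columns={"index": "term"})
        for col, val in zip(group_cols, keys):
            tab[col] = val
        rows.append(tab)
    out = pd.concat(rows, ignore_index=True)
    if bh_adjust:
        mask = out["p"].notna() & out["term"].str.split("×").apply(lambda t: "L" in t)
        out["p_adj"] = np.nan
        out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
        term_to_cat = {v: k for k, v in CATEGORY_TERMS.items()}
        out["call"] = [
            term_to_cat.get(t, "") if (q == q and q < alpha) else ""
            for t, q in zip(out["term"], out["p_adj"])
        ]
    cols = list(group_cols) + [c for c in out.columns if c not in group_cols]
    return out[cols]
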