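"""Balanced factorial ANOVA with mixed-model expected mean squares.

This module is the numerical core of the package.  It implements, for
perfectly balanced full-factorial designs with a mix of fixed and random
factors:

* sums of squares / degrees of freedom / mean squares by cell-mean
  contrasts (Type I = Type III for balanced data);
* expected mean squares (EMS) under the *unrestricted* mixed-model
  convention, in which any term containing at least one random factor is
  a random term and its variance component appears in the EMS of every
  term whose factor set it contains;
* synthesized F-test denominators — exact signed linear combinations of
  other mean squares whose expectation matches the null EMS — with
  Satterthwaite-approximated denominator degrees of freedom;
* method-of-moments variance components with propagated standard errors
  and truncation of negative estimates at zero.

The engine refuses unbalanced data: the method-of-moments identities it
relies on hold only when every cell has the same number of replicates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Factor",
    "ModelSpec",
    "EMSTable",
    "AnovaTable",
    "VarianceComponents",
    "derive_ems",
    "fit_balanced_anova",
    "synthesize_tests",
    "estimate_components",
]

RESIDUAL = "residual"


class UnbalancedDataError(ValueError):
    """Raised when cell counts are unequal (the engine is balanced-only)."""


@dataclass(frozen=True)
class Factor:
    """A crossed factor of the design.

    Parameters
    ----------
    name
        Column name in the long-format data table.
    n_levels
        Number of levels (>= 2).
    fixed
        True for a fixed factor, False for a random one.
    """

    name: str
    n_levels: int
    fixed: bool

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"factor {self.name!r} needs >= 2 levels, got {self.n_levels}")


@dataclass(frozen=True)
class ModelSpec:
    """A full-factorial design: every main effect and interaction, plus residual."""

    factors: tuple[Factor, ...]
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names")

    # -- bookkeeping -------------------------------------------------

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def n_cells(self) -> int:
        return int(np.prod([f.n_levels for f in self.factors]))

    @property
    def n_obs(self) -> int:
        return self.n_cells * self.n_replicates

    def terms(self) -> list[tuple[str, ...]]:
        """All non-empty factor subsets, main effects first, in factor order."""
        out: list[tuple[str, ...]] = []
        for k in range(1, len(self.factors) + 1):
            out.extend(itertools.combinations(self.factor_names, k))
        return out

    def term_name(self, term: tuple[str, ...]) -> str:
        return "×".join(term) if term else RESIDUAL

    def levels(self, term: tuple[str, ...]) -> int:
        by_name = {f.name: f.n_levels for f in self.factors}
        return int(np.prod([by_name[t] for t in term])) if term else 1

    def term_df(self, term: tuple[str, ...]) -> int:
        by_name = {f.name: f.n_levels for f in self.factors}
        return int(np.prod([by_name[t] - 1 for t in term]))

    def residual_df(self) -> int:
        return self.n_cells * (self.n_replicates - 1)

    def is_random(self, term: tuple[str, ...]) -> bool:
        """Unrestricted convention: random iff the term contains a random factor."""
        fixed = {f.name: f.fixed for f in self.factors}
        return any(not fixed[t] for t in term)


@dataclass
class EMSTable:
    """EMS coefficient matrix and synthesized denominators for a model.

    ``coef`` has one row per term plus the residual, one column per
    variance component (every random term plus the residual); entry
    (T, U) is the multiplier of sigma^2_U in E[MS_T].  Fixed terms carry
    an additional quadratic form in their own EMS, marked in
    ``has_fixed_form`` but not part of the component basis.
    ``denominators`` maps each testable term to the weights (over other
    terms' mean squares) of its exact synthesized error term.
    """

    model: ModelSpec
    coef: pd.DataFrame
    has_fixed_form: dict[str, bool]
    denominators: dict[str, dict[str, float]]

    @property
    def component_names(self) -> list[str]:
        return list(self.coef.columns)


@dataclass
class AnovaTable:
    """SS / df / MS decomposition, optionally with F, Satterthwaite df and P."""

    model: ModelSpec
    table: pd.DataFrame  # index: term names + "residual"; cols ss, df, ms [, f, df_denom, p]

    @classmethod
    def from_mean_squares(
        cls,
        model: ModelSpec,
        mean_squares: dict[str, float],
        dfs: dict[str, float] | None = None,
    ) -> "AnovaTable":
        """Build a table from externally reported MS (and optionally df) columns.

        Useful for re-deriving F ratios and variance components from a
        published ANOVA table without access to the raw observations.
        """
        rows = []
        for term in model.terms():
            name = model.term_name(term)
            df_t = dfs.get(name) if dfs else model.term_df(term)
            ms = mean_squares[name]
            rows.append((name, ms * df_t, df_t, ms))
        df_r = dfs.get(RESIDUAL) if dfs else model.residual_df()
        ms_r = mean_squares[RESIDUAL]
        rows.append((RESIDUAL, ms_r * df_r, df_r, ms_r))
        tab = pd.DataFrame(rows, columns=["term", "ss", "df", "ms"]).set_index("term")
        return cls(model=model, table=tab)


@dataclass
class VarianceComponents:
    """Method-of-moments variance components with standard errors.

    ``table`` rows are the random terms plus the residual; columns:
    ``estimate`` (post-truncation), ``se`` (zero where truncated),
    ``raw`` and ``raw_se`` (pre-truncation), ``truncated`` flag.
    """

    model: ModelSpec
    table: pd.DataFrame

    def __getitem__(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])

    @property
    def residual(self) -> float:
        return float(self.table.loc[RESIDUAL, "estimate"])

    def genetic_sum(self, line_factor: str = "L") -> float:
        """Sum of every component whose term involves the line factor."""
        mask = [
            line_factor in name.split("×")
            for name in self.table.index
        ]
        return float(self.table.loc[mask, "estimate"].sum())


# ---------------------------------------------------------------------------
# EMS derivation
# ---------------------------------------------------------------------------


def derive_ems(model: ModelSpec) -> EMSTable:
    """Derive EMS coefficients and synthesized denominators for a full factorial.

    Unrestricted mixed-model convention: sigma^2_U (U any term containing at
    least one random factor) enters E[MS_T] iff T's factor set is a subset of
    U's, with coefficient N / (product of level counts of U's factors).  The
    residual enters every EMS with coefficient 1.  For each term the
    denominator is synthesized by triangular elimination over components in
    order of increasing interaction order; for a full factorial this always
    terminates with an exact (often single-MS) combination.
    """
    terms = model.terms()
    n = model.n_obs
    random_terms = [t for t in terms if model.is_random(t)]
    components = [model.term_name(t) for t in random_terms] + [RESIDUAL]
    row_names = [model.term_name(t) for t in terms] + [RESIDUAL]

    coef = pd.DataFrame(0.0, index=row_names, columns=components)
    coef[RESIDUAL] = 1.0
    for t in terms:
        for u in random_terms:
            if set(t) <= set(u):
                coef.loc[model.term_name(t), model.term_name(u)] = n / model.levels(u)

    has_fixed_form = {model.term_name(t): not model.is_random(t) for t in terms}

    comp_by_name = {model.term_name(t): t for t in random_terms}
    # components ordered by interaction order, so elimination is triangular
    ordered = sorted(comp_by_name, key=lambda c: len(comp_by_name[c]))

    denominators: dict[str, dict[str, float]] = {}
    for t in terms:
        name = model.term_name(t)
        target = coef.loc[name].copy()
        if model.is_random(t):
            target[name] = 0.0  # the null hypothesis removes the term's own component
        weights: dict[str, float] = {}
        for c in ordered:
            if c == name or abs(target[c]) < 1e-12:
                continue
            w = target[c] / coef.loc[c, c]
            weights[c] = weights.get(c, 0.0) + w
            target = target - w * coef.loc[c]
        if abs(target[RESIDUAL]) > 1e-12:
            weights[RESIDUAL] = weights.get(RESIDUAL, 0.0) + float(target[RESIDUAL])
            target[RESIDUAL] = 0.0
        if np.abs(target.to_numpy()).max() > 1e-9:
            raise ValueError(f"no exact denominator combination exists for term {name}")
        denominators[name] = {k: v for k, v in weights.items() if abs(v) > 1e-12}

    return EMSTable(model=model, coef=coef, has_fixed_form=has_fixed_form,
                    denominators=denominators)


# ---------------------------------------------------------------------------
# Sums of squares
# ---------------------------------------------------------------------------


def _check_balance(data: pd.DataFrame, model: ModelSpec) -> None:
    counts = data.groupby(list(model.factor_names), observed=True).size()
    expected_cells = model.n_cells
    if len(counts) != expected_cells or counts.nunique() != 1:
        bad = counts[counts != counts.max()]
        raise UnbalancedDataError(
            f"design is not balanced: expected {expected_cells} cells of equal size, "
            f"found {len(counts)} cells; deficient cells: {bad.index.tolist()[:10]}"
        )
    for f in model.factors:
        observed = data[f.name].nunique()
        if observed != f.n_levels:
            raise UnbalancedDataError(
                f"factor {f.name!r}: expected {f.n_levels} levels, found {observed}"
            )
    if int(counts.iloc[0]) != model.n_replicates:
        raise UnbalancedDataError(
            f"expected {model.n_replicates} replicates per cell, found {int(counts.iloc[0])}"
        )


def fit_balanced_anova(data: pd.DataFrame, model: ModelSpec, response: str) -> AnovaTable:
    """SS, df and MS for every term of a balanced full factorial.

    Effects are estimated by inclusion–exclusion over marginal cell means,
    the classical balanced-data decomposition for which sequential and
    marginal sums of squares coincide.
    """
    _check_balance(data, model)
    y = data[response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    n = model.n_obs
    terms = model.terms()
    names = model.factor_names
    shape = tuple(f.n_levels for f in model.factors)

    codes = [
        pd.Categorical(data[f.name], categories=np.sort(data[f.name].unique())).codes
        for f in model.factors
    ]
    flat = np.ravel_multi_index(codes, shape)
    cell_mean = (
        np.bincount(flat, weights=y, minlength=int(np.prod(shape))).reshape(shape)
        / model.n_replicates
    )

    # marginal means over every factor subset (balanced: simple axis means)
    marg: dict[tuple[str, ...], np.ndarray | float] = {(): float(cell_mean.mean())}
    for t in terms:
        drop = tuple(i for i, nm in enumerate(names) if nm not in t)
        marg[t] = cell_mean.mean(axis=drop) if drop else cell_mean

    rows = []
    for t in terms:
        axes_t = [nm for nm in names if nm in t]
        eff = np.zeros(tuple(shape[names.index(nm)] for nm in axes_t))
        for k in range(len(t) + 1):
            for sub in itertools.combinations(t, k):
                sign = (-1) ** (len(t) - len(sub))
                if not sub:
                    eff = eff + sign * marg[()]
                else:
                    expand = tuple(i for i, nm in enumerate(axes_t) if nm not in sub)
                    eff = eff + sign * np.expand_dims(marg[sub], axis=expand)
        ss = n / model.levels(t) * float(np.sum(eff**2))
        df_t = model.term_df(t)
        rows.append((model.term_name(t), ss, df_t, ss / df_t))

    ss_res = float(np.sum((y - cell_mean.reshape(-1)[flat]) ** 2))
    df_res = model.residual_df()
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    rows.append((RESIDUAL, ss_res, df_res, ms_res))

    tab = pd.DataFrame(rows, columns=["term", "ss", "df", "ms"]).set_index("term")
    return AnovaTable(model=model, table=tab)


# ---------------------------------------------------------------------------
# Synthesized tests and variance components
# ---------------------------------------------------------------------------


def synthesize_tests(anova: AnovaTable, ems: EMSTable) -> AnovaTable:
    """Fill in F ratios, Satterthwaite denominator df, and P-values.

    F(T) = MS(T) / sum_i c_i MS_i, with the weights c_i of the synthesized
    denominator; denominator df = (sum c_i MS_i)^2 / sum (c_i MS_i)^2 / df_i;
    P from the upper tail of the F distribution.  A non-positive synthesized
    denominator yields a missing F with a warning flag.
    """
    tab = anova.table.copy()
    tab["f"] = np.nan
    tab["df_denom"] = np.nan
    tab["p"] = np.nan
    tab["denom_nonpositive"] = False
    for name, weights in ems.denominators.items():
        ms_t = tab.loc[name, "ms"]
        contrib = np.array([w * tab.loc[k, "ms"] for k, w in weights.items()])
        dfs = np.array([tab.loc[k, "df"] for k in weights])
        denom = float(contrib.sum())
        if denom <= 0:
            tab.loc[name, "denom_nonpositive"] = True
            continue
        df_den = denom**2 / float(np.sum(contrib**2 / dfs))
        f = float(ms_t) / denom
        tab.loc[name, "f"] = f
        tab.loc[name, "df_denom"] = df_den
        tab.loc[name, "p"] = stats.f.sf(f, tab.loc[name, "df"], df_den)
    return AnovaTable(model=anova.model, table=tab)


def estimate_components(anova: AnovaTable, ems: EMSTable) -> VarianceComponents:
    """Method-of-moments variance components from the observed mean squares.

    Solves the (triangular, for full factorials) linear system formed by the
    EMS rows of the random terms plus the residual.  Each estimator is a
    signed linear combination sum_i c_i MS_i of mean squares; its standard
    error is sqrt(sum_i c_i^2 * 2 MS_i^2 / df_i).  Negative estimates are
    truncated to zero (flag set, SE reported as 0); the raw values are
    retained and no other component is re-fitted.
    """
    comp_names = ems.component_names
    a = ems.coef.loc[comp_names, comp_names].to_numpy()
    if abs(np.linalg.det(a)) < 1e-12:
        raise ValueError("EMS system is singular over the random components")
    ms = anova.table.loc[comp_names, "ms"].to_numpy(dtype=float)
    dfs = anova.table.loc[comp_names, "df"].to_numpy(dtype=float)
    w = np.linalg.inv(a)
    raw = w @ ms
    raw_se = np.sqrt(w**2 @ (2.0 * ms**2 / dfs))
    truncated = raw < 0
    est = np.where(truncated, 0.0, raw)
    se = np.where(truncated, 0.0, raw_se)
    tab = pd.DataFrame(
        {"estimate": est, "se": se, "raw": raw, "raw_se": raw_se, "truncated": truncated},
        index=comp_names,
    )
    return VarianceComponents(model=anova.model, table=tab)
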