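"""Line-mean genome-wide association for inbred panels.

Inbred lines are homozygous, so each biallelic variant partitions the
panel into two genotype classes and the additive single-variant test on
line means reduces to an ordinary least-squares slope test, equivalent
to an equal-variance two-sample t-test between the classes.  Allele
frequency is counted in units of lines.  Candidate variants are called
at a lenient per-test threshold (default 5e-5) with a Bonferroni bound
reported alongside; variants are assigned to every gene whose body,
extended by a fixed window on both sides, contains their position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "filter_variants",
    "associate",
    "bonferroni_threshold",
    "assign_genes",
]

CANDIDATE_P = 5e-5


@dataclass
class GenotypeMatrix:
    """Homozygous biallelic calls for an inbred line panel.

    ``variants`` has columns chrom, pos (1-based), id, ref, alt, sorted
    by position within chromosome.  ``calls`` is a lines x variants
    float array with values 0 (homozygous reference), 2 (homozygous
    alternate) or NaN (missing).
    """

    variants: pd.DataFrame
    calls: np.ndarray
    line_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.line_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.variants)} variants"
            )
        vals = self.calls[~np.isnan(self.calls)]
        if not np.isin(vals, [0.0, 2.0]).all():
            raise ValueError("calls must be 0, 2 or missing (inbred homozygous panel)")
        for _, grp in self.variants.groupby("chrom", observed=True):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("variant positions must be sorted within chromosome")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, in line units, over non-missing calls."""
        with np.errstate(invalid="ignore"):
            alt_freq = np.nanmean(self.calls, axis=0) / 2.0
        return np.minimum(alt_freq, 1.0 - alt_freq)

    def take(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            variants=self.variants.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
            line_ids=list(self.line_ids),
        )


def filter_variants(
    genotypes: GenotypeMatrix, maf_min: float = 0.05, max_missing: float = 0.2
) -> GenotypeMatrix:
    """Keep variants with MAF >= ``maf_min`` and missingness <= ``max_missing``.

    MAF is computed over the non-missing lines only.  An empty result is
    returned as-is (callers may warn); it is not an error.
    """
    miss = np.mean(np.isnan(genotypes.calls), axis=0)
    maf = genotypes.maf()
    keep = np.flatnonzero((maf >= maf_min) & (miss <= max_missing) & ~np.isnan(maf))
    return genotypes.take(keep)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


def associate(
    line_means: pd.DataFrame,
    genotypes: GenotypeMatrix,
    trait: str,
    sex: str | None = None,
    candidate_p: float = CANDIDATE_P,
    bonferroni_m: int | None = None,
    alpha: float = 0.05,
    min_class_lines: int = 2,
) -> pd.DataFrame:
    """Single-variant additive association of a trait's line means.

    Regresses the line mean on the allele code per variant (OLS), which
    for a homozygous panel equals the pooled-variance two-sample t-test
    between the two genotype classes.  Missing genotypes are dropped per
    variant and MAF recomputed on the scored lines.  Variants with fewer
    than ``min_class_lines`` lines in either class are skipped with a
    reason code.

    Returns one row per variant: effect (difference of class means,
    minor minus major, in trait units), t, p, maf, n_minor, candidate
    and bonferroni flags, and a skip reason where applicable.
    """
    df = line_means
    if sex is not None:
        df = df[df["sex"] == sex]
    df = df.set_index("line_id")
    missing_lines = [l for l in genotypes.line_ids if l not in df.index]
    if missing_lines:
        raise ValueError(f"line means missing for genotyped lines: {missing_lines[:5]}")
    y_all = df.loc[genotypes.line_ids, trait].to_numpy(dtype=float)
    m = bonferroni_m if bonferroni_m is not None else genotypes.n_variants
    bonf = bonferroni_threshold(alpha, m) if m >= 1 else np.nan

    rows = []
    for j in range(genotypes.n_variants):
        g = genotypes.calls[:, j]
        ok = ~np.isnan(g) & ~np.isnan(y_all)
        g_ok, y_ok = g[ok], y_all[ok]
        n = len(g_ok)
        n_alt = int(np.sum(g_ok == 2.0))
        n_ref = n - n_alt
        maf = min(n_alt, n_ref) / n if n else np.nan
        minor_is_alt = n_alt <= n_ref
        rec = dict(genotypes.variants.iloc[j])
        rec.update(trait=trait, sex=sex, maf=maf,
                   n_minor=min(n_alt, n_ref), effect=np.nan, t=np.nan, p=np.nan,
                   candidate=False, bonferroni=False, skip_reason="")
        if min(n_alt, n_ref) < min_class_lines:
            rec["skip_reason"] = "genotype class below minimum line count"
            rows.append(rec)
            continue
        y1 = y_ok[g_ok == (2.0 if minor_is_alt else 0.0)]   # minor class
        y0 = y_ok[g_ok == (0.0 if minor_is_alt else 2.0)]
        effect = float(y1.mean() - y0.mean())
        ss = float(np.sum((y1 - y1.mean()) ** 2) + np.sum((y0 - y0.mean()) ** 2))
        dof = n - 2
        s2 = ss / dof if dof > 0 else np.nan
        se = np.sqrt(s2 * (1.0 / len(y1) + 1.0 / len(y0)))
        if se == 0:
            t = np.inf if effect != 0 else 0.0
            p = 0.0 if effect != 0 else 1.0
        else:
            t = effect / se
            p = 2.0 * stats.t.sf(abs(t), dof)
        rec.update(effect=effect, t=float(t), p=float(p),
                   candidate=bool(p < candidate_p), bonferroni=bool(p < bonf))
        rows.append(rec)
    return pd.DataFrame(rows)


def assign_genes(
    results: pd.DataFrame, annotation: pd.DataFrame, window_bp: int = 1000
) -> pd.DataFrame:
    """Map variants to genes within ``window_bp`` of the gene body.

    ``annotation`` uses 1-based inclusive coordinates (columns gene_id,
    symbol, chrom, start, end, strand).  A variant maps to every gene
    whose [start - window, end + window] interval contains its position;
    windows apply to the gene body regardless of strand.  Variants with
    no gene are labelled intergenic (empty gene_id).

    Returns the results table expanded to one row per variant x
    overlapping gene (intergenic variants keep a single row).
    """
    res_chroms = set(results["chrom"].unique())
    ann_chroms = set(annotation["chrom"].unique())
    unmatched = res_chroms - ann_chroms
    if unmatched and not (res_chroms & ann_chroms):
        raise ValueError(f"no shared chromosome names; unmatched: {sorted(unmatched)}")

    trees: dict[str, IntervalTree] = {}
    for chrom, grp in annotation.groupby("chrom", observed=True):
        t = IntervalTree()
        for row in grp.itertuples():
            # half-open interval over integer positions: [start-w, end+w] inclusive
            t.addi(row.start - window_bp, row.end + window_bp + 1, row.gene_id)
        trees[chrom] = t

    rows = []
    for rec in results.to_dict("records"):
        tree = trees.get(rec["chrom"])
        hits = sorted(iv.data for iv in tree[rec["pos"]]) if tree is not None else []
        if not hits:
            rows.append({**rec, "gene_id": "", "intergenic": True})
        else:
            for g in hits:
                rows.append({**rec, "gene_id": g, "intergenic": False})
    return pd.DataFrame(rows)


def candidate_genes(assigned: pd.DataFrame) -> list[str]:
    """Deduplicated gene ids carrying at least one candidate variant."""
    hits = assigned[(assigned["candidate"]) & (~assigned["intergenic"])]
    return sorted(hits["gene_id"].unique())
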