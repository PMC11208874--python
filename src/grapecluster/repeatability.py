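"""Trait repeatability and correlations from a replicated block design.

Repeatability is the fraction of phenotypic variance attributable to
genotype, sigma2_g / (sigma2_g + sigma2_e) — an upper bound on
broad-sense heritability.  Cluster-level trait values are first averaged
to one value per genotype x block (vine); additive block effects are
removed by centering each block at its mean; genotypic and residual
variances then come from a one-way method-of-moments ANOVA with the
standard unbalanced-design replicate coefficient.  Negative variance
estimates are truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "VarianceComponents",
    "aggregate_to_vine",
    "estimate_repeatability",
    "trait_correlations",
]


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_genotype: float
    sigma2_residual: float
    repeatability: float
    n_genotypes: int
    mean_replicates: float


def aggregate_to_vine(
    table: pd.DataFrame, trait: str, count_like: bool = False
) -> pd.DataFrame:
    """Average cluster replicates to one value per genotype x block.

    For count-like traits the per-cluster value is the maximum over the
    available view angles (the view showing the most berries); for shape
    traits it is the mean over angles.  Cluster values are then averaged
    within the vine.  Returns columns genotype, block, value.
    """
    if trait not in table.columns:
        raise KeyError(f"trait column {trait!r} not found")
    df = table.copy()
    group_cols = [c for c in ("genotype", "block", "vine", "cluster") if c in df]
    per_cluster = (
        df.groupby(group_cols, sort=True)[trait].max()
        if count_like
        else df.groupby(group_cols, sort=True)[trait].mean()
    )
    out = (
        per_cluster.groupby(level=["genotype", "block"]).mean().reset_index()
    )
    return out.rename(columns={trait: "value"})


def estimate_repeatability(
    values: pd.DataFrame, trait: str = "value"
) -> VarianceComponents:
    """Genotypic variance fraction from genotype x block values.

    ``values`` needs columns genotype, (optionally) block, and the trait.
    Block means are subtracted first, which removes any additive block
    effect exactly; the genotypic and residual variances come from
    one-way ANOVA mean squares with
    n0 = (N - sum n_i^2 / N) / (k - 1).
    """
    df = values.copy()
    if trait not in df.columns:
        raise KeyError(f"trait column {trait!r} not found")
    y = df[trait].astype(float)
    if "block" in df.columns:
        y = y - df.groupby("block")[trait].transform("mean")
    geno = df["genotype"]
    counts = geno.value_counts()
    k = len(counts)
    if k < 2:
        raise ValueError("need at least 2 genotypes")
    if (counts < 2).all():
        raise ValueError("all genotypes unreplicated: residual undefined")
    N = len(y)
    group_mean = y.groupby(geno).transform("mean")
    grand = y.mean()
    ss_between = float(((group_mean - grand) ** 2).sum())
    ss_within = float(((y - group_mean) ** 2).sum())
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - (counts**2).sum() / N) / (k - 1)
    sigma2_g = max(0.0, (ms_between - ms_within) / n0)
    sigma2_e = ms_within
    total = sigma2_g + sigma2_e
    rep = 0.0 if total == 0 else min(1.0, max(0.0, sigma2_g / total))
    return VarianceComponents(
        sigma2_genotype=sigma2_g,
        sigma2_residual=sigma2_e,
        repeatability=rep,
        n_genotypes=k,
        mean_replicates=float(counts.mean()),
    )


def trait_correlations(
    table: pd.DataFrame, traits: list[str], count_like: set[str] = frozenset()
) -> pd.DataFrame:
    """Pairwise Pearson correlations on vine-aggregated trait values.

    Constant traits give undefined correlations, recorded as NaN.
    """
    cols = {}
    for t in traits:
        agg = aggregate_to_vine(table, t, count_like=t in count_like)
        cols[t] = agg.set_index(["genotype", "block"])["value"]
    wide = pd.DataFrame(cols)
    if len(wide.dropna()) < 3:
        raise ValueError("need at least 3 complete vine-level rows")
    return wide.corr(method="pearson")
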