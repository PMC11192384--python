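"""Competitive gene-set testing by rank-sum permutation.

The question asked: is the differential-expression evidence for a set of
genes (say, an annotated cartilage-development list) collectively
stronger than for random groups of the same size drawn from the same
expressed-gene universe? The statistic is the Wilcoxon rank-sum W of the
set genes' DE p-values (midranks under ties; small W = set enriched for
small p). The null is Monte-Carlo: W recomputed for N uniformly drawn
size-m gene groups, with a plus-one-corrected empirical p-value. An
exhaustive enumerator over all C(n, m) subsets serves as the exact
oracle on small problems.

`RankSumPermutationTest` is the model-object surface; the underlying
functions (`ranksum_stat`, `permutation_null`, `empirical_pvalue`,
`exhaustive_null`) are importable on their own.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, rankdata

__all__ = [
    "GeneSet",
    "PermutationResult",
    "RankSumPermutationTest",
    "match_set",
    "ranksum_stat",
    "permutation_null",
    "empirical_pvalue",
    "exhaustive_null",
    "abs_lfc_shift",
]

EXHAUSTIVE_LIMIT = 200_000
ALTERNATIVES = ("two-sided", "less", "greater")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers.

    Members are stored deduplicated in first-seen order; ``provenance``
    records where the list came from (typically the source filename and
    which annotation variant was used).
    """

    name: str
    members: tuple
    provenance: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        seen, unique = set(), []
        for m in self.members:
            if m not in seen:
                seen.add(m)
                unique.append(m)
        if len(unique) != len(self.members):
            warnings.warn(
                f"gene set {self.name!r}: {len(self.members) - len(unique)} "
                "duplicate id(s) removed",
                stacklevel=3,
            )
            object.__setattr__(self, "members", tuple(unique))

    def __len__(self) -> int:
        return len(self.members)


def match_set(expressed_ids, gene_set: GeneSet):
    """Match a gene set against the expressed-gene universe.

    Exact, case-sensitive string matching. Returns ``(mask, n_matched)``
    where mask is boolean over ``expressed_ids``; raises if no member is
    expressed (the competitive test is then undefined).
    """
    expressed_ids = np.asarray(expressed_ids)
    if len(np.unique(expressed_ids)) != len(expressed_ids):
        raise ValueError("expressed ids contain duplicates")
    members = set(gene_set.members)
    mask = np.fromiter((g in members for g in expressed_ids), dtype=bool,
                       count=len(expressed_ids))
    n_matched = int(mask.sum())
    if n_matched == 0:
        raise ValueError(
            f"no member of gene set {gene_set.name!r} is in the expressed universe"
        )
    return mask, n_matched


def ranksum_stat(p_values, mask) -> float:
    """Rank-sum W of the masked genes' p-values (midranks under ties)."""
    p = np.asarray(p_values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if p.shape != mask.shape:
        raise ValueError("p_values and mask have different lengths")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    m = int(mask.sum())
    if m == 0 or m == p.size:
        raise ValueError("mask must select a strict, nonempty subset")
    return float(rankdata(p)[mask].sum())


def permutation_null(p_values, m: int, n_iter: int = 10_000, seed=None) -> np.ndarray:
    """Null rank-sum statistics from random size-m gene groups.

    Groups are drawn uniformly without replacement from the whole
    expressed universe (competitive null — the observed set's genes are
    not excluded). Midranks are computed once and reused.
    """
    p = np.asarray(p_values, dtype=float)
    n = p.size
    if not 0 < m < n:
        raise ValueError("need 0 < m < n")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ranks = rankdata(p)
    rng = np.random.default_rng(seed)
    out = np.empty(n_iter)
    for i in range(n_iter):
        out[i] = ranks[rng.choice(n, size=m, replace=False)].sum()
    return out


def empirical_pvalue(w_obs: float, null_stats, m: int, n: int,
                     alternative: str = "two-sided") -> float:
    """Plus-one-corrected Monte-Carlo p-value for an observed rank-sum.

    ``p = (1 + #{null at least as extreme}) / (N + 1)``; two-sided
    extremity is the absolute deviation from the exchangeable-null mean
    m(n+1)/2, so the smallest attainable value is 1/(N+1).
    """
    null_stats = np.asarray(null_stats, dtype=float)
    if null_stats.size == 0:
        raise ValueError("null_stats is empty")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    if alternative == "less":
        extreme = null_stats <= w_obs
    elif alternative == "greater":
        extreme = null_stats >= w_obs
    else:
        center = m * (n + 1) / 2.0
        extreme = np.abs(null_stats - center) >= abs(w_obs - center)
    return float((1 + extreme.sum()) / (null_stats.size + 1))


def exhaustive_null(p_values, m: int) -> np.ndarray:
    """Exact null: the rank-sum of every size-m subset (with multiplicity).

    Limited to C(n, m) <= 200,000 subsets; beyond that the Monte-Carlo
    path (`permutation_null`) is the supported route.
    """
    from itertools import combinations

    p = np.asarray(p_values, dtype=float)
    n = p.size
    if not 0 < m < n:
        raise ValueError("need 0 < m < n")
    n_subsets = math.comb(n, m)
    if n_subsets > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"C({n}, {m}) = {n_subsets} exceeds the exhaustive limit "
            f"{EXHAUSTIVE_LIMIT}; use permutation_null instead"
        )
    ranks = rankdata(p)
    out = np.empty(n_subsets)
    for i, combo in enumerate(combinations(range(n), m)):
        out[i] = ranks[list(combo)].sum()
    return out


def abs_lfc_shift(det: pd.DataFrame, mask) -> dict:
    """Absolute fold-change shift of set genes versus background.

    Returns the mean |lfc| in each stratum, their difference, the
    two-sample Kolmogorov-Smirnov distance, and the raw |lfc| samples
    for density plotting.
    """
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(det):
        raise ValueError("mask length does not match the DE table")
    abs_lfc = np.abs(det["lfc"].to_numpy(dtype=float))
    in_set = abs_lfc[mask]
    background = abs_lfc[~mask]
    in_set = in_set[np.isfinite(in_set)]
    background = background[np.isfinite(background)]
    if in_set.size == 0 or background.size == 0:
        raise ValueError("both strata must be nonempty")
    ks = ks_2samp(in_set, background)
    return {
        "mean_abs_lfc_set": float(in_set.mean()),
        "mean_abs_lfc_background": float(background.mean()),
        "mean_difference": float(in_set.mean() - background.mean()),
        "ks_distance": float(ks.statistic),
        "set_values": in_set,
        "background_values": background,
    }


@dataclass
class PermutationResult:
    """Outcome of one competitive rank-sum permutation test."""

    set_name: str
    w_obs: float
    null_stats: np.ndarray
    n_iter: int
    m: int
    n: int
    p_value: float
    alternative: str
    seed: int | None

    @property
    def null_mean(self) -> float:
        return float(self.null_stats.mean())

    @property
    def expected_mean(self) -> float:
        """Exchangeable-null expectation m(n+1)/2 of the rank-sum."""
        return self.m * (self.n + 1) / 2.0

    def summary(self) -> str:
        direction = "enriched" if self.w_obs < self.expected_mean else "depleted"
        lines = [
            "Competitive rank-sum permutation test",
            "=" * 54,
            f"gene set:          {self.set_name}",
            f"matched set size:  {self.m} (universe {self.n} expressed genes)",
            f"observed W:        {self.w_obs:.1f}",
            f"null mean W:       {self.null_mean:.1f} (expected {self.expected_mean:.1f})",
            f"iterations:        {self.n_iter}",
            f"empirical p:       {self.p_value:.4g} ({self.alternative})",
            f"direction:         {direction} for small p-values",
            "=" * 54,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "set_name": self.set_name,
            "w_obs": self.w_obs,
            "n_iter": self.n_iter,
            "m": self.m,
            "n": self.n,
            "p_value": self.p_value,
            "alternative": self.alternative,
            "seed": self.seed,
            "null_mean": self.null_mean,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def write_null_stats(self, path) -> None:
        pd.DataFrame({"null_W": self.null_stats}).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )


class RankSumPermutationTest:
    """Competitive gene-set test on per-gene DE p-values.

    Parameters
    ----------
    p_values : array-like
        Raw DE p-values of all expressed genes (finite, in [0, 1]).
    gene_ids : array-like
        Matching gene identifiers (unique).
    gene_set : GeneSet
        The candidate set; matched against ``gene_ids`` exactly. The
        null uses the matched size, not the list's nominal size.
    alternative : str
        'two-sided' (default; deviation from the null mean in either
        direction), 'less' (enrichment for small p) or 'greater'.
    """

    def __init__(self, p_values, gene_ids, gene_set: GeneSet,
                 alternative: str = "two-sided"):
        self.p_values = np.asarray(p_values, dtype=float)
        self.gene_ids = np.asarray(gene_ids)
        if self.p_values.size != self.gene_ids.size:
            raise ValueError("p_values and gene_ids have different lengths")
        if alternative not in ALTERNATIVES:
            raise ValueError(f"alternative must be one of {ALTERNATIVES}")
        self.gene_set = gene_set
        self.alternative = alternative
        self.mask, self.n_matched = match_set(self.gene_ids, gene_set)

    def fit(self, n_iter: int = 10_000, seed: int | None = None) -> PermutationResult:
        w_obs = ranksum_stat(self.p_values, self.mask)
        null = permutation_null(self.p_values, self.n_matched,
                                n_iter=n_iter, seed=seed)
        p = empirical_pvalue(w_obs, null, self.n_matched, self.p_values.size,
                             alternative=self.alternative)
        return PermutationResult(
            set_name=self.gene_set.name,
            w_obs=w_obs,
            null_stats=null,
            n_iter=n_iter,
            m=self.n_matched,
            n=int(self.p_values.size),
            p_value=p,
            alternative=self.alternative,
            seed=seed,
        )
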