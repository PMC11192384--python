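"""Cross-disorder and cross-dataset comparison analytics.

Given per-gene DE tables from two contrasts (e.g. the two knockout arms
at Day 14, or a new experiment against a prior reference dataset), these
routines quantify how much of the DE program is shared: conditional
p-value histograms (one contrast's raw p-values stratified by the other
contrast's significance calls), sign-concordance summaries among genes
significant in both, fold-change pairing for FC-FC scatter plots, the
catalogue of standard contrasts for the two-arm two-timepoint design,
and a PCA overview of the samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .de import ContrastSpec, size_factors

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordanceSummary",
    "PCAResult",
    "pair_results",
    "conditional_p_hist",
    "sign_concordance",
    "assemble_contrasts",
    "pca_overview",
    "cross_dataset_validation",
    "fcfc_scatter_table",
]


def _round_half_up_1dp(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def pair_results(det_a: pd.DataFrame, det_b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two DE tables on gene id into a paired table.

    Columns are suffixed ``_a`` / ``_b``; genes missing from either
    table are dropped (counts logged). Duplicate gene ids are an error.
    """
    for label, det in (("A", det_a), ("B", det_b)):
        if det["gene_id"].duplicated().any():
            raise ValueError(f"duplicate gene ids in table {label}")
    cols = ["gene_id", "lfc", "p", "padj", "significant"]
    a = det_a[cols].rename(columns={c: f"{c}_a" for c in cols if c != "gene_id"})
    b = det_b[cols].rename(columns={c: f"{c}_b" for c in cols if c != "gene_id"})
    paired = a.merge(b, on="gene_id", how="inner")
    paired = paired.rename(
        columns={"significant_a": "sig_a", "significant_b": "sig_b"}
    )
    if paired.empty:
        raise ValueError("the two DE tables share no gene ids")
    logger.info(
        "pair_results: %d shared genes (%d dropped from A, %d from B)",
        len(paired), len(det_a) - len(paired), len(det_b) - len(paired),
    )
    return paired


def conditional_p_hist(paired: pd.DataFrame, stratify_by: str = "b",
                       bins: int = 20) -> dict:
    """Conditional p-value histograms.

    Stratifies genes by significance in one contrast and histograms the
    *other* contrast's raw p-values within each stratum, on uniform
    [0, 1] bin edges, normalised to unit area. A flat pair of histograms
    indicates independent DE programs; a near-zero spike in the
    significant stratum indicates a shared program.
    """
    stratify_by = stratify_by.lower()
    if stratify_by not in ("a", "b"):
        raise ValueError("stratify_by must be 'a' or 'b'")
    other = "a" if stratify_by == "b" else "b"
    strat_flags = paired[f"sig_{stratify_by}"].to_numpy(dtype=bool)
    p_other = paired[f"p_{other}"].to_numpy(dtype=float)

    edges = np.linspace(0.0, 1.0, bins + 1)
    out = {"bin_edges": edges, "stratified_by": stratify_by, "p_from": other}
    for name, sel in (("significant", strat_flags), ("nonsignificant", ~strat_flags)):
        vals = p_other[sel & np.isfinite(p_other)]
        if vals.size == 0:
            raise ValueError(f"the {name} stratum is empty")
        density, _ = np.histogram(vals, bins=edges, density=True)
        out[f"density_{name}"] = density
        out[f"n_{name}"] = int(vals.size)
    return out


@dataclass(frozen=True)
class ConcordanceSummary:
    """Sign agreement of fold-changes among genes significant in both contrasts."""

    n_both_sig: int
    up_up: int
    down_down: int
    discordant: int
    pct_concordant: float  # half-up, 1 decimal; NaN when n_both_sig == 0

    def __post_init__(self):
        if self.up_up + self.down_down + self.discordant != self.n_both_sig:
            raise ValueError("concordance counts do not sum to n_both_sig")

    def to_dict(self) -> dict:
        return {
            "n_both_sig": self.n_both_sig,
            "up_up": self.up_up,
            "down_down": self.down_down,
            "discordant": self.discordant,
            "pct_concordant": self.pct_concordant,
        }


def sign_concordance(paired: pd.DataFrame) -> ConcordanceSummary:
    """Classify both-significant genes by fold-change sign pair.

    A zero fold-change in a both-significant row (possible only in
    synthetic data) is counted discordant with a warning.
    """
    both = paired[paired["sig_a"] & paired["sig_b"]]
    n = len(both)
    if n == 0:
        return ConcordanceSummary(0, 0, 0, 0, float("nan"))
    la = both["lfc_a"].to_numpy(dtype=float)
    lb = both["lfc_b"].to_numpy(dtype=float)
    zero = (la == 0) | (lb == 0)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} both-significant gene(s) with lfc exactly 0 "
            "counted discordant",
            stacklevel=2,
        )
    up_up = int(((la > 0) & (lb > 0)).sum())
    down_down = int(((la < 0) & (lb < 0)).sum())
    discordant = n - up_up - down_down
    pct = _round_half_up_1dp(100.0 * (up_up + down_down) / n)
    return ConcordanceSummary(n, up_up, down_down, discordant, pct)


def assemble_contrasts(samples: pd.DataFrame) -> list[ContrastSpec]:
    """The standard contrast battery for the two-arm, two-timepoint design.

    Per arm and timepoint, knockout versus that arm's matched wild-type
    (four specs), plus the Day 14 versus Day 7 differentiation
    trajectory within each arm's knockouts (two specs). Specs whose
    levels have fewer than two samples are dropped with a warning.
    """
    specs: list[ContrastSpec] = []
    candidates: list[ContrastSpec] = []
    for arm in sorted(samples["arm"].unique()):
        for tp in ("D7", "D14"):
            candidates.append(ContrastSpec(
                factor="genotype", numerator="KO", denominator="WT",
                where={"arm": arm, "timepoint": tp},
            ))
        candidates.append(ContrastSpec(
            factor="timepoint", numerator="D14", denominator="D7",
            where={"arm": arm, "genotype": "KO"},
        ))
    for spec in candidates:
        sub = spec.select(samples)
        sizes = {lvl: int((sub[spec.factor] == lvl).sum())
                 for lvl in (spec.numerator, spec.denominator)}
        if all(v >= 2 for v in sizes.values()):
            specs.append(spec)
        else:
            warnings.warn(
                f"contrast {spec.name} dropped: group sizes {sizes}", stacklevel=2
            )
    return specs


@dataclass
class PCAResult:
    """Sample coordinates and variance fractions from a PCA overview."""

    coordinates: pd.DataFrame  # samples x components ("PC1", ...)
    variance_fractions: np.ndarray
    n_top: int
    degenerate: bool = False

    def summary(self) -> str:
        lines = ["PCA overview", "=" * 40,
                 f"samples: {len(self.coordinates)}; top genes: {self.n_top}"]
        if self.degenerate:
            lines.append("degenerate: no between-sample variance")
        else:
            for i, f in enumerate(self.variance_fractions[:5], start=1):
                lines.append(f"PC{i}: {100 * f:.1f}% of variance")
        lines.append("=" * 40)
        return "\n".join(lines)


def pca_overview(counts: pd.DataFrame, n_top: int = 500,
                 size_factors_: pd.Series | None = None) -> PCAResult:
    """PCA of samples on log2(normalised count + 1) values.

    Restricted to the ``n_top`` most variable genes (clamped to the gene
    count with a warning), gene-centered, decomposed by SVD. Variance
    fractions are singular values squared over their total.
    """
    if counts.shape[1] < 3:
        raise ValueError("PCA overview needs at least 3 samples")
    if size_factors_ is None:
        size_factors_ = size_factors(counts)
    x = np.log2(counts.to_numpy(dtype=float)
                / size_factors_.loc[counts.columns].to_numpy()[None, :] + 1.0)
    if n_top > x.shape[0]:
        warnings.warn(
            f"n_top={n_top} exceeds the {x.shape[0]} available genes; clamped",
            stacklevel=2,
        )
        n_top = x.shape[0]
    gene_var = x.var(axis=1)
    top = np.argsort(gene_var)[::-1][:n_top]
    xt = x[top]
    centered = (xt - xt.mean(axis=1, keepdims=True)).T  # samples x genes
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    total = (s**2).sum()
    if total <= 0:
        k = min(centered.shape)
        coords = pd.DataFrame(
            np.zeros((counts.shape[1], k)), index=counts.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        return PCAResult(coords, np.full(k, np.nan), n_top, degenerate=True)
    fractions = s**2 / total
    coords = pd.DataFrame(
        u * s, index=counts.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return PCAResult(coords, fractions, n_top)


def cross_dataset_validation(det_new: pd.DataFrame, det_ref: pd.DataFrame,
                             bins: int = 20) -> dict:
    """Validate a new DE table against a reference dataset's table.

    Pairs the tables, histograms the new contrast's raw p-values
    stratified by significance in the reference, and summarises the
    fold-change sign concordance among genes significant in both.
    """
    paired = pair_results(det_new, det_ref)
    hist = conditional_p_hist(paired, stratify_by="b", bins=bins)
    concordance = sign_concordance(paired)
    return {"paired": paired, "histograms": hist, "concordance": concordance}


def fcfc_scatter_table(paired: pd.DataFrame, set_members=None) -> pd.DataFrame:
    """Figure-ready FC-FC scatter data with a category column.

    Categories: 'both' (significant in both contrasts), 'one'
    (significant in exactly one), 'ns' otherwise; membership in the
    supplied gene set overrides to 'set-member'.
    """
    members = set(set_members) if set_members is not None else set()
    sig_a = paired["sig_a"].to_numpy(dtype=bool)
    sig_b = paired["sig_b"].to_numpy(dtype=bool)
    category = np.where(sig_a & sig_b, "both",
                        np.where(sig_a | sig_b, "one", "ns")).astype(object)
    if members:
        in_set = paired["gene_id"].isin(members).to_numpy()
        category[in_set] = "set-member"
    return pd.DataFrame(
        {
            "gene_id": paired["gene_id"],
            "lfc_a": paired["lfc_a"],
            "lfc_b": paired["lfc_b"],
            "category": category,
        }
    )
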