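"""Negative-binomial Wald differential expression for count matrices.

The engine follows the conventional bulk RNA-seq recipe: drop non- and
low-expressed genes by a median-count rule, normalise libraries with
median-of-ratios size factors, model each gene's counts as negative
binomial with a log link and the size factors as fixed offsets, and test
the group coefficient with a Wald z statistic, correcting across genes by
Benjamini-Hochberg. Gene-wise dispersions are estimated by pooled
method-of-moments on normalised counts — deliberately simpler than the
empirical-Bayes shrinkage of dedicated DE packages, so results are
comparable in structure rather than value.

The model surface is `NegativeBinomialDE(counts, samples, contrast)` whose
`fit()` returns a :class:`DEResults`; `fit_nb_contrast` is the one-call
functional equivalent returning the plain table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastSpec",
    "DEResults",
    "NegativeBinomialDE",
    "filter_low_expressed",
    "size_factors",
    "fit_nb_contrast",
    "bh_adjust",
    "significance_threshold",
]

DE_COLUMNS = ["gene_id", "base_mean", "lfc", "se", "wald", "p", "padj", "significant"]

DISPERSION_FLOOR = 1e-8
_MEAN_FLOOR = 1e-8


@dataclass(frozen=True)
class ContrastSpec:
    """One two-group comparison within a slice of the sample table.

    ``where`` restricts samples by factor=level conjunctions (e.g.
    ``{"arm": "KS2", "timepoint": "D14"}``); ``factor`` is the tested
    column with ``numerator`` compared against ``denominator`` (positive
    lfc = higher in numerator). ``covariates`` are optional known
    factors adjusted for in a per-gene GLM.
    """

    factor: str
    numerator: str
    denominator: str
    where: dict = field(default_factory=dict)
    covariates: tuple = ()

    def __post_init__(self):
        if self.numerator == self.denominator:
            raise ValueError("numerator and denominator levels must differ")

    @property
    def name(self) -> str:
        scope = "_".join(f"{v}" for v in self.where.values())
        base = f"{self.factor}_{self.numerator}_vs_{self.denominator}"
        return f"{scope}_{base}" if scope else base

    def select(self, samples: pd.DataFrame) -> pd.DataFrame:
        sub = samples
        for col, level in self.where.items():
            sub = sub[sub[col] == level]
        sub = sub[sub[self.factor].isin([self.numerator, self.denominator])]
        return sub


def filter_low_expressed(counts: pd.DataFrame, min_median: int = 10) -> pd.DataFrame:
    """Keep genes whose median count across samples is >= min_median.

    The rule drops strictly-below-threshold genes, so a gene sitting
    exactly at the median threshold survives.
    """
    medians = counts.median(axis=1)
    kept = counts.loc[medians >= min_median]
    if kept.empty:
        warnings.warn("filter_low_expressed removed every gene", stacklevel=2)
    logger.info("filter_low_expressed: kept %d / %d genes", len(kept), len(counts))
    return kept


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors, rescaled to geometric mean 1.

    Reference genes are those with positive counts in every sample; if
    none exist, genes positive in >= 90% of samples are used with the
    geometric mean and median taken over their positive entries.
    """
    x = counts.to_numpy(dtype=float)
    positive_all = (x > 0).all(axis=1)
    if positive_all.any():
        ref = x[positive_all]
        log_geomean = np.log(ref).mean(axis=1)
        log_ratios = np.log(ref) - log_geomean[:, None]
        log_sf = np.median(log_ratios, axis=0)
    else:
        frac_pos = (x > 0).mean(axis=1)
        ref = x[frac_pos >= 0.9]
        if ref.size == 0:
            raise ValueError(
                "no gene is positive in >= 90% of samples; cannot estimate size factors"
            )
        with np.errstate(divide="ignore"):
            logs = np.where(ref > 0, np.log(ref), np.nan)
        log_geomean = np.nanmean(logs, axis=1)
        log_ratios = logs - log_geomean[:, None]
        log_sf = np.nanmedian(log_ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, NaN-aware.

    Missing entries are ignored (excluded from the BH denominator) and
    returned missing; order of the input is preserved.
    """
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    padj = np.full_like(p, np.nan)
    if ok.sum():
        padj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return padj


def significance_threshold(det: pd.DataFrame, alpha: float = 0.1):
    """Flags at padj < alpha and the raw-p threshold they imply.

    Returns ``(flags, p_star)`` where p_star is the largest raw p-value
    among significant genes (the volcano-plot cut line); NaN when no
    gene is significant.
    """
    flags = det["padj"] < alpha
    p_star = det.loc[flags, "p"].max() if flags.any() else float("nan")
    return flags, float(p_star) if flags.any() else float("nan")


def _mom_dispersion(q: np.ndarray, group_idx: list[np.ndarray], inv_sf: np.ndarray):
    """Pooled method-of-moments NB dispersion per gene.

    ``q`` is the genes x samples normalised-count matrix. For each group
    the within-group sample variance in excess of the Poisson term
    mu * mean(1/sf) estimates alpha * mu^2; estimates are pooled across
    groups with n_g - 1 weights and floored.
    """
    num = np.zeros(q.shape[0])
    den = np.zeros(q.shape[0])
    for idx in group_idx:
        ng = len(idx)
        if ng < 2:
            continue
        sub = q[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        pois = m * inv_sf[idx].mean()
        num += (ng - 1) * (v - pois)
        # E[m^2] = mu^2 + Var(m); subtract the v/ng moment correction so the
        # denominator estimates mu^2 without downward-biasing alpha
        den += (ng - 1) * np.maximum(m**2 - v / ng, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.maximum(alpha, DISPERSION_FLOOR)


def _fit_group_log_mean(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray):
    """NB MLE of each gene's group mean (log scale) with fixed offsets.

    Solves the one-dimensional score equation
    sum_j (y_ij - mu_ij) / (1 + alpha_i * mu_ij) = 0 with
    mu_ij = sf_j * exp(eta_i) by Newton steps, vectorised over genes.
    Returns (eta, fisher_info). Genes with zero total count get the
    floored mean.
    """
    total = y.sum(axis=1)
    eta = np.log(np.maximum(total / sf.sum(), _MEAN_FLOOR))
    for _ in range(50):
        mu = sf[None, :] * np.exp(eta)[:, None]
        w = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.maximum(eta, np.log(_MEAN_FLOOR))
    mu = sf[None, :] * np.exp(eta)[:, None]
    w = 1.0 + alpha[:, None] * mu
    info = (mu / w).sum(axis=1)
    return eta, info


@dataclass
class DEResults:
    """Differential-expression results for one contrast.

    ``table`` carries one row per tested gene in the spec'd column
    order; helper accessors expose the pieces downstream analytics use.
    """

    table: pd.DataFrame
    contrast: ContrastSpec
    alpha: float
    n_samples: int

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def p_star(self) -> float:
        return significance_threshold(self.table, self.alpha)[1]

    def summary(self) -> str:
        t = self.table
        sig = t[t["significant"]]
        up = int((sig["lfc"] > 0).sum())
        down = int((sig["lfc"] < 0).sum())
        lines = [
            "Negative-binomial Wald differential expression",
            "=" * 54,
            f"contrast:        {self.contrast.name}",
            f"samples tested:  {self.n_samples}",
            f"genes tested:    {t['p'].notna().sum()} (of {len(t)})",
            f"FDR level:       {self.alpha}",
            f"significant:     {self.n_significant} ({up} up, {down} down)",
            f"raw-p threshold: {self.p_star:.4g}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


class NegativeBinomialDE:
    """Per-gene NB Wald model for a two-group contrast.

    Parameters
    ----------
    counts : DataFrame
        Filtered gene x sample count matrix (genes indexed by id).
    samples : DataFrame
        Sample sheet with a ``sample_id`` column plus the contrast's
        factors.
    contrast : ContrastSpec
        Which samples to use and which factor levels to compare.
    size_factors_ : Series, optional
        Precomputed library-size factors; estimated on the contrast's
        samples when omitted.
    """

    def __init__(self, counts, samples, contrast, size_factors_=None):
        if counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if (np.asarray(counts) < 0).any():
            raise ValueError("negative counts")
        sub = contrast.select(samples)
        for level in (contrast.numerator, contrast.denominator):
            n_level = int((sub[contrast.factor] == level).sum())
            if n_level < 2:
                raise ValueError(
                    f"level {level!r} of {contrast.factor!r} has {n_level} sample(s); "
                    "need >= 2"
                )
        self.contrast = contrast
        self.samples = sub.reset_index(drop=True)
        self.counts = counts[self.samples["sample_id"].tolist()]
        if size_factors_ is None:
            size_factors_ = size_factors(self.counts)
        self.size_factors_ = size_factors_.loc[self.counts.columns]

    def fit(self, alpha: float = 0.1) -> DEResults:
        c = self.contrast
        y = self.counts.to_numpy(dtype=float)
        sf = self.size_factors_.to_numpy()
        labels = self.samples[c.factor].to_numpy()
        idx_num = np.where(labels == c.numerator)[0]
        idx_den = np.where(labels == c.denominator)[0]

        q = y / sf[None, :]
        disp = _mom_dispersion(q, [idx_num, idx_den], 1.0 / sf)

        if c.covariates:
            lfc_ln, se_ln = self._fit_glm_covariates(y, sf, disp)
        else:
            eta_n, info_n = _fit_group_log_mean(y[:, idx_num], sf[idx_num], disp)
            eta_d, info_d = _fit_group_log_mean(y[:, idx_den], sf[idx_den], disp)
            lfc_ln = eta_n - eta_d
            se_ln = np.sqrt(1.0 / np.maximum(info_n, 1e-300)
                            + 1.0 / np.maximum(info_d, 1e-300))

        ln2 = np.log(2.0)
        lfc = lfc_ln / ln2
        se = se_ln / ln2
        with np.errstate(divide="ignore", invalid="ignore"):
            wald = np.where(se > 0, lfc / se, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(wald))

        all_zero = (y[:, idx_num].sum(axis=1) == 0) & (y[:, idx_den].sum(axis=1) == 0)
        p[all_zero] = np.nan
        lfc[all_zero] = np.nan
        padj = bh_adjust(p)
        significant = padj < alpha

        table = pd.DataFrame(
            {
                "gene_id": self.counts.index.to_numpy(),
                "base_mean": q.mean(axis=1),
                "lfc": lfc,
                "se": se,
                "wald": wald,
                "p": p,
                "padj": padj,
                "significant": significant,
            }
        )
        return DEResults(table=table, contrast=c, alpha=alpha,
                         n_samples=len(self.samples))

    def _fit_glm_covariates(self, y, sf, disp):
        """Per-gene NB GLM with known covariate factors (statsmodels)."""
        import statsmodels.api as sm

        c = self.contrast
        design = pd.DataFrame(
            {"__test": (self.samples[c.factor] == c.numerator).astype(float)}
        )
        for cov in c.covariates:
            dummies = pd.get_dummies(
                self.samples[cov], prefix=cov, drop_first=True, dtype=float
            )
            design = pd.concat([design, dummies], axis=1)
        X = sm.add_constant(design.to_numpy())
        offset = np.log(sf)
        lfc = np.empty(y.shape[0])
        se = np.empty(y.shape[0])
        for i in range(y.shape[0]):
            fam = sm.families.NegativeBinomial(alpha=max(disp[i], DISPERSION_FLOOR))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.GLM(y[i], X, family=fam, offset=offset).fit()
                lfc[i], se[i] = res.params[1], res.bse[1]
            except Exception:  # non-convergent gene: report as uninformative
                lfc[i], se[i] = 0.0, np.inf
        return lfc, se


def fit_nb_contrast(counts, samples, contrast, alpha: float = 0.1,
                    size_factors_=None) -> pd.DataFrame:
    """Functional one-call DE: returns the per-gene result table."""
    model = NegativeBinomialDE(counts, samples, contrast, size_factors_=size_factors_)
    return model.fit(alpha=alpha).table
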