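"""Synthetic bulk RNA-seq count generator for a two-disorder knockout design.

Emulates the study design the downstream analytics expect: two CRISPR
knockout arms (a KMT2D-null "KS1" arm and a KDM6A-null "KS2" arm), each
with its own matched wild-type clones, sampled at two timepoints of
chondrogenic differentiation (Day 7 and Day 14), with negative-binomial
gene counts. The differential-expression program is partially shared
between the two arms — jointly perturbed genes receive correlated log2
fold-changes — and a designated gene set (the stand-in for a cartilage
development annotation list) can carry inflated effect sizes.

The generator returns both the observable data (a gene x sample count
matrix plus a sample sheet) and the ground truth needed for recovery
tests (per-gene baseline mean, NB dispersion, true fold-changes and DE
flags per contrast, set membership).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "draw_de_program",
    "simulate_counts",
    "simulate_dataset",
    "write_dataset",
]

ARMS = ("KS1", "KS2")
GENOTYPES = ("WT", "KO")
TIMEPOINTS = ("D7", "D14")

#: truth-table columns carrying per-contrast true log2 fold-changes
LFC_COLUMNS = ("lfc_ks1_d7", "lfc_ks1_d14", "lfc_ks2_d7", "lfc_ks2_d14")
DE_COLUMNS = ("de_ks1_d7", "de_ks1_d14", "de_ks2_d7", "de_ks2_d14")


@dataclass(frozen=True)
class GeneratorConfig:
    """Free parameters of the synthetic dataset.

    Baseline gene means and NB dispersions are log-normal across genes
    (``baseline_mean_log_*`` and ``dispersion_log_*`` are natural-log
    location/scale). ``de_fraction`` is the per-arm probability a gene is
    differentially expressed; ``shared_de_overlap`` is the probability
    that a gene DE in one arm is also DE in the other; jointly DE genes
    draw their two arms' log2 fold-changes from a bivariate normal with
    standard deviation ``lfc_sd`` and correlation ``lfc_correlation``.
    ``set_enrichment_multiplier`` scales both |LFC| and DE probability
    for the ``set_size`` designated genes. The differentiation
    trajectory is an additive per-gene LFC applied to every Day-14
    sample, with standard deviation ``timepoint_shift_sd``; Day 7 is the
    reference state. Library-size multipliers are uniform on
    ``size_factor_range``.
    """

    n_genes: int = 2000
    replicates_per_group: int = 5
    baseline_mean_log_mu: float = 3.0
    baseline_mean_log_sd: float = 1.5
    dispersion_log_mu: float = -3.0
    dispersion_log_sd: float = 0.5
    de_fraction: float = 0.2
    shared_de_overlap: float = 0.8
    lfc_sd: float = 1.0
    lfc_correlation: float = 0.9
    set_size: int = 164
    set_enrichment_multiplier: float = 1.0
    timepoint_shift_sd: float = 0.5
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.replicates_per_group < 1:
            raise ValueError("n_genes and replicates_per_group must be positive")
        for name in ("de_fraction", "shared_de_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not -1.0 <= self.lfc_correlation <= 1.0:
            raise ValueError("lfc_correlation must lie in [-1, 1]")
        if not 0 < self.set_size <= self.n_genes:
            raise ValueError("set_size must lie in (0, n_genes]")
        if self.set_enrichment_multiplier < 0:
            raise ValueError("set_enrichment_multiplier must be >= 0")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must be a positive interval")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["size_factor_range"] = list(self.size_factor_range)
        return d

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one of the generator's random stages."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


def _gene_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"G{str(i).zfill(width)}" for i in range(1, n + 1)])


def draw_de_program(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the ground-truth DE program (TruthTable) for both arms.

    Arm-1 DE flags are Bernoulli(p) with p = de_fraction (scaled for set
    genes). Conditional on arm-1 status, arm-2 flags are drawn so that
    P(DE2 | DE1) = shared_de_overlap while preserving the arm-2 marginal
    where feasible. Jointly DE genes receive a correlated bivariate-normal
    LFC pair; genes DE in a single arm draw an independent N(0, lfc_sd)
    LFC. The knockout effect of an arm is the same at Day 7 and Day 14;
    the Day-14 trajectory shift is a separate per-gene effect shared by
    all genotypes.
    """
    rng = config.rng(0)
    n = config.n_genes

    baseline = rng.lognormal(
        config.baseline_mean_log_mu, config.baseline_mean_log_sd, size=n
    )
    dispersion = rng.lognormal(
        config.dispersion_log_mu, config.dispersion_log_sd, size=n
    )

    in_set = np.zeros(n, dtype=bool)
    in_set[rng.choice(n, size=config.set_size, replace=False)] = True

    mult = config.set_enrichment_multiplier
    p_de = np.full(n, config.de_fraction)
    p_de[in_set] = np.minimum(1.0, config.de_fraction * mult)

    de1 = rng.random(n) < p_de
    # arm-2 flags: keep the marginal at p_de while hitting the overlap where
    # the two are compatible (p_cond clipped otherwise)
    overlap = config.shared_de_overlap
    with np.errstate(divide="ignore", invalid="ignore"):
        p_not = np.where(p_de < 1.0, p_de * (1.0 - overlap) / (1.0 - p_de), 0.0)
    p_not = np.clip(p_not, 0.0, 1.0)
    u = rng.random(n)
    de2 = np.where(de1, u < overlap, u < p_not)

    sd = config.lfc_sd
    rho = config.lfc_correlation
    # explicit correlated construction stays exact at rho = +/-1
    z1 = rng.normal(0.0, 1.0, size=n)
    z2 = rng.normal(0.0, 1.0, size=n)
    pair1 = sd * z1
    pair2 = sd * (rho * z1 + np.sqrt(max(1.0 - rho * rho, 0.0)) * z2)
    solo = rng.normal(0.0, sd, size=(n, 2))

    lfc1 = np.where(de1 & de2, pair1, np.where(de1, solo[:, 0], 0.0))
    lfc2 = np.where(de1 & de2, pair2, np.where(de2, solo[:, 1], 0.0))
    lfc1 = np.where(in_set, lfc1 * mult, lfc1)
    lfc2 = np.where(in_set, lfc2 * mult, lfc2)

    tp_shift = rng.normal(0.0, config.timepoint_shift_sd, size=n)

    truth = pd.DataFrame(
        {
            "gene_id": _gene_ids(n),
            "baseline_mean": baseline,
            "dispersion": dispersion,
            "lfc_ks1_d7": lfc1,
            "lfc_ks1_d14": lfc1,
            "lfc_ks2_d7": lfc2,
            "lfc_ks2_d14": lfc2,
            "de_ks1_d7": de1,
            "de_ks1_d14": de1,
            "de_ks2_d7": de2,
            "de_ks2_d14": de2,
            "timepoint_lfc": tp_shift,
            "in_set": in_set,
        }
    )
    return truth


def _sample_sheet(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for arm in ARMS:
        for genotype in GENOTYPES:
            for tp in TIMEPOINTS:
                for clone in range(1, config.replicates_per_group + 1):
                    rows.append(
                        {
                            "sample_id": f"{arm}_{genotype}_{tp}_c{clone}",
                            "arm": arm,
                            "genotype": genotype,
                            "timepoint": tp,
                            "clone": f"{arm}_{genotype}_{clone}",
                        }
                    )
    return pd.DataFrame(rows)


def simulate_counts(
    truth: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit NB counts for the full two-arm, two-timepoint design.

    The expected count of gene i in sample j is
    ``size_factor_j * baseline_i * 2**(ko_lfc_i [if KO]) *
    2**(timepoint_lfc_i [if Day 14])`` and counts are drawn NB with
    variance ``mu + dispersion * mu**2``. Clones are exchangeable
    replicates. Returns ``(counts, samples)`` with counts indexed by
    gene_id, one column per sample.
    """
    if len(truth) != config.n_genes:
        raise ValueError(
            f"truth table has {len(truth)} rows but config.n_genes = {config.n_genes}"
        )
    rng = config.rng(1)
    samples = _sample_sheet(config)
    n_samples = len(samples)

    size_factors = rng.uniform(*config.size_factor_range, size=n_samples)
    samples = samples.assign(true_size_factor=size_factors)

    baseline = truth["baseline_mean"].to_numpy()
    alpha = truth["dispersion"].to_numpy()
    tp_shift = truth["timepoint_lfc"].to_numpy()

    counts = np.empty((config.n_genes, n_samples), dtype=np.int64)
    for j, row in samples.iterrows():
        log2_effect = np.zeros(config.n_genes)
        if row["genotype"] == "KO":
            arm_col = "lfc_ks1_d7" if row["arm"] == "KS1" else "lfc_ks2_d7"
            day_col = arm_col.replace("d7", "d14")
            col = arm_col if row["timepoint"] == "D7" else day_col
            log2_effect += truth[col].to_numpy()
        if row["timepoint"] == "D14":
            log2_effect += tp_shift
        mu = size_factors[j] * baseline * np.exp2(log2_effect)
        # NB via shape n = 1/alpha, success prob n/(n+mu)
        n_shape = 1.0 / np.maximum(alpha, 1e-12)
        p = n_shape / (n_shape + mu)
        counts[:, j] = rng.negative_binomial(n_shape, p)

    count_df = pd.DataFrame(
        counts, index=pd.Index(truth["gene_id"], name="gene_id"),
        columns=samples["sample_id"],
    )
    count_df.columns.name = None
    return count_df, samples


def simulate_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: (counts, samples, truth) for one config."""
    truth = draw_de_program(config)
    counts, samples = simulate_counts(truth, config)
    return counts, samples, truth


def write_dataset(outdir, config: GeneratorConfig) -> dict:
    """Write counts/samples/truth TSVs plus the echoed config YAML.

    Returns a dict of the written paths.
    """
    import pathlib

    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, samples, truth = simulate_dataset(config)

    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "generator_config.yaml",
    }
    counts.to_csv(paths["counts"], sep="\t")
    samples.to_csv(paths["samples"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return {k: str(v) for k, v in paths.items()}
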