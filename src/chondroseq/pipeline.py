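"""End-to-end orchestration: filter -> contrasts -> gene-set tests -> concordance.

`run_pipeline` reproduces the standard analysis order on a dataset (real
or simulated): low-expression filtering, the contrast battery for the
two-arm two-timepoint design, competitive gene-set permutation tests on
each knockout contrast's p-values, cross-arm concordance at each
timepoint plus the differentiation-trajectory comparison, and a PCA
overview. All outputs are TSV/JSON under the configured output
directory, together with a manifest (config echo, package version, seed,
input checksums) sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import pandas as pd

from . import __version__, compare, de, io, simulate
from .geneset import RankSumPermutationTest

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and constants for one pipeline run.

    Defaults carry the conventional analysis constants: FDR level 0.1,
    median-count filter threshold 10, 10,000 permutation iterations.
    Either the input paths or a generator sub-config must be supplied.
    """

    outdir: str = "chondroseq_out"
    counts: str | None = None
    samples: str | None = None
    gene_sets: tuple = ()
    alpha: float = 0.1
    min_median: int = 10
    n_iter: int = 10_000
    bins: int = 20
    n_top: int = 500
    seed: int = 0
    generator: simulate.GeneratorConfig | None = None

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie strictly in (0, 1), got {self.alpha}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.min_median < 0:
            raise ValueError("min_median must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        if gen is not None:
            if "size_factor_range" in gen:
                gen["size_factor_range"] = tuple(gen["size_factor_range"])
            gen = simulate.GeneratorConfig(**gen)
        if "gene_sets" in raw:
            raw["gene_sets"] = tuple(raw["gene_sets"])
        return cls(generator=gen, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_sets"] = list(self.gene_sets)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: PipelineConfig, outdir: pathlib.Path):
    """Read counts/samples from disk, or simulate them when a generator
    sub-config is present (simulated inputs are also written out)."""
    checksums = {}
    truth = None
    if config.generator is not None:
        gen = config.generator.replace(seed=config.seed)
        counts, samples, truth = simulate.simulate_dataset(gen)
        simdir = outdir / "simulated_input"
        simdir.mkdir(parents=True, exist_ok=True)
        io.write_counts(counts, simdir / "counts.tsv")
        io.write_samples(samples, simdir / "samples.tsv")
        truth.to_csv(simdir / "truth.tsv", sep="\t", index=False,
                     lineterminator="\n")
    else:
        if config.counts is None or config.samples is None:
            raise ValueError("either counts+samples paths or a generator "
                             "sub-config must be provided")
        counts = io.read_counts(config.counts)
        samples = io.read_samples(config.samples)
        checksums[config.counts] = _sha256(config.counts)
        checksums[config.samples] = _sha256(config.samples)
    for gs_path in config.gene_sets:
        checksums[str(gs_path)] = _sha256(gs_path)
    return counts, samples, truth, checksums


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns a summary dict."""
    t0 = time.time()
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts, samples, truth, checksums = _load_inputs(config, outdir)

    stage = "filter"
    try:
        filtered = de.filter_low_expressed(counts, min_median=config.min_median)
        sf = de.size_factors(filtered)

        stage = "contrasts"
        specs = compare.assemble_contrasts(samples)
        de_results: dict[str, de.DEResults] = {}
        for spec in specs:
            model = de.NegativeBinomialDE(filtered, samples, spec)
            res = model.fit(alpha=config.alpha)
            de_results[spec.name] = res
            res.write(outdir / f"de_{spec.name}.tsv")
            logger.info("contrast %s: %d significant at FDR %.2g",
                        spec.name, res.n_significant, config.alpha)

        stage = "gene-set tests"
        gene_sets = []
        for path in config.gene_sets:
            gene_sets.extend(io.read_gene_sets(path))
        perm_reports = {}
        ko_contrasts = [s for s in specs if s.factor == "genotype"]
        for gs in gene_sets:
            for spec in ko_contrasts:
                table = de_results[spec.name].table
                tested = table[table["p"].notna()]
                test = RankSumPermutationTest(
                    tested["p"].to_numpy(), tested["gene_id"].to_numpy(), gs
                )
                result = test.fit(n_iter=config.n_iter, seed=config.seed)
                key = f"{gs.name}__{spec.name}"
                result.write_json(outdir / f"permutation_{key}.json")
                result.write_null_stats(outdir / f"permutation_{key}_null.tsv")
                perm_reports[key] = result.p_value

        stage = "concordance"
        concordance_report = {}
        arms = sorted(samples["arm"].unique())
        if len(arms) == 2:
            a1, a2 = arms
            for tp in ("D7", "D14"):
                na = f"{a1}_{tp}_genotype_KO_vs_WT"
                nb = f"{a2}_{tp}_genotype_KO_vs_WT"
                if na in de_results and nb in de_results:
                    paired = compare.pair_results(
                        de_results[na].table, de_results[nb].table
                    )
                    hist = compare.conditional_p_hist(paired, "b", config.bins)
                    summary = compare.sign_concordance(paired)
                    paired.to_csv(outdir / f"paired_{tp}.tsv", sep="\t",
                                  index=False, lineterminator="\n")
                    compare.fcfc_scatter_table(paired).to_csv(
                        outdir / f"fcfc_{tp}.tsv", sep="\t", index=False,
                        lineterminator="\n")
                    concordance_report[tp] = {
                        "concordance": summary.to_dict(),
                        "histograms": {
                            k: v for k, v in hist.items()
                            if k.startswith(("density", "n_", "bin"))
                        },
                    }
            ta = f"{a1}_KO_timepoint_D14_vs_D7"
            tb = f"{a2}_KO_timepoint_D14_vs_D7"
            if ta in de_results and tb in de_results:
                paired = compare.pair_results(de_results[ta].table,
                                              de_results[tb].table)
                summary = compare.sign_concordance(paired)
                concordance_report["trajectory"] = {
                    "concordance": summary.to_dict()
                }
        io.write_json_report(concordance_report, outdir / "concordance.json")

        stage = "pca"
        pca = compare.pca_overview(filtered, n_top=config.n_top, size_factors_=sf)
        pca_table = pca.coordinates.copy()
        pca_table.insert(0, "sample_id", pca_table.index)
        pca_table = pca_table.merge(samples, on="sample_id", how="left")
        pca_table.to_csv(outdir / "pca.tsv", sep="\t", index=False,
                         lineterminator="\n")
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed in stage {stage!r}: {err}"
        ) from err

    manifest = {
        "package": "chondroseq",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "input_checksums": checksums,
        "n_genes_input": int(len(counts)),
        "n_genes_expressed": int(len(filtered)),
        "contrasts": sorted(de_results),
        "permutation_p_values": perm_reports,
        "pca_variance_fractions": [float(f) for f in pca.variance_fractions[:5]],
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    io.write_json_report(manifest, outdir / "manifest.json")
    logger.info("pipeline complete in %.1f s", manifest["elapsed_seconds"])
    return manifest
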