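"""End-to-end orchestration: one configured run producing report tables.

A run reads (or simulates) a genotype table, cleans it, and emits per
population and locus: allele frequency tables with bins, alpha-diversity
and similarity tables, MDS coordinates for every locus combination, ALD
tables, within-locus pair frequencies, a unique-allele summary, HWE and
Ewens-Watterson test tables, ranked haplotype tables in tilde notation
and rarefaction curves.  Every output is a TSV/CSV with a commented
metadata header recording the generating parameters and seeds; a
manifest ties the bundle together.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ald import ald_matrix
from .cartography import classical_mds, population_distances, profile_matrix
from .cooccurrence import pair_frequencies, pair_frequency_long_table
from .diversity import alpha_diversity_table, average_diversity, similarity_matrix
from .frequencies import count_alleles, frequency_long_table, unique_allele_table
from .genotypes import LOCI, GenotypeTable, clean_genotypes, read_genotype_table
from .haplotypes import em_haplotypes
from .locus_tests import ew_table, hwe_table
from .rarefaction import rarefaction_curve

log = logging.getLogger("hladiv")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    input: str | None = None
    output_dir: str = "hladiv_out"
    seed: int = 0
    loci: tuple[str, ...] = LOCI
    schema: dict = field(default_factory=dict)
    populations: list[str] | None = None  # default: all countries present
    # stage parameters
    em_tol: float = 1e-8
    em_max_iter: int = 5000
    posterior_threshold: float = 1e-4
    hwe_dememorization: int = 100_000
    hwe_batches: int = 20
    hwe_steps_per_batch: int = 5_000
    ew_n_sim: int = 100_000
    bootstrap: int = 50
    top_allele_threshold: float = 0.05
    mds_hf_threshold: float = 0.01
    rarefaction_extrapolate_factor: float = 1.5
    rarefaction_depth_points: int = 30

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.loci = tuple(cfg.loci)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["loci"] = list(d["loci"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _write_table(df: pd.DataFrame, path: Path, meta: dict, sep: str = "\t",
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep=sep, index=index, float_format="%.6g")


def run_pipeline(config: RunConfig, table: GenotypeTable | None = None
                 ) -> dict[str, Path]:
    """Execute every stage; returns {artifact name: path}.

    Any stage failure aborts with the stage name in the exception;
    artifacts written before the failure are preserved on disk.
    """
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    artifacts: dict[str, Path] = {"config": outdir / "config.yaml"}
    base_meta = {"hladiv_version": __version__, "seed": config.seed}
    stage = "input"
    try:
        if table is None:
            if config.input is None:
                raise ValueError("no input file and no in-memory table supplied")
            table, rejections = read_genotype_table(config.input, schema=config.schema,
                                                    loci=config.loci)
            for line in rejections:
                log.warning("WARN rejected_row %s", line)
        table, report = clean_genotypes(table)
        report.to_tsv(outdir / "cleaning_report.tsv")
        artifacts["cleaning_report"] = outdir / "cleaning_report.tsv"
        pops = config.populations or table.countries
        log.info("stage=%s done n_subjects=%d populations=%s", stage,
                 table.n_subjects, pops)

        stage = "allele_frequencies"
        t0 = time.time()
        freq_sets = {
            (pop, locus): count_alleles(table, locus, country=pop)
            for pop in pops for locus in config.loci
        }
        long = frequency_long_table(list(freq_sets.values()))
        _write_table(long, outdir / "allele_frequencies.tsv",
                     {**base_meta, "bins": "high>=0.05,low<0.01"})
        artifacts["allele_frequencies"] = outdir / "allele_frequencies.tsv"
        uniq = pd.concat(
            [unique_allele_table({p: freq_sets[(p, l)] for p in pops})
             for l in config.loci], ignore_index=True)
        _write_table(
            uniq, outdir / "unique_alleles.tsv",
            {**base_meta,
             "unique_frequency_definition":
                 "summed relative frequency of population-unique alleles x100"})
        artifacts["unique_alleles"] = outdir / "unique_alleles.tsv"
        log.info("stage=%s done in %.1fs", stage, time.time() - t0)

        stage = "alpha_diversity"
        alpha = alpha_diversity_table(list(freq_sets.values()))
        _write_table(alpha, outdir / "alpha_diversity.tsv", base_meta)
        artifacts["alpha_diversity"] = outdir / "alpha_diversity.tsv"

        stage = "similarity"
        t0 = time.time()
        sim_mats = {}
        for locus in config.loci:
            sm = similarity_matrix({p: freq_sets[(p, locus)] for p in pops})
            sim_mats[locus] = sm
            path = outdir / f"similarity_{locus}.csv"
            _write_table(sm.values, path,
                         {**base_meta, "locus": locus,
                          "similarity_definition": "(1-HellingerDistance)x100"},
                         sep=",", index=True)
            artifacts[f"similarity_{locus}"] = path
        div_rows = [
            {"population": p,
             "avg_diversity_pct": average_diversity(
                 list(sim_mats.values()), p, [q for q in pops if q != p])}
            for p in pops
        ]
        _write_table(pd.DataFrame(div_rows), outdir / "diversity_summary.tsv",
                     {**base_meta, "diversity_definition": "mean over loci and "
                      "partners of (100 - similarity%)"})
        artifacts["diversity_summary"] = outdir / "diversity_summary.tsv"
        log.info("stage=%s done in %.1fs", stage, time.time() - t0)

        stage = "haplotypes"
        t0 = time.time()
        combos = [c for r in (2, 3) for c in itertools.combinations(config.loci, r)]
        hap_fits: dict[tuple, dict] = {}
        hap_frames = []
        for combo in combos:
            hap_fits[combo] = {}
            for pop in pops:
                fit = em_haplotypes(
                    table, combo, tol=config.em_tol, max_iter=config.em_max_iter,
                    posterior_threshold=config.posterior_threshold, country=pop)
                if not fit.converged:
                    log.warning("WARN em_not_converged population=%s loci=%s",
                                pop, combo)
                hap_fits[combo][pop] = fit
                e = fit.entries
                e.insert(0, "population", pop)
                hap_frames.append(e)
        _write_table(pd.concat(hap_frames, ignore_index=True),
                     outdir / "haplotypes.tsv",
                     {**base_meta, "posterior_threshold": config.posterior_threshold})
        artifacts["haplotypes"] = outdir / "haplotypes.tsv"
        log.info("stage=%s done in %.1fs", stage, time.time() - t0)

        stage = "ald"
        t0 = time.time()
        ald_frames = [
            ald_matrix(table, config.loci, country=pop, tol=config.em_tol,
                       max_iter=config.em_max_iter,
                       posterior_threshold=config.posterior_threshold)
            for pop in pops
        ]
        _write_table(pd.concat(ald_frames, ignore_index=True), outdir / "ald.tsv",
                     {**base_meta,
                      "direction": "focal locus conditioned on conditioning locus"})
        artifacts["ald"] = outdir / "ald.tsv"
        log.info("stage=%s done in %.1fs", stage, time.time() - t0)

        stage = "mds"
        for combo in combos:
            prof = profile_matrix(hap_fits[combo], threshold=config.mds_hf_threshold)
            dist = population_distances(prof)
            emb = classical_mds(dist)
            tag = "_".join(combo)
            _write_table(dist, outdir / f"distances_{tag}.csv",
                         {**base_meta, "loci": ":".join(combo),
                          "metric": "euclidean",
                          "hf_threshold": config.mds_hf_threshold},
                         sep=",", index=True)
            _write_table(emb.as_frame(), outdir / f"mds_{tag}.csv",
                         {**base_meta, "loci": ":".join(combo),
                          "variance_explained": f"{emb.variance_explained:.4f}"},
                         sep=",")
            artifacts[f"mds_{tag}"] = outdir / f"mds_{tag}.csv"

        stage = "pair_frequencies"
        pair_tables = [pair_frequencies(table, locus, country=pop)
                       for pop in pops for locus in config.loci]
        _write_table(pair_frequency_long_table(pair_tables),
                     outdir / "pair_frequencies.tsv", base_meta)
        artifacts["pair_frequencies"] = outdir / "pair_frequencies.tsv"

        stage = "hwe"
        t0 = time.time()
        hwe = hwe_table(table, config.loci, pops, seed=config.seed,
                        dememorization=config.hwe_dememorization,
                        batches=config.hwe_batches,
                        steps_per_batch=config.hwe_steps_per_batch)
        _write_table(hwe, outdir / "hwe.tsv",
                     {**base_meta, "dememorization": config.hwe_dememorization,
                      "exp_het": "unbiased (2n/(2n-1))(1-sum p^2)",
                      "bh_family": "populations within locus"})
        artifacts["hwe"] = outdir / "hwe.tsv"
        log.info("stage=%s done in %.1fs", stage, time.time() - t0)

        stage = "ewens_watterson"
        t0 = time.time()
        ew = ew_table(table, config.loci, pops, seed=config.seed,
                      n_sim=config.ew_n_sim)
        _write_table(ew, outdir / "ewens_watterson.tsv",
                     {**base_meta, "tail": "lower (P(F_null <= F_obs))",
                      "bh_family": "populations within locus"})
        artifacts["ewens_watterson"] = outdir / "ewens_watterson.tsv"
        log.info("stage=%s done in %.1fs", stage, time.time() - t0)

        stage = "rarefaction"
        t0 = time.time()
        rare_frames = []
        for pop in pops:
            for locus in config.loci:
                n_p = len(table.subset(country=pop).typed_at(locus))
                curve = rarefaction_curve(
                    table, locus, country=pop,
                    extrapolate_to=int(n_p * config.rarefaction_extrapolate_factor),
                    n_depths=config.rarefaction_depth_points,
                    bootstrap=config.bootstrap, seed=config.seed)
                t = curve.table
                t.insert(0, "population", pop)
                t.insert(1, "locus", locus)
                rare_frames.append(t)
        _write_table(pd.concat(rare_frames, ignore_index=True),
                     outdir / "rarefaction.tsv",
                     {**base_meta, "bootstrap": config.bootstrap,
                      "ci": "percentile 95%"})
        artifacts["rarefaction"] = outdir / "rarefaction.tsv"
        log.info("stage=%s done in %.1fs", stage, time.time() - t0)

        manifest = {
            "hladiv_version": __version__,
            "seed": config.seed,
            "n_subjects": table.n_subjects,
            "populations": pops,
            "loci": list(config.loci),
            "artifacts": {k: str(v) for k, v in artifacts.items()},
            "metadata": {
                "exp_het": "unbiased gene diversity",
                "similarity": "(1-HD)x100",
                "unique_frequency": "summed freq of population-unique alleles",
                "rarefaction_units": "participants (2 gene copies each)",
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        artifacts["manifest"] = outdir / "manifest.json"
        log.info("pipeline complete in %.1fs", time.time() - t_start)
        return artifacts
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
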