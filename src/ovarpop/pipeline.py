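"""End-to-end orchestration: simulate -> type -> analyse, driven by one config.

All randomness flows from named seeds in the config; rerunning the same
config reproduces every output byte-for-byte.  Outputs are CSV, FASTA,
Newick and a JSON index; every CSV carries a header comment with the tool
version and the config hash, and analysis tables reference the genotype
table they came from by content hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .alleles import AlleleDatabase
from .distances import (bootstrap_support, breed_distance_matrix,
                        allele_sharing_summary, common_allele_profile,
                        neighbor_joining, upgma)
from .genotypes import GenotypeTable, allele_frequencies
from .io import (read_fasta, read_genotype_csv, write_fasta,
                 write_fastq_pairs, write_genotype_csv, write_newick,
                 _write_csv)
from .ordination import pca_frequencies
from .popgen import diversity_report, fst_weir_cockerham
from .seqdiv import diversity_table, pocket_motif_frequencies
from .simulate import (BreedSpec, generate_allele_library,
                       sample_population_genotypes, simulate_amplicon_reads)
from .typing import TypingParams, type_cohort

_KNOWN_KEYS = {
    "outdir", "seeds", "simulate", "typing", "popgen", "distances",
    "seq_diversity", "inputs",
}


@dataclass
class RunConfig:
    """Validated run configuration (unknown top-level keys rejected)."""

    outdir: Path
    seeds: dict[str, int]
    simulate: dict[str, Any] | None = None
    typing: dict[str, Any] | None = None
    popgen: dict[str, Any] | None = None
    distances: dict[str, Any] | None = None
    seq_diversity: dict[str, Any] | None = None
    inputs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        unknown = set(cfg) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in cfg:
            raise ValueError("config requires 'outdir'")
        seeds = cfg.get("seeds", {})
        stochastic = [
            k for k in ("simulate", "popgen", "distances") if cfg.get(k)
        ]
        missing = [k for k in stochastic if k not in seeds]
        if missing:
            raise ValueError(f"missing seeds for stages: {missing}")
        return cls(
            outdir=Path(cfg["outdir"]),
            seeds={k: int(v) for k, v in seeds.items()},
            simulate=cfg.get("simulate"),
            typing=cfg.get("typing"),
            popgen=cfg.get("popgen"),
            distances=cfg.get("distances"),
            seq_diversity=cfg.get("seq_diversity"),
            inputs=dict(cfg.get("inputs", {})),
        )

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "seeds": self.seeds,
                "simulate": self.simulate,
                "typing": self.typing,
                "popgen": self.popgen,
                "distances": self.distances,
                "seq_diversity": self.seq_diversity,
                "inputs": self.inputs,
            },
            sort_keys=True,
            default=str,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class AnalysisReport:
    """Index of everything one run produced."""

    config_hash: str
    genotype_hash: str | None
    outputs: dict[str, str]

    def to_json(self, path) -> None:
        import os

        base = Path(path).parent
        rel = {
            k: os.path.relpath(v, base) for k, v in self.outputs.items()
        }
        with open(path, "w") as fh:
            json.dump(
                {
                    "tool": f"ovarpop {__version__}",
                    "config_hash": self.config_hash,
                    "genotype_hash": self.genotype_hash,
                    "outputs": rel,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def _stage(name: str):
    """Wrap stage errors with a stage tag."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return _Ctx()


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the configured stages; any stage may be skipped."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()
    header = f"ovarpop {__version__} config={chash}"
    outputs: dict[str, str] = {}

    def record(key: str, path: Path) -> None:
        outputs[key] = str(path)

    db: AlleleDatabase | None = None
    gt: GenotypeTable | None = None
    readsets = None

    if config.inputs.get("allele_fasta"):
        db = read_fasta(config.inputs["allele_fasta"])
    if config.inputs.get("genotype_csv"):
        gt = read_genotype_csv(config.inputs["genotype_csv"])

    if config.simulate is not None:
        with _stage("simulate"):
            sim = dict(config.simulate)
            seed = config.seeds["simulate"]
            lib = sim.get("library", {})
            db = generate_allele_library(
                n_alleles=lib.get("n_alleles", 46),
                length=lib.get("length", 270),
                min_pairwise_diff=lib.get("min_pairwise_diff", 2),
                seed=seed,
            )
            specs = [
                BreedSpec(
                    name=b["name"],
                    n_individuals=b["n_individuals"],
                    freq_model=b["freq_model"],
                    inbreeding_f=b.get("inbreeding_f", 0.0),
                )
                for b in sim["breeds"]
            ]
            truth_gt = sample_population_genotypes(db, specs, seed=seed + 1)
            reads_cfg = sim.get("reads", {})
            readsets = simulate_amplicon_reads(
                truth_gt, db,
                depth_mean=reads_cfg.get("depth_mean", 32.61),
                depth_sd=reads_cfg.get("depth_sd", 18.29),
                read_len=reads_cfg.get("read_len"),
                error_rate=reads_cfg.get("error_rate", 0.002),
                seed=seed + 2,
            )
            known = sim.get("known_alleles")
            typing_db = db.subset(known) if known else db
            write_fasta(typing_db, outdir / "allele_library.fasta")
            record("allele_fasta", outdir / "allele_library.fasta")
            write_genotype_csv(truth_gt, outdir / "truth_genotypes.csv",
                               header)
            record("truth_genotypes", outdir / "truth_genotypes.csv")
            if sim.get("write_fastq", False):
                write_fastq_pairs(readsets, outdir / "reads")
                record("reads_dir", outdir / "reads")
            db = typing_db
            if not config.typing:
                gt = truth_gt

    if config.typing is not None:
        with _stage("type"):
            if readsets is None or db is None:
                raise ValueError("typing requires simulated or loaded reads")
            params = TypingParams(**config.typing.get("params", {}))
            gt, qc, db, novel = type_cohort(readsets, db, params)
            write_genotype_csv(gt, outdir / "genotypes.csv", header)
            record("genotypes", outdir / "genotypes.csv")
            _write_csv(qc, outdir / "typing_qc.csv", header)
            record("typing_qc", outdir / "typing_qc.csv")
            _write_csv(novel, outdir / "novel_alleles.csv", header)
            record("novel_alleles", outdir / "novel_alleles.csv")
            write_fasta(db, outdir / "allele_library_extended.fasta")
            record("allele_fasta_extended",
                   outdir / "allele_library_extended.fasta")

    ghash = gt.content_hash() if gt is not None else None
    gt_header = f"{header} genotypes={ghash}" if ghash else header

    if config.popgen is not None:
        with _stage("popgen"):
            if gt is None and not config.inputs.get("frequency_csv"):
                raise ValueError(
                    "popgen requires a genotype table or frequency CSV"
                )
            if gt is None:
                # frequency-only input: the computable subset (N, n_a, h_E)
                from .io import read_frequency_csv
                from .popgen import heterozygosity_from_frequencies

                fm_in = read_frequency_csv(
                    config.inputs["frequency_csv"],
                    n_samples=config.popgen.get("n_samples"),
                )
                rep = heterozygosity_from_frequencies(fm_in)
                _write_csv(rep, outdir / "diversity.csv", gt_header)
                record("diversity", outdir / "diversity.csv")
            else:
                rep = diversity_report(
                    gt,
                    n_reps_hwe=config.popgen.get("n_reps_hwe", 100_000),
                    n_reps_slatkin=config.popgen.get(
                        "n_reps_slatkin", 100_000),
                    seed=config.seeds["popgen"],
                )
                _write_csv(rep, outdir / "diversity.csv", gt_header)
                record("diversity", outdir / "diversity.csv")
                fst = fst_weir_cockerham(
                    gt,
                    n_perms=config.popgen.get("n_perms_fst", 10_000),
                    seed=config.seeds["popgen"] + 1,
                )
                _write_csv(fst.pairwise, outdir / "fst_pairwise.csv",
                           gt_header, index=True)
                record("fst_pairwise", outdir / "fst_pairwise.csv")
                _write_csv(
                    pd.DataFrame(
                        {"theta": [fst.theta_global], "p": [fst.p_global]}
                    ),
                    outdir / "fst_global.csv", gt_header,
                )
                record("fst_global", outdir / "fst_global.csv")

    if config.distances is not None:
        with _stage("distances"):
            if gt is not None:
                fm = allele_frequencies(gt)
            elif config.inputs.get("frequency_csv"):
                from .io import read_frequency_csv

                fm = read_frequency_csv(config.inputs["frequency_csv"])
            else:
                raise ValueError("distances require genotypes or frequencies")
            dcfg = config.distances
            for metric in dcfg.get("metrics", ["DA", "Ds"]):
                dm = breed_distance_matrix(fm, metric)
                _write_csv(dm.df, outdir / f"dist_{metric}.csv",
                           gt_header, index=True)
                record(f"dist_{metric}", outdir / f"dist_{metric}.csv")
            tree_metric = dcfg.get("tree_metric", "DA")
            for method, build in (("nj", neighbor_joining), ("upgma", upgma)):
                if gt is not None and dcfg.get("bootstrap_reps", 0) >= 100:
                    tree, _ = bootstrap_support(
                        gt, tree_metric, method,
                        n_reps=dcfg["bootstrap_reps"],
                        seed=config.seeds["distances"],
                    )
                else:
                    tree = build(breed_distance_matrix(fm, tree_metric))
                path = outdir / f"tree_{method}_{tree_metric}.nwk"
                write_newick(tree, path)
                record(f"tree_{method}", path)
            pca = pca_frequencies(fm, dcfg.get("pca_matrix", "covariance"))
            _write_csv(pca.scores, outdir / "pca_scores.csv", gt_header,
                       index=True)
            _write_csv(pca.loadings, outdir / "pca_loadings.csv", gt_header,
                       index=True)
            _write_csv(pca.percent_variance.to_frame(),
                       outdir / "pca_variance.csv", gt_header, index=True)
            for key in ("pca_scores", "pca_loadings", "pca_variance"):
                record(key, outdir / f"{key}.csv")
            cells, counts = allele_sharing_summary(fm)
            _write_csv(cells, outdir / "allele_sharing.csv", gt_header)
            record("allele_sharing", outdir / "allele_sharing.csv")
            summary, curves = common_allele_profile(
                fm, dcfg.get("common_threshold", 0.05))
            _write_csv(summary, outdir / "common_alleles.csv", gt_header)
            _write_csv(curves, outdir / "frequency_curves.csv", gt_header)
            record("common_alleles", outdir / "common_alleles.csv")
            record("frequency_curves", outdir / "frequency_curves.csv")

    if config.seq_diversity is not None:
        with _stage("seq_diversity"):
            if gt is None or db is None:
                raise ValueError(
                    "sequence diversity requires genotypes and sequences"
                )
            scfg = config.seq_diversity
            tab = diversity_table(gt, db, r=scfg.get("R", 2.0))
            _write_csv(tab, outdir / "seq_diversity.csv", gt_header)
            record("seq_diversity", outdir / "seq_diversity.csv")
            try:
                motifs = pocket_motif_frequencies(
                    gt, db, mature_start=scfg.get("mature_start", 6))
            except ValueError:
                motifs = {}  # pockets outside the translated region
            for pid, fm_p in motifs.items():
                path = outdir / f"pocket_{pid}_motifs.csv"
                _write_csv(fm_p.df, path, gt_header, index=True)
                record(f"pocket_{pid}", path)

    report = AnalysisReport(chash, ghash, outputs)
    report.to_json(outdir / "report.json")
    return report
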