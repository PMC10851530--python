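"""Readers and writers for the interchange formats.

FASTA for allele libraries, paired FASTQ for reads (gzip-transparent),
CSV for genotype tables / frequency matrices / reports, Newick for trees,
YAML for run configuration.  CSV writers can prepend a ``#`` header
comment carrying the tool version and config hash; all CSV readers skip
``#`` lines.
"""

from __future__ import annotations

import gzip
import io as _io
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alleles import AlleleDatabase, AlleleSequence
from .genotypes import GenotypeTable, REQUIRED_COLUMNS
from .simulate import ReadPairSet


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, frame_offset: int = 0, strict: bool = True
               ) -> AlleleDatabase:
    """Read an allele library; duplicate names are an error.

    Lowercase sequences are uppercased with a warning; with strict=True
    non-ACGT characters raise.
    """
    db = AlleleDatabase()
    seen = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA record {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq)
            if seq != seq.upper():
                warnings.warn(f"record {rec.id!r}: lowercase normalised")
                seq = seq.upper()
            if strict and (set(seq) - set("ACGT")):
                raise ValueError(f"record {rec.id!r}: non-ACGT characters")
            db.add(AlleleSequence(rec.id, seq, frame_offset))
    return db


def write_fasta(db: AlleleDatabase | Iterable[AlleleSequence], path) -> None:
    """Write one record per allele, sequence on a single line."""
    with _open_text(path, "wt") as fh:
        for allele in db:
            fh.write(f">{allele.name}\n{allele.seq}\n")


# ---------------------------------------------------------------------------
# FASTQ


def write_fastq_pairs(readsets: Sequence[ReadPairSet], outdir,
                      gzipped: bool = False) -> list[tuple[Path, Path]]:
    """Two FASTQ files per sample (``<sample>_R1.fastq``/``_R2.fastq``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzipped else ".fastq"
    paths = []
    for rs in readsets:
        p1 = outdir / f"{rs.sample_id}_R1{ext}"
        p2 = outdir / f"{rs.sample_id}_R2{ext}"
        with _open_text(p1, "wt") as f1, _open_text(p2, "wt") as f2:
            for i, (fwd, fq, rev, rq) in enumerate(rs.pairs, start=1):
                f1.write(f"@{rs.sample_id}.{i}/1\n{fwd}\n+\n{fq}\n")
                f2.write(f"@{rs.sample_id}.{i}/2\n{rev}\n+\n{rq}\n")
        paths.append((p1, p2))
    return paths


def read_fastq_pairs(directory, breed_of: dict[str, str] | None = None
                     ) -> list[ReadPairSet]:
    """Load every ``*_R1.fastq[.gz]``/``*_R2`` pair in a directory.

    Sample ids come from the file names; breeds from ``breed_of`` (default
    'unknown').  Truth alleles are unknown for real data.
    """
    directory = Path(directory)
    r1_files = sorted(
        list(directory.glob("*_R1.fastq")) + list(directory.glob("*_R1.fastq.gz"))
    )
    if not r1_files:
        raise FileNotFoundError(f"no *_R1.fastq[.gz] files in {directory}")
    out = []
    for p1 in r1_files:
        name = p1.name
        sample = name[: name.index("_R1.fastq")]
        suffix = name[name.index("_R1.fastq") + 3:]
        p2 = directory / f"{sample}_R2{suffix}"
        if not p2.exists():
            raise FileNotFoundError(f"missing mate file {p2}")
        pairs = []
        with _open_text(p1) as f1, _open_text(p2) as f2:
            for rec1, rec2 in zip(
                SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")
            ):
                q1 = "".join(
                    chr(q + 33)
                    for q in rec1.letter_annotations["phred_quality"]
                )
                q2 = "".join(
                    chr(q + 33)
                    for q in rec2.letter_annotations["phred_quality"]
                )
                pairs.append((str(rec1.seq), q1, str(rec2.seq), q2))
        breed = (breed_of or {}).get(sample, "unknown")
        out.append(ReadPairSet(sample, breed, pairs, ("", "")))
    return out


# ---------------------------------------------------------------------------
# CSV


def _write_csv(df: pd.DataFrame, path, header_comment: str | None = None,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=index)


def read_genotype_csv(path, db: AlleleDatabase | None = None
                      ) -> GenotypeTable:
    """Read a genotype table (columns sample, breed, allele1, allele2).

    Decimal commas in any numeric extra columns are tolerated; ``#`` lines
    are comments.  With ``db`` given, allele names are validated against it.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    gt = GenotypeTable(df)
    if db is not None:
        unknown = sorted(
            set(gt.df["allele1"]) | set(gt.df["allele2"])
        - set(db.names))
        if unknown:
            raise ValueError(f"alleles absent from database: {unknown[:5]}")
    return gt


def write_genotype_csv(gt: GenotypeTable, path,
                       header_comment: str | None = None) -> None:
    _write_csv(gt.df, path, header_comment)


def read_frequency_csv(path, n_samples: dict[str, int] | None = None,
                       percent: bool | None = None):
    """Breed-by-allele frequency matrix from CSV (alleles in rows or cols).

    Accepts comma decimal separators.  ``percent=None`` auto-detects the
    scale from the row sums.
    """
    from .genotypes import FrequencyMatrix

    df = pd.read_csv(path, comment="#", index_col=0)
    if df.map(lambda v: isinstance(v, str)).any().any():
        df = df.map(
            lambda v: float(str(v).replace(",", ".")) if pd.notna(v) else 0.0
        )
    df = df.fillna(0.0).astype(float)
    # orient: breeds in rows; a table with alleles in rows is transposed
    if n_samples and all(b in df.columns for b in n_samples):
        df = df.T
    row_sums = df.sum(axis=1)
    if percent is None:
        percent = bool((row_sums > 50).all())
    if percent:
        return FrequencyMatrix.from_percent(df, n_samples)
    df = df.div(row_sums, axis=0)
    return FrequencyMatrix(df, n_samples)


# ---------------------------------------------------------------------------
# trees and misc


def write_newick(tree, path) -> None:
    tree.write(str(path), format="newick")


def write_pairwise_table(upper: pd.DataFrame, lower: pd.DataFrame,
                         path, header_comment: str | None = None) -> None:
    """Combined matrix: ``upper`` above the diagonal, ``lower`` below.

    The published supplementary layout places genetic distances above and
    F_ST (p-values in parentheses) below the diagonal.
    """
    labels = list(upper.index)
    out = pd.DataFrame("", index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                out.loc[a, b] = f"{upper.loc[a, b]:.4f}"
            elif i > j:
                out.loc[a, b] = f"{lower.loc[a, b]:.4f}"
    _write_csv(out, path, header_comment, index=True)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: YAML config must be a mapping")
    return cfg
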