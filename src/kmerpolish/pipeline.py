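"""File-level entry points: polish an assembly on disk, report QV, simulate data.

These functions are the library's equivalents of command-line subcommands:
they read standard formats (FASTA assemblies; FASTQ or FASTA reads, plain or
gzipped, detected by file magic rather than extension), run the in-memory
operations, and write a polished FASTA (same record order and identifiers,
60-column wrapping), a corrections TSV (1-based positions), and a summary to
the module logger, including the chosen C_eq/R_t/A_t and the first 100
histogram bins for auditability.

Internally all coordinates are 0-based; the 1-based convention appears only
in the TSV boundary.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import corrector, kmerdb, simgen
from .corrector import PolishReport, QVReport
from .kmerdb import KmerCountTable, KmerParams
from .thresholds import Thresholds, thresholds_from_histogram

__all__ = [
    "RunConfig",
    "run_polish",
    "run_qv",
    "run_simulate",
    "read_fasta",
    "write_fasta",
    "iter_read_files",
    "load_count_table",
]

logger = logging.getLogger("kmerpolish")

FASTA_WIDTH = 60


@dataclass
class RunConfig:
    """Configuration shared by the polish/QV entry points."""

    assembly: str
    reads: List[str] = field(default_factory=list)
    k: int = 37
    passes: int = 2
    threads: int = 1
    db_in: Optional[str] = None
    db_out: Optional[str] = None
    out_prefix: str = "kmerpolish"
    c_eq: Optional[int] = None  # manual override, bypasses the histogram scan
    max_paths: int = corrector.DEFAULT_MAX_PATHS
    log_level: int = logging.INFO

    def __post_init__(self) -> None:
        KmerParams(self.k)  # validates odd k >= 3
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if not self.reads and self.db_in is None:
            raise ValueError("provide read files or a pre-computed count dump")


def _open_text(path) -> Iterator[str]:
    """Open possibly-gzipped text, detecting gzip by its 2-byte magic."""
    path = str(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> List[Tuple[str, str]]:
    """FASTA records as (first-word id, uppercase sequence), input order kept."""
    out: List[Tuple[str, str]] = []
    with _open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            out.append((title.split()[0], seq.upper()))
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(path, contigs: Sequence[Tuple[str, str]], width: int = FASTA_WIDTH) -> None:
    with open(path, "w") as fh:
        for cid, seq in contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_read_files(paths: Iterable) -> Iterator[str]:
    """Stream read sequences from FASTQ or FASTA files (format sniffed)."""
    for path in paths:
        fh = _open_text(path)
        with fh:
            first = fh.read(1)
            fh.seek(0)
            if first == "@":
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    yield seq
            elif first == ">":
                for _title, seq in SimpleFastaParser(fh):
                    yield seq
            elif first == "":
                continue
            else:
                raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")


def load_count_table(config: RunConfig) -> KmerCountTable:
    """Count table from the dump file if given, else by counting the reads."""
    if config.db_in is not None:
        table = kmerdb.load_table(config.db_in)
        if table.params.k != config.k and table.counts:
            raise ValueError(
                f"{config.db_in}: dump holds {table.params.k}-mers, config wants k={config.k}"
            )
        return table
    table = kmerdb.count_kmers(iter_read_files(config.reads), KmerParams(config.k))
    if config.db_out is not None:
        kmerdb.save_table(table, config.db_out)
    return table


def _derive_thresholds(table: KmerCountTable, config: RunConfig) -> Thresholds:
    hist = table.histogram()
    thr = thresholds_from_histogram(hist, c_eq=config.c_eq)
    first_bins = {c: hist.n_of_c.get(c, 0) for c in range(1, 101)}
    logger.info(
        "thresholds: C_eq=%d R_t=%d A_t=%d%s",
        thr.c_eq, thr.r_t, thr.a_t,
        " (manual C_eq override)" if config.c_eq is not None else "",
    )
    logger.info("histogram bins 1..100: %s", first_bins)
    return thr


def _write_corrections_tsv(path, corrections) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tremoved\tadded\tkind\tpass\n")
        for c in corrections:
            fh.write(
                f"{c.contig_id}\t{c.position + 1}\t{c.removed or '.'}\t"
                f"{c.added or '.'}\t{c.kind.value}\t{c.pass_index}\n"
            )


def run_polish(config: RunConfig) -> PolishReport:
    """Polish the assembly and write <out_prefix>.polished.fasta plus
    <out_prefix>.corrections.tsv.

    Raises :class:`~kmerpolish.thresholds.UnsuitableDataError` when C_eq < 4
    (the read data cannot support polishing) and ``ValueError``/``OSError``
    naming the offending file for unreadable or malformed inputs.
    """
    logging.basicConfig(level=config.log_level)
    assembly = read_fasta(config.assembly)
    table = load_count_table(config)
    thr = _derive_thresholds(table, config)
    polished, report = corrector.polish(
        assembly,
        table,
        thr,
        passes=config.passes,
        max_paths=config.max_paths,
        threads=config.threads,
    )
    out_fasta = f"{config.out_prefix}.polished.fasta"
    out_tsv = f"{config.out_prefix}.corrections.tsv"
    write_fasta(out_fasta, polished)
    _write_corrections_tsv(out_tsv, report.corrections)
    logger.info("corrections per pass: %s", report.corrections_per_pass)
    if report.qv_before and report.qv_after:
        logger.info(
            "QV before polishing: %.2f  after: %.2f",
            report.qv_before.qv, report.qv_after.qv,
        )
    return report


def run_qv(config: RunConfig) -> QVReport:
    """Report the assembly QV without modifying anything."""
    logging.basicConfig(level=config.log_level)
    assembly = read_fasta(config.assembly)
    table = load_count_table(config)
    thr = _derive_thresholds(table, config)
    qv = corrector.assembly_qv(assembly, table, thr)
    logger.info(
        "unreliable k-mers: %d  genome size (k-mer positions): %d  "
        "E_k: %.6g  E_b: %.6g  QV: %.2f",
        qv.unreliable_kmers, qv.genome_size, qv.e_k, qv.e_b, qv.qv,
    )
    return qv


def run_simulate(
    out_prefix: str,
    length: int,
    seed: int,
    coverage: float = 30.0,
    sub_rate: float = 3.3e-4,
    indel_rate: float = 6.6e-4,
    read_len: int = 150,
    fragment_len: int = 500,
    error_rate: float = 0.01,
    gc: float = 0.5,
    k: int = 37,
) -> Dict[str, str]:
    """Write a seeded synthetic data set: clean genome, mutated assembly,
    truth TSV, and paired FASTQ reads simulated from the clean genome.

    Returns a dict of the written paths.  Invalid parameter combinations
    raise ``ValueError``.
    """
    genome = simgen.generate_genome(length, seed=seed, gc=gc)
    mutated, truth = simgen.inject_errors(
        genome, sub_rate, indel_rate, seed=seed + 1, k=k
    )
    pairs = simgen.simulate_reads(
        genome, coverage, read_len=read_len, fragment_len=fragment_len,
        error_rate=error_rate, seed=seed + 2,
    )
    paths = {
        "genome": f"{out_prefix}.genome.fasta",
        "mutated": f"{out_prefix}.mutated.fasta",
        "truth": f"{out_prefix}.truth.tsv",
        "reads1": f"{out_prefix}.reads_1.fastq",
        "reads2": f"{out_prefix}.reads_2.fastq",
    }
    write_fasta(paths["genome"], [("genome", genome)])
    write_fasta(paths["mutated"], [("contig", mutated)])
    with open(paths["truth"], "w") as fh:
        fh.write("contig\tpos\tkind\toriginal\tmutated\n")
        for e in truth.edits:
            fh.write(
                f"{e.contig_id}\t{e.position + 1}\t{e.kind.value}\t"
                f"{e.original or '.'}\t{e.mutated or '.'}\n"
            )
    qual = "I" * read_len
    with open(paths["reads1"], "w") as f1, open(paths["reads2"], "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.read1}\n+\n{qual}\n")
            f2.write(f"@{p.name}/2\n{p.read2}\n+\n{qual}\n")
    return paths
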