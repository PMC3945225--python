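"""Shared plumbing for the numbered analysis drivers: default locations and
loaders for the run directory written by 01_simulate_data.py."""

from __future__ import annotations

import argparse
from pathlib import Path

from mitobook import io as mio

RUN_DIR = Path("scratch/analysis_run")
RESULTS = Path("results")
CONDITIONS = ("asynchronous", "mitotic", "input")


def make_parser(description: str) -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--run-dir", type=Path, default=RUN_DIR)
    p.add_argument("--results", type=Path, default=RESULTS)
    return p


def load_genome(run_dir: Path):
    genome = mio.read_gene_table(run_dir / "genes.tsv")
    sequences = mio.read_fasta(run_dir / "genome.fa")
    return genome, sequences


def load_tags(run_dir: Path, genome):
    return {
        cond: mio.read_tag_bed(run_dir / f"tags_{cond}.bed", genome.chrom_lengths)
        for cond in CONDITIONS
    }


def load_peaks(run_dir: Path, genome):
    return {
        cond: mio.read_peaks_bed(run_dir / f"peaks_{cond}.bed", genome.chrom_lengths)
        for cond in ("asynchronous", "mitotic")
    }


def load_sites(run_dir: Path):
    return mio.read_sites_bed(run_dir / "sites.bed")
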