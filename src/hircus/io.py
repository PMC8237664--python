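"""Plain-text readers/writers: pileup TSV, EIGENSTRAT, BED, FASTA, Newick.

EIGENSTRAT is the geno/snp/ind triple used by ancient-DNA genotype panels:
``.geno`` one line per site of per-sample dosage characters (9 = missing),
``.snp`` whitespace-separated site metadata, ``.ind`` sample/sex/population
rows.  Pileup TSV is the per-site allele-count table produced by the
simulator (chrom, pos [1-based], ref_count, alt_count).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING_GENO = 9

__all__ = [
    "write_pileup",
    "read_pileup",
    "write_eigenstrat",
    "read_eigenstrat",
    "write_bed",
    "write_fasta",
    "read_fasta",
]


def write_pileup(path, chrom, pos, ref_count, alt_count) -> None:
    pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref_count": ref_count, "alt_count": alt_count}
    ).to_csv(path, sep="\t", index=False)


def read_pileup(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_eigenstrat(
    prefix,
    sites: pd.DataFrame,
    genotypes: np.ndarray,
    samples: list[str],
    populations: list[str],
    sexes: list[str] | None = None,
) -> None:
    """Write a geno/snp/ind triple.

    ``genotypes`` is samples x sites dosage (0/1/2, -1 missing); the
    .geno file is sites x samples, one character per sample.
    """
    prefix = Path(prefix)
    g = np.asarray(genotypes)
    coded = np.where(g == -1, MISSING_GENO, g).astype(np.int8)
    with open(prefix.with_suffix(".geno"), "w") as fh:
        for col in coded.T:
            fh.write("".join(str(int(v)) for v in col) + "\n")
    with open(prefix.with_suffix(".snp"), "w") as fh:
        for i, row in sites.iterrows():
            name = f"{row['chrom']}_{row['pos']}"
            fh.write(
                f"{name}\t{row['chrom']}\t0.0\t{row['pos']}\t{row['ref']}\t{row['alt']}\n"
            )
    sexes = sexes or ["U"] * len(samples)
    with open(prefix.with_suffix(".ind"), "w") as fh:
        for s, x, p in zip(samples, sexes, populations):
            fh.write(f"{s}\t{x}\t{p}\n")


def read_eigenstrat(prefix) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Read a geno/snp/ind triple -> (sites, genotypes, individuals)."""
    prefix = Path(prefix)
    snp = pd.read_csv(
        prefix.with_suffix(".snp"),
        sep=r"\s+",
        header=None,
        names=["name", "chrom", "gpos", "pos", "ref", "alt"],
        dtype={"chrom": str},
    )
    ind = pd.read_csv(
        prefix.with_suffix(".ind"),
        sep=r"\s+",
        header=None,
        names=["sample", "sex", "pop"],
    )
    with open(prefix.with_suffix(".geno")) as fh:
        rows = [
            np.frombuffer(line.strip().encode(), dtype=np.uint8).astype(np.int8)
            - ord("0")
            for line in fh
        ]
    geno = np.array(rows).T
    geno = np.where(geno == MISSING_GENO, -1, geno).astype(np.int8)
    sites = snp[["chrom", "pos", "ref", "alt"]].copy()
    return sites, geno, ind


def write_call_matrix(path, matrix) -> None:
    """Write a PseudohaploidMatrix as TSV: site columns then one column
    of {-1,0,1} calls per sample."""
    df = matrix.panel.sites[["chrom", "pos", "ref", "alt"]].copy()
    for i, s in enumerate(matrix.samples):
        df[s] = matrix.calls[i]
    df.to_csv(path, sep="\t", index=False)


def read_call_matrix(path):
    from .genotypes import PseudohaploidMatrix, SitePanel

    df = pd.read_csv(path, sep="\t")
    site_cols = ["chrom", "pos", "ref", "alt"]
    samples = tuple(c for c in df.columns if c not in site_cols)
    panel = SitePanel(df[site_cols].copy())
    calls = df[list(samples)].to_numpy(dtype=np.int8).T
    return PseudohaploidMatrix(calls, samples, panel)


def write_bed(path, intervals: pd.DataFrame) -> None:
    """Write chrom/start/end intervals as BED (converting to 0-based half-open)."""
    bed = intervals.copy()
    bed["start"] = bed["start"] - 1
    bed[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
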