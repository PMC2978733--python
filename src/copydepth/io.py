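"""Readers and writers for the plain-text formats the pipeline speaks.

All intervals are BED-style: 0-based, half-open.  1-based input must be
converted by the caller — there is deliberately no auto-detection, to
avoid silent coordinate drift.  Missing genotypes are the literal string
"NA" in TSV output.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mappability import Locus

logger = logging.getLogger(__name__)


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(reference: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in reference.items()]
    SeqIO.write(records, str(path), "fasta")


def read_loci(path) -> List[Locus]:
    """Parse BED3+ loci; optional 4th column is the name, 6th the strand.

    Duplicate names are rejected; unsorted input is sorted with a warning.
    """
    loci: List[Locus] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            name = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "+"
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate locus name {name!r}")
            seen.add(name)
            loci.append(Locus(id=name, chrom=chrom, start=start, end=end, strand=strand))
    ordered = sorted(loci, key=lambda l: (l.chrom, l.start, l.end))
    if [l.id for l in ordered] != [l.id for l in loci]:
        warnings.warn(f"{path}: loci were not coordinate-sorted; sorting")
        loci = ordered
    return loci


def write_bed(intervals, path) -> None:
    """Write (chrom, start, end[, name]) tuples or Locus objects as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            if isinstance(iv, Locus):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{iv.strand}\n")
            else:
                fh.write("\t".join(str(x) for x in iv) + "\n")


def write_locus_table(loci: Sequence[Locus], path) -> None:
    """Per-locus annotation table: locus_id, chrom, start, end, u, gc."""
    pd.DataFrame(
        [
            {"locus_id": l.id, "chrom": l.chrom, "start": l.start, "end": l.end, "u": l.u, "gc": l.gc}
            for l in loci
        ]
    ).to_csv(path, sep="\t", index=False)


def extend_loci(
    loci: Sequence[Locus],
    upstream: int = 100,
    downstream: int = 2000,
    strand_aware: bool = True,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> List[Locus]:
    """Grow loci by flanking sequence (defaults: 100 nt 5', 2 kb 3').

    On the minus strand, 5' is the interval end; extensions are clamped
    at chromosome boundaries when sizes are given.
    """
    out = []
    for loc in loci:
        if strand_aware and loc.strand == "-":
            start, end = loc.start - downstream, loc.end + upstream
        else:
            start, end = loc.start - upstream, loc.end + downstream
        start = max(0, start)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[loc.chrom])
        out.append(Locus(id=loc.id, chrom=loc.chrom, start=start, end=end, strand=loc.strand))
    return out


def read_counts(path) -> pd.DataFrame:
    """Read a (sample_id, locus_id, D) TSV count table."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})
    missing = {"sample_id", "locus_id", "D"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_depths(depths: pd.DataFrame, path) -> None:
    depths.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_depths(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})


def calls_to_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Long call table -> loci x samples genotype matrix (nullable Int64)."""
    return calls.pivot(index="locus_id", columns="sample_id", values="cng").astype("Int64")


def write_genotype_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.sort_index().sort_index(axis=1).to_csv(path, sep="\t", na_rep="NA")


def read_genotype_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return df.astype("Int64")


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_vcf(
    calls: pd.DataFrame,
    loci: Sequence[Locus],
    path,
    source: str = "copydepth",
) -> None:
    """Symbolic <CNV> records with a per-sample integer copy-number field.

    One record per locus; genotype NA becomes a missing CN value.
    """
    matrix = calls_to_matrix(calls)
    samples = list(matrix.columns)
    by_id = {l.id: l for l in loci}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write('##ALT=<ID=CNV,Description="Copy-number variable region">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End of the interval">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of variant">\n')
        fh.write('##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Integer copy-number genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for locus_id in sorted(matrix.index, key=lambda i: (by_id[i].chrom, by_id[i].start)):
            loc = by_id[locus_id]
            cns = [
                "." if pd.isna(matrix.at[locus_id, s]) else str(int(matrix.at[locus_id, s]))
                for s in samples
            ]
            fh.write(
                f"{loc.chrom}\t{loc.start + 1}\t{locus_id}\tN\t<CNV>\t.\tPASS\t"
                f"END={loc.end};SVTYPE=CNV\tCN\t" + "\t".join(cns) + "\n"
            )


@dataclass
class RunConfig:
    """Pipeline-wide settings; round-trips through YAML unchanged."""

    k: int = 36
    min_u: int = 500
    q_threshold: float = 0.05
    lod_threshold: float = 0.0
    c_max: int = 10
    qc_cutoff: float = 0.01
    seed: int = 0
    out_dir: str = "."
    inputs: Dict[str, str] = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def log_settings(self) -> None:
        for key, val in dataclasses.asdict(self).items():
            logger.info("config %s = %r", key, val)
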