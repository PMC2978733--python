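"""Observed and expected locus read-depths and raw read-depth ratios.

The observed depth D of a locus is the number of uniquely aligned reads
whose start position falls on a frequency-1 k-mer start inside the locus.
The expected depth at baseline (diploid) copy number is E = u * N / G,
where u is the locus's count of uniquely mappable start positions, N the
sample's genome-wide count of uniquely aligned reads, and G the genome
size.  The raw read-depth ratio r_raw = D / E has expectation m/2 at
copy-number genotype m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mappability import GenomeKmerMap, Locus

#: hg18 genome size excluding the mitochondrial genome, as used for human data.
HG18_GENOME_SIZE = 2_858_018_193


@dataclass
class SampleProfile:
    """Per-sample sequencing summary.

    N is the genome-wide number of uniquely aligned (deduplicated) reads;
    G the genome size in nucleotides.  The expected per-locus depth scales
    as u*N/G.
    """

    sample_id: str
    N: int
    G: int = HG18_GENOME_SIZE

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.G <= 0:
            raise ValueError("G must be > 0")


def observed_depth(
    read_starts: Mapping[str, np.ndarray] | np.ndarray,
    locus: Locus,
    kmap: GenomeKmerMap,
) -> int:
    """Count reads starting on unique k-mer positions inside the locus.

    ``read_starts`` maps chromosome -> array of alignment start positions
    (0-based); a bare array is taken to be on the locus's chromosome.
    Reads on chromosomes absent from the map are ignored.
    """
    if isinstance(read_starts, Mapping):
        starts = read_starts.get(locus.chrom)
        if starts is None:
            return 0
    else:
        starts = read_starts
    if locus.chrom not in kmap.freq:
        return 0
    f = kmap.freq[locus.chrom]
    starts = np.asarray(starts, dtype=np.int64)
    hi = min(locus.end - kmap.k, len(f) - 1)
    sel = starts[(starts >= locus.start) & (starts <= hi)]
    return int(np.count_nonzero(f[sel] == 1))


def expected_depth(u: int, N: int, G: int) -> float:
    """Expected read count on the locus's unique positions at baseline copy number."""
    if u <= 0:
        raise ValueError("locus unmappable (u = 0)")
    if N <= 0 or G <= 0:
        raise ValueError("N and G must be positive")
    return u * N / G


def raw_rdr(D: int, E: float) -> float:
    """Raw read-depth ratio D/E; expectation m/2 at copy-number genotype m."""
    if E <= 0:
        raise ValueError("expected depth must be positive")
    return D / E


def depth_table(
    read_starts_by_sample: Mapping[str, Mapping[str, np.ndarray]],
    loci: Sequence[Locus],
    kmap: GenomeKmerMap,
    profiles: Mapping[str, SampleProfile],
) -> pd.DataFrame:
    """Per-(sample, locus) table of D, E and r_raw from read start positions."""
    rows = []
    for sample_id, starts in read_starts_by_sample.items():
        prof = profiles[sample_id]
        for loc in loci:
            if loc.u is None:
                raise ValueError(f"locus {loc.id}: u not computed")
            D = observed_depth(starts, loc, kmap)
            E = expected_depth(loc.u, prof.N, prof.G)
            rows.append(
                {
                    "sample_id": sample_id,
                    "locus_id": loc.id,
                    "D": D,
                    "E": E,
                    "r_raw": raw_rdr(D, E),
                }
            )
    return pd.DataFrame(rows)


def depths_from_counts(
    counts: pd.DataFrame,
    loci: Sequence[Locus],
    profiles: Mapping[str, SampleProfile],
) -> pd.DataFrame:
    """Build the depth table from a (sample_id, locus_id, D) count table.

    Bypasses alignment parsing entirely; loci must carry ``u``.
    """
    u_by_id = {}
    for loc in loci:
        if loc.u is None:
            raise ValueError(f"locus {loc.id}: u not computed")
        u_by_id[loc.id] = loc.u
    df = counts.copy()
    unknown = set(df["locus_id"]) - set(u_by_id)
    if unknown:
        raise KeyError(f"count table references unknown loci: {sorted(unknown)[:5]}")
    df["E"] = [
        expected_depth(u_by_id[l], profiles[s].N, profiles[s].G)
        for s, l in zip(df["sample_id"], df["locus_id"])
    ]
    df["r_raw"] = df["D"] / df["E"]
    return df[["sample_id", "locus_id", "D", "E", "r_raw"]]


def read_sam_read_starts(
    path: str, min_mapq: int = 1
) -> Tuple[Dict[str, np.ndarray], int]:
    """Extract uniquely mapped, non-duplicate primary read starts from SAM/BAM.

    Mapping quality >= ``min_mapq`` is the uniqueness proxy for aligners that
    assign MAPQ 0 to multi-mappers.  Returns (starts by chromosome, total N).
    """
    import pysam

    starts: Dict[str, list] = {}
    n = 0
    with pysam.AlignmentFile(path) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_duplicate or rec.mapping_quality < min_mapq:
                continue
            starts.setdefault(rec.reference_name, []).append(rec.reference_start)
            n += 1
    return {c: np.array(v, dtype=np.int64) for c, v in starts.items()}, n
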