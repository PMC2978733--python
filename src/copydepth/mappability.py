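"""k-mer mappability maps and per-locus unique-position counts.

Read-depth genotyping only trusts reads whose start position falls on a
k-mer that occurs exactly once in the reference (counting both strands).
This module builds the per-position k-mer frequency map, derives the
count ``u`` of uniquely mappable read-start positions inside each locus,
and computes locus GC content over the mappable nucleotides.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_K = 36
DEFAULT_MIN_UNIQUE_KMERS = 500

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: bytes | str) -> bytes:
    if isinstance(seq, str):
        seq = seq.encode()
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Locus:
    """Genomic interval, 0-based half-open, with mappability annotations.

    ``u`` is the number of k-mer start positions inside the interval whose
    genome-wide frequency is exactly one; ``gc`` is the G+C fraction of the
    mappable nucleotides (union of unique k-mer footprints).
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    u: Optional[int] = None
    gc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"locus {self.id}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeKmerMap:
    """Per-position k-mer occurrence counts over a reference.

    ``freq[chrom][p]`` is the number of exact occurrences of the k-mer
    starting at forward-strand position ``p``, summed over both strands
    (forward occurrences plus forward occurrences of its reverse
    complement).  k-mers containing N are unmappable and carry frequency 0.
    """

    k: int
    freq: Dict[str, np.ndarray] = field(default_factory=dict)

    def unique_mask(self, chrom: str) -> np.ndarray:
        return self.freq[chrom] == 1


def build_kmer_map(reference: Mapping[str, str], k: int) -> GenomeKmerMap:
    """Count genome-wide occurrences of every k-mer on both strands.

    A position's frequency is the forward-strand occurrence count of its
    k-mer plus that of the k-mer's reverse complement, so palindromic
    k-mers always have frequency >= 2 and frequency 1 means the read start
    is strand-unambiguous.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = {name: str(seq).upper().encode() for name, seq in reference.items()}
    counts: Counter = Counter()
    for s in seqs.values():
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if b"N" not in kmer:
                counts[kmer] += 1
    if not counts and any(len(s) >= k for s in seqs.values()):
        # sequences long enough but all k-mers ambiguous
        warnings.warn("no mappable k-mers in reference (all contain N)")
    if all(len(s) < k for s in seqs.values()):
        warnings.warn(f"k={k} exceeds every sequence length; empty mappability map")

    freq: Dict[str, np.ndarray] = {}
    for name, s in seqs.items():
        n = len(s) - k + 1
        arr = np.zeros(max(n, 0), dtype=np.int64)
        for i in range(n):
            kmer = s[i : i + k]
            if b"N" in kmer:
                continue
            arr[i] = counts[kmer] + counts[reverse_complement(kmer)]
        freq[name] = arr
    return GenomeKmerMap(k=k, freq=freq)


def count_unique_starts(locus: Locus, kmap: GenomeKmerMap) -> int:
    """Number of unique k-mer start positions fully inside the locus."""
    if locus.chrom not in kmap.freq:
        raise KeyError(f"chromosome {locus.chrom!r} absent from mappability map")
    if locus.length < kmap.k:
        return 0
    f = kmap.freq[locus.chrom]
    lo = locus.start
    hi = min(locus.end - kmap.k, len(f) - 1)
    if hi < lo:
        return 0
    return int(np.count_nonzero(f[lo : hi + 1] == 1))


def mappable_base_mask(locus: Locus, kmap: GenomeKmerMap) -> np.ndarray:
    """Boolean mask over locus bases covered by >=1 unique k-mer footprint."""
    k = kmap.k
    mask = np.zeros(locus.length, dtype=bool)
    if locus.length < k or locus.chrom not in kmap.freq:
        return mask
    f = kmap.freq[locus.chrom]
    hi = min(locus.end - k, len(f) - 1)
    for p in range(locus.start, hi + 1):
        if f[p] == 1:
            mask[p - locus.start : p - locus.start + k] = True
    return mask


def locus_gc(locus: Locus, reference: Mapping[str, str], kmap: Optional[GenomeKmerMap] = None) -> float:
    """G+C fraction of the locus, over mappable nucleotides when a map is given.

    Falls back to all unambiguous bases when the locus has no unique k-mer.
    """
    seq = str(reference[locus.chrom]).upper()[locus.start : locus.end]
    arr = np.frombuffer(seq.encode(), dtype="S1")
    if kmap is not None:
        mask = mappable_base_mask(locus, kmap)
        if mask.any():
            arr = arr[mask]
    acgt = np.isin(arr, [b"A", b"C", b"G", b"T"])
    if not acgt.any():
        return 0.0
    gc = np.isin(arr, [b"G", b"C"])
    return float(gc.sum() / acgt.sum())


def annotate_loci(
    loci: Iterable[Locus], reference: Mapping[str, str], kmap: GenomeKmerMap
) -> List[Locus]:
    """Fill ``u`` and ``gc`` on each locus in place; returns the list."""
    out = list(loci)
    for loc in out:
        loc.u = count_unique_starts(loc, kmap)
        loc.gc = locus_gc(loc, reference, kmap)
    return out


def filter_low_mappability(
    loci: Sequence[Locus], min_u: int = DEFAULT_MIN_UNIQUE_KMERS
) -> Tuple[List[Locus], List[Locus]]:
    """Split loci into (kept, excluded) at u >= min_u ("at least" semantics)."""
    kept, excluded = [], []
    for loc in loci:
        if loc.u is None:
            raise ValueError(f"locus {loc.id}: u not computed; call annotate_loci first")
        (kept if loc.u >= min_u else excluded).append(loc)
    for loc in excluded:
        logger.info("excluding locus %s: u=%d < %d", loc.id, loc.u, min_u)
    return kept, excluded


def unique_intervals(kmap: GenomeKmerMap) -> List[Tuple[str, int, int]]:
    """Maximal runs of frequency-1 start positions, as 0-based half-open intervals."""
    out: List[Tuple[str, int, int]] = []
    for chrom in sorted(kmap.freq):
        mask = kmap.freq[chrom] == 1
        if mask.size == 0:
            continue
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append((chrom, int(s), int(e)))
    return out
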