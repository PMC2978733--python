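"""Synthetic data with the noise structure the genotyper assumes.

Counts for a locus with baseline expected depth E2 and genotype m are
drawn gamma-Poisson (negative binomial) with mean

    lambda = (m/2) * E2 * (1 + gc_bias(gc)) * (1 + eps),
    eps ~ Normal(0, sigma2_bg) truncated at -1,

and count variance alpha*lambda, so the read-depth ratio has mean m/2
and, at the baseline genotype, variance alpha/E2 + sigma2_bg — the exact
decomposition the variance model estimates.  alpha = 1 falls back to
plain Poisson (the gamma-Poisson mixture cannot under-disperse).

Defaults emulate the study conditions of low-coverage human resequencing:
150 samples, ~3 kb loci at about 67 expected reads per kb (E2 ~ 200 for
a 3 kb locus), alpha = 2.5 (mid of the ~1-4 range seen on real data) and
sigma2_bg = 0.002.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mappability import Locus

DEFAULT_ALPHA = 2.5
DEFAULT_SIGMA2_BG = 0.002
DEFAULT_DEPTH_PER_KB = 200.0 / 3.0  # E2 ~ 200 for a 3 kb locus


@dataclass
class SimLocus:
    id: str
    length: int
    gc: float
    E2: float  # expected baseline depth at genotype 2


@dataclass
class SimConfig:
    n_samples: int
    loci: List[SimLocus]
    genotypes: np.ndarray  # loci x samples, integers
    seed: int
    alpha: float = DEFAULT_ALPHA
    sigma2_bg: float = DEFAULT_SIGMA2_BG
    gc_bias: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        if self.genotypes.shape != (len(self.loci), self.n_samples):
            raise ValueError("genotype matrix must be loci x samples")
        if self.sigma2_bg < 0:
            raise ValueError("sigma2_bg must be >= 0")
        if np.any(self.genotypes < 0):
            raise ValueError("genotypes must be >= 0")


@dataclass
class TruthSet:
    genotypes: pd.DataFrame  # loci x samples
    counts: pd.DataFrame
    config: SimConfig


def _overdispersed_counts(rng: np.random.Generator, lam: np.ndarray, alpha: float) -> np.ndarray:
    """Counts with mean lam and variance alpha*lam (NB; Poisson at alpha=1)."""
    lam = np.maximum(lam, 0.0)
    if alpha < 1:
        warnings.warn("alpha < 1 cannot be realized by a gamma-Poisson mixture; using plain Poisson")
        alpha = 1.0
    if alpha == 1.0:
        return rng.poisson(lam)
    p = 1.0 / alpha
    n = lam * p / (1.0 - p)  # = lam / (alpha - 1)
    out = np.zeros_like(lam, dtype=np.int64)
    pos = lam > 0
    out[pos] = rng.negative_binomial(n[pos], p)
    return out


def simulate_counts(config: SimConfig) -> Tuple[pd.DataFrame, TruthSet]:
    """Draw the per-(sample, locus) count table and its ground truth.

    Deterministic given the config (seeded generator; no global state).
    The returned table carries D, the baseline expectation E, and the raw
    ratio r_raw = D/E (GC bias, if any, still in it).
    """
    rng = np.random.default_rng(config.seed)
    n_loci = len(config.loci)
    E2 = np.array([l.E2 for l in config.loci], dtype=float)
    gc = np.array([l.gc for l in config.loci], dtype=float)
    bias = config.gc_bias(gc) if config.gc_bias is not None else np.zeros(n_loci)

    lam = (config.genotypes / 2.0) * (E2 * (1.0 + bias))[:, None]
    eps = rng.normal(0.0, np.sqrt(config.sigma2_bg), size=lam.shape) if config.sigma2_bg > 0 else np.zeros_like(lam)
    eps = np.maximum(eps, -1.0)  # counts stay >= 0
    D = _overdispersed_counts(rng, lam * (1.0 + eps), config.alpha)

    locus_ids = [l.id for l in config.loci]
    sample_ids = [f"S{j:03d}" for j in range(config.n_samples)]
    counts = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, n_loci),
            "locus_id": np.tile(locus_ids, config.n_samples),
            "D": D.T.ravel(),
            "E": np.tile(E2, config.n_samples),
            "gc": np.tile(gc, config.n_samples),
        }
    )
    counts["r_raw"] = counts["D"] / counts["E"]
    truth = TruthSet(
        genotypes=pd.DataFrame(config.genotypes, index=locus_ids, columns=sample_ids),
        counts=counts,
        config=config,
    )
    return counts, truth


def uniform_loci(
    n_loci: int,
    length: int = 3000,
    gc_range: Tuple[float, float] = (0.3, 0.6),
    depth_per_kb: float = DEFAULT_DEPTH_PER_KB,
    seed: int | None = None,
) -> List[SimLocus]:
    """Convenience locus set: fixed length, GC uniform over a plausible range."""
    rng = np.random.default_rng(seed)
    gcs = rng.uniform(*gc_range, size=n_loci)
    E2 = depth_per_kb * length / 1000.0
    return [SimLocus(id=f"L{i:04d}", length=length, gc=float(g), E2=E2) for i, g in enumerate(gcs)]


def genotypes_from_allele_freq(
    n_loci: int,
    n_samples: int,
    variant_freq: float,
    kind: str = "deletion",
    seed: int | None = None,
) -> np.ndarray:
    """Hardy-Weinberg genotype matrix for bi-allelic loci.

    Each sample draws two alleles; deletions map (vv, vr, rr) -> (0, 1, 2),
    duplications -> (4, 3, 2).
    """
    rng = np.random.default_rng(seed)
    n_variant = rng.binomial(2, variant_freq, size=(n_loci, n_samples))
    if kind == "deletion":
        return 2 - n_variant
    if kind == "duplication":
        return 2 + n_variant
    raise ValueError("kind must be 'deletion' or 'duplication'")


def simulate_trio(
    variant_freqs: Sequence[float],
    kinds: Sequence[str],
    seed: int,
) -> pd.DataFrame:
    """Mendelian-consistent trio genotypes at bi-allelic loci.

    Parents draw allele pairs from the variant frequency; the child
    inherits one uniformly chosen allele from each parent.  Returns a
    table with father/mother/child genotypes and the locus kind.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, (f, kind) in enumerate(zip(variant_freqs, kinds)):
        if kind not in ("deletion", "duplication"):
            raise ValueError("kinds must be 'deletion' or 'duplication'")
        father = rng.random(2) < f
        mother = rng.random(2) < f
        child = np.array([father[rng.integers(2)], mother[rng.integers(2)]])

        def to_cng(pair):
            nv = int(pair.sum())
            return 2 - nv if kind == "deletion" else 2 + nv

        rows.append(
            {
                "locus_id": f"T{i:04d}",
                "kind": kind,
                "father": to_cng(father),
                "mother": to_cng(mother),
                "child": to_cng(child),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GenomeSim:
    reference: Dict[str, str]
    loci: List[Locus]
    read_starts: Dict[str, Dict[str, np.ndarray]]  # sample -> chrom -> positions
    N: Dict[str, int]  # genome-wide uniquely aligned read totals per sample
    G: int
    truth: pd.DataFrame  # loci x samples genotype matrix


def simulate_genome(
    genome_length: int = 1_000_000,
    n_loci: int = 100,
    locus_length: int = 3000,
    n_samples: int = 4,
    k: int = 36,
    target_E2: float = 200.0,
    c_max_truth: int = 4,
    alpha: float = 1.0,
    sigma2_bg: float = DEFAULT_SIGMA2_BG,
    duplications: Optional[Sequence[Tuple[int, int, int]]] = None,
    seed: int = 0,
    chrom: str = "chrS",
) -> GenomeSim:
    """End-to-end fixture: random genome, loci, and per-sample read starts.

    Planted genotypes are uniform over {0..c_max_truth}.  Read starts are
    placed on uniquely mappable positions inside each locus with counts
    from the gamma-Poisson model, so the full pipeline (FASTA -> k-mer
    map -> depths -> genotypes) can run against known truth.
    ``duplications`` is a list of (src_start, length, dest_start) exact
    copies pasted into the genome to create non-unique k-mers.
    """
    from .mappability import annotate_loci, build_kmer_map

    if genome_length > 5_000_000:
        raise ValueError("genome fixture limited to 5 Mb")
    rng = np.random.default_rng(seed)
    genome = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=genome_length)
    for src, length, dest in duplications or []:
        if src + length > genome_length or dest + length > genome_length:
            raise ValueError("duplication exceeds genome size")
        genome[dest : dest + length] = genome[src : src + length]
    seq = genome.tobytes().decode()
    reference = {chrom: seq}

    spacing = genome_length // n_loci
    if spacing < locus_length:
        raise ValueError("loci do not fit into the genome")
    loci = [
        Locus(id=f"L{i:04d}", chrom=chrom, start=i * spacing, end=i * spacing + locus_length)
        for i in range(n_loci)
    ]
    kmap = build_kmer_map(reference, k)
    annotate_loci(loci, reference, kmap)

    G = genome_length
    mean_u = float(np.mean([l.u for l in loci])) or 1.0
    N_target = int(round(target_E2 * G / mean_u))

    truth = rng.integers(0, c_max_truth + 1, size=(n_loci, n_samples))
    sample_ids = [f"S{j:03d}" for j in range(n_samples)]
    read_starts: Dict[str, Dict[str, np.ndarray]] = {}
    f = kmap.freq[chrom]
    for j, sid in enumerate(sample_ids):
        positions: List[np.ndarray] = []
        for i, loc in enumerate(loci):
            if loc.u == 0:
                continue
            E2 = loc.u * N_target / G
            lam = (truth[i, j] / 2.0) * E2
            eps = max(rng.normal(0.0, np.sqrt(sigma2_bg)), -1.0) if sigma2_bg > 0 else 0.0
            D = int(_overdispersed_counts(rng, np.array([lam * (1 + eps)]), alpha)[0])
            if D == 0:
                continue
            uniq = np.flatnonzero(f[loc.start : loc.end - k + 1] == 1) + loc.start
            positions.append(rng.choice(uniq, size=D, replace=True))
        allpos = np.sort(np.concatenate(positions)) if positions else np.array([], dtype=np.int64)
        read_starts[sid] = {chrom: allpos}
    return GenomeSim(
        reference=reference,
        loci=loci,
        read_starts=read_starts,
        N={sid: N_target for sid in sample_ids},
        G=G,
        truth=pd.DataFrame(truth, index=[l.id for l in loci], columns=sample_ids),
    )
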