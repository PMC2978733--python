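"""Population-genetic summaries over integer copy-number genotype calls.

Covers locus classification (non-variable / bi-allelic deletion or
duplication / multi-allelic), allele-frequency estimation with Wilson
confidence intervals, inter-individual genotype-difference statistics,
trio Mendelian-consistency checks, a label-permutation enrichment test,
merging of adjacent same-direction calls into candidate large events,
boundary substitution from external breakpoint sets, and the exact-match
concordance metric used to compare two call sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.proportion import proportion_confint

from .mappability import Locus

NON_VARIABLE = "non-variable"
BIALLELIC_DELETION = "bi-allelic deletion"
BIALLELIC_DUPLICATION = "bi-allelic duplication"
MULTI_ALLELIC = "multi-allelic"


@dataclass
class LocusClassification:
    label: str
    genotype_counts: Dict[int, int]
    variant_freq: Optional[float] = None
    ref_freq: Optional[float] = None
    ci95: Optional[Tuple[float, float]] = None


def _clean(genotypes) -> np.ndarray:
    g = pd.array(genotypes)
    g = g[~pd.isna(g)]
    return np.asarray(g, dtype=int)


def classify_locus(genotypes) -> LocusClassification:
    """Classify a locus from its observed genotype multiset.

    All 2 -> non-variable; within {0,1,2} with a value below 2 ->
    bi-allelic deletion; within {2,3,4} with a value above 2 ->
    bi-allelic duplication; anything else (both directions present, or
    any genotype >= 5) -> multi-allelic.  NA entries are dropped first.
    """
    g = _clean(genotypes)
    if g.size == 0:
        raise ValueError("no genotypes to classify")
    vals = set(g.tolist())
    counts = {int(v): int(n) for v, n in zip(*np.unique(g, return_counts=True))}
    if vals == {2}:
        label = NON_VARIABLE
    elif vals <= {0, 1, 2}:
        label = BIALLELIC_DELETION
    elif vals <= {2, 3, 4}:
        label = BIALLELIC_DUPLICATION
    else:
        label = MULTI_ALLELIC
    return LocusClassification(label=label, genotype_counts=counts)


def allele_freq_biallelic(genotypes) -> Tuple[float, float, Tuple[float, float]]:
    """Variant/reference allele frequency of a bi-allelic locus.

    Deletion loci: variant count = 2*#(cng 0) + #(cng 1); duplication
    loci: 2*#(cng 4) + #(cng 3).  The 95% CI on the reference frequency
    is a Wilson interval (well-behaved at extreme frequencies).
    """
    g = _clean(genotypes)
    cls = classify_locus(g)
    if cls.label not in (BIALLELIC_DELETION, BIALLELIC_DUPLICATION, NON_VARIABLE):
        raise ValueError(f"locus is {cls.label}; allele counting is only defined for bi-allelic loci")
    n_alleles = 2 * g.size
    c = cls.genotype_counts
    if cls.label == BIALLELIC_DUPLICATION:
        variant = 2 * c.get(4, 0) + c.get(3, 0)
    else:
        variant = 2 * c.get(0, 0) + c.get(1, 0)
    variant_freq = variant / n_alleles
    ref_count = n_alleles - variant
    lo, hi = proportion_confint(ref_count, n_alleles, alpha=0.05, method="wilson")
    return variant_freq, 1.0 - variant_freq, (float(lo), float(hi))


def ref_freq_multiallelic(genotypes, estimator: str = "sqrt") -> float:
    """Reference allele frequency of a multi-allelic locus.

    Assumes samples at genotype 2 are homozygous reference; under random
    mating the homozygote fraction p2 gives allele frequency sqrt(p2)
    (``estimator='sqrt'``, default).  ``estimator='p2'`` reports the raw
    homozygote fraction instead.
    """
    g = _clean(genotypes)
    if g.size == 0:
        raise ValueError("no genotypes")
    p2 = float(np.mean(g == 2))
    if estimator == "sqrt":
        return float(np.sqrt(p2))
    if estimator == "p2":
        return p2
    raise ValueError("estimator must be 'sqrt' or 'p2'")


def pairwise_diff(matrix: pd.DataFrame) -> pd.DataFrame:
    """L1 distance between samples: d(s,t) = sum over loci |g_s - g_t|.

    ``matrix`` is loci x samples.  Rows with any NA are dropped so every
    pair is compared over the same loci.
    """
    m = matrix.dropna(axis=0)
    x = m.to_numpy(dtype=float).T
    d = squareform(pdist(x, metric="cityblock"))
    return pd.DataFrame(d, index=m.columns, columns=m.columns)


def ranked_cumulative_diff(matrix: pd.DataFrame) -> pd.DataFrame:
    """Share of inter-individual difference carried by the commonest CNVs.

    Loci are ranked by CNV frequency (fraction of samples with genotype
    != 2); the rarest frequency class is dropped at each step and the
    mean pairwise difference recomputed, expressed as % of the full-set
    mean.  Returns columns pct_loci_kept (of variable loci) and
    pct_max_diff.
    """
    m = matrix.dropna(axis=0)
    freq = (m != 2).mean(axis=1)
    variable = m.loc[freq > 0]
    freq = freq.loc[variable.index]
    n_var = len(variable)
    if n_var == 0:
        return pd.DataFrame({"pct_loci_kept": [0.0], "pct_max_diff": [0.0]})
    max_mean = _mean_pairwise(variable)
    levels = np.sort(freq.unique())
    rows = [{"pct_loci_kept": 100.0, "pct_max_diff": 100.0}]
    kept = variable
    for lvl in levels[:-1]:
        kept = kept.loc[freq.loc[kept.index] > lvl]
        rows.append(
            {
                "pct_loci_kept": 100.0 * len(kept) / n_var,
                "pct_max_diff": 100.0 * _mean_pairwise(kept) / max_mean if max_mean > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _mean_pairwise(matrix: pd.DataFrame) -> float:
    if matrix.shape[0] == 0:
        return 0.0
    d = pdist(matrix.to_numpy(dtype=float).T, metric="cityblock")
    return float(d.mean()) if d.size else 0.0


_DELETION_PAIRS = {0: ("v", "v"), 1: ("v", "r"), 2: ("r", "r")}
_DUPLICATION_PAIRS = {2: ("r", "r"), 3: ("v", "r"), 4: ("v", "v")}


def mendelian_check(father_cng: int, mother_cng: int, child_cng: int, kind: str) -> bool:
    """Mendelian consistency of a trio at a bi-allelic locus.

    ``kind`` is 'deletion' (0=vv, 1=vr, 2=rr) or 'duplication'
    (2=rr, 3=vr, 4=vv).  Consistent iff some choice of one allele from
    each parent reproduces the child's unordered pair.
    """
    if kind == "deletion":
        pairs = _DELETION_PAIRS
    elif kind == "duplication":
        pairs = _DUPLICATION_PAIRS
    else:
        raise ValueError("ambiguous decomposition: kind must be 'deletion' or 'duplication'")
    try:
        f, m, c = pairs[father_cng], pairs[mother_cng], pairs[child_cng]
    except KeyError as exc:
        raise ValueError(f"genotype {exc} not decomposable at a bi-allelic {kind} locus")
    child = tuple(sorted(c))
    for a in set(f):
        for b in set(m):
            if tuple(sorted((a, b))) == child:
                return True
    return False


def permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 1000,
    seed: int | None = None,
) -> Tuple[float, float]:
    """Two-sided label-permutation test on the difference of group means.

    Returns (t_observed, p).  p is the proportion of sampled label
    permutations whose |mean(A*) - mean(B*)| >= |t_observed|.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t_obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        t = perm[: a.size].mean() - perm[a.size :].mean()
        if abs(t) >= abs(t_obs) - 1e-12:
            hits += 1
    return float(t_obs), hits / n_perm


@dataclass
class MergedEvent:
    direction: str  # 'deletion' or 'duplication'
    first_index: int
    last_index: int
    locus_ids: List[str]

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def multi_locus(self) -> bool:
        return self.n_loci > 1


def merge_adjacent_calls(locus_ids: Sequence[str], genotypes) -> List[MergedEvent]:
    """Merge runs of adjacent same-direction CNV calls into events.

    Input loci must be ordered by genomic coordinate within one annotated
    cluster.  A maximal run of adjacent deletions (cng < 2) or
    duplications (cng > 2) becomes one event; reference or NA calls break
    runs.
    """
    g = pd.array(genotypes)
    if len(locus_ids) != len(g):
        raise ValueError("locus_ids and genotypes must align")
    events: List[MergedEvent] = []
    current: Optional[MergedEvent] = None
    for i, (lid, cng) in enumerate(zip(locus_ids, g)):
        if pd.isna(cng) or cng == 2:
            direction = None
        else:
            direction = "deletion" if cng < 2 else "duplication"
        if direction is None:
            current = None
        elif current is not None and current.direction == direction:
            current.last_index = i
            current.locus_ids.append(lid)
        else:
            current = MergedEvent(direction, i, i, [lid])
            events.append(current)
    return events


def substitute_boundaries(
    loci: Sequence[Locus],
    breakpoints: Sequence[Tuple[str, int, int]],
    min_reciprocal_overlap: float = 0.51,
) -> List[Locus]:
    """Replace locus intervals by externally determined breakpoint intervals.

    A locus is substituted by the breakpoint interval with which it has
    the largest reciprocal overlap, provided both overlap fractions
    exceed ``min_reciprocal_overlap`` (default >51%).  Ties between
    candidates keep the original locus with a warning.
    """
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in breakpoints:
        if e <= s:
            raise ValueError(f"degenerate breakpoint interval {chrom}:{s}-{e}")
        by_chrom.setdefault(chrom, []).append((s, e))
    out: List[Locus] = []
    for loc in loci:
        best_score, best_iv, tie = 0.0, None, False
        for s, e in by_chrom.get(loc.chrom, []):
            ov = min(loc.end, e) - max(loc.start, s)
            if ov <= 0:
                continue
            frac_locus = ov / loc.length
            frac_bp = ov / (e - s)
            if frac_locus <= min_reciprocal_overlap or frac_bp <= min_reciprocal_overlap:
                continue
            score = min(frac_locus, frac_bp)
            if score > best_score:
                best_score, best_iv, tie = score, (s, e), False
            elif score == best_score and best_iv is not None and (s, e) != best_iv:
                tie = True
        if best_iv is not None and not tie:
            out.append(
                Locus(id=loc.id, chrom=loc.chrom, start=best_iv[0], end=best_iv[1], strand=loc.strand)
            )
        else:
            if tie:
                warnings.warn(f"locus {loc.id}: multiple equally good breakpoint candidates; kept original")
            out.append(loc)
    return out


def concordance(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> float:
    """Fraction of jointly genotyped cells with exactly identical integer calls.

    Matrices are aligned on shared index/columns; NA cells in either are
    excluded from numerator and denominator.
    """
    idx = calls_a.index.intersection(calls_b.index)
    cols = calls_a.columns.intersection(calls_b.columns)
    a = calls_a.loc[idx, cols]
    b = calls_b.loc[idx, cols]
    mask = a.notna() & b.notna()
    n = int(mask.to_numpy().sum())
    if n == 0:
        raise ValueError("no jointly genotyped cells")
    equal = (a == b) & mask
    return float(equal.to_numpy().sum() / n)
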