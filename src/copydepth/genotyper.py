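"""Two-stage copy-number genotyping.

Stage 1 (*CNV identification*) tests, for every (locus, sample) pair,
the null hypothesis that the GC-adjusted read-depth ratio comes from the
baseline genotype 2 (mean 1), via a z-statistic whose variance comes
from the calibrated variance model.  Two-sided normal p-values are
corrected once, globally, by Benjamini-Hochberg FDR; pairs whose
Q-value is not below the threshold (default 5%) keep genotype 2.

Stage 2 (*copy-number inference*) assigns significant pairs the integer
genotype m in {0..c_max} maximizing the posterior under Gaussian
likelihoods N(m/2, sigma2_m) and a uniform prior.  Confidence is a LOD
score: log10 of the ratio between the best and second-best posterior
(LOD 2 means a 100-fold margin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .variance import VarianceModel, sigma2_for

DEFAULT_Q_THRESHOLD = 0.05
DEFAULT_C_MAX = 10
LOD_CAP = 300.0

_TINY_VAR = 1e-30  # floor so a zero-variance genotype density degenerates gracefully


@dataclass
class GenotypeModel:
    """Gaussian classifier over integer genotypes {0..c_max}.

    Means follow the ratio ladder mu_m = m/2; the prior is uniform,
    p(C_m) = 1/(c_max+1) — a neutral choice that needs no training data.
    """

    c_max: int = DEFAULT_C_MAX

    def __post_init__(self) -> None:
        if self.c_max < 2:
            raise ValueError("c_max must be >= 2 to include the baseline genotype")

    @property
    def genotypes(self) -> np.ndarray:
        return np.arange(self.c_max + 1)

    @property
    def prior(self) -> np.ndarray:
        return np.full(self.c_max + 1, 1.0 / (self.c_max + 1))

    def mu(self, m) -> np.ndarray:
        return np.asarray(m) / 2.0


def z_score(r_adj: float, E2: float, model: VarianceModel) -> float:
    """Deviation of the adjusted ratio from the baseline mean 1, in null SDs."""
    var = sigma2_for(E2, 2, model)
    if var <= 0:
        raise ValueError("null variance is zero; cannot standardize")
    return (r_adj - 1.0) / np.sqrt(var)


def p_value(z) -> float:
    """Two-sided p-value from the standard normal: p = 2*(1 - Phi(|z|))."""
    return 2.0 * stats.norm.sf(np.abs(z))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (Q-values), input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def identify_cnv(q, q_threshold: float = DEFAULT_Q_THRESHOLD):
    """CNV flag: strictly q < threshold (a pair exactly at the threshold is not a CNV)."""
    return np.asarray(q) < q_threshold


def _log_posteriors(
    r_adj: np.ndarray, E2: np.ndarray, vmodel: VarianceModel, gmodel: GenotypeModel
) -> np.ndarray:
    """Log posterior matrix, one row per observation, one column per genotype."""
    m = gmodel.genotypes
    var = vmodel.alpha * (m / 2.0) / np.asarray(E2, dtype=float)[:, None] + vmodel.sigma2_bg
    var = np.maximum(var, _TINY_VAR)
    mu = gmodel.mu(m)[None, :]
    x = np.asarray(r_adj, dtype=float)[:, None]
    loglik = -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)
    # uniform prior: constant in m, cancels in the normalization
    return loglik - logsumexp(loglik, axis=1, keepdims=True)


def map_genotype(
    r_adj: float, E2: float, vmodel: VarianceModel, gmodel: GenotypeModel
) -> Tuple[int, np.ndarray]:
    """MAP genotype and normalized posterior vector for one observation.

    Densities are evaluated in log space and normalized by log-sum-exp;
    exact posterior ties resolve to the lower genotype.
    """
    if E2 <= 0:
        raise ValueError("E2 must be > 0")
    lp = _log_posteriors(np.array([r_adj]), np.array([E2]), vmodel, gmodel)[0]
    return int(np.argmax(lp)), np.exp(lp)


def lod_score(posteriors: Sequence[float], cap: float = LOD_CAP) -> float:
    """log10 ratio of the best to the second-best genotype posterior.

    Capped (default 300) when the second-best probability underflows to 0.
    """
    p = np.asarray(posteriors, dtype=float)
    if p.size < 2:
        raise ValueError("need at least two genotype posteriors")
    top2 = np.partition(p, -2)[-2:]
    second, best = top2
    if second <= 0:
        return cap
    return float(min(np.log10(best / second), cap))


def _lod_from_logpost(lp: np.ndarray, cap: float = LOD_CAP) -> np.ndarray:
    """Row-wise LOD from a log-posterior matrix (underflow-safe)."""
    srt = np.sort(lp, axis=1)
    lod = (srt[:, -1] - srt[:, -2]) / np.log(10)
    return np.minimum(lod, cap)


def genotype_run(
    depths: pd.DataFrame,
    vmodel: VarianceModel,
    gmodel: GenotypeModel | None = None,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    lod_threshold: float = 0.0,
) -> pd.DataFrame:
    """Genotype every (locus, sample) pair of an adjusted depth table.

    ``depths`` needs columns sample_id, locus_id, E (baseline expected
    depth) and r_adj.  BH correction is applied once across all tests in
    the run.  Non-significant pairs keep genotype 2 (z, p, q recorded,
    no MAP evaluation).  Significant pairs get the MAP genotype; calls
    with LOD <= ``lod_threshold`` are masked to NA but retain their
    posterior summary.  A significant pair whose MAP is nonetheless 2 is
    reported as genotype 2 with its is_cnv flag kept — the conflict is
    surfaced, not hidden.  Output is ordered by (locus_id, sample_id).
    """
    if gmodel is None:
        gmodel = GenotypeModel()
    required = {"sample_id", "locus_id", "E", "r_adj"}
    missing = required - set(depths.columns)
    if missing:
        raise ValueError(f"depth table missing columns: {sorted(missing)}")

    df = depths.sort_values(["locus_id", "sample_id"], kind="stable").reset_index(drop=True)
    E2 = df["E"].to_numpy(dtype=float)
    r = df["r_adj"].to_numpy(dtype=float)

    var0 = vmodel.alpha / E2 + vmodel.sigma2_bg  # sigma2_for at genotype 2, vectorized
    if np.any(var0 <= 0) or np.any(E2 <= 0):
        raise ValueError("non-positive null variance or expected depth")
    z = (r - 1.0) / np.sqrt(var0)
    p = p_value(z)
    q = bh_fdr(p)
    is_cnv = identify_cnv(q, q_threshold)

    cng = np.full(len(df), 2, dtype=object)
    lod = np.full(len(df), np.nan)
    post_best = np.full(len(df), np.nan)

    if is_cnv.any():
        lp = _log_posteriors(r[is_cnv], E2[is_cnv], vmodel, gmodel)
        map_g = np.argmax(lp, axis=1)
        lod_sig = _lod_from_logpost(lp)
        best_sig = np.exp(np.max(lp, axis=1))
        n_conflict = int(np.sum(map_g == 2))
        if n_conflict:
            warnings.warn(
                f"{n_conflict} significant pair(s) have MAP genotype 2; "
                "reported as genotype 2 with is_cnv=True"
            )
        idx = np.flatnonzero(is_cnv)
        for j, i in enumerate(idx):
            g = int(map_g[j])
            cng[i] = pd.NA if lod_sig[j] <= lod_threshold else g
            lod[i] = lod_sig[j]
            post_best[i] = best_sig[j]

    out = pd.DataFrame(
        {
            "locus_id": df["locus_id"],
            "sample_id": df["sample_id"],
            "z": z,
            "p": p,
            "q": q,
            "is_cnv": is_cnv,
            "cng": pd.array(cng, dtype="Int64"),
            "lod": lod,
            "posterior_best": post_best,
        }
    )
    return out
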