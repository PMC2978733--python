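"""Two-parameter read-depth-ratio variance model.

The observed ratio variance for loci of a given length decomposes into a
scaled Poisson term and a length-independent background term:

    Var(r) = alpha * poisson_var + sigma2_bg,   poisson_var = 1/E

where E is the expected baseline depth of the locus.  alpha (typically
~1-4) captures over-dispersion relative to pure Poisson sampling;
sigma2_bg (~0.002 on real data) captures residual experimental noise.
Both are estimated by ordinary least squares over locus length classes
obtained by subdividing long copy-number-invariant loci.

At copy-number genotype m the genotype-dependent ratio variance is

    sigma2_m = alpha * (m/2) / E2 + sigma2_bg

with E2 the expected depth at the baseline genotype 2 (the Poisson count
variance at genotype m is (m/2)*E2, and dividing by E2^2 gives m/(2*E2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mappability import Locus

#: subdivision lengths (nt) of the 50 kb invariant loci; the undivided
#: 50 kb locus is the 15th length class.
DEFAULT_SEGMENT_SIZES = [
    1_000, 1_250, 1_500, 1_750, 2_000, 2_250, 2_500,
    3_000, 5_000, 7_500, 10_000, 20_000, 30_000, 40_000, 50_000,
]


@dataclass
class VarianceModel:
    alpha: float
    sigma2_bg: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.sigma2_bg < 0:
            raise ValueError("sigma2_bg must be >= 0")


def sigma2_for(E2: float, m: int, model: VarianceModel) -> float:
    """Ratio variance at genotype m given baseline expected depth E2."""
    if E2 <= 0:
        raise ValueError("E2 must be > 0")
    if m < 0:
        raise ValueError("genotype must be >= 0")
    return model.alpha * (m / 2.0) / E2 + model.sigma2_bg


def subdivide_locus(locus: Locus, size: int) -> List[Locus]:
    """Non-overlapping segments of ``size`` nt from the locus start.

    The trailing remainder shorter than ``size`` is discarded.
    """
    n = locus.length // size
    return [
        Locus(
            id=f"{locus.id}|{size}|{i}",
            chrom=locus.chrom,
            start=locus.start + i * size,
            end=locus.start + (i + 1) * size,
        )
        for i in range(n)
    ]


def build_variance_dataset(
    segment_depths: pd.DataFrame,
    min_segments: int = 2,
) -> pd.DataFrame:
    """Per length-class (poisson_var, observed_var) pairs.

    ``segment_depths`` has one row per segment with columns ``size``
    (length class), ``E`` (expected baseline depth) and ``r_adj``; rows
    from several samples may be present, in which case statistics are
    computed per (sample, size) class.  Classes with fewer than
    ``min_segments`` segments are dropped with a warning.
    """
    keys = ["size"]
    if "sample_id" in segment_depths.columns:
        keys = ["sample_id", "size"]
    rows = []
    for key, grp in segment_depths.groupby(keys):
        if len(grp) < min_segments:
            warnings.warn(f"length class {key}: fewer than {min_segments} segments; dropped")
            continue
        rows.append(
            {
                **dict(zip(keys, key if isinstance(key, tuple) else (key,))),
                "poisson_var": float(np.mean(1.0 / grp["E"].to_numpy())),
                "observed_var": float(np.var(grp["r_adj"].to_numpy(), ddof=1)),
                "n_segments": len(grp),
            }
        )
    return pd.DataFrame(rows)


def estimate_model(pairs: pd.DataFrame) -> VarianceModel:
    """OLS of observed_var on poisson_var: slope = alpha, intercept = sigma2_bg.

    A negative intercept is clamped to zero with a warning (a variance
    cannot be negative); needs >= 3 length classes.
    """
    x = np.asarray(pairs["poisson_var"], dtype=float)
    y = np.asarray(pairs["observed_var"], dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 length classes to fit the variance model")
    if np.allclose(x, x[0]):
        raise ValueError("singular design: poisson_var has no spread")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = fit.params
    if slope <= 0:
        raise ValueError(f"fitted alpha {slope:.4g} is not positive; data unusable")
    if intercept < 0:
        warnings.warn(f"negative background-variance intercept {intercept:.3g}; clamped to 0")
        intercept = 0.0
    return VarianceModel(alpha=float(slope), sigma2_bg=float(intercept))


def qq_r_squared(values: Sequence[float]) -> float:
    """R^2 of the normal quantile-quantile line of ``values``.

    Diagnostic for the normality assumption behind the z-test and the
    Gaussian genotype densities.
    """
    from scipy import stats

    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    r = np.corrcoef(theo, v)[0, 1]
    return float(r**2)
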