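"""Sample-specific GC-bias normalization of read-depth ratios.

Illumina coverage depends smoothly on local G+C content.  For each sample
a cubic smoothing spline f(gc) is fitted to zero-centered raw read-depth
ratios of copy-number-invariant normalization loci (smoothing parameter
chosen by generalized cross-validation), after removing outlier loci by a
conservative 3*IQR rule.  Ratios are then corrected multiplicatively,
r_adj = r_raw / (1 + f(gc)), which preserves the m/2 genotype ladder.
Samples whose corrected ratios remain too variable on the normalization
loci fail QC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline

DEFAULT_QC_CUTOFF = 0.01  # variance of r_adj on normalization loci

IQR_FACTOR = 3.0
MIN_FIT_POINTS = 50
MIN_GC_SPREAD = 0.1
MAX_SPLINE_KNOTS = 200


def outlier_filter(values: Sequence[float]) -> np.ndarray:
    """Drop ratios outside [Q1 - 3*IQR, Q3 + 3*IQR].

    Quartiles use the linear-interpolation convention so the filter is
    reproducible bit-for-bit.  Conservative on purpose: only gross
    outliers (e.g. an unrecognized CNV among the normalization loci) go.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for quartile-based filtering")
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - IQR_FACTOR * iqr, q3 + IQR_FACTOR * iqr
    kept = v[(v >= lo) & (v <= hi)]
    if kept.size == 0:
        raise ValueError("degenerate normalization set: every value filtered")
    return kept


def outlier_mask(values: Sequence[float]) -> np.ndarray:
    """Boolean keep-mask version of :func:`outlier_filter`."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for quartile-based filtering")
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    iqr = q3 - q1
    mask = (v >= q1 - IQR_FACTOR * iqr) & (v <= q3 + IQR_FACTOR * iqr)
    if not mask.any():
        raise ValueError("degenerate normalization set: every value filtered")
    return mask


@dataclass
class GCCurve:
    """Fitted GC-bias curve: gc -> expected zero-centered ratio deviation.

    Evaluation outside the training GC range is clamped to the boundary
    (cubic spline tails diverge and are never trusted).
    """

    spline: BSpline
    gc_min: float
    gc_max: float

    def __call__(self, gc) -> np.ndarray:
        g = np.clip(np.asarray(gc, dtype=float), self.gc_min, self.gc_max)
        return self.spline(g)


def fit_gc_curve(gc: Sequence[float], r_raw: Sequence[float]) -> GCCurve:
    """Fit the sample-specific cubic smoothing spline to zero-centered ratios.

    The penalty is chosen by generalized cross-validation.  Duplicate GC
    values are merged (weighted by multiplicity) since the spline solver
    requires strictly increasing abscissae, and — as in classical
    smoothing-spline implementations — large inputs are reduced to at
    most ``MAX_SPLINE_KNOTS`` weighted knots before the GCV search,
    which is both faster and better conditioned.
    """
    g = np.asarray(gc, dtype=float)
    y = np.asarray(r_raw, dtype=float) - 1.0  # zero-centering
    if g.size != y.size:
        raise ValueError("gc and r_raw must have equal length")
    if g.size < MIN_FIT_POINTS:
        raise ValueError(f"need >= {MIN_FIT_POINTS} points to fit the GC curve")
    if g.max() - g.min() < MIN_GC_SPREAD:
        raise ValueError(
            f"GC spread {g.max() - g.min():.3f} < {MIN_GC_SPREAD}; cannot fit a bias curve"
        )
    order = np.argsort(g, kind="stable")
    g, y = g[order], y[order]
    ug, inverse, counts = np.unique(g, return_inverse=True, return_counts=True)
    ym = np.zeros_like(ug)
    np.add.at(ym, inverse, y)
    ym /= counts
    w = counts.astype(float)
    if ug.size > MAX_SPLINE_KNOTS:
        # weighted-average within quantile bins of the observed GC values
        edges = np.quantile(g, np.linspace(0, 1, MAX_SPLINE_KNOTS + 1))
        idx = np.clip(np.searchsorted(edges, ug, side="right") - 1, 0, MAX_SPLINE_KNOTS - 1)
        xb = np.bincount(idx, weights=w * ug, minlength=MAX_SPLINE_KNOTS)
        yb = np.bincount(idx, weights=w * ym, minlength=MAX_SPLINE_KNOTS)
        wb = np.bincount(idx, weights=w, minlength=MAX_SPLINE_KNOTS)
        keep = wb > 0
        ug, ym, w = xb[keep] / wb[keep], yb[keep] / wb[keep], wb[keep]
    spline = make_smoothing_spline(ug, ym, w=w, lam=None)
    return GCCurve(spline=spline, gc_min=float(ug[0]), gc_max=float(ug[-1]))


def adjust_rdr(r_raw, gc, curve: GCCurve):
    """Multiplicative GC correction: r_adj = r_raw / (1 + f(gc)).

    Consumes *raw* ratios only; applying it to already-adjusted ratios is a
    contract violation (see :func:`normalize_depths`, which enforces it).
    """
    denom = 1.0 + curve(gc)
    if np.any(denom <= 0):
        raise ValueError("pathological curve: 1 + f(gc) <= 0")
    out = np.asarray(r_raw, dtype=float) / denom
    return float(out) if np.isscalar(r_raw) else out


def sample_qc(
    r_adj: Sequence[float], cutoff: float = DEFAULT_QC_CUTOFF
) -> Tuple[bool, float]:
    """QC on the adjusted ratios of the normalization loci.

    Returns (passed, variance); a sample fails when the variance exceeds
    the cutoff (default 0.01), flagging e.g. very low coverage.
    """
    var = float(np.var(np.asarray(r_adj, dtype=float), ddof=1))
    return var <= cutoff, var


def fit_sample_curve(norm_depths: pd.DataFrame) -> GCCurve:
    """Outlier-filter one sample's normalization loci and fit its GC curve.

    ``norm_depths`` needs columns ``gc`` and ``r_raw`` for a single sample.
    """
    mask = outlier_mask(norm_depths["r_raw"].to_numpy())
    kept = norm_depths.loc[mask]
    return fit_gc_curve(kept["gc"].to_numpy(), kept["r_raw"].to_numpy())


def normalize_depths(depths: pd.DataFrame, curve: GCCurve) -> pd.DataFrame:
    """Append ``r_adj`` to a single-sample depth table carrying ``gc``.

    Refuses tables already adjusted: the curve consumes raw ratios only.
    """
    if "r_adj" in depths.columns:
        raise ValueError("table already GC-adjusted; re-adjustment is forbidden")
    out = depths.copy()
    out["r_adj"] = adjust_rdr(out["r_raw"].to_numpy(), out["gc"].to_numpy(), curve)
    return out


def sample_normalization_loci(
    chrom_sizes: dict,
    bin_size: int = 10_000,
    n_loci: int = 3000,
    exclude=None,
    seed: int | None = None,
):
    """Sample copy-number-invariant normalization loci as fixed-size bins.

    Emulates drawing ~1% of the genome in 10 kb bins while excluding known
    copy-number-variable intervals (``exclude``: iterable of
    (chrom, start, end)).  Returns a list of :class:`~copydepth.mappability.Locus`.
    """
    from .mappability import Locus

    rng = np.random.default_rng(seed)
    excl = {}
    for chrom, s, e in exclude or []:
        excl.setdefault(chrom, []).append((s, e))
    candidates = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size - bin_size + 1, bin_size):
            end = start + bin_size
            bad = any(s < end and start < e for s, e in excl.get(chrom, []))
            if not bad:
                candidates.append((chrom, start, end))
    if len(candidates) < n_loci:
        n_loci = len(candidates)
    idx = rng.choice(len(candidates), size=n_loci, replace=False)
    return [
        Locus(id=f"norm_{c}:{s}-{e}", chrom=c, start=s, end=e)
        for c, s, e in (candidates[i] for i in sorted(idx))
    ]
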