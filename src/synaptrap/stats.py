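"""Binding-curve fits, disassembly-force group statistics, recombination
frequencies and the stability-efficiency correlation.

EMSA band intensities yield bound fractions b = I_bound / (I_bound +
I_unbound), fitted with the Hill-Langmuir curve

    b(c) = b_max / (1 + (c_half / c)^n),   n = 4 by default

(four integrase subunits assemble the synaptic complex).  Disassembly
force groups are compared by one-way ANOVA, pairwise Welch t tests with
Holm correction, and Kruskal-Wallis rank sums.  Recombination frequency
is the ratio of recombinant to recipient CFU counts, with the all-zero
case reported as the limit of detection 1 / (summed recipients).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "BindingSeries",
    "HillFitResult",
    "GroupSample",
    "GroupSummary",
    "GroupComparison",
    "RecombinationResult",
    "CorrelationResult",
    "bound_fraction",
    "hill_curve",
    "fit_hill",
    "group_summary",
    "median_ci",
    "holm_adjust",
    "compare_groups",
    "recombination_frequency",
    "stability_efficiency_correlation",
]


@dataclass
class BindingSeries:
    """EMSA titration: concentrations (nM) with bound/unbound intensities."""

    concentration: np.ndarray
    I_bound: np.ndarray
    I_unbound: np.ndarray

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.I_bound = np.asarray(self.I_bound, dtype=float)
        self.I_unbound = np.asarray(self.I_unbound, dtype=float)
        if not (len(self.concentration) == len(self.I_bound)
                == len(self.I_unbound)):
            raise ValueError("columns must have equal length")
        if np.any(self.I_bound < 0) or np.any(self.I_unbound < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class HillFitResult:
    c_half: float                   # nM
    b_max: float                    # maximum bound fraction
    c_half_stderr: float
    b_max_stderr: float
    rms_residual: float
    exponent: float
    success: bool
    message: str = ""


def bound_fraction(I_bound, I_unbound):
    """Fraction of bound species b = I_bound / (I_bound + I_unbound).

    Rows where both intensities are zero are undefined and returned as
    NaN with a warning (callers exclude them).
    """
    ib = np.asarray(I_bound, dtype=float)
    iu = np.asarray(I_unbound, dtype=float)
    total = ib + iu
    zero = total == 0
    if np.any(zero):
        warnings.warn("row(s) with zero total intensity excluded",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(zero, np.nan, ib / np.where(zero, 1.0, total))
    return float(b) if np.ndim(I_bound) == 0 and np.ndim(I_unbound) == 0 else b


def hill_curve(c, c_half: float, b_max: float, exponent: float = 4.0):
    """Hill-Langmuir bound fraction b(c) = b_max / (1 + (c_half/c)^n)."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr <= 0):
        raise ValueError("concentration must be positive")
    out = b_max / (1.0 + (c_half / c_arr) ** exponent)
    return float(out) if np.ndim(c) == 0 else out


def fit_hill(series: BindingSeries, exponent: float = 4.0) -> HillFitResult:
    """Nonlinear least-squares Hill-Langmuir fit of a binding series.

    Requires at least 4 nonzero concentrations.  Parameter standard
    errors come from the fit covariance.  Non-convergence is reported in
    the result (``success=False``) rather than raised.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        b = bound_fraction(series.I_bound, series.I_unbound)
    mask = (series.concentration > 0) & np.isfinite(b)
    c, b = series.concentration[mask], b[mask]
    if len(c) < 4:
        raise ValueError("need at least 4 usable concentrations to fit")

    b_max0 = min(max(float(b.max()), 1e-3), 1.0)
    half = b_max0 / 2.0
    c_half0 = float(c[np.argmin(np.abs(b - half))])

    def model(cc, c_half, b_max):
        return b_max / (1.0 + (c_half / cc) ** exponent)

    try:
        popt, pcov = optimize.curve_fit(
            model, c, b, p0=[max(c_half0, 1e-6), b_max0],
            bounds=([1e-12, 1e-12], [np.inf, 1.0]), maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning, ValueError) as exc:
        return HillFitResult(math.nan, math.nan, math.nan, math.nan,
                             math.nan, exponent, False, str(exc))
    resid = b - model(c, *popt)
    stderr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else \
        np.array([math.nan, math.nan])
    return HillFitResult(float(popt[0]), float(popt[1]), float(stderr[0]),
                         float(stderr[1]), float(np.sqrt(np.mean(resid**2))),
                         exponent, True)


# ---------------------------------------------------------------------------
# Group statistics of disassembly / unbinding forces
# ---------------------------------------------------------------------------

@dataclass
class GroupSample:
    """Forces (pN) measured for one attC/protein combination."""

    label: str
    forces: np.ndarray

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if len(self.forces) == 0:
            raise ValueError("a group needs at least one observation")

    @property
    def n(self) -> int:
        return len(self.forces)


@dataclass
class GroupSummary:
    label: str
    median: float
    q1: float
    q3: float
    n: int


def group_summary(sample: GroupSample) -> GroupSummary:
    """Median and quartiles (linear-interpolation convention) of a group."""
    q1, med, q3 = np.quantile(sample.forces, [0.25, 0.5, 0.75])
    return GroupSummary(sample.label, float(med), float(q1), float(q3),
                        sample.n)


def median_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free confidence interval of the median.

    Order-statistic (binomial) interval: the bounds are the sample
    values at the binomial(n, 1/2) quantiles of ``level``.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    alpha = 1.0 - level
    lo = int(sps.binom.ppf(alpha / 2.0, n, 0.5))
    hi = int(sps.binom.ppf(1.0 - alpha / 2.0, n, 0.5))
    return float(x[max(lo, 0)]), float(x[min(hi, n - 1)])


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values.

    Sorted ascending, p_(i) is multiplied by (m - i + 1), a running
    maximum enforces monotonicity, values are capped at 1, and the
    original order is restored.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class GroupComparison:
    anova_F: float
    anova_p: float
    kruskal_H: float
    kruskal_p: float
    pairwise: pd.DataFrame          # columns: group_a, group_b, t, p, p_holm
    posthoc_significant: bool       # ANOVA p < 0.05 gates the pairwise tests


def compare_groups(samples: list[GroupSample], alpha: float = 0.05
                   ) -> GroupComparison:
    """One-way ANOVA, Holm-adjusted pairwise Welch t tests, Kruskal-Wallis.

    Pairwise tests are always reported but flagged as post-hoc evidence
    only when the ANOVA is significant at ``alpha``.  Degenerate input
    (all observations identical) yields H = 0, p = 1.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for s in samples:
        if s.n < 2:
            raise ValueError(f"group {s.label!r} needs n >= 2")
    arrays = [s.forces for s in samples]

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        anova_F, anova_p = 0.0, 1.0
        kruskal_H, kruskal_p = 0.0, 1.0
    else:
        anova_F, anova_p = sps.f_oneway(*arrays)
        try:
            kruskal_H, kruskal_p = sps.kruskal(*arrays)
        except ValueError:  # all values identical within float ties
            kruskal_H, kruskal_p = 0.0, 1.0

    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            if np.ptp(np.concatenate([arrays[i], arrays[j]])) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(arrays[i], arrays[j], equal_var=False)
            rows.append({"group_a": samples[i].label,
                         "group_b": samples[j].label,
                         "t": float(t), "p": float(p)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = holm_adjust(pairwise["p"].to_numpy())

    return GroupComparison(float(anova_F), float(anova_p), float(kruskal_H),
                           float(kruskal_p), pairwise,
                           bool(anova_p < alpha))


# ---------------------------------------------------------------------------
# Recombination frequency
# ---------------------------------------------------------------------------

@dataclass
class RecombinationResult:
    frequency: float                    # mean ratio, or the LOD bound
    sd: float | None                    # None when undefined (LOD or n = 1)
    per_replicate: np.ndarray
    is_limit_of_detection: bool


def recombination_frequency(recombinant_cfu, recipient_cfu
                            ) -> RecombinationResult:
    """Recombination frequency from per-replicate CFU counts.

    The frequency is the per-replicate ratio of recombinant to recipient
    CFUs, averaged across replicates.  When no recombinants are observed
    in any replicate, the result is the limit of detection: one
    recombinant CFU over the total recipients of all replicates, flagged,
    with the SD undefined.
    """
    rec = np.asarray(recombinant_cfu, dtype=float)
    tot = np.asarray(recipient_cfu, dtype=float)
    if len(rec) != len(tot) or len(rec) == 0:
        raise ValueError("need matching, nonempty replicate counts")
    if np.any(tot <= 0):
        raise ValueError("recipient counts must be positive")
    if np.any(rec < 0):
        raise ValueError("recombinant counts must be >= 0")
    ratios = rec / tot
    if np.all(rec == 0):
        return RecombinationResult(float(1.0 / tot.sum()), None, ratios, True)
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else None
    return RecombinationResult(float(ratios.mean()), sd, ratios, False)


# ---------------------------------------------------------------------------
# Stability-efficiency correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    pearson_r: float            # on (mean force, log10 efficiency)
    pearson_p: float
    spearman_rho: float         # on raw pairs
    spearman_p: float
    n: int
    n_lod_excluded: int = 0
    note: str = ""


def stability_efficiency_correlation(mean_forces, efficiencies,
                                     lod_flags=None,
                                     include_lod: bool = False
                                     ) -> CorrelationResult:
    """Correlate mean disassembly force with relative recombination
    efficiency across conditions.

    Pearson r is computed on (force, log10 efficiency) since efficiencies
    span orders of magnitude; Spearman rho uses the raw pairs.
    Conditions flagged as limit-of-detection are excluded unless
    ``include_lod`` is set.
    """
    f = np.asarray(mean_forces, dtype=float)
    e = np.asarray(efficiencies, dtype=float)
    if len(f) != len(e):
        raise ValueError("forces and efficiencies must pair up")
    if np.any(e <= 0):
        raise ValueError("efficiencies must be positive")
    lod = (np.zeros(len(f), dtype=bool) if lod_flags is None
           else np.asarray(lod_flags, dtype=bool))
    keep = np.ones(len(f), dtype=bool) if include_lod else ~lod
    n_excluded = int((~keep).sum())
    f, e = f[keep], e[keep]
    if len(f) < 3:
        raise ValueError("need at least 3 paired conditions")
    if np.ptp(e) == 0 or np.ptp(f) == 0:
        return CorrelationResult(math.nan, math.nan, math.nan, math.nan,
                                 len(f), n_excluded,
                                 "degenerate: constant input, r undefined")
    pr = sps.pearsonr(f, np.log10(e))
    sr = sps.spearmanr(f, e)
    return CorrelationResult(float(pr.statistic), float(pr.pvalue),
                             float(sr.statistic), float(sr.pvalue),
                             len(f), n_excluded)
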