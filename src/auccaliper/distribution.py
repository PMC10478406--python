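"""Histogram and smooth-fit analysis of reported AUC values.

The central question this module answers is whether the distribution of
AUC values reported in the literature is smooth, or shows discontinuities
(a "caliper" signature) at the qualitative thresholds 0.7, 0.8 and 0.9.
The analysis is:

1. bin values into 100 half-open bins ``(lower, upper]`` of width 0.01
   spanning (0, 1];
2. estimate the smooth shape of the distribution with a Poisson
   regression of the bin counts on a natural cubic spline of the bin
   midpoints (4 degrees of freedom by default);
3. form residuals ``observed - fitted`` so that an excess of values in a
   bin appears as a positive residual;
4. summarise the residuals in the bins immediately below and above each
   threshold.

Values printed with a single decimal place (e.g. "0.8") are excluded
from the histogram by default, because rounding alone concentrates them
on the thresholds and would create spikes unrelated to any re-analysis
behaviour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .extraction import AUCMatch

N_BINS = 100
BIN_WIDTH = 0.01

__all__ = [
    "HistogramSpec",
    "Histogram",
    "SmoothFit",
    "ThresholdBins",
    "ThresholdReport",
    "build_histogram",
    "natural_spline_basis",
    "spline_knots",
    "fit_poisson_spline",
    "threshold_report",
    "max_per_abstract",
    "subset_results_section",
    "subset_journal",
]


@dataclass(frozen=True)
class HistogramSpec:
    """Binning convention for AUC values.

    The grid is fixed: 100 bins ``(k/100, (k+1)/100]`` for k = 0..99, so a
    value of exactly 0.70 falls in (0.69, 0.70] and 0.70001 in
    (0.70, 0.71]. ``exclude_one_decimal`` drops values printed with one
    decimal place; ``roles_included`` selects which match roles are
    counted (point estimates only by default, i.e. confidence-interval
    limits are excluded).
    """

    exclude_one_decimal: bool = True
    roles_included: frozenset[str] = frozenset({"point"})

    @property
    def lower_edges(self) -> np.ndarray:
        return np.round(np.arange(N_BINS) * BIN_WIDTH, 10)

    @property
    def upper_edges(self) -> np.ndarray:
        return np.round((np.arange(N_BINS) + 1) * BIN_WIDTH, 10)

    @property
    def midpoints(self) -> np.ndarray:
        return np.round(self.lower_edges + BIN_WIDTH / 2, 10)


@dataclass
class Histogram:
    spec: HistogramSpec
    counts: np.ndarray  # 100 non-negative ints
    n_excluded_one_decimal: int = 0
    n_excluded_role: int = 0

    @property
    def n_values(self) -> int:
        return int(self.counts.sum())


def bin_index(value: float) -> int:
    """Index of the half-open bin ``(lower, upper]`` containing ``value``.

    Defined for 0 < value < 1 (a value of exactly 0 belongs to no bin of
    the (0, 1] grid). The small jitter guards against values that are
    exact bin edges up to floating-point noise.
    """
    if not 0.0 < value < 1.0:
        raise ValueError(f"value {value!r} outside (0, 1)")
    idx = int(np.ceil(value * 100.0 - 1e-9)) - 1
    return min(max(idx, 0), N_BINS - 1)


def build_histogram(
    values: Iterable[AUCMatch] | Sequence[float] | np.ndarray,
    spec: HistogramSpec | None = None,
) -> Histogram:
    """Bin AUC values into the 100-bin (lower, upper] histogram.

    ``values`` may be extracted :class:`AUCMatch` objects, in which case
    the spec's role filter and one-decimal exclusion apply, or a plain
    sequence of floats in (0, 1), which are all assumed eligible.

    Raises ``ValueError`` for any value outside [0, 1); values of exactly
    0 cannot be binned on the (0, 1] grid and also raise.
    """
    spec = spec or HistogramSpec()
    counts = np.zeros(N_BINS, dtype=np.int64)
    n_one_decimal = 0
    n_role = 0

    values = list(values) if not isinstance(values, np.ndarray) else values
    if len(values) and isinstance(values[0], AUCMatch):
        for m in values:
            if m.role not in spec.roles_included:
                n_role += 1
                continue
            if spec.exclude_one_decimal and m.decimal_places == 1:
                n_one_decimal += 1
                continue
            counts[bin_index(m.value)] += 1
    else:
        arr = np.asarray(values, dtype=float)
        if arr.size:
            if np.any(arr <= 0.0) or np.any(arr >= 1.0):
                bad = arr[(arr <= 0.0) | (arr >= 1.0)]
                raise ValueError(f"values outside (0, 1): {bad[:5]}")
            idx = np.ceil(arr * 100.0 - 1e-9).astype(int) - 1
            np.clip(idx, 0, N_BINS - 1, out=idx)
            counts = np.bincount(idx, minlength=N_BINS).astype(np.int64)

    return Histogram(
        spec=spec,
        counts=counts,
        n_excluded_one_decimal=n_one_decimal,
        n_excluded_role=n_role,
    )


# ---------------------------------------------------------------------------
# Natural cubic spline basis
# ---------------------------------------------------------------------------

def spline_knots(
    x: np.ndarray, df: int, boundary: tuple[float, float] | None = None
) -> np.ndarray:
    """Knot vector (boundary + interior) for a ``df``-dimensional natural
    cubic spline basis on ``x``.

    Interior knots sit at equally spaced quantiles of ``x`` (the 25th,
    50th and 75th percentiles for df = 4); boundary knots default to the
    range of ``x``.
    """
    if df < 2:
        raise ValueError("natural spline needs df >= 2")
    x = np.asarray(x, dtype=float)
    lo, hi = boundary if boundary is not None else (x.min(), x.max())
    n_interior = df - 1
    probs = np.arange(1, n_interior + 1) / (n_interior + 1)
    interior = np.quantile(x, probs)
    knots = np.concatenate([[lo], interior, [hi]])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"duplicate or unordered knots: {knots}")
    return knots


def natural_spline_basis(
    x: np.ndarray | Sequence[float],
    df: int = 4,
    boundary: tuple[float, float] | None = None,
    knots: np.ndarray | None = None,
) -> np.ndarray:
    """Natural cubic spline basis matrix (without intercept).

    Each of the ``df`` columns is a piecewise cubic with continuous
    second derivatives that is linear beyond the boundary knots. The
    construction is the classical truncated-power one: with knots
    xi_1 < ... < xi_K (K = df + 1, the outer two being boundary knots),

        N_1(x)      = x
        N_{k+1}(x)  = d_k(x) - d_{K-1}(x),        k = 1..K-2
        d_k(x)      = [(x - xi_k)^3_+ - (x - xi_K)^3_+] / (xi_K - xi_k)

    which enforces zero second and third derivatives outside the
    boundary.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = spline_knots(x, df, boundary)
    else:
        knots = np.asarray(knots, dtype=float)
        if np.any(np.diff(knots) <= 0):
            raise ValueError(f"duplicate or unordered knots: {knots}")
        df = len(knots) - 1
    K = len(knots)

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0.0, None) ** 3 - np.clip(x - knots[K - 1], 0.0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


@dataclass
class SmoothFit:
    """Poisson natural-spline fit to a histogram.

    ``fitted`` and ``residuals`` are full-length (100) arrays; bins
    outside the fit domain hold NaN. Residuals are observed - fitted, so
    an excess of values in a bin is positive.
    """

    coefficients: np.ndarray  # intercept + df spline coefficients
    knots: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    deviance: float
    converged: bool
    n_iterations: int
    bin_mask: np.ndarray  # True for bins included in the fit
    df: int = 4

    @property
    def observed(self) -> np.ndarray:
        return self.fitted + self.residuals


def fit_poisson_spline(
    hist: Histogram,
    df: int = 4,
    fit_domain: tuple[float, float] | None = None,
) -> SmoothFit:
    """Fit the smooth null distribution: Poisson GLM with log link of bin
    counts on intercept + natural spline of bin midpoints.

    ``fit_domain`` optionally restricts the fit to bins whose midpoint
    lies in ``(lo, hi]`` — useful when the data occupy only part of
    (0, 1], since bins far outside the support carry no information and
    distort a low-dimensional spline. Fitting uses iteratively
    reweighted least squares (convergence when the relative deviance
    change falls below 1e-8, at most 100 iterations). With the intercept
    in the model the Poisson score equations force the fitted counts to
    sum to the observed count over the fitted bins.
    """
    counts = np.asarray(hist.counts, dtype=float)
    mids = hist.spec.midpoints
    if fit_domain is not None:
        lo, hi = fit_domain
        mask = (mids > lo) & (mids <= hi)
    else:
        mask = np.ones(N_BINS, dtype=bool)
    y = counts[mask]
    x = mids[mask]
    if y.sum() == 0:
        raise ValueError("all bin counts are zero; nothing to fit")
    if mask.sum() < df + 2:
        raise ValueError(f"need at least {df + 2} bins to fit a df={df} spline")

    knots = spline_knots(x, df)
    X = sm.add_constant(natural_spline_basis(x, df, knots=knots))
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100, tol=1e-8)

    fitted = np.full(N_BINS, np.nan)
    residuals = np.full(N_BINS, np.nan)
    fitted[mask] = res.fittedvalues
    residuals[mask] = y - res.fittedvalues
    return SmoothFit(
        coefficients=np.asarray(res.params),
        knots=knots,
        fitted=fitted,
        residuals=residuals,
        deviance=float(res.deviance),
        converged=bool(res.converged),
        n_iterations=int(res.fit_history["iteration"]),
        bin_mask=mask,
        df=df,
    )


# ---------------------------------------------------------------------------
# Threshold reports
# ---------------------------------------------------------------------------

@dataclass
class ThresholdBins:
    threshold: float
    observed_below: int
    observed_above: int
    fitted_below: float
    fitted_above: float
    residual_below: float
    residual_above: float

    @property
    def excess_ratio_above(self) -> float:
        """Observed/fitted in the bin just above the threshold.

        A descriptive convenience on top of the residuals: 1 means the
        above-threshold bin is exactly on the smooth curve.
        """
        return self.observed_above / self.fitted_above


@dataclass
class ThresholdReport:
    entries: list[ThresholdBins] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, threshold: float) -> ThresholdBins:
        for e in self.entries:
            if abs(e.threshold - threshold) < 1e-9:
                return e
        raise KeyError(threshold)

    def to_dict(self) -> dict:
        return {
            f"{e.threshold:.2f}": {
                "observed_below": e.observed_below,
                "observed_above": e.observed_above,
                "fitted_below": e.fitted_below,
                "fitted_above": e.fitted_above,
                "residual_below": e.residual_below,
                "residual_above": e.residual_above,
                "excess_ratio_above": e.excess_ratio_above,
            }
            for e in self.entries
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def threshold_report(
    hist: Histogram,
    fit: SmoothFit,
    thresholds: Sequence[float] = (0.7, 0.8, 0.9),
) -> ThresholdReport:
    """Observed/fitted/residual for the bins adjacent to each threshold.

    For a threshold t the "below" bin is (t - 0.01, t] — the bin that
    *contains* t under the half-open convention — and the "above" bin is
    (t, t + 0.01]. Thresholds must lie on the 0.01 grid, strictly inside
    (0.01, 0.99).
    """
    entries = []
    for t in thresholds:
        scaled = t * 100.0
        if abs(scaled - round(scaled)) > 1e-9:
            raise ValueError(f"threshold {t} not aligned to the 0.01 bin grid")
        k = int(round(scaled))
        if not 1 < k < 99:
            raise ValueError(f"threshold {t} too close to the edge of (0, 1]")
        below, above = k - 1, k
        entries.append(
            ThresholdBins(
                threshold=float(t),
                observed_below=int(hist.counts[below]),
                observed_above=int(hist.counts[above]),
                fitted_below=float(fit.fitted[below]),
                fitted_above=float(fit.fitted[above]),
                residual_below=float(fit.residuals[below]),
                residual_above=float(fit.residuals[above]),
            )
        )
    return ThresholdReport(entries)


# ---------------------------------------------------------------------------
# Subgroup helpers
# ---------------------------------------------------------------------------

def max_per_abstract(matches: Iterable[AUCMatch]) -> list[AUCMatch]:
    """Keep the highest point value per abstract (ties: first occurrence).

    Used for the "best model per abstract" subgroup: many abstracts
    report several competing models, and if authors aim for thresholds
    the best value is the one most likely to sit just above one.
    """
    best: dict[str, AUCMatch] = {}
    for m in matches:
        if m.role != "point":
            raise ValueError("max_per_abstract expects point-role matches only")
        cur = best.get(m.pmid)
        if cur is None or m.value > cur.value:
            best[m.pmid] = m
    return list(best.values())


def subset_results_section(matches: Iterable[AUCMatch]) -> list[AUCMatch]:
    """Matches from the results section of structured abstracts.

    Unlabelled sections (unstructured abstracts) are dropped: mentions in
    background or methods text are more often generic references to the
    AUC scale than model results.
    """
    return [m for m in matches if "RESULT" in m.section_label.upper()]


def subset_journal(
    matches: Iterable[AUCMatch],
    pmid_to_journal: dict[str, str],
    journal_name: str,
) -> list[AUCMatch]:
    """Matches from abstracts published in one journal (case-insensitive)."""
    target = journal_name.strip().casefold()
    return [
        m
        for m in matches
        if pmid_to_journal.get(m.pmid, "").strip().casefold() == target
    ]
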