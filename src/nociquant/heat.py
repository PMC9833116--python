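"""Heat-activation thresholds from ramp recordings, and their population mixture.

Per cell, the ratio signal recorded during a linear heat ramp is re-expressed
in Arrhenius coordinates -- log10 of the baseline-subtracted signal against
reciprocal absolute temperature (x = 1000/T_K).  A thermally gated cell shows
two regimes: a shallow sub-threshold slope and a steeper, "accelerating"
supra-threshold slope.  The breakpoint is found by exhaustive search over
interior grid points, fitting an independent least-squares line to each side;
the heat threshold is the temperature at the analytic intersection of the two
extrapolated lines.

The per-cell thresholds of a cohort are then decomposed into K Gaussian
populations by least-squares fitting a sum of Gaussian curves to the binned
threshold histogram (the Origin "multiple peak fit" style), with multi-start
optimisation and model selection across K by a sequential F-test on the SSE
reduction.  A raw-data EM fit is provided as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .calcium import Trace

__all__ = [
    "ArrheniusFit",
    "ThresholdEstimate",
    "MixtureFit",
    "arrhenius_points",
    "accelerating_filter",
    "arrhenius_threshold",
    "estimate_thresholds",
    "fit_threshold_mixture",
    "em_mixture",
    "cumulative_threshold",
]

#: minimum points per fitted segment for an accepted threshold
MIN_SEGMENT = 5
#: two-segment SSE must undercut the single line by this factor ...
SSE_IMPROVEMENT = 0.7
#: ... and the supra/sub slope-magnitude ratio must exceed this
SLOPE_RATIO = 1.5

_KELVIN = 273.15


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and SSE of y ~ x."""
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    denom = float(dx @ dx)
    if denom == 0.0:
        return 0.0, float(ym), float(((y - ym) ** 2).sum())
    m = float(dx @ (y - ym)) / denom
    c = float(ym - m * xm)
    resid = y - (m * x + c)
    return m, c, float(resid @ resid)


def arrhenius_points(trace: Trace, eps_scale: float = 1e-3,
                     ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Arrhenius coordinates (x = 1000/T_K, y = log10(R - mu_b + eps)) of the ramp.

    The resting baseline is taken from the pre-ramp hold: the leading samples
    whose temperature stays within 0.05 degC of the coolest value.  When no
    hold is present the first five ramp samples serve as baseline (biased
    high by the sub-threshold signal; documented limitation).  eps is
    ``eps_scale`` times the baseline SD (floored at 1e-12) and keeps the
    logarithm defined; values below eps are clipped to it.

    Returns (x, y, mu_b, sigma_b).  Raises on a missing temperature channel
    or a non-monotone ramp.
    """
    if trace.temp_C is None:
        raise ValueError(f"cell {trace.cell_id}: no temperature channel")
    temp = trace.temp_C
    ratio = trace.ratio
    t0 = temp[0]
    hold = np.flatnonzero(temp > t0 + 0.05)
    start = int(hold[0]) if hold.size else len(temp)
    if start >= len(temp) - 2 * MIN_SEGMENT:
        raise ValueError(f"cell {trace.cell_id}: ramp too short")
    if start >= 3:
        base = ratio[:start]
    else:
        base = ratio[start:start + 5]
    mu_b = float(base.mean())
    sigma_b = float(base.std(ddof=1)) if len(base) > 1 else 0.0

    rtemp = temp[start:]
    rratio = ratio[start:]
    if np.any(np.diff(rtemp) <= 0):
        raise ValueError(f"cell {trace.cell_id}: temperature ramp is not monotone increasing")
    eps = max(eps_scale * sigma_b, 1e-12)
    x = 1000.0 / (rtemp + _KELVIN)
    y = np.log10(np.maximum(rratio - mu_b, 0.0) + eps)
    return x, y, mu_b, sigma_b


@dataclass
class ArrheniusFit:
    """Two-segment Arrhenius fit with its single-line comparison."""

    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    slope_sub: float
    intercept_sub: float
    slope_supra: float
    intercept_supra: float
    break_index: int
    x_star: float | None
    sse_total: float
    sse_single: float

    @property
    def accelerating(self) -> bool:
        """Two segments beat one line and the supra slope is steeper.

        Slopes are negative against x = 1000/T (signal grows with
        temperature); the supra segment must descend at least
        ``SLOPE_RATIO`` times faster than the sub segment.
        """
        if self.sse_single == 0.0:
            return False
        return (
            self.sse_total < SSE_IMPROVEMENT * self.sse_single
            and self.slope_supra < 0
            and abs(self.slope_supra) > SLOPE_RATIO * abs(self.slope_sub)
        )


@dataclass
class ThresholdEstimate:
    threshold_C: float | None
    fit: ArrheniusFit
    accepted: bool


def _two_segment_search(x: np.ndarray, y: np.ndarray,
                        min_seg: int = MIN_SEGMENT) -> ArrheniusFit:
    """Exhaustive breakpoint search: independent OLS lines on each side."""
    n = len(x)
    if n < 2 * min_seg:
        raise ValueError("too few ramp samples for a two-segment fit")
    best = None
    for i in range(min_seg, n - min_seg + 1):
        m1, c1, s1 = _ols_line(x[:i], y[:i])
        m2, c2, s2 = _ols_line(x[i:], y[i:])
        sse = s1 + s2
        if best is None or sse < best[0]:
            best = (sse, i, m1, c1, m2, c2)
    sse, i, m1, c1, m2, c2 = best
    _, _, sse_single = _ols_line(x, y)
    x_star = None
    if m1 != m2:
        x_star = (c2 - c1) / (m1 - m2)
    return ArrheniusFit(
        x=x, y=y, slope_sub=m1, intercept_sub=c1, slope_supra=m2,
        intercept_supra=c2, break_index=i, x_star=x_star,
        sse_total=sse, sse_single=sse_single,
    )


def accelerating_filter(trace: Trace) -> bool:
    """True iff the Arrhenius plot shows an accelerating calcium rise."""
    x, y, _, _ = arrhenius_points(trace)
    return _two_segment_search(x, y).accelerating


def arrhenius_threshold(trace: Trace) -> ThresholdEstimate:
    """Heat threshold as the intersection of the extrapolated segments.

    ``accepted`` requires the accelerating criterion, non-parallel fitted
    lines, and an intersection temperature inside the recorded ramp range.
    """
    x, y, _, _ = arrhenius_points(trace)
    fit = _two_segment_search(x, y)
    threshold = None
    ok = fit.accelerating and fit.x_star is not None
    if fit.x_star is not None and fit.x_star > 0:
        threshold = 1000.0 / fit.x_star - _KELVIN
    if ok:
        t_lo = 1000.0 / x[0] - _KELVIN
        t_hi = 1000.0 / x[-1] - _KELVIN
        ok = threshold is not None and t_lo <= threshold <= t_hi
    return ThresholdEstimate(threshold_C=threshold, fit=fit, accepted=bool(ok))


def estimate_thresholds(traces: list[Trace]) -> pd.DataFrame:
    """Per-cell thresholds for a heat-ramp cohort (cell_id, threshold_C, accepted)."""
    rows = []
    for tr in traces:
        est = arrhenius_threshold(tr)
        rows.append(dict(cell_id=tr.cell_id, threshold_C=est.threshold_C,
                         accepted=est.accepted))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gaussian multi-peak decomposition of the threshold histogram
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """K Gaussian components fitted to a binned threshold distribution."""

    K: int
    means: np.ndarray       # degC, ascending
    sds: np.ndarray         # degC
    weights: np.ndarray     # sum to 1
    amplitudes: np.ndarray  # histogram-curve peak heights (counts)
    sse: float
    scores: dict            # per candidate K: sse, bic, p_vs_next, valid
    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    def pdf_counts(self, x: np.ndarray) -> np.ndarray:
        """Fitted curve on the histogram-count scale."""
        x = np.asarray(x, dtype=float)
        return _gauss_sum(x, np.concatenate([self.amplitudes, self.means, self.sds]))


def _gauss_sum(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    k = len(params) // 3
    a, mu, s = params[:k], params[k:2 * k], params[2 * k:]
    return (a[:, None] * np.exp(-0.5 * ((x[None, :] - mu[:, None]) / s[:, None]) ** 2)).sum(axis=0)


_S_LO = 0.3  # degC, lower bound on component SD (below: degenerate spike)


def _fit_k(centers: np.ndarray, counts: np.ndarray, data: np.ndarray, k: int,
           rng: np.random.Generator, n_starts: int = 8) -> tuple[np.ndarray, float, bool]:
    """Multi-start bounded least squares of a K-Gaussian curve to the histogram."""
    lo_t, hi_t = centers[0], centers[-1]
    width = centers[1] - centers[0] if len(centers) > 1 else 1.0
    span = max(hi_t - lo_t, 1.0)
    s0 = max(np.std(data) / max(k, 1), _S_LO * 2)
    n = len(data)

    inits = []
    qs = np.quantile(data, (np.arange(k) + 0.5) / k)
    inits.append((qs, np.full(k, s0)))
    # peak-seeded start: the K tallest separated bins
    order = np.argsort(counts)[::-1]
    picked: list[float] = []
    for j in order:
        if all(abs(centers[j] - p) > 2 * width for p in picked):
            picked.append(centers[j])
        if len(picked) == k:
            break
    if len(picked) == k:
        inits.append((np.sort(np.array(picked)), np.full(k, s0)))
    for _ in range(n_starts):
        mu = np.sort(rng.uniform(lo_t, hi_t, k))
        s = np.exp(rng.normal(np.log(s0), 0.4, k))
        inits.append((mu, s))

    lower = np.concatenate([np.zeros(k), np.full(k, lo_t - 2), np.full(k, _S_LO)])
    upper = np.concatenate([np.full(k, counts.max() * 3 + 1), np.full(k, hi_t + 2),
                            np.full(k, span)])
    best_p, best_sse = None, np.inf
    for mu, s in inits:
        a0 = np.full(k, n * width / (k * s0 * np.sqrt(2 * np.pi)))
        p0 = np.clip(np.concatenate([a0, mu, s]), lower, upper)
        try:
            res = optimize.least_squares(
                lambda p: _gauss_sum(centers, p) - counts, p0,
                bounds=(lower, upper), method="trf", max_nfev=2000,
            )
        except Exception:
            continue
        sse = float(res.fun @ res.fun)
        if sse < best_sse:
            best_sse, best_p = sse, res.x
    if best_p is None:
        return np.zeros(3 * k), np.inf, False
    a, mu, s = best_p[:k], best_p[k:2 * k], best_p[2 * k:]
    w = a * s  # component mass up to sqrt(2*pi)
    degenerate = bool(np.any((s <= _S_LO * 1.05) & (w / max(w.sum(), 1e-300) > 0.02)))
    return best_p, best_sse, not degenerate


def fit_threshold_mixture(thresholds, K_candidates=(1, 2, 3, 4, 5),
                          bin_edges: np.ndarray | None = None,
                          alpha: float = 0.05, seed: int = 0) -> MixtureFit:
    """Origin-style multiple-peak fit of the threshold histogram.

    For each candidate K a sum of K Gaussian curves is least-squares fitted
    to the 1-degC binned histogram (multi-start, bounded).  K is selected as
    the smallest candidate for which adding one more component fails a
    sequential F-test on the SSE reduction at level ``alpha``; BIC is
    reported alongside.  Candidates whose best fit keeps a degenerate
    (spike) component are rejected.
    """
    data = np.asarray(list(thresholds), dtype=float)
    if data.size == 0:
        raise ValueError("no thresholds to fit")
    if np.ptp(data) == 0.0:
        # point mass: a single component at the common value (SD degenerate)
        edges = np.arange(np.floor(data[0]) - 1, np.ceil(data[0]) + 2.0)
        counts, _ = np.histogram(data, bins=edges)
        return MixtureFit(K=1, means=np.array([data[0]]), sds=np.array([0.0]),
                          weights=np.array([1.0]), amplitudes=np.array([float(data.size)]),
                          sse=0.0, scores={1: {"sse": 0.0, "bic": -np.inf,
                                               "p_vs_next": None, "valid": True}},
                          bin_edges=edges, counts=counts.astype(float))
    K_candidates = sorted(K_candidates)
    feasible = [k for k in K_candidates if data.size >= 5 * k]
    if not feasible:
        raise ValueError("too few observations for the smallest candidate K")
    if bin_edges is None:
        lo = min(32.0, np.floor(data.min()))
        hi = max(55.0, np.ceil(data.max()))
        bin_edges = np.arange(lo, hi + 1.0, 1.0)
    counts, _ = np.histogram(data, bins=bin_edges)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    counts = counts.astype(float)
    nbins = len(centers)
    rng = np.random.default_rng(seed)

    fits: dict[int, tuple[np.ndarray, float, bool]] = {}
    for k in feasible:
        if 3 * k >= nbins:
            break
        fits[k] = _fit_k(centers, counts, data, k, rng)

    scores: dict[int, dict] = {}
    ks = sorted(fits)
    for k in ks:
        _, sse, valid = fits[k]
        dof = nbins - 3 * k
        bic = nbins * np.log(max(sse, 1e-300) / nbins) + 3 * k * np.log(nbins)
        scores[k] = {"sse": sse, "bic": float(bic), "valid": valid, "p_vs_next": None}
    # pure-error variance from the richest candidate: the denominator of the
    # sequential F-tests (using the next model's own SSE under-rejects while
    # both models still show lack of fit)
    k_err = ks[-1]
    df_err = nbins - 3 * k_err
    sigma2 = scores[k_err]["sse"] / df_err if df_err > 0 else 0.0
    for k, k2 in zip(ks, ks[1:]):
        s1, s2 = scores[k]["sse"], scores[k2]["sse"]
        if sigma2 <= 1e-12:
            p = 1.0 if s1 - s2 <= 1e-9 * max(s1, 1.0) else 0.0
        else:
            f = max(s1 - s2, 0.0) / (3.0 * (k2 - k)) / sigma2
            p = float(stats.f.sf(f, 3 * (k2 - k), df_err))
        scores[k]["p_vs_next"] = p

    selected = None
    for k in ks:
        if not scores[k]["valid"]:
            continue
        p = scores[k]["p_vs_next"]
        if p is None or p > alpha:
            selected = k
            break
    if selected is None:
        valid = [k for k in ks if scores[k]["valid"]]
        pool = valid if valid else ks
        selected = min(pool, key=lambda k: scores[k]["sse"])

    params, sse, _ = fits[selected]
    kk = selected
    a, mu, s = params[:kk], params[kk:2 * kk], params[2 * kk:]
    order = np.argsort(mu)
    a, mu, s = a[order], mu[order], s[order]
    mass = a * s * np.sqrt(2 * np.pi)
    total = mass.sum()
    w = mass / total if total > 0 else np.full(kk, 1.0 / kk)
    return MixtureFit(K=kk, means=mu, sds=s, weights=w, amplitudes=a, sse=sse,
                      scores=scores, bin_edges=bin_edges, counts=counts)


def em_mixture(thresholds, K: int, seed: int = 0, n_iter: int = 500,
               tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plain EM Gaussian-mixture fit on the raw thresholds (cross-check route).

    Returns (means ascending, sds, weights).  Initialised from data
    quantiles with a little seeded jitter; single restart is adequate for
    the well-separated mixtures this cross-check targets.
    """
    x = np.asarray(list(thresholds), dtype=float)
    rng = np.random.default_rng(seed)
    mu = np.quantile(x, (np.arange(K) + 0.5) / K) + rng.normal(0, 0.1, K)
    s = np.full(K, max(x.std() / K, 0.5))
    w = np.full(K, 1.0 / K)
    ll_old = -np.inf
    for _ in range(n_iter):
        logp = (
            np.log(w)[:, None]
            - 0.5 * np.log(2 * np.pi * s[:, None] ** 2)
            - 0.5 * ((x[None, :] - mu[:, None]) / s[:, None]) ** 2
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        r = np.exp(logp - lse)
        nk = r.sum(axis=1)
        w = nk / x.size
        mu = (r @ x) / nk
        s = np.sqrt((r * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk)
        s = np.maximum(s, 1e-3)
        ll = float(lse.sum())
        if ll - ll_old < tol:
            break
        ll_old = ll
    order = np.argsort(mu)
    return mu[order], s[order], w[order]


def cumulative_threshold(thresholds, mode: str = "pooled-fit",
                         mixture: MixtureFit | None = None, seed: int = 0) -> float:
    """Single summary threshold for a pooled population.

    ``pooled-fit``: mean of a single-Gaussian least-squares fit to the
    pooled histogram.  ``weighted-mean``: sum of weight * mean over the
    mixture components (fitted here if not supplied).
    """
    data = np.asarray(list(thresholds), dtype=float)
    if data.size == 0:
        raise ValueError("no thresholds")
    if data.size == 1:
        return float(data[0])
    if mode == "pooled-fit":
        fit = fit_threshold_mixture(data, K_candidates=(1,), seed=seed)
        return float(fit.means[0])
    if mode == "weighted-mean":
        if mixture is None:
            mixture = fit_threshold_mixture(data, seed=seed)
        return float(np.dot(mixture.weights, mixture.means))
    raise ValueError(f"unknown mode {mode!r}")
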