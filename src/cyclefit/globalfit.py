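"""Weighted multi-exponential global fit of time-resolved difference spectra.

The model assumes the photocycle is a sequence of first-order reactions, so
every channel shares the same exponential rate constants while carrying its
own pre-factors.  The quantity minimized is the weighted squared error

    F = Σₙ Σₘ w(ν̃ₙ)² · ( ΔE(ν̃ₙ, tₘ) − [ a∞(ν̃ₙ) + Σᵢ aᵢ(ν̃ₙ)·e^(−kᵢ tₘ) ] )²

over the shared rates kᵢ, the per-channel amplitude spectra aᵢ(ν̃) and the
offsets a∞(ν̃); w(ν̃) are per-channel, noise-dependent weighting factors.

Implementation: variable projection.  The objective is separable — for fixed
rates the amplitudes and offsets are an exact linear least-squares problem per
channel — so the outer nonlinear search runs over log₁₀ kᵢ only (positivity
plus a seven-decade dynamic range make the log parameterization the natural
one), with the thousands of linear parameters projected out exactly at every
step.  A minimizer of the projected problem is a minimizer of F.  The outer
bounded trust-region search is restarted from several log-spaced/jittered
rate tuples (seeded) to guard against local minima.

Because the weight is constant along time for a given channel, the per-channel
linear solution coincides with the unweighted least-squares solution; the
weights enter when aggregating channels into F and its gradient.

The number of exponentials N is normally fixed by the experimenter; an
automated choice via BIC over N = 1..n_max is provided for convenience.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .dataset import SpectralDataset
from .kinetics import LN2

__all__ = [
    "WeightVector",
    "GlobalFitResult",
    "estimate_weights",
    "solve_amplitudes",
    "objective_F",
    "fit_global",
    "OrderScore",
    "OrderSelection",
    "select_order",
    "bic_score",
]

logger = logging.getLogger(__name__)

#: fitted rate pairs closer than this factor are flagged as poorly identifiable
IDENTIFIABILITY_FACTOR = 3.0


@dataclass
class WeightVector:
    """Per-channel weights w(ν̃) with the estimation method that produced them."""

    values: np.ndarray
    method: str = "uniform"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("weights must be a non-empty vector")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("weights must be finite and non-negative")
        if not np.any(self.values > 0):
            raise ValueError("weights must not all be zero")


def _weight_values(weights, n_channels: int) -> tuple[np.ndarray, str]:
    if weights is None:
        return np.ones(n_channels), "uniform"
    if isinstance(weights, WeightVector):
        w, method = weights.values, weights.method
    else:
        w, method = WeightVector(np.asarray(weights, dtype=float)).values, "custom"
    if w.size != n_channels:
        raise ValueError(f"weight vector length {w.size} != n_channels {n_channels}")
    return w, method


def estimate_weights(dataset: SpectralDataset, method: str = "uniform") -> WeightVector:
    """Per-channel weights for the global fit.

    ``"uniform"``: all ones.  ``"inverse_noise"``: ``w = 1/σ̂`` with the noise
    level σ̂ per channel estimated from second differences along time divided
    by √6 (a difference filter annihilates constant and linear trends, so
    slowly varying kinetics contribute little).  σ̂ is floored at the 5th
    percentile across channels so that quiet channels cannot acquire
    unbounded weight.
    """
    if method == "uniform":
        return WeightVector(np.ones(dataset.n_channels), method="uniform")
    if method != "inverse_noise":
        raise ValueError(f"unknown weight method {method!r}")
    if dataset.n_times < 3:
        raise ValueError("inverse_noise weighting needs at least 3 time points")
    d2 = np.diff(dataset.values, n=2, axis=1)
    sigma = np.sqrt(np.mean(d2 * d2, axis=1) / 6.0)
    top = float(np.max(sigma))
    if top == 0.0:
        logger.warning("all channels are noise-free; falling back to uniform weights")
        return WeightVector(np.ones(dataset.n_channels), method="inverse_noise")
    floor = max(float(np.percentile(sigma, 5.0)), 1e-12 * top)
    n_floored = int(np.sum(sigma < floor))
    if n_floored:
        logger.warning("floored %d channel noise estimates at %.3g", n_floored, floor)
    return WeightVector(1.0 / np.maximum(sigma, floor), method="inverse_noise")


# ---------------------------------------------------------------------------
# linear sub-problem and objective
# ---------------------------------------------------------------------------

def _check_rates(rates: np.ndarray) -> None:
    if np.any(rates <= 0) or not np.all(np.isfinite(rates)):
        raise ValueError("rates must be positive and finite")
    srt = np.sort(rates)
    for a, b in zip(srt[:-1], srt[1:]):
        if (b - a) <= 1e-9 * max(a, b):
            raise ValueError(
                f"rates {a:.9g} and {b:.9g} are degenerate "
                "(relative gap <= 1e-9): the design is rank deficient"
            )


def _design(times: np.ndarray, rates: np.ndarray, with_offset: bool) -> np.ndarray:
    E = np.exp(-np.outer(times, rates))
    if with_offset:
        E = np.column_stack([E, np.ones_like(times)])
    return E


def solve_amplitudes(
    dataset: SpectralDataset,
    rates,
    weights=None,
    with_offset: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-channel least-squares amplitudes and offsets for fixed rates.

    Returns ``(amplitude_spectra, offset)`` with shapes ``(N, n_channels)``
    and ``(n_channels,)`` (zeros when ``with_offset`` is False).  The weights
    argument is accepted for interface symmetry: since w(ν̃) is constant along
    time within a channel, it cancels from the per-channel minimizer.
    Raises when the rates are too close relative to the time grid for the
    exponential design to have full rank, naming the offending pair.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    _check_rates(rates)
    _weight_values(weights, dataset.n_channels)  # shape validation only
    E = _design(dataset.times, rates, with_offset)
    sv = np.linalg.svd(E, compute_uv=False)
    if sv[-1] <= sv[0] * 1e-12:
        logk = np.log10(np.sort(rates))
        gaps = np.diff(logk)
        j = int(np.argmin(gaps)) if gaps.size else 0
        pair = 10.0 ** logk[j : j + 2]
        raise ValueError(
            "exponential design is rank deficient on this time grid; "
            f"closest rate pair: {pair[0]:.6g} and {pair[-1]:.6g} s^-1"
        )
    coef, *_ = np.linalg.lstsq(E, dataset.values.T, rcond=None)
    n = rates.size
    amplitudes = coef[:n]
    offset = coef[n] if with_offset else np.zeros(dataset.n_channels)
    return amplitudes, offset


def objective_F(dataset: SpectralDataset, rates, amplitude_spectra, offset, weights=None) -> float:
    """Evaluate the weighted squared-error objective F for given parameters."""
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    A = np.atleast_2d(np.asarray(amplitude_spectra, dtype=float))
    offset = np.asarray(offset, dtype=float)
    if A.shape != (rates.size, dataset.n_channels):
        raise ValueError(
            f"amplitude_spectra shape {A.shape} != (n_rates={rates.size}, "
            f"n_channels={dataset.n_channels})"
        )
    if offset.shape != (dataset.n_channels,):
        raise ValueError("offset must have one entry per channel")
    w, _ = _weight_values(weights, dataset.n_channels)
    E = _design(dataset.times, rates, with_offset=True)
    model = (E @ np.vstack([A, offset])).T
    resid = dataset.values - model
    return float(np.sum((w[:, None] * resid) ** 2))


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------

@dataclass
class GlobalFitResult:
    """Result of a multi-exponential global fit.

    Rates are sorted descending (fastest process first); ``halflives`` are
    ``ln 2 / k`` so they compare directly with printed transition tables.
    ``identifiability_warnings`` lists rate pairs closer than a factor of
    three — the practical resolution limit of exponential analysis.
    """

    rates: np.ndarray
    taus: np.ndarray
    halflives: np.ndarray
    amplitude_spectra: np.ndarray
    offset: np.ndarray
    weights: np.ndarray
    weight_method: str
    F: float
    residuals: np.ndarray
    n_exponentials: int
    converged: bool
    n_starts: int
    seed: int
    axis: np.ndarray
    times: np.ndarray
    identifiability_warnings: tuple[tuple[float, float], ...] = ()

    @property
    def halflives_ascending(self) -> np.ndarray:
        return self.halflives[::-1]


def fit_global(
    dataset: SpectralDataset,
    n_exponentials: int,
    weights=None,
    *,
    n_starts: int = 20,
    seed: int = 0,
    rate_bounds: tuple[float, float] | None = None,
    tol: float = 1e-10,
    with_offset: bool = True,
    max_nfev: int | None = None,
) -> GlobalFitResult:
    """Minimize F over shared rates by multi-start variable projection.

    Parameters
    ----------
    n_exponentials : number N of exponential components; the dataset must have
        at least ``2N + 1`` time points.
    weights : ``WeightVector``, plain vector, or None (uniform).
    n_starts : number of outer-optimizer starts; the first start is a
        deterministic log-spaced rate ladder across the observed time window,
        the rest are seeded jitters of it.
    rate_bounds : (k_min, k_max); default ``[1/(10·t_max), 10/t_min]``.
    tol : relative convergence tolerance of the outer trust-region optimizer.
    max_nfev : cap on outer function evaluations per start (None = automatic).

    A result with ``converged=False`` is returned (not raised) when no start
    met the tolerance within its evaluation budget.
    """
    N = int(n_exponentials)
    if N < 1:
        raise ValueError("n_exponentials must be >= 1")
    if dataset.n_times < 2 * N + 1:
        raise ValueError(
            f"need at least {2 * N + 1} time points for N={N}, got {dataset.n_times}"
        )
    w, weight_method = _weight_values(weights, dataset.n_channels)
    t = dataset.times
    D = dataset.values
    k_lo, k_hi = rate_bounds if rate_bounds is not None else (1.0 / (10.0 * t[-1]), 10.0 / t[0])
    if not 0 < k_lo < k_hi:
        raise ValueError("rate_bounds must satisfy 0 < k_min < k_max")
    lb, ub = math.log10(k_lo), math.log10(k_hi)

    span_lo = max(math.log10(1.0 / t[-1]), lb)
    span_hi = min(math.log10(1.0 / t[0]), ub)
    if N > 1:
        base = np.linspace(span_lo, span_hi, N)
    else:
        base = np.array([0.5 * (span_lo + span_hi)])
    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.clip(base + rng.normal(0.0, 0.5, N), lb + 1e-9, ub - 1e-9))

    n_linear = N + (1 if with_offset else 0)

    def residual(x: np.ndarray) -> np.ndarray:
        E = np.exp(-np.outer(t, 10.0**x))
        if with_offset:
            E = np.column_stack([E, np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(E, D.T, rcond=None)
        R = D.T - E @ coef
        return (R * w[None, :]).ravel()

    best = None
    all_deficient = True
    for x0 in starts:
        res = scipy.optimize.least_squares(
            residual,
            np.sort(x0),
            bounds=(lb, ub),
            method="trf",
            ftol=tol,
            xtol=tol,
            gtol=tol,
            max_nfev=max_nfev,
        )
        E = _design(t, 10.0**res.x, with_offset)
        sv = np.linalg.svd(E, compute_uv=False)
        deficient = sv[-1] <= sv[0] * 1e-12
        all_deficient &= deficient
        if not deficient and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        if all_deficient:
            raise ValueError(
                f"N={N} is too large for the time support: the exponential design "
                "is rank deficient at every start"
            )
        raise RuntimeError("global fit failed at every start")

    k = np.sort(10.0**best.x)[::-1]
    try:
        A, offs = solve_amplitudes(dataset, k, with_offset=with_offset)
    except ValueError:
        # degenerate final rates: fall back to the minimum-norm solution
        E = _design(t, k, with_offset)
        coef, *_ = np.linalg.lstsq(E, D.T, rcond=None)
        A = coef[:N]
        offs = coef[N] if with_offset else np.zeros(dataset.n_channels)
    F = objective_F(dataset, k, A, offs, w)
    E = _design(t, k, with_offset=True)
    model = (E @ np.vstack([A, offs])).T

    warnings_: list[tuple[float, float]] = []
    for ki, kj in zip(k[:-1], k[1:]):
        if ki < IDENTIFIABILITY_FACTOR * kj:
            warnings_.append((float(ki), float(kj)))
    if warnings_:
        logger.warning(
            "fitted rate pairs within a factor of %g: %s",
            IDENTIFIABILITY_FACTOR,
            ", ".join(f"({a:.3g}, {b:.3g})" for a, b in warnings_),
        )

    return GlobalFitResult(
        rates=k,
        taus=1.0 / k,
        halflives=LN2 / k,
        amplitude_spectra=A,
        offset=offs,
        weights=w,
        weight_method=weight_method,
        F=F,
        residuals=dataset.values - model,
        n_exponentials=N,
        converged=bool(best.status > 0),
        n_starts=n_starts,
        seed=seed,
        axis=dataset.axis.copy(),
        times=dataset.times.copy(),
        identifiability_warnings=tuple(warnings_),
    )


# ---------------------------------------------------------------------------
# model-order selection
# ---------------------------------------------------------------------------

def bic_score(F: float, n_cells: int, n_parameters: int) -> float:
    """Gaussian-likelihood BIC from a (weighted) residual sum of squares.

    ``BIC = M·ln(F/M) + p·ln(M)`` with M data cells and p free parameters.
    F is floored at ``M·1e−28`` so that numerically perfect fits stay finite
    and comparable.
    """
    F_eff = max(float(F), n_cells * 1e-28)
    return n_cells * math.log(F_eff / n_cells) + n_parameters * math.log(n_cells)


@dataclass(frozen=True)
class OrderScore:
    n_exponentials: int
    F: float
    n_parameters: int
    bic: float
    converged: bool


@dataclass(frozen=True)
class OrderSelection:
    chosen_n: int
    scores: tuple[OrderScore, ...]
    non_informative: bool


def select_order(
    dataset: SpectralDataset,
    n_max: int,
    criterion: str = "bic",
    weights=None,
    **fit_options,
) -> OrderSelection:
    """Fit N = 1..n_max and choose the number of exponentials by BIC.

    The parameter count charges the shared rates plus every per-channel
    amplitude and offset.  ``non_informative`` is set when the offset-only
    (zero-exponential) model scores at least as well by BIC as every fitted
    order, i.e. the data carry no resolvable kinetics.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if criterion != "bic":
        raise ValueError(f"unknown criterion {criterion!r}")
    w, _ = _weight_values(weights, dataset.n_channels)
    M = dataset.values.size
    mean = dataset.values.mean(axis=1, keepdims=True)
    F0 = float(np.sum((w[:, None] * (dataset.values - mean)) ** 2))

    scores = []
    for n in range(1, n_max + 1):
        fit = fit_global(dataset, n, weights=w, **fit_options)
        p = n + dataset.n_channels * (n + 1)
        scores.append(
            OrderScore(
                n_exponentials=n,
                F=fit.F,
                n_parameters=p,
                bic=bic_score(fit.F, M, p),
                converged=fit.converged,
            )
        )
    best = min(scores, key=lambda s: s.bic)
    bic0 = bic_score(F0, M, dataset.n_channels)
    non_informative = bic0 <= best.bic
    return OrderSelection(
        chosen_n=best.n_exponentials, scores=tuple(scores), non_informative=non_informative
    )
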