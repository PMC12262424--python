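"""Pairwise TMRCA decoding, selection-coefficient inference and
satellite mutation-rate estimation.

Three inference layers live here:

* A windowed HMM over discretised coalescence times for one haplotype pair:
  the hidden state of a window is its TMRCA bin T_j, the emission is the
  Poisson-distributed pairwise difference count with mean 2*mu*L*T_j, and
  transitions mix a stay probability with prior-weighted switches. Posterior
  decoding yields a TMRCA grid whose recent-mass fraction scores selective
  sweeps (a sweep compresses coalescence times among carriers).

* A Wright-Fisher frequency-grid likelihood for an allele trajectory under
  genic selection s: the population frequency lives on a grid, drifts with
  variance p(1-p)/(2N) and deterministic increment s*p(1-p)/(1+s*p) per
  generation (Gaussian transition, absorbing boundaries), and is observed
  through binomial samples at given times. Single-epoch and two-epoch
  (piecewise s with one free change time) models are fitted by maximum
  likelihood and compared to neutrality with a chi-squared test on the
  log-likelihood-ratio statistic (deviance).

* Divergence-based mutation-rate estimation for alpha-satellite higher-order
  repeats: with per-window divergence d, divergence time T (years),
  generation time g and ancestral diploid size N_anc, the neutral-model
  estimate is mu = d / (2*T/g + 4*N_anc) per bp per generation, evaluated on
  a (T, N_anc) grid spanning the assumed ranges. Phred-scale QV/error-rate
  conversion utilities round out the toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "TMRCAGrid",
    "TrajectoryObservations",
    "SelectionFit",
    "MutationRateEstimate",
    "pairwise_tmrca_posterior",
    "sweep_score",
    "wf_loglik",
    "fit_selection",
    "chi2_sf",
    "hor_mutation_rate",
    "phred_convert",
    "pairwise_divergence",
]


# ---------------------------------------------------------------------------
# pairwise TMRCA decoding
# ---------------------------------------------------------------------------


@dataclass
class TMRCAGrid:
    """Posterior over discretised TMRCA (generations) per window."""

    window_starts: np.ndarray
    window_ends: np.ndarray
    time_bins: np.ndarray
    posterior: np.ndarray  # (windows, bins)
    mu: float
    L: int
    prior: np.ndarray

    def posterior_mean(self) -> np.ndarray:
        return self.posterior @ self.time_bins

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.posterior, columns=[f"t{int(t)}" for t in self.time_bins]
        )
        df.insert(0, "end", self.window_ends)
        df.insert(0, "start", self.window_starts)
        return df


def pairwise_tmrca_posterior(
    diff_counts: np.ndarray,
    L: int,
    mu: float,
    time_bins: np.ndarray,
    prior: np.ndarray | None = None,
    switch_prob: float = 0.1,
    window_starts: np.ndarray | None = None,
) -> TMRCAGrid:
    """Forward-backward posterior over TMRCA bins for consecutive windows.

    ``diff_counts[w]`` is the number of pairwise differences in window w of
    length ``L`` bp. Emissions are Poisson(2*mu*L*T_j). Transitions stay in
    the current bin with probability 1-switch_prob and otherwise move to a
    bin drawn from the prior (self-transitions through the prior included),
    a single-parameter stand-in for the sequential-coalescent switch rates.
    """
    diff_counts = np.asarray(diff_counts, dtype=float)
    time_bins = np.asarray(time_bins, dtype=float)
    if time_bins.size < 2:
        raise ValueError("need >= 2 time bins")
    if np.any(np.diff(time_bins) <= 0) or time_bins[0] <= 0:
        raise ValueError("time bins must be positive and strictly increasing")
    if np.any(diff_counts < 0):
        raise ValueError("difference counts must be >= 0")
    if prior is None:
        prior = np.full(time_bins.size, 1.0 / time_bins.size)
    prior = np.asarray(prior, dtype=float)
    if prior.sum() <= 0:
        raise ValueError("prior must have positive mass")
    prior = prior / prior.sum()

    lam = 2.0 * mu * L * time_bins
    k = diff_counts[:, None]
    logb = k * np.log(lam[None, :]) - lam[None, :] - gammaln(k + 1)
    rowmax = logb.max(axis=1, keepdims=True)
    b = np.exp(logb - rowmax)

    nbins = time_bins.size
    A = (1 - switch_prob) * np.eye(nbins) + switch_prob * np.tile(prior, (nbins, 1))
    n = diff_counts.size
    alpha = np.empty((n, nbins))
    scale = np.empty(n)
    alpha[0] = prior * b[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ A) * b[t]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta = np.ones((n, nbins))
    for t in range(n - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)

    if window_starts is None:
        window_starts = np.arange(n) * L
    window_starts = np.asarray(window_starts, dtype=int)
    return TMRCAGrid(
        window_starts=window_starts,
        window_ends=window_starts + L,
        time_bins=time_bins,
        posterior=post,
        mu=mu,
        L=L,
        prior=prior,
    )


def sweep_score(grid: TMRCAGrid, recent_threshold: float) -> tuple[np.ndarray, float]:
    """Posterior mass on TMRCA bins younger than ``recent_threshold``,
    per window and aggregated (mean over windows)."""
    if not grid.time_bins.min() <= recent_threshold <= grid.time_bins.max():
        raise ValueError("threshold outside the bin range")
    recent = grid.time_bins < recent_threshold
    per_window = grid.posterior[:, recent].sum(axis=1)
    return per_window, float(per_window.mean())


# ---------------------------------------------------------------------------
# Wright-Fisher trajectory likelihood
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryObservations:
    """Derived-allele counts in samples taken along a trajectory.

    ``times`` are generations before present, strictly decreasing (oldest
    first); a present-day sample has time 0.
    """

    times: np.ndarray
    counts: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if np.any(np.diff(self.times) >= 0):
            raise ValueError("times must be strictly decreasing toward present")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(self.counts > self.sizes) or np.any(self.counts < 0):
            raise ValueError("counts must lie in [0, size]")


_matrix_cache: dict = {}


def _transition_matrix(s: float, N: float, grid: np.ndarray) -> np.ndarray:
    """One-generation frequency-transition matrix on the grid.

    Interior rows are Gaussian with mean p + s*p*(1-p)/(1+s*p) and variance
    p*(1-p)/(2N), integrated over grid cells (midpoint boundaries); tail mass
    goes to the absorbing states at 0 and 1.
    """
    key = ("M", round(float(s), 12), float(N), grid.size)
    if key in _matrix_cache:
        return _matrix_cache[key]
    n = grid.size
    edges = np.concatenate(([-np.inf], (grid[:-1] + grid[1:]) / 2, [np.inf]))
    M = np.zeros((n, n))
    p = grid[1:-1]
    mean = p + s * p * (1 - p) / (1 + s * p)
    sd = np.sqrt(p * (1 - p) / (2 * N))
    cdf = stats.norm.cdf((edges[None, :] - mean[:, None]) / sd[:, None])
    M[1:-1, :] = np.diff(cdf, axis=1)
    M[0, 0] = 1.0
    M[-1, -1] = 1.0
    if len(_matrix_cache) > 512:
        _matrix_cache.clear()
    _matrix_cache[key] = M
    return M


def _matrix_power_cached(s: float, N: float, grid: np.ndarray, dt: int) -> np.ndarray:
    key = ("P", round(float(s), 12), float(N), grid.size, int(dt))
    if key in _matrix_cache:
        return _matrix_cache[key]
    M = _transition_matrix(s, N, grid)
    P = np.linalg.matrix_power(M, int(dt))
    if len(_matrix_cache) > 512:
        _matrix_cache.clear()
        _matrix_cache[("M", round(float(s), 12), float(N), grid.size)] = M
    _matrix_cache[key] = P
    return P


def _s_at(t: float, s_schedule) -> float:
    """Selection coefficient in force at ``t`` generations before present.

    ``s_schedule`` lists (epoch_start_time, s) with strictly decreasing start
    times; epoch i covers (start_{i+1}, start_i]. Times older than the first
    start fall into the first epoch.
    """
    if np.isscalar(s_schedule):
        return float(s_schedule)
    chosen = s_schedule[0][1]
    for start, s in s_schedule:
        if start >= t:
            chosen = s
        else:
            break
    return float(chosen)


def wf_loglik(
    obs: TrajectoryObservations,
    s_schedule,
    N: float,
    grid_size: int = 151,
) -> float:
    """Forward log-likelihood of the observations under the frequency-grid
    Wright-Fisher HMM.

    ``s_schedule`` is a single genic selection coefficient or a list of
    (epoch_start_generations_before_present, s) pairs with strictly
    decreasing start times; each epoch runs from its start toward the next
    start (or the present). The initial frequency prior at the oldest
    observation time is uniform on (0, 1) with trapezoid weights.
    """
    if grid_size < 100:
        raise ValueError("frequency grid must have >= 100 points")
    grid = np.linspace(0.0, 1.0, grid_size)
    # trapezoid weights of a uniform density; boundary states get half cells
    w = np.full(grid_size, 1.0 / (grid_size - 1))
    w[0] = w[-1] = 0.5 / (grid_size - 1)
    v = w.copy()

    loglik = 0.0
    t_prev = None
    for t, k, n in zip(obs.times, obs.counts, obs.sizes):
        if t_prev is not None:
            # propagate from t_prev down to t, splitting at epoch boundaries
            t_hi = t_prev
            while t_hi > t:
                if np.isscalar(s_schedule):
                    t_lo = t
                else:
                    inner = [st for st, _ in s_schedule if t < st < t_hi]
                    t_lo = max(inner) if inner else t
                s_here = _s_at(t_hi, s_schedule)
                dt = int(round(t_hi - t_lo))
                if dt > 0:
                    v = v @ _matrix_power_cached(s_here, N, grid, dt)
                t_hi = t_lo
        emit = stats.binom.pmf(k, n, grid)
        v = v * emit
        tot = v.sum()
        if tot <= 0:
            return -np.inf
        loglik += np.log(tot)
        v = v / tot
        t_prev = t
    return float(loglik)


@dataclass
class SelectionFit:
    """Maximum-likelihood selection fit with a nested neutral comparison.

    ``statistic`` is the log-likelihood-ratio statistic (the deviance,
    2*(LL_alt - LL_null)) referred to a chi-squared distribution with ``df``
    degrees of freedom — the free parameters the alternative adds over
    neutrality (1 for a single epoch; 3 for two epochs with a free change
    time)."""

    model: str
    params: dict
    loglik_alt: float
    loglik_null: float
    statistic: float
    df: int
    p_value: float
    converged: bool = True

    def summary(self) -> str:
        par = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return (
            f"{self.model}: {par}; LLR={self.statistic:.4f}, df={self.df}, "
            f"p={self.p_value:.4g}{'' if self.converged else ' (not converged)'}"
        )


def _s_grid() -> np.ndarray:
    mags = np.concatenate([[0.0], np.logspace(-4, np.log10(0.5), 13)])
    return np.unique(np.concatenate([-mags, mags]))


def fit_selection(
    obs: TrajectoryObservations,
    model: str = "single_epoch",
    N: float = 10_000.0,
    grid_size: int = 151,
    change_time_candidates: Sequence[float] | None = None,
) -> SelectionFit:
    """Fit a selection model to trajectory observations and test neutrality.

    ``model='single_epoch'`` fits one constant s (df=1);
    ``model='two_epoch'`` fits (s1, s2) with one free change time chosen
    among ``change_time_candidates`` (df=3). The log-likelihood ratio
    against s=0 serves directly as the chi-squared statistic.
    """
    ll_null = wf_loglik(obs, 0.0, N, grid_size)
    converged = True

    if model == "single_epoch":
        sgrid = _s_grid()
        lls = [wf_loglik(obs, s, N, grid_size) for s in sgrid]
        i_best = int(np.argmax(lls))
        s0 = sgrid[i_best]
        lo = sgrid[max(i_best - 1, 0)]
        hi = sgrid[min(i_best + 1, sgrid.size - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda s: -wf_loglik(obs, float(s), N, grid_size),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-4, "maxiter": 25},
            )
            if -res.fun >= lls[i_best]:
                s_mle, ll_alt = float(res.x), float(-res.fun)
            else:
                s_mle, ll_alt = float(s0), float(lls[i_best])
                converged = False
        else:
            s_mle, ll_alt = float(s0), float(lls[i_best])
        params = {"s": s_mle}
        df = 1
    elif model == "two_epoch":
        t0 = float(obs.times.max())
        if change_time_candidates is None:
            change_time_candidates = np.unique(
                np.round(t0 * np.array([0.25, 0.5, 0.75]))
            )
        coarse = np.unique(
            np.concatenate([[0.0], np.logspace(-3, np.log10(0.5), 7),
                            -np.logspace(-3, np.log10(0.5), 7)])
        )
        best = (-np.inf, None)
        for tc in change_time_candidates:
            for s1 in coarse:
                for s2 in coarse:
                    ll = wf_loglik(obs, [(t0, s1), (float(tc), s2)], N, grid_size)
                    if ll > best[0]:
                        best = (ll, (float(s1), float(s2), float(tc)))
        ll_alt, (s1, s2, tc) = best
        res = optimize.minimize(
            lambda x: -wf_loglik(obs, [(t0, x[0]), (tc, x[1])], N, grid_size),
            x0=[s1, s2], method="Nelder-Mead",
            options={"maxiter": 60, "xatol": 1e-4, "fatol": 1e-4},
        )
        if -res.fun > ll_alt:
            ll_alt = float(-res.fun)
            s1, s2 = float(res.x[0]), float(res.x[1])
        params = {"s1": s1, "s2": s2, "change_time": tc}
        df = 3
    else:
        raise ValueError("model must be 'single_epoch' or 'two_epoch'")

    ll_alt = max(ll_alt, ll_null)  # nesting: s=0 is inside the alternative
    statistic = 2.0 * (ll_alt - ll_null)
    return SelectionFit(
        model=model, params=params, loglik_alt=ll_alt, loglik_null=ll_null,
        statistic=statistic, df=df, p_value=chi2_sf(statistic, df),
        converged=converged,
    )


def chi2_sf(statistic: float, df: int) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    if statistic < 0:
        raise ValueError("statistic must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(statistic, df))


# ---------------------------------------------------------------------------
# satellite mutation rates
# ---------------------------------------------------------------------------


@dataclass
class MutationRateEstimate:
    """Per-window, per-(T, N_anc) mutation-rate estimates with summaries.

    ``estimates[w, i, j]`` is the rate from window w at divergence time
    T_grid[i] (years) and ancestral size N_grid[j]; units are per bp per
    generation. ``per_allele(length)`` rescales to per allele per generation.
    """

    divergences: np.ndarray
    T_grid: np.ndarray
    N_grid: np.ndarray
    generation_time: float
    estimates: np.ndarray
    saturated: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.estimates))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.estimates))

    @property
    def per_window_mean(self) -> np.ndarray:
        return np.nanmean(self.estimates, axis=(1, 2))

    def per_allele(self, allele_length: float) -> float:
        return self.mean * allele_length


def hor_mutation_rate(
    divergence_per_window: np.ndarray,
    T_years_range: tuple[float, float],
    N_anc_range: tuple[float, float],
    g: float = 29.0,
    n_grid: int = 4,
) -> MutationRateEstimate:
    """Neutral-model mutation rate from per-window divergence.

    For each window divergence d and (T, N_anc) grid point,
    mu = d / (2*T/g + 4*N_anc): the expected divergence of orthologous
    neutral sequence is 2*mu*t generations of branch plus the coalescent
    contribution 4*N_anc*mu in the common ancestor. Windows with d >= 0.75
    (beyond Jukes-Cantor saturation) are flagged and excluded from summaries.
    """
    d = np.asarray(divergence_per_window, dtype=float)
    if np.any((d < 0) | (d >= 1)):
        raise ValueError("divergences must be in [0, 1)")
    if T_years_range[0] > T_years_range[1] or N_anc_range[0] > N_anc_range[1]:
        raise ValueError("ranges must be (low, high)")
    T_grid = np.linspace(T_years_range[0], T_years_range[1], n_grid)
    N_grid = np.linspace(N_anc_range[0], N_anc_range[1], n_grid)
    t_gen = T_grid / g
    denom = 2.0 * t_gen[:, None] + 4.0 * N_grid[None, :]
    est = d[:, None, None] / denom[None, :, :]
    saturated = d >= 0.75
    est = est.astype(float)
    est[saturated, :, :] = np.nan
    return MutationRateEstimate(
        divergences=d, T_grid=T_grid, N_grid=N_grid, generation_time=g,
        estimates=est, saturated=saturated,
    )


# ---------------------------------------------------------------------------
# Phred / divergence utilities
# ---------------------------------------------------------------------------


def phred_convert(value: float, direction: str) -> float:
    """Convert between Phred-scaled quality (QV) and error rate.

    ``direction='to_error'``: error = 10^(-QV/10);
    ``direction='to_qv'``: QV = -10*log10(error). An error rate of 0 maps
    to +inf QV (flagged by a warning)."""
    if direction == "to_error":
        if value < 0:
            raise ValueError("QV must be >= 0")
        return float(10 ** (-value / 10))
    if direction == "to_qv":
        if value == 0:
            warnings.warn("error rate 0: QV is infinite")
            return float("inf")
        if not 0 < value <= 1:
            raise ValueError("error rate must be in (0, 1]")
        return float(-10 * np.log10(value))
    raise ValueError("direction must be 'to_error' or 'to_qv'")


def pairwise_divergence(
    seq_a: str,
    seq_b: str,
    window: int = 20000,
    jc_correct: bool = False,
    min_aligned_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-window divergence between two aligned (or equal-length) sequences.

    Gap characters '-' mark alignment columns; a column counts toward the
    denominator only when both sequences have a base there. Raw divergence is
    mismatches / aligned columns; the optional Jukes-Cantor correction is
    d_JC = -(3/4) ln(1 - (4/3) d), with d >= 0.75 flagged as saturated
    (NaN). Windows with fewer than ``min_aligned_fraction`` aligned columns
    are flagged missing. Unequal-length ungapped sequences are globally
    aligned first.
    """
    if len(seq_a) != len(seq_b):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        aln = aligner.align(seq_a, seq_b)[0]
        seq_a, seq_b = str(aln[0]), str(aln[1])
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    gap = ord("-")
    both = (a != gap) & (b != gap)
    mism = both & (a != b)
    rows = []
    for ws in range(0, len(a), window):
        we = min(ws + window, len(a))
        n_cols = int(both[ws:we].sum())
        n_mis = int(mism[ws:we].sum())
        if n_cols < min_aligned_fraction * (we - ws):
            rows.append({"start": ws, "end": we, "divergence": np.nan,
                         "flag": "missing"})
            continue
        d = n_mis / n_cols
        flag = ""
        if jc_correct:
            if d >= 0.75:
                d, flag = np.nan, "saturated"
            else:
                d = -0.75 * np.log(1 - 4 * d / 3)
        rows.append({"start": ws, "end": we, "divergence": d, "flag": flag})
    return pd.DataFrame(rows)
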