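"""Archaic-introgression segment calling on phased haplotypes.

A two-state (modern/archaic) hidden Markov model runs along fixed windows of
one haplotype. The observable per window is the number of *private* derived
variants — derived alleles the focal haplotype carries at sites where an
outgroup panel (African-like, essentially archaic-free) carries no derived
allele. Archaic tracts are enriched for such variants because of the long
archaic branch. Emissions are Poisson with a per-state rate scaled by the
window's callable fraction; parameters are fitted by Baum-Welch and segments
decoded from forward-backward posteriors.

Called segments are then assigned an archaic origin by their derived-allele
match rate to each available archaic genome (e.g. a Neanderthal and a
Denisovan): segments matching neither beyond a low-affinity floor (default
10%) are rejected; a clear excess toward one archaic labels the segment with
that origin; anything else is ambiguous (AMB). External segment sets (e.g.
from Sprime) can be intersected with HMM calls to form consensus segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "HMMParams",
    "SegmentCall",
    "ArchaicMatchProfile",
    "window_private_variants",
    "state_posteriors",
    "fit_hmm",
    "decode_segments",
    "match_rate",
    "classify_origin",
    "consensus_segments",
    "segments_to_frame",
]

MODERN, ARCHAIC = 0, 1


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------


def window_private_variants(
    focal_positions: np.ndarray,
    outgroup_positions: np.ndarray,
    window_size: int,
    chrom_length: int,
    *,
    chrom: str = "chr1",
    callable_fraction: np.ndarray | None = None,
) -> pd.DataFrame:
    """Count focal derived alleles private w.r.t. the outgroup panel per window.

    ``focal_positions``: positions (0-based) where the focal haplotype carries
    a derived allele. ``outgroup_positions``: positions where *any* outgroup
    haplotype carries a derived allele. Windows tile [0, chrom_length) without
    overlap; the last window may be short.
    """
    if window_size < 1000:
        raise ValueError("window_size must be >= 1000 bp")
    outgroup_positions = np.asarray(outgroup_positions)
    if outgroup_positions.size == 0:
        raise ValueError(
            "empty outgroup panel: every focal variant would be private"
        )
    focal_positions = np.asarray(focal_positions)
    private = np.setdiff1d(focal_positions, outgroup_positions, assume_unique=False)
    starts = np.arange(0, chrom_length, window_size, dtype=int)
    ends = np.minimum(starts + window_size, chrom_length)
    counts, _ = np.histogram(private, bins=np.append(starts, chrom_length))
    if callable_fraction is None:
        callable_fraction = np.ones(len(starts))
    callable_fraction = np.asarray(callable_fraction, dtype=float)
    if callable_fraction.shape != starts.shape:
        raise ValueError("callable_fraction must have one value per window")
    if np.any((callable_fraction < 0) | (callable_fraction > 1)):
        raise ValueError("callable fraction must be in [0, 1]")
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "count": counts.astype(int),
            "callable": callable_fraction,
        }
    )


# ---------------------------------------------------------------------------
# HMM parameters
# ---------------------------------------------------------------------------


@dataclass
class HMMParams:
    """Two-state HMM parameters; state 0 = modern, state 1 = archaic.

    ``rates`` are expected private-variant counts per fully callable window;
    the effective Poisson mean in a window is ``rate * callable``.
    """

    initial: np.ndarray = field(
        default_factory=lambda: np.array([0.97, 0.03])
    )
    transition: np.ndarray = field(
        default_factory=lambda: np.array([[0.999, 0.001], [0.02, 0.98]])
    )
    rates: np.ndarray = field(default_factory=lambda: np.array([0.3, 4.0]))
    converged: bool = False
    warning: str | None = None
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.initial.shape != (2,) or self.transition.shape != (2, 2):
            raise ValueError("two states expected")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.initial < 0) or np.any(self.transition < 0):
            raise ValueError("probabilities must be >= 0")
        if np.any(self.rates < 0):
            raise ValueError("emission rates must be >= 0")


def _log_emissions(counts: np.ndarray, callable_frac: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """(n, 2) log Poisson(count; rate * callable); rate 0 handled exactly."""
    lam = np.outer(callable_frac, rates)  # (n, 2)
    k = counts[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logpmf = k * np.log(lam) - lam - gammaln(k + 1)
    zero = lam == 0
    logpmf[zero] = np.where(k.repeat(2, axis=1)[zero] == 0, 0.0, -np.inf)
    return logpmf


def _fb_kernel(b: np.ndarray, initial: np.ndarray, A: np.ndarray):
    """Scaled two-state forward-backward on emission likelihoods ``b``.

    Returns (gamma, xi_sum, log sum of scales). Per-window normalization
    keeps everything in linear space without underflow, independent of
    sequence length.
    """
    n = b.shape[0]
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    a00, a01 = A[0, 0], A[0, 1]
    a10, a11 = A[1, 0], A[1, 1]
    f0 = initial[0] * b[0, 0]
    f1 = initial[1] * b[0, 1]
    s = f0 + f1
    alpha[0, 0] = f0 / s
    alpha[0, 1] = f1 / s
    scale[0] = s
    for t in range(1, n):
        p0, p1 = alpha[t - 1, 0], alpha[t - 1, 1]
        f0 = (p0 * a00 + p1 * a10) * b[t, 0]
        f1 = (p0 * a01 + p1 * a11) * b[t, 1]
        s = f0 + f1
        alpha[t, 0] = f0 / s
        alpha[t, 1] = f1 / s
        scale[t] = s
    gamma = np.empty((n, 2))
    xi = np.zeros((2, 2))
    bt0, bt1 = 1.0, 1.0
    gamma[n - 1, 0] = alpha[n - 1, 0]
    gamma[n - 1, 1] = alpha[n - 1, 1]
    for t in range(n - 2, -1, -1):
        e0 = b[t + 1, 0] * bt0
        e1 = b[t + 1, 1] * bt1
        inv = 1.0 / scale[t + 1]
        nb0 = (a00 * e0 + a01 * e1) * inv
        nb1 = (a10 * e0 + a11 * e1) * inv
        p0, p1 = alpha[t, 0], alpha[t, 1]
        xi[0, 0] += p0 * a00 * e0 * inv
        xi[0, 1] += p0 * a01 * e1 * inv
        xi[1, 0] += p1 * a10 * e0 * inv
        xi[1, 1] += p1 * a11 * e1 * inv
        g0 = p0 * nb0
        g1 = p1 * nb1
        gs = g0 + g1
        gamma[t, 0] = g0 / gs
        gamma[t, 1] = g1 / gs
        bt0, bt1 = nb0, nb1
    return gamma, xi, np.sum(np.log(scale))


try:  # JIT-compile the sequential recursion when numba is available
    import numba

    _fb_kernel = numba.njit(cache=True)(_fb_kernel)
except ImportError:  # pragma: no cover
    pass


def _forward_backward(
    counts: np.ndarray, callable_frac: np.ndarray, params: HMMParams
):
    logb = _log_emissions(counts, callable_frac, params.rates)
    rowmax = logb.max(axis=1, keepdims=True)
    b = np.exp(logb - rowmax)
    gamma, xi_sum, logscale = _fb_kernel(
        b, params.initial.astype(float), params.transition.astype(float)
    )
    loglik = float(logscale + rowmax.sum())
    return gamma, xi_sum, loglik


def state_posteriors(
    observations: pd.DataFrame, params: HMMParams
) -> tuple[np.ndarray, float]:
    """Per-window posterior P(state | all windows) and total log-likelihood."""
    gamma, _, ll = _forward_backward(
        observations["count"].to_numpy(float),
        observations["callable"].to_numpy(float),
        params,
    )
    return gamma, ll


def fit_hmm(
    observations: pd.DataFrame,
    init: HMMParams | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> HMMParams:
    """Baum-Welch fit of the two-state Poisson HMM.

    The log-likelihood is non-decreasing across iterations; iteration stops
    when the improvement drops below ``tol`` or after ``max_iter`` rounds.
    States are relabelled, if needed, so that the archaic state has the
    larger emission rate. Degenerate data (all counts equal) returns the
    initial parameters with a warning flag.
    """
    if len(observations) < 100:
        raise ValueError("need >= 100 windows to fit")
    params = replace(init) if init is not None else HMMParams()
    counts = observations["count"].to_numpy(float)
    callable_frac = observations["callable"].to_numpy(float)
    if np.all(counts == counts[0]):
        out = replace(params)
        out.warning = "degenerate data: all window counts equal; returning init"
        return out

    trace: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        gamma, xi_sum, ll = _forward_backward(counts, callable_frac, params)
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        initial = gamma[0] / gamma[0].sum()
        transition = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        denom = gamma.T @ callable_frac
        rates = (gamma.T @ counts) / np.maximum(denom, 1e-300)
        params = HMMParams(initial=initial, transition=transition, rates=rates)

    if params.rates[ARCHAIC] < params.rates[MODERN]:
        perm = [ARCHAIC, MODERN]
        params = HMMParams(
            initial=params.initial[perm],
            transition=params.transition[np.ix_(perm, perm)],
            rates=params.rates[perm],
        )
    params.converged = converged
    params.loglik_trace = trace
    return params


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------


@dataclass
class ArchaicMatchProfile:
    """Per-archaic informative/matched site counts for one segment.

    ``rates`` maps archaic name -> matched/informative, NaN when a segment
    has no informative site covered by that archaic genome.
    """

    informative: dict[str, int]
    matched: dict[str, int]

    @property
    def rates(self) -> dict[str, float]:
        return {
            k: (self.matched[k] / self.informative[k]) if self.informative[k] else float("nan")
            for k in self.informative
        }

    @property
    def defined(self) -> bool:
        return any(v > 0 for v in self.informative.values())


@dataclass
class SegmentCall:
    """One putatively introgressed interval on one haplotype."""

    chrom: str
    start: int
    end: int
    haplotype: str
    mean_posterior: float
    match_profile: ArchaicMatchProfile | None = None
    origin: str = "AMB"
    source: str = "hmm"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")
        if not 0 <= self.mean_posterior <= 1:
            raise ValueError("posterior must be in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


def decode_segments(
    observations: pd.DataFrame,
    params: HMMParams,
    posterior_cutoff: float = 0.8,
    haplotype: str = "hap",
) -> list[SegmentCall]:
    """Merge maximal runs of windows with archaic posterior >= cutoff."""
    if not 0.5 < posterior_cutoff < 1:
        raise ValueError("posterior_cutoff must be in (0.5, 1)")
    gamma, _ = state_posteriors(observations, params)
    arch = gamma[:, ARCHAIC]
    flag = arch >= posterior_cutoff
    starts = observations["start"].to_numpy()
    ends = observations["end"].to_numpy()
    chrom = observations["chrom"].iloc[0] if len(observations) else "chr1"
    segs: list[SegmentCall] = []
    i = 0
    n = len(flag)
    while i < n:
        if flag[i]:
            j = i
            while j + 1 < n and flag[j + 1]:
                j += 1
            segs.append(
                SegmentCall(
                    chrom=chrom,
                    start=int(starts[i]),
                    end=int(ends[j]),
                    haplotype=haplotype,
                    mean_posterior=float(arch[i : j + 1].mean()),
                )
            )
            i = j + 1
        else:
            i += 1
    return segs


# ---------------------------------------------------------------------------
# origin classification
# ---------------------------------------------------------------------------


def match_rate(
    segment: SegmentCall,
    focal_positions: np.ndarray,
    archaic_genotypes: Mapping[str, Mapping[str, np.ndarray]],
    outgroup_positions: np.ndarray,
) -> ArchaicMatchProfile:
    """Derived-allele match profile of a segment against archaic genomes.

    ``archaic_genotypes`` maps archaic name to a dict with key ``derived``
    (positions where that archaic carries the derived allele) and optional
    ``covered`` (positions genotyped in that archaic; when given, informative
    sites are restricted to it — missing archaic sites do not count).
    Informative sites are the focal haplotype's private derived alleles
    inside the segment. A segment with zero informative sites everywhere is
    labelled REJECTED by :func:`classify_origin`.
    """
    focal_positions = np.asarray(focal_positions)
    inseg = focal_positions[
        (focal_positions >= segment.start) & (focal_positions < segment.end)
    ]
    private = np.setdiff1d(inseg, np.asarray(outgroup_positions))
    informative: dict[str, int] = {}
    matched: dict[str, int] = {}
    for name, data in archaic_genotypes.items():
        sites = private
        cov = data.get("covered")
        if cov is not None:
            sites = np.intersect1d(sites, np.asarray(cov))
        informative[name] = int(sites.size)
        matched[name] = int(np.intersect1d(sites, np.asarray(data["derived"])).size)
    return ArchaicMatchProfile(informative=informative, matched=matched)


def classify_origin(
    profile: ArchaicMatchProfile | None, low: float = 0.1, high: float = 0.3
) -> str:
    """Label a segment's archaic origin from its match profile.

    Rules: undefined profile -> REJECTED; all rates below ``low`` (the
    low-affinity floor) -> REJECTED; exactly one archaic at or above ``high``
    with all others below -> that archaic's label; otherwise AMB.
    """
    if profile is None or not profile.defined:
        return "REJECTED"
    rates = {k: v for k, v in profile.rates.items() if not np.isnan(v)}
    if not rates:
        return "REJECTED"
    if all(v < low for v in rates.values()):
        return "REJECTED"
    above = [k for k, v in rates.items() if v >= high]
    if len(above) == 1:
        return above[0]
    return "AMB"


# ---------------------------------------------------------------------------
# consensus with external segment sets
# ---------------------------------------------------------------------------


def consensus_segments(
    set_a: Sequence[SegmentCall],
    set_b: Sequence[SegmentCall],
    min_overlap_bp: int = 0,
    match_profile_fn: Callable[[SegmentCall], ArchaicMatchProfile] | None = None,
) -> list[SegmentCall]:
    """Intersections of two segment sets on matching haplotypes.

    Each pairwise intersection >= ``min_overlap_bp`` becomes a consensus
    segment. When ``match_profile_fn`` is given it is called on the
    intersected span to recompute the match profile and origin; otherwise the
    consensus carries no profile and keeps origin AMB.
    """
    out: list[SegmentCall] = []
    by_hap: dict[str, list[SegmentCall]] = {}
    for seg in set_b:
        by_hap.setdefault(seg.haplotype, []).append(seg)
    for a in set_a:
        for b in by_hap.get(a.haplotype, ()):
            if a.chrom != b.chrom:
                continue
            s, e = max(a.start, b.start), min(a.end, b.end)
            if e - s <= 0 or e - s < min_overlap_bp:
                continue
            seg = SegmentCall(
                chrom=a.chrom,
                start=s,
                end=e,
                haplotype=a.haplotype,
                mean_posterior=a.mean_posterior,
                source="consensus",
            )
            if match_profile_fn is not None:
                seg.match_profile = match_profile_fn(seg)
                seg.origin = classify_origin(seg.match_profile)
            out.append(seg)
    out.sort(key=lambda s: (s.haplotype, s.start, s.end))
    return out


def segments_to_frame(segments: Iterable[SegmentCall]) -> pd.DataFrame:
    """Tabular (BED6+-style) view of segment calls."""
    rows = []
    for s in segments:
        rates = s.match_profile.rates if s.match_profile is not None else {}
        rows.append(
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "haplotype": s.haplotype,
                "posterior": s.mean_posterior,
                "origin": s.origin,
                "source": s.source,
                **{f"rate_{k}": v for k, v in sorted(rates.items())},
            }
        )
    return pd.DataFrame(rows)
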