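"""Selection and introgression statistics with simulation-based significance.

Implements the Hudson estimator of F_ST, the population branch statistic
(PBS) over non-overlapping 100-SNV segments and for individual structural
variants, the f_D estimator of the local admixture fraction (an ABBA-BABA
derivative robust to low-diversity windows), r2 and Lewontin's D' linkage
statistics, and empirical p-values against a coalescent-simulated null
distribution generated under the same demographic model and computed through
the same code path as the observed statistics.

Frequencies are of *derived* alleles; ancestral state comes from a
designated outgroup/ancestral source, and sites with missing polarity are
dropped (and counted) before any statistic is formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import child_seed

__all__ = [
    "NullDistribution",
    "hudson_fst_components",
    "hudson_fst",
    "pbs",
    "segment_scan",
    "pbs_sv",
    "fd",
    "ld_stats",
    "empirical_p",
    "simulate_null",
    "freq_table_from_cohort",
]


# ---------------------------------------------------------------------------
# F_ST and PBS
# ---------------------------------------------------------------------------


def hudson_fst_components(p1, n1, p2, n2):
    """Hudson estimator per-site numerator and denominator.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    ``n`` are haplotype sample sizes (>= 2). Accepts scalars or arrays.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    if np.any(n1 <= 1) or np.any(n2 <= 1):
        raise ValueError("sample sizes must be >= 2")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst(p1, n1, p2, n2):
    """Per-site Hudson F_ST; NaN where the denominator is zero
    (monomorphic in both populations). Slightly negative values at finite n
    are expected and retained."""
    num, den = hudson_fst_components(p1, n1, p2, n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return float(out) if np.isscalar(p1) or out.ndim == 0 else out


def pbs(fst_focal_sister, fst_focal_out, fst_sister_out):
    """Population branch statistic for the focal branch.

    T(x) = -ln(1-x); PBS = (T(fs) + T(fo) - T(so)) / 2. Any F_ST equal to 1
    yields NaN (flagged undefined: the branch length diverges)."""
    arrs = [np.asarray(x, float) for x in (fst_focal_sister, fst_focal_out, fst_sister_out)]
    bad = np.zeros(arrs[0].shape, dtype=bool)
    for a in arrs:
        bad |= a >= 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = [-np.log1p(-np.clip(a, None, 1 - 1e-300)) for a in arrs]
        out = (t[0] + t[1] - t[2]) / 2
    out = np.where(bad, np.nan, out)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# frequency tables
# ---------------------------------------------------------------------------


def freq_table_from_cohort(
    cohort,
    focal: str = "PNG",
    sister: str = "EAS",
    outgroup: str = "AFR",
    archaic: str | None = None,
) -> pd.DataFrame:
    """Per-site derived-allele frequencies of a simulated cohort.

    Polarity is known in simulation (allele 0 ancestral), so no sites are
    dropped here; with real data, unpolarised sites would be excluded first.
    """
    cols: dict[str, np.ndarray] = {
        "chrom": np.repeat(cohort.chrom, len(cohort.variants)),
        "pos": cohort.variants["pos"].to_numpy(),
    }
    groups = {"focal": focal, "sister": sister, "out": outgroup}
    if archaic is not None:
        groups["arc"] = archaic
    for label, pop in groups.items():
        idx = [cohort.hap_index(h) for h in cohort.haplotypes_of(pop)]
        if not idx:
            raise ValueError(f"population {pop} has no haplotypes")
        sub = cohort.genotypes[:, idx]
        cols[f"p_{label}"] = sub.mean(axis=1)
        cols[f"n_{label}"] = np.full(len(cohort.variants), len(idx))
    return pd.DataFrame(cols)


def _block_pbs(block: pd.DataFrame) -> float:
    """Ratio-of-averages block PBS: mean numerator over mean denominator per
    population pair, then the T-transform."""
    pairs = [("focal", "sister"), ("focal", "out"), ("sister", "out")]
    fsts = []
    for a, b in pairs:
        num, den = hudson_fst_components(
            block[f"p_{a}"], block[f"n_{a}"], block[f"p_{b}"], block[f"n_{b}"]
        )
        dmean = np.mean(den)
        fsts.append(np.mean(num) / dmean if dmean > 0 else np.nan)
    return float(pbs(*fsts))


def segment_scan(freq_table: pd.DataFrame, segment_size: int = 100) -> pd.DataFrame:
    """PBS (and f_D when an archaic column is present) over consecutive
    non-overlapping blocks of exactly ``segment_size`` SNVs; a trailing
    remainder is dropped. Returns one row per segment."""
    tab = freq_table.sort_values("pos", kind="mergesort").reset_index(drop=True)
    n_seg = len(tab) // segment_size
    if n_seg == 0:
        warnings.warn("fewer SNVs than one segment; empty scan")
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_snvs", "pbs"]
        )
    rows = []
    has_arc = "p_arc" in tab.columns
    for i in range(n_seg):
        block = tab.iloc[i * segment_size : (i + 1) * segment_size]
        row = {
            "chrom": block["chrom"].iloc[0],
            "start": int(block["pos"].iloc[0]),
            "end": int(block["pos"].iloc[-1]) + 1,
            "n_snvs": segment_size,
            "pbs": _block_pbs(block),
        }
        if has_arc:
            row["fd"] = fd(block)
        rows.append(row)
    return pd.DataFrame(rows)


def pbs_sv(
    p_focal: float, n_focal: int,
    p_sister: float, n_sister: int,
    p_out: float, n_out: int,
) -> float:
    """Single-site PBS of an SV allele from its carrier frequencies.

    A population pair monomorphic for the same allele (zero Hudson
    denominator) contributes F_ST = 0 — no differentiation — so that an SV
    absent from both reference groups still has a defined focal branch."""
    def _fst(p1, n1, p2, n2):
        num, den = hudson_fst_components(p1, n1, p2, n2)
        return float(num / den) if den > 0 else 0.0

    return float(
        pbs(
            _fst(p_focal, n_focal, p_sister, n_sister),
            _fst(p_focal, n_focal, p_out, n_out),
            _fst(p_sister, n_sister, p_out, n_out),
        )
    )


# ---------------------------------------------------------------------------
# f_D
# ---------------------------------------------------------------------------


def _abba_baba_sum(pa, pb, pc, pd_) -> float:
    return float(np.sum((1 - pa) * pb * pc * (1 - pd_) - pa * (1 - pb) * pc * (1 - pd_)))


def fd(window: pd.DataFrame) -> float:
    """f_D admixture-fraction estimator over one window.

    Expects per-site derived frequencies p_sister (P1), p_focal (P2), p_arc
    (P3) and p_out (O, the ancestral-state source). The denominator replaces
    both P2 and P3 with the donor proxy P_D, the one of {P2, P3} with the
    larger derived frequency at each site. NaN when the denominator is zero.
    """
    p1 = window["p_sister"].to_numpy(float)
    p2 = window["p_focal"].to_numpy(float)
    p3 = window["p_arc"].to_numpy(float)
    po = window["p_out"].to_numpy(float)
    num = _abba_baba_sum(p1, p2, p3, po)
    pdn = np.maximum(p2, p3)
    den = _abba_baba_sum(p1, pdn, pdn, po)
    if den == 0:
        return float("nan")
    return num / den


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_stats(hap_a: np.ndarray, hap_b: np.ndarray) -> tuple[float, float]:
    """(r2, D') between two biallelic loci from phased 0/1 haplotype vectors.

    D = p_AB - p_A p_B; r2 = D^2 / (p_A(1-p_A) p_B(1-p_B));
    D' = D / D_max with the sign-dependent D_max convention. Returns
    (nan, nan) when either locus is monomorphic."""
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("haplotype vectors must be equal length")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan"), float("nan")
    pab = np.mean(a * b)
    D = pab - pa * pb
    r2 = D**2 / (pa * (1 - pa) * pb * (1 - pb))
    if D > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif D < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return 0.0, 0.0
    return float(r2), float(D / dmax)


# ---------------------------------------------------------------------------
# null distributions and empirical p-values
# ---------------------------------------------------------------------------


@dataclass
class NullDistribution:
    statistic: str
    draws: np.ndarray
    model_id: str
    seed: int
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        self.draws = np.sort(np.asarray(self.draws, dtype=float))
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("null draws must be finite")

    @property
    def n(self) -> int:
        return self.draws.size

    def save(self, path) -> None:
        pd.DataFrame({"draw": self.draws}).to_csv(
            path, sep="\t", index=False,
            header=[f"{self.statistic}|{self.model_id}|{self.seed}|{self.n_redrawn}"],
        )

    @classmethod
    def load(cls, path) -> "NullDistribution":
        df = pd.read_csv(path, sep="\t")
        stat, model_id, seed, n_re = df.columns[0].split("|")
        return cls(statistic=stat, draws=df.iloc[:, 0].to_numpy(),
                   model_id=model_id, seed=int(seed), n_redrawn=int(n_re))


def empirical_p(observed: float, null: NullDistribution) -> float:
    """Rank-based p-value (1 + #{draws >= observed}) / (1 + n); never zero."""
    if null.n == 0:
        raise ValueError("empty null distribution")
    k = null.n - np.searchsorted(null.draws, observed, side="left")
    return float((1 + k) / (1 + null.n))


def simulate_null(
    model,
    statistic: str,
    n_rep: int,
    seed: int,
    *,
    n_snvs: int = 100,
    n_per_pop: dict[str, int] | None = None,
    region_length: int = 150_000,
    model_id: str = "model",
) -> NullDistribution:
    """Null distribution of a segment statistic under the demographic model.

    Each replicate simulates a region, takes the first ``n_snvs`` SNVs, and
    computes the statistic with the same code path as observed data
    (:func:`segment_scan`). Replicates where the statistic is undefined, or
    that yield too few SNVs, are redrawn (the count is recorded).
    ``statistic`` is ``"pbs"`` or ``"fd"``.
    """
    from . import simgen

    if n_rep < 100:
        raise ValueError("n_rep must be >= 100")
    if statistic not in ("pbs", "fd"):
        raise ValueError("statistic must be 'pbs' or 'fd'")
    if n_per_pop is None:
        n_per_pop = {"AFR": 20, "EAS": 20, "PNG": 20}
        if statistic == "fd":
            donors = sorted({p.donor for p in model.pulses})
            if donors:
                n_per_pop[donors[0]] = 4
    archaic = None
    if statistic == "fd":
        donors = sorted({p.donor for p in model.pulses})
        archaic = donors[0] if donors else None
        if archaic is None:
            raise ValueError("fd null needs a donor population in the model")

    draws: list[float] = []
    n_redrawn = 0
    attempt = 0
    while len(draws) < n_rep:
        rep_seed = child_seed(seed, attempt)
        attempt += 1
        coh = simgen.simulate_cohort(
            model, region_length, n_per_pop, seed=rep_seed
        )
        tab = freq_table_from_cohort(coh, archaic=archaic)
        if len(tab) < n_snvs:
            n_redrawn += 1
            continue
        scan = segment_scan(tab.iloc[:n_snvs], segment_size=n_snvs)
        val = scan[statistic].iloc[0] if len(scan) else np.nan
        if not np.isfinite(val):
            n_redrawn += 1
            continue
        draws.append(float(val))
    return NullDistribution(
        statistic=statistic, draws=np.array(draws), model_id=model_id,
        seed=seed, n_redrawn=n_redrawn,
    )
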