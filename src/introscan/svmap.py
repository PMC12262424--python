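"""Structural-variant merging, projection onto introgressed segments, and
genic-enrichment testing.

Call sets from different callers are merged per SV type: deletions and
inversions link when they overlap reciprocally by at least 50% of both
lengths; insertions (whose reciprocal overlap is ill-defined) link when their
breakpoints fall within 500 bp and their size ratio is at least the same
threshold. Clusters are single-linkage connected components; the
representative is the longest member (ties: leftmost, then source name).

Merged SVs are projected onto introgressed segments per haplotype: an SV is
introgressed on haplotype h when h carries it and its breakpoint interval is
fully contained in a non-rejected segment on h (an overlap mode is available
for sensitivity analyses). Genic enrichment of introgressed SVs is assessed
with a one-sided Fisher exact test and a length-preserving within-chromosome
permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import spawn_rngs
from .archdetect import SegmentCall

__all__ = [
    "SVRecord",
    "MergedSV",
    "IntrogressionMap",
    "EnrichmentResult",
    "merge_svs",
    "project_svs",
    "tally_bases",
    "genic_enrichment",
    "genotype_concordance",
    "read_sv_vcf",
]

SV_TYPES = ("INS", "DEL", "INV")


@dataclass(frozen=True)
class SVRecord:
    """A typed structural variant (half-open coordinates).

    For INS the reference footprint is the 1 bp breakpoint interval
    [start, start+1) and ``length`` is the insert length; for DEL/INV the
    interval spans the event and ``length`` equals end - start.
    """

    chrom: str
    start: int
    end: int
    type: str
    length: int
    carriers: frozenset[str] = frozenset()
    source: str = ""

    def __post_init__(self) -> None:
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.type!r}")
        if self.length < 50:
            raise ValueError("SVs are >= 50 bp by definition")
        if self.type == "INS":
            if self.end != self.start + 1:
                raise ValueError("INS records span exactly the 1 bp breakpoint")
        elif self.end - self.start != self.length:
            raise ValueError("DEL/INV length must equal end - start")


@dataclass
class MergedSV:
    representative: SVRecord
    members: list[SVRecord]
    carriers: frozenset[str]

    @property
    def type(self) -> str:
        return self.representative.type


def _reciprocal_linked(a: SVRecord, b: SVRecord, reciprocal: float) -> bool:
    ov = min(a.end, b.end) - max(a.start, b.start)
    return ov >= reciprocal * a.length and ov >= reciprocal * b.length


def _ins_linked(a: SVRecord, b: SVRecord, reciprocal: float, window: int) -> bool:
    if abs(a.start - b.start) > window:
        return False
    lo, hi = sorted((a.length, b.length))
    return lo >= reciprocal * hi


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_svs(
    call_sets: Sequence[Sequence[SVRecord]] | Sequence[SVRecord],
    reciprocal: float = 0.5,
    ins_breakpoint_window: int = 500,
) -> list[MergedSV]:
    """Single-linkage merge of SV records across call sets.

    Input is either one flat record list or several call sets. Records are
    canonically sorted first, so clustering does not depend on input order.
    Mixed-type links are impossible (records only pair within a type).
    """
    if call_sets and isinstance(call_sets[0], SVRecord):
        records = list(call_sets)  # type: ignore[arg-type]
    else:
        records = [r for cs in call_sets for r in cs]
    records = sorted(
        records, key=lambda r: (r.chrom, r.start, r.end, r.type, r.source, -r.length)
    )
    uf = _UnionFind(len(records))
    # sweep within (chrom, type); candidates must be within the max feasible
    # distance, so a sorted active-window scan suffices.
    by_group: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(records):
        by_group.setdefault((r.chrom, r.type), []).append(i)
    for (chrom, svtype), idxs in by_group.items():
        for a_pos, i in enumerate(idxs):
            a = records[i]
            for j in idxs[a_pos + 1 :]:
                b = records[j]
                if svtype == "INS":
                    if b.start - a.start > ins_breakpoint_window:
                        break
                    if _ins_linked(a, b, reciprocal, ins_breakpoint_window):
                        uf.union(i, j)
                else:
                    if b.start >= a.end:
                        break
                    if _reciprocal_linked(a, b, reciprocal):
                        uf.union(i, j)

    clusters: dict[int, list[SVRecord]] = {}
    for i, r in enumerate(records):
        clusters.setdefault(uf.find(i), []).append(r)
    merged = []
    for members in clusters.values():
        rep = min(members, key=lambda r: (-r.length, r.start, r.source))
        carriers = frozenset().union(*(m.carriers for m in members))
        merged.append(MergedSV(representative=rep, members=members, carriers=carriers))
    merged.sort(key=lambda m: (m.representative.chrom, m.representative.start,
                               m.representative.end, m.representative.type))
    return merged


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


@dataclass
class IntrogressionMap:
    """Per-haplotype (SV, segment, origin) assignments.

    ``entries`` holds one row per (merged SV, carrier haplotype, containing
    segment) with the origin inherited from the segment.
    """

    entries: list[tuple[MergedSV, SegmentCall, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sv, seg, origin in self.entries:
            rows.append(
                {
                    "chrom": sv.representative.chrom,
                    "sv_start": sv.representative.start,
                    "sv_end": sv.representative.end,
                    "type": sv.type,
                    "length": sv.representative.length,
                    "haplotype": seg.haplotype,
                    "seg_start": seg.start,
                    "seg_end": seg.end,
                    "origin": origin,
                }
            )
        return pd.DataFrame(rows)


def project_svs(
    merged_svs: Sequence[MergedSV],
    segments: Sequence[SegmentCall],
    mode: str = "contained",
) -> IntrogressionMap:
    """Assign merged SVs to introgressed segments per carrier haplotype.

    ``mode='contained'`` (default) requires the SV's reference interval to be
    fully inside a non-REJECTED segment on a carrier haplotype;
    ``mode='overlap'`` accepts any overlap. Origin is inherited from the
    segment. Shrinking segments can only remove assignments (monotonicity).
    """
    if mode not in ("contained", "overlap"):
        raise ValueError("mode must be 'contained' or 'overlap'")
    by_hap: dict[str, list[SegmentCall]] = {}
    for seg in segments:
        if seg.origin != "REJECTED":
            by_hap.setdefault(seg.haplotype, []).append(seg)
    imap = IntrogressionMap()
    for sv in merged_svs:
        rep = sv.representative
        for hap in sorted(sv.carriers):
            for seg in by_hap.get(hap, ()):
                if seg.chrom != rep.chrom:
                    continue
                if mode == "contained":
                    hit = seg.start <= rep.start and rep.end <= seg.end
                else:
                    hit = min(seg.end, rep.end) - max(seg.start, rep.start) > 0
                if hit:
                    imap.entries.append((sv, seg, seg.origin))
                    break
    return imap


def tally_bases(imap: IntrogressionMap) -> pd.DataFrame:
    """Introgressed INS/DEL bases per genome (sample) and origin.

    INS bases sum insert lengths, DEL bases sum deleted lengths; each
    (SV, sample) pair counts once even if both haplotypes carry it.
    """
    seen: set[tuple[int, str]] = set()
    acc: dict[tuple[str, str, str], int] = {}
    for sv, seg, origin in imap.entries:
        sample = seg.haplotype.rsplit("_hap", 1)[0]
        key = (id(sv), sample)
        if key in seen or sv.type == "INV":
            continue
        seen.add(key)
        k = (sample, origin, sv.type)
        acc[k] = acc.get(k, 0) + sv.representative.length
    rows = [
        {"sample": s, "origin": o, "type": t, "bases": b}
        for (s, o, t), b in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["sample", "origin", "type", "bases"])


# ---------------------------------------------------------------------------
# genic enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    odds_ratio: float
    fisher_p: float
    perm_p: float
    n_perm: int
    table: np.ndarray
    or_corrected: bool = False

    def __post_init__(self) -> None:
        if self.n_perm and not (1 / (self.n_perm + 1) <= self.perm_p <= 1):
            raise ValueError("permutation p outside its attainable range")


def _near_gene(
    starts: np.ndarray, ends: np.ndarray, gene_iv: np.ndarray, flank: int
) -> np.ndarray:
    """Boolean: SV interval within ``flank`` bp of any (disjoint, sorted) gene."""
    if gene_iv.size == 0:
        return np.zeros(len(starts), dtype=bool)
    gs = gene_iv[:, 0] - flank
    ge = gene_iv[:, 1] + flank
    # an SV [s,e) is near a gene iff some expanded gene interval overlaps it
    idx = np.searchsorted(gs, ends, side="left")  # first gene starting >= end
    prev = idx - 1
    ok = prev >= 0
    out = np.zeros(len(starts), dtype=bool)
    out[ok] = ge[prev[ok]] > starts[ok]
    # also genes entirely inside the SV interval but starting after it: the
    # searchsorted above already covers every gene with gs < end, which is all
    # overlap candidates for sorted disjoint genes.
    return out


def genic_enrichment(
    sv_table: pd.DataFrame,
    gene_intervals: np.ndarray | Sequence[tuple[int, int]],
    chrom_length: int,
    flank: int = 1000,
    n_perm: int = 1000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Are introgressed SVs enriched near genes?

    ``sv_table`` needs columns start, end, introgressed (bool); genes are
    merged/disjoint intervals on the same chromosome. The 2x2 table crosses
    {introgressed, not} x {within ``flank`` of a gene, not}; the one-sided
    Fisher exact p tests enrichment, and a permutation p re-places all SVs
    uniformly on the chromosome (lengths preserved) n_perm times, comparing
    the count of introgressed-and-genic SVs.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    genes = np.asarray(sorted(map(tuple, gene_intervals)), dtype=int).reshape(-1, 2)
    starts = sv_table["start"].to_numpy(int)
    ends = sv_table["end"].to_numpy(int)
    intro = sv_table["introgressed"].to_numpy(bool)
    near = _near_gene(starts, ends, genes, flank)
    a = int(np.sum(intro & near))
    b = int(np.sum(intro & ~near))
    c = int(np.sum(~intro & near))
    d = int(np.sum(~intro & ~near))
    table = np.array([[a, b], [c, d]])
    _, fisher_p = stats.fisher_exact(table, alternative="greater")
    corrected = False
    if min(a, b, c, d) == 0 or min(a + b, c + d, a + c, b + d) == 0:
        corrected = True
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
        odds = (aa * dd) / (bb * cc)
    else:
        odds = (a * d) / (b * c)

    rng = spawn_rngs(seed, ["perm"])["perm"]
    lengths = ends - starts
    hits = 0
    for _ in range(n_perm):
        new_starts = rng.integers(0, np.maximum(chrom_length - lengths, 1))
        pnear = _near_gene(new_starts, new_starts + lengths, genes, flank)
        if int(np.sum(intro & pnear)) >= a:
            hits += 1
    perm_p = (1 + hits) / (1 + n_perm)
    return EnrichmentResult(
        odds_ratio=float(odds),
        fisher_p=float(fisher_p),
        perm_p=float(perm_p),
        n_perm=n_perm,
        table=table,
        or_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# genotype concordance
# ---------------------------------------------------------------------------


def _norm_gt(gt: str) -> tuple[int, ...] | None:
    if gt in (".", "./.", ".|.", ""):
        return None
    sep = "|" if "|" in gt else "/"
    try:
        return tuple(sorted(int(x) for x in gt.split(sep)))
    except ValueError:
        return None


def genotype_concordance(
    truth: pd.DataFrame,
    test: pd.DataFrame,
    size_bins: Sequence[int] = (50, 1000, 10000),
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Diploid genotype concordance between two call sets.

    Both tables are keyed by (chrom, pos, ref, alt) and carry a ``class``
    column (SNV/indel/INS/DEL), a ``length`` column, and one column per
    sample holding GT strings. Genotypes compare as unordered allele pairs;
    missing genotypes leave the denominator. SV classes are additionally
    stratified by ``size_bins`` (left edges; the last bin is open-ended).
    Raises if the two tables share no variant keys.
    """
    key = ["chrom", "pos", "ref", "alt"]
    joined = truth.merge(test, on=key, suffixes=("_truth", "_test"))
    if joined.empty:
        raise ValueError("no shared variant keys between the two sets")
    if samples is None:
        samples = [
            c[: -len("_truth")]
            for c in joined.columns
            if c.endswith("_truth") and c not in ("class_truth", "length_truth")
        ]

    edges = list(size_bins) + [np.inf]

    def bin_label(cls: str, length: float) -> str:
        if cls in ("SNV", "indel"):
            return cls
        for lo, hi in zip(edges[:-1], edges[1:]):
            if lo <= length < hi:
                hi_s = "inf" if np.isinf(hi) else str(int(hi))
                return f"{cls}[{int(lo)},{hi_s})"
        return cls

    acc: dict[tuple[str, str], list[int]] = {}
    for _, row in joined.iterrows():
        label = bin_label(str(row["class_truth"]), float(row["length_truth"]))
        for s in samples:
            gt_t = _norm_gt(str(row[f"{s}_truth"]))
            gt_q = _norm_gt(str(row[f"{s}_test"]))
            if gt_t is None or gt_q is None:
                continue
            cell = acc.setdefault((s, label), [0, 0])
            cell[1] += 1
            if gt_t == gt_q:
                cell[0] += 1
    rows = [
        {"sample": s, "class": lab, "n_compared": tot, "concordance": m / tot}
        for (s, lab), (m, tot) in sorted(acc.items())
        if tot
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


def read_sv_vcf(path, source: str = "") -> list[SVRecord]:
    """Read typed SVs from a VCF (symbolic <DEL>/<INS>/<INV> ALTs or
    SVTYPE/SVLEN INFO keys); carrier haplotypes are taken from phased GTs as
    SAMPLE_hap1/SAMPLE_hap2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    out: list[SVRecord] = []
    for var in vcf:
        svtype = var.INFO.get("SVTYPE")
        if svtype is None:
            alt = var.ALT[0] if var.ALT else ""
            if alt.startswith("<") and alt[1:-1] in SV_TYPES:
                svtype = alt[1:-1]
            else:
                continue
        if svtype not in SV_TYPES:
            continue
        svlen = var.INFO.get("SVLEN")
        length = abs(int(svlen)) if svlen is not None else None
        start = var.POS - 1
        end_info = var.INFO.get("END")
        if svtype == "INS":
            if length is None:
                raise ValueError("INS record without SVLEN")
            end = start + 1
        else:
            end = int(end_info) if end_info is not None else start + length
            length = end - start
        carriers = set()
        for j, gt in enumerate(var.genotypes):
            if gt[0] == 1:
                carriers.add(f"{vcf_samples[j]}_hap1")
            if len(gt) > 2 and gt[1] == 1:
                carriers.add(f"{vcf_samples[j]}_hap2")
        out.append(
            SVRecord(
                chrom=var.CHROM, start=start, end=end, type=svtype,
                length=length, carriers=frozenset(carriers), source=source,
            )
        )
    vcf.close()
    return out
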