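"""Alignment-free archaic-specific k-mer screening.

The method builds a set of canonical k-mers seen repeatedly in archaic
(Neanderthal/Denisovan) sequence but absent from an African-like outgroup
panel, counts those k-mers in fixed windows (default 2 kbp) across each
haplotype assembly, calibrates an integer count cutoff so the flagged window
fraction matches the genome-wide introgression fraction, and tests whether
windows overlapping introgressed segments carry higher counts (one-sided
Mann-Whitney U). Because k-mer counting needs no alignment it reaches
regions, such as centromeric satellite, where variant calling is unreliable.

A window-identity operation (sliding query windows locally aligned to a
target, best hit retained, identity counting substitutions and indel bases)
supports structural comparison of satellite arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KmerSet",
    "WindowCountTrack",
    "IdentityMatrix",
    "canonical",
    "build_archaic_specific_kmers",
    "count_kmers_in_windows",
    "calibrate_threshold",
    "enrichment_test",
    "window_identity",
]

_COMP = str.maketrans("ACGTN", "TGCAN")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def canonical(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMP)[::-1]
    return kmer if kmer <= rc else rc


def _encode_seq(seq: str) -> np.ndarray:
    """2-bit codes; anything outside ACGT becomes -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical integer code of each k-mer start position, plus validity mask.

    Uses a strided window dot product; with k <= 31 codes fit in uint64.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        valid &= col >= 0
        fwd += col.astype(np.uint64) * np.uint64(4 ** (k - 1 - j))
        rev += (3 - col).astype(np.uint64) * np.uint64(4**j)
    return np.minimum(fwd, rev), valid


def _encode_kmer_string(kmer: str) -> int:
    v = 0
    for ch in kmer:
        v = v * 4 + _CODE[ch]
    return v


@dataclass
class KmerSet:
    """Canonical k-mers specific to archaic inputs.

    Every member is its own canonical form and, by construction, absent from
    all outgroup sequences supplied at build time.
    """

    k: int
    kmers: frozenset[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.kmers

    def codes(self) -> np.ndarray:
        """Sorted canonical integer codes, for vectorised membership tests."""
        return np.sort(
            np.array([_encode_kmer_string(s) for s in self.kmers], dtype=np.uint64)
        )

    def write(self, path) -> None:
        """Plain-text serialisation: one canonical ACGT k-mer per line, sorted."""
        with open(path, "w") as fh:
            for s in sorted(self.kmers):
                fh.write(s + "\n")

    @classmethod
    def read(cls, path, provenance: dict | None = None) -> "KmerSet":
        with open(path) as fh:
            kmers = frozenset(line.strip() for line in fh if line.strip())
        ks = {len(s) for s in kmers}
        if len(ks) > 1:
            raise ValueError("mixed k-mer lengths in file")
        return cls(k=ks.pop() if ks else 0, kmers=kmers, provenance=provenance or {})


def build_archaic_specific_kmers(
    archaic_seqs: Iterable[str],
    outgroup_seqs: Iterable[str],
    k: int = 31,
    min_archaic_occurrences: int = 2,
) -> KmerSet:
    """Canonical k-mers occurring >= ``min_archaic_occurrences`` times across
    the archaic inputs and never in the outgroup inputs.

    Occurrences are counted over all archaic sequences and both strands
    (canonical form). K-mers containing non-ACGT characters are skipped. The
    occurrence floor suppresses k-mers created by isolated sequencing errors
    in archaic short-read data.
    """
    archaic_seqs = list(archaic_seqs)
    outgroup_seqs = list(outgroup_seqs)
    from collections import Counter

    counts: Counter[str] = Counter()
    n_arch = 0
    for seq in archaic_seqs:
        n_arch += 1
        s = seq.upper()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if set(km) <= set("ACGT"):
                counts[canonical(km)] += 1
    if n_arch == 0 or not counts:
        warnings.warn("no usable archaic input; k-mer set is empty")
    keep = {km for km, c in counts.items() if c >= min_archaic_occurrences}
    for seq in outgroup_seqs:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if set(km) <= set("ACGT"):
                keep.discard(canonical(km))
    return KmerSet(
        k=k,
        kmers=frozenset(keep),
        provenance={
            "n_archaic_seqs": len(archaic_seqs),
            "n_outgroup_seqs": len(outgroup_seqs),
            "min_archaic_occurrences": min_archaic_occurrences,
        },
    )


@dataclass
class WindowCountTrack:
    """Archaic-specific k-mer counts per fixed window of one assembly."""

    assembly: str
    window: int
    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.assembly, "start": self.starts, "end": self.ends,
             "count": self.counts}
        )

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for s, e, c in zip(self.starts, self.ends, self.counts):
                fh.write(f"{self.assembly}\t{s}\t{e}\t{c}\n")


def count_kmers_in_windows(
    assembly_seq: str,
    kmer_set: KmerSet,
    window: int = 2000,
    assembly: str = "asm",
) -> WindowCountTrack:
    """Member-k-mer start positions per window.

    A position belongs to window [w, w+window) when the k-mer starting there
    fits inside it, i.e. start < w_end - k + 1; k-mers straddling a window
    boundary are not counted for either window.
    """
    k = kmer_set.k
    if window < k:
        raise ValueError("window must be >= k")
    L = len(assembly_seq)
    starts = np.arange(0, L, window, dtype=int)
    ends = np.minimum(starts + window, L)
    if len(kmer_set) == 0 or L < k:
        return WindowCountTrack(assembly, window, starts, ends,
                                np.zeros(len(starts), dtype=int))
    codes = _encode_seq(assembly_seq)
    kcodes, valid = _kmer_codes(codes, k)
    member_codes = kmer_set.codes()
    idx = np.searchsorted(member_codes, kcodes)
    idx[idx == member_codes.size] = 0
    hit = valid & (member_codes[np.minimum(idx, member_codes.size - 1)] == kcodes)
    hit_pos = np.nonzero(hit)[0]
    counts = np.zeros(len(starts), dtype=int)
    for i, (ws, we) in enumerate(zip(starts, ends)):
        hi = we - k + 1
        if hi <= ws:
            continue
        lo_i, hi_i = np.searchsorted(hit_pos, [ws, hi])
        counts[i] = hi_i - lo_i
    return WindowCountTrack(assembly, window, starts, ends, counts)


def calibrate_threshold(
    track: WindowCountTrack, genome_introgression_fraction: float
) -> int:
    """Smallest candidate count cutoff whose flagged-window fraction does not
    exceed the genome-wide introgression fraction.

    Candidates are 0, the observed count values and max+1 (the flagged set
    only changes at observed counts). When even flagging a single window
    would overshoot the target fraction, max+1 is returned with a warning.
    """
    if not 0 < genome_introgression_fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    counts = np.asarray(track.counts)
    if counts.size == 0:
        raise ValueError("empty track")
    if genome_introgression_fraction < 1 / counts.size:
        warnings.warn(
            "target fraction below 1/#windows: no attainable cutoff, "
            "returning max count + 1"
        )
        return int(counts.max()) + 1
    sorted_counts = np.sort(counts)
    candidates = np.unique(np.concatenate(([0], counts, [counts.max() + 1])))
    for t in candidates:
        frac = (counts.size - np.searchsorted(sorted_counts, t, side="left")) / counts.size
        if frac <= genome_introgression_fraction:
            return int(t)
    return int(counts.max()) + 1  # pragma: no cover


def enrichment_test(
    track: WindowCountTrack, segments: Sequence
) -> tuple[float, float]:
    """One-sided Mann-Whitney U: do windows overlapping introgressed segments
    carry higher archaic-specific k-mer counts?

    ``segments`` is any sequence of objects with start/end (SegmentCall or
    (start, end) tuples). Returns (U, p). Exact enumeration when both groups
    are small (<= 50) and tie-free; midranks with tie-corrected normal
    approximation otherwise.
    """
    iv = []
    for s in segments:
        if hasattr(s, "start"):
            iv.append((s.start, s.end))
        else:
            iv.append((s[0], s[1]))
    overlap = np.zeros(len(track.starts), dtype=bool)
    for s, e in iv:
        overlap |= (track.starts < e) & (track.ends > s)
    x = np.asarray(track.counts)[overlap]
    y = np.asarray(track.counts)[~overlap]
    if x.size == 0 or y.size == 0:
        raise ValueError("both window groups must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 50 and y.size <= 50 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# window identity
# ---------------------------------------------------------------------------


@dataclass
class IdentityMatrix:
    """Best-hit percent identity of sliding query windows against a target."""

    window: int
    step: int
    table: pd.DataFrame  # query_start, query_end, target_start, target_end, identity

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _alignment_identity(alignment) -> tuple[float, int, int]:
    """(percent identity, target_start, target_end) of one local alignment.

    Identity counts matches over matches + mismatches + indel bases inside
    the aligned span (end gaps outside the local alignment do not count).
    """
    tseq, qseq = alignment.target, alignment.query
    blocks_t, blocks_q = alignment.aligned
    matches = mismatches = indels = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            indels += (ts - prev_t) + (qs - prev_q)
        a = tseq[ts:te]
        b = qseq[qs:qe]
        m = sum(1 for x, y in zip(a, b) if x == y)
        matches += m
        mismatches += (te - ts) - m
        prev_t, prev_q = te, qe
    denom = matches + mismatches + indels
    ident = 100.0 * matches / denom if denom else 0.0
    t_start = int(blocks_t[0][0]) if len(blocks_t) else 0
    t_end = int(blocks_t[-1][1]) if len(blocks_t) else 0
    return ident, t_start, t_end


def window_identity(
    query_seq: str,
    target_seq: str,
    window: int = 20000,
    step: int = 1000,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> IdentityMatrix:
    """Align sliding query windows to the target; keep the best local hit.

    Each window of the query (length ``window``, stride ``step``) is aligned
    to the full target with an optimal local alignment under the given
    scores; the single best-scoring location is retained and its percent
    identity (substitutions and indel bases both counted) reported.
    """
    from Bio import Align

    if window > len(query_seq):
        raise ValueError("window longer than query")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    rows = []
    last_start = len(query_seq) - window
    for qs in range(0, last_start + 1, step):
        wseq = query_seq[qs : qs + window]
        aln = aligner.align(target_seq, wseq)
        best = aln[0]
        ident, ts, te = _alignment_identity(best)
        rows.append(
            {
                "query_start": qs,
                "query_end": qs + window,
                "target_start": ts,
                "target_end": te,
                "identity": ident,
                "score": float(best.score),
            }
        )
    return IdentityMatrix(window=window, step=step, table=pd.DataFrame(rows))
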