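"""Shared helpers: seed derivation, interval arithmetic, digests."""

from __future__ import annotations

import hashlib
from typing import Iterable, Sequence

import numpy as np


def spawn_rngs(seed: int, labels: Sequence[str]) -> dict[str, np.random.Generator]:
    """Derive one independent generator per labelled stage from a master seed.

    Each label is hashed into the seed sequence, so the stream a stage
    receives depends only on (seed, label), never on which other stages run.
    """
    if seed is None:
        raise ValueError("a master seed is required (reproducibility contract)")
    out = {}
    for lab in labels:
        h = int(hashlib.sha256(lab.encode()).hexdigest()[:8], 16)
        out[lab] = np.random.default_rng(np.random.SeedSequence([int(seed), h]))
    return out


def child_seed(seed: int, index: int) -> int:
    """A deterministic 31-bit child seed (for libraries that take int seeds)."""
    ss = np.random.SeedSequence(int(seed)).spawn(index + 1)[index]
    return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1


def merge_intervals(intervals: Iterable[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    """Union of half-open intervals; intervals closer than ``gap`` are joined."""
    ivs = sorted(intervals)
    if not ivs:
        return []
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def sha256_of(*parts) -> str:
    """Stable digest of a heterogeneous collection of arrays/strings/numbers."""
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p).tobytes())
            h.update(str(p.dtype).encode())
        else:
            h.update(repr(p).encode())
    return h.hexdigest()
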