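"""Long-read mapping, depth profiles and depth-ratio copy-number estimation.

The mapper is a deliberately simple exact-seed voting mapper: reads are
assigned to the (reference, strand, diagonal) maximizing the number of
exact seed hits, which is sufficient for substitution-only reads and keeps
the whole pipeline self-contained. The copy number of a multicopy element
is then the ratio of its median binned depth to the pooled median of the
background (single-copy) contigs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .align import ReadAlignment
from .sequtil import encode, revcomp
from .synth import ReadSet


@dataclass
class DepthProfile:
    ref_name: str
    bin_size: int
    per_base: np.ndarray  # float per-base coverage
    bin_depth: np.ndarray  # mean coverage of complete bins only

    @property
    def median_depth(self) -> float:
        return float(np.median(self.bin_depth)) if len(self.bin_depth) else 0.0


@dataclass
class CopyNumberEstimate:
    target_median: float
    background_median: float
    ratio: float
    n_background_contigs: int


class SeedIndex:
    """Exact k-mer index over a set of reference sequences."""

    def __init__(self, refs: dict[str, str], k: int = 15):
        if not refs:
            raise ValueError("empty reference set")
        if k < 11:
            raise ValueError("seed_k must be >= 11")
        self.k = k
        self.names = list(refs)
        self.seqs = refs
        self.codes = {name: encode(s) for name, s in refs.items()}
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ri, name in enumerate(self.names):
            s = refs[name]
            for i in range(len(s) - k + 1):
                self.index.setdefault(s[i: i + k], []).append((ri, i))

    def hits(self, kmer: str):
        return self.index.get(kmer, ())


def map_long_reads(
    reads: ReadSet,
    refs: dict[str, str],
    seed_k: int = 15,
    min_seed_chain: int = 2,
    seed_stride: int = 30,
    index: SeedIndex | None = None,
) -> list[ReadAlignment]:
    """Assign each read to the best exact-seed-supported diagonal.

    Substitution errors between seeds are tolerated (they only reduce the
    vote count); reads with fewer than `min_seed_chain` supporting seeds
    stay unmapped. Ties break deterministically toward the forward strand,
    reference order, then the leftmost diagonal.
    """
    idx = index if index is not None else SeedIndex(refs, seed_k)
    k = idx.k
    out: list[ReadAlignment] = []
    for read in reads:
        best = None  # (count, strand_rank, ref_idx, diag, oriented_seq)
        for strand, oriented in (("+", read.seq), ("-", revcomp(read.seq))):
            n = len(oriented) - k + 1
            if n <= 0:
                continue
            positions = list(range(0, n, seed_stride))
            if positions[-1] != n - 1:
                positions.append(n - 1)
            votes: Counter = Counter()
            for p in positions:
                for ri, rp in idx.hits(oriented[p: p + k]):
                    votes[(ri, rp - p)] += 1
            if not votes:
                continue
            count, (ri, diag) = max(
                ((c, key) for key, c in votes.items()),
                key=lambda t: (t[0], -t[1][0], -t[1][1]),
            )
            rank = 0 if strand == "+" else 1
            cand = (count, -rank, -ri, -diag, oriented)
            if best is None or cand[:4] > best[:4]:
                best = (count, -rank, -ri, -diag, oriented)
        if best is None or best[0] < min_seed_chain:
            continue
        count, nrank, nri, ndiag, oriented = best
        ri, diag = -nri, -ndiag
        name = idx.names[ri]
        ref_len = len(idx.seqs[name])
        lread = len(oriented)
        pre = max(0, -diag)
        suf = max(0, diag + lread - ref_len)
        if lread - pre - suf <= 0:
            continue
        block = ((pre, lread - suf), (diag + pre, diag + lread - suf))
        rc = idx.codes[name]
        seg = encode(oriented)[pre: lread - suf]
        nm = int(np.sum(seg != rc[diag + pre: diag + lread - suf]))
        out.append(
            ReadAlignment(
                read.id, name, [block],
                strand="+" if nrank == 0 else "-",
                clipped_prefix=pre, clipped_suffix=suf, n_mismatch=nm,
                meta=dict(read.meta),
            )
        )
    return out


def depth_profile(
    alignments: list[ReadAlignment],
    ref_lengths: dict[str, int],
    bin_size: int = 100,
) -> dict[str, DepthProfile]:
    """Per-base coverage and binned means for every reference."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    diffs = {name: np.zeros(length + 1) for name, length in ref_lengths.items()}
    for a in alignments:
        d = diffs.get(a.ref_name)
        if d is None:
            continue
        for _, (ts, te) in a.blocks:
            d[ts] += 1
            d[te] -= 1
    out = {}
    for name, length in ref_lengths.items():
        per_base = np.cumsum(diffs[name][:-1])
        n_complete = length // bin_size
        bins = (
            per_base[: n_complete * bin_size].reshape(n_complete, bin_size).mean(axis=1)
            if n_complete
            else np.empty(0)
        )
        out[name] = DepthProfile(name, bin_size, per_base, bins)
    return out


def copy_number(
    target_profile: DepthProfile,
    background_profiles: list[DepthProfile],
) -> CopyNumberEstimate:
    """Ratio of the target's median bin depth to the pooled background median."""
    if not background_profiles:
        raise ValueError("need at least one background profile")
    pooled = np.concatenate([p.bin_depth for p in background_profiles])
    bg_median = float(np.median(pooled)) if len(pooled) else 0.0
    if bg_median <= 0:
        raise ValueError("background median depth is zero")
    t_median = target_profile.median_depth
    return CopyNumberEstimate(
        t_median, bg_median, t_median / bg_median, len(background_profiles)
    )
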