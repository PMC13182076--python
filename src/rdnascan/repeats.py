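"""Blind rediscovery of repeat architecture from sequence alone.

The workhorse is an exact k-mer self-comparison ("self dot plot") whose
sense and antisense diagonal runs are assembled into tandem-array,
palindrome and telomere calls. Quadratic-ish scans are deliberate: the
target molecules are tens of kilobases and clarity beats asymptotics here.

Coordinates follow the package convention (0-based half-open). An
antisense match pairs base x on the left arm with base A - x on the right
arm, where A is the pairing sum (anti-diagonal) of the run; this pairing
is what keeps arm comparisons aligned even when run edges are clipped by
point mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequtil import complement, encode, revcomp


@dataclass
class MatchSegment:
    """A maximal merged diagonal run of exact k-mer matches."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    orientation: str  # {sense, antisense}

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def diagonal(self) -> int:
        """Sense: t - q offset. Antisense: pairing sum of matched bases."""
        if self.orientation == "sense":
            return self.t_start - self.q_start
        return self.q_start + self.t_end - 1

    def mirrored(self) -> "MatchSegment":
        return MatchSegment(self.t_start, self.t_end, self.q_start, self.q_end,
                            self.orientation)


@dataclass
class PalindromeCall:
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    loop_length: int
    half_identity: float = float("nan")

    @property
    def span(self) -> int:
        return self.right_arm[1] - self.left_arm[0]

    @property
    def pairing_sum(self) -> int:
        # base x pairs with pairing_sum - x
        return self.left_arm[0] + self.right_arm[1] - 1


@dataclass
class RepeatArrayCall:
    start: int
    end: int
    unit_length: int
    copies: int
    mean_pairwise_identity: float
    unit_boundaries: list[int] = field(default_factory=list)


@dataclass
class TelomereCall:
    end: str  # {left, right}
    start: int
    stop: int
    motif: str
    repeat_count: float
    purity: float


# ---------------------------------------------------------------------------
# k-mer machinery


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mer codes at every start; -1 where any base is non-ACGT."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    out = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j: j + n]
        out = (out << 2) | (c & 3).astype(np.int64)
        ok &= valid[j: j + n]
    out[~ok] = -1
    return out


def _merge_runs(starts: list[int], k: int, gap: int) -> list[tuple[int, int]]:
    """Merge sorted k-mer start positions into base intervals, closing holes
    of at most `gap` bases (an isolated substitution leaves a 1-base hole)."""
    if not starts:
        return []
    out = []
    s0 = starts[0]
    prev_end = starts[0] + k
    for s in starts[1:]:
        if s <= prev_end + gap:
            prev_end = max(prev_end, s + k)
        else:
            out.append((s0, prev_end))
            s0, prev_end = s, s + k
    out.append((s0, prev_end))
    return out


def self_dotplot(
    seq: str, k: int = 12, min_run: int = 20, merge_gap: int = 2
) -> list[MatchSegment]:
    """All maximal sense/antisense repeat runs of a sequence against itself.

    Returns a symmetric match set ((q,t) present iff (t,q) present), with
    the trivial main diagonal excluded. Non-ACGT characters simply produce
    no k-mers.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if len(seq) < k:
        raise ValueError("sequence shorter than k")
    codes = encode(seq)
    fwd = _kmer_codes(codes, k)
    # index i -> code of revcomp(seq[i:i+k])
    rc_full = _kmer_codes(encode(revcomp(seq)), k)[::-1]

    pos_by_code: dict[int, list[int]] = {}
    for i, c in enumerate(fwd):
        if c >= 0:
            pos_by_code.setdefault(int(c), []).append(i)

    sense: dict[int, list[int]] = {}
    for positions in pos_by_code.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                i, j = positions[a], positions[b]
                sense.setdefault(j - i, []).append(i)

    anti: dict[int, list[int]] = {}
    for i, c in enumerate(rc_full):
        if c < 0 or int(c) not in pos_by_code:
            continue
        # positions j with fwd kmer == revcomp kmer at i <=> antisense pair (j, i)
        for j in pos_by_code[int(c)]:
            if j < i:
                anti.setdefault(j + i, []).append(j)
            elif j == i:
                anti.setdefault(2 * i, []).append(i)

    out: list[MatchSegment] = []
    for d, starts in sense.items():
        starts = sorted(set(starts))
        for qs, qe in _merge_runs(starts, k, merge_gap):
            if qe - qs >= min_run:
                out.append(MatchSegment(qs, qe, qs + d, qe + d, "sense"))
    for s, starts in anti.items():
        starts = sorted(set(starts))
        for qs, qe in _merge_runs(starts, k, merge_gap):
            if qe - qs >= min_run:
                t_lo, t_hi = s + k - qe, s + k - qs
                out.append(MatchSegment(qs, qe, t_lo, t_hi, "antisense"))
    return out + [m.mirrored() for m in out if (m.q_start, m.q_end) != (m.t_start, m.t_end)]


def canonical_matches(matches: list[MatchSegment]) -> list[MatchSegment]:
    """One representative per symmetric pair, with q no later than t."""
    out = []
    for m in matches:
        if (m.q_start, m.q_end) <= (m.t_start, m.t_end):
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# palindromes


def _pair_ok(seq: str, x: int, y: int) -> bool:
    return 0 <= x < len(seq) and 0 <= y < len(seq) and seq[x] == complement(seq[y])


def _extend_outward(seq: str, qs: int, a: int, lookahead: int = 8) -> int:
    """Extend the left-arm start outward while bases keep pairing; a single
    mismatching pair may be skipped when the next `lookahead` pairs almost
    all match (recovers sub-k fragments clipped off by an edge mutation)."""
    x = qs - 1
    while True:
        if _pair_ok(seq, x, a - x):
            x -= 1
            continue
        good = sum(
            _pair_ok(seq, x - 1 - i, a - (x - 1 - i)) for i in range(lookahead)
        )
        if good >= lookahead - 1 and x - lookahead >= 0:
            x -= 1
            continue
        break
    return x + 1


def _extend_inward(seq: str, qe: int, a: int, lookahead: int = 8) -> int:
    """Extend the left-arm end toward the pairing center (same skip rule)."""
    x = qe
    center = (a + 1) // 2  # first x with x >= its partner
    while x < center:
        if _pair_ok(seq, x, a - x):
            x += 1
            continue
        good = sum(
            _pair_ok(seq, x + 1 + i, a - (x + 1 + i)) for i in range(lookahead)
        )
        if good >= lookahead - 1 and x + lookahead < center:
            x += 1
            continue
        break
    return x


def find_palindromes(
    matches: list[MatchSegment],
    min_arm: int = 50,
    max_loop: int = 100,
    seq: str | None = None,
    assembly_gap: int = 50,
    diag_tol: int = 3,
) -> list[PalindromeCall]:
    """Assemble antisense runs into palindrome calls.

    Runs sharing a pairing sum (within `diag_tol`) are merged across gaps of
    up to `assembly_gap` bases; candidates with disjoint, near-adjacent arms
    (loop <= `max_loop`) and arms >= `min_arm` become calls, sorted by span
    descending with overlapping calls resolved to the largest span. When the
    sequence is supplied, call boundaries are refined base-wise and
    half-arm identity is computed.
    """
    anti = [m for m in canonical_matches(matches) if m.orientation == "antisense"]
    if not anti:
        return []
    anti.sort(key=lambda m: (m.diagonal, m.q_start))
    clusters: list[list[MatchSegment]] = []
    for m in anti:
        if clusters and m.diagonal - clusters[-1][-1].diagonal <= diag_tol:
            clusters[-1].append(m)
        else:
            clusters.append([m])

    calls: list[PalindromeCall] = []
    for cl in clusters:
        a = int(round(float(np.median([m.diagonal for m in cl]))))
        # merge q-intervals along the shared anti-diagonal
        ivs = sorted((m.q_start, m.q_end) for m in cl)
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + assembly_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for qs, qe in merged:
            qe = min(qe, (a + 1) // 2)  # arms may not cross the center
            if qe <= qs:
                continue
            if seq is not None:
                qs = _extend_outward(seq, qs, a)
                qe = _extend_inward(seq, qe, a)
            ts, te = a + 1 - qe, a + 1 - qs
            loop = ts - qe
            if loop < 0 or loop > max_loop:
                continue
            if qe - qs < min_arm:
                continue
            call = PalindromeCall((qs, qe), (ts, te), loop)
            if seq is not None:
                call.half_identity = half_identity(seq, call)
            calls.append(call)

    calls.sort(key=lambda c: -c.span)
    kept: list[PalindromeCall] = []
    for c in calls:
        if all(
            c.right_arm[1] <= k.left_arm[0] or k.right_arm[1] <= c.left_arm[0]
            for k in kept
        ):
            kept.append(c)
    return kept


def half_identity(seq: str, call: PalindromeCall) -> float:
    """Base-wise identity of the left arm vs the reverse complement of the
    right arm, aligned through the call's pairing sum."""
    arm = min(call.left_arm[1] - call.left_arm[0],
              call.right_arm[1] - call.right_arm[0])
    if arm <= 0:
        raise ValueError("zero-length palindrome arm")
    a = call.pairing_sum
    qe = call.left_arm[1]
    left = seq[qe - arm: qe]
    right = "".join(seq[a - x] for x in range(qe - arm, qe))
    matches = sum(1 for lb, rb in zip(left, right) if lb == complement(rb))
    return matches / arm


# ---------------------------------------------------------------------------
# tandem arrays


def _extend_array_left(codes: np.ndarray, fs: int, p: int, lookahead: int = 8) -> int:
    while fs > 0:
        if codes[fs - 1] == codes[fs - 1 + p]:
            fs -= 1
            continue
        if fs - 1 - lookahead >= 0:
            good = sum(
                codes[fs - 2 - i] == codes[fs - 2 - i + p] for i in range(lookahead)
            )
            if good >= lookahead - 1:
                fs -= 1
                continue
        break
    return fs


def _extend_array_right(codes: np.ndarray, fe: int, p: int, lookahead: int = 8) -> int:
    n = len(codes)
    while fe < n:
        if codes[fe] == codes[fe - p]:
            fe += 1
            continue
        if fe + 1 + lookahead <= n:
            good = sum(
                codes[fe + 1 + i] == codes[fe + 1 + i - p] for i in range(lookahead)
            )
            if good >= lookahead - 1:
                fe += 1
                continue
        break
    return fe


def _period_score(codes: np.ndarray, start: int, end: int, p: int) -> float:
    a = codes[start: end - p]
    b = codes[start + p: end]
    if len(a) == 0:
        return 0.0
    return float(np.mean(a == b))


def find_tandem_arrays(
    seq: str,
    matches: list[MatchSegment],
    min_copies: int = 2,
    unit_range: tuple[int, int] = (5, 2000),
    score_slack: float = 0.95,
) -> list[RepeatArrayCall]:
    """Decompose clusters of sense off-diagonal runs into tandem arrays.

    The period is the smallest candidate offset whose autocorrelation score
    reaches `score_slack` of the best (canonical minimal unit, so a 5-copy
    array reports its unit length, not a multiple).
    """
    lo, hi = unit_range
    if lo < 5 or hi > 5000:
        raise ValueError("unit_range must lie within [5, 5000]")
    sense = [
        m for m in canonical_matches(matches)
        if m.orientation == "sense" and 0 < m.diagonal
    ]
    if not sense:
        return []
    codes = encode(seq)
    # cluster segments whose footprints (q start .. t end) overlap by more
    # than a small margin; a tandem array's own runs overlap heavily, while
    # adjacent distinct arrays at most leak a couple of chance-matching
    # bases across the boundary
    margin = 8
    sense.sort(key=lambda m: (m.q_start, m.t_end))
    clusters: list[list[MatchSegment]] = []
    cur_end = -1
    for m in sense:
        if clusters and m.q_start < cur_end - margin:
            clusters[-1].append(m)
            cur_end = max(cur_end, m.t_end)
        else:
            clusters.append([m])
            cur_end = m.t_end

    calls: list[RepeatArrayCall] = []
    for segs in clusters:
        fs = min(m.q_start for m in segs)
        fe = max(m.t_end for m in segs)
        offsets = sorted({m.diagonal for m in segs if lo <= m.diagonal <= hi})
        if not offsets:
            continue
        scores = {p: _period_score(codes, fs, fe, p) for p in offsets}
        best = max(scores.values())
        period = min(p for p in offsets if scores[p] >= score_slack * best)
        # refine footprint edges across the period (recovers sub-k clips)
        fs = _extend_array_left(codes, fs, period)
        fe = _extend_array_right(codes, fe, period)
        copies = int(round((fe - fs) / period))
        if copies < min_copies:
            continue
        bounds = [fs + i * period for i in range(copies)]
        n_full = (fe - fs) // period
        ident = 1.0
        if n_full >= 2:
            pair_ids = []
            units = [codes[fs + i * period: fs + (i + 1) * period]
                     for i in range(n_full)]
            for i in range(n_full):
                for j in range(i + 1, n_full):
                    pair_ids.append(float(np.mean(units[i] == units[j])))
            ident = float(np.mean(pair_ids))
        calls.append(RepeatArrayCall(fs, fe, period, copies, ident, bounds))
    return calls


# ---------------------------------------------------------------------------
# telomeres


def _motif_cover(window: str, motifs: list[str]) -> list[tuple[int, int, str]]:
    """Non-overlapping motif occurrences (greedy left-to-right)."""
    hits = []
    for motif in motifs:
        start = 0
        while True:
            i = window.find(motif, start)
            if i < 0:
                break
            hits.append((i, i + len(motif), motif))
            start = i + 1
    hits.sort()
    chosen, last_end = [], -1
    for s, e, m in hits:
        if s >= last_end:
            chosen.append((s, e, m))
            last_end = e
    return chosen


def detect_telomeres(
    seq: str,
    motifs: tuple[str, ...] = ("TTAGGG", "CCCTAA"),
    window: int = 500,
    purity_threshold: float = 0.8,
    min_copies: int = 4,
    max_offset: int = 100,
) -> list[TelomereCall]:
    """Report motif arrays at the chromosome termini.

    A call is a maximal terminal interval, trimmed to whole motif copies,
    whose fraction covered by motif hits is at least `purity_threshold` and
    that begins within `max_offset` of its chromosome end.
    """
    if not motifs:
        raise ValueError("need at least one telomere motif")
    calls = []
    n = len(seq)
    for which in ("left", "right"):
        win = seq[:window] if which == "left" else seq[-window:]
        base = 0 if which == "left" else n - len(win)
        cover = _motif_cover(win, list(motifs))
        if which == "right":
            # scan from the chromosome end inward
            cover = [(len(win) - e, len(win) - s, m) for s, e, m in cover]
            cover.sort()
        best = None
        covered = 0
        first_start = None
        for s, e, m in cover:
            if first_start is None:
                first_start = s
            covered += e - s
            purity = covered / (e - first_start)
            if purity >= purity_threshold:
                best = (first_start, e, covered)
        if best is None:
            continue
        s, e, covered = best
        if which == "right":
            s, e = len(win) - e, len(win) - s
        lo, hi = base + s, base + e
        dist_to_end = lo if which == "left" else n - hi
        if dist_to_end > max_offset:
            continue
        inner = seq[lo:hi]
        inner_cover = _motif_cover(inner, list(motifs))
        cov_len = sum(e2 - s2 for s2, e2, _ in inner_cover)
        counts: dict[str, int] = {}
        for _, _, m in inner_cover:
            counts[m] = counts.get(m, 0) + 1
        motif = max(counts, key=counts.get)
        repeat_count = cov_len / len(motif)
        if repeat_count < min_copies:
            continue
        calls.append(
            TelomereCall(which, lo, hi, motif, repeat_count, cov_len / (hi - lo))
        )
    return calls


# ---------------------------------------------------------------------------
# exact motif search


def motif_longest_exact_match(
    query: str, region: str
) -> tuple[int, list[tuple[int, str]]]:
    """Longest exact substring shared by `query` and `region` (both strands).

    Returns the match length and all maximal hit start positions in forward
    region coordinates, tagged with the matching strand.
    """
    if not query or not region:
        raise ValueError("query and region must be non-empty")
    q = encode(query)
    best_len = 0
    hits: list[tuple[int, str]] = []
    for strand in "+-":
        reg = encode(region) if strand == "+" else encode(revcomp(region))
        prev = np.zeros(len(reg), dtype=np.int32)
        ends = np.zeros(len(reg), dtype=np.int32)  # best run length ending at j
        for qi in range(len(q)):
            cur = np.where(reg == q[qi], 1, 0).astype(np.int32)
            cur[1:] += np.where(cur[1:] > 0, prev[:-1], 0)
            ends = np.maximum(ends, cur)
            prev = cur
        m = int(ends.max(initial=0))
        if m == 0:
            continue
        for j in np.nonzero(ends == m)[0]:
            start = int(j) - m + 1
            if strand == "-":
                start = len(region) - (start + m)
            entry = (start, strand)
            if m > best_len:
                best_len, hits = m, [entry]
            elif m == best_len and entry not in hits:
                hits.append(entry)
    hits.sort()
    return best_len, hits
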