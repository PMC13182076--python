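"""Junction-aware mapping of 3'-tag RNA reads and transcript-species calls.

The split mapper places each read either contiguously or as two blocks
separated by a reference gap (a removed intron). Gaps that exactly join an
annotated intron's ends are "perfect ligations" — the RNA-level evidence
that the intron was spliced out. Untemplated 3' adenosine runs are
soft-clipped and clustered into poly(A) site calls; junction and poly(A)
evidence together classify reads into the transcript species RNA1 (ligated
SSU rRNA), RNA2 (polyadenylated, I51-retaining homing-endonuclease
transcript) and RNA3 (mature HE mRNA with I51 removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import ReadAlignment
from .features import Annotation
from .sequtil import encode, revcomp
from .synth import ReadSet


@dataclass
class JunctionCall:
    donor: int  # first intron base (half-open start of the gap)
    acceptor: int  # first exon base after the intron (half-open end of gap)
    support: int
    perfect_ligation: bool

    @property
    def gap_length(self) -> int:
        return self.acceptor - self.donor


@dataclass
class PolyACall:
    position: int  # half-open end of the templated part
    support: int
    mean_tail_len: float


@dataclass
class TranscriptSpecies:
    label: str
    defining_evidence: str
    read_count: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.read_count.values())

    def normalized(self, mapped_per_stage: dict[str, int]) -> dict[str, float]:
        """Reads per 10,000 mapped, per stage."""
        return {
            st: 1e4 * n / mapped_per_stage[st]
            for st, n in self.read_count.items()
            if mapped_per_stage.get(st)
        }


@dataclass
class CoverageTrack:
    stage: str
    coverage: np.ndarray

    @property
    def log10_display(self) -> np.ndarray:
        return np.log10(self.coverage + 1.0)


# ---------------------------------------------------------------------------
# split mapping


def _first_break(mismatch_pos: np.ndarray, length: int, pair_window: int = 3) -> int:
    """Length of the reliable prefix: stop at the first pair of mismatches
    within `pair_window` bases of each other (isolated substitutions pass)."""
    if len(mismatch_pos) < 2:
        return length
    close = np.nonzero(np.diff(mismatch_pos) <= pair_window)[0]
    if len(close) == 0:
        return length
    return int(mismatch_pos[close[0]])


def _intron_intervals(annotation: Annotation) -> list[tuple[int, int]]:
    return [
        (f.start, f.end)
        for f in annotation.of_type("intron", "spliceosomal_intron")
    ]


class TagMapper:
    """Annotation-guided two-block split mapper for short RNA reads."""

    def __init__(
        self,
        ref: str,
        annotation: Annotation | None = None,
        seed_k: int = 15,
        seed_stride: int = 10,
        min_anchor: int = 8,
        min_tail: int = 4,
    ):
        if min_anchor < 6:
            raise ValueError("min_anchor must be >= 6")
        self.ref = ref
        self.codes = encode(ref)
        self.k = seed_k
        self.stride = seed_stride
        self.min_anchor = min_anchor
        self.min_tail = min_tail
        self.introns = _intron_intervals(annotation) if annotation else []
        self.index: dict[str, list[int]] = {}
        for i in range(len(ref) - seed_k + 1):
            self.index.setdefault(ref[i: i + seed_k], []).append(i)

    def _seed_hits(self, seq: str) -> list[tuple[int, int]]:
        n = len(seq) - self.k + 1
        if n <= 0:
            return []
        positions = list(range(0, n, self.stride))
        if positions[-1] != n - 1:
            positions.append(n - 1)
        hits = []
        for p in positions:
            for rp in self.index.get(seq[p: p + self.k], ()):
                hits.append((p, rp - p))
        return hits

    def _map_oriented(self, seq: str):
        """Return (blocks, n_mismatch, templated_end, tail) or None."""
        tail = 0
        core = seq
        while tail < len(seq) and seq[len(seq) - 1 - tail] == "A":
            tail += 1
        if tail >= self.min_tail:
            core = seq[: len(seq) - tail]
        else:
            tail = 0
        L = len(core)
        if L < self.k:
            return None
        hits = self._seed_hits(core)
        if len(hits) < 1:
            return None
        rcodes = encode(core)

        def mismatches(diag: int, lo: int, hi: int) -> np.ndarray:
            a = rcodes[lo:hi]
            b = self.codes[diag + lo: diag + hi]
            if len(a) != len(b):
                return np.arange(lo, hi)
            return np.nonzero(a != b)[0] + lo

        votes: dict[int, int] = {}
        for _, d in hits:
            votes[d] = votes.get(d, 0) + 1
        diags = sorted(
            (d for d in votes if 0 <= d and d + L <= len(self.ref)),
            key=lambda d: (-votes[d], d),
        )
        # a read that any single diagonal explains (isolated substitutions
        # only) is contiguous — repeat-internal reads must never be forced
        # into spurious spliced placements
        max_mm = max(2, int(0.1 * L))
        for d in diags:
            mm = mismatches(d, 0, L)
            if len(mm) <= max_mm and _first_break(mm, L) == L:
                return [((0, L), (d, d + L))], len(mm), d + L, tail

        # annotation-guided splicing from a single diagonal: a short exon
        # anchor (>= min_anchor but < k) cannot seed, so test each
        # annotated intron from the diagonals we do have
        for d in diags[:6]:
            mm = mismatches(d, 0, L)
            r_max = _first_break(mm, L)
            mm_rev = (L - 1) - mm[::-1]
            l_min = L - _first_break(mm_rev, L)
            for s, e in self.introns:
                gap = e - s
                # d as the left (5') diagonal
                split = s - d
                if (
                    self.min_anchor <= split <= L - self.min_anchor
                    and split <= r_max
                    and 0 <= d + gap and d + gap + L <= len(self.ref)
                ):
                    mmR = mismatches(d + gap, split, L)
                    if len(mmR) == 0 or (
                        len(mmR) <= max_mm
                        and _first_break(mmR - split, L - split) == L - split
                    ):
                        nm = len(np.nonzero(mm < split)[0]) + len(mmR)
                        if nm <= max_mm:
                            blocks = [
                                ((0, split), (d, d + split)),
                                ((split, L), (e, e + L - split)),
                            ]
                            return blocks, nm, e + L - split, tail
                # d as the right (3') diagonal
                d_left2 = d - gap
                split = s - d_left2
                if (
                    self.min_anchor <= split <= L - self.min_anchor
                    and split >= l_min
                    and 0 <= d_left2
                ):
                    mmL = mismatches(d_left2, 0, split)
                    if len(mmL) == 0 or (
                        len(mmL) <= max_mm and _first_break(mmL, split) == split
                    ):
                        nm = len(mmL) + len(np.nonzero(mm >= split)[0])
                        if nm <= max_mm:
                            blocks = [
                                ((0, split), (d_left2, s)),
                                ((split, L), (e, d + L)),
                            ]
                            return blocks, nm, d + L, tail

        # de novo spliced: test ordered diagonal pairs, best-supported first
        for d_left in diags[:6]:
            for d_right in diags[:6]:
                gap = d_right - d_left
                if gap <= 0:
                    continue
                mmL = mismatches(d_left, 0, L)
                r_max = _first_break(mmL, L)
                mmR = mismatches(d_right, 0, L)
                mm_rev = (L - 1) - mmR[::-1]
                l_min = L - _first_break(mm_rev, L)
                lo = max(l_min, self.min_anchor)
                hi = min(r_max, L - self.min_anchor)
                if lo > hi:
                    continue
                split = None
                for s, e in self.introns:
                    if e - s == gap and lo <= s - d_left <= hi:
                        split = s - d_left
                        break
                if split is None:
                    split = hi  # maximal left extension, deterministic
                nm = len(mismatches(d_left, 0, split)) + len(
                    np.nonzero(mmR >= split)[0]
                )
                if nm > max_mm:
                    continue
                blocks = [
                    ((0, split), (d_left, d_left + split)),
                    ((split, L), (d_right + split, d_right + L)),
                ]
                return blocks, nm, d_right + L, tail
        return None

    def map_read(self, read_id: str, seq: str, meta=None) -> ReadAlignment | None:
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            res = self._map_oriented(oriented)
            if res is None:
                continue
            blocks, nm, end, tail = res
            # re-extend templated adenosines from the clipped tail
            while tail > 0 and end < len(self.ref) and self.ref[end] == "A":
                (rs, re_), (ts, te) = blocks[-1]
                blocks[-1] = ((rs, re_ + 1), (ts, te + 1))
                end += 1
                tail -= 1
            return ReadAlignment(
                read_id, "ref", blocks, strand=strand,
                clipped_suffix=tail, n_mismatch=nm,
                meta={**(meta or {}), "tail_a": tail, "templated_end": end},
            )
        return None


def map_tag_reads(
    reads: ReadSet,
    ref: str,
    annotation: Annotation | None = None,
    min_anchor: int = 8,
    mapper: TagMapper | None = None,
) -> list[ReadAlignment]:
    """Map 3'-tag reads contiguously or as annotation-guided/de-novo
    two-block spliced alignments; untemplated 3' A-runs are soft-clipped."""
    m = mapper if mapper is not None else TagMapper(
        ref, annotation, min_anchor=min_anchor
    )
    out = []
    for read in reads:
        a = m.map_read(read.id, read.seq, meta=read.meta)
        if a is not None:
            out.append(a)
    return out


# ---------------------------------------------------------------------------
# evidence calls


def call_junctions(
    alignments: list[ReadAlignment],
    annotation: Annotation | None = None,
    min_anchor: int = 8,
) -> list[JunctionCall]:
    """One call per distinct (donor, acceptor) with read support counts."""
    introns = set(_intron_intervals(annotation)) if annotation else set()
    support: dict[tuple[int, int], int] = {}
    for a in alignments:
        if not a.is_spliced:
            continue
        anchors_ok = all(
            re_ - rs >= min_anchor for (rs, re_), _ in (a.blocks[0], a.blocks[-1])
        )
        if not anchors_ok:
            continue
        for donor, acceptor in a.gaps():
            support[(donor, acceptor)] = support.get((donor, acceptor), 0) + 1
    return [
        JunctionCall(d, ac, n, (d, ac) in introns)
        for (d, ac), n in sorted(support.items())
    ]


def call_polya(
    alignments: list[ReadAlignment],
    ref: str,
    min_a: int = 10,
    cluster_radius: int = 5,
    min_support: int = 2,
) -> list[PolyACall]:
    """Cluster untemplated 3' A-tail positions into poly(A) site calls."""
    if min_a < 5:
        raise ValueError("min_a must be >= 5")
    events = sorted(
        (a.meta["templated_end"], a.meta["tail_a"])
        for a in alignments
        if a.meta.get("tail_a", 0) >= min_a
    )
    calls: list[PolyACall] = []
    cluster: list[tuple[int, int]] = []
    for pos, tail in events + [(None, None)]:
        if cluster and (pos is None or pos - cluster[-1][0] > cluster_radius):
            if len(cluster) >= min_support:
                positions = [p for p, _ in cluster]
                tails = [t for _, t in cluster]
                calls.append(
                    PolyACall(
                        int(np.median(positions)), len(cluster),
                        float(np.mean(tails)),
                    )
                )
            cluster = []
        if pos is not None:
            cluster.append((pos, tail))
    return calls


def _span_within(a: ReadAlignment, interval: tuple[int, int]) -> bool:
    return interval[0] <= a.ref_start and a.ref_end <= interval[1]


def classify_species(
    junctions: list[JunctionCall],
    polya: list[PolyACall],
    alignments: list[ReadAlignment],
    annotation: Annotation,
) -> list[TranscriptSpecies]:
    """Partition reads into transcript species by their defining evidence.

    Reads inside the HEG region that carry no I51-informative evidence are
    consistent with both RNA2 and RNA3 and are left unassigned; reads with
    conflicting I51 evidence are flagged ambiguous and excluded.
    """
    del junctions, polya  # species predicates are evaluated per read
    i51 = None
    spliceosomal = annotation.of_type("spliceosomal_intron")
    if spliceosomal:
        i51 = (spliceosomal[0].start, spliceosomal[0].end)
    heg = None
    heg_feats = annotation.of_type("HEG")
    if heg_feats:
        heg = (heg_feats[0].start, heg_feats[0].end)
    elif i51 is not None:
        for f in annotation.of_type("intron"):
            if f.start <= i51[0] and i51[1] <= f.end:
                heg = (f.start, f.end)
    ssu_introns = [
        (f.start, f.end) for f in annotation.of_type("intron")
        if f.attributes.get("gene") == "SSU"
    ]
    lsu_introns = [
        (f.start, f.end) for f in annotation.of_type("intron")
        if f.attributes.get("gene") == "26S"
    ]

    def exon_span(gene):
        exons = [f for f in annotation.of_type("exon")
                 if f.attributes.get("gene") == gene]
        if not exons:
            return None
        return min(f.start for f in exons), max(f.end for f in exons)

    ssu_span = exon_span("SSU")
    s58_span = exon_span("5.8S")
    s26_span = exon_span("26S")
    ets_span = None
    ets = [f for f in annotation.of_type("ETS")]
    if ets:
        ets_span = (ets[0].start, ets[0].end)

    evidence = {
        "RNA1": "S956 exon-exon junction or SSU exon placement",
        "RNA2": "I51 interior coverage (intron retained)",
        "RNA3": "spliced I51 junction",
        "rRNA_5.8S": "placement within the 5.8S gene",
        "rRNA_26S": "L1949/L2449 junction or 26S exon placement",
        "ETS_fragment": "placement within the ETS",
    }
    counts: dict[str, dict[str, int]] = {k: {} for k in evidence}

    for a in alignments:
        stage = a.meta.get("stage", "none")
        gaps = a.gaps()
        label = None
        if i51 is not None:
            has_i51_junction = (i51[0], i51[1]) in gaps
            covers_i51 = any(
                ts < i51[1] and i51[0] < te for _, (ts, te) in a.blocks
            )
            if has_i51_junction and covers_i51:
                continue  # conflicting evidence: ambiguous
            if has_i51_junction:
                label = "RNA3"
            elif covers_i51:
                label = "RNA2"
        if label is None and any(g in ssu_introns for g in gaps):
            label = "RNA1"
        if label is None and any(g in lsu_introns for g in gaps):
            label = "rRNA_26S"
        if label is None:
            if heg is not None and _span_within(a, heg):
                label = None  # RNA2/RNA3 indistinguishable here
            elif s58_span and _span_within(a, s58_span):
                label = "rRNA_5.8S"
            elif ets_span and _span_within(a, ets_span):
                label = "ETS_fragment"
            elif ssu_span and _span_within(a, ssu_span):
                label = "RNA1"
            elif s26_span and _span_within(a, s26_span):
                label = "rRNA_26S"
        if label is not None:
            counts[label][stage] = counts[label].get(stage, 0) + 1

    return [
        TranscriptSpecies(label, evidence[label], counts[label])
        for label in evidence
        if counts[label]
    ]


def coverage_tracks(
    alignments_by_stage: dict[str, list[ReadAlignment]], ref_length: int
) -> dict[str, CoverageTrack]:
    """Per-base coverage per stage plus the pooled track."""
    out = {}
    pooled = np.zeros(ref_length)
    for stage, alns in alignments_by_stage.items():
        diff = np.zeros(ref_length + 1)
        for a in alns:
            for _, (ts, te) in a.blocks:
                diff[ts] += 1
                diff[te] -= 1
        cov = np.cumsum(diff[:-1])
        pooled += cov
        out[stage] = CoverageTrack(stage, cov)
    out["pooled"] = CoverageTrack("pooled", pooled)
    return out


def enriched_regions(
    track: CoverageTrack, factor: float = 5.0, window: int = 500
) -> list[tuple[int, int]]:
    """Descriptive coverage peaks >= `factor` x the local median coverage."""
    cov = track.coverage
    hot = np.zeros(len(cov), dtype=bool)
    for i in range(0, len(cov), window):
        local = cov[max(0, i - window): i + 2 * window]
        med = np.median(local[local > 0]) if np.any(local > 0) else 0.0
        if med > 0:
            hot[i: i + window] = cov[i: i + window] >= factor * med
    out, start = [], None
    for i, h in enumerate(hot):
        if h and start is None:
            start = i
        elif not h and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(cov)))
    return out
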