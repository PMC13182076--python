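"""Synthetic chromosome construction and read simulation.

`build_chromosome` turns a :class:`~rdnascan.plan.SegmentPlan` into a
concrete DNA sequence plus a ground-truth annotation of every planted
element. Sequence content is drawn from two separate random streams: the
plan's template seed fixes the layout sequences (repeat units, fillers,
palindrome arms), while the run seed drives per-copy mutation, palindrome
arm divergence and read sampling. Two runs with the same (plan, seed) are
byte-identical.

`simulate_long_reads` and `simulate_tag_reads` emulate, at desk scale,
whole-genome long-read sequencing (substitution errors only) and 3'-tag
RNA libraries with a preference for polyadenylated transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import Annotation, Feature
from .plan import PRO_MOTIF, SegmentPlan
from .sequtil import mutate, random_dna, revcomp

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A segment's length is incompatible with its embedded elements."""


@dataclass
class Read:
    id: str
    seq: str
    meta: dict = field(default_factory=dict)


@dataclass
class ReadSet:
    reads: list[Read]
    origin: str  # {dna_long, rna_tag}
    stage: str | None = None
    seed: int = 0

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# elementary constructors


def _make_palindrome(arm: str, divergence: float, loop: str, rng) -> str:
    if not (0 <= divergence < 0.5):
        raise ValueError("divergence must be in [0, 0.5)")
    return arm + loop + mutate(revcomp(arm), divergence, rng)


def make_palindrome(arm: str, divergence: float, loop: str = "", seed: int = 0) -> str:
    """arm + loop + (mutated) reverse complement of arm."""
    return _make_palindrome(arm, divergence, loop, np.random.default_rng(seed))


def _make_tandem_array(unit: str, copies: int, rate: float, rng) -> tuple[str, list[int]]:
    if copies < 1:
        raise ValueError("copies must be >= 1")
    pieces, bounds, pos = [], [], 0
    for _ in range(copies):
        pieces.append(mutate(unit, rate, rng))
        bounds.append(pos)
        pos += len(unit)
    return "".join(pieces), bounds


def make_tandem_array(
    unit: str, copies: int, per_copy_mut_rate: float = 0.0, seed: int = 0
) -> tuple[str, list[int]]:
    """Tandem copies of `unit`, each independently mutated; returns unit starts."""
    return _make_tandem_array(unit, copies, per_copy_mut_rate, np.random.default_rng(seed))


def _plant(seq: str, pos: int, motif: str) -> str:
    return seq[:pos] + motif + seq[pos + len(motif):]


# ---------------------------------------------------------------------------
# segment builders: each returns (sequence, local features)


def _build_telomere(spec, trng, rrng):
    unit = spec.params["unit"]
    copies = spec.params["copies"]
    if copies * len(unit) != spec.length:
        raise ConfigurationError(
            f"{spec.name}: {copies} x {len(unit)} bp != segment length {spec.length}"
        )
    seq = unit * copies
    feats = [
        Feature(
            spec.name, "telomere", 0, spec.length,
            attributes={"motif": unit, "copies": copies},
        )
    ]
    return seq, feats


def _build_palindrome_nts(spec, trng, rrng):
    p = spec.params
    arm_len, loop_len = p["arm"], p.get("loop", 0)
    if 2 * arm_len + loop_len != spec.length:
        raise ConfigurationError(
            f"{spec.name}: 2 x {arm_len} + {loop_len} != segment length {spec.length}"
        )
    arm = random_dna(arm_len, trng)
    loop = random_dna(loop_len, trng) if loop_len else ""
    seq = _make_palindrome(arm, p.get("divergence", 0.0), loop, rrng)
    pro_off = p.get("pro_offset")
    feats = [
        Feature(
            spec.name, "palindrome", 0, spec.length,
            attributes={"arm": arm_len, "loop": loop_len},
        )
    ]
    if pro_off is not None:
        motif = p.get("pro_motif", PRO_MOTIF)
        if pro_off + len(motif) > arm_len:
            raise ConfigurationError(f"{spec.name}: PRO motif outside arm")
        # plant the origin motif in the left arm and its mirror-image
        # counterpart in the right arm (pairing x <-> L-1-x), after the
        # divergence mutations so both copies stay exact
        seq = _plant(seq, pro_off, motif)
        mirror = spec.length - pro_off - len(motif)
        seq = _plant(seq, mirror, revcomp(motif))
        feats.append(
            Feature("PRO1", "motif_hit", pro_off, pro_off + len(motif),
                    attributes={"motif": "PRO"}))
        feats.append(
            Feature("PRO2", "motif_hit", mirror, mirror + len(motif),
                    strand="-", attributes={"motif": "PRO"}))
    return seq, feats


def _build_repeat_array(spec, trng, rrng):
    p = spec.params
    unit_len, copies = p["unit_length"], p["copies"]
    if unit_len * copies != spec.length:
        raise ConfigurationError(
            f"{spec.name}: {copies} x {unit_len} bp != segment length {spec.length}"
        )
    unit = p.get("unit") or random_dna(unit_len, trng)
    seq, bounds = _make_tandem_array(unit, copies, p.get("mut_rate", 0.0), rrng)
    label = spec.name.split("_")[-1]
    feats = [
        Feature(
            spec.name, "tandem_array", 0, spec.length,
            attributes={"unit_length": unit_len, "copies": copies, "motif": label},
        )
    ]
    for i, b in enumerate(bounds):
        feats.append(
            Feature(f"{spec.name}_unit{i + 1}", "repeat_unit", b, b + unit_len,
                    attributes={"motif": label, "index": i + 1}))
    return seq, feats


def _build_upr(spec, trng, rrng):
    p = spec.params
    unit_len, copies = p["unit_length"], p["copies"]
    if unit_len * copies != spec.length:
        raise ConfigurationError(
            f"{spec.name}: {copies} x {unit_len} bp != segment length {spec.length}"
        )
    pal_off, pal_arm = p["pal_offset"], p["pal_arm"]
    ir5_off, ir_arm, ir_loop = p["ir5_offset"], p["ir_arm"], p["ir_loop"]
    if pal_off + 2 * pal_arm > unit_len:
        raise ConfigurationError(f"{spec.name}: 140 bp palindrome outside D unit")
    if ir5_off + 2 * ir_arm + ir_loop > pal_off:
        raise ConfigurationError(f"{spec.name}: nested IR outside the left D sub-unit")
    # D-unit template: nested inverted repeat at the left end, palindrome at
    # the right end
    unit = random_dna(unit_len, trng)
    ir5 = unit[ir5_off: ir5_off + ir_arm]
    ir3_start = ir5_off + ir_arm + ir_loop
    unit = _plant(unit, ir3_start, revcomp(ir5))
    parm = unit[pal_off: pal_off + pal_arm]
    unit = _plant(unit, pal_off + pal_arm, revcomp(parm))

    pieces, feats = [], [
        Feature(
            spec.name, "tandem_array", 0, spec.length,
            attributes={"unit_length": unit_len, "copies": copies, "motif": "D"},
        )
    ]
    for i in range(copies):
        cp = mutate(unit, p.get("mut_rate", 0.0), rrng)
        # copies diverge from one another, but each copy's internal
        # palindrome stays perfectly self-complementary (cruciform-forming
        # palindromes are maintained intact within a unit)
        cp = _plant(cp, pal_off + pal_arm, revcomp(cp[pal_off: pal_off + pal_arm]))
        off = i * unit_len
        pieces.append(cp)
        feats.append(
            Feature(f"D_unit{i + 1}", "repeat_unit", off, off + unit_len,
                    attributes={"motif": "D", "index": i + 1}))
        feats.append(
            Feature(f"D_pal{i + 1}", "palindrome",
                    off + pal_off, off + pal_off + 2 * pal_arm,
                    attributes={"arm": pal_arm, "loop": 0}))
        feats.append(
            Feature(f"IR5p_{i + 1}", "ir_motif", off + ir5_off,
                    off + ir5_off + ir_arm, attributes={"motif": "IR5'"}))
        feats.append(
            Feature(f"IR3p_{i + 1}", "ir_motif", off + ir3_start,
                    off + ir3_start + ir_arm, strand="-",
                    attributes={"motif": "IR3'"}))
    return "".join(pieces), feats


def _build_region_with_arrays(spec, trng, rrng, region_type):
    p = spec.params
    seq = random_dna(spec.length, trng)
    feats = [Feature(spec.name, region_type, 0, spec.length)]
    for arr in p.get("arrays", []):
        unit_len, copies, off = arr["unit_length"], arr["copies"], arr["offset"]
        if off + unit_len * copies > spec.length:
            raise ConfigurationError(
                f"{spec.name}: array {arr['name']} exceeds segment bounds"
            )
        unit = random_dna(unit_len, trng)
        arr_seq, bounds = _make_tandem_array(
            unit, copies, p.get("mut_rate", 0.0), rrng
        )
        seq = _plant(seq, off, arr_seq)
        feats.append(
            Feature(
                f"{spec.name}_array_{arr['name']}", "tandem_array",
                off, off + len(arr_seq),
                attributes={"unit_length": unit_len, "copies": copies,
                            "motif": arr["name"]},
            )
        )
        for i, b in enumerate(bounds):
            feats.append(
                Feature(f"{spec.name}_{arr['name']}_unit{i + 1}", "repeat_unit",
                        off + b, off + b + unit_len,
                        attributes={"motif": arr["name"], "index": i + 1}))
    return seq, feats


def _build_s956(spec, trng, rrng):
    p = spec.params
    r5, lc, heg = p["ribozyme5"], p["lc_ribozyme"], p["heg"]
    i51_off, i51_len = p["i51_offset"], p["i51_length"]
    if r5 + lc + heg > spec.length:
        raise ConfigurationError(f"{spec.name}: sub-elements exceed intron length")
    if i51_off + i51_len > heg:
        raise ConfigurationError(f"{spec.name}: I51 outside the HEG")
    seq = random_dna(spec.length, trng)
    heg_start = r5 + lc
    feats = [
        Feature(spec.name, "intron", 0, spec.length,
                attributes={"gene": "SSU", "subtype": "group_I"}),
        Feature("GIR_core", "ribozyme", 0, r5,
                attributes={"subtype": "group_I_core"}),
        Feature("LC_ribozyme", "ribozyme", r5, heg_start,
                attributes={"subtype": "lariat_capping"}),
        Feature("HEG", "HEG", heg_start, heg_start + heg),
        Feature("I51", "spliceosomal_intron",
                heg_start + i51_off, heg_start + i51_off + i51_len,
                attributes={"gene": "HEG"}),
        Feature("polyA_HEG", "polyA_site", heg_start + heg - 1, heg_start + heg,
                attributes={"end": heg_start + heg}),
    ]
    return seq, feats


def _build_exon(gene):
    def build(spec, trng, rrng):
        seq = random_dna(spec.length, trng)
        return seq, [Feature(spec.name, "exon", 0, spec.length,
                             attributes={"gene": gene})]
    return build


def _build_region(region_type):
    def build(spec, trng, rrng):
        return random_dna(spec.length, trng), [
            Feature(spec.name, region_type, 0, spec.length)
        ]
    return build


_BUILDERS = {
    "telomere_left": _build_telomere,
    "telomere_right": _build_telomere,
    "palindrome_NTS": _build_palindrome_nts,
    "UPR": _build_upr,
    "ETS": lambda s, t, r: _build_region_with_arrays(s, t, r, "ETS"),
    "ITS1": lambda s, t, r: _build_region_with_arrays(s, t, r, "ITS1"),
    "ITS2": _build_region("ITS2"),
    "SSU_exon1": _build_exon("SSU"),
    "SSU_exon2": _build_exon("SSU"),
    "S956-1": _build_s956,
    "5.8S": _build_exon("5.8S"),
    "26S_exon1": _build_exon("26S"),
    "26S_exon2": _build_exon("26S"),
    "26S_exon3": _build_exon("26S"),
    "L1949": lambda s, t, r: (
        random_dna(s.length, t),
        [Feature(s.name, "intron", 0, s.length,
                 attributes={"gene": "26S", "subtype": "group_I"})],
    ),
    "L2449": lambda s, t, r: (
        random_dna(s.length, t),
        [Feature(s.name, "intron", 0, s.length,
                 attributes={"gene": "26S", "subtype": "group_I"})],
    ),
    "trailer": _build_region("trailer"),
}


def build_chromosome(plan: SegmentPlan, seed: int) -> tuple[str, Annotation]:
    """Realize a plan into (sequence, ground-truth annotation)."""
    plan.validate()
    trng = np.random.default_rng(plan.seed)
    rrng = np.random.default_rng(seed)
    pieces: list[str] = []
    feats: list[Feature] = []
    pos = 0
    for spec in plan.segments:
        builder = _BUILDERS.get(spec.name)
        if builder is None:
            if spec.name.startswith("repeat_array"):
                builder = _build_repeat_array
            else:
                builder = _build_region("region")
        seq, local = builder(spec, trng, rrng)
        if len(seq) != spec.length:
            raise ConfigurationError(
                f"{spec.name}: built {len(seq)} bp, expected {spec.length}"
            )
        for f in local:
            f = f.copy()
            f.start += pos
            f.end += pos
            feats.append(f)
        pieces.append(seq)
        pos += spec.length
    total = pos
    # gene models spanning exons and their introns
    for gene in ("SSU", "5.8S", "26S"):
        exons = [f for f in feats if f.type == "exon"
                 and f.attributes.get("gene") == gene]
        if exons:
            feats.append(
                Feature(f"{gene}_gene", "gene",
                        min(e.start for e in exons), max(e.end for e in exons),
                        attributes={"gene": gene}))
    has_tu = any(
        s.name in ("ETS", "SSU_exon1", "5.8S", "trailer") for s in plan.segments
    )
    if has_tu and plan.ts_offset < plan.tt_offset:
        feats.append(Feature("Ts", "transcription_start",
                             plan.ts_offset, plan.ts_offset + 1))
        feats.append(Feature("tt", "transcription_terminator",
                             plan.tt_offset - 1, plan.tt_offset))
        if plan.ts_offset > 0:
            feats.append(Feature("NTS_upstream", "NTS", 0, plan.ts_offset))
        if plan.tt_offset < total:
            feats.append(Feature("NTS_downstream", "NTS", plan.tt_offset, total))
    truth = Annotation(total, feats).sorted()
    return "".join(pieces), truth


# ---------------------------------------------------------------------------
# transcript models


@dataclass
class Transcript:
    """A mature RNA species: ordered genomic blocks plus optional A-tail."""

    label: str
    blocks: list[tuple[int, int]]
    tail: int = 0  # untemplated 3' adenosines
    seq: str = ""

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks) + self.tail

    def genomic_blocks(self, tstart: int, tend: int) -> list[tuple[int, int]]:
        """Genomic intervals covered by transcript window [tstart, tend)."""
        out, pos = [], 0
        for s, e in self.blocks:
            blen = e - s
            lo, hi = max(tstart - pos, 0), min(tend - pos, blen)
            if lo < hi:
                out.append((s + lo, s + hi))
            pos += blen
        return out


def build_transcript_models(
    truth: Annotation, sequence: str, polya_tail: int = 25
) -> dict[str, Transcript]:
    """Derive the simulated RNA species from the ground-truth annotation.

    RNA1 is the ligated (intron-free) SSU rRNA; RNA2 the polyadenylated,
    I51-retaining HEG transcript; RNA3 the mature homing-endonuclease mRNA
    (I51 removed, polyadenylated); plus 5.8S, ligated 26S and ETS fragments.
    """
    models: dict[str, Transcript] = {}

    def exon_blocks(gene):
        exons = sorted(
            (f for f in truth.of_type("exon") if f.attributes.get("gene") == gene),
            key=lambda f: f.start,
        )
        return [(f.start, f.end) for f in exons]

    if exon_blocks("SSU"):
        models["RNA1"] = Transcript("RNA1", exon_blocks("SSU"))
    if exon_blocks("5.8S"):
        models["rRNA_5.8S"] = Transcript("rRNA_5.8S", exon_blocks("5.8S"))
    if exon_blocks("26S"):
        models["rRNA_26S"] = Transcript("rRNA_26S", exon_blocks("26S"))
    try:
        ets = truth.get("ETS")
        models["ETS_fragment"] = Transcript("ETS_fragment", [(ets.start, ets.end)])
    except KeyError:
        pass
    try:
        heg = truth.get("HEG")
        i51 = truth.get("I51")
        models["RNA2"] = Transcript("RNA2", [(heg.start, heg.end)], tail=polya_tail)
        models["RNA3"] = Transcript(
            "RNA3", [(heg.start, i51.start), (i51.end, heg.end)], tail=polya_tail
        )
    except KeyError:
        pass
    for t in models.values():
        t.seq = "".join(sequence[s:e] for s, e in t.blocks) + "A" * t.tail
    return models


# ---------------------------------------------------------------------------
# read simulators


def simulate_long_reads(
    refs: dict[str, str],
    depth_map: dict[str, float],
    read_len_mean: int = 200,
    read_len_sd: int = 40,
    error_rate: float = 0.02,
    seed: int = 0,
    min_read_len: int = 50,
) -> ReadSet:
    """Whole-molecule sampling with substitution errors only.

    Read breakpoints are uniform over the molecule including overhangs
    (reads are truncated at the ends), so the expected coverage equals the
    requested depth at every position — the property the depth-ratio
    estimator relies on.
    """
    if not (0 <= error_rate <= 0.1):
        raise ValueError("error_rate must be in [0, 0.1]")
    for name, depth in depth_map.items():
        if depth <= 0:
            raise ValueError(f"depth for {name} must be positive")
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    idx = 0
    for name, ref in refs.items():
        depth = depth_map.get(name)
        if depth is None:
            continue
        L = len(ref)
        if L < read_len_mean:
            logger.warning(
                "reference %s shorter than mean read length; reads truncated", name
            )
        n = int(round(depth * (L + read_len_mean - 1) / read_len_mean))
        lengths = np.clip(
            rng.normal(read_len_mean, read_len_sd, size=n).round().astype(int),
            min_read_len, None,
        )
        for length in lengths:
            length = int(length)
            start = int(rng.integers(-(length - 1), L))
            lo, hi = max(start, 0), min(start + length, L)
            seq = ref[lo:hi]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            seq = mutate(seq, error_rate, rng)
            reads.append(
                Read(
                    f"long_{idx}", seq,
                    meta={"ref": name, "start": lo, "end": hi, "strand": strand},
                )
            )
            idx += 1
    return ReadSet(reads, origin="dna_long", stage="none", seed=seed)


STAGES = ("amoeba", "microcyst", "flagellate", "plasmodium")

DEFAULT_ABUNDANCES = {
    "RNA1": 0.45,
    "rRNA_5.8S": 0.05,
    "rRNA_26S": 0.40,
    "RNA3": 0.06,
    "RNA2": 0.03,
    "ETS_fragment": 0.01,
}


def simulate_tag_reads(
    truth: Annotation,
    sequence: str,
    species_abundances: dict | None = None,
    n_reads: int = 5000,
    read_len: int = 100,
    seed: int = 0,
    polya_tail: int = 25,
    three_prime_lambda: float = 0.002,
    ets_anchor_frac: float = 0.3,
    error_rate: float = 0.0,
    stages: tuple[str, ...] = STAGES,
) -> ReadSet:
    """Simulate 3'-tag RNA reads (`n_reads` per life stage).

    `species_abundances` is either one weight map used for every stage or a
    per-stage mapping {stage: {species: weight}}. Polyadenylated species are
    sampled with a geometric 3'-end bias; ETS fragments have a defined 5'
    end (a fraction of reads starts exactly at the transcription start).
    """
    if species_abundances is None:
        species_abundances = DEFAULT_ABUNDANCES
    per_stage = {
        st: dict(species_abundances.get(st, species_abundances))
        if any(k in stages for k in species_abundances)
        else dict(species_abundances)
        for st in stages
    }
    models = build_transcript_models(truth, sequence, polya_tail=polya_tail)
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    idx = 0
    for stage in stages:
        weights = {k: v for k, v in per_stage[stage].items() if v > 0 and k in models}
        if not weights:
            raise ValueError(f"stage {stage}: total species abundance is zero")
        labels = sorted(weights)
        probs = np.array([weights[k] for k in labels], dtype=float)
        probs /= probs.sum()
        counts = rng.multinomial(n_reads, probs)
        for label, count in zip(labels, counts):
            t = models[label]
            lt = t.length
            span = min(read_len, lt)
            max_start = lt - span
            starts = np.arange(max_start + 1)
            if t.tail > 0:
                dist3 = max_start - starts
                w = np.exp(-three_prime_lambda * dist3)
            elif label == "ETS_fragment":
                w = np.ones_like(starts, dtype=float)
                w /= w.sum()
                w *= 1 - ets_anchor_frac
                w[0] += ets_anchor_frac
            else:
                w = np.ones_like(starts, dtype=float)
            w = w / w.sum()
            chosen = rng.choice(starts, size=count, p=w)
            for s in chosen:
                s = int(s)
                seq = t.seq[s: s + span]
                seq = mutate(seq, error_rate, rng)
                reads.append(
                    Read(
                        f"tag_{idx}", seq,
                        meta={"species": label, "stage": stage,
                              "tstart": s, "tend": s + len(seq)},
                    )
                )
                idx += 1
    return ReadSet(reads, origin="rna_tag", stage=None, seed=seed)
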