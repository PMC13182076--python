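"""Parametrized layout of the synthetic linear rDNA chromosome.

The default plan encodes the architecture of the *Didymium iridis* rDNA
chromosome: a 20,300 bp linear molecule with CCCTAA / TTAGGG telomeric
arrays, a 4.2 kb palindromic non-transcribed spacer carrying two putative
replication-origin (PRO) motifs, direct-repeat arrays A-C, a 5 x 260 bp
upstream promoter region (UPR) whose D-type units each contain a 140 bp
palindrome and a nested inverted repeat, and an 11.3 kb RNA polymerase I
transcription unit (1,483 bp ETS; SSU rRNA gene split by the 1,436 nt
group I intron S956-1 whose homing-endonuclease gene carries a 51 nt
spliceosomal intron; ITS-1 with I/J repeat arrays; 154 bp 5.8S; ITS-2;
26S rRNA gene split by group I introns L1949 and L2449), a short trailer,
sub-telomeric arrays K-N and the right telomere.

Every printed total is satisfied simultaneously: ETS 1,483; mature SSU
(19S) 1,916; S956-1 1,436; I51 51; 5.8S 154; mature 26S 3,702;
transcription unit 11,300; chromosome 20,300.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import yaml

# 15 bp replication-origin stand-in motif (the published motif is figure-only;
# the detectors test exact-match geometry, not literal sequence).
PRO_MOTIF = "GACTACGGATTGCCA"

# Fixed seed for the plan's template sequences (repeat units, fillers, arms),
# so the layout sequence is a property of the plan, not of the run seed.
TEMPLATE_SEED = 20300

SEGMENT_NAMES = (
    "telomere_left",
    "palindrome_NTS",
    "repeat_array_A",
    "repeat_array_B",
    "repeat_array_C",
    "UPR",
    "ETS",
    "SSU_exon1",
    "S956-1",
    "SSU_exon2",
    "ITS1",
    "5.8S",
    "ITS2",
    "26S_exon1",
    "L1949",
    "26S_exon2",
    "L2449",
    "26S_exon3",
    "trailer",
    "repeat_array_K",
    "repeat_array_L",
    "repeat_array_M",
    "repeat_array_N",
    "telomere_right",
)


@dataclass
class SegmentSpec:
    """One named segment of the chromosome layout."""

    name: str
    length: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be positive")


@dataclass
class SegmentPlan:
    """Ordered segment layout; doubles as the ground truth of a simulation."""

    segments: list[SegmentSpec]
    ts_offset: int
    tt_offset: int
    seed: int = TEMPLATE_SEED

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(names) != len(set(names)):
            raise ValueError("segment names must be unique within a plan")

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def offsets(self) -> dict[str, tuple[int, int]]:
        """Half-open genomic interval of every segment."""
        out = {}
        pos = 0
        for s in self.segments:
            out[s.name] = (pos, pos + s.length)
            pos += s.length
        return out

    def get(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def has(self, name: str) -> bool:
        return any(s.name == name for s in self.segments)

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("empty plan")
        if not (0 <= self.ts_offset < self.tt_offset <= self.total_length):
            raise ValueError("transcription start/termination outside chromosome")


def _array_params(unit_length: int, copies: int, mut_rate: float = 0.01) -> dict:
    return {"unit_length": unit_length, "copies": copies, "mut_rate": mut_rate}


def default_plan() -> SegmentPlan:
    """The default 20,300 bp chromosome satisfying all printed totals."""
    segs = [
        SegmentSpec("telomere_left", 150, {"unit": "CCCTAA", "copies": 25}),
        SegmentSpec(
            "palindrome_NTS",
            4200,
            {"arm": 2100, "loop": 0, "divergence": 0.01, "pro_offset": 800},
        ),
        SegmentSpec("repeat_array_A", 400, _array_params(40, 10)),
        SegmentSpec("repeat_array_B", 600, _array_params(60, 10)),
        SegmentSpec("repeat_array_C", 1400, _array_params(70, 20)),
        SegmentSpec(
            "UPR",
            1300,
            {
                "unit_length": 260,
                "copies": 5,
                "mut_rate": 0.01,
                "pal_offset": 120,
                "pal_arm": 70,
                "ir5_offset": 5,
                "ir_arm": 20,
                "ir_loop": 10,
            },
        ),
        SegmentSpec(
            "ETS",
            1483,
            {
                "mut_rate": 0.01,
                "arrays": [
                    {"name": "E", "unit_length": 30, "copies": 5, "offset": 100},
                    {"name": "F", "unit_length": 40, "copies": 3, "offset": 350},
                    {"name": "G", "unit_length": 25, "copies": 4, "offset": 600},
                    {"name": "H", "unit_length": 35, "copies": 2, "offset": 800},
                ],
            },
        ),
        SegmentSpec("SSU_exon1", 956),
        SegmentSpec(
            "S956-1",
            1436,
            {
                "ribozyme5": 250,
                "lc_ribozyme": 180,
                "heg": 955,
                "i51_offset": 300,
                "i51_length": 51,
            },
        ),
        SegmentSpec("SSU_exon2", 960),
        SegmentSpec(
            "ITS1",
            500,
            {
                "mut_rate": 0.01,
                "polymorphic": "I",
                "arrays": [
                    {"name": "I", "unit_length": 40, "copies": 3, "offset": 50},
                    {"name": "J", "unit_length": 50, "copies": 2, "offset": 250},
                ],
            },
        ),
        SegmentSpec("5.8S", 154),
        SegmentSpec("ITS2", 300),
        SegmentSpec("26S_exon1", 1795),
        SegmentSpec("L1949", 900),
        SegmentSpec("26S_exon2", 500),
        SegmentSpec("L2449", 850),
        SegmentSpec("26S_exon3", 1407),
        SegmentSpec("trailer", 59),
        SegmentSpec("repeat_array_K", 200, _array_params(20, 10)),
        SegmentSpec("repeat_array_L", 200, _array_params(25, 8)),
        SegmentSpec("repeat_array_M", 200, _array_params(50, 4)),
        SegmentSpec("repeat_array_N", 200, _array_params(40, 5)),
        SegmentSpec("telomere_right", 150, {"unit": "TTAGGG", "copies": 25}),
    ]
    plan = SegmentPlan(segments=segs, ts_offset=0, tt_offset=0)
    offs = plan.offsets()
    plan.ts_offset = offs["ETS"][0]
    plan.tt_offset = offs["trailer"][1]
    plan.validate()
    assert plan.total_length == 20300
    assert plan.tt_offset - plan.ts_offset == 11300
    return plan


def strain_variant(plan: SegmentPlan, isolate: str) -> SegmentPlan:
    """Apply isolate-specific polymorphisms to a plan.

    Pan2 is the reference isolate (identity). Hon1 carries one extra copy of
    the polymorphic ITS-1 array and lacks the optional S956-1 intron, leaving
    the SSU rRNA gene as a single contiguous exon.
    """
    if isolate == "Pan2":
        return _copy.deepcopy(plan)
    if isolate != "Hon1":
        raise ValueError(f"unknown isolate {isolate!r}")
    if not plan.has("ITS1"):
        raise ValueError("plan has no ITS1 segment")
    out = _copy.deepcopy(plan)
    its1 = out.get("ITS1")
    poly = its1.params.get("polymorphic", "I")
    grown = 0
    for arr in its1.params["arrays"]:
        if arr["name"] == poly:
            arr["copies"] += 1
            grown = arr["unit_length"]
    its1.length += grown
    # shift downstream arrays clear of the grown polymorphic array
    for arr in its1.params["arrays"]:
        if arr["name"] != poly:
            arr["offset"] += grown
    if out.has("S956-1"):
        intron_len = out.get("S956-1").length
        exon1 = out.get("SSU_exon1")
        exon2 = out.get("SSU_exon2")
        exon1.length += exon2.length  # one contiguous SSU exon
        out.segments = [
            s for s in out.segments if s.name not in ("S956-1", "SSU_exon2")
        ]
        del intron_len
    offs = out.offsets()
    out.ts_offset = offs["ETS"][0]
    out.tt_offset = offs["trailer"][1]
    out.validate()
    return out


def plan_to_dict(plan: SegmentPlan) -> dict:
    return {
        "seed": plan.seed,
        "ts_offset": plan.ts_offset,
        "tt_offset": plan.tt_offset,
        "segments": [
            {"name": s.name, "length": s.length, "params": _copy.deepcopy(s.params)}
            for s in plan.segments
        ],
    }


def plan_from_dict(data: dict) -> SegmentPlan:
    plan = SegmentPlan(
        segments=[
            SegmentSpec(d["name"], d["length"], _copy.deepcopy(d.get("params", {})))
            for d in data["segments"]
        ],
        ts_offset=data["ts_offset"],
        tt_offset=data["tt_offset"],
        seed=data.get("seed", TEMPLATE_SEED),
    )
    plan.validate()
    return plan


def save_plan(plan: SegmentPlan, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(plan_to_dict(plan), fh, sort_keys=False)


def load_plan(path) -> SegmentPlan:
    with open(path) as fh:
        return plan_from_dict(yaml.safe_load(fh))
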