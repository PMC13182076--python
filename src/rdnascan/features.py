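"""Genomic interval features — the annotation currency of the package.

All coordinates are 0-based half-open on the forward strand of a single
reference sequence. GFF3 output converts to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


# Feature types the detectors claim to recover blindly; everything else in a
# ground-truth annotation is bookkeeping (sub-motifs, region labels, gene
# models) and is excluded from precision/recall scoring.
RECOVERABLE_TYPES = frozenset(
    {
        "telomere",
        "palindrome",
        "tandem_array",
        "motif_hit",
        "intron",
        "spliceosomal_intron",
        "exon",
        "polyA_site",
        "transcription_start",
    }
)


@dataclass
class Feature:
    """A typed genomic interval with strand and free-form attributes."""

    id: str
    type: str
    start: int
    end: int
    strand: str = "+"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Feature") -> bool:
        return self.start < other.end and other.start < self.end

    def copy(self) -> "Feature":
        return replace(self, attributes=dict(self.attributes))


@dataclass
class Annotation:
    """An ordered feature set over one sequence of known length."""

    seq_length: int
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate feature ids in annotation")
        for f in self.features:
            if f.end > self.seq_length:
                raise ValueError(
                    f"feature {f.id} extends past sequence end ({f.end} > {self.seq_length})"
                )

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def of_type(self, *types: str) -> list[Feature]:
        wanted = set(types)
        return [f for f in self.features if f.type in wanted]

    def get(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.id == feature_id:
                return f
        raise KeyError(feature_id)

    def add(self, feature: Feature) -> None:
        if any(f.id == feature.id for f in self.features):
            raise ValueError(f"duplicate feature id {feature.id}")
        if feature.end > self.seq_length:
            raise ValueError(f"feature {feature.id} extends past sequence end")
        self.features.append(feature)

    def sorted(self) -> "Annotation":
        return Annotation(
            self.seq_length,
            sorted(self.features, key=lambda f: (f.start, f.end, f.id)),
        )
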