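"""Merge detector outputs into a coherent annotation and score recovery.

`assemble_annotation` combines repeat calls with RNA evidence: perfect
exon-ligation junctions become intron features (a junction-intron nested
inside another is a spliceosomal intron), exons are the complements of the
top-level introns within their gene spans, the transcription start is the
5'-most onset of RNA coverage, and poly(A) clusters become site features.
`segment_lengths` then reproduces the chromosome's length bookkeeping
(mature rRNA lengths = gene span minus inferred introns) and
`compare_to_truth` scores a recovered annotation against the generator's
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .features import RECOVERABLE_TYPES, Annotation, Feature

# which truth types a call of a given type may legitimately recover
_COMPAT = {
    "tandem_array": {"tandem_array", "telomere"},
    "telomere": {"telomere"},
    "palindrome": {"palindrome"},
    "motif_hit": {"motif_hit"},
    "intron": {"intron"},
    "spliceosomal_intron": {"spliceosomal_intron"},
    "exon": {"exon"},
    "polyA_site": {"polyA_site"},
    "transcription_start": {"transcription_start"},
}


@dataclass
class RecoveryReport:
    truth_status: dict[str, str]
    call_status: dict[str, str]
    precision: float
    recall: float
    length_table: dict = field(default_factory=dict)


def assemble_annotation(
    chrom_length: int,
    telomeres=(),
    palindromes=(),
    arrays=(),
    motif_hits=(),
    junctions=(),
    polya=(),
    gene_model: Annotation | None = None,
    coverage: np.ndarray | None = None,
    tt: int | None = None,
) -> Annotation:
    """Build one coherent feature set from detector and RNA evidence.

    `motif_hits` are (start, end, strand, name) tuples in chromosome
    coordinates; `gene_model` supplies gene spans (features of type
    "gene") within which exons are inferred; `tt` is a transcription
    terminator coordinate carried through as inferred (3'-tag data gives
    no direct terminator evidence).
    """
    ann = Annotation(chrom_length, [])
    ann.add(Feature("chromosome", "region", 0, chrom_length))

    for call in telomeres:
        ann.add(
            Feature(
                f"telomere_{call.end}", "telomere", call.start, call.stop,
                attributes={
                    "motif": call.motif,
                    "copies": round(call.repeat_count, 1),
                    "purity": round(call.purity, 3),
                },
            )
        )
    for i, call in enumerate(sorted(palindromes, key=lambda c: c.left_arm[0])):
        ann.add(
            Feature(
                f"palindrome_{i + 1}", "palindrome",
                call.left_arm[0], call.right_arm[1],
                attributes={
                    "arm": call.left_arm[1] - call.left_arm[0],
                    "loop": call.loop_length,
                    "half_identity": round(call.half_identity, 4),
                },
            )
        )
    for i, call in enumerate(sorted(arrays, key=lambda c: c.start)):
        ann.add(
            Feature(
                f"array_{i + 1}", "tandem_array", call.start, call.end,
                attributes={
                    "unit_length": call.unit_length,
                    "copies": call.copies,
                    "identity": round(call.mean_pairwise_identity, 4),
                },
            )
        )
    for i, (start, end, strand, name) in enumerate(sorted(motif_hits)):
        ann.add(
            Feature(f"motif_{i + 1}", "motif_hit", start, end, strand=strand,
                    attributes={"motif": name})
        )

    # introns from perfect-ligation junctions; nested => spliceosomal
    perfect = sorted(
        {(j.donor, j.acceptor) for j in junctions if j.perfect_ligation}
    )
    supports = {(j.donor, j.acceptor): j.support for j in junctions}
    nested = {
        (s, e)
        for s, e in perfect
        if any((s2 <= s and e <= e2 and (s2, e2) != (s, e)) for s2, e2 in perfect)
    }
    intron_feats = []
    for s, e in perfect:
        ftype = "spliceosomal_intron" if (s, e) in nested else "intron"
        intron_feats.append(
            Feature(f"intron_{s}_{e}", ftype, s, e,
                    attributes={"support": supports[(s, e)]})
        )
        ann.add(intron_feats[-1])

    # exons: complements of top-level introns within each gene span
    if gene_model is not None:
        top = [f for f in intron_feats if f.type == "intron"]
        for gene in gene_model.of_type("gene"):
            name = gene.attributes.get("gene", gene.id)
            inside = sorted(
                (f for f in top if gene.start <= f.start and f.end <= gene.end),
                key=lambda f: f.start,
            )
            for f in top:
                if f.overlaps(gene) and f not in inside:
                    raise ValueError(
                        f"junction {f.id} implies a negative-length exon in {name}"
                    )
            pos, n = gene.start, 0
            for f in inside + [Feature("_end", "region", gene.end, gene.end + 1)]:
                if f.start < pos:
                    raise ValueError(
                        f"junction {f.id} implies a negative-length exon in {name}"
                    )
                if f.start > pos:
                    n += 1
                    ann.add(
                        Feature(f"{name}_exon{n}", "exon", pos, f.start,
                                attributes={"gene": name})
                    )
                pos = f.end
            for f in inside:
                f.attributes["gene"] = name

    if coverage is not None:
        onset = np.nonzero(np.asarray(coverage) > 0)[0]
        if len(onset):
            ts = int(onset[0])
            ann.add(Feature("Ts", "transcription_start", ts, ts + 1,
                            attributes={"evidence": "RNA coverage onset"}))
    for i, call in enumerate(polya):
        ann.add(
            Feature(
                f"polyA_{i + 1}", "polyA_site", call.position - 1, call.position,
                attributes={"end": call.position, "support": call.support,
                            "mean_tail": round(call.mean_tail_len, 1)},
            )
        )
    if tt is not None:
        ann.add(Feature("tt", "transcription_terminator", tt - 1, tt,
                        attributes={"inferred": "true"}))
    return ann.sorted()


def kb_string(bp: int | None) -> str | None:
    """Render base pairs as kb with one decimal, round half away from zero."""
    if bp is None:
        return None
    kb = (Decimal(bp) / Decimal(1000)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    return f"{kb} kb"


def segment_lengths(annotation: Annotation) -> dict[str, int | None]:
    """Length bookkeeping of the annotated transcription unit.

    Mature rRNA lengths are gene spans minus their inferred introns (i.e.
    summed exon lengths); missing transcription start/terminator entries
    yield explicit None values rather than an error.
    """
    def exons(gene):
        return [f for f in annotation.of_type("exon")
                if f.attributes.get("gene") == gene]

    def introns(gene, types=("intron",)):
        return [f for f in annotation.of_type(*types)
                if f.attributes.get("gene") == gene]

    ts_feats = annotation.of_type("transcription_start")
    tt_feats = annotation.of_type("transcription_terminator")
    ts = ts_feats[0].start if ts_feats else None
    tt = tt_feats[0].end if tt_feats else None

    ssu_exons = exons("SSU")
    table: dict[str, int | None] = {}
    table["chromosome"] = annotation.seq_length
    table["transcription_unit"] = (tt - ts) if ts is not None and tt is not None else None
    table["ETS"] = (
        min(f.start for f in ssu_exons) - ts if ssu_exons and ts is not None else None
    )
    table["19S"] = sum(f.length for f in ssu_exons) or None
    table["S956-1"] = sum(f.length for f in introns("SSU")) or None
    i51 = annotation.of_type("spliceosomal_intron")
    table["I51"] = sum(f.length for f in i51) or None
    table["5.8S"] = sum(f.length for f in exons("5.8S")) or None
    table["26S"] = sum(f.length for f in exons("26S")) or None
    return table


def length_table_text(table: dict[str, int | None]) -> str:
    lines = [f"{'segment':<20}{'bp':>8}  kb"]
    for name, bp in table.items():
        lines.append(
            f"{name:<20}{bp if bp is not None else '-':>8}  "
            f"{kb_string(bp) or '-'}"
        )
    return "\n".join(lines)


def compare_to_truth(
    features: Annotation, truth: Annotation, tolerance: int = 10
) -> RecoveryReport:
    """Score a recovered annotation against ground truth.

    Matching is by feature-type compatibility plus boundary agreement
    within `tolerance` bp. Only truth features of the recoverable types
    are considered; sub-motifs and region labels are generator bookkeeping
    the detectors do not claim to find.
    """
    truth_feats = [f for f in truth if f.type in RECOVERABLE_TYPES]
    calls = [f for f in features if f.type in RECOVERABLE_TYPES]

    truth_status: dict[str, str] = {}
    matched_calls: set[str] = set()
    for tf in truth_feats:
        best = None
        for cf in calls:
            if tf.type not in _COMPAT.get(cf.type, ()):
                continue
            if not cf.overlaps(tf):
                continue
            delta = max(abs(cf.start - tf.start), abs(cf.end - tf.end))
            if best is None or delta < best[0]:
                best = (delta, cf)
        if best is None:
            truth_status[tf.id] = "missed"
        elif best[0] <= tolerance:
            truth_status[tf.id] = "recovered"
            matched_calls.add(best[1].id)
        else:
            truth_status[tf.id] = f"boundary_shifted({best[0]})"

    call_status: dict[str, str] = {}
    for cf in calls:
        ok = any(
            tf.type in _COMPAT.get(cf.type, ())
            and cf.overlaps(tf)
            and max(abs(cf.start - tf.start), abs(cf.end - tf.end)) <= tolerance
            for tf in truth_feats
        )
        call_status[cf.id] = "true" if ok else "spurious"

    n_truth = len(truth_feats)
    n_calls = len(calls)
    recall = (
        sum(1 for s in truth_status.values() if s == "recovered") / n_truth
        if n_truth
        else 1.0
    )
    precision = (
        sum(1 for s in call_status.values() if s == "true") / n_calls
        if n_calls
        else 1.0
    )
    return RecoveryReport(
        truth_status, call_status, precision, recall,
        length_table=segment_lengths(features),
    )
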