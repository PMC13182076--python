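"""Readers and writers for the standard text formats the pipeline touches.

FASTA/FASTQ go through Biopython; GFF3 records are parsed with gffutils'
line parser. Feature attributes survive a GFF3 round trip: scalar values are
stringified on write and kept as strings on read.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import Annotation, Feature

_GFF_ESCAPE = {";": "%3B", "=": "%3D", ",": "%2C", "&": "%26"}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads, path, qual_char: str = "I") -> None:
    """Write (id, sequence) pairs with a constant placeholder quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual_char * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fastq")]


def _escape(value: str) -> str:
    out = str(value)
    for ch, rep in _GFF_ESCAPE.items():
        out = out.replace(ch, rep)
    return out


def write_gff3(annotation: Annotation, seqid: str, path) -> None:
    """Emit an annotation as GFF3 (1-based inclusive coordinates).

    Column 3 carries the package's controlled feature-type vocabulary
    (SO terms where one exists: telomere, intron, exon, polyA_site, ...).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {annotation.seq_length}\n")
        for f in annotation.sorted():
            attrs = [f"ID={_escape(f.id)}"]
            for k in sorted(f.attributes):
                attrs.append(f"{_escape(k)}={_escape(f.attributes[k])}")
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "rdnascan",
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> Annotation:
    seq_length = None
    features: list[Feature] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("##sequence-region"):
            seq_length = int(line.split()[3])
            continue
        if not line or line.startswith("#"):
            continue
        rec = gffutils.feature.feature_from_line(line)
        attrs = {k: v[0] for k, v in rec.attributes.items() if k != "ID"}
        rec_id = rec.attributes["ID"][0] if "ID" in rec.attributes else rec.id
        features.append(
            Feature(
                id=rec_id,
                type=rec.featuretype,
                start=rec.start - 1,
                end=rec.end,
                strand=rec.strand if rec.strand in "+-" else ".",
                attributes=attrs,
            )
        )
    if seq_length is None:
        seq_length = max((f.end for f in features), default=1)
    return Annotation(seq_length, features)


def write_bed(annotation: Annotation, seqid: str, path) -> None:
    with open(path, "w") as fh:
        for f in annotation.sorted():
            fh.write(f"{seqid}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n")


def write_bedgraph(values, seqid: str, path) -> None:
    """Write a per-base track, run-length compressed into bedGraph lines."""
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={seqid}\n")
        start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[start]:
                fh.write(f"{seqid}\t{start}\t{i}\t{values[start]:g}\n")
                start = i
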