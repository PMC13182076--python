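"""Block-structured read placements shared by the DNA and RNA mappers.

By design there are no indels anywhere in the pipeline, so every alignment
block pairs a read interval with a reference interval of equal length;
spliced RNA alignments simply carry two blocks separated by a reference
gap (the removed intron).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ReadAlignment:
    read_id: str
    ref_name: str
    # [( (read_start, read_end), (ref_start, ref_end) ), ...] sorted
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]
    strand: str = "+"
    clipped_prefix: int = 0
    clipped_suffix: int = 0
    n_mismatch: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (rs, re_), (ts, te) in self.blocks:
            if re_ - rs != te - ts:
                raise ValueError(
                    f"{self.read_id}: block lengths differ on read and reference"
                )

    @property
    def ref_start(self) -> int:
        return self.blocks[0][1][0]

    @property
    def ref_end(self) -> int:
        return self.blocks[-1][1][1]

    @property
    def aligned_bases(self) -> int:
        return sum(re_ - rs for (rs, re_), _ in self.blocks)

    @property
    def is_spliced(self) -> bool:
        return len(self.blocks) > 1

    def gaps(self) -> list[tuple[int, int]]:
        """Reference gaps (introns) between consecutive blocks."""
        out = []
        for (_, (_, te)), (_, (ts, _)) in zip(self.blocks, self.blocks[1:]):
            out.append((te, ts))
        return out


def write_sam(alignments, ref_lengths: dict[str, int], path) -> None:
    """Minimal SAM output with substitution-only CIGARs (S/M/N)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in ref_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for a in alignments:
            cigar = []
            if a.clipped_prefix:
                cigar.append(f"{a.clipped_prefix}S")
            for i, ((rs, re_), (ts, te)) in enumerate(a.blocks):
                if i:
                    prev_te = a.blocks[i - 1][1][1]
                    cigar.append(f"{ts - prev_te}N")
                cigar.append(f"{re_ - rs}M")
            if a.clipped_suffix:
                cigar.append(f"{a.clipped_suffix}S")
            flag = 16 if a.strand == "-" else 0
            fh.write(
                f"{a.read_id}\t{flag}\t{a.ref_name}\t{a.ref_start + 1}\t60\t"
                f"{''.join(cigar)}\t*\t0\t0\t*\t*\tNM:i:{a.n_mismatch}\n"
            )
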