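"""End-to-end runs wiring the generator, detectors and evidence calls.

These functions define the package's default experiment: build the
synthetic chromosome, rediscover its architecture blindly from sequence,
estimate copy number from simulated long reads, and recover the
transcription-unit anatomy from simulated 3'-tag RNA reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import annotate, depth, repeats, rna, synth
from .features import Annotation
from .plan import PRO_MOTIF, SegmentPlan, default_plan

#: background contigs emulate single-copy chromosomal sequence
N_BACKGROUND = 3
BACKGROUND_LEN = 50_000
BACKGROUND_DEPTH = 5.0
RDNA_COPY_NUMBER = 132


def background_contigs(
    seed: int, n: int = N_BACKGROUND, length: int = BACKGROUND_LEN
) -> dict[str, str]:
    rng = np.random.default_rng([seed, 7])
    from .sequtil import random_dna

    return {f"bg_{i + 1}": random_dna(length, rng) for i in range(n)}


def run_copy_number(
    plan: SegmentPlan | None = None,
    seed: int = 1,
    copy_number: int = RDNA_COPY_NUMBER,
    bg_depth: float = BACKGROUND_DEPTH,
    bin_size: int = 1000,
    **sim_kwargs,
) -> depth.CopyNumberEstimate:
    """Simulate default long reads and estimate the rDNA copy number."""
    plan = plan or default_plan()
    chrom, _ = synth.build_chromosome(plan, seed)
    refs = {"rDNA": chrom, **background_contigs(seed)}
    depth_map = {
        name: (bg_depth * copy_number if name == "rDNA" else bg_depth)
        for name in refs
    }
    reads = synth.simulate_long_reads(refs, depth_map, seed=seed, **sim_kwargs)
    alignments = depth.map_long_reads(reads, refs)
    profiles = depth.depth_profile(
        alignments, {k: len(v) for k, v in refs.items()}, bin_size=bin_size
    )
    return depth.copy_number(
        profiles["rDNA"], [profiles[k] for k in refs if k != "rDNA"]
    )


@dataclass
class RnaRun:
    chrom: str
    truth: Annotation
    reads: synth.ReadSet
    alignments: list
    by_stage: dict[str, list]
    junctions: list[rna.JunctionCall]
    polya: list[rna.PolyACall]
    species: list[rna.TranscriptSpecies]
    tracks: dict[str, rna.CoverageTrack]


def run_rna(
    plan: SegmentPlan | None = None,
    seed: int = 1,
    n_reads: int = 5000,
    chrom: str | None = None,
    truth: Annotation | None = None,
    **sim_kwargs,
) -> RnaRun:
    """Simulate the four-stage 3'-tag experiment and call all RNA evidence."""
    plan = plan or default_plan()
    if chrom is None or truth is None:
        chrom, truth = synth.build_chromosome(plan, seed)
    reads = synth.simulate_tag_reads(
        truth, chrom, n_reads=n_reads, seed=seed, **sim_kwargs
    )
    mapper = rna.TagMapper(chrom, truth)
    alignments = rna.map_tag_reads(reads, chrom, truth, mapper=mapper)
    by_stage: dict[str, list] = {}
    for a in alignments:
        by_stage.setdefault(a.meta.get("stage", "none"), []).append(a)
    junctions = rna.call_junctions(alignments, truth)
    polya = rna.call_polya(alignments, chrom)
    species = rna.classify_species(junctions, polya, alignments, truth)
    tracks = rna.coverage_tracks(by_stage, len(chrom))
    return RnaRun(
        chrom, truth, reads, alignments, by_stage, junctions, polya, species,
        tracks,
    )


@dataclass
class RepeatScan:
    matches: list
    telomeres: list
    palindromes: list
    arrays: list
    motif_hits: list = field(default_factory=list)


def run_repeat_scan(
    chrom: str,
    k: int = 12,
    min_run: int = 20,
    min_arm: int = 50,
    max_loop: int = 100,
    pro_query: str = PRO_MOTIF,
) -> RepeatScan:
    """Blind repeat-architecture discovery on one chromosome sequence."""
    matches = repeats.self_dotplot(chrom, k=k, min_run=min_run)
    telomeres = repeats.detect_telomeres(chrom)
    palindromes = repeats.find_palindromes(
        matches, min_arm=min_arm, max_loop=max_loop, seq=chrom
    )
    arrays = repeats.find_tandem_arrays(chrom, matches)
    motif_hits = []
    if palindromes and pro_query:
        top = palindromes[0]
        lo, hi = top.left_arm[0], top.right_arm[1]
        length, hits = repeats.motif_longest_exact_match(pro_query, chrom[lo:hi])
        motif_hits = [
            (lo + start, lo + start + length, strand, "PRO")
            for start, strand in hits
        ]
    return RepeatScan(matches, telomeres, palindromes, arrays, motif_hits)


@dataclass
class FullRun:
    chrom: str
    truth: Annotation
    scan: RepeatScan
    rna: RnaRun
    annotation: Annotation
    lengths: dict
    report: annotate.RecoveryReport


def run_full(
    plan: SegmentPlan | None = None,
    seed: int = 1,
    n_reads: int = 5000,
    tolerance: int = 10,
) -> FullRun:
    """The complete default experiment: simulate, rediscover, score."""
    plan = plan or default_plan()
    chrom, truth = synth.build_chromosome(plan, seed)
    scan = run_repeat_scan(chrom)
    rna_run = run_rna(plan, seed, n_reads=n_reads, chrom=chrom, truth=truth)
    gene_model = Annotation(len(chrom), [f.copy() for f in truth.of_type("gene")])
    annotation = annotate.assemble_annotation(
        len(chrom),
        telomeres=scan.telomeres,
        palindromes=scan.palindromes,
        arrays=scan.arrays,
        motif_hits=scan.motif_hits,
        junctions=rna_run.junctions,
        polya=rna_run.polya,
        gene_model=gene_model,
        coverage=rna_run.tracks["pooled"].coverage,
        tt=plan.tt_offset,
    )
    lengths = annotate.segment_lengths(annotation)
    report = annotate.compare_to_truth(annotation, truth, tolerance=tolerance)
    return FullRun(chrom, truth, scan, rna_run, annotation, lengths, report)
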