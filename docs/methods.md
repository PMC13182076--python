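# Methods

`rdnascan` characterizes the architecture of a linear, multicopy,
non-Mendelian rDNA chromosome of the kind found in myxomycetes and other
unicellular eukaryotes: telomere-capped ends, a repeat-dense non-transcribed
spacer (NTS) with a large cruciform-capable palindrome and an upstream
promoter region (UPR) built from tandem D-type units, and a single RNA
polymerase I transcription unit whose rRNA genes are interrupted by group I
introns — one of which carries a homing endonuclease gene (HEG) that is
itself interrupted by a small spliceosomal intron. Because the package must
be verifiable without downloads, it pairs every detector with a synthetic
chromosome generator whose output doubles as ground truth.

## The synthetic chromosome

The default `SegmentPlan` realizes a 20,300 bp chromosome whose bookkeeping
satisfies, simultaneously, every architectural total the pipeline is meant
to recover: 1,483 bp ETS; a small-subunit rRNA gene encoding a 1,916 nt
mature 19S rRNA split by the 1,436 nt group I intron S956-1; a 51 nt
spliceosomal intron (I51) inside the intron's HEG; a 154 bp 5.8S rRNA; a
3,702 bp mature 26S rRNA split by the group I introns L1949 and L2449; an
11,300 bp transcription unit; a 4,200 bp NTS palindrome; and a UPR of five
260 bp D units, each containing a 140 bp palindrome and a nested inverted
repeat. Only the totals are externally constrained; internal partitions the
source material does not pin down (ITS lengths, the L-intron lengths, the
trailer, the sub-telomeric arrays, the intron's internal layout of group I
core / lariat-capping ribozyme / HEG) are package defaults chosen to sum
correctly, and all of them are configurable through the plan.

Sequence content comes from two independent random streams. The plan's
*template seed* (default 20300) fixes the layout sequences — repeat units,
palindrome arms, exon filler — so they are properties of the plan. The *run
seed* drives everything stochastic within a realization: per-copy repeat
mutation, palindrome arm divergence, and read sampling. Identical
(plan, seed) pairs are byte-identical end to end.

Specific generator choices:

- **Repeat heterogeneity.** Copies within an array are independently
  substituted at 1%/bp (substitutions always change the base, so expected
  pairwise copy identity is (1−r)² ≈ 0.98). This models the observed
  "similar but not identical" character of the arrays.
- **D-unit palindromes.** After per-copy mutation, each D unit's 140 bp
  palindrome is re-symmetrized within the copy: copies diverge from one
  another, but the palindrome stays perfectly self-complementary inside a
  copy, reflecting the structural constraint on cruciform-forming elements.
- **Replication-origin motifs.** A fixed 15 bp PRO stand-in motif is planted
  at mirror-image positions in both arms of the NTS palindrome (the second
  copy as its reverse complement), after divergence is applied, so the
  motif's cross-arm identity is exact. The published motif appears only in
  figures; the detectors test geometry and exact-match length, not literal
  sequence.
- **Poly(A).** Mature and unprocessed HEG transcripts (RNA3/RNA2) carry a
  25 nt untemplated A tail at the HEG 3' end. The site position is the
  assertion being tested; the tail length is free.
- **Isolate variants.** `strain_variant` implements the Pan2 (reference)
  and Hon1 layouts: Hon1 adds one copy to the polymorphic ITS-1 array and
  lacks the optional S956-1 intron entirely, leaving a contiguous SSU exon.

### Read simulation

Long DNA reads use uniform breakpoints over each molecule *including
overhangs*, truncated at the ends, so expected coverage equals the requested
depth at every position — the property the copy-number estimator relies on.
Errors are uniform substitutions (default 2%); indels are deliberately out
of scope, which is what permits block-structured, gap-free alignments
throughout. Defaults: read length 200 ± 40 bp, three 50 kb background
contigs at depth 5, and the rDNA at 5 × 132. These desk-scale sizes keep a
20-seed copy-number run around a minute while giving the pooled background
median ~1% sampling error.

3'-tag RNA reads (100 nt, error-free by default, per-stage for amoeba,
microcyst, flagellate and plasmodium) are drawn from mature species
sequences: ligated 19S (RNA1), 5.8S, ligated 26S, ETS fragments, and the
two polyadenylated HEG species — RNA2 (I51 retained) and RNA3 (I51
spliced). Polyadenylated species are sampled with a geometric 3'-end bias
(decay 0.002/nt); ETS fragments have a defined 5' end, with 30% of reads
anchored exactly at the transcription start. Default species weights
(rRNA-derived 0.90, RNA3 0.06, RNA2 0.03, ETS 0.01, identical across
stages) are free parameters: the source evidence is log-scale coverage
figures, not counts.

**What the generator does not emulate:** realistic long-read error profiles
(indels, homopolymer compression, chimeras), RNA secondary structure,
transcription/processing kinetics, low-complexity and homopolymer tracts in
the NTS (arms are uniform-random), and library-specific biases beyond the
single geometric 3' decay. Passing tests therefore demonstrate that the
detectors recover planted architecture under substitution noise at desk
scale — not performance on real ONT/Illumina data.

## Repeat discovery

`self_dotplot` enumerates exact k-mer matches (default k = 12) of the
sequence against itself and its reverse complement, merges k-mer start runs
into base intervals per diagonal (sense) or per pairing sum (antisense),
closes holes of ≤ 2 bp — the footprint a single substitution leaves — and
reports runs ≥ 20 bp. Quadratic behavior is acceptable and intentional at
n ≈ 20 kb.

*Palindromes.* An antisense run pairs base x with base A − x, where A is
the run's pairing sum; both edges of a run clip together under mutation, so
this pairing keeps arm comparisons aligned without any gapped alignment.
Runs sharing A (±3) merge across gaps up to 50 bp (a 2.1 kb arm at 1%
divergence occasionally has two close substitutions that break the ≤ 2 bp
rule), arms are refined base-wise outward and inward — one mismatching pair
may be skipped when ≥ 7 of the next 8 pairs match, which recovers the
sub-k fragment an edge mutation otherwise hides — and candidates with arms
≥ 50 bp and loop ≤ 100 bp become calls, largest span winning overlaps.
`half_identity` is the ungapped fraction of complementary pairs across the
trimmed arms (the generator introduces substitutions only, so gapped
comparison would add machinery without information).

*Tandem arrays.* Sense runs whose footprints overlap by more than 8 bp are
clustered (adjacent distinct arrays leak at most a couple of
chance-matching bases across their boundary, so requiring a real overlap
separates them); the period is the smallest observed offset whose
autocorrelation identity reaches 95% of the best — the canonical minimal
unit, since multiples of the true period score equally well up to mutation
noise. Edges are refined across the period with the same skip rule, copies
are rounded from footprint/period, and mean pairwise identity is computed
over all full-unit pairs.

*Telomeres.* Terminal windows (500 bp) are scanned for non-overlapping
occurrences of the motif set (TTAGGG/CCCTAA); the maximal terminal interval
with motif purity ≥ 0.8 is trimmed to whole copies and reported when it
holds ≥ 4 copies and begins within 100 bp of the chromosome end. Terminal
partial copies make `repeat_count` fractional.

*Motif search.* `motif_longest_exact_match` is a longest-common-substring
dynamic program over both strands, returning all maximal hit positions.

## Copy number from read depth

Reads are placed by an exact-seed voting mapper (15-mer seeds every 30 bp;
a read goes to the (reference, strand, diagonal) with most seed votes,
ties broken toward the forward strand and leftmost coordinate; < 2 seeds
leaves a read unmapped). Substitution-only reads need no gapped extension:
each alignment is one block plus end clips. Coverage is binned (default
1 kb) and the copy number is the target's median bin depth over the pooled
background median. Two numerical points matter: (i) uniform-breakpoint
simulation makes expected coverage flat, and (ii) at background depth 5
the binned-coverage distribution is right-skewed, and with 100 bp bins its
median sits ~3% below the mean, biasing the ratio upward; 1 kb bins average
enough reads for the median to be effectively unbiased, which is why that
is the default. With defaults the estimator is unbiased to within ~1%
(20-seed mean ≈ 132–133 for a configured 132) with ~1–2% single-seed
spread.

## RNA evidence

The tag-read mapper indexes the chromosome's 15-mers and tries, in order:
(1) a contiguous placement on any seed-supported diagonal whose mismatches
are isolated substitutions (no two mismatches within 3 bp) — this must come
first, because reads inside tandem arrays are explainable on several
diagonals and must never be forced into spurious spliced placements;
(2) annotation-guided splicing from a single diagonal, testing each
candidate intron — this recovers junction reads whose short exon anchor
(≥ 8 but < 15 nt) cannot contain a seed; (3) de novo two-diagonal splicing,
with the split placed at an annotated intron when one is compatible and at
the maximal exact left extension otherwise. Untemplated 3' A runs are
soft-clipped before seeding and re-extended base by base wherever the
reference itself continues with adenosines, so templated A runs never
masquerade as tails.

Junction calls aggregate distinct (donor, acceptor) gaps with ≥ 8 nt
anchors; a call is a *perfect ligation* when it matches an annotated
intron's coordinates exactly. Poly(A) calls cluster tail positions within
5 bp and require ≥ 10 untemplated A's and support ≥ 2. Species
classification is per read: an I51-spanning spliced read is RNA3, a read
covering I51's interior is RNA2, a read with both signals is ambiguous and
excluded; reads with the S956 exon-exon junction (or placed within SSU
exons) are RNA1, and so on for 5.8S, 26S and ETS. HEG-region reads with no
I51-informative evidence are consistent with both RNA2 and RNA3 and are
left unassigned rather than guessed — reported species counts are counts
of evidence-bearing reads. Stage comparison uses raw and per-10,000-mapped
counts; no differential statistics are attempted.

Coverage tracks are per-base, per stage plus pooled, with a log10(c+1)
display transform. ETS coverage peaks ≥ 5× the local median can be listed
descriptively (`enriched_regions`); they carry no species label.

## Annotation assembly and scoring

Perfect-ligation junctions become intron features; a junction-intron nested
inside another is typed as a spliceosomal intron. Gene spans (SSU, 5.8S,
26S) are an *input* gene model — in a real study they come from homology
and curation, which is out of scope here — and exons are their complements
around the top-level inferred introns, so mature lengths in the length
table are genuinely evidence-derived (gene span minus junction-inferred
introns). The transcription start is placed at the 5'-most onset of pooled
RNA coverage; an optional external query motif can substitute for coverage
when none is available. The terminator has no direct 3'-tag evidence and is
carried through from the plan flagged as inferred. kb renderings use
round-half-away-from-zero to one decimal.

`compare_to_truth` scores recovered features against ground truth by
type-compatible interval matching with a 10 bp boundary tolerance. Scoring
is restricted to the feature types the detectors claim to recover
(telomere, palindrome, tandem array, motif hit, intron, spliceosomal
intron, exon, poly(A) site, transcription start); generator bookkeeping —
per-unit boundaries, IR5'/IR3' sub-motifs, ribozyme sub-regions, region
labels, the inferred terminator — is excluded, since including targets no
detector addresses would make perfect recovery unattainable by
construction. A tandem-array call may legitimately match a telomere truth
feature (a telomere is a tandem array of the motif).

## Known limitations

- No indel handling anywhere: mappers, identity measures and the error
  model are substitution-only by design.
- De novo splice discovery needs a seedable (≥ 15 nt) anchor on both sides;
  shorter anchors are recovered only with annotation guidance.
- The tandem-array decomposer assumes arrays are locally contiguous; it
  does not phase interleaved or higher-order repeat structures.
- Telomere detection assumes the canonical motif set is known a priori.
- RNA2/RNA3 abundances are recoverable only up to their informative-read
  fractions; total-molecule abundances are not identifiable from 3'-tag
  data alone and are not reported.
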