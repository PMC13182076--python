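"""RNA-evidence tests: split mapping, junctions, poly(A), species, coverage."""

import numpy as np
import pytest

from rdnascan.pipeline import run_rna
from rdnascan.rna import (
    TagMapper,
    call_junctions,
    call_polya,
    classify_species,
    coverage_tracks,
    map_tag_reads,
)
from rdnascan.synth import (
    Read,
    ReadSet,
    build_transcript_models,
    simulate_tag_reads,
)


@pytest.fixture(scope="module")
def mapper(chrom_truth):
    chrom, truth = chrom_truth
    return TagMapper(chrom, truth)


class TestSplitMapping:
    def test_exonic_read_single_block(self, chrom_truth, mapper):
        chrom, truth = chrom_truth
        e1 = truth.get("SSU_exon1")
        a = mapper.map_read("r", chrom[e1.start + 100: e1.start + 200])
        assert a is not None and not a.is_spliced
        assert a.blocks == [((0, 100), (e1.start + 100, e1.start + 200))]

    def test_ligated_s956_junction_two_blocks(self, chrom_truth, mapper):
        chrom, truth = chrom_truth
        models = build_transcript_models(truth, chrom)
        rna1 = models["RNA1"].seq
        # 50 bases on each side of the exon1|exon2 ligation (position 956)
        a = mapper.map_read("r", rna1[906:1006])
        assert a is not None and a.is_spliced
        s956 = truth.get("S956-1")
        assert a.gaps() == [(s956.start, s956.end)]

    def test_rna3_reads_split_with_gap_51(self, chrom_truth, mapper):
        # oracle: simulator truth says which reads span the I51 locus
        chrom, truth = chrom_truth
        rs = simulate_tag_reads(
            truth, chrom, species_abundances={"RNA3": 1.0}, n_reads=125,
            seed=12, stages=("amoeba",),
        )
        i51 = truth.get("I51")
        models = build_transcript_models(truth, chrom)
        spanning = mapped_spanning = 0
        for r in rs:
            blocks = models["RNA3"].genomic_blocks(r.meta["tstart"], r.meta["tend"])
            spans = len(blocks) == 2 and min(
                blocks[0][1] - blocks[0][0], blocks[1][1] - blocks[1][0]
            ) >= 8
            a = mapper.map_read(r.id, r.seq)
            if spans:
                spanning += 1
                assert a is not None and a.is_spliced
                assert a.gaps() == [(i51.start, i51.end)]
                mapped_spanning += 1
            elif a is not None and a.is_spliced:
                assert a.gaps() == [(i51.start, i51.end)]
        assert spanning > 0 and mapped_spanning == spanning

    def test_min_anchor_validation(self, chrom_truth):
        chrom, truth = chrom_truth
        with pytest.raises(ValueError):
            TagMapper(chrom, truth, min_anchor=3)


class TestJunctions:
    def test_no_spliced_alignments_empty(self, chrom_truth, mapper):
        chrom, truth = chrom_truth
        e1 = truth.get("SSU_exon1")
        a = mapper.map_read("r", chrom[e1.start: e1.start + 100])
        assert call_junctions([a], truth) == []

    def test_default_run_exactly_four_perfect_junctions(self, full_run):
        perfect = [j for j in full_run.rna.junctions if j.perfect_ligation]
        assert len(perfect) == 4
        gaps = sorted(j.gap_length for j in perfect)
        assert gaps == [51, 850, 900, 1436]
        # false-junction rate 0 on error-free reads
        assert all(j.perfect_ligation for j in full_run.rna.junctions)

    def test_support_matches_truth_count_oracle(self, chrom_truth, mapper):
        # simulator truth: count emitted reads spanning the S956 ligation
        # with >= 8 nt anchors on both sides
        chrom, truth = chrom_truth
        rs = simulate_tag_reads(
            truth, chrom, species_abundances={"RNA1": 1.0}, n_reads=500,
            seed=13, stages=("amoeba",),
        )
        models = build_transcript_models(truth, chrom)
        expected = 0
        for r in rs:
            blocks = models["RNA1"].genomic_blocks(r.meta["tstart"], r.meta["tend"])
            if len(blocks) == 2 and min(
                b[1] - b[0] for b in blocks
            ) >= 8:
                expected += 1
        alns = map_tag_reads(rs, chrom, truth, mapper=mapper)
        calls = call_junctions(alns, truth)
        s956 = truth.get("S956-1")
        sup = [c.support for c in calls if (c.donor, c.acceptor) == (s956.start, s956.end)]
        assert sup == [expected]

    def test_junction_recall_with_2pct_errors(self, chrom_truth, mapper):
        # junctions with >= 10 error-free spanning reads at 2% substitution
        # error must be recovered in >= 95% of seeds
        chrom, truth = chrom_truth
        s956 = truth.get("S956-1")
        models = build_transcript_models(truth, chrom)
        eligible = found = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rs = simulate_tag_reads(
                truth, chrom, species_abundances={"RNA1": 1.0}, n_reads=250,
                seed=200 + seed, stages=("amoeba",), error_rate=0.02,
            )
            spanning = sum(
                1
                for r in rs
                if len(
                    models["RNA1"].genomic_blocks(r.meta["tstart"], r.meta["tend"])
                ) == 2
            )
            if spanning < 10:
                continue
            eligible += 1
            alns = map_tag_reads(rs, chrom, truth, mapper=mapper)
            calls = call_junctions(alns, truth)
            if any(
                (c.donor, c.acceptor) == (s956.start, s956.end)
                and c.perfect_ligation
                for c in calls
            ):
                found += 1
        assert eligible >= 10
        assert found / eligible >= 0.95


class TestPolyA:
    def test_default_run_exactly_one_site_at_heg_end(self, full_run):
        assert len(full_run.rna.polya) == 1
        heg = full_run.truth.get("HEG")
        assert abs(full_run.rna.polya[0].position - heg.end) <= 2

    def test_templated_a_runs_do_not_call(self, mapper, chrom_truth):
        chrom, truth = chrom_truth
        # a read whose 3' A-run is genomic (templated) must not produce a
        # poly(A) event: plant one inside an exon copy of the reference
        e1 = truth.get("SSU_exon1")
        frag = chrom[e1.start: e1.start + 80]
        m = TagMapper(chrom[: e1.start] + frag[:60] + "A" * 20 +
                      chrom[e1.start + 80:], None)
        a = m.map_read("r", frag[:60] + "A" * 20)
        assert a is not None
        assert a.meta["tail_a"] == 0
        assert call_polya([a], chrom) == []

    def test_support_matches_tail_truth_oracle(self, chrom_truth, mapper):
        chrom, truth = chrom_truth
        rs = simulate_tag_reads(
            truth, chrom, species_abundances={"RNA2": 1.0}, n_reads=300,
            seed=14, stages=("amoeba",),
        )
        models = build_transcript_models(truth, chrom)
        t = models["RNA2"]
        templated = t.length - t.tail
        expected = sum(
            1 for r in rs
            if r.meta["tend"] - templated >= 10
            and templated - r.meta["tstart"] >= 15
        )
        alns = map_tag_reads(rs, chrom, truth, mapper=mapper)
        calls = call_polya(alns, chrom)
        assert len(calls) == 1
        assert calls[0].support == expected


class TestSpecies:
    def test_rna3_present_in_all_four_stages(self, full_run):
        by_label = {s.label: s for s in full_run.rna.species}
        assert set(by_label["RNA3"].read_count) == {
            "amoeba", "microcyst", "flagellate", "plasmodium",
        }
        assert all(v > 0 for v in by_label["RNA3"].read_count.values())

    def test_zero_rna3_abundance_gives_no_rna3(self, chrom_truth):
        chrom, truth = chrom_truth
        rs = simulate_tag_reads(
            truth, chrom,
            species_abundances={"RNA1": 0.9, "RNA2": 0.1},
            n_reads=400, seed=15, stages=("amoeba",),
        )
        mapper = TagMapper(chrom, truth)
        alns = map_tag_reads(rs, chrom, truth, mapper=mapper)
        junctions = call_junctions(alns, truth)
        polya = call_polya(alns, chrom)
        species = classify_species(junctions, polya, alns, truth)
        assert "RNA3" not in {s.label for s in species}

    def test_counts_within_binomial_ci_of_expected_evidence(self, full_run):
        # oracle: from simulator truth, count reads whose placement carries
        # each species' defining evidence; observed counts must fall within
        # the 99% binomial envelope of those expectations (n = 20,000)
        chrom, truth = full_run.chrom, full_run.truth
        models = build_transcript_models(truth, chrom)
        i51 = truth.get("I51")
        expected = {"RNA3": 0, "RNA2": 0}
        for r in full_run.rna.reads:
            sp = r.meta["species"]
            t = models[sp]
            blocks = t.genomic_blocks(r.meta["tstart"], r.meta["tend"])
            if sp == "RNA3":
                if len(blocks) == 2 and min(b[1] - b[0] for b in blocks) >= 8:
                    expected["RNA3"] += 1
            elif sp == "RNA2":
                if any(s < i51.end and i51.start < e for s, e in blocks):
                    expected["RNA2"] += 1
        got = {s.label: s.total for s in full_run.rna.species}
        for label in ("RNA2", "RNA3"):
            n = expected[label]
            sd = np.sqrt(n) + 1
            assert abs(got[label] - n) <= 3 * sd

    def test_classification_stable_under_permutation(self, full_run):
        rng = np.random.default_rng(0)
        alns = list(full_run.rna.alignments)
        rng.shuffle(alns)
        species = classify_species(
            full_run.rna.junctions, full_run.rna.polya, alns, full_run.truth
        )
        orig = {s.label: s.read_count for s in full_run.rna.species}
        assert {s.label: s.read_count for s in species} == orig


class TestCoverage:
    def test_nts_coverage_identically_zero(self, full_run):
        cov = full_run.rna.tracks["pooled"].coverage
        ts, tt = 8050, 19350
        assert cov[:ts].max() == 0
        assert cov[tt:].max() == 0
        assert cov[ts:tt].max() > 0

    def test_single_read_track_sums_to_its_length(self, chrom_truth, mapper):
        chrom, truth = chrom_truth
        e1 = truth.get("SSU_exon1")
        a = mapper.map_read("r", chrom[e1.start: e1.start + 100])
        tracks = coverage_tracks({"amoeba": [a]}, len(chrom))
        assert tracks["amoeba"].coverage.sum() == 100

    def test_pooled_equals_sum_of_stages(self, full_run):
        tracks = full_run.rna.tracks
        stage_sum = sum(
            tracks[st].coverage
            for st in ("amoeba", "microcyst", "flagellate", "plasmodium")
        )
        assert np.array_equal(tracks["pooled"].coverage, stage_sum)

    def test_track_sum_equals_aligned_bases(self, full_run):
        for st, alns in full_run.rna.by_stage.items():
            total = sum(a.aligned_bases for a in alns)
            assert int(full_run.rna.tracks[st].coverage.sum()) == total

    def test_log10_display_monotone(self, full_run):
        t = full_run.rna.tracks["pooled"]
        order = np.argsort(t.coverage)
        assert np.all(np.diff(t.log10_display[order]) >= 0)


def test_stage_mix_reproducible(plan):
    a = run_rna(plan, 3, n_reads=300)
    b = run_rna(plan, 3, n_reads=300)
    assert [(j.donor, j.acceptor, j.support) for j in a.junctions] == [
        (j.donor, j.acceptor, j.support) for j in b.junctions
    ]
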