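import math
import random

import pytest

from _oracles import select_oracle
from ripper.io_genbank import GeneFeature, GenomicRegion
from ripper.orf_caller import CandidateOrf, CodingModel
from ripper.retrieval import (
    RipperConfig,
    apply_strand_reward,
    collect_annotated_short_genes,
    distance_from_te,
    filter_candidates,
    read_table,
    rescue_distant,
    select_peptides,
    tabulate,
)


def orf(start, length_aa=30, strand=1, score=0.0, annotated=False):
    end = start + 3 * (length_aa + 1)
    c = CandidateOrf(start, end, strand, "M" + "A" * (length_aa - 1),
                     annotated=annotated)
    c.total_score = score
    return c


RTE = GeneFeature("rte", 10000, 11200, 1)


def make_region(candidates=(), features=(), length=30000):
    feats = [RTE] + list(features)
    return GenomicRegion("ACC1", "Synthetica exemplaris", "A" * length,
                         feats, "rte")


class TestFilter:
    def test_overlap_boundary_20_vs_21(self):
        cfg = RipperConfig()
        gene = GeneFeature("g", 1000, 2000, 1)
        # candidate ending 20 nt into the gene: retained
        c20 = orf(1020 - 93)  # end = 1020, overlap 20
        c21 = orf(1021 - 93)  # end = 1021, overlap 21
        assert c20.end == 1020 and c21.end == 1021
        kept = filter_candidates([c20, c21], [gene], cfg)
        assert kept == [c20]

    def test_candidate_inside_annotated_gene_removed(self):
        cfg = RipperConfig()
        gene = GeneFeature("g", 1000, 3000, 1)
        assert filter_candidates([orf(1500)], [gene], cfg) == []

    def test_peptide_length_window(self):
        cfg = RipperConfig()
        assert filter_candidates([orf(0, length_aa=19)], [], cfg) == []
        assert len(filter_candidates([orf(0, length_aa=20)], [], cfg)) == 1
        assert len(filter_candidates([orf(0, length_aa=120)], [], cfg)) == 1
        assert filter_candidates([orf(0, length_aa=121)], [], cfg) == []

    def test_matches_pairwise_interval_oracle(self):
        rng = random.Random(9)
        cfg = RipperConfig()
        for _ in range(50):
            feats = [
                GeneFeature(f"g{i}", s := rng.randrange(0, 5000), s + rng.randrange(60, 900), 1)
                for i in range(rng.randrange(1, 6))
            ]
            cands = [orf(rng.randrange(0, 5000), rng.randrange(20, 121)) for _ in range(20)]
            got = filter_candidates(cands, feats, cfg)
            expect = [
                c for c in cands
                if all(
                    max(0, min(c.end, f.end) - max(c.start, f.start)) <= 20
                    for f in feats
                )
            ]
            assert got == expect


class TestStrandReward:
    def test_zero_reward_no_change(self):
        c = orf(0, score=10.0)
        apply_strand_reward([c], RTE, 0.0)
        assert c.total_score == 10.0

    def test_default_reward_same_strand_only(self):
        same, opp = orf(0, score=10.0, strand=1), orf(0, score=10.0, strand=-1)
        apply_strand_reward([same, opp], RTE, 5.0)
        assert same.total_score == 15.0
        assert opp.total_score == 10.0

    def test_double_application_is_noop(self):
        c = orf(0, score=10.0)
        apply_strand_reward([c], RTE, 5.0)
        apply_strand_reward([c], RTE, 5.0)
        assert c.total_score == 15.0
        assert "already applied" in c.notes


class TestDistance:
    def test_overlapping_is_zero(self):
        assert distance_from_te(GeneFeature("x", 10500, 10600, 1), RTE) == 0

    def test_gap_arithmetic(self):
        rte = GeneFeature("rte", 1100, 1400, 1)
        assert distance_from_te(GeneFeature("x", 900, 1000, 1), rte) == 100

    def test_abutting_half_open_is_zero(self):
        rte = GeneFeature("rte", 1000, 1400, 1)
        assert distance_from_te(GeneFeature("x", 700, 1000, 1), rte) == 0


class TestAnnotatedShortGenes:
    def _region_with(self, aa_len):
        nt = 3 * (aa_len + 1)
        gene = GeneFeature("short1", 500, 500 + nt, 1, translation="M" + "A" * (aa_len - 1))
        return make_region(features=[gene])

    def test_short_gene_collected(self):
        region = self._region_with(80)
        got = collect_annotated_short_genes(region, RipperConfig(), CodingModel())
        assert [c.feature_id for c in got] == ["short1"]
        assert got[0].annotated is True

    def test_130aa_gene_excluded(self):
        region = self._region_with(130)
        assert collect_annotated_short_genes(region, RipperConfig(), CodingModel()) == []

    def test_rte_itself_never_collected(self):
        region = make_region()
        region.features[0].translation = "M" + "A" * 79  # short RTE edge case
        assert collect_annotated_short_genes(region, RipperConfig(), CodingModel()) == []


class TestSelect:
    def _run(self, scores, limit, thresh, distance_step=100):
        cfg = RipperConfig(fasta_output_limit=limit, prodigal_score_thresh=thresh)
        cands = [
            orf(12000 + i * 1000, score=s) for i, s in enumerate(scores)
        ]
        region = make_region()
        rows = select_peptides(cands, region, cfg)
        return sorted((r.score for r in rows), reverse=True)

    def test_top3_only(self):
        assert self._run([20, 16, 10, 9, 3], 3, 15) == [20, 16, 10]

    def test_top3_plus_threshold(self):
        assert self._run([20, 18, 16, 15, 9], 3, 15) == [20, 18, 16, 15]

    def test_empty_window(self):
        cfg = RipperConfig()
        region = make_region()
        far = [orf(25000, score=50.0)]  # 13.8 kb away, outside ±8 kb
        assert select_peptides(far, region, cfg) == []

    def test_threshold_monotonicity(self):
        rng = random.Random(3)
        cands = [orf(11500 + i * 400, score=rng.choice(range(0, 25))) for i in range(30)]
        region = make_region()
        prev = None
        for thresh in (0, 5, 10, 15, 20, 1000):
            cfg = RipperConfig(prodigal_score_thresh=thresh)
            got = {r.key for r in select_peptides(cands, region, cfg)}
            if prev is not None:
                assert got <= prev
            prev = got

    def test_matches_bruteforce_specification(self):
        rng = random.Random(17)
        region = make_region()
        for _ in range(300):
            n = rng.randrange(0, 25)
            cands = []
            for _i in range(n):
                start = rng.randrange(0, 29000, 3)
                c = orf(start, length_aa=rng.randrange(20, 60),
                        strand=rng.choice((1, -1)),
                        score=float(rng.choice(range(0, 12))))
                cands.append(c)
                if rng.random() < 0.15:  # exact duplicate locus
                    cands.append(orf(start, length_aa=(c.end - c.start) // 3 - 1,
                                     strand=c.strand, score=c.total_score))
            limit = rng.choice((0, 1, 3, 5))
            thresh = rng.choice((2.0, 7.5, 15.0))
            cfg = RipperConfig(fasta_output_limit=limit, prodigal_score_thresh=thresh)
            got = [r.key[1:] for r in select_peptides(cands, region, cfg)]
            items = [
                {
                    "key": c.key,
                    "score": c.total_score,
                    "start": c.start,
                    "dist": (
                        c.start - RTE.end if c.start >= RTE.end
                        else (RTE.start - c.end if RTE.start >= c.end else 0)
                    ),
                }
                for c in cands
            ]
            expect = select_oracle(items, limit, thresh, cfg.max_dist_from_te)
            assert sorted(got) == sorted(expect)
            assert len(got) == len(expect)


class TestRescueAndTabulate:
    def test_no_hits_empty_distant(self):
        region = make_region()
        cands = [orf(25000, score=1.0)]
        assert rescue_distant(cands, [], {}, region) == []

    def test_distant_hit_rescued_and_buckets_disjoint(self):
        region = make_region()
        near = orf(12000, score=20.0)
        far = orf(25000, score=1.0)
        cfg = RipperConfig()
        retrieved = select_peptides([near, far], region, cfg)
        assert [r.start for r in retrieved] == [12000]
        hits = {near.key: ["domA"], far.key: ["domA"]}
        distant = rescue_distant([near, far], retrieved, hits, region)
        assert [r.start for r in distant] == [25000]
        assert distant[0].domains == ["domA"]
        assert distant[0].bucket == "distant"

    def test_tabulate_roundtrip_and_collation(self, tmp_path):
        region = make_region()
        cfg = RipperConfig()
        rows = []
        for shift in (0, 50):
            cands = [orf(12000 + shift + i * 600, score=10.0 + i) for i in range(3)]
            rows.extend(select_peptides(cands, region, cfg))
        path = tmp_path / "out.txt"
        tabulate(rows, path)
        text = path.read_text().splitlines()
        assert len(text) == 7  # header + 2 regions x 3 peptides
        back = read_table(path)
        assert [(r.start, r.end, r.strand) for r in back] == [
            (r.start, r.end, r.strand) for r in rows
        ]
        assert [r.peptide for r in back] == [r.peptide for r in rows]
        assert all(back[i].score == pytest.approx(rows[i].score, abs=1e-3) for i in range(6))

    def test_empty_inputs_header_only(self, tmp_path):
        path = tmp_path / "out.txt"
        tabulate([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("te_accession\tsource_accession")
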