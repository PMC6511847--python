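import math
import random

import pytest

from _oracles import (
    brute_orf_scan,
    count_inframe_hexamers,
    revcomp,
    translate_oracle,
)
from ripper.io_genbank import GeneFeature, GenomicRegion
from ripper.orf_caller import (
    CODING_SCALE,
    START_SCALE,
    CandidateOrf,
    CodingModel,
    InternalStopError,
    enumerate_orfs,
    score_candidate,
    train_coding_model,
    translate_cds,
)
from conftest import random_dna


class TestTranslate:
    def test_single_codon(self):
        assert translate_cds("ATGTAA") == "M"

    def test_alternative_start_renders_met(self):
        assert translate_cds("GTGGCTTAA") == "MA"
        assert translate_cds("TTGGCTTAA") == "MA"

    def test_internal_stop_names_offset(self):
        with pytest.raises(InternalStopError) as exc:
            translate_cds("ATGTAAGCTTAA")
        assert exc.value.offset == 3

    def test_reverse_strand(self):
        assert translate_cds(revcomp("ATGGCTTAA"), strand=-1) == "MA"

    def test_random_frames_match_codon_table_oracle(self):
        rng = random.Random(42)
        done = 0
        while done < 30:
            nt = random_dna(rng, 99)
            aa = translate_oracle(nt)
            if "*" in aa:
                continue
            assert translate_cds(nt) == aa
            done += 1


class TestEnumerate:
    def test_poly_a_has_no_candidates(self):
        region = GenomicRegion("R", "o", "A" * 500, [], "")
        assert enumerate_orfs(region) == []

    def test_minimum_length_boundary(self):
        rng = random.Random(5)
        # start + 19 codons + stop = 63 nt, peptide 20 aa
        body = "".join(rng.choice(("GCT", "GAA", "CTG", "AAA")) for _ in range(19))
        seq = "CC" + "ATG" + body + "TAA" + "CC"
        region = GenomicRegion("R", "o", seq, [], "")
        hits = [c for c in enumerate_orfs(region, min_nt=60) if c.strand == 1]
        assert len(hits) == 1
        c = hits[0]
        assert (c.start, c.end) == (2, 65)
        assert len(c.peptide) == 20
        # a 57 nt span (16 body codons) falls below the 60 nt floor
        seq2 = "CC" + "ATG" + body[:-9] + "TAA" + "CC"
        region2 = GenomicRegion("R", "o", seq2, [], "")
        assert [c for c in enumerate_orfs(region2, min_nt=60) if c.strand == 1] == []

    def test_matches_bruteforce_six_frame_scan(self):
        rng = random.Random(7)
        for _ in range(60):
            seq = random_dna(rng, 240, gc=rng.uniform(0.3, 0.7))
            region = GenomicRegion("R", "o", seq, [], "")
            got = {(c.start, c.end, c.strand) for c in enumerate_orfs(region)}
            assert got == brute_orf_scan(seq)

    def test_peptides_match_coordinates(self, fixture_region):
        region, _ = fixture_region
        for c in enumerate_orfs(region)[:50]:
            nt = region.sequence[c.start : c.end]
            assert translate_cds(nt, c.strand) == c.peptide


class TestTraining:
    def test_untrained_on_empty_region(self):
        region = GenomicRegion("R", "o", "ACGT" * 300, [], "")
        model = train_coding_model(region)
        assert model.trained is False
        assert model.hexamer_logodds == {}

    def test_hexamer_counts_match_bruteforce_counter(self, toy_region):
        model = train_coding_model(toy_region, min_training_nt=200)
        assert model.trained
        spans = []
        for f in toy_region.features:
            spans.append(toy_region.sequence[f.start : f.end])
        counts = count_inframe_hexamers(spans)
        total = sum(counts.values())
        # background counts, both strands, overlapping step 1
        bg = {}
        for s in (toy_region.sequence, revcomp(toy_region.sequence)):
            for i in range(len(s) - 5):
                bg[s[i : i + 6]] = bg.get(s[i : i + 6], 0) + 1
        bg_total = sum(bg.values())
        for h in ("GCTGAA", "AAAAAA", "CTGGCT"):
            expect = math.log(
                ((counts.get(h, 0) + 1) / (total + 4096))
                / ((bg.get(h, 0) + 1) / (bg_total + 4096))
            )
            assert model.hexamer_logodds[h] == pytest.approx(expect)

    def test_real_gene_beats_frameshuffled_counterpart(self, fixture_region):
        region, _ = fixture_region
        model = train_coding_model(region)
        # hold-out check: score each annotated gene body vs its codon-shuffled
        # counterpart under the trained hexamer table
        rng = random.Random(1)
        wins = 0
        genes = [f for f in region.features if f.length >= 300]
        for f in genes:
            body = region.sequence[f.start : f.end]
            if f.strand == -1:
                body = revcomp(body)
            codons = [body[i : i + 3] for i in range(0, len(body), 3)]
            inner = codons[1:-1]
            rng.shuffle(inner)
            shuffled = codons[0] + "".join(inner) + codons[-1]

            def hexmean(s):
                vals = [
                    model.hexamer_logodds.get(s[i : i + 6], 0.0)
                    for i in range(0, len(s) - 5, 3)
                ]
                return sum(vals) / len(vals)

            if hexmean(body) > hexmean(shuffled):
                wins += 1
        assert wins >= 0.8 * len(genes)

    def test_model_dump_load_roundtrip(self, toy_region, tmp_path):
        model = train_coding_model(toy_region, min_training_nt=200)
        path = tmp_path / "model.tsv"
        model.dump(path)
        back = CodingModel.load(path)
        assert back.trained == model.trained
        assert back.training_cds_count == model.training_cds_count
        assert back.rbs_weights == pytest.approx(model.rbs_weights)
        for h, v in model.hexamer_logodds.items():
            assert back.hexamer_logodds[h] == pytest.approx(v, abs=1e-7)


class TestScoring:
    def test_background_composition_scores_zero_coding(self):
        region = GenomicRegion("R", "o", "CC" + "ATG" + "GCA" * 20 + "TAA" + "CC", [], "")
        model = CodingModel(trained=True)  # all-absent keys -> log-odds 0
        orf = enumerate_orfs(region)[0]
        score_candidate(orf, model, region)
        assert orf.coding_score == 0.0

    def test_hand_filled_model_sums(self):
        # 9-codon ORF (8 aa + stop), hand-set hexamer table
        seq = "ATG" + "GCTGAAGCTGAAGCTGAA" + "TAA"
        region = GenomicRegion("R", "o", seq, [], "")
        model = CodingModel(trained=True)
        model.hexamer_logodds = {"ATGGCT": 1.0, "GCTGAA": 0.5, "GAAGCT": -0.25}
        model.start_weights = {"ATG": 0.4}
        orf = [
            c for c in enumerate_orfs(region, min_nt=24)
            if (c.start, c.end, c.strand) == (0, 24, 1)
        ][0]
        score_candidate(orf, model, region)
        # body hexamers (step 3): ATGGCT, GCTGAA, GAAGCT, GCTGAA, GAAGCT, GCTGAA
        mean = (1.0 + 0.5 - 0.25 + 0.5 - 0.25 + 0.5) / 6
        assert orf.coding_score == pytest.approx(CODING_SCALE * mean * 7)
        assert orf.start_bonus == pytest.approx(START_SCALE * 0.4)
        assert orf.rbs_score == 0.0
        assert orf.total_score == pytest.approx(
            orf.coding_score + orf.rbs_score + orf.start_bonus
        )

    def test_untrained_model_flags_notes(self, toy_region):
        model = CodingModel()
        orf = enumerate_orfs(toy_region)[0]
        score_candidate(orf, model, toy_region)
        assert "untrained" in orf.notes
        assert orf.coding_score == 0.0

    def test_scores_invariant_under_reverse_complement(self, fixture_region):
        region, _ = fixture_region
        model = train_coding_model(region)
        orfs = enumerate_orfs(region)
        rc_features = [
            GeneFeature(
                f.feature_id,
                len(region) - f.end,
                len(region) - f.start,
                -f.strand,
                product=f.product,
                translation=f.translation,
            )
            for f in region.features
        ]
        rc_region = GenomicRegion(
            region.accession, region.organism, revcomp(region.sequence),
            rc_features, region.rte_feature_id,
        )
        rc_model = train_coding_model(rc_region)
        rc_orfs = enumerate_orfs(rc_region)
        n = len(region)
        mirrored = {(n - c.end, n - c.start, -c.strand) for c in orfs}
        assert {(c.start, c.end, c.strand) for c in rc_orfs} == mirrored
        scored = {
            c.key: round(score_candidate(c, model, region).total_score, 9)
            for c in orfs[:80]
        }
        for c in rc_orfs:
            key = (n - c.end, n - c.start, -c.strand)
            if key in scored:
                score_candidate(c, rc_model, rc_region)
                assert round(c.total_score, 9) == scored[key]

    def test_planted_precursor_beats_intergenic_median(self):
        """On seeded fixtures the planted gene outscores the noise median."""
        import statistics
        from ripper.synthetic import make_synthetic_region, standard_region_spec
        wins = trials = 0
        for seed in range(25):
            region, truth = make_synthetic_region(standard_region_spec(seed))
            model = train_coding_model(region)
            orfs = enumerate_orfs(region)
            for c in orfs:
                score_candidate(c, model, region)
            truth_keys = {(t.start, t.end, t.strand) for t in truth}
            planted = [c for c in orfs if c.key in truth_keys]
            noise = [c.total_score for c in orfs if c.key not in truth_keys]
            trials += 1
            if planted and planted[0].total_score > statistics.median(noise):
                wins += 1
        assert wins >= 0.9 * trials
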