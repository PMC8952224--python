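import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_longest_orf
from cerna_switch.io_formats import ExpressionMatrix, TranscriptModel
from cerna_switch.lncrna_discovery import (
    CodingPotentialReport,
    FilterConfig,
    coding_report,
    consensus_coding,
    fickett_score,
    filter_candidates,
    longest_orf,
)


class TestLongestOrf:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("ATGTAA", 6),
            ("AAAAAAAAAA", 0),
            ("ATGAAATAG", 9),
            ("CATGAAATAGC", 9),  # frame 1
            ("ATGATGAAATGA", 12),  # nested start, outer ORF wins
            ("ATGAAAAAA", 0),  # start without stop is not an ORF
            ("auguaa", 6),  # RNA alphabet, case-insensitive
        ],
    )
    def test_known_cases(self, seq, expected):
        assert longest_orf(seq) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            longest_orf("")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 300))
        assert longest_orf(seq) == brute_longest_orf(seq)


class TestFickett:
    def test_homopolymer_hand_computed(self):
        # A*300: position value 100/101 -> lowest bin for every base;
        # content values 1,0,0,0 -> top bin for A, bottom for C/G/T.
        # Hand sum over the embedded tables = 0.3458.
        assert fickett_score("A" * 300) == pytest.approx(0.3458)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="200"):
            fickett_score("ACGT" * 40)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_score_bounded(self, seed):
        rng = np.random.default_rng(seed)
        gc = rng.uniform(0.2, 0.8)
        seq = "".join(
            rng.choice(list("ACGT"), 250, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        )
        assert 0.16 <= fickett_score(seq) <= 1.82

    def test_not_strand_symmetric(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 300))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        # no symmetry is assumed; scores generally differ
        assert fickett_score(seq) != pytest.approx(fickett_score(rc), abs=1e-12)


class TestConsensus:
    @pytest.mark.parametrize(
        "orf, fick, expected",
        [
            (0, 0.5, "noncoding"),
            (600, 0.5, "coding"),
            (150, 1.2, "coding"),
            (300, 0.94, "coding"),
            (299, 0.94, "noncoding"),
        ],
    )
    def test_vote_combinations(self, orf, fick, expected):
        rep = CodingPotentialReport(
            "t", orf, fick,
            "coding" if orf >= 300 else "noncoding",
            "coding" if fick >= 0.95 else "noncoding",
            "",
        )
        assert consensus_coding(rep) == expected


def _tx(tid, exons, biotype="lncRNA_candidate", chrom="chr1", strand="+", seq=None):
    return TranscriptModel(
        tid, tid, chrom, strand, exons[0][0], exons[-1][1], exons, biotype, seq
    )


@pytest.fixture
def toy_world():
    """12 candidates engineered to exercise each filter step, plus a
    reference with one protein-coding and one known lncRNA transcript."""
    rng = np.random.default_rng(10)
    noncod = lambda n: "".join(rng.choice(list("AC"), n))  # ORF-free, low fickett
    coding = "A" * 30 + "ATG" + "GCT" * 120 + "TAA" + "A" * 30
    ref_coding = _tx("ref_m", [(1000, 1400), (1600, 2000)], "protein_coding")
    ref_known = _tx("ref_k", [(9000, 9300), (9500, 9800)], "known_lncRNA")
    cands = [
        _tx("single", [(100, 700)], seq=noncod(601)),  # step 1
        _tx("short", [(100, 180), (300, 380)], seq=noncod(162)),  # step 2
        _tx("hits_ref", [(1000, 1400), (1600, 2000)], seq=noncod(802)),  # step 3
        _tx("lowfpkm", [(3000, 3200), (3400, 3600)], seq=noncod(402)),  # step 4
        _tx("codes", [(5000, 5200), (5400, 5625)], seq=coding),  # step 5
        _tx("clean1", [(7000, 7200), (7400, 7600)], seq=noncod(402)),
        _tx("clean2", [(11000, 11200), (11400, 11600)], seq=noncod(402)),
        _tx("matches_known", [(9000, 9300), (9500, 9800)], seq=noncod(602)),
        _tx("other_strand", [(1000, 1400), (1600, 2000)], strand="-", seq=noncod(802)),
        _tx("other_chrom", [(1000, 1400), (1600, 2000)], chrom="chr2", seq=noncod(802)),
        _tx("partial_ref", [(1300, 1400), (1600, 1700)], seq=noncod(202)),  # 100% overlap
        _tx("edge_ref", [(2000, 2200), (2500, 2700)], seq=noncod(402)),  # 1 bp overlap
    ]
    fpkm_vals = pd.DataFrame(
        {"s1": 5.0, "s2": 5.0},
        index=[t.transcript_id for t in cands],
    )
    fpkm_vals.loc["lowfpkm"] = 0.2
    fpkm = ExpressionMatrix(
        fpkm_vals,
        pd.Series({"s1": "control", "s2": "treated"}),
        pd.Series("lncRNA", index=fpkm_vals.index),
        unit="FPKM",
    )
    return cands, fpkm, [ref_coding, ref_known]


class TestFilterCandidates:
    def test_matches_independent_predicate_oracle(self, toy_world):
        cands, fpkm, ref = toy_world
        survivors, traces, _ = filter_candidates(cands, fpkm, ref)

        # oracle: apply the five predicates independently, first failure wins
        def oracle(t):
            if t.exon_count < 2:
                return 1
            if t.spliced_length <= 200 or t.exon_count < 2:
                return 2
            cover = 0
            r = ref[0]
            if (t.chromosome, t.strand) == (r.chromosome, r.strand):
                for (cs, ce) in t.exons:
                    for (rs, re_) in r.exons:
                        cover += max(0, min(ce, re_) - max(cs, rs) + 1)
            if cover / t.spliced_length > 0.5:
                return 3
            if float(fpkm.values.loc[t.transcript_id].max()) < 0.5:
                return 4
            from _oracles import brute_longest_orf

            if brute_longest_orf(t.sequence) >= 300 or fickett_score(t.sequence) >= 0.95:
                return 5
            return None

        expected = {t.transcript_id: oracle(t) for t in cands}
        got = {t.transcript_id: t.step_failed for t in traces}
        assert got == expected
        assert {t.transcript_id for t in survivors} == {
            k for k, v in expected.items() if v is None
        }

    def test_each_transcript_traced_once(self, toy_world):
        cands, fpkm, ref = toy_world
        _, traces, _ = filter_candidates(cands, fpkm, ref)
        ids = [t.transcript_id for t in traces]
        assert sorted(ids) == sorted(t.transcript_id for t in cands)

    def test_permutation_invariance(self, toy_world):
        cands, fpkm, ref = toy_world
        s1, t1, _ = filter_candidates(cands, fpkm, ref)
        s2, t2, _ = filter_candidates(list(reversed(cands)), fpkm, ref)
        assert {t.transcript_id for t in s1} == {t.transcript_id for t in s2}
        assert {(t.transcript_id, t.step_failed) for t in t1} == {
            (t.transcript_id, t.step_failed) for t in t2
        }

    def test_known_lncRNA_relabeled(self, toy_world):
        cands, fpkm, ref = toy_world
        survivors, _, _ = filter_candidates(cands, fpkm, ref)
        by_id = {t.transcript_id: t for t in survivors}
        assert by_id["matches_known"].biotype == "known_lncRNA"
        assert by_id["clean1"].biotype == "lncRNA_candidate"

    def test_missing_fpkm_rejected(self, toy_world):
        cands, fpkm, ref = toy_world
        bad = cands + [_tx("ghost", [(1, 100), (200, 300)], seq="AC" * 150)]
        with pytest.raises(ValueError, match="ghost"):
            filter_candidates(bad, fpkm, ref)

    def test_strict_exon_reading_available(self, toy_world):
        cands, fpkm, ref = toy_world
        survivors, traces, _ = filter_candidates(
            cands, fpkm, ref, FilterConfig(min_exons=3)
        )
        assert survivors == []  # every toy candidate has <= 2 exons


class TestSyntheticConsensusRecovery:
    def test_recovers_planted_coding_labels(self, default_study):
        labels = default_study.truth.coding_labels
        lnc_ids = [
            t.transcript_id
            for t in default_study.transcripts
            if t.biotype in ("lncRNA_candidate", "known_lncRNA")
            and t.spliced_length >= 200
        ]
        mrna_sample = [
            t.transcript_id for t in default_study.transcripts
            if t.biotype == "protein_coding"
        ][:100]
        correct = total = 0
        for tid in lnc_ids + mrna_sample:
            rep = coding_report(tid, default_study.sequences[tid])
            total += 1
            correct += rep.consensus == labels[tid]
        assert correct / total >= 0.95
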