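import numpy as np
import pytest

from conftest import random_seq
from oracles import min_cover_size, rc

from crisprhgt.analytics import (
    annotate_hits,
    call_sample,
    categorize_provenance,
    minimal_covering_set,
    normalized_spacer_mapping,
    pam_summary,
    window_coverage,
)
from crisprhgt.io import GffFeature
from crisprhgt.model import MatchHit, ReferenceSeq


def hit(sid, ref, start, end, strand="+"):
    return MatchHit(spacer_id=sid, ref_id=ref, start=start, end=end,
                    strand=strand, identity=100.0, coverage=100.0)


class TestNormalizedMapping:
    def test_arithmetic(self):
        hits = [hit(f"s{i}", "p", i * 40, i * 40 + 33) for i in range(50)]
        prof = normalized_spacer_mapping(hits, {"p": 5000}, total_exogenous=2000)
        assert prof[0].normalized_spacer_mapping == pytest.approx(5.0)
        assert prof[0].n_spacers == 50

    def test_zero_spacers_flagged_not_dropped(self):
        prof = normalized_spacer_mapping([], {"p": 5000}, total_exogenous=10)
        assert prof[0].normalized_spacer_mapping == 0.0 and prof[0].is_zero

    def test_scale_invariance(self):
        hits = [hit(f"s{i}", "p", 0, 33) for i in range(10)]
        a = normalized_spacer_mapping(hits, {"p": 4000}, 500)[0]
        doubled = hits + [hit(f"t{i}", "p", 0, 33) for i in range(10)]
        b = normalized_spacer_mapping(doubled, {"p": 4000}, 1000)[0]
        assert a.normalized_spacer_mapping == pytest.approx(b.normalized_spacer_mapping)

    def test_spacer_counted_once_per_ref(self):
        hits = [hit("s1", "p", 0, 33), hit("s1", "p", 100, 133)]
        assert normalized_spacer_mapping(hits, {"p": 1000}, 10)[0].n_spacers == 1

    def test_zero_total_error(self):
        with pytest.raises(ValueError):
            normalized_spacer_mapping([], {"p": 100}, 0)


class TestWindowCoverage:
    def test_single_hit_inside_window(self):
        cov = window_coverage([hit("s", "p", 10, 43)], ref_len=1000)
        assert cov[0][1] == pytest.approx(33 / 200)
        assert all(v == 0 for (_, v) in cov[1:])

    def test_boundary_spanning_hit_split(self):
        cov = window_coverage([hit("s", "p", 190, 223)], ref_len=400)
        assert cov[0][1] == pytest.approx(10 / 200)
        assert cov[1][1] == pytest.approx(23 / 200)

    def test_last_partial_window_own_length(self):
        cov = window_coverage([hit("s", "p", 400, 433)], ref_len=450)
        assert cov[-1][0] == (400, 450)
        assert cov[-1][1] == pytest.approx(33 / 50)

    def test_mass_conservation_random_hits(self, rng):
        ref_len = 10000
        hits = []
        for i in range(200):
            s = int(rng.integers(0, ref_len - 45))
            hits.append(hit(f"s{i}", "p", s, s + int(rng.integers(25, 46))))
        cov = window_coverage(hits, ref_len)
        mass = sum(v * (we - ws) for (ws, we), v in cov)
        assert mass == pytest.approx(sum(h.end - h.start for h in hits))


class TestCallSample:
    def test_positive(self):
        c = call_sample("s", 1000, percent_exogenous=0.10, n_unique_exogenous=12)
        assert c.is_hgt_positive

    def test_spacer_count_gate(self):
        c = call_sample("s", 1000, percent_exogenous=5.0, n_unique_exogenous=9)
        assert not c.is_hgt_positive

    def test_effective_threshold_fold_times_control(self):
        c = call_sample("s", 0, 0.0, 0, control_percent=0.03, fold=3)
        assert c.effective_threshold == pytest.approx(0.09, abs=1e-12)

    def test_monotone_in_both_inputs(self, rng):
        for _ in range(50):
            pct = float(rng.uniform(0, 0.3))
            n = int(rng.integers(0, 30))
            base = call_sample("s", 0, pct, n)
            assert call_sample("s", 0, pct + 0.05, n).is_hgt_positive >= base.is_hgt_positive
            assert call_sample("s", 0, pct, n + 5).is_hgt_positive >= base.is_hgt_positive

    def test_negative_control_rejected(self):
        with pytest.raises(ValueError):
            call_sample("s", 0, 0.0, 0, control_percent=-1.0)


class TestCoverSet:
    def make_hits(self, sets_by_ref):
        return [hit(s, ref, 0, 33) for ref, ss in sets_by_ref.items() for s in ss]

    def test_three_set_instance_optimal(self):
        sets = {"A": {"s1", "s2", "s3"}, "B": {"s3", "s4"}, "C": {"s4", "s5"}}
        cover = minimal_covering_set(self.make_hits(sets))
        assert len(cover.rows) == 2 == min_cover_size(sets)
        assert set(cover.ref_ids) == {"A", "C"}
        assert cover.rows[-1][2] == 5  # cumulative covers everything

    def test_single_ref_covers_all(self):
        sets = {"A": {"s1", "s2"}, "B": {"s1"}}
        cover = minimal_covering_set(self.make_hits(sets))
        assert cover.ref_ids == ["A"] and cover.rows[0][1] == 2

    def test_empty(self):
        cover = minimal_covering_set([])
        assert cover.rows == [] and cover.uncovered_spacers == 0

    def test_rows_sorted_by_assigned_desc(self):
        sets = {"A": {"s1"}, "B": {"s2", "s3", "s4"}}
        cover = minimal_covering_set(self.make_hits(sets))
        counts = [n for _, n, _ in cover.rows]
        assert counts == sorted(counts, reverse=True)

    def test_exact_mode_matches_bruteforce(self, rng):
        for _ in range(30):
            n_refs = int(rng.integers(2, 8))
            sets = {f"r{j}": {f"s{int(x)}" for x in rng.integers(0, 10, size=rng.integers(1, 6))}
                    for j in range(n_refs)}
            cover = minimal_covering_set(self.make_hits(sets), method="exact")
            assert len(cover.rows) == min_cover_size(sets)

    def test_longer_ref_wins_ties(self):
        sets = {"A": {"s1"}, "B": {"s1"}}
        cover = minimal_covering_set(self.make_hits(sets), ref_len_by_id={"A": 10, "B": 99})
        assert cover.ref_ids == ["B"]


class TestPamSummary:
    def test_plus_strand_aag(self):
        ref = ReferenceSeq("p", "T" * 97 + "AAG" + "C" * 40)
        pam = pam_summary([hit("s", "p", 100, 133)], [ref])
        assert pam.counts == {"AAG": 1} and pam.aag_fraction == 1.0

    def test_minus_strand_revcomp_context(self):
        # '-' hit: context is revcomp of ref[end:end+3]; plant CTT -> AAG
        ref = ReferenceSeq("p", "G" * 50 + "CTT" + "A" * 20)
        pam = pam_summary([hit("s", "p", 17, 50, strand="-")], [ref])
        assert pam.counts == {"AAG": 1}

    def test_near_end_skipped(self):
        ref = ReferenceSeq("p", "ACGT" * 20)
        pam = pam_summary([hit("s", "p", 1, 34)], [ref])
        assert pam.n_skipped == 1 and pam.n_extractable == 0

    def test_counts_sum(self, rng):
        seq = random_seq(rng, 2000)
        ref = ReferenceSeq("p", seq)
        hits = [hit(f"s{i}", "p", int(p), int(p) + 33)
                for i, p in enumerate(rng.integers(3, 1960, size=50))]
        pam = pam_summary(hits, [ref])
        assert sum(pam.counts.values()) == pam.n_extractable == 50


class TestAnnotateHits:
    FEATS = [GffFeature("p", 100, 400, "+", "CDS", "conjugation"),
             GffFeature("p", 400, 700, "+", "CDS", "replication")]

    def test_inside_orf(self):
        counts = dict(annotate_hits([hit("s", "p", 150, 183)], self.FEATS))
        assert counts == {"conjugation": 1}

    def test_intergenic(self):
        counts = dict(annotate_hits([hit("s", "p", 800, 833)], self.FEATS))
        assert counts == {"intergenic": 1}

    def test_spanning_two_orfs_counts_both(self):
        counts = dict(annotate_hits([hit("s", "p", 390, 423)], self.FEATS))
        assert counts == {"conjugation": 1, "replication": 1}

    def test_sorted_descending(self):
        hits = [hit(f"s{i}", "p", 150, 183) for i in range(3)] + \
               [hit("t", "p", 500, 533)]
        table = annotate_hits(hits, self.FEATS)
        assert table[0] == ("conjugation", 3)


class TestProvenance:
    def test_categories(self):
        meta = [hit("s1", "m1", 0, 33), hit("s2", "m1", 0, 33)]
        plas = [hit("s2", "p1", 0, 33), hit("s3", "p1", 0, 33)]
        cats, table = categorize_provenance(meta, plas, ["s1", "s2", "s3", "s4"])
        assert cats == {"s1": "metagenome_only", "s2": "both",
                        "s3": "plasmid_only", "s4": "unmatched"}
        assert sum(table.values()) == pytest.approx(100.0)

    def test_empty(self):
        cats, table = categorize_provenance([], [], [])
        assert cats == {} and all(v == 0.0 for v in table.values())

    def test_plasmid_only_constructed_fixture(self, rng):
        # a plasmid absent from the synthetic metagenome: its spacers are
        # plasmid_only when both dbs are queried at the same threshold
        from crisprhgt.classify import records_from_sequences
        from crisprhgt.matching import match_to_database
        plasmid = ReferenceSeq("plasmidX", random_seq(rng, 3000))
        metagenome = [ReferenceSeq("contig1", random_seq(rng, 8000))]
        spacers = records_from_sequences(
            [plasmid.seq[i:i + 33] for i in range(0, 330, 33)])
        meta_hits = match_to_database(spacers, metagenome)
        plas_hits = match_to_database(spacers, [plasmid])
        cats, table = categorize_provenance(meta_hits, plas_hits,
                                            [r.spacer_id for r in spacers])
        assert set(cats.values()) == {"plasmid_only"}
        assert table["plasmid_only"] == pytest.approx(100.0)
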