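import numpy as np
import pytest
from sklearn.base import clone

from cypminer.align import identity_between
from cypminer.classify import (
    FAMILY,
    NEW_FAMILY,
    SUBFAMILY,
    NearestHomologClassifier,
    ReferenceDB,
    allocate_placeholders,
    assign,
    classify_proteome,
)
from cypminer.io import CypName, ProteinRecord, parse_cyp_name
from cypminer.simulate import mutate_to_identity, random_p450_like


def _q(seq, pid="q1", sp="sp1"):
    return ProteinRecord(pid, sp, seq)


class TestAssign:
    def test_identical_query_is_subfamily_level(self, small_refdb, scheme):
        refdb, _ = small_refdb
        name, seq = refdb.entries[0]
        a = assign(_q(seq), refdb, scheme)
        assert a.best_identity == 100.0
        assert a.level == SUBFAMILY
        assert a.best_ref == name
        assert a.subfamily_label == name.subfamily_label

    def test_midrange_identity_is_family_level(self, small_refdb, scheme, rng):
        refdb, _ = small_refdb
        name, seq = refdb.entries[0]
        mutant = mutate_to_identity(seq, 48, rng, scheme)
        a = assign(_q(mutant), refdb, scheme)
        assert 46 <= a.best_identity <= 50
        assert a.level == FAMILY
        assert a.family_label == name.family_label
        assert a.subfamily_label is None  # placeholder pending

    def test_distant_query_founds_new_family(self, small_refdb, scheme, rng):
        refdb, _ = small_refdb
        for _ in range(10):
            seq, _anchors = random_p450_like(rng, 420)
            if all(identity_between(seq, s, scheme) < 35 for _, s in refdb.entries):
                break
        a = assign(_q(seq), refdb, scheme)
        assert a.level == NEW_FAMILY
        assert a.family_label is None and a.subfamily_label is None

    def test_identity_ties_break_to_smallest_name(self, scheme, rng):
        seq, _ = random_p450_like(rng, 420)
        refdb = ReferenceDB([(CypName(9102, "A", 1), seq), (CypName(9101, "A", 1), seq)])
        a = assign(_q(seq), refdb, scheme)
        assert str(a.best_ref) == "CYP9101A1"

    def test_empty_reference_db_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ReferenceDB([])


class TestPlaceholders:
    def test_single_novel_query_gets_first_label(self, small_refdb, scheme, rng):
        refdb, _ = small_refdb
        seq, _anchors = random_p450_like(rng, 420)
        out = classify_proteome([_q(seq)], refdb, scheme)
        assert out[0].family_label == "NEWF001"
        assert out[0].subfamily_label == "NEWF001-newSF1"

    def test_mutually_close_novel_queries_share_family(self, small_refdb, scheme, rng):
        refdb, _ = small_refdb
        s1, _ = random_p450_like(rng, 420)
        s2 = mutate_to_identity(s1, 80, rng, scheme)
        out = classify_proteome([_q(s1, "qa"), _q(s2, "qb")], refdb, scheme)
        assert [a.level for a in out] == [NEW_FAMILY, NEW_FAMILY]
        assert out[0].family_label == out[1].family_label == "NEWF001"
        # 80% mutual identity also exceeds the subfamily threshold
        assert out[0].subfamily_label == out[1].subfamily_label

    def test_mutually_distant_novel_queries_get_distinct_families(
        self, small_refdb, scheme, rng
    ):
        refdb, _ = small_refdb
        s1, _ = random_p450_like(rng, 420)
        s2, _ = random_p450_like(rng, 420)
        assert identity_between(s1, s2, scheme) < 40
        out = classify_proteome([_q(s1, "qa"), _q(s2, "qb")], refdb, scheme)
        assert {a.family_label for a in out} == {"NEWF001", "NEWF002"}

    def test_family_level_queries_get_per_family_subfamily_placeholders(
        self, small_refdb, scheme, rng
    ):
        refdb, _ = small_refdb
        name, seq = refdb.entries[0]
        m1 = mutate_to_identity(seq, 48, rng, scheme)
        m2 = mutate_to_identity(seq, 48, rng, scheme)
        out = classify_proteome([_q(m1, "qa"), _q(m2, "qb")], refdb, scheme)
        labels = {a.subfamily_label for a in out}
        if identity_between(m1, m2, scheme) > 55:
            assert labels == {f"{name.family_label}-newSF1"}
        else:
            assert labels == {
                f"{name.family_label}-newSF1",
                f"{name.family_label}-newSF2",
            }

    def test_unsorted_assignments_rejected(self, small_refdb, scheme, rng):
        refdb, _ = small_refdb
        s1, _ = random_p450_like(rng, 420)
        s2, _ = random_p450_like(rng, 420)
        a = [assign(_q(s1, "b"), refdb, scheme), assign(_q(s2, "a"), refdb, scheme)]
        with pytest.raises(ValueError, match="sorted"):
            allocate_placeholders(a, {"a": s2, "b": s1}, scheme)


class TestClassifyProteome:
    def test_empty_input_gives_empty_output(self, small_refdb, scheme):
        refdb, _ = small_refdb
        assert classify_proteome([], refdb, scheme) == []

    def test_output_sorted_and_deterministic(self, small_refdb, scheme, rng):
        refdb, _ = small_refdb
        queries = [
            _q(refdb.entries[i % len(refdb.entries)][1], f"q{9 - i}") for i in range(4)
        ]
        out1 = classify_proteome(queries, refdb, scheme)
        out2 = classify_proteome(list(reversed(queries)), refdb, scheme)
        assert out1 == out2
        assert [a.protein_id for a in out1] == sorted(a.protein_id for a in out1)

    def test_level_monotone_in_identity(self, small_refdb, scheme, rng):
        """Raising planted identity never demotes the assignment level."""
        refdb, _ = small_refdb
        _, seq = refdb.entries[0]
        rank = {NEW_FAMILY: 0, FAMILY: 1, SUBFAMILY: 2}
        levels = []
        for target in (25, 48, 75, 100):
            mutant = mutate_to_identity(seq, target, rng, scheme)
            levels.append(rank[assign(_q(mutant), refdb, scheme).level])
        assert levels == sorted(levels)


class TestEstimator:
    def test_fit_predict_from_name_sequence_pairs(self, small_refdb):
        refdb, _ = small_refdb
        pairs = [(str(n), s) for n, s in refdb.entries]
        clf = NearestHomologClassifier().fit(pairs)
        assert clf.n_references_ == len(refdb)
        out = clf.predict([_q(refdb.entries[0][1])])
        assert out[0].level == SUBFAMILY

    def test_unfitted_predict_raises(self):
        with pytest.raises(ValueError, match="fit"):
            NearestHomologClassifier().predict([])

    def test_clone_round_trips_params(self):
        clf = NearestHomologClassifier(gap_open=12.0, subfamily_threshold=60.0)
        params = clone(clf).get_params()
        assert params["gap_open"] == 12.0
        assert params["subfamily_threshold"] == 60.0

    def test_reference_db_requires_complete_triage(self):
        with pytest.raises(ValueError, match="COMPLETE"):
            ReferenceDB([(parse_cyp_name("CYP9001A1"), "MKVLLDW" * 30)])
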