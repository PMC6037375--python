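"""chapter association: table building, exact test vs enumeration, profiles."""

import itertools

import numpy as np
import pytest
import scipy.stats

from agedense import (
    ClusterAssignment,
    ContingencyTable,
    associate_all,
    build_table,
    cluster_patient_profile,
    fisher_exact,
)
from agedense.association import benjamini_hochberg
from agedense.records import DataError

from conftest import fisher_oracle, make_cohort


class TestBuildTable:
    def test_all_in_one_cell(self):
        asg = ClusterAssignment({"J06": 1, "J10": 1}, k=1)
        t = build_table(asg, {"J06": "X", "J10": "X"}, 1, "X")
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 0)

    def test_manual_cross_tabulation(self):
        labels = {f"C{i}": (1 if i < 5 else 2) for i in range(10)}
        chap = {f"C{i}": ("X" if i in (0, 1, 2, 7) else "IX") for i in range(10)}
        t = build_table(ClusterAssignment(labels, 2), chap, 1, "X")
        assert (t.a, t.b, t.c, t.d) == (3, 2, 1, 4)
        assert t.total == 10

    def test_unmapped_codes_excluded(self):
        asg = ClusterAssignment({"J06": 1, "D49": 2}, k=2)
        t = build_table(asg, {"J06": "X", "D49": None}, 1, "X")
        assert t.total == 1

    def test_unknown_labels(self):
        asg = ClusterAssignment({"J06": 1}, k=1)
        with pytest.raises(DataError):
            build_table(asg, {"J06": "X"}, 99, "X")
        with pytest.raises(DataError):
            build_table(asg, {"J06": "X"}, 1, "XV")


class TestFisherExact:
    def test_degenerate_margins_give_one(self):
        for t in (ContingencyTable(0, 0, 3, 4), ContingencyTable(0, 5, 0, 4),
                  ContingencyTable(0, 0, 0, 0)):
            assert fisher_exact(t, "greater") == 1.0
            assert fisher_exact(t, "two-sided") == 1.0

    def test_hand_enumerated_example(self):
        # margins 4/4 out of 8; P(A>=3) = (16+1)/70
        p = fisher_exact(ContingencyTable(3, 1, 1, 3), "greater")
        assert p == pytest.approx(17 / 70, abs=1e-12)

    @pytest.mark.parametrize("alternative", ["greater", "two-sided"])
    def test_matches_scipy(self, alternative):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, 4)
            ours = fisher_exact(ContingencyTable(int(a), int(b), int(c), int(d)), alternative)
            theirs = scipy.stats.fisher_exact(
                [[a, b], [c, d]],
                alternative="greater" if alternative == "greater" else "two-sided",
            ).pvalue
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)

    def test_matches_rational_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 8, 4))
            for alt in ("greater", "two-sided"):
                want = float(fisher_oracle(a, b, c, d, alt))
                got = fisher_exact(ContingencyTable(a, b, c, d), alt)
                assert got == pytest.approx(want, abs=1e-12)

    def test_greater_monotone_in_a(self):
        """With margins fixed, shifting mass into cell a shrinks the
        one-sided p-value."""
        prev = 1.1
        for a in range(0, 6):
            t = ContingencyTable(a, 5 - a, 5 - a, 10 + a)
            p = fisher_exact(t, "greater")
            assert p <= prev + 1e-12
            prev = p

    def test_two_sided_symmetric_under_row_and_column_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
            p1 = fisher_exact(ContingencyTable(a, b, c, d), "two-sided")
            p2 = fisher_exact(ContingencyTable(d, c, b, a), "two-sided")
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_large_margins_stable(self):
        t = ContingencyTable(1200, 98800, 800, 899200)
        p = fisher_exact(t, "greater")
        assert 0.0 <= p < 1e-6  # strong enrichment at million-scale margins


class TestAssociateAll:
    def test_planted_enrichment_recovered(self, default_cohort):
        """Clusters recover their archetypes' designated chapters with
        score > 0.99, and no foreign chapter reaches that score for the
        single-chapter archetypes."""
        from agedense import (chapter_of, compute_all_densities, cut_tree,
                              ward_linkage)

        cohort, truth = default_cohort
        dens = compute_all_densities(cohort, min_patients=100)
        codes = [d.code for d in dens]
        asg = cut_tree(ward_linkage(np.array([d.p for d in dens])), 6, codes=codes)
        chap = {c: chapter_of(c) for c in codes}
        results = {(r.cluster, r.chapter): r.score
                   for r in associate_all(asg, chap, "greater")}
        # majority archetype per cluster
        from collections import Counter

        arch_of = {}
        for cl in range(1, 7):
            members = [truth.code_archetype[c] for c in asg.members(cl)]
            arch_of[cl] = Counter(members).most_common(1)[0][0]
        designated = {"A": {"X", "VIII"}, "B": {"I"}, "C": {"XV"},
                      "D": {"VII", "XI"}, "E": {"XIII"}, "F": {"IX", "XIV"}}
        for cl, arch in arch_of.items():
            for ch in designated[arch]:
                assert results[(cl, ch)] > 0.99, (cl, arch, ch)
            for ch in {c for s in designated.values() for c in s} - designated[arch]:
                assert results[(cl, ch)] < 0.99, (cl, arch, ch)

    def test_single_cluster_all_degenerate(self):
        labels = {f"J{i:02d}": 1 for i in range(5)}
        res = associate_all(ClusterAssignment(labels, 1), {c: "X" for c in labels})
        assert all(r.p_value == 1.0 and r.score == 0.0 for r in res)

    def test_sorted_by_cluster_then_chapter(self):
        labels = {"J06": 2, "M54": 1, "A09": 1}
        res = associate_all(
            ClusterAssignment(labels, 2), {"J06": "X", "M54": "XIII", "A09": "I"}
        )
        keys = [(r.cluster, r.chapter) for r in res]
        assert keys == sorted(keys)

    def test_score_complements_p(self):
        labels = {"J06": 1, "J10": 1, "M54": 2, "M25": 2}
        res = associate_all(
            ClusterAssignment(labels, 2),
            {"J06": "X", "J10": "X", "M54": "XIII", "M25": "XIII"},
        )
        for r in res:
            assert r.score == pytest.approx(1.0 - r.p_value, abs=1e-12)

    def test_benjamini_hochberg_monotone(self):
        labels = {f"C{i:02d}".replace("C", "J"): 1 + i % 3 for i in range(12)}
        res = associate_all(
            ClusterAssignment(labels, 3),
            {c: ("X" if i % 2 else "IX") for i, c in enumerate(labels)},
        )
        q = benjamini_hochberg(res)
        assert all(qq >= r.p_value - 1e-12 for qq, r in zip(q, res))
        assert all(0 <= qq <= 1 for qq in q)


class TestPatientProfile:
    def test_single_patient_cluster(self):
        c = make_cohort([("p1", 25, "female", "O82")])
        asg = ClusterAssignment({"O82": 1}, 1)
        sex, hist = cluster_patient_profile(c, asg, 1)
        assert sex["female"] == 1.0
        assert hist[25] == 1 and hist.sum() == 1

    def test_patient_in_two_clusters_counted_twice(self):
        c = make_cohort([("p1", 40, "male", "J06"), ("p1", 40, "male", "M54")])
        asg = ClusterAssignment({"J06": 1, "M54": 2}, 2)
        for cl in (1, 2):
            _, hist = cluster_patient_profile(c, asg, cl)
            assert hist[40] == 1

    def test_unknown_cluster(self, tiny_cohort):
        with pytest.raises(DataError):
            cluster_patient_profile(tiny_cohort, ClusterAssignment({"J06": 1}, 1), 9)

    def test_reproductive_cluster_female_share(self, default_cohort):
        """The planted reproductive-age archetype's female share is
        recovered near its 0.95 sex bias."""
        cohort, truth = default_cohort
        c_codes = {c for c, a in truth.code_archetype.items() if a == "C"}
        asg = ClusterAssignment(
            {c: (1 if c in c_codes else 2) for c in truth.code_archetype}, 2
        )
        sex, _ = cluster_patient_profile(cohort, asg, 1)
        assert abs(sex["female"] - 0.95) < 0.03
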