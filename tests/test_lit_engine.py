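"""LIT congruence: baseline choice, stability, PI flags, specimen
selection and morphological reconciliation."""

import numpy as np
import pytest

from fairylit import (
    DistanceMatrix,
    MorphoLabel,
    Partition,
    SpecimenRecord,
    assess_pi,
    choose_baseline,
    reconcile,
    report,
    select_specimens,
    stability_flags,
)


def dm_from(ids, d):
    return DistanceMatrix(tuple(ids), np.asarray(d, dtype=float))


def make_partition(label, *clusters, method="manual", score=None):
    return Partition(
        method, label,
        {f"C{i+1}": frozenset(c) for i, c in enumerate(clusters)},
        score=score,
    )


class TestChooseBaseline:
    def test_fewest_clusters_wins(self):
        p42 = make_partition("p42", *[{f"s{i}"} for i in range(3)], {"x", "y"})
        p83 = make_partition("p83", *[{f"s{i}"} for i in range(3)], {"x"}, {"y"})
        assert choose_baseline([p83, p42]).label == "p42"

    def test_single_candidate(self):
        p = make_partition("only", {"a"})
        assert choose_baseline([p]) is p

    def test_tie_broken_by_score(self):
        a = make_partition("a", {"x"}, {"y"}, score=2.0)
        b = make_partition("b", {"x"}, {"y"}, score=1.5)
        assert choose_baseline([a, b]).label == "b"


class TestStability:
    def test_identical_partitions_all_stable(self):
        base = make_partition("b", {"a", "b"}, {"c"})
        assert stability_flags(base, [base]) == {"C1": True, "C2": True}

    def test_split_cluster_unstable(self):
        base = make_partition("b", {"a", "b"}, {"c"})
        other = make_partition("o", {"a"}, {"b"}, {"c"})
        flags = {
            frozenset(base.clusters[cid]): v
            for cid, v in stability_flags(base, [other]).items()
        }
        assert flags[frozenset({"a", "b"})] is False
        assert flags[frozenset({"c"})] is True

    def test_universe_mismatch_rejected(self):
        base = make_partition("b", {"a"})
        other = make_partition("o", {"a"}, {"b"})
        with pytest.raises(ValueError, match="different specimen set"):
            stability_flags(base, [other])


class TestAssessPI:
    @pytest.fixture
    def setup(self):
        # cluster X: two specimens 2% apart (distance-flag), cluster Y tight
        ids = ("x1", "x2", "y1", "y2")
        d = np.array(
            [
                [0.00, 0.020, 0.09, 0.09],
                [0.020, 0.00, 0.09, 0.09],
                [0.09, 0.09, 0.00, 0.005],
                [0.09, 0.09, 0.005, 0.00],
            ]
        )
        base = make_partition("b", {"x1", "x2"}, {"y1", "y2"})
        return dm_from(ids, d), base

    def test_distance_only_flag(self, setup):
        dm, base = setup
        out = {a.cluster_id: a for a in assess_pi(base, [base], dm)}
        x = out["C1"]
        assert x.pi and x.pi_reason == "distance_only"
        assert x.stable and x.max_intra_p == 2.0
        y = out["C2"]
        assert not y.pi and y.pi_reason == "none"

    def test_both_flag_and_reason_partition(self, setup):
        dm, base = setup
        other = make_partition("o", {"x1"}, {"x2"}, {"y1", "y2"})
        out = assess_pi(base, [other], dm)
        reasons = {a.cluster_id: a.pi_reason for a in out}
        assert reasons == {"C1": "both", "C2": "none"}
        # the four reasons partition the clusters
        for a in out:
            assert a.pi == (a.pi_reason != "none")
            assert (not a.stable) == (a.pi_reason in ("unstable_only", "both"))

    def test_all_identical_cluster_not_flagged(self):
        dm = dm_from("ab", np.zeros((2, 2)))
        base = make_partition("b", {"a", "b"})
        (a,) = assess_pi(base, [base], dm)
        assert not a.pi and a.max_intra_p == 0.0


class TestSelectSpecimens:
    def _community(self):
        """10 specimens over 4 haplotypes with frequencies {4, 3, 2, 1}."""
        hap_of = {}
        specimens = []
        sexes = {}
        layout = [("h1", 4), ("h2", 3), ("h3", 2), ("h4", 1)]
        sid = 0
        for hap, count in layout:
            for k in range(count):
                sid += 1
                name = f"s{sid:02d}"
                hap_of[name] = hap
                sex = "female" if k % 2 == 0 else "male"
                sexes[name] = sex
                specimens.append(SpecimenRecord(name, sex=sex))
        ids = sorted(hap_of)
        # distances by haplotype: h1..h4 on a line, h1-h4 most divergent
        coord = {"h1": 0.0, "h2": 0.01, "h3": 0.02, "h4": 0.05}
        n = len(ids)
        d = np.zeros((n, n))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                d[i, j] = abs(coord[hap_of[a]] - coord[hap_of[b]])
        return frozenset(ids), dm_from(ids, d), hap_of, specimens

    def test_pi_cluster_covers_divergent_and_dominant(self):
        cluster, dm, hap_of, specimens = self._community()
        plan = select_specimens(cluster, dm, hap_of, pi=True, specimens=specimens)
        chosen_haps = {hap_of[s] for s in plan.chosen_specimens}
        # divergent pair = {h1, h4}; dominant (>20%) = h1 (40%) and h2 (30%)
        assert chosen_haps == {"h1", "h2", "h4"}
        roles = set(plan.roles.values())
        assert "divergent_haplotype" in roles and "dominant_haplotype" in roles

    def test_non_pi_cluster_two_haplotypes_only(self):
        cluster, dm, hap_of, specimens = self._community()
        plan = select_specimens(cluster, dm, hap_of, pi=False, specimens=specimens)
        assert {hap_of[s] for s in plan.chosen_specimens} == {"h1", "h4"}

    def test_pi_never_fewer_than_non_pi(self):
        cluster, dm, hap_of, specimens = self._community()
        non_pi = select_specimens(cluster, dm, hap_of, pi=False, specimens=specimens)
        pi = select_specimens(cluster, dm, hap_of, pi=True, specimens=specimens)
        assert len(pi.chosen_specimens) >= len(non_pi.chosen_specimens)

    def test_singleton_cluster(self):
        dm = dm_from(["solo"], [[0.0]])
        plan = select_specimens(
            frozenset({"solo"}), dm, {"solo": "h1"}, pi=False,
            specimens=[SpecimenRecord("solo", sex="male")],
        )
        assert plan.chosen_specimens == ("solo",)
        assert plan.roles["solo"] == "divergent_haplotype"
        assert plan.males_only

    def test_females_preferred_two_each(self):
        cluster, dm, hap_of, specimens = self._community()
        plan = select_specimens(cluster, dm, hap_of, pi=False, specimens=specimens)
        by_spec = {s.specimen_id: s.sex for s in specimens}
        # h1 has 2 females -> both female; h4's only specimen is female
        h1_chosen = [s for s in plan.chosen_specimens if hap_of[s] == "h1"]
        assert len(h1_chosen) == 2
        assert all(by_spec[s] == "female" for s in h1_chosen)

    def test_male_only_haplotype_gets_female_supplement(self):
        ids = ["m1", "m2", "f1", "f2"]
        hap_of = {"m1": "hA", "m2": "hA", "f1": "hB", "f2": "hB"}
        specimens = [
            SpecimenRecord("m1", sex="male"),
            SpecimenRecord("m2", sex="male"),
            SpecimenRecord("f1", sex="female"),
            SpecimenRecord("f2", sex="female"),
        ]
        d = np.array(
            [
                [0.00, 0.00, 0.02, 0.02],
                [0.00, 0.00, 0.02, 0.02],
                [0.02, 0.02, 0.00, 0.00],
                [0.02, 0.02, 0.00, 0.00],
            ]
        )
        plan = select_specimens(
            frozenset(ids), dm_from(ids, d), hap_of, pi=False, specimens=specimens
        )
        assert "female_supplement" in plan.roles.values() or any(
            hap_of[s] == "hB" for s in plan.chosen_specimens
        )
        assert not plan.males_only


class TestReconcile:
    @pytest.fixture
    def split_case(self):
        """Baseline lumps two morphospecies; a finer candidate separates them."""
        ids = list("ABCDEF")
        d = np.full((6, 6), 0.06)
        for grp in (range(3), range(3, 6)):
            grp = list(grp)
            for i in grp:
                for j in grp:
                    d[i, j] = 0.005 if i != j else 0.0
        dm = dm_from(ids, d)
        baseline = make_partition("base", set(ids))
        finer = make_partition("fine", {"A", "B", "C"}, {"D", "E", "F"})
        morpho = [
            MorphoLabel("A", "X"),
            MorphoLabel("B", "X"),
            MorphoLabel("D", "Y"),
        ]
        return dm, baseline, finer, morpho

    def test_homogeneous_clusters_congruent(self):
        dm = dm_from("ab", np.zeros((2, 2)))
        base = make_partition("base", {"a"}, {"b"})
        morpho = [MorphoLabel("a", "X"), MorphoLabel("b", "Y")]
        delim = reconcile([base], base, morpho, dm)
        assert set(delim.status.values()) == {"congruent"}
        assert sorted(delim.species_label.values()) == ["X", "Y"]

    def test_conflict_resolved_by_finer_candidate(self, split_case):
        dm, baseline, finer, morpho = split_case
        delim = reconcile([baseline, finer], baseline, morpho, dm)
        assert set(delim.status.values()) == {"split"}
        assert set(delim.clusters.values()) == {
            frozenset({"A", "B", "C"}),
            frozenset({"D", "E", "F"}),
        }
        labels = {min(m): delim.species_label[c] for c, m in delim.clusters.items()}
        assert labels == {"A": "X", "D": "Y"}  # unvalidated inherit

    def test_unresolvable_conflict_stays_whole(self, split_case):
        dm, baseline, _, morpho = split_case
        # no finer candidate separates the labels
        delim = reconcile([baseline], baseline, morpho, dm)
        assert list(delim.status.values()) == ["unresolved"]
        assert list(delim.species_label.values()) == [""]
        assert set(delim.clusters.values()) == set(baseline.clusters.values())

    def test_lump_merges_shared_confirmed_label(self):
        dm = dm_from("abcd", np.full((4, 4), 0.08) - 0.08 * np.eye(4))
        base = make_partition("base", {"a", "b"}, {"c", "d"})
        morpho = [MorphoLabel("a", "Same sp."), MorphoLabel("c", "Same sp.")]
        delim = reconcile([base], base, morpho, dm)
        assert delim.n_clusters == 1
        assert list(delim.status.values()) == ["lumped"]
        assert set(delim.clusters.values()) == {frozenset("abcd")}

    def test_near_labels_are_distinct_no_lump(self):
        dm = dm_from("abcd", np.full((4, 4), 0.08) - 0.08 * np.eye(4))
        base = make_partition("base", {"a", "b"}, {"c", "d"})
        morpho = [
            MorphoLabel("a", "Same sp.", "confirmed"),
            MorphoLabel("c", "Same sp.", "near"),
        ]
        delim = reconcile([base], base, morpho, dm)
        assert delim.n_clusters == 2

    def test_unknown_specimen_label_rejected(self):
        dm = dm_from("ab", np.zeros((2, 2)))
        base = make_partition("base", {"a", "b"})
        with pytest.raises(KeyError):
            reconcile([base], base, [MorphoLabel("zz", "X")], dm)

    def test_split_never_crosses_baseline_boundary(self, gap_community, gap_community_dm):
        """Every final cluster is inside one baseline cluster (or an
        explicit lump of same-label clusters)."""
        from fairylit import analyse, morpho_oracle

        aln, specimens, truth = gap_community
        res = analyse(aln, specimens, morpho_oracle(truth, 0.0, 3))
        base_sets = list(res.baseline.clusters.values())
        for cid, members in res.delimitation.clusters.items():
            if res.delimitation.status[cid] == "lumped":
                continue
            assert sum(members <= b for b in base_sets) == 1


class TestReport:
    def test_singleton_row(self):
        dm = dm_from("ab", np.array([[0.0, 0.07], [0.07, 0.0]]))
        base = make_partition("base", {"a"}, {"b"})
        morpho = [MorphoLabel("a", "X"), MorphoLabel("b", "Y")]
        delim = reconcile([base], base, morpho, dm)
        table = report(delim, dm)
        assert list(table["n"]) == [1, 1]
        assert list(table["mean_p_dist"]) == [0.0, 0.0]
        assert list(table["max_p_dist"]) == [0.0, 0.0]

    def test_values_match_brute_force(self, split_case=None):
        ids = list("ABC")
        d = np.array(
            [[0.0, 0.01, 0.02], [0.01, 0.0, 0.03], [0.02, 0.03, 0.0]]
        )
        dm = dm_from(ids, d)
        base = make_partition("base", set(ids))
        delim = reconcile([base], base, [MorphoLabel("A", "X")], dm)
        row = report(delim, dm).iloc[0]
        assert row["n"] == 3
        assert row["mean_p_dist"] == pytest.approx(100 * (0.01 + 0.02 + 0.03) / 3)
        assert row["max_p_dist"] == pytest.approx(3.0)
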