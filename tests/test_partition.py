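import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gfsrisk import agglomerate, build_partition, cluster_distance, partition_all
from gfsrisk.data import Dataset, FeatureSchema, PatientCase, RiskLabel
from gfsrisk.partition import Cluster, DegeneratePartitionError, FuzzyPartition

from conftest import brute_force_agglomerate


class TestClusterDistance:
    @pytest.mark.parametrize(
        "c1,c2,expected",
        [
            ([74], [81], 7.0),
            ([71, 74], [76, 81], 6.0),  # (5+10+2+7)/4 by hand enumeration
            ([74, 74], [74], 0.0),
        ],
    )
    def test_average_pairwise_distance(self, c1, c2, expected):
        assert cluster_distance(Cluster(c1), Cluster(c2)) == pytest.approx(expected)

    def test_symmetric(self):
        a, b = Cluster([1.0, 2.0]), Cluster([5.0])
        assert cluster_distance(a, b) == cluster_distance(b, a)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            Cluster([])


class TestAgglomerate:
    def test_separated_values_stay_apart(self):
        clusters = agglomerate([1, 2, 100], epsilon=5)
        assert [sorted(c.members) for c in clusters] == [[1, 2], [100]]

    def test_single_value(self):
        (c,) = agglomerate([7], epsilon=100)
        assert c.members == [7.0]

    def test_epsilon_zero_keeps_distinct_values_apart(self):
        clusters = agglomerate([1, 2, 3], epsilon=0)
        assert len(clusters) == 3

    def test_epsilon_zero_merges_duplicates(self):
        clusters = agglomerate([74, 74, 80], epsilon=0)
        assert [sorted(c.members) for c in clusters] == [[74, 74], [80]]

    def test_table1_ages(self):
        # duplicate 74s merge first, then {74,74}+{76}; all other gaps > 3
        clusters = agglomerate([67, 71, 74, 74, 76, 81], epsilon=3)
        assert [sorted(c.members) for c in clusters] == [
            [67], [71], [74, 74, 76], [81]]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            agglomerate([], epsilon=1)

    def test_matches_brute_force_oracle_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(1, 13))
            values = np.round(rng.uniform(0, 50, size=n), 1)
            eps = float(rng.uniform(0, 15))
            fast = [
                sorted(c.members) for c in agglomerate(values, eps)
            ]
            assert fast == brute_force_agglomerate(values, eps)

    def test_merge_distances_monotone_nondecreasing(self):
        # average linkage on 1-D data admits no inversions
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = sorted(rng.uniform(0, 100, size=10))
            blocks = [[v] for v in values]
            dists = []
            while len(blocks) > 1:
                cents = [float(np.mean(b)) for b in blocks]
                gaps = [b - a for a, b in zip(cents, cents[1:])]
                i = int(np.argmin(gaps))
                dists.append(gaps[i])
                blocks[i: i + 2] = [blocks[i] + blocks[i + 1]]
            assert all(a <= b + 1e-12 for a, b in zip(dists, dists[1:]))


class TestBuildPartition:
    def test_teaching_age_partition_has_four_sets(self):
        p = FuzzyPartition("age", 30, [56, 74], 87,
                           ["young", "middle-aged", "old", "very old"])
        assert p.n_sets == 4
        assert p.knots == [30, 56, 74, 87]

    def test_two_distinct_values_give_two_semi_trapezoids(self):
        p = build_partition("x", [1.0, 2.0], epsilon=0)
        assert p.midpoints == [] and p.n_sets == 2

    def test_table1_ages_default_epsilon(self):
        p = build_partition("age", [67, 71, 74, 74, 76, 81])
        assert p.v0 == 67 and p.vmax == 81
        # clusters {67} {71} {74,74,76} {81}; bound centroids dropped
        assert p.midpoints == pytest.approx([71.0, 74 + 2 / 3])

    def test_constant_feature_raises_degenerate(self):
        with pytest.raises(DegeneratePartitionError):
            build_partition("x", [5.0, 5.0, 5.0])

    def test_set_count_capped(self):
        rng = np.random.default_rng(0)
        p = build_partition("x", rng.uniform(0, 1, 200), epsilon=0.0)
        assert p.n_sets <= 5


class TestMembership:
    @pytest.fixture
    def teaching_age(self):
        return FuzzyPartition("age", 30, [56, 74], 87,
                              ["young", "middle-aged", "old", "very old"])

    @pytest.mark.parametrize(
        "j,x,expected",
        [
            (2, 74, 1.0),    # triangle apex
            (1, 65, 0.5),    # (74-65)/(74-56)
            (0, 25, 1.0),    # below the domain minimum
            (0, 56, 0.0),
            (3, 90, 1.0),    # above the domain maximum
            (3, 74, 0.0),
        ],
    )
    def test_reference_values(self, teaching_age, j, x, expected):
        assert teaching_age.membership(j, x) == pytest.approx(expected)

    def test_index_out_of_range(self, teaching_age):
        with pytest.raises(IndexError):
            teaching_age.membership(4, 50)

    def test_interior_sets_peak_at_their_midpoint(self, teaching_age):
        for j, mid in enumerate(teaching_age.midpoints, start=1):
            assert teaching_age.membership(j, mid) == 1.0

    @given(
        mids=st.lists(st.integers(1, 98), min_size=0, max_size=3, unique=True),
        xs=st.lists(st.floats(-10, 110), min_size=1, max_size=20),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_partition_of_unity_property(self, mids, xs):
        p = FuzzyPartition("f", 0, sorted(mids), 100)
        for x in xs:
            total = sum(p.membership(j, x) for j in range(p.n_sets))
            if 0 <= x <= 100:
                assert total == pytest.approx(1.0, abs=1e-9)
            assert all(0 <= p.membership(j, x) <= 1 for j in range(p.n_sets))

    def test_missing_values_have_zero_membership(self, teaching_age):
        mat = teaching_age.membership_matrix([np.nan, 60.0])
        assert mat[0].sum() == 0.0
        assert mat[1].sum() == pytest.approx(1.0)


class TestPartitionAll:
    def test_one_partition_per_numerical_feature(self):
        from gfsrisk import GeneratorConfig, generate

        d = generate(GeneratorConfig(n_cases=60, seed=5))
        parts = partition_all(d)
        assert len(parts) == 9
        assert set(parts) == {f.name for f in d.schema if f.is_numerical}

    def test_no_numerical_features_gives_empty_mapping(self):
        d = Dataset(
            [FeatureSchema("sex", "categorical", ["male", "female"])],
            [PatientCase("p", {"sex": "male"}, RiskLabel.LOW)],
        )
        assert partition_all(d) == {}

    def test_deterministic(self, table1):
        p1 = partition_all(table1)
        p2 = partition_all(table1)
        assert {k: v.to_dict() for k, v in p1.items()} == {
            k: v.to_dict() for k, v in p2.items()
        }

    def test_serialization_roundtrip(self, table1, tmp_path):
        from gfsrisk.partition import load_partitions, save_partitions

        parts = partition_all(table1)
        path = tmp_path / "p.json"
        save_partitions(parts, path)
        again = load_partitions(path)
        assert {k: v.to_dict() for k, v in parts.items()} == {
            k: v.to_dict() for k, v in again.items()
        }
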