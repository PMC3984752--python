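import numpy as np
import pytest

from gfsrisk import (
    Dataset,
    FeatureSchema,
    GAConfig,
    PatientCase,
    RiskLabel,
    partition_all,
    table1_fixture,
)
from gfsrisk.partition import Cluster, cluster_distance
from gfsrisk.rules import RuleSpace
from gfsrisk.simulate import toy_age_partition


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_partitions(table1):
    return partition_all(table1)


@pytest.fixture(scope="session")
def toy_partitions():
    """The teaching age partition: [30, 87] with midpoints 56 and 74."""
    return {"age": toy_age_partition()}


@pytest.fixture(scope="session")
def toy_space(table1, toy_partitions):
    return RuleSpace(table1.schema, toy_partitions)


@pytest.fixture
def two_feature_dataset():
    """Two binary categorical features, four labelled cases."""
    schema = [
        FeatureSchema("a", "categorical", ["yes", "no"]),
        FeatureSchema("b", "categorical", ["yes", "no"]),
    ]
    cases = [
        PatientCase("c1", {"a": "yes", "b": "yes"}, RiskLabel.HIGH),
        PatientCase("c2", {"a": "yes", "b": "no"}, RiskLabel.HIGH),
        PatientCase("c3", {"a": "no", "b": "yes"}, RiskLabel.LOW),
        PatientCase("c4", {"a": "no", "b": "no"}, RiskLabel.MEDIUM),
    ]
    return Dataset(schema, cases)


def brute_force_agglomerate(values, epsilon):
    """Exhaustive average-linkage trace: all pair distances recomputed at
    every step, ties broken by (distance, left centroid, list order)."""
    clusters = [Cluster([v]) for v in sorted(float(v) for v in values)]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = cluster_distance(clusters[i], clusters[j])
                key = (dist, clusters[i].centroid, i, j)
                if best is None or key < best:
                    best = key
        dist, _, i, j = best
        if dist > epsilon:
            break
        clusters[i] = Cluster(clusters[i].members + clusters[j].members)
        del clusters[j]
    return sorted(
        (sorted(c.members) for c in clusters),
        key=lambda ms: float(np.mean(ms)),
    )
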