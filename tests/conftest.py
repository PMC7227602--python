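import numpy as np
import pytest

from tcmpattern import (
    BinaryFeatureMatrix, ClusterModel, KnowledgeBase, demo_thesaurus,
    generate_knowledge_base,
)


@pytest.fixture(scope="session")
def thesaurus():
    return demo_thesaurus()


@pytest.fixture(scope="session")
def demo_kb() -> KnowledgeBase:
    return generate_knowledge_base()


@pytest.fixture
def toy_kb() -> KnowledgeBase:
    """Three codes with overlapping terms; small enough to score by hand."""
    return KnowledgeBase(
        {
            "alpha": {"a": 2, "b": 1, "c": 1},
            "beta": {"b": 3, "d": 1},
            "gamma": {"c": 1, "d": 1, "e": 2},
        }
    )


def make_matrix(freqs_by_cluster: dict[int, dict[tuple[str, str], float]],
                n_per_cluster: int = 200):
    """Deterministic binary matrix with exact within-cluster frequencies.

    ``freqs_by_cluster[c][(term, category)]`` is the fraction of cluster c's
    cases with the feature present; the first round(f*n) cases carry it, so
    frequencies are exact (up to the 1/n grid) and nothing is sampled.
    Returns (matrix, model) where the model just holds the fixed assignments.
    """
    clusters = sorted(freqs_by_cluster)
    variables = sorted({v for f in freqs_by_cluster.values() for v in f},
                       key=lambda v: (v[1], v[0]))
    case_ids, rows, assignments = [], [], {}
    for c in clusters:
        for i in range(n_per_cluster):
            cid = f"c{c}-{i:04d}"
            case_ids.append(cid)
            assignments[cid] = c
            row = [
                1 if i < round(freqs_by_cluster[c].get(v, 0.0) * n_per_cluster)
                else 0
                for v in variables
            ]
            rows.append(row)
    matrix = BinaryFeatureMatrix(
        case_ids=case_ids, variables=variables, values=np.array(rows)
    )
    model = ClusterModel(
        k=len(clusters), assignments=assignments,
        centroids=np.empty((0, len(variables))), total_wss=0.0,
    )
    return matrix, model
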