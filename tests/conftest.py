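import numpy as np
import pytest

from spongescore import BipartiteNetwork, ExpressionMatrix, TargetClass


@pytest.fixture
def toy_net():
    """Network [(A,G1),(A,G2),(A,G3),(B,G3)]: G1,G2 single-line to A."""
    return BipartiteNetwork.from_edges(
        [("A", "G1"), ("A", "G2"), ("A", "G3"), ("B", "G3")], TargetClass.MRNA
    )


@pytest.fixture
def two_group_expr():
    """4 features x 6 samples, 3 per group; f2 is strongly down in case."""
    rng = np.random.default_rng(7)
    values = rng.normal(8.0, 0.3, (4, 6))
    values[1, 3:] -= 3.0  # f2 down in case
    samples = ("r1", "r2", "r3", "c1", "c2", "c3")
    return ExpressionMatrix(
        feature_ids=("f1", "f2", "f3", "f4"),
        sample_ids=samples,
        values=values,
        labels={s: ("ref" if s.startswith("r") else "case") for s in samples},
        reference="ref",
        case="case",
    )


def random_bipartite(rng, n_mirnas=8, n_targets=12, p=0.25,
                     target_class=TargetClass.MRNA):
    mirnas = [f"m{i}" for i in range(n_mirnas)]
    targets = [f"t{j}" for j in range(n_targets)]
    edges = [
        (m, t) for m in mirnas for t in targets if rng.random() < p
    ]
    return BipartiteNetwork.from_edges(edges, target_class)
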