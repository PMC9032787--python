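import random

import pytest

from gcmed import (
    CellValue,
    GraphCode,
    MultimediaFeatureGraph,
    PRESENCE,
)

# relationship-type codes available to random generators
REL_CODES = (2, 3, 4, 5)


@pytest.fixture
def table2_graph() -> MultimediaFeatureGraph:
    """The face-landmark example with distances as discrete edge payloads."""
    g = MultimediaFeatureGraph(asset_id="faces")
    for n in ("Face 1", "Face 2", "Eye Distance"):
        g.add_node(n)
    g.add_edge("Face 1", "Eye Distance", value=27.21)
    g.add_edge("Face 2", "Eye Distance", value=18.14)
    return g


@pytest.fixture
def table1_code() -> GraphCode:
    """The face-landmark example with distance values stored as vocabulary
    terms (the printed 5x5 matrix, reproduced verbatim)."""
    terms = ["Face 1", "Face 2", "Eye Distance", "27.21", "18.14"]
    gc = GraphCode(dictionary=terms, asset_id="faces-verbose")
    for t in terms:
        gc.set_cell(t, t, PRESENCE)
    for r, c in [
        ("Face 2", "Eye Distance"),
        ("Eye Distance", "Face 1"),
        ("Eye Distance", "Face 2"),
        ("27.21", "Face 1"),
        ("27.21", "Eye Distance"),
        ("18.14", "Face 2"),
        ("18.14", "Eye Distance"),
    ]:
        gc.set_cell(r, c, CellValue.rel(3))
    return gc


def random_mmfg(seed: int, n_nodes: int = 8, density: float = 0.3) -> MultimediaFeatureGraph:
    """Seeded random feature graph mixing typed and discrete edges."""
    rng = random.Random(seed)
    g = MultimediaFeatureGraph(asset_id=f"rand-{seed}")
    labels = [f"term {k}" for k in range(n_nodes)]
    for lbl in labels:
        g.add_node(lbl)
    for s in labels:
        for t in labels:
            if s != t and rng.random() < density:
                if rng.random() < 0.3:
                    g.add_edge(s, t, value=round(rng.uniform(0, 100), 2))
                else:
                    g.add_edge(s, t, rel_type=rng.choice(REL_CODES))
    return g


def random_code(seed: int, n_terms: int = 6, density: float = 0.3) -> GraphCode:
    """Seeded random non-query Graph Code with presence diagonal."""
    from gcmed.graph_code import encode

    return encode(random_mmfg(seed, n_nodes=n_terms, density=density))
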