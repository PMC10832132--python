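import numpy as np
import pytest

from protofun.io_formats import AnnotationTable
from protofun.ontology import from_edges

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng, length):
    return "".join(rng.choice(list(ALPHABET), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_ontology():
    """Hand-checkable DAG: one namespace chain + diamond, two small others.

    biological_process:                 molecular_function:   cellular_component:
        root B:1 (level 1)                 root M:1              root C:1
        B:2, B:3 children of B:1           M:2 -> M:1            C:2 -> C:1
        B:4 child of B:2 AND B:3 (diamond) M:3 -> M:2
        B:5 child of B:4 (level 4)
        B:6 child of B:5 (level 5)
    """
    ns = {
        "B:1": "biological_process", "B:2": "biological_process",
        "B:3": "biological_process", "B:4": "biological_process",
        "B:5": "biological_process", "B:6": "biological_process",
        "M:1": "molecular_function", "M:2": "molecular_function",
        "M:3": "molecular_function",
        "C:1": "cellular_component", "C:2": "cellular_component",
    }
    edges = [
        ("B:2", "B:1"), ("B:3", "B:1"), ("B:4", "B:2"), ("B:4", "B:3"),
        ("B:5", "B:4"), ("B:6", "B:5"),
        ("M:2", "M:1"), ("M:3", "M:2"),
        ("C:2", "C:1"),
    ]
    return from_edges(ns, edges)


@pytest.fixture
def toy_annotations():
    """Unpropagated pairs over the toy ontology."""
    return AnnotationTable(pairs={
        ("p1", "B:6"), ("p2", "B:4"), ("p3", "B:2"),
        ("p1", "M:3"), ("p2", "M:2"), ("p3", "C:2"),
    })
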