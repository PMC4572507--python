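import pytest

from phenominer.corpus import synthetic_ontology
from phenominer.ontology import Ontology, OntologyTerm


@pytest.fixture(scope="session")
def chain_ontology() -> Ontology:
    """root <- A <- B."""
    return Ontology(
        [
            OntologyTerm("T:R", "root"),
            OntologyTerm("T:A", "alpha", parents=("T:R",)),
            OntologyTerm("T:B", "beta", parents=("T:A",)),
        ]
    )


@pytest.fixture(scope="session")
def diamond_ontology() -> Ontology:
    """root <- {A, B} <- C."""
    return Ontology(
        [
            OntologyTerm("T:R", "root"),
            OntologyTerm("T:A", "alpha", parents=("T:R",)),
            OntologyTerm("T:B", "beta", parents=("T:R",)),
            OntologyTerm("T:C", "gamma", parents=("T:A", "T:B")),
        ]
    )


@pytest.fixture(scope="session")
def head_skeleton_ontology() -> Ontology:
    """A small hand-built lexicon for recognizer and similarity tests.

    root <- phenotypic abnormality <- {head category, skeleton category};
    head: macrocephaly (syn "large head"), headache;
    skeleton: finger anomaly (syn "finger"), short finger (child),
    cranial hyperostosis <- calvarial hyperostosis.
    """
    return Ontology(
        [
            OntologyTerm("HS:0", "all"),
            OntologyTerm("HS:1", "phenotypic abnormality", parents=("HS:0",)),
            OntologyTerm("HS:H", "abnormality of the head", parents=("HS:1",)),
            OntologyTerm("HS:S", "abnormality of the skeleton", parents=("HS:1",)),
            OntologyTerm(
                "HS:MAC", "macrocephaly", synonyms=("large head",), parents=("HS:H",)
            ),
            OntologyTerm("HS:HEA", "headache", parents=("HS:H",)),
            OntologyTerm("HS:FIN", "finger anomaly", synonyms=("finger",), parents=("HS:S",)),
            OntologyTerm("HS:SHF", "short finger", parents=("HS:FIN",)),
            OntologyTerm("HS:CRH", "cranial hyperostosis", parents=("HS:S",)),
            OntologyTerm("HS:CAH", "calvarial hyperostosis", parents=("HS:CRH",)),
        ]
    )


@pytest.fixture(scope="session")
def toy_ontology() -> Ontology:
    """A mid-size random DAG shared by property tests."""
    return synthetic_ontology(n_top_level=4, terms_per_group=10, seed=11)
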