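import warnings

import pytest
from hypothesis import settings

from modq import (
    FixtureSpec,
    GeneSet,
    Namespace,
    generate_fixture_set,
)
from modq.kegg_io import ModuleRecord
from modq.grammar import parse_definition

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


def make_module(module_id, definition, name="test module",
                class_levels=("Pathway modules", "Energy metabolism")):
    return ModuleRecord(
        module_id=module_id,
        name=name,
        class_levels=list(class_levels),
        definition_text=definition,
        ast=parse_definition(definition),
    )


@pytest.fixture
def simple_module():
    return make_module("MFX001", "K00001 K00002,K00003 (K00004+K00005)")


@pytest.fixture
def module_db():
    """Five handcrafted modules spanning the grammar, two in the Energy
    class and three elsewhere."""
    return [
        make_module("MFX001", "K00001 K00002,K00003 (K00004+K00005)",
                    name="Methane fixture pathway",
                    class_levels=["Pathway modules", "Energy metabolism"]),
        make_module("MFX002", "K00010 K00011",
                    name="Sugar fixture pathway",
                    class_levels=["Pathway modules", "Carbohydrate metabolism"]),
        make_module("MFX003", "K00020+K00021-K00022",
                    name="Complex fixture",
                    class_levels=["Pathway modules", "Energy metabolism"]),
        make_module("MFX004", "K00030 -- K00031",
                    name="Gapped fixture",
                    class_levels=["Signature modules", "Metabolic capacity"]),
        make_module("MFX005", "(K00040 K00041),K00042",
                    name="Nested fixture",
                    class_levels=["Pathway modules", "Amino acid metabolism"]),
    ]


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """A full synthetic database (modules, genomes, ground truth, mapping)
    written to disk once per session."""
    outdir = tmp_path_factory.mktemp("fixture_db")
    spec = FixtureSpec(seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        modules, genomes, truth, mapping = generate_fixture_set(spec, outdir)
    return {
        "dir": outdir,
        "spec": spec,
        "modules": modules,
        "genomes": genomes,
        "truth": truth,
        "mapping": mapping,
    }


def gene_set(*identifiers, namespace=Namespace.ORTHOLOG):
    return GeneSet.from_identifiers(identifiers, namespace)


@pytest.fixture
def empty_genes():
    return GeneSet(Namespace.ORTHOLOG, frozenset())
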