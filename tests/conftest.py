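import pytest

from phenologs import (
    AssociationTable,
    Orthogroup,
    OrthologyMap,
    SynthConfig,
    build_matrix_set,
    generate,
)


@pytest.fixture
def toy_orthology() -> OrthologyMap:
    """Three orthogroups between human and mouse: one 1:1, one with a
    three-way human expansion, one with a mouse expansion."""
    pair = ("human", "mouse")
    return OrthologyMap(
        [
            Orthogroup("OG1", pair, {"human": frozenset({"hA"}),
                                     "mouse": frozenset({"mA"})}),
            Orthogroup("OG2", pair, {"human": frozenset({"hB", "hB2", "hB3"}),
                                     "mouse": frozenset({"mB"})}),
            Orthogroup("OG3", pair, {"human": frozenset({"hC"}),
                                     "mouse": frozenset({"mC", "mC2"})}),
        ]
    )


@pytest.fixture
def toy_tables() -> dict[str, AssociationTable]:
    human = AssociationTable.from_records(
        [
            ("human", "H:P1", "human phenotype 1", "hA"),
            ("human", "H:P1", "human phenotype 1", "hB"),
            ("human", "H:P1", "human phenotype 1", "hC"),
            ("human", "H:P2", "human phenotype 2", "hA"),
            ("human", "H:P2", "human phenotype 2", "hB2"),
            ("human", "H:P2", "human phenotype 2", "hC"),
        ]
    )
    mouse = AssociationTable.from_records(
        [
            ("mouse", "M:P1", "mouse phenotype 1", "mA"),
            ("mouse", "M:P1", "mouse phenotype 1", "mB"),
            ("mouse", "M:P1", "mouse phenotype 1", "mC"),
            ("mouse", "M:P2", "mouse phenotype 2", "mA"),
            ("mouse", "M:P2", "mouse phenotype 2", "mB"),
            ("mouse", "M:P2", "mouse phenotype 2", "mC2"),
        ]
    )
    return {"human": human, "mouse": mouse}


@pytest.fixture
def small_synth():
    """A small planted-structure dataset shared by integration tests."""
    cfg = SynthConfig(
        species=("human", "mouse", "yeast"),
        n_orthogroups=120,
        expansion_mean=1.5,
        ortholog_retention=0.9,
        n_modules=3,
        module_size=15,
        phenotypes_per_module=3,
        signal_fraction=0.6,
        background_phenotypes=4,
        phenotype_size_range=(4, 9),
        seed=11,
    )
    return generate(cfg)


@pytest.fixture
def small_matrix_set(small_synth):
    return build_matrix_set(small_synth.associations, small_synth.orthology, "human")


def one_to_one_config(seed: int) -> SynthConfig:
    """Degenerate generator settings giving strict 1:1 orthology."""
    return SynthConfig(
        species=("human", "mouse", "yeast"),
        n_orthogroups=80,
        expansion_mean=1.0,
        ortholog_retention=1.0,
        n_modules=2,
        module_size=12,
        phenotypes_per_module=3,
        signal_fraction=0.6,
        background_phenotypes=3,
        phenotype_size_range=(4, 8),
        seed=seed,
    )
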