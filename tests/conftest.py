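import pytest

from taxlca import FixtureSpec, Rank, Taxonomy, make_fixture


def build_linear_taxonomy():
    """A small hand-built taxonomy with one species-depth lineage and siblings
    at genus, family and phylum level for LCA and demotion tests."""
    t = Taxonomy.create("root")
    bacteria = t.add("Bacteria", t.root, Rank.DOMAIN)
    proteo = t.add("Proteobacteria", bacteria, Rank.PHYLUM)
    gamma = t.add("Gammaproteobacteria", proteo, Rank.CLASS)
    entero_o = t.add("Enterobacterales", gamma, Rank.ORDER)
    entero_f = t.add("Enterobacteriaceae", entero_o, Rank.FAMILY)
    escherichia = t.add("Escherichia", entero_f, Rank.GENUS)
    t.add("Escherichia coli", escherichia, Rank.SPECIES)
    t.add("Salmonella", entero_f, Rank.GENUS)
    vibrio_f = t.add("Vibrionaceae", entero_o, Rank.FAMILY)
    t.add("Vibrio", vibrio_f, Rank.GENUS)
    firmicutes = t.add("Firmicutes", proteo.parent, Rank.PHYLUM)
    bacilli = t.add("Bacilli", firmicutes, Rank.CLASS)
    lacto_o = t.add("Lactobacillales", bacilli, Rank.ORDER)
    lacto_f = t.add("Lactobacillaceae", lacto_o, Rank.FAMILY)
    t.add("Lactobacillus", lacto_f, Rank.GENUS)
    archaea = t.add("Archaea", t.root, Rank.DOMAIN)
    t.add("Thaumarchaeota", archaea, Rank.PHYLUM)
    return t


@pytest.fixture(scope="session")
def linear_taxonomy():
    return build_linear_taxonomy()


@pytest.fixture(scope="session")
def default_db():
    """Default synthetic reference database (16 genera, 3 sequences each)."""
    return make_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def clean_db():
    """Well-separated, noise-free database: identical sequences within each
    genus and divergences large enough that sibling genera never enter a 2%
    bit-score window."""
    return make_fixture(
        FixtureSpec(divergences=(20.0, 12.0, 8.0, 6.0, 4.0, 3.0), seq_divergence=0.0)
    )
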