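import logging
from pathlib import Path

import pytest

from karyomorph import synthetic, traits
from karyomorph.phylo import Phylogeny, read_newick

DATA_DIR = Path(__file__).parent / "data"

logging.getLogger("karyomorph").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fixture_species_path() -> Path:
    return DATA_DIR / "fixture_species.csv"


@pytest.fixture(scope="session")
def fixture_tree_path() -> Path:
    return DATA_DIR / "fixture_tree.nwk"


@pytest.fixture(scope="session")
def fixture_records(fixture_species_path):
    return traits.read_species_table(str(fixture_species_path))


@pytest.fixture(scope="session")
def fixture_tree(fixture_tree_path) -> Phylogeny:
    return read_newick(str(fixture_tree_path))


def make_record(name="Genus species", clade="mammal", head_shape="spatulate",
                length=5.0, width=3.0, method="optical", n=20, lmax=6.0,
                lmin=1.5, genome=3.0, nucleus_fraction=None) -> traits.SpeciesRecord:
    """Hand-built species record with sensible defaults for unit tests."""
    return traits.SpeciesRecord(
        species_name=name, clade=clade, head_shape=head_shape,
        head_length_um=length, head_width_um=width, method=method,
        nucleus_fraction=nucleus_fraction, genome_pg=genome,
        karyotype=traits.KaryotypeSummary(haploid_n=n, L_max_um=lmax,
                                          L_min_um=lmin))
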