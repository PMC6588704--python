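import numpy as np
import pytest

import convflight as cf


@pytest.fixture(scope="session")
def labels4():
    """2 flight-degenerate + 2 flying species."""
    return cf.SpeciesGroupTable(
        {
            "deg01": "flight_degenerate",
            "deg02": "flight_degenerate",
            "fly01": "flying",
            "fly02": "flying",
        }
    )


@pytest.fixture(scope="session")
def hky_model():
    return cf.hky85(2.0, np.array([0.3, 0.2, 0.2, 0.3]), gamma_shape=0.5, n_categories=4)


@pytest.fixture(scope="session")
def planted_bundle():
    """Small study: 16 species (5 foreground), 3 genes, convergence planted in gene001."""
    return cf.synthetic_study(
        n_species=16, n_foreground=5, n_genes=3, n_sites=150,
        n_planted_genes=1, planted_sites_per_gene=1, seed=7,
    )


def make_tree(newick: str, tmp_path, name="t.nwk") -> cf.Phylogeny:
    p = tmp_path / name
    p.write_text(newick + "\n")
    return cf.read_tree(p)


@pytest.fixture
def tree_factory(tmp_path):
    def factory(newick: str, default_branch_length=None):
        p = tmp_path / f"tree_{abs(hash(newick)) % 10**8}.nwk"
        p.write_text(newick + "\n")
        return cf.read_tree(p, default_branch_length=default_branch_length)

    return factory
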