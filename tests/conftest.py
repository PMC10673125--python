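import numpy as np
import pytest

from metpath.chem_graph import Atom, Bond, MolecularGraph
from metpath.dataset_pipeline import build_dataset
from metpath.synthetic_data import GeneratorConfig, generate_benchmark

ETHANOL_MOLFILE = """ethanol
  test

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
"""


@pytest.fixture
def ethanol_molfile() -> str:
    return ETHANOL_MOLFILE


@pytest.fixture
def ethanol() -> MolecularGraph:
    """Heavy-atom ethanol: C-C-O, single bonds."""
    return MolecularGraph(
        [Atom(0, "C"), Atom(1, "C"), Atom(2, "O")],
        [Bond(0, 1), Bond(1, 2)],
        source_id="ethanol",
    )


@pytest.fixture
def benzene() -> MolecularGraph:
    """Kekulé benzene: six equivalent carbons, alternating bond orders."""
    atoms = [Atom(i, "C") for i in range(6)]
    bonds = [Bond(i, (i + 1) % 6, order=1 + (i % 2)) for i in range(6)]
    return MolecularGraph(atoms, bonds, source_id="benzene")


def random_graphs(n: int, seed: int, max_atoms: int = 12):
    """Seeded stream of small random molecular graphs (chirality, bond
    order and stereo all exercised)."""
    cfg = GeneratorConfig(
        atom_count_range=(1, max_atoms),
        atom_count_log_mean=1.6,
        atom_count_log_sd=0.6,
        p_chiral=0.25,
        p_stereo_bond=0.2,
        p_r_group=0.0,
        p_repeat_marker=0.0,
    )
    rng = np.random.default_rng(seed)
    from metpath.synthetic_data import generate_molecule

    out = []
    for i in range(n):
        g = generate_molecule(cfg, rng)
        g.source_id = f"G{i:04d}"
        out.append(g)
    return out


@pytest.fixture(scope="session")
def small_benchmark():
    """Default-condition benchmark at reduced compound count."""
    return generate_benchmark(GeneratorConfig(n_compounds=300, seed=3))


@pytest.fixture(scope="session")
def small_dataset(small_benchmark):
    b = small_benchmark
    return build_dataset(b.graphs, b.links, b.hierarchy, categories=b.categories)


@pytest.fixture(scope="session")
def separable_dataset():
    """Noiseless, fully separable task set: every compound's labels are
    exactly its planted motifs (no size-gated noise, no seeded duplicates,
    minimal background structural diversity)."""
    cfg = GeneratorConfig(
        n_compounds=400,
        seed=8,
        signal_size_threshold=0,
        n_duplicate_molfiles=0,
        n_permuted_duplicates=0,
        atom_count_range=(6, 6),
        element_weights={"C": 1.0},
        p_chiral=0.0,
        p_stereo_bond=0.0,
        ring_edge_rate=0.0,
        p_r_group=0.0,
        p_repeat_marker=0.0,
        motif_scaffold_len=3,
        n_categories=4,
        positive_proportions=(0.35,) * 4,
    )
    b = generate_benchmark(cfg)
    return build_dataset(b.graphs, b.links, b.hierarchy, categories=b.categories)
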