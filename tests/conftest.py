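import networkx as nx
import numpy as np
import pytest

from midomain.structure_model import AtomRecord, ChainRecord, ComplexRecord, ResidueRef


def make_chain(chain_id: str, coords, sequence: str | None = None,
               bio_unit: int = 1, identity: bool = True) -> ChainRecord:
    """Chain with one C-alpha per residue at the given coordinates."""
    coords = np.asarray(coords, dtype=float)
    sequence = sequence or "A" * len(coords)
    residues = []
    for i, (aa, xyz) in enumerate(zip(sequence, coords)):
        residues.append(ResidueRef(
            chain_id=chain_id, seq_num=i + 1, icode="", aa=aa,
            atoms=[AtomRecord(serial=i + 1, name="CA", element="C", coords=xyz)]))
    return ChainRecord(chain_id=chain_id, residues=residues, bio_unit=bio_unit,
                       transform_is_identity=identity)


def make_complex(chains, entry_id="TST1", resolution=2.0,
                 method="X-RAY DIFFRACTION") -> ComplexRecord:
    return ComplexRecord(entry_id=entry_id, resolution=resolution,
                         method=method, chains=list(chains))


def lgraph(labels: dict[int, str], edges) -> nx.Graph:
    g = nx.Graph()
    for n, l in labels.items():
        g.add_node(n, aa=l)
    g.add_edges_from(edges)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
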