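import numpy as np
import pytest

from daqrefine import (ProbabilityVolume, SyntheticSpec, compute_daq,
                       core_fixture, cyclic_sequence, make_backbone,
                       make_probability_volume)

PDB_3RES = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.675   7.170  -4.943  1.00  0.00           C
ATOM      4  CA  GLY A   2      14.856   7.731  -4.058  1.00  0.00           C
ATOM      5  CA  SER A   4      17.119   9.165  -2.470  1.00  0.00           C
ATOM      6  OG  SER A   4      18.012  10.355  -2.712  1.00  0.00           O
TER
END
"""

# Same chain expressed in mmCIF dialect (coordinates authored identically).
CIF_3RES = """\
data_toy
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
ATOM 1 N N . ALA A 1 1 ? 11.104 6.134 -6.504 1.00 0.00 1 A
ATOM 2 C CA . ALA A 1 1 ? 11.639 6.071 -5.147 1.00 0.00 1 A
ATOM 3 C C . ALA A 1 1 ? 12.675 7.170 -4.943 1.00 0.00 1 A
ATOM 4 C CA . GLY A 1 2 ? 14.856 7.731 -4.058 1.00 0.00 2 A
ATOM 5 C CA . SER A 1 3 ? 17.119 9.165 -2.470 1.00 0.00 4 A
ATOM 6 O OG . SER A 1 3 ? 18.012 10.355 -2.712 1.00 0.00 4 A
"""

A3M_TOY = """\
>query
MKVLANQREW
>hom1
MKVLGNQREW
>hom2
MK-LANQaaREW
"""


@pytest.fixture
def pdb_3res(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(PDB_3RES)
    return p


@pytest.fixture
def cif_3res(tmp_path):
    p = tmp_path / "toy.cif"
    p.write_text(CIF_3RES)
    return p


@pytest.fixture
def a3m_toy(tmp_path):
    p = tmp_path / "toy.a3m"
    p.write_text(A3M_TOY)
    return p


def uniform_volume(dims=(6, 6, 6), origin=(0.0, 0.0, 0.0), spacing=1.0):
    data = np.full((20, *dims), 1 / 20)
    return ProbabilityVolume(origin=np.array(origin, dtype=float),
                             spacing=np.full(3, float(spacing)), data=data)


@pytest.fixture
def uniform_vol():
    return uniform_volume()


@pytest.fixture(scope="session")
def core():
    """The seeded planted-shift experiment, computed once per session."""
    spec, clean, shifted, volume = core_fixture(seed=0)
    return {
        "spec": spec, "clean": clean, "shifted": shifted, "volume": volume,
        "track_clean": compute_daq(clean, volume),
        "track_shifted": compute_daq(shifted, volume),
        "region": set(range(46, 56)),
    }


@pytest.fixture(scope="session")
def helix20():
    spec = SyntheticSpec(n_residues=20, sequence=cyclic_sequence(20), seed=1)
    model = make_backbone(spec)
    return spec, model, make_probability_volume(model, spec)
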