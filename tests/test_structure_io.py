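import numpy as np
import pytest

from gik.errors import (
    CongruenceError,
    EmptyInputError,
    FormatError,
    ParameterError,
    SelectionError,
)
from gik.structure_io import (
    AtomRecord,
    ResidueKey,
    Structure,
    TrajectoryEnsemble,
    read_frames,
    read_structure,
    select,
    write_mmcif,
    write_pdb,
)


def _toy_structure():
    residues = [
        (ResidueKey("A", 1, "", "GLY"),
         [AtomRecord("N", "N", [0.0, 0.0, 0.0]),
          AtomRecord("CA", "C", [1.5, 0.0, 0.0]),
          AtomRecord("C", "C", [2.3, 1.1, 0.0])]),
        (ResidueKey("A", 2, "", "ALA"),
         [AtomRecord("CA", "C", [4.0, 1.0, 0.5])]),
        (ResidueKey("B", 7, "", "SER"),
         [AtomRecord("CA", "C", [8.0, -2.0, 3.0]),
          AtomRecord("OG", "O", [9.1, -2.5, 3.2])]),
    ]
    return Structure("toy", residues)


def test_pdb_round_trip_preserves_topology_and_coords(tmp_path):
    st = _toy_structure()
    path = tmp_path / "toy.pdb"
    write_pdb(st, path)
    back = read_structure(path)
    assert back.chains() == ["A", "B"]
    assert [str(k) for k in back.residue_keys()] == [str(k) for k in st.residue_keys()]
    assert back.n_atoms == st.n_atoms
    np.testing.assert_allclose(back.coords(), st.coords(), atol=1e-2)


def test_mmcif_round_trip(tmp_path):
    st = _toy_structure()
    path = tmp_path / "toy.cif"
    write_mmcif(st, path)
    back = read_structure(path)
    assert back.n_atoms == st.n_atoms
    np.testing.assert_allclose(back.coords(), st.coords(), atol=1e-3)


def test_water_stripping(tmp_path):
    residues = _toy_structure().residues + [
        (ResidueKey("W", 100, "", "HOH"), [AtomRecord("O", "O", [20.0, 20.0, 20.0])])]
    st = Structure("wet", residues)
    path = tmp_path / "wet.pdb"
    write_pdb(st, path)
    assert read_structure(path).n_atoms == st.n_atoms - 1
    assert read_structure(path, keep_waters=True).n_atoms == st.n_atoms


def test_multi_model_frames_round_trip(tmp_path):
    st = _toy_structure()
    frames = [st.coords() + i * 0.5 for i in range(4)]
    path = tmp_path / "traj.pdb"
    write_pdb(st, path, frames=frames)
    stack = read_frames(path)
    assert stack.shape == (4, st.n_atoms, 3)
    np.testing.assert_allclose(stack[3], frames[3], atol=1e-2)
    assert read_structure(path).n_models == 4


def test_empty_and_malformed_inputs(tmp_path):
    empty = tmp_path / "empty.pdb"
    empty.write_text("")
    with pytest.raises(EmptyInputError):
        read_structure(empty)
    bad = tmp_path / "bad.cif"
    bad.write_text("this is not a structure file\n")
    with pytest.raises((FormatError, EmptyInputError)):
        read_structure(bad, format="mmcif")
    with pytest.raises(FormatError):
        read_structure(tmp_path / "missing.pdb")


def test_atomrecord_rejects_non_finite():
    with pytest.raises(ParameterError):
        AtomRecord("CA", "C", [np.nan, 0.0, 0.0])
    with pytest.raises(ParameterError):
        AtomRecord("CA", "C", [0.0, 0.0])


def test_duplicate_residue_rejected():
    key = ResidueKey("A", 1, "", "GLY")
    atoms = [AtomRecord("CA", "C", [0.0, 0.0, 0.0])]
    with pytest.raises(ParameterError):
        Structure("dup", [(key, atoms), (key, atoms)])


def test_with_coords_congruence():
    st = _toy_structure()
    moved = st.with_coords(st.coords() + 1.0)
    np.testing.assert_allclose(moved.coords(), st.coords() + 1.0)
    with pytest.raises(CongruenceError):
        st.with_coords(np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_select_grammar():
    st = _toy_structure()
    assert list(select(st, "chain A")) == [0, 1, 2, 3]
    assert list(select(st, "chain B and name CA")) == [4]
    assert list(select(st, "resnum 1-2 and name CA")) == [1, 3]
    assert list(select(st, "element O")) == [5]
    assert list(select(st, "resname SER GLY and name CA")) == [1, 4]


def test_select_empty_vs_unknown():
    st = _toy_structure()
    # empty match is a result, unknown chain is an error
    assert select(st, "chain A and name OXT").size == 0
    with pytest.raises(SelectionError):
        select(st, "chain Z")
    with pytest.raises(SelectionError):
        select(st, "nonsense CA")
    with pytest.raises(SelectionError):
        select(st, "bw 3.50")  # generic labels need maps


def test_select_by_generic_label(planted_record):
    rec = planted_record
    idx = select(rec.structure, "bw 3.50 and name CA",
                 maps=[rec.receptor_map, rec.galpha_map])
    assert idx.size == 1
    key = rec.receptor_map.lookup_position("3.50")
    assert rec.structure.atom_index(key, "CA") == idx[0]


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def test_ensemble_discard_and_congruence():
    st = _toy_structure()
    reps = [np.repeat(st.coords()[None], 10, axis=0),
            np.repeat(st.coords()[None], 8, axis=0)]
    ens = TrajectoryEnsemble(st, reps, frame_interval_ns=1.0, discard_fraction=0.5)
    assert ens.n_frames == 18
    slices = ens.retained_slices()
    assert [s.start for s in slices] == [5, 4]
    assert ens.analyzed_frames().shape[0] == 9
    assert ens.analyzed_frames(0.0).shape[0] == 18
    with pytest.raises(ParameterError):
        ens.retained_slices(1.0)
    with pytest.raises(CongruenceError):
        TrajectoryEnsemble(st, [np.zeros((3, 2, 3))], 1.0)
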