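import numpy as np
import pytest

from gik import synthetic_data as sd
from gik.contacts import (
    HEAVY_CONTACT_CUTOFF,
    hbond_present,
    heavy_atom_contacts,
    occupancy_map,
    per_residue_contact_counts,
)
from gik.errors import AtomMissingError, ParameterError, SelectionError
from gik.structure_io import AtomRecord, ResidueKey, Structure, TrajectoryEnsemble


def _random_two_chain_structure(rng, n_a=12, n_b=12):
    residues = []
    for chain, n, center in (("A", n_a, (0.0, 0.0, 0.0)), ("B", n_b, (6.0, 0.0, 0.0))):
        for i in range(n):
            base = np.asarray(center) + rng.uniform(-6, 6, 3)
            atoms = [AtomRecord(f"X{j}", "C", base + rng.uniform(-1.5, 1.5, 3))
                     for j in range(rng.integers(1, 5))]
            residues.append((ResidueKey(chain, i + 1, "", "ALA"), atoms))
    return Structure("rand", residues)


def _brute_force_pairs(st, chain_a, chain_b, cutoff):
    """Oracle: all-pairs double loop over heavy atoms."""
    arr = st._arrays()
    xyz, out = arr["coords"], set()
    for ra, (ka, atoms_a) in enumerate(st.residues):
        if ka.chain_id != chain_a:
            continue
        for rb, (kb, atoms_b) in enumerate(st.residues):
            if kb.chain_id != chain_b:
                continue
            ia = [i for i in st.atom_indices_of_residue(ra) if arr["element"][i] != "H"]
            ib = [i for i in st.atom_indices_of_residue(rb) if arr["element"][i] != "H"]
            dmin = min(np.linalg.norm(xyz[i] - xyz[j]) for i in ia for j in ib)
            if dmin <= cutoff:
                out.add((str(ka), str(kb)))
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_contact_search_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    st = _random_two_chain_structure(rng)
    got = heavy_atom_contacts(st, "chain A", "chain B", HEAVY_CONTACT_CUTOFF)
    assert {(str(p.a), str(p.b)) for p in got} == \
        _brute_force_pairs(st, "A", "B", HEAVY_CONTACT_CUTOFF)
    # symmetric in the groups
    swapped = heavy_atom_contacts(st, "chain B", "chain A", HEAVY_CONTACT_CUTOFF)
    assert {(str(p.b), str(p.a)) for p in swapped} == \
        {(str(p.a), str(p.b)) for p in got}


def _two_residue_structure(distance, resnames=("LEU", "LEU"), element="C"):
    residues = [
        (ResidueKey("A", 1, "", resnames[0]),
         [AtomRecord("CA", "C", [0.0, 0.0, 0.0]),
          AtomRecord("SC", element, [1.0, 0.0, 0.0])]),
        (ResidueKey("B", 1, "", resnames[1]),
         [AtomRecord("CA", "C", [1.0 + distance + 3.0, 0.0, 0.0]),
          AtomRecord("SC", element, [1.0 + distance, 0.0, 0.0])]),
    ]
    return Structure("pair", residues)


def test_cutoff_boundary_is_inclusive():
    st = _two_residue_structure(HEAVY_CONTACT_CUTOFF)
    assert len(heavy_atom_contacts(st, "chain A", "chain B")) == 1
    st = _two_residue_structure(HEAVY_CONTACT_CUTOFF + 0.01)
    assert len(heavy_atom_contacts(st, "chain A", "chain B")) == 0


def test_polar_criterion_requires_polar_sidechains():
    polar = _two_residue_structure(3.8, resnames=("SER", "ASP"), element="O")
    apolar = _two_residue_structure(3.8, resnames=("LEU", "VAL"), element="C")
    assert len(heavy_atom_contacts(polar, "chain A", "chain B", 4.0, kind="polar")) == 1
    assert len(heavy_atom_contacts(apolar, "chain A", "chain B", 4.0, kind="polar")) == 0


def test_groups_must_be_disjoint_and_nonempty():
    st = _two_residue_structure(3.0)
    with pytest.raises(ParameterError):
        heavy_atom_contacts(st, "chain A", "chain A")
    with pytest.raises(SelectionError):
        heavy_atom_contacts(st, "chain A and name OXT", "chain B")
    with pytest.raises(ParameterError):
        heavy_atom_contacts(st, "chain A", "chain B", cutoff=-1.0)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def test_hbond_geometry_accept_and_reject():
    for d, dev, expect in [(2.8, 5.0, True), (2.8, 19.9, True),
                           (2.8, 25.0, False), (3.2, 5.0, False),
                           (2.99, 0.0, True)]:
        st, dd, hh, aa = sd.make_hbond_geometry(d, dev)
        assert hbond_present(st.coords(), dd, hh, aa) is expect, (d, dev)


def test_hbond_without_hydrogen_is_an_error():
    st, dd, _, aa = sd.make_hbond_geometry(2.8, 5.0)
    with pytest.raises(AtomMissingError):
        hbond_present(st.coords(), dd, None, aa)


def test_hbond_occupancy_over_frames():
    st, dd, hh, aa = sd.make_hbond_geometry(2.8, 5.0)
    good = st.coords()
    st_bad, _, _, _ = sd.make_hbond_geometry(2.8, 40.0)
    bad = st_bad.coords()
    frames = np.stack([good, good, bad, good])  # no discard -> 3/4
    ens = TrajectoryEnsemble(st, [frames], 1.0, discard_fraction=0.0)
    recs = occupancy_map(ens, "chain A", "chain B", kind="hbond", min_occupancy=0.0)
    assert len(recs) == 1
    assert recs[0].occupancy == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def test_occupancy_matches_per_frame_oracle(small_ensemble, small_ensemble_record):
    rec = small_ensemble_record
    maps = [rec.receptor_map, rec.galpha_map]
    records = occupancy_map(small_ensemble, "chain R", "chain G",
                            min_occupancy=0.0, maps=maps)
    by_pair = {r.pair.generic_pair(): r for r in records}
    frames = small_ensemble.analyzed_frames()
    st = small_ensemble.topology
    arr = st._arrays()

    def oracle(rpos, gpos):
        ra = st.residue_index(rec.receptor_map.lookup_position(rpos))
        rb = st.residue_index(rec.galpha_map.lookup_position(gpos))
        ia = [i for i in st.atom_indices_of_residue(ra) if arr["element"][i] != "H"]
        ib = [i for i in st.atom_indices_of_residue(rb) if arr["element"][i] != "H"]
        hits = 0
        for f in frames:
            dmin = min(np.linalg.norm(f[i] - f[j]) for i in ia for j in ib)
            hits += dmin <= HEAVY_CONTACT_CUTOFF
        return hits / len(frames)

    for pair in (("3.54", "H5.20"), ("6.33", "H5.25")):
        assert pair in by_pair
        assert by_pair[pair].occupancy == pytest.approx(oracle(*pair))
    # occupancy is an exact frame fraction
    r = by_pair[("3.54", "H5.20")]
    assert r.frames_total == frames.shape[0]
    assert r.occupancy == r.frames_present / r.frames_total


def test_occupancy_threshold_filters(small_ensemble, small_ensemble_record):
    rec = small_ensemble_record
    maps = [rec.receptor_map, rec.galpha_map]
    all_recs = occupancy_map(small_ensemble, "chain R", "chain G",
                             min_occupancy=0.0, maps=maps)
    kept = occupancy_map(small_ensemble, "chain R", "chain G",
                         min_occupancy=0.4, maps=maps)
    assert {r.pair.generic_pair() for r in kept} == \
        {r.pair.generic_pair() for r in all_recs if r.occupancy >= 0.4}
    occs = [r.occupancy for r in kept]
    assert occs == sorted(occs, reverse=True)


# ---------------------------------------------------------------------------
# per-residue contact counts
# ---------------------------------------------------------------------------

def test_pocket_contact_counts():
    """A planted 5-partner pocket: the pocket residue tops the count table."""
    extras = [("S3.01", 217, "VAL"), ("S1.02", 41, "HIS")]
    contacts = [sd.PlantedContact("34.51", g, 1.0)
                for g in ("H5.08", "H5.12", "H5.15", "S3.01", "S1.02")]
    contacts.append(sd.PlantedContact("3.54", "H5.20", 1.0))
    rec = sd.make_complex(sd.ScenarioSpec(seed=5, planted_contacts=contacts,
                                          extra_galpha=extras))
    df = per_residue_contact_counts(
        [(rec.structure, [rec.receptor_map, rec.galpha_map])],
        ["34.51", "3.54", "2.39"], "chain G",
        maps=[rec.receptor_map, rec.galpha_map])
    assert df.loc["34.51", "mean_count"] == 5.0
    assert df.loc["3.54", "mean_count"] == 1.0
    assert df.loc["2.39", "mean_count"] == 0.0
    assert bool(df.loc["34.51", "is_max"])
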