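"""Synthetic inputs with planted ground truth.

Everything the analysis pipeline consumes can be generated here: ideal
helices, a toy 7-helix receptor bundle with a docked Galpha alpha5-like
helix and geometrically realized residue contacts, multi-replicate frame
ensembles with planted conformational basins, hydrogen-bond geometries, and
Galpha subfamily alignments with chosen conserved columns.

The generators are deterministic functions of their arguments (one RNG
stream per scenario, seeded explicitly), and every planted quantity - basin
populations, contact probabilities, conserved columns - is recoverable by
the corresponding analysis operation, which is what the test suite leans on.

Geometry conventions: the bundle axis is +z (membrane normal), the
intracellular side is at low z, helices are straight Calpha traces with
small backbone offsets, and each residue carries pseudo side-chain atoms
("SC", "SC2", ...).  A planted contact between residues is realized by
placing one pseudo atom of each residue on the segment between their Calpha
positions, ``contact_distance`` apart (default 3.0 A, inside both the
heavy-atom and the polar criterion); an absent contact points the pseudo
atoms away from each other.  The pseudo side chains are explicitly
non-physical: their reach is whatever the planted geometry requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import ComplexRecord
from .contacts import heavy_atom_contacts
from .errors import GenerationError, ParameterError
from .numbering import GenericLabel, NumberingMap
from .structure_io import AtomRecord, ResidueKey, Structure, TrajectoryEnsemble

_SC_ELEMENT = {
    "ARG": "N", "LYS": "N", "HIS": "N",
    "ASP": "O", "GLU": "O", "ASN": "O", "GLN": "O",
    "SER": "O", "THR": "O", "TYR": "O",
}

# bundle layout: (BW helix, first BW index, first resnum, direction)
# direction +1: N-terminus intracellular (z grows with sequence);
# direction -1: sequence descends from the extracellular side.
# The resnum anchors reproduce the published CB1 numbering at the positions
# the analyses use (3.54 -> 218, 6.33 -> 341, 2.39 -> 152, 34.51 -> 222).
_BUNDLE = [
    (1, 40, 100, +1),
    (2, 37, 150, +1),
    (3, 41, 205, -1),
    (4, 40, 230, +1),
    (5, 57, 288, -1),
    (6, 28, 336, +1),
    (7, 41, 385, -1),
]
_TM_LEN = 16
_BUNDLE_RADIUS = 13.0
_ICL2_RADIUS = 10.5
_RISE = 1.5
_GALPHA_OFFSET = {"Gs": 368, "Gi": 328, "Gq": 340, "other": 368}
_MAX_ARM = 10.0  # longest allowed pseudo side-chain reach in a static complex


@dataclass
class Basin:
    """One planted conformational basin of the docked helix."""

    fraction: float
    displacement: tuple = (0.0, 0.0, 0.0)
    rotation_deg: float = 0.0


@dataclass
class PlantedContact:
    """A receptor-Galpha contact planted with a per-frame presence probability."""

    receptor_label: str
    galpha_label: str
    probability: float = 1.0


@dataclass
class ScenarioSpec:
    """Full description of a synthetic study scenario."""

    seed: int = 0
    n_replicates: int = 12
    frames_per_replicate: int = 625
    frame_interval_ns: float = 1.0
    basins: list = field(default_factory=lambda: [
        Basin(0.47, (0.0, 0.0, 0.0), 0.0),
        Basin(0.155, (6.0, 0.0, 0.0), 30.0),
        Basin(0.149, (-7.0, 0.0, 0.0), -30.0),
    ])
    noise_sigma: float = 0.5
    planted_contacts: list = field(default_factory=list)
    planted_hbonds: list = field(default_factory=list)  # (d_DA, deviation_deg)
    resnames: dict = field(default_factory=dict)        # label -> 3-letter code
    extra_galpha: list = field(default_factory=list)    # (cgn_label, resnum, resname)
    family: str = "Gs"
    contact_distance: float = 3.0
    complex_id: str = "synthetic-complex"

    def __post_init__(self) -> None:
        self.planted_contacts = [
            c if isinstance(c, PlantedContact) else PlantedContact(*c)
            for c in self.planted_contacts]
        self.basins = [b if isinstance(b, Basin) else Basin(*b) for b in self.basins]
        total = sum(b.fraction for b in self.basins)
        if total > 1.0 + 1e-12:
            raise ParameterError(f"basin fractions sum to {total} > 1")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        for c in self.planted_contacts:
            if not 0.0 <= c.probability <= 1.0:
                raise ParameterError(f"contact probability {c.probability} not in [0,1]")
        if self.n_replicates < 1 or self.frames_per_replicate < 1:
            raise ParameterError("need at least one replicate and one frame")


# ---------------------------------------------------------------------------
# ideal helix
# ---------------------------------------------------------------------------

def make_helix(n_res: int, origin=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0),
               chain_id: str = "A", start_resnum: int = 1, resname: str = "ALA",
               radius: float = 2.3, structure_id: str = "helix",
               with_hydrogens: bool = True) -> Structure:
    """An ideal alpha-helix backbone: 1.5 A rise and 100 degrees twist per residue.

    Each residue carries N (with an amide H unless disabled), CA, C, O and one
    side-chain pseudo atom SC placed radially outward.  ``radius=0`` gives a
    straight Calpha trace, used for schematic bundle geometry.
    """
    if n_res < 4:
        raise ParameterError("a helix needs at least 4 residues")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # orthonormal frame around the axis
    seed_vec = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, seed_vec)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    origin = np.asarray(origin, dtype=float)

    residues = []
    sc_elem = _SC_ELEMENT.get(resname.upper(), "C")
    for i in range(n_res):
        theta = np.radians(100.0 * i)
        radial = np.cos(theta) * u + np.sin(theta) * v
        ca = origin + _RISE * i * d + radius * radial
        out = radial if radius > 0 else u
        atoms = [
            AtomRecord("N", "N", ca - 0.6 * d + 0.35 * out),
            AtomRecord("CA", "C", ca),
            AtomRecord("C", "C", ca + 0.6 * d + 0.35 * out),
            AtomRecord("O", "O", ca + 0.9 * d + 0.9 * out),
            AtomRecord("SC", sc_elem, ca + 1.0 * out),
        ]
        if with_hydrogens:
            atoms.insert(1, AtomRecord("H", "H", ca - 0.6 * d + 1.35 * out))
        key = ResidueKey(chain_id, start_resnum + i, "", resname.upper())
        residues.append((key, atoms))
    return Structure(structure_id, residues)


# ---------------------------------------------------------------------------
# toy complex
# ---------------------------------------------------------------------------

def _residue_atoms(ca: np.ndarray, d: np.ndarray, sc_dir: np.ndarray,
                   resname: str) -> list[AtomRecord]:
    elem = _SC_ELEMENT.get(resname.upper(), "C")
    return [
        AtomRecord("N", "N", ca - 0.6 * d + 0.35 * sc_dir),
        AtomRecord("CA", "C", ca.copy()),
        AtomRecord("C", "C", ca + 0.6 * d + 0.35 * sc_dir),
        AtomRecord("O", "O", ca + 0.9 * d + 0.9 * sc_dir),
        AtomRecord("SC", elem, ca + 1.0 * sc_dir),
    ]


_SCAFFOLD_RESNAMES: dict[str, dict] = {}


def _scaffold_resnames(family: str) -> dict:
    """Default residue names per generic label, from the packaged reference tables."""
    key = "gas" if family != "Gi" else "gai1"
    if key not in _SCAFFOLD_RESNAMES:
        from .numbering import _AA3_TO_1, load_reference
        aa3 = {v: k for k, v in _AA3_TO_1.items()}
        names = {}
        for table in ("cb1", key):
            df = load_reference(table).df
            for _, row in df.iterrows():
                if row.generic_label:
                    names[row.generic_label] = aa3.get(row.ref_aa, "UNK")
        _SCAFFOLD_RESNAMES[key] = names
    return _SCAFFOLD_RESNAMES[key]


def _build_complex(spec: ScenarioSpec):
    """The toy receptor-Galpha complex plus bookkeeping for the generators.

    Returns ``(ComplexRecord, meta)`` where ``meta`` maps labels to atom
    indices and records each planted contact's Calpha/SC atom indices.
    """
    scaffold = _scaffold_resnames(spec.family)
    resname_of = lambda label: spec.resnames.get(label, scaffold.get(label, "LEU"))
    up = np.array([0.0, 0.0, 1.0])

    residues = []  # (key, atoms, label, scheme)
    # --- receptor bundle
    for k, (helix, idx0, res0, direction) in enumerate(_BUNDLE):
        az = np.radians(k * 360.0 / 7.0)
        radial = np.array([np.cos(az), np.sin(az), 0.0])
        base = _BUNDLE_RADIUS * radial
        for i in range(_TM_LEN):
            label = f"{helix}.{idx0 + i}"
            z = _RISE * i if direction > 0 else _RISE * (_TM_LEN - 1) - _RISE * i
            ca = base + z * up
            d = up * direction
            residues.append((ResidueKey("R", res0 + i, "", resname_of(label)),
                             _residue_atoms(ca, d, radial, resname_of(label)),
                             label, "BW"))
    # --- ICL2 (34.50-34.57), descending below the membrane between TM3/TM4
    az = np.radians(2.5 * 360.0 / 7.0)
    radial = np.array([np.cos(az), np.sin(az), 0.0])
    for i in range(8):
        label = f"34.{50 + i}"
        ca = _ICL2_RADIUS * radial + np.array([0.0, 0.0, -1.5 - _RISE * i])
        residues.append((ResidueKey("R", 221 + i, "", resname_of(label)),
                         _residue_atoms(ca, -up, radial, resname_of(label)),
                         label, "BW"))
    # --- helix 8, tangential at the TM7 base
    az7 = np.radians(6 * 360.0 / 7.0)
    base = _BUNDLE_RADIUS * np.array([np.cos(az7), np.sin(az7), 0.0]) + np.array([0, 0, -1.5])
    tangent = np.array([-np.sin(az7), np.cos(az7), 0.0])
    for i in range(8):
        label = f"8.{47 + i}"
        ca = base + _RISE * i * tangent
        residues.append((ResidueKey("R", 401 + i, "", resname_of(label)),
                         _residue_atoms(ca, tangent, np.array([np.cos(az7), np.sin(az7), 0.0]),
                                        resname_of(label)),
                         label, "BW"))
    # --- Galpha alpha5 helix through the intracellular cavity, C-terminus up
    offset = _GALPHA_OFFSET.get(spec.family, 368)
    for i in range(1, 27):
        label = f"H5.{i:02d}"
        ca = np.array([0.0, 0.0, -27.0 + _RISE * i])
        residues.append((ResidueKey("G", offset + i, "", resname_of(label)),
                         _residue_atoms(ca, up, np.array([1.0, 0.0, 0.0]),
                                        resname_of(label)),
                         label, "CGN"))
    # --- optional extra Galpha residues (ray-domain positions near ICL2)
    for j, (label, resnum, resname) in enumerate(spec.extra_galpha):
        ca = 3.5 * radial + np.array([0.0, 0.0, -2.0 - 2.0 * j])
        key = ResidueKey("G", resnum, "", resname)
        atoms = [AtomRecord("CA", "C", ca.copy()),
                 AtomRecord("SC", _SC_ELEMENT.get(resname, "C"), ca - 1.0 * radial)]
        residues.append((key, atoms, label, "CGN"))

    # sequence order within each chain follows author numbering (ICL2 sits
    # between TM3 and TM4), which alignment-based annotation relies on
    residues.sort(key=lambda r: (r[0].chain_id != "R", r[0].resnum))

    # --- realize planted contacts with dedicated pseudo atoms
    by_label = {lab: i for i, (_, _, lab, _) in enumerate(residues)}
    contact_meta = []
    for c in spec.planted_contacts:
        for lab in (c.receptor_label, c.galpha_label):
            if lab not in by_label:
                raise GenerationError(f"planted contact references unknown label {lab!r}")
        ir, ig = by_label[c.receptor_label], by_label[c.galpha_label]
        ca_r = residues[ir][1][_ca_pos(residues[ir][1])].coords
        ca_g = residues[ig][1][_ca_pos(residues[ig][1])].coords
        dist = float(np.linalg.norm(ca_g - ca_r))
        arm = (dist - spec.contact_distance) / 2.0
        if arm > _MAX_ARM or arm < 0:
            raise GenerationError(
                f"contact {c.receptor_label}-{c.galpha_label}: Calpha separation "
                f"{dist:.1f} A cannot be bridged (arm {arm:.1f} A)")
        u = (ca_g - ca_r) / dist
        on = c.probability >= 0.5  # static realization; ensembles draw per frame
        sc_r = ca_r + (arm if on else -1.0) * u
        sc_g = ca_g - (arm if on else -1.0) * u
        elem_r = _SC_ELEMENT.get(residues[ir][0].resname, "C")
        elem_g = _SC_ELEMENT.get(residues[ig][0].resname, "C")
        name_r = f"SC{sum(1 for m in contact_meta if m['ir'] == ir) + 2}"
        name_g = f"SC{sum(1 for m in contact_meta if m['ig'] == ig) + 2}"
        residues[ir][1].append(AtomRecord(name_r, elem_r, sc_r))
        residues[ig][1].append(AtomRecord(name_g, elem_g, sc_g))
        contact_meta.append({"ir": ir, "ig": ig, "name_r": name_r, "name_g": name_g,
                             "probability": c.probability,
                             "pair": (c.receptor_label, c.galpha_label)})

    structure = Structure(spec.complex_id, [(k, a) for k, a, _, _ in residues])
    rmap = NumberingMap("R", [(k, GenericLabel.parse(lab, "BW"))
                              for k, _, lab, sch in residues if sch == "BW"],
                        source="synthetic")
    gmap = NumberingMap("G", [(k, GenericLabel.parse(lab, "CGN"))
                              for k, _, lab, sch in residues if sch == "CGN"],
                        source="synthetic")
    record = ComplexRecord(spec.complex_id, structure, rmap, gmap, spec.family)

    meta = {
        "contacts": [
            {"ca_r": structure.atom_index(residues[m["ir"]][0], "CA"),
             "ca_g": structure.atom_index(residues[m["ig"]][0], "CA"),
             "sc_r": structure.atom_index(residues[m["ir"]][0], m["name_r"]),
             "sc_g": structure.atom_index(residues[m["ig"]][0], m["name_g"]),
             "probability": m["probability"], "pair": m["pair"]}
            for m in contact_meta],
        "galpha_atoms": np.flatnonzero(structure._arrays()["chain"] == "G"),
        "contact_distance": spec.contact_distance,
    }
    return record, meta


def _ca_pos(atoms) -> int:
    for i, a in enumerate(atoms):
        if a.name == "CA":
            return i
    raise GenerationError("residue without CA")


def make_complex(spec: ScenarioSpec, verify: bool = True) -> ComplexRecord:
    """Build the toy annotated complex and verify the planted interface.

    Verification runs the heavy-atom contact detector at its default cutoff
    and demands that every contact planted ON is found and every contact
    planted OFF is not; a violation (e.g. two plantings demanding
    contradictory pseudo-atom placements) raises naming the pair.
    """
    record, meta = _build_complex(spec)
    if verify and spec.planted_contacts:
        from .conservation import complex_contact_pairs
        found = complex_contact_pairs(record)
        for c in spec.planted_contacts:
            pair = (c.receptor_label, c.galpha_label)
            if c.probability >= 0.5 and pair not in found:
                raise GenerationError(f"planted contact {pair} was not realized")
            if c.probability < 0.5 and pair in found:
                raise GenerationError(f"suppressed contact {pair} is present anyway")
    return record


def h5_ca_indices(record: ComplexRecord) -> np.ndarray:
    """Atom indices of the alpha5-helix Calpha trace (the clustering selection)."""
    idx = []
    for i in range(1, 27):
        key = record.galpha_map.lookup_position(f"H5.{i:02d}")
        if key is not None:
            idx.append(record.structure.atom_index(key, "CA"))
    return np.array(idx, dtype=int)


def receptor_ca_indices(record: ComplexRecord) -> np.ndarray:
    """Atom indices of the receptor bundle Calpha trace (the fit selection)."""
    arr = record.structure._arrays()
    return np.flatnonzero((arr["chain"] == "R") & (arr["name"] == "CA"))


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def _rot_z(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_ensemble(spec: ScenarioSpec) -> TrajectoryEnsemble:
    """Multi-replicate frame series with planted basins and contacts.

    Frames draw a basin label iid from the planted populations (remainder =
    diffuse frames scattered well away from every basin); the docked helix is
    rigidly transformed per basin (rotation about its axis + translation),
    planted contacts are re-realized per frame from Bernoulli draws of their
    probabilities, and iid Gaussian noise of ``noise_sigma`` is added to all
    atoms.  Everything is reproducible from ``spec.seed``.
    """
    record, meta = _build_complex(spec)
    base = record.structure.coords()
    n_atoms = base.shape[0]
    g_idx = meta["galpha_atoms"]
    rng = np.random.default_rng(spec.seed)

    F = spec.n_replicates * spec.frames_per_replicate
    probs = np.array([b.fraction for b in spec.basins]
                     + [max(0.0, 1.0 - sum(b.fraction for b in spec.basins))])
    probs /= probs.sum()
    basin_of = rng.choice(len(spec.basins) + 1, size=F, p=probs)

    frames = np.repeat(base[None, :, :], F, axis=0)
    for bi, basin in enumerate(spec.basins):
        sel = np.flatnonzero(basin_of == bi)
        if sel.size == 0:
            continue
        moved = base[g_idx] @ _rot_z(basin.rotation_deg).T + np.asarray(basin.displacement)
        frames[np.ix_(sel, g_idx)] = moved
    # diffuse frames: random rotation, random displacement in a far shell
    for fi in np.flatnonzero(basin_of == len(spec.basins)):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        disp = direction * rng.uniform(14.0, 30.0)
        frames[fi, g_idx] = base[g_idx] @ _rot_z(rng.uniform(0.0, 360.0)).T + disp

    # per-frame contact realization
    cd = spec.contact_distance
    for cm in meta["contacts"]:
        on = rng.random(F) < cm["probability"]
        ca_r = frames[:, cm["ca_r"], :]
        ca_g = frames[:, cm["ca_g"], :]
        delta = ca_g - ca_r
        dist = np.linalg.norm(delta, axis=1, keepdims=True)
        u = delta / dist
        arm = np.where(on[:, None], (dist - cd) / 2.0, -1.0)
        frames[:, cm["sc_r"], :] = ca_r + arm * u
        frames[:, cm["sc_g"], :] = ca_g - arm * u

    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape)

    replicates = list(frames.reshape(spec.n_replicates, spec.frames_per_replicate,
                                     n_atoms, 3))
    return TrajectoryEnsemble(record.structure, replicates,
                              spec.frame_interval_ns, discard_fraction=0.5)


# ---------------------------------------------------------------------------
# hydrogen-bond geometry
# ---------------------------------------------------------------------------

def make_hbond_geometry(d_da: float, deviation_deg: float):
    """A donor-hydrogen-acceptor triple with exact planted geometry.

    Returns ``(Structure, donor_idx, hydrogen_idx, acceptor_idx)`` where the
    donor-acceptor distance is ``d_da`` and the D-H...A arrangement deviates
    from linearity by ``deviation_deg``.
    """
    d = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    theta = np.radians(deviation_deg)
    u = np.array([np.cos(theta), np.sin(theta), 0.0])
    # |h + t*u| = d_da  ->  t^2 + 2 t cos(theta) + 1 - d_da^2 = 0
    t = -np.cos(theta) + np.sqrt(np.cos(theta) ** 2 - 1.0 + d_da ** 2)
    a = h + t * u
    donor_res = (ResidueKey("A", 1, "", "ASN"),
                 [AtomRecord("CA", "C", d + np.array([0.0, -1.5, 0.0])),
                  AtomRecord("ND2", "N", d), AtomRecord("HD21", "H", h)])
    accep_res = (ResidueKey("B", 1, "", "SER"),
                 [AtomRecord("CA", "C", a + np.array([0.0, 1.5, 0.0])),
                  AtomRecord("OG", "O", a)])
    st = Structure("hbond-fixture", [donor_res, accep_res])
    return st, st.atom_index(donor_res[0], "ND2"), st.atom_index(donor_res[0], "HD21"), \
        st.atom_index(accep_res[0], "OG")


# ---------------------------------------------------------------------------
# alignments and the restraint-funnel fixture
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_alignment(conserved_labels, families=("Gs", "Gi1", "Gi2", "Gq", "G12"),
                   seed: int = 0) -> pd.DataFrame:
    """A Galpha H5 alignment where exactly ``conserved_labels`` are invariant.

    Columns are CGN position strings H5.01-H5.26, rows are subfamily
    sequences.  Non-conserved columns are guaranteed to hold at least two
    residue types (when two or more families are requested).
    """
    conserved = {str(GenericLabel.parse(str(l), "CGN")) for l in conserved_labels}
    for lab in conserved:
        if not lab.startswith("H5."):
            raise ParameterError(f"conserved label {lab!r} is outside segment H5")
    rng = np.random.default_rng(seed)
    cols = [f"H5.{i:02d}" for i in range(1, 27)]
    data = {}
    for col in cols:
        if col in conserved:
            data[col] = [_AA[rng.integers(len(_AA))]] * len(families)
        else:
            letters = [_AA[rng.integers(len(_AA))] for _ in families]
            if len(set(letters)) == 1 and len(families) > 1:
                pool = _AA.replace(letters[0], "")
                letters[-1] = pool[rng.integers(len(pool))]
            data[col] = letters
    return pd.DataFrame(data, index=list(families))


REFERENCE_CONSERVED_H5 = ["H5.01", "H5.03", "H5.07", "H5.08", "H5.13", "H5.20", "H5.25"]


def funnel_fixture(seed: int = 0, n_per_family: int = 4):
    """The packaged scenario reproducing the restraint-selection funnel.

    Seven H5 positions are sequence-conserved; four of them (H5.08, H5.13,
    H5.20, H5.25) appear at the interface in at least one complex of both
    the Gi-bound and Gs-bound sets; only H5.20 (partner 3.54) and H5.25
    (partner 6.33) contact the receptor consistently (in every complex of
    both sets), so they alone survive the conservation filter.

    Returns ``(alignment, gi_set, gs_set, target_record)``.
    """
    alignment = make_alignment(REFERENCE_CONSERVED_H5, seed=seed)

    def complexes(family: str) -> list[ComplexRecord]:
        out = []
        for i in range(n_per_family):
            contacts = [PlantedContact("3.54", "H5.20", 1.0),
                        PlantedContact("6.33", "H5.25", 1.0)]
            # sporadic interface presence: enough to be "shared", too rare
            # to pass the conservation filter
            contacts.append(PlantedContact("2.39", "H5.08", 1.0 if i == 0 else 0.0))
            contacts.append(PlantedContact("4.41", "H5.13", 1.0 if i == 0 else 0.0))
            spec = ScenarioSpec(seed=seed, planted_contacts=contacts,
                                family=family, complex_id=f"{family.lower()}-{i}")
            out.append(make_complex(spec))
        return out

    gi_set = complexes("Gi")
    gs_set = complexes("Gs")
    target = make_complex(ScenarioSpec(seed=seed, family="Gs", complex_id="target"))
    return alignment, gi_set, gs_set, target
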