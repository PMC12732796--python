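"""Structures, trajectory ensembles, and atom selection.

Coordinates are in Angstrom throughout, in the frame of the input file; for
membrane-protein inputs the convention is an OPM-style orientation with the
membrane normal along +z.  Parsing and writing of PDB/mmCIF goes through
gemmi; this module only defines the light in-memory containers the analysis
layers operate on.

Trajectories are carried natively as multi-model PDB (one model per frame).
Binary formats (XTC/DCD) enter through the same adapter contract: any reader
that yields per-frame ``(n_atoms, 3)`` arrays congruent with the topology can
feed :class:`TrajectoryEnsemble` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    CongruenceError,
    EmptyInputError,
    FormatError,
    ParameterError,
    SelectionError,
)

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "H2O", "SOL", "TIP"}


@dataclass
class AtomRecord:
    """One atom: name, element symbol, position (Angstrom), alt-loc flag."""

    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ParameterError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name:
            raise ParameterError("atom name must be non-empty")


@dataclass(frozen=True)
class ResidueKey:
    """Identity of a residue in author numbering, unique per structure."""

    chain_id: str
    resnum: int
    icode: str = ""
    resname: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.resname}{self.resnum}{self.icode}"


class Structure:
    """Ordered residues with atoms; order is file order.

    ``residues`` is a list of ``(ResidueKey, [AtomRecord, ...])``.  The
    structure is treated as immutable once built; per-atom lookup arrays are
    cached on first use.
    """

    def __init__(self, id: str, residues, model_index: int = 0, n_models: int = 1):
        self.id = id
        self.residues = list(residues)
        self.model_index = model_index
        self.n_models = n_models
        seen = set()
        for key, atoms in self.residues:
            if not atoms:
                raise ParameterError(f"residue {key} has no atoms")
            ident = (key.chain_id, key.resnum, key.icode)
            if ident in seen:
                raise ParameterError(f"duplicate residue {key}")
            seen.add(ident)
        self._cache: dict | None = None

    # -- cached flat views -------------------------------------------------
    def _arrays(self) -> dict:
        if self._cache is None:
            chain, name, resname, resnum, icode, residx, elem, xyz = [], [], [], [], [], [], [], []
            for i, (key, atoms) in enumerate(self.residues):
                for a in atoms:
                    chain.append(key.chain_id)
                    name.append(a.name)
                    resname.append(key.resname)
                    resnum.append(key.resnum)
                    icode.append(key.icode)
                    elem.append(a.element)
                    residx.append(i)
                    xyz.append(a.coords)
            self._cache = {
                "chain": np.array(chain, dtype=object),
                "name": np.array(name, dtype=object),
                "resname": np.array(resname, dtype=object),
                "resnum": np.array(resnum, dtype=int),
                "icode": np.array(icode, dtype=object),
                "element": np.array(elem, dtype=object),
                "residx": np.array(residx, dtype=int),
                "coords": np.array(xyz, dtype=float).reshape(-1, 3),
            }
        return self._cache

    @property
    def n_atoms(self) -> int:
        return sum(len(atoms) for _, atoms in self.residues)

    def coords(self) -> np.ndarray:
        """All atom coordinates, shape (n_atoms, 3), in file order."""
        return self._arrays()["coords"].copy()

    def chains(self) -> list[str]:
        out: list[str] = []
        for key, _ in self.residues:
            if key.chain_id not in out:
                out.append(key.chain_id)
        return out

    def residue_keys(self) -> list[ResidueKey]:
        return [key for key, _ in self.residues]

    def residue_index(self, key: ResidueKey) -> int:
        for i, (k, _) in enumerate(self.residues):
            if (k.chain_id, k.resnum, k.icode) == (key.chain_id, key.resnum, key.icode):
                return i
        raise SelectionError(f"residue {key} not in structure {self.id!r}")

    def atom_indices_of_residue(self, residue_index: int) -> np.ndarray:
        return np.flatnonzero(self._arrays()["residx"] == residue_index)

    def atom_index(self, key: ResidueKey, atom_name: str) -> int:
        ri = self.residue_index(key)
        arr = self._arrays()
        hit = np.flatnonzero((arr["residx"] == ri) & (arr["name"] == atom_name))
        if hit.size == 0:
            raise SelectionError(f"atom {atom_name!r} not found in residue {key}")
        return int(hit[0])

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """A copy of this structure carrying new coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise CongruenceError(
                f"coords shape {coords.shape} does not match {self.n_atoms} atoms"
            )
        residues, pos = [], 0
        for key, atoms in self.residues:
            new_atoms = []
            for a in atoms:
                new_atoms.append(AtomRecord(a.name, a.element, coords[pos], a.altloc))
                pos += 1
            residues.append((key, new_atoms))
        return Structure(id or self.id, residues, self.model_index, self.n_models)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _gemmi_read(path: str | Path, format: str | None) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise EmptyInputError(f"empty file: {path}")
    fmt = {None: gemmi.CoorFormat.Detect,
           "pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif}.get(format)
    if fmt is None:
        raise ParameterError(f"unknown format {format!r} (expected pdb or mmcif)")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyInputError(f"{path}: no models found")
    return st


def _model_to_structure(st: gemmi.Structure, model_idx: int, *,
                        keep_waters: bool, sid: str) -> Structure:
    model = st[model_idx]
    residues = []
    for chain in model:
        for res in chain:
            if not keep_waters and res.name.strip() in WATER_RESNAMES:
                continue
            key = ResidueKey(chain.name, res.seqid.num, (res.seqid.icode or " ").strip(),
                             res.name.strip())
            # alt-locs: keep the highest-occupancy conformer per atom name
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif (atom.occ or 0.0) > (prev.occ or 0.0):
                    best[atom.name] = atom
            atoms = [AtomRecord(n, best[n].element.name,
                                np.array([best[n].pos.x, best[n].pos.y, best[n].pos.z]),
                                best[n].altloc or "")
                     for n in order]
            if atoms:
                residues.append((key, atoms))
    if not residues:
        raise EmptyInputError(f"{sid}: model {model_idx} contains no residues")
    return Structure(sid, residues, model_index=model_idx, n_models=len(st))


def read_structure(path: str | Path, format: str | None = None, *,
                   model: int = 0, keep_waters: bool = False) -> Structure:
    """Read one model of a PDB/mmCIF file.

    HETATM waters are stripped by default (``keep_waters=True`` retains
    them).  ``Structure.n_models`` exposes the model count of multi-model
    files.
    """
    st = _gemmi_read(path, format)
    if model >= len(st):
        raise ParameterError(f"model {model} out of range ({len(st)} models)")
    return _model_to_structure(st, model, keep_waters=keep_waters, sid=Path(path).stem)


def read_frames(path: str | Path, format: str | None = None,
                keep_waters: bool = False) -> np.ndarray:
    """All models of a multi-model file as a coordinate stack (F, N, 3)."""
    st = _gemmi_read(path, format)
    frames = []
    for m in range(len(st)):
        s = _model_to_structure(st, m, keep_waters=keep_waters, sid=Path(path).stem)
        frames.append(s.coords())
    n0 = frames[0].shape[0]
    for i, f in enumerate(frames):
        if f.shape[0] != n0:
            raise CongruenceError(f"{path}: model {i} has {f.shape[0]} atoms, expected {n0}")
    return np.stack(frames)


def _to_gemmi(structure: Structure, frames: Sequence[np.ndarray] | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    coord_sets = [structure.coords()] if frames is None else [np.asarray(f) for f in frames]
    for mi, xyz in enumerate(coord_sets):
        if xyz.shape != (structure.n_atoms, 3):
            raise CongruenceError(f"frame {mi}: shape {xyz.shape} vs {structure.n_atoms} atoms")
        model = gemmi.Model(mi + 1)
        chains: dict[str, gemmi.Chain] = {}
        pos = 0
        for key, atoms in structure.residues:
            if key.chain_id not in chains:
                chains[key.chain_id] = gemmi.Chain(key.chain_id)
                model.add_chain(chains[key.chain_id])
            res = gemmi.Residue()
            res.name = key.resname or "UNK"
            res.seqid = gemmi.SeqId(key.resnum, key.icode or " ")
            for a in atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element or "X")
                atom.pos = gemmi.Position(*xyz[pos])
                atom.occ = 1.0
                pos += 1
                res.add_atom(atom)
            # add_chain copies; fetch the live chain from the model
            model[key.chain_id].add_residue(res)
        st.add_model(model)
    return st


def write_pdb(structure: Structure, path: str | Path,
              frames: Sequence[np.ndarray] | None = None) -> None:
    """Write a structure (or a frame stack as a multi-model PDB)."""
    st = _to_gemmi(structure, frames)
    st.write_pdb(str(path))


def write_mmcif(structure: Structure, path: str | Path) -> None:
    st = _to_gemmi(structure)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# trajectory ensembles
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryEnsemble:
    """R replicates x F frames on a shared topology.

    Replicates are kept separate; concatenation (and the discard of the
    initial equilibration fraction of each replicate) is an explicit choice
    made by the analysis operations via :meth:`analyzed_frames`.
    """

    topology: Structure
    replicates: list[np.ndarray]
    frame_interval_ns: float
    discard_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.frame_interval_ns <= 0:
            raise ParameterError("frame_interval_ns must be > 0")
        if not 0.0 <= self.discard_fraction < 1.0:
            raise ParameterError("discard_fraction must be in [0, 1)")
        n = self.topology.n_atoms
        reps = []
        for i, rep in enumerate(self.replicates):
            arr = np.asarray(rep, dtype=float)
            if arr.ndim != 3 or arr.shape[1] != n or arr.shape[2] != 3:
                raise CongruenceError(
                    f"replicate {i}: frames of shape {arr.shape[1:]} are not congruent "
                    f"with topology ({n} atoms)")
            reps.append(arr)
        self.replicates = reps

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def n_frames(self) -> int:
        return sum(r.shape[0] for r in self.replicates)

    def retained_slices(self, discard_fraction: float | None = None) -> list[slice]:
        """Per-replicate slice of frames kept after equilibration discard."""
        d = self.discard_fraction if discard_fraction is None else discard_fraction
        if not 0.0 <= d < 1.0:
            raise ParameterError("discard_fraction must be in [0, 1)")
        return [slice(int(round(r.shape[0] * d)), r.shape[0]) for r in self.replicates]

    def analyzed_frames(self, discard_fraction: float | None = None) -> np.ndarray:
        """Concatenated retained frames, shape (F_kept, n_atoms, 3)."""
        slices = self.retained_slices(discard_fraction)
        kept = [r[s] for r, s in zip(self.replicates, slices)]
        total = sum(k.shape[0] for k in kept)
        if total == 0:
            from .errors import AnalysisError
            raise AnalysisError("no frames remain after equilibration discard")
        return np.concatenate(kept, axis=0)


def read_ensemble(topology: Structure, frame_sources: Iterable[str | Path],
                  frame_interval_ns: float,
                  discard_fraction: float = 0.5) -> TrajectoryEnsemble:
    """Load one replicate per source file (multi-model PDB frame series).

    All frames are retained here; equilibration discard is applied by the
    analysis operations.
    """
    reps = []
    for i, src in enumerate(frame_sources):
        frames = read_frames(src)
        if frames.shape[1] != topology.n_atoms:
            raise CongruenceError(
                f"replicate {i} ({src}): {frames.shape[1]} atoms, "
                f"topology has {topology.n_atoms}")
        reps.append(frames)
    if not reps:
        raise EmptyInputError("no frame sources given")
    return TrajectoryEnsemble(topology, reps, frame_interval_ns, discard_fraction)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _parse_values(text: str) -> list[str]:
    return [v for v in text.replace(",", " ").split() if v]


def select(structure: Structure, expression: str, maps: Sequence | None = None) -> np.ndarray:
    """Atom indices matching a selection expression.

    Grammar: clauses joined by ``and``; each clause is ``field values`` with
    fields ``chain``, ``name``, ``element``, ``resname``, ``resnum`` (single
    numbers or ``lo-hi`` ranges), ``bw`` and ``cgn`` (generic labels, which
    require annotated ``maps``).  The result is a deterministic, order-stable
    index list; an empty match is an empty list, but naming an unknown chain
    or generic label is a :class:`SelectionError`.
    """
    arr = structure._arrays()
    mask = np.ones(structure.n_atoms, dtype=bool)
    expression = expression.strip()
    if not expression:
        raise SelectionError("empty selection expression")
    for clause in expression.split(" and "):
        parts = clause.strip().split(None, 1)
        if len(parts) != 2:
            raise SelectionError(f"cannot parse clause {clause.strip()!r}")
        fieldname, rest = parts[0].lower(), parts[1]
        values = _parse_values(rest)
        if fieldname == "chain":
            known = set(structure.chains())
            unknown = [v for v in values if v not in known]
            if unknown:
                raise SelectionError(f"unknown chain(s) {unknown} in {structure.id!r}")
            mask &= np.isin(arr["chain"], values)
        elif fieldname == "name":
            mask &= np.isin(arr["name"], values)
        elif fieldname == "element":
            mask &= np.isin(arr["element"], values)
        elif fieldname == "resname":
            mask &= np.isin(arr["resname"], values)
        elif fieldname == "resnum":
            m = np.zeros_like(mask)
            for v in values:
                if "-" in v[1:]:
                    cut = v.index("-", 1)
                    lo, hi = int(v[:cut]), int(v[cut + 1:])
                    m |= (arr["resnum"] >= lo) & (arr["resnum"] <= hi)
                else:
                    m |= arr["resnum"] == int(v)
            mask &= m
        elif fieldname in ("bw", "cgn"):
            if not maps:
                raise SelectionError(f"{fieldname!r} selection requires numbering maps")
            m = np.zeros_like(mask)
            for v in values:
                hit = None
                for nm in maps:
                    key = nm.lookup_position(v)
                    if key is not None:
                        hit = key
                        break
                if hit is None:
                    raise SelectionError(f"generic label {v!r} not found in any map")
                ri = structure.residue_index(hit)
                m |= arr["residx"] == ri
            mask &= m
        else:
            raise SelectionError(f"unknown selection field {fieldname!r}")
    return np.flatnonzero(mask)
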