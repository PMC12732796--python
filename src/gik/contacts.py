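"""Residue contacts, hydrogen bonds, and occupancy over trajectory ensembles.

Three contact criteria are used across the analyses:

* ``heavy_atom`` - two residues are in contact when the minimum distance over
  their heavy-atom pairs is within a cutoff (default 4.5 A, a common
  heavy-atom convention; every report echoes the cutoff actually used).
* ``hbond`` - donor-acceptor distance within 3.0 A and the D-H...A angle
  within 20 degrees of linear (the defaults of the VMD hydrogen-bond tool).
* ``polar`` - side-chain N/O atoms of polar or charged residues within
  4.0 A, with no angle term; this counts salt-bridge-like engagement rather
  than strict hydrogen bonds.

Occupancy of a pair is the exact fraction of analyzed frames in which the
criterion holds; the first ``discard_fraction`` of each replicate is treated
as equilibration and excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    AnalysisError,
    AtomMissingError,
    ParameterError,
    SelectionError,
)
from .structure_io import ResidueKey, Structure, TrajectoryEnsemble, select

HEAVY_CONTACT_CUTOFF = 4.5
POLAR_CONTACT_CUTOFF = 4.0
HBOND_DA_CUTOFF = 3.0
HBOND_ANGLE_CUTOFF = 20.0

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "HN"}
POLAR_RESNAMES = {"ARG", "LYS", "HIS", "ASP", "GLU", "SER", "THR",
                  "ASN", "GLN", "TYR", "TRP", "CYS"}


@dataclass
class ContactPair:
    """An unordered residue pair satisfying a contact criterion."""

    a: ResidueKey
    b: ResidueKey
    kind: str = "heavy_atom"
    min_distance: float = float("nan")
    label_a: object = None
    label_b: object = None

    def unordered_key(self):
        ka = (self.a.chain_id, self.a.resnum, self.a.icode)
        kb = (self.b.chain_id, self.b.resnum, self.b.icode)
        return frozenset((ka, kb))

    def generic_pair(self) -> tuple[str, str] | None:
        if self.label_a is None or self.label_b is None:
            return None
        return (str(self.label_a), str(self.label_b))

    def sort_key(self) -> tuple:
        gp = self.generic_pair()
        if gp is not None:
            return gp
        return (str(self.a), str(self.b))


@dataclass
class OccupancyRecord:
    """Per-pair contact persistence over the analyzed frames."""

    pair: ContactPair
    frames_present: int
    frames_total: int

    @property
    def occupancy(self) -> float:
        return self.frames_present / self.frames_total


# ---------------------------------------------------------------------------
# group handling
# ---------------------------------------------------------------------------

def _resolve_group(structure: Structure, group, maps=None) -> np.ndarray:
    if isinstance(group, str):
        idx = select(structure, group, maps)
    else:
        idx = np.asarray(group, dtype=int)
    if idx.size == 0:
        raise SelectionError("empty atom group")
    return idx


def _split_by_residue(structure: Structure, idx: np.ndarray,
                      atom_filter=None) -> list[tuple[int, np.ndarray]]:
    """Group atom indices by residue index, optionally filtering atoms."""
    arr = structure._arrays()
    if atom_filter is not None:
        keep = atom_filter(arr, idx)
        idx = idx[keep]
    out = []
    for ri in np.unique(arr["residx"][idx]):
        out.append((int(ri), idx[arr["residx"][idx] == ri]))
    return out


def _heavy_filter(arr, idx):
    return arr["element"][idx] != "H"


def _polar_sidechain_filter(arr, idx):
    heavy = np.isin(arr["element"][idx], ("N", "O"))
    sidechain = ~np.isin(arr["name"][idx], tuple(BACKBONE_ATOMS))
    polar_res = np.isin(arr["resname"][idx], tuple(POLAR_RESNAMES))
    return heavy & sidechain & polar_res


_KIND_FILTER = {"heavy_atom": _heavy_filter, "polar": _polar_sidechain_filter}
_KIND_CUTOFF = {"heavy_atom": HEAVY_CONTACT_CUTOFF, "polar": POLAR_CONTACT_CUTOFF}


def _label_of(structure: Structure, ri: int, maps):
    key = structure.residues[ri][0]
    for nm in maps or ():
        if nm.chain_id == key.chain_id:
            try:
                return nm.to_generic(key)
            except Exception:
                return None
    return None


# ---------------------------------------------------------------------------
# single-frame contacts
# ---------------------------------------------------------------------------

def heavy_atom_contacts(structure: Structure, group_a, group_b,
                        cutoff: float = HEAVY_CONTACT_CUTOFF, *,
                        coords: np.ndarray | None = None,
                        kind: str = "heavy_atom",
                        maps=None) -> list[ContactPair]:
    """Residue pairs of two disjoint groups with min atom distance <= cutoff.

    Uses a k-d tree over the group atoms; the result is symmetric in the two
    groups and sorted by the pair key for determinism.  ``kind='polar'``
    restricts atoms to polar side-chain N/O (cutoff then defaults to that
    criterion's own value via :func:`occupancy_map`; here the passed cutoff
    is used as-is).
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    ia = _resolve_group(structure, group_a, maps)
    ib = _resolve_group(structure, group_b, maps)
    if np.intersect1d(ia, ib).size:
        raise ParameterError("contact groups must be disjoint")
    xyz = structure.coords() if coords is None else np.asarray(coords, dtype=float)

    atom_filter = _KIND_FILTER[kind]
    res_a = _split_by_residue(structure, ia, atom_filter)
    res_b = _split_by_residue(structure, ib, atom_filter)
    if not res_a or not res_b:
        return []
    flat_a = np.concatenate([g for _, g in res_a])
    flat_b = np.concatenate([g for _, g in res_b])
    owner_a = np.concatenate([[ri] * len(g) for ri, g in res_a])
    owner_b = np.concatenate([[ri] * len(g) for ri, g in res_b])

    tree_a = cKDTree(xyz[flat_a])
    tree_b = cKDTree(xyz[flat_b])
    sdm = tree_a.sparse_distance_matrix(tree_b, cutoff, output_type="coo_matrix")

    best: dict[tuple[int, int], float] = {}
    for i, j, d in zip(sdm.row, sdm.col, sdm.data):
        kk = (int(owner_a[i]), int(owner_b[j]))
        if d < best.get(kk, np.inf):
            best[kk] = float(d)
    pairs = []
    for (ra, rb), d in best.items():
        pairs.append(ContactPair(structure.residues[ra][0], structure.residues[rb][0],
                                 kind=kind, min_distance=d,
                                 label_a=_label_of(structure, ra, maps),
                                 label_b=_label_of(structure, rb, maps)))
    pairs.sort(key=lambda p: p.sort_key())
    return pairs


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def hbond_present(coords: np.ndarray, donor: int, hydrogen: int | None, acceptor: int,
                  dist_cutoff: float = HBOND_DA_CUTOFF,
                  angle_cutoff: float = HBOND_ANGLE_CUTOFF) -> bool:
    """Geometric hydrogen-bond test for one D-H...A triple.

    True iff the donor-acceptor distance is within ``dist_cutoff`` and the
    D-H...A arrangement deviates from linearity by at most ``angle_cutoff``
    degrees.  A donor without an attached hydrogen is an error: callers that
    analyze heavy-atom-only models should fall back to a distance-only
    (``polar``) criterion instead.
    """
    coords = np.asarray(coords, dtype=float)
    if hydrogen is None:
        raise AtomMissingError(
            "donor has no attached hydrogen; use the heavy-atom-only 'polar' "
            "criterion for structures without hydrogens")
    d, h, a = coords[donor], coords[hydrogen], coords[acceptor]
    if np.linalg.norm(d - a) > dist_cutoff:
        return False
    v1, v2 = d - h, a - h
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return False
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))  # D-H...A angle; 180 = linear
    return bool((180.0 - angle) <= angle_cutoff)


def _hbond_triples(structure: Structure, idx_donor_side: np.ndarray,
                   idx_acceptor_side: np.ndarray) -> list[tuple[int, int, int]]:
    """Enumerate (donor, hydrogen, acceptor) triples between two groups."""
    arr = structure._arrays()
    xyz = arr["coords"]
    triples = []
    don = idx_donor_side[np.isin(arr["element"][idx_donor_side], ("N", "O", "S"))]
    acc = idx_acceptor_side[np.isin(arr["element"][idx_acceptor_side], ("N", "O", "S"))]
    if don.size == 0 or acc.size == 0:
        return []
    hyd_all = np.flatnonzero(arr["element"] == "H")
    for dd in don:
        same_res = hyd_all[arr["residx"][hyd_all] == arr["residx"][dd]]
        attached = same_res[np.linalg.norm(xyz[same_res] - xyz[dd], axis=1) < 1.3]
        for hh in attached:
            for aa in acc:
                triples.append((int(dd), int(hh), int(aa)))
    return triples


# ---------------------------------------------------------------------------
# ensemble occupancy
# ---------------------------------------------------------------------------

def _min_dist_series(frames: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    diff = frames[:, ia, None, :] - frames[:, None, ib, :]
    return np.sqrt((diff ** 2).sum(-1)).min(axis=(1, 2))


def occupancy_map(ensemble: TrajectoryEnsemble, group_a, group_b,
                  kind: str = "heavy_atom",
                  min_occupancy: float = 0.05,
                  cutoff: float | None = None,
                  discard_fraction: float | None = None,
                  maps=None,
                  hbond_dist: float = HBOND_DA_CUTOFF,
                  hbond_angle: float = HBOND_ANGLE_CUTOFF) -> list[OccupancyRecord]:
    """Per-pair contact occupancy over the retained frames of an ensemble.

    Returns records with occupancy >= ``min_occupancy`` (default 0.05, i.e.
    pairs present in at least 5% of the analyzed trajectory), sorted by
    descending occupancy with ties broken by the pair's lexicographic key.
    """
    if not 0.0 <= min_occupancy <= 1.0:
        raise ParameterError("min_occupancy must be in [0, 1]")
    topo = ensemble.topology
    ia = _resolve_group(topo, group_a, maps)
    ib = _resolve_group(topo, group_b, maps)
    if np.intersect1d(ia, ib).size:
        raise ParameterError("contact groups must be disjoint")
    frames = ensemble.analyzed_frames(discard_fraction)
    n_frames = frames.shape[0]
    if n_frames == 0:
        raise AnalysisError("no frames to analyze")

    records: list[OccupancyRecord] = []
    if kind in ("heavy_atom", "polar"):
        cut = _KIND_CUTOFF[kind] if cutoff is None else cutoff
        res_a = _split_by_residue(topo, ia, _KIND_FILTER[kind])
        res_b = _split_by_residue(topo, ib, _KIND_FILTER[kind])
        # coarse prefilter: exact distances only on frames where the residue
        # centroids are within reach of each other
        cent_a = {ra: frames[:, ga, :].mean(axis=1) for ra, ga in res_a}
        cent_b = {rb: frames[:, gb, :].mean(axis=1) for rb, gb in res_b}
        rad_a = {ra: _max_radius(frames, ga) for ra, ga in res_a}
        rad_b = {rb: _max_radius(frames, gb) for rb, gb in res_b}
        for ra, ga in res_a:
            for rb, gb in res_b:
                reach = cut + rad_a[ra] + rad_b[rb]
                cand = np.flatnonzero(
                    np.linalg.norm(cent_a[ra] - cent_b[rb], axis=1) <= reach)
                if cand.size == 0:
                    continue
                present = int((_min_dist_series(frames[cand], ga, gb) <= cut).sum())
                if present == 0:
                    continue
                records.append(_make_record(topo, ra, rb, kind, present, n_frames, maps))
    elif kind == "hbond":
        triples = _hbond_triples(topo, ia, ib) + _hbond_triples(topo, ib, ia)
        if not triples:
            raise AtomMissingError(
                "no donor-hydrogen-acceptor triples found between the groups; "
                "for hydrogen-free models use kind='polar'")
        arr = topo._arrays()
        per_pair: dict[tuple[int, int], np.ndarray] = {}
        for dd, hh, aa in triples:
            dvec = frames[:, dd] - frames[:, aa]
            da_ok = np.linalg.norm(dvec, axis=1) <= hbond_dist
            v1 = frames[:, dd] - frames[:, hh]
            v2 = frames[:, aa] - frames[:, hh]
            denom = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            cosang = np.clip((v1 * v2).sum(1) / np.where(denom == 0, np.inf, denom), -1, 1)
            ang_ok = (180.0 - np.degrees(np.arccos(cosang))) <= hbond_angle
            ok = da_ok & ang_ok
            ra, rb = int(arr["residx"][dd]), int(arr["residx"][aa])
            kk = (min(ra, rb), max(ra, rb))
            per_pair[kk] = per_pair.get(kk, np.zeros(n_frames, bool)) | ok
        for (ra, rb), mask in per_pair.items():
            present = int(mask.sum())
            if present:
                records.append(_make_record(topo, ra, rb, kind, present, n_frames, maps))
    else:
        raise ParameterError(f"unknown contact kind {kind!r}")

    records = [r for r in records if r.occupancy >= min_occupancy]
    records.sort(key=lambda r: (-r.occupancy, r.pair.sort_key()))
    return records


def _max_radius(frames: np.ndarray, idx: np.ndarray) -> float:
    c = frames[:, idx, :].mean(axis=1, keepdims=True)
    return float(np.linalg.norm(frames[:, idx, :] - c, axis=2).max())


def _make_record(topo: Structure, ra: int, rb: int, kind: str,
                 present: int, total: int, maps) -> OccupancyRecord:
    pair = ContactPair(topo.residues[ra][0], topo.residues[rb][0], kind=kind,
                       label_a=_label_of(topo, ra, maps),
                       label_b=_label_of(topo, rb, maps))
    return OccupancyRecord(pair, present, total)


# ---------------------------------------------------------------------------
# per-residue contact counts
# ---------------------------------------------------------------------------

def per_residue_contact_counts(source, residues, partner_group, maps,
                               cutoff: float = HEAVY_CONTACT_CUTOFF,
                               discard_fraction: float | None = None):
    """Mean number of partner residues contacted by each listed residue.

    ``source`` is either a :class:`TrajectoryEnsemble` (mean contacts per
    analyzed frame) or a list of :class:`Structure` (count per structure,
    then mean across the set).  ``residues`` are generic labels resolved
    through ``maps``.  Returns a DataFrame indexed by label with columns
    ``mean_count``, ``provenance`` and ``is_max`` (True on the argmax row;
    ties flag the first label in the given order).
    """
    import pandas as pd

    labels = [str(r) for r in residues]

    def resolve(structure: Structure, maps) -> dict[str, int]:
        out = {}
        for lab in labels:
            for nm in maps:
                key = nm.lookup_position(lab)
                if key is not None:
                    out[lab] = structure.residue_index(key)
                    break
            else:
                from .errors import MappingError
                raise MappingError(f"label {lab!r} not mapped")
        return out

    if isinstance(source, TrajectoryEnsemble):
        topo = source.topology
        idx_by_label = resolve(topo, maps)
        ib = _resolve_group(topo, partner_group, maps)
        res_b = _split_by_residue(topo, ib, _heavy_filter)
        frames = source.analyzed_frames(discard_fraction)
        n_frames = frames.shape[0]
        means = {}
        for lab, ri in idx_by_label.items():
            ga = topo.atom_indices_of_residue(ri)
            ga = ga[topo._arrays()["element"][ga] != "H"]
            count = np.zeros(n_frames)
            for rb, gb in res_b:
                if rb == ri:
                    continue
                count += (_min_dist_series(frames, ga, gb) <= cutoff)
            means[lab] = count.mean()
        provenance = f"ensemble:{n_frames}frames"
    else:
        # each item is a Structure (using the shared `maps`) or a
        # (Structure, maps) tuple when complexes carry their own annotation
        structures = [(it, maps) if isinstance(it, Structure) else tuple(it)
                      for it in source]
        per_struct = {lab: [] for lab in labels}
        for st, st_maps in structures:
            idx_by_label = resolve(st, st_maps)
            ib = _resolve_group(st, partner_group, st_maps)
            res_b = _split_by_residue(st, ib, _heavy_filter)
            xyz = st.coords()[None]
            for lab, ri in idx_by_label.items():
                ga = st.atom_indices_of_residue(ri)
                ga = ga[st._arrays()["element"][ga] != "H"]
                n = sum(1 for rb, gb in res_b
                        if rb != ri and _min_dist_series(xyz, ga, gb)[0] <= cutoff)
                per_struct[lab].append(n)
        means = {lab: float(np.mean(v)) for lab, v in per_struct.items()}
        provenance = f"structures:{len(structures)}"

    df = pd.DataFrame({"mean_count": [means[lab] for lab in labels]}, index=labels)
    df["provenance"] = provenance
    df["is_max"] = False
    df.loc[df["mean_count"].idxmax(), "is_max"] = True
    return df
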