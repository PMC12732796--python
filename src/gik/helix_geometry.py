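"""Helix-axis descriptors, membrane-frame projections, and TM distances.

The membrane normal is taken to be the +z axis of the input frame (OPM-style
orientation); the XZ and XY projections used to describe helix orientation
follow the input frame axes.  Inter-helix comparisons are only meaningful
after all structures are brought into a common receptor-aligned frame, which
:func:`superpose` provides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from MDAnalysis.analysis import align as _mda_align

from .errors import AtomMissingError, GeometryError, MappingError, SelectionError
from .numbering import GenericLabel, NumberingMap
from .structure_io import Structure


@dataclass
class HelixFrameDescriptor:
    """Axis (unit vector, N-to-C), centroid origin, length, and projections."""

    origin: np.ndarray
    axis: np.ndarray
    length: float
    projection_xz: np.ndarray  # (n, 2) Calpha coordinates in the x-z plane
    projection_xy: np.ndarray  # (n, 2) Calpha coordinates in the x-y plane


def helix_axis(ca_coords: np.ndarray) -> HelixFrameDescriptor:
    """Principal axis of an ordered Calpha trace, sign-fixed N-to-C.

    The axis is the leading principal component of the centered coordinates;
    its sign is chosen so that it points from the N-terminal half centroid
    toward the C-terminal half centroid.  Needs at least 4 points.
    """
    X = np.asarray(ca_coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 4:
        raise GeometryError("helix_axis needs an (n>=4, 3) Calpha array")
    origin = X.mean(axis=0)
    centered = X - origin
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    half = X.shape[0] // 2
    direction = X[half:].mean(axis=0) - X[:half].mean(axis=0)
    if axis @ direction < 0:
        axis = -axis
    axis = axis / np.linalg.norm(axis)
    t = centered @ axis
    return HelixFrameDescriptor(
        origin=origin,
        axis=axis,
        length=float(t.max() - t.min()),
        projection_xz=X[:, [0, 2]].copy(),
        projection_xy=X[:, [0, 1]].copy(),
    )


def tm_distance(structure: Structure, nmap: NumberingMap | list,
                label_a: GenericLabel | str, label_b: GenericLabel | str,
                coords: np.ndarray | None = None) -> float:
    """Calpha-Calpha distance between two generic positions (Angstrom).

    Used for the TM6-opening proxy (positions 6.33 on TM6 and 2.39 on TM2).
    Symmetric in its labels and invariant under rigid motion of the frame.
    """
    maps = nmap if isinstance(nmap, (list, tuple)) else [nmap]

    def ca_index(label):
        pos = str(label)
        for nm in maps:
            key = nm.lookup_position(pos)
            if key is not None:
                try:
                    return structure.atom_index(key, "CA")
                except SelectionError:
                    raise AtomMissingError(f"residue {key} has no CA atom") from None
        raise MappingError(f"label {pos!r} not mapped")

    ia, ib = ca_index(label_a), ca_index(label_b)
    xyz = structure.coords() if coords is None else np.asarray(coords, dtype=float)
    return float(np.linalg.norm(xyz[ia] - xyz[ib]))


def tm_distance_series(ensemble, nmap, label_a, label_b,
                       discard_fraction: float | None = None) -> np.ndarray:
    """TM distance for every analyzed frame of an ensemble."""
    maps = nmap if isinstance(nmap, (list, tuple)) else [nmap]
    topo = ensemble.topology

    def ca_index(label):
        for nm in maps:
            key = nm.lookup_position(str(label))
            if key is not None:
                return topo.atom_index(key, "CA")
        raise MappingError(f"label {label!r} not mapped")

    ia, ib = ca_index(label_a), ca_index(label_b)
    frames = ensemble.analyzed_frames(discard_fraction)
    return np.linalg.norm(frames[:, ia] - frames[:, ib], axis=1)


def orientation_compare(target: HelixFrameDescriptor,
                        references: list[HelixFrameDescriptor]) -> list[tuple[float, float]]:
    """Angle (degrees) and origin offset (Angstrom) of a helix vs references.

    All descriptors must have been extracted in a common receptor-aligned
    frame; the comparison itself is frame-free once that holds.
    """
    out = []
    for ref in references:
        cosang = float(np.clip(target.axis @ ref.axis, -1.0, 1.0))
        angle = float(np.degrees(np.arccos(cosang)))
        offset = float(np.linalg.norm(target.origin - ref.origin))
        out.append((angle, offset))
    return out


def nearest_family(target: HelixFrameDescriptor,
                   families: dict[str, list[HelixFrameDescriptor]]) -> str:
    """Family whose references have the smallest mean axis angle to the target."""
    best, best_angle = None, np.inf
    for name in sorted(families):
        angles = [a for a, _ in orientation_compare(target, families[name])]
        mean = float(np.mean(angles))
        if mean < best_angle:
            best, best_angle = name, mean
    if best is None:
        raise GeometryError("no reference families given")
    return best


def superpose(mobile_coords: np.ndarray, reference_coords: np.ndarray,
              fit_idx: np.ndarray) -> np.ndarray:
    """Least-squares fit of a full coordinate set onto a reference.

    The optimal rotation is computed on the ``fit_idx`` atoms (e.g. the 7TM
    bundle Calpha) and applied to all atoms.  Returns transformed copies.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    fit_idx = np.asarray(fit_idx, dtype=int)
    mc = mob[fit_idx].mean(axis=0)
    rc = ref[fit_idx].mean(axis=0)
    R, _ = _mda_align.rotation_matrix(mob[fit_idx] - mc, ref[fit_idx] - rc)
    return (mob - mc) @ np.asarray(R).T + rc
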