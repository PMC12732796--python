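"""RMSD, block-averaged statistics, and GROMOS conformational clustering.

Block averaging treats a correlated per-frame RMSD series as a set of
quasi-independent block means (default 50 frames per block at 1 frame/ns);
the per-replicate mean and SEM come from those block means, and the
across-replicate estimate treats each replicate mean as one independent
observation (sample standard deviation, n-1, divided by sqrt(R)).

Clustering follows the GROMOS neighbor-count scheme: on a pairwise RMSD
matrix, the frame with the most neighbors within the cutoff becomes a
cluster center, its neighborhood is assigned and removed, and the procedure
repeats.  Ties break toward the lowest frame index, making the result
deterministic.  For clustering the *position* of a structural element the
frames are first brought into a common frame by fitting on a separate
selection (e.g. the receptor), and the pairwise RMSD of the analysis
selection is then computed without further fitting; a ``superpose=True``
path is available for clustering internal shape instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from MDAnalysis.analysis import rms as _mda_rms

from .errors import AnalysisError, CongruenceError, GikError, ParameterError
from .structure_io import TrajectoryEnsemble


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = True) -> float:
    """Root-mean-square deviation between two coordinate sets (Angstrom).

    With ``superpose=True`` the optimal least-squares (Kabsch) fit is applied
    first, making the value invariant to rigid motion of either input.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise CongruenceError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if superpose:
        return float(_mda_rms.rmsd(a, b, center=True, superposition=True))
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


@dataclass
class RmsdSeries:
    """Per-frame RMSD time series of one replicate."""

    replicate_id: int
    values: np.ndarray
    frame_interval_ns: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if np.any(self.values < 0):
            raise ParameterError("RMSD values must be non-negative")


def rmsd_series(ensemble: TrajectoryEnsemble, reference: np.ndarray,
                selection_idx: np.ndarray, superpose: bool = True,
                discard_fraction: float | None = None) -> list[RmsdSeries]:
    """Per-replicate RMSD time series against a common reference.

    Each retained frame's selected atoms are least-squares fitted to the
    corresponding reference atoms before the deviation is measured.
    """
    sel = np.asarray(selection_idx, dtype=int)
    ref = np.asarray(reference, dtype=float)[sel]
    out = []
    for rid, (rep, sl) in enumerate(zip(ensemble.replicates,
                                        ensemble.retained_slices(discard_fraction))):
        vals = [rmsd(frame[sel], ref, superpose=superpose) for frame in rep[sl]]
        out.append(RmsdSeries(rid, np.array(vals), ensemble.frame_interval_ns))
    return out


# ---------------------------------------------------------------------------
# block statistics
# ---------------------------------------------------------------------------

@dataclass
class ReplicateBlockStats:
    replicate_id: int
    block_means: np.ndarray
    mean: float
    sem: float


@dataclass
class BlockStats:
    """Per-replicate block means/SEM and the across-replicate estimate."""

    block_size_frames: int
    per_replicate: list[ReplicateBlockStats]
    ensemble_mean: float
    ensemble_sem: float
    dropped_frames: int = 0


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


def block_stats(series_set, block_size: int) -> BlockStats:
    """Block-averaged statistics over a set of RMSD series.

    Each series is divided into non-overlapping blocks of ``block_size``
    frames (a trailing partial block is dropped and counted in
    ``dropped_frames``).  The replicate mean is the mean of its block means;
    the across-replicate mean and SEM treat each replicate mean as one
    independent observation.
    """
    if block_size < 1:
        raise ParameterError("block_size must be >= 1")
    per_rep, dropped = [], 0
    for rid, series in enumerate(series_set):
        if isinstance(series, RmsdSeries):
            vals, rep_id = series.values, series.replicate_id
        else:
            vals, rep_id = np.asarray(series, dtype=float).ravel(), rid
        n_blocks = vals.size // block_size
        if n_blocks == 0:
            raise ParameterError(
                f"replicate {rep_id}: block_size {block_size} exceeds series "
                f"length {vals.size}")
        dropped += vals.size - n_blocks * block_size
        blocks = vals[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)
        per_rep.append(ReplicateBlockStats(rep_id, blocks,
                                           float(blocks.mean()), _sem(blocks)))
    if not per_rep:
        raise AnalysisError("no series given")
    rep_means = np.array([r.mean for r in per_rep])
    return BlockStats(block_size, per_rep,
                      float(rep_means.mean()), _sem(rep_means), dropped)


def population_percentages(counts, anchor_count: int, anchor_percent: float):
    """Cluster percentages from frame counts plus one (count, percent) anchor.

    Infers the total analyzed-frame number from the anchor cluster and
    expresses every count as a percentage of it (1-dp rounding).  Returns
    ``(percentages, inferred_total)``.
    """
    if anchor_percent <= 0 or anchor_count <= 0:
        raise ParameterError("anchor count and percent must be positive")
    total = int(round(anchor_count / (anchor_percent / 100.0)))
    return [round(100.0 * c / total, 1) for c in counts], total


# ---------------------------------------------------------------------------
# GROMOS clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Frame assignments, populations, medoids and centers of one clustering."""

    assignments: np.ndarray          # frame -> cluster id (1-based)
    populations: dict                # id -> (count, fraction of analyzed frames)
    medoids: dict                    # id -> frame index (min mean RMSD to members)
    centers: dict                    # id -> frame index (max neighbor count)
    cutoff: float
    n_frames: int

    def sorted_ids(self) -> list[int]:
        return sorted(self.populations, key=lambda c: (-self.populations[c][0], c))


def _pairwise_rmsd_matrix(frames: np.ndarray, superpose: bool) -> np.ndarray:
    F, A, _ = frames.shape
    if not superpose:
        flat = frames.reshape(F, -1)
        sq = (flat ** 2).sum(axis=1)
        gram = flat @ flat.T
        d2 = (sq[:, None] + sq[None, :] - 2.0 * gram) / A
        np.maximum(d2, 0.0, out=d2)
        return np.sqrt(d2, dtype=np.float64).astype(np.float32)
    D = np.zeros((F, F), dtype=np.float32)
    for i in range(F):
        for j in range(i + 1, F):
            D[i, j] = D[j, i] = rmsd(frames[i], frames[j], superpose=True)
    return D


def cluster_frames(frames_or_ensemble, selection_idx: np.ndarray | None = None,
                   cutoff: float = 1.5, superpose: bool = False,
                   fit_idx: np.ndarray | None = None,
                   reference: np.ndarray | None = None,
                   discard_fraction: float | None = None) -> ClusterResult:
    """GROMOS neighbor-count clustering of frames on pairwise Calpha RMSD.

    ``frames_or_ensemble`` is a (F, A, 3) array or a TrajectoryEnsemble (in
    which case ``selection_idx`` picks the analysis atoms from the retained
    frames).  ``fit_idx`` optionally superposes every frame onto the
    reference (topology coordinates by default) on a separate fit selection
    before positional RMSDs are computed.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    if isinstance(frames_or_ensemble, TrajectoryEnsemble):
        ens = frames_or_ensemble
        all_frames = ens.analyzed_frames(discard_fraction)
        if fit_idx is not None:
            from .helix_geometry import superpose as _fit
            ref = ens.topology.coords() if reference is None else reference
            all_frames = np.stack([_fit(f, ref, fit_idx) for f in all_frames])
        frames = all_frames if selection_idx is None else all_frames[:, np.asarray(selection_idx, int), :]
    else:
        frames = np.asarray(frames_or_ensemble, dtype=float)
        if selection_idx is not None:
            frames = frames[:, np.asarray(selection_idx, int), :]
    if frames.ndim != 3:
        raise ParameterError("frames must have shape (F, A, 3)")
    F = frames.shape[0]
    if F < 1:
        raise AnalysisError("no frames to cluster")

    D = _pairwise_rmsd_matrix(frames, superpose)
    adjacency = D <= cutoff  # includes self

    assignments = np.zeros(F, dtype=int)
    counts = adjacency.sum(axis=1).astype(np.int64)
    active = np.ones(F, dtype=bool)
    populations, medoids, centers = {}, {}, {}
    cid = 0
    while active.any():
        cid += 1
        masked = np.where(active, counts, -1)
        center = int(masked.argmax())  # argmax -> lowest index on ties
        members = np.flatnonzero(active & adjacency[center])
        sub = D[np.ix_(members, members)]
        medoids[cid] = int(members[int(sub.mean(axis=1).argmin())])
        centers[cid] = center
        assignments[members] = cid
        populations[cid] = (int(members.size), members.size / F)
        counts -= adjacency[:, members].sum(axis=1)
        active[members] = False
    return ClusterResult(assignments, populations, medoids, centers,
                         cutoff=float(cutoff), n_frames=F)


def representative(result: ClusterResult, cluster_id: int) -> int:
    """Medoid frame of a cluster (minimal mean RMSD to its members)."""
    try:
        return result.medoids[cluster_id]
    except KeyError:
        raise GikError(f"unknown cluster id {cluster_id}") from None
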