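"""Config-driven workflows composing the analysis layers.

Two workflows are provided, each writing a small set of text artifacts plus a
run log that records every parameter actually used:

* ``restraints`` - the conservation funnel: alignment -> shared interface ->
  contact conservation -> residue-level docking restraints (TSV + ClusPro-style
  JSON + funnel provenance).
* ``ensemble`` - trajectory characterization: GROMOS clustering of the
  docked-helix position, contact occupancy, a TM-distance series summary, and
  block-averaged RMSD statistics.

Outputs are deterministic: rerunning the same config writes byte-identical
files (sorted keys, fixed float formats, no timestamps).  Inputs may be real
files (topology + multi-model PDB frame sets) or, by default, the packaged
synthetic scenario generated from the config's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import contacts as cts
from . import ensemble_stats as es
from . import helix_geometry as hg
from . import synthetic_data as sd
from .errors import InputError, ParameterError
from .structure_io import read_ensemble, read_structure

_WORKFLOWS = ("restraints", "ensemble")


@dataclass
class RunConfig:
    """Validated workflow configuration (YAML-backed)."""

    workflow: str
    seed: int = 0
    out_dir: str = "results"
    # restraint workflow
    conservation_min: float = 0.77
    contact_cutoff: float = cts.HEAVY_CONTACT_CUTOFF
    max_distance: float = 5.0
    n_per_family: int = 4
    # ensemble workflow
    n_replicates: int = 12
    frames_per_replicate: int = 625
    frame_interval_ns: float = 1.0
    discard_fraction: float = 0.5
    cluster_cutoff: float = 1.5
    block_size: int = 50
    min_occupancy: float = 0.05
    tm_labels: tuple = ("6.33", "2.39")
    # optional file inputs (default: synthetic scenario from `seed`)
    topology: str | None = None
    frame_files: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.workflow not in _WORKFLOWS:
            raise ParameterError(
                f"unknown workflow {self.workflow!r} (expected one of {_WORKFLOWS})")
        if not 0 <= self.seed < 2**31:
            raise ParameterError("seed must be in [0, 2^31)")

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"no such config file: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict) or "workflow" not in raw:
            raise InputError(f"{path}: config must be a mapping with a 'workflow' key")
        known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        if "tm_labels" in kwargs:
            kwargs["tm_labels"] = tuple(str(x) for x in kwargs["tm_labels"])
        return RunConfig(extra=extra, **kwargs)


def load_packaged_alignment() -> pd.DataFrame:
    """The packaged Galpha H5 subfamily alignment fixture."""
    with resources.files("gik").joinpath("data/galpha_h5_alignment.synthetic.tsv").open("r") as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def _log_lines(cfg: RunConfig, params: dict) -> str:
    lines = [f"workflow={cfg.workflow}", f"seed={cfg.seed}"]
    lines += [f"{k}={v}" for k, v in sorted(params.items())]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# restraint workflow
# ---------------------------------------------------------------------------

def run_restraint_workflow(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the conservation funnel and write restraint artifacts.

    Returns a summary dict mirroring ``funnel.json``.
    """
    out = Path(out_dir or cfg.out_dir)
    alignment, gi_set, gs_set, target = sd.funnel_fixture(
        seed=cfg.seed, n_per_family=cfg.n_per_family)
    sel = cons.select_restraints(
        alignment, gi_set, gs_set, target.receptor_map, target.galpha_map,
        cutoff=cfg.contact_cutoff, conservation_min=cfg.conservation_min,
        max_distance=cfg.max_distance)

    _write(out / "restraints.tsv", cons.restraints_to_tsv(sel))
    _write(out / "restraints.cluspro.json", cons.restraints_to_cluspro_json(sel) + "\n")
    summary = {
        "stage_counts": list(sel.stage_counts),
        "conserved_h5": [str(l) for l in sel.conserved_h5],
        "shared_positions": [str(l) for l in sel.shared_positions],
        "final_positions": [str(l) for l in sel.final_positions],
        "partners": dict(sorted(sel.partners.items())),
        "restraints": [
            {"receptor": str(r.receptor_key), "receptor_label": str(r.receptor_label),
             "galpha": str(r.galpha_key), "galpha_label": str(r.galpha_label),
             "max_distance": r.max_distance}
            for r in sel.restraints],
        "parameters": sel.parameters,
        "message": sel.message,
    }
    _write(out / "funnel.json", json.dumps(summary, indent=2, sort_keys=True) + "\n")
    _write(out / "run.log", _log_lines(cfg, sel.parameters))
    return summary


# ---------------------------------------------------------------------------
# ensemble workflow
# ---------------------------------------------------------------------------

def _load_or_generate(cfg: RunConfig):
    """(ensemble, record) from file inputs or the synthetic scenario."""
    spec = sd.ScenarioSpec(
        seed=cfg.seed, n_replicates=cfg.n_replicates,
        frames_per_replicate=cfg.frames_per_replicate,
        frame_interval_ns=cfg.frame_interval_ns,
        planted_contacts=[sd.PlantedContact("3.54", "H5.20", 1.0),
                          sd.PlantedContact("6.33", "H5.25", 1.0)])
    record = sd.make_complex(spec, verify=False)
    if cfg.topology:
        topo = read_structure(cfg.topology)
        if not cfg.frame_files:
            raise InputError("ensemble workflow with a topology needs frame_files")
        ens = read_ensemble(topo, cfg.frame_files, cfg.frame_interval_ns,
                            cfg.discard_fraction)
        return ens, None
    ens = sd.make_ensemble(spec)
    ens.discard_fraction = cfg.discard_fraction
    return ens, record


def run_ensemble_report(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Cluster, occupancy, TM-distance and block-RMSD report for an ensemble."""
    out = Path(out_dir or cfg.out_dir)
    ens, record = _load_or_generate(cfg)
    if record is None:
        raise InputError(
            "file-based ensembles need annotated numbering maps; this workflow "
            "currently reports on the synthetic scenario (omit 'topology')")
    maps = [record.receptor_map, record.galpha_map]
    sel_idx = sd.h5_ca_indices(record)
    fit_idx = sd.receptor_ca_indices(record)

    clus = es.cluster_frames(ens, selection_idx=sel_idx, cutoff=cfg.cluster_cutoff,
                             fit_idx=fit_idx)
    occ = cts.occupancy_map(ens, "chain R", "chain G", kind="heavy_atom",
                            min_occupancy=cfg.min_occupancy, maps=maps)
    tm = hg.tm_distance_series(ens, [record.receptor_map, record.galpha_map],
                               cfg.tm_labels[0], cfg.tm_labels[1])
    series = es.rmsd_series(ens, ens.topology.coords(), sel_idx, superpose=False)
    blocks = es.block_stats(series, cfg.block_size)

    clus_rows = ["cluster_id\tcount\tfraction\tmedoid_frame"]
    for cid in clus.sorted_ids():
        n, frac = clus.populations[cid]
        clus_rows.append(f"{cid}\t{n}\t{frac:.4f}\t{clus.medoids[cid]}")
    _write(out / "clusters.tsv", "\n".join(clus_rows) + "\n")

    occ_rows = ["residue_a\tlabel_a\tresidue_b\tlabel_b\toccupancy"]
    for r in occ:
        occ_rows.append(f"{r.pair.a}\t{r.pair.label_a or ''}\t{r.pair.b}\t"
                        f"{r.pair.label_b or ''}\t{r.occupancy:.4f}")
    _write(out / "occupancy.tsv", "\n".join(occ_rows) + "\n")

    blk_rows = ["replicate\tmean_A\tsem_A\tn_blocks"]
    for rep in blocks.per_replicate:
        blk_rows.append(f"{rep.replicate_id}\t{rep.mean:.4f}\t{rep.sem:.4f}"
                        f"\t{rep.block_means.size}")
    blk_rows.append(f"ensemble\t{blocks.ensemble_mean:.4f}\t{blocks.ensemble_sem:.4f}"
                    f"\t{len(blocks.per_replicate)}")
    _write(out / "rmsd_blocks.tsv", "\n".join(blk_rows) + "\n")

    params = {
        "cluster_cutoff": cfg.cluster_cutoff, "block_size": cfg.block_size,
        "min_occupancy": cfg.min_occupancy,
        "discard_fraction": ens.discard_fraction,
        "tm_labels": "-".join(cfg.tm_labels),
        "n_replicates": ens.n_replicates, "n_frames_analyzed": clus.n_frames,
    }
    summary = {
        "clusters": [{"id": cid, "count": clus.populations[cid][0],
                      "fraction": round(clus.populations[cid][1], 4),
                      "medoid_frame": clus.medoids[cid]}
                     for cid in clus.sorted_ids()],
        "occupancy": [{"pair": list(r.pair.generic_pair() or
                                    (str(r.pair.a), str(r.pair.b))),
                       "occupancy": round(r.occupancy, 4)} for r in occ],
        "tm_distance": {"labels": list(cfg.tm_labels),
                        "mean_A": round(float(tm.mean()), 3),
                        "sd_A": round(float(tm.std(ddof=1)), 3)},
        "rmsd_blocks": {"ensemble_mean_A": round(blocks.ensemble_mean, 4),
                        "ensemble_sem_A": round(blocks.ensemble_sem, 4),
                        "block_size_frames": blocks.block_size_frames},
        "parameters": params,
    }
    _write(out / "report.json", json.dumps(summary, indent=2, sort_keys=True) + "\n")
    _write(out / "run.log", _log_lines(cfg, params))
    return summary


def run(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Dispatch a config to its workflow."""
    if cfg.workflow == "restraints":
        return run_restraint_workflow(cfg, out_dir)
    return run_ensemble_report(cfg, out_dir)
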