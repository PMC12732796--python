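"""Contact conservation over complex sets and docking-restraint selection.

The restraint-selection workflow narrows Galpha alpha5-helix (H5) positions
through a funnel:

1. positions fully conserved in sequence across Galpha subfamilies;
2. of those, positions found at the receptor interface in both the Gi-bound
   and the Gs-bound structure sets;
3. of those, positions whose receptor contact is itself conserved (present in
   at least ``conservation_min`` of each family set, default 0.77);
4. surviving positions are paired with their modal receptor partner and
   mapped onto the target proteins as residue-level docking restraints.

"Interface conservation" of a generic contact pair over a structure set is
tabulated exactly: the fraction of complexes in which the pair is in
heavy-atom contact at the stated cutoff.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

from .contacts import HEAVY_CONTACT_CUTOFF, heavy_atom_contacts
from .errors import AlignmentError, EmptyInputError, InputError, ParameterError
from .numbering import GenericLabel, NumberingMap
from .structure_io import ResidueKey, Structure

# ClusPro publishes its model score as a weighted sum of component energies;
# the weights are recorded here as metadata and applied by
# `cluspro_weighted_score` to user-supplied component values.  Computing the
# component energies themselves is out of scope.
CLUSPRO_WEIGHTS = {"e_rep": 0.40, "e_att": -0.40, "e_elect": 600.0, "e_dars": 1.00}


def cluspro_weighted_score(e_rep: float, e_att: float, e_elect: float,
                           e_dars: float, weights: dict = CLUSPRO_WEIGHTS) -> float:
    return (weights["e_rep"] * e_rep + weights["e_att"] * e_att
            + weights["e_elect"] * e_elect + weights["e_dars"] * e_dars)


@dataclass
class ComplexRecord:
    """One annotated receptor-Galpha complex."""

    id: str
    structure: Structure
    receptor_map: NumberingMap
    galpha_map: NumberingMap
    family: str = "other"  # Gs | Gi | Gq | other


@dataclass
class RestraintPair:
    """A residue-level docking restraint between receptor and Galpha."""

    receptor_key: ResidueKey
    receptor_label: GenericLabel
    galpha_key: ResidueKey
    galpha_label: GenericLabel
    max_distance: float = 5.0


class ConservationTable:
    """Per generic contact pair, the fraction of a complex set containing it."""

    def __init__(self, counts: dict, n_total: int, cutoff: float):
        self._counts = dict(counts)  # (receptor_pos, galpha_pos) -> n_present
        self.n_total = n_total
        self.cutoff = cutoff

    def fraction(self, pair: tuple[str, str]) -> float:
        return self._counts.get(pair, 0) / self.n_total

    def count(self, pair: tuple[str, str]) -> int:
        return self._counts.get(pair, 0)

    def pairs(self) -> dict:
        return {p: (n, self.n_total, n / self.n_total) for p, n in self._counts.items()}

    def __len__(self) -> int:
        return len(self._counts)


# ---------------------------------------------------------------------------
# per-complex interface extraction
# ---------------------------------------------------------------------------

def complex_contact_pairs(cx: ComplexRecord,
                          cutoff: float = HEAVY_CONTACT_CUTOFF) -> set[tuple[str, str]]:
    """Generic (receptor, Galpha) contact pairs of one complex.

    Only residues carrying a generic label on both sides are reported.
    """
    arr = cx.structure._arrays()
    import numpy as np
    ia = np.flatnonzero(arr["chain"] == cx.receptor_map.chain_id)
    ib = np.flatnonzero(arr["chain"] == cx.galpha_map.chain_id)
    pairs = heavy_atom_contacts(cx.structure, ia, ib, cutoff,
                                maps=[cx.receptor_map, cx.galpha_map])
    out = set()
    for p in pairs:
        gp = p.generic_pair()
        if gp is not None:
            out.add(gp)
    return out


# ---------------------------------------------------------------------------
# funnel stages
# ---------------------------------------------------------------------------

def h5_conserved_positions(alignment) -> list[GenericLabel]:
    """H5 positions with exactly one residue type across all aligned sequences.

    ``alignment`` is a DataFrame whose columns are CGN position strings and
    whose rows are Galpha subfamily sequences (single letters; gaps count as
    a distinct type).  Needs at least two sequences.
    """
    if len(alignment) < 2:
        raise AlignmentError("alignment needs at least two sequences")
    conserved = []
    for col in alignment.columns:
        try:
            label = GenericLabel.parse(str(col), "CGN")
        except ParameterError as exc:
            raise AlignmentError(f"alignment column {col!r} is not a CGN label") from exc
        if label.segment != "H5":
            continue
        values = set(str(v) for v in alignment[col])
        if len(values) == 1:
            conserved.append(label)
    conserved.sort(key=lambda l: l.position)
    return conserved


def _positions_at_interface(cx: ComplexRecord, cutoff: float) -> set[str]:
    return {gpos for _, gpos in complex_contact_pairs(cx, cutoff)}


def shared_interface_positions(gi_set: list[ComplexRecord], gs_set: list[ComplexRecord],
                               candidates: list[GenericLabel],
                               cutoff: float = HEAVY_CONTACT_CUTOFF,
                               membership: str = "any") -> list[GenericLabel]:
    """Candidate Galpha positions at the receptor interface in BOTH family sets.

    ``membership='any'`` (default) requires at least one complex per set;
    ``'majority'`` requires more than half of each set.
    """
    if not gi_set or not gs_set:
        raise EmptyInputError("both family sets must be non-empty")
    if membership not in ("any", "majority"):
        raise ParameterError(f"unknown membership rule {membership!r}")

    def present(positions_per_complex: list[set[str]], pos: str) -> bool:
        hits = sum(pos in s for s in positions_per_complex)
        need = 1 if membership == "any" else len(positions_per_complex) // 2 + 1
        return hits >= need

    gi_pos = [_positions_at_interface(cx, cutoff) for cx in gi_set]
    gs_pos = [_positions_at_interface(cx, cutoff) for cx in gs_set]
    return [lab for lab in candidates
            if present(gi_pos, lab.position) and present(gs_pos, lab.position)]


def build_conservation_table(complexes: list[ComplexRecord],
                             cutoff: float = HEAVY_CONTACT_CUTOFF) -> ConservationTable:
    """Exact contact-pair counts over a set of complexes."""
    if not complexes:
        raise EmptyInputError("empty complex set")
    ids = [cx.id for cx in complexes]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate complex ids in set")
    counts: Counter = Counter()
    for cx in complexes:
        counts.update(complex_contact_pairs(cx, cutoff))
    return ConservationTable(counts, len(complexes), cutoff)


def conserved_pairs(table: ConservationTable, min_fraction: float) -> list[tuple]:
    """Pairs at or above a conservation threshold, sorted by fraction desc.

    Returns ``[((receptor_pos, galpha_pos), fraction), ...]``.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ParameterError("min_fraction must be in (0, 1]")
    hits = [(p, n / table.n_total) for p, n in table._counts.items()
            if n / table.n_total >= min_fraction]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits


def check_model_contacts(model: ComplexRecord, reference_pairs,
                         cutoff: float = HEAVY_CONTACT_CUTOFF):
    """Partition reference generic pairs by presence in a model.

    Returns ``(preserved, missing, unmappable)``: an exhaustive, disjoint
    partition.  A pair whose label is absent from the model's numbering maps
    is reported as unmappable rather than silently dropped.
    """
    refs = [(str(a), str(b)) for a, b in reference_pairs]
    model_pairs = complex_contact_pairs(model, cutoff)
    preserved, missing, unmappable = [], [], []
    for rpos, gpos in refs:
        if (model.receptor_map.lookup_position(rpos) is None
                or model.galpha_map.lookup_position(gpos) is None):
            unmappable.append((rpos, gpos))
        elif (rpos, gpos) in model_pairs:
            preserved.append((rpos, gpos))
        else:
            missing.append((rpos, gpos))
    return preserved, missing, unmappable


# ---------------------------------------------------------------------------
# the full restraint-selection workflow
# ---------------------------------------------------------------------------

@dataclass
class RestraintSelection:
    """Outcome of the funnel with per-stage survivors for provenance."""

    restraints: list[RestraintPair]
    stage_counts: tuple[int, int, int]
    conserved_h5: list[GenericLabel]
    shared_positions: list[GenericLabel]
    final_positions: list[GenericLabel]
    partners: dict
    parameters: dict = field(default_factory=dict)
    message: str = ""


def select_restraints(alignment, gi_set: list[ComplexRecord], gs_set: list[ComplexRecord],
                      receptor_map: NumberingMap, galpha_map: NumberingMap,
                      cutoff: float = HEAVY_CONTACT_CUTOFF,
                      conservation_min: float = 0.77,
                      max_distance: float = 5.0) -> RestraintSelection:
    """Run the funnel and emit residue-level docking restraints.

    A Galpha position survives the final stage when it contacts some receptor
    position in at least ``conservation_min`` of the complexes of *each*
    family set; it is then paired with its modal receptor partner (most
    frequent across both sets, ties to the lexicographically smaller label).
    An empty survivor set is a reported outcome, not an error.
    """
    stage1 = h5_conserved_positions(alignment)
    stage2 = shared_interface_positions(gi_set, gs_set, stage1, cutoff) if stage1 else []

    gi_pairs = [complex_contact_pairs(cx, cutoff) for cx in gi_set]
    gs_pairs = [complex_contact_pairs(cx, cutoff) for cx in gs_set]

    final, partners = [], {}
    for lab in stage2:
        fracs = []
        for fam_pairs in (gi_pairs, gs_pairs):
            hits = sum(any(g == lab.position for _, g in s) for s in fam_pairs)
            fracs.append(hits / len(fam_pairs))
        if all(f >= conservation_min for f in fracs):
            partner_counts = Counter()
            for s in gi_pairs + gs_pairs:
                partner_counts.update(r for r, g in s if g == lab.position)
            modal = min((p for p, n in partner_counts.items()
                         if n == max(partner_counts.values())))
            final.append(lab)
            partners[lab.position] = modal

    restraints = []
    for lab in final:
        rpos = partners[lab.position]
        rkey = receptor_map.lookup_position(rpos)
        gkey = galpha_map.lookup_position(lab.position)
        if rkey is None or gkey is None:
            continue
        restraints.append(RestraintPair(rkey, GenericLabel.parse(rpos, "BW"),
                                        gkey, lab, max_distance))

    counts = (len(stage1), len(stage2), len(final))
    msg = "" if restraints else (
        f"no restraints derivable; stage survivors {counts[0]} -> {counts[1]} -> {counts[2]}")
    return RestraintSelection(
        restraints, counts, stage1, stage2, final, partners,
        parameters={"cutoff": cutoff, "conservation_min": conservation_min,
                    "max_distance": max_distance},
        message=msg)


def restraints_to_tsv(sel: RestraintSelection) -> str:
    lines = ["# cutoff=%.2f conservation_min=%.2f max_distance=%.2f" % (
        sel.parameters.get("cutoff", float("nan")),
        sel.parameters.get("conservation_min", float("nan")),
        sel.parameters.get("max_distance", float("nan"))),
        "receptor_label\treceptor_residue\tgalpha_label\tgalpha_residue\tmax_distance"]
    for r in sel.restraints:
        lines.append(f"{r.receptor_label}\t{r.receptor_key}\t{r.galpha_label}\t"
                     f"{r.galpha_key}\t{r.max_distance:.1f}")
    return "\n".join(lines) + "\n"


def restraints_to_cluspro_json(sel: RestraintSelection) -> str:
    """Attraction restraints in a ClusPro-style JSON shape."""
    groups = [{
        "required": len(sel.restraints),
        "restraints": [
            {"rec_chain": r.receptor_key.chain_id, "rec_resid": r.receptor_key.resnum,
             "lig_chain": r.galpha_key.chain_id, "lig_resid": r.galpha_key.resnum,
             "dmax": r.max_distance, "dmin": 2.0}
            for r in sel.restraints],
    }]
    return json.dumps({"groups": groups}, indent=2, sort_keys=True)
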