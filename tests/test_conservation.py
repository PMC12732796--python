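import itertools

import pytest

from gik import synthetic_data as sd
from gik.conservation import (
    CLUSPRO_WEIGHTS,
    build_conservation_table,
    check_model_contacts,
    cluspro_weighted_score,
    complex_contact_pairs,
    conserved_pairs,
    h5_conserved_positions,
    restraints_to_cluspro_json,
    restraints_to_tsv,
    select_restraints,
    shared_interface_positions,
)
from gik.errors import AlignmentError, EmptyInputError, InputError, ParameterError
from gik.numbering import parse_label


def _complex_set(pair_presence, seed=3, family="Gs"):
    """One complex per row; each row maps (rpos, gpos) -> on/off."""
    out = []
    for i, row in enumerate(pair_presence):
        contacts = [sd.PlantedContact(r, g, 1.0 if on else 0.0)
                    for (r, g), on in row.items()]
        out.append(sd.make_complex(sd.ScenarioSpec(
            seed=seed, planted_contacts=contacts, family=family,
            complex_id=f"{family}-{i}")))
    return out


def test_conservation_table_matches_brute_force_recount():
    pair1, pair2 = ("3.54", "H5.20"), ("6.33", "H5.25")
    presence = [{pair1: True, pair2: True},
                {pair1: True, pair2: False},
                {pair1: True, pair2: True},
                {pair1: False, pair2: True}]
    complexes = _complex_set(presence)
    table = build_conservation_table(complexes)
    assert table.n_total == 4
    assert table.fraction(pair1) == pytest.approx(3 / 4)
    assert table.fraction(pair2) == pytest.approx(3 / 4)
    assert table.fraction(("1.40", "H5.01")) == 0.0
    # oracle: recount contacts per complex with the per-complex extractor
    recount = {}
    for cx in complexes:
        for p in complex_contact_pairs(cx):
            recount[p] = recount.get(p, 0) + 1
    assert {p: table.count(p) for p in recount} == recount
    assert sum(table.count(p) for p in (pair1, pair2)) == 6


def test_conserved_pairs_threshold_and_order():
    presence = [{("3.54", "H5.20"): True, ("6.33", "H5.25"): i < 3}
                for i in range(4)]
    table = build_conservation_table(_complex_set(presence))
    hits = conserved_pairs(table, 0.77)
    assert hits == [(("3.54", "H5.20"), 1.0)]
    hits_low = conserved_pairs(table, 0.5)
    assert [h[0] for h in hits_low] == [("3.54", "H5.20"), ("6.33", "H5.25")]
    with pytest.raises(ParameterError):
        conserved_pairs(table, 0.0)


def test_duplicate_complex_ids_rejected():
    cx = sd.make_complex(sd.ScenarioSpec(seed=1, complex_id="same"))
    with pytest.raises(InputError):
        build_conservation_table([cx, cx])
    with pytest.raises(EmptyInputError):
        build_conservation_table([])


def test_h5_conserved_positions_exact():
    planted = ["H5.03", "H5.17", "H5.26"]
    aln = sd.make_alignment(planted, seed=9)
    assert [str(l) for l in h5_conserved_positions(aln)] == planted
    with pytest.raises(AlignmentError):
        h5_conserved_positions(aln.iloc[:1])
    bad = aln.rename(columns={"H5.01": "whatever"})
    with pytest.raises(AlignmentError):
        h5_conserved_positions(bad)


def test_shared_interface_membership_rules(funnel):
    _, gi_set, gs_set, _ = funnel
    candidates = [parse_label(p) for p in sd.REFERENCE_CONSERVED_H5]
    anyshared = shared_interface_positions(gi_set, gs_set, candidates, membership="any")
    assert [str(l) for l in anyshared] == ["H5.08", "H5.13", "H5.20", "H5.25"]
    major = shared_interface_positions(gi_set, gs_set, candidates, membership="majority")
    assert [str(l) for l in major] == ["H5.20", "H5.25"]
    with pytest.raises(EmptyInputError):
        shared_interface_positions([], gs_set, candidates)
    with pytest.raises(ParameterError):
        shared_interface_positions(gi_set, gs_set, candidates, membership="most")


def test_check_model_contacts_partition():
    reference = [("3.50", "H5.23"), ("3.53", "H5.23"), ("3.54", "H5.16"),
                 ("3.54", "H5.20"), ("5.65", "H5.20"), ("7.53", "H5.26")]
    present = [sd.PlantedContact(r, g, 1.0) for r, g in reference[:5]]
    model = sd.make_complex(sd.ScenarioSpec(seed=4, planted_contacts=present))
    preserved, missing, unmappable = check_model_contacts(model, reference)
    assert len(preserved) == 5
    assert missing == [("7.53", "H5.26")]
    assert unmappable == []
    assert len(preserved) + len(missing) + len(unmappable) == len(reference)
    # an unknown label lands in `unmappable`, never silently dropped
    p2, m2, u2 = check_model_contacts(model, reference + [("3.50", "HN.99")])
    assert u2 == [("3.50", "HN.99")]
    assert len(p2) + len(m2) + len(u2) == len(reference) + 1


def test_select_restraints_empty_outcome_is_reported(funnel):
    aln, gi_set, gs_set, target = funnel
    no_conserved = sd.make_alignment([], seed=2)
    sel = select_restraints(no_conserved, gi_set, gs_set,
                            target.receptor_map, target.galpha_map)
    assert sel.restraints == []
    assert sel.stage_counts == (0, 0, 0)
    assert "no restraints" in sel.message


def test_restraint_outputs_round_trip(funnel):
    aln, gi_set, gs_set, target = funnel
    sel = select_restraints(aln, gi_set, gs_set,
                            target.receptor_map, target.galpha_map)
    tsv = restraints_to_tsv(sel)
    assert "3.54" in tsv and "H5.20" in tsv and "cutoff=4.50" in tsv
    import json
    doc = json.loads(restraints_to_cluspro_json(sel))
    assert doc["groups"][0]["required"] == 2
    resids = {(r["rec_resid"], r["lig_resid"]) for r in doc["groups"][0]["restraints"]}
    assert resids == {(218, 388), (341, 393)}


def test_cluspro_weighted_score():
    assert cluspro_weighted_score(1.0, 1.0, 0.0, 0.0) == pytest.approx(0.0)
    assert cluspro_weighted_score(10.0, 5.0, 0.01, 2.0) == pytest.approx(
        0.4 * 10 - 0.4 * 5 + 600 * 0.01 + 1.0 * 2.0)
    assert set(CLUSPRO_WEIGHTS) == {"e_rep", "e_att", "e_elect", "e_dars"}
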