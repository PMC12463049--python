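"""Interface descriptor components on hand-built geometries and planted
fixtures."""

import json

import numpy as np
import pytest

from impscan.interface import (ContactCriteria, HBondCriteria,
                               InterfaceDescriptor, SaltBridgeCriteria,
                               buried_surface_area, classify_contacts,
                               count_hydrogen_bonds, count_salt_bridges,
                               find_interface, interface_report,
                               nis_percentages)
from impscan.structure import Atom, Chain, ComplexView, Residue, Structure
from impscan.synth import ComplexSpec, build_toy_complex


def _res(aa, num, atoms):
    return Residue(aa, num, atoms=[
        Atom(name, "S" if name in ("SG", "SD") else name.lstrip("0123456789")[0],
             np.asarray(xyz, float))
        for name, xyz in atoms.items()])


def _two_chain(res_a, res_b):
    st = Structure(chains=[Chain("A", res_a), Chain("B", res_b)])
    return ComplexView(st, frozenset("A"), frozenset("B"))


def _gly_at(num, x):
    return _res("G", num, {"N": (x - 1.4, 1.0, 0), "CA": (x, 0, 0),
                           "C": (x + 1.4, 1.0, 0), "O": (x + 1.4, 2.2, 0)})


def test_contact_at_5A_detected_but_not_at_6A():
    view = _two_chain([_gly_at(1, 0.0)], [_gly_at(1, 5.0)])
    ra, rb, pairs = find_interface(view)
    # CA-CA 5.0 < 5.5, but N/C atoms may also pair; residue-level count is 1
    assert pairs == [(("A", 1, ""), ("B", 1, ""))]
    far = _two_chain([_res("G", 1, {"N": (0, 30, 0), "CA": (0, 0, 0),
                                    "C": (0, -30, 0)})],
                     [_res("G", 1, {"N": (6.0, 30, 0), "CA": (6.0, 0, 0),
                                    "C": (6.0, -30, 0)})])
    ra, rb, pairs = find_interface(far)
    assert not pairs and not ra and not rb


def test_classify_lys_glu_is_charged_charged():
    view = _two_chain(
        [_res("K", 1, {"N": (0, 9, 0), "CA": (0, 0, 0), "C": (0, -9, 0),
                       "NZ": (1.0, 0, 0)})],
        [_res("E", 1, {"N": (5.5, 9, 0), "CA": (5.5, 0, 0), "C": (5.5, -9, 0),
                       "OE1": (4.5, 0, 0)})])
    ic = classify_contacts(view)
    assert ic == {"cc": 1, "cp": 0, "ca": 0, "pp": 0, "pa": 0, "aa": 0}


def test_classify_mixed_classes():
    view = _two_chain(
        [_res("K", 1, {"N": (0, 9, 0), "CA": (0, 0, 0), "C": (0, -9, 0)}),
         _res("S", 2, {"N": (40, 9, 0), "CA": (40, 0, 0), "C": (40, -9, 0)})],
        [_res("L", 1, {"N": (5, 9, 0), "CA": (5, 0, 0), "C": (5, -9, 0)}),
         _res("T", 2, {"N": (45, 9, 0), "CA": (45, 0, 0), "C": (45, -9, 0)})])
    ic = classify_contacts(view)
    assert ic == {"cc": 0, "cp": 0, "ca": 1, "pp": 1, "pa": 0, "aa": 0}


@pytest.mark.parametrize("d,expected", [(2.9, 1), (3.8, 0)])
def test_hbond_backbone_distance_rule(d, expected):
    view = _two_chain(
        [_res("G", 1, {"N": (0, 9, 0), "CA": (0, 5, 0), "C": (0, 2, 0),
                       "O": (0, 0, 0)})],
        [_res("G", 1, {"N": (d, 0, 0), "CA": (d, -5, 0), "C": (d, -9, 0),
                       "O": (d, -11, 0)})])
    n, bonds = count_hydrogen_bonds(view)
    assert n == expected


def test_salt_bridge_and_same_charge_rejection():
    lys = _res("K", 1, {"N": (0, 9, 0), "CA": (0, 5, 0), "C": (0, 12, 0),
                        "NZ": (0, 0, 0)})
    glu = _res("E", 1, {"N": (3.5, -9, 0), "CA": (3.5, -5, 0),
                        "C": (3.5, -12, 0), "OE1": (3.5, 0, 0)})
    arg = _res("R", 1, {"N": (3.0, -9, 0), "CA": (3.0, -5, 0),
                        "C": (3.0, -12, 0), "NH1": (3.0, 0, 0)})
    n, pairs = count_salt_bridges(_two_chain([lys], [glu]))
    assert n == 1 and pairs == [(("A", 1, ""), ("B", 1, ""))]
    n, _ = count_salt_bridges(_two_chain([lys], [arg]))
    assert n == 0


def test_nis_percentage_arithmetic():
    """3 Lys + 1 Leu on the surface, none interfacial: 75% charged,
    25% apolar, 0% polar."""
    res_a = [_res("K", i, {"N": (20 * i, 1.4, 0), "CA": (20 * i, 0, 0),
                           "C": (20 * i, -1.4, 0)}) for i in range(1, 4)]
    res_a.append(_res("L", 4, {"N": (80, 1.4, 0), "CA": (80, 0, 0),
                               "C": (80, -1.4, 0)}))
    # partner chain is a non-canonical placeholder, excluded from NIS classes
    res_b = [_res("X", 1, {"N": (0, 200, 0), "CA": (1.4, 200, 0),
                           "C": (2.8, 200, 0)})]
    view = _two_chain(res_a, res_b)
    charged, apolar, polar = nis_percentages(view)
    assert (charged, apolar, polar) == (75.0, 25.0, 0.0)


def test_nis_all_interfacial_warns_and_zeroes():
    view = _two_chain(
        [_res("K", 1, {"N": (0, 9, 0), "CA": (0, 0, 0), "C": (0, -9, 0)})],
        [_res("L", 1, {"N": (5, 9, 0), "CA": (5, 0, 0), "C": (5, -9, 0)})])
    with pytest.warns(UserWarning):
        assert nis_percentages(view) == (0.0, 0.0, 0.0)


def test_separated_groups_all_zero_descriptor():
    spec = ComplexSpec(n_residues_a=6, n_residues_b=6,
                       planted_ic={}, separation=50.0, seed=0)
    st, _ = build_toy_complex(spec)
    view = ComplexView(st, frozenset("A"), frozenset("B"))
    desc = interface_report(view)
    assert desc.total_contacts() == 0
    assert desc.n_hbonds == 0 and desc.n_salt_bridges == 0
    assert desc.bsa <= 1.0
    assert not desc.interface_residues_a and not desc.interface_residues_b


def test_bsa_zero_when_far_apart():
    res_a = [_gly_at(1, 0.0)]
    res_b = [_gly_at(1, 100.0)]
    assert buried_surface_area(_two_chain(res_a, res_b)) <= 1.0


def test_bsa_monotone_on_approach(standard_view):
    """Translating the ligand closer along the interface normal (no clash)
    does not decrease buried area."""
    st = standard_view.structure
    bsa0 = buried_surface_area(standard_view)
    moved = st.copy()
    for _, res in moved.iter_residues(["B"]):
        for a in res.atoms:
            a.coords = a.coords - np.array([0.0, 0.0, 0.4])
    bsa1 = buried_surface_area(
        ComplexView(moved, frozenset("A"), frozenset("B")))
    assert bsa1 >= bsa0 - 1e-6


@pytest.mark.parametrize("seed", range(10))
def test_planted_descriptor_recovery(seed):
    """Classified contact counts, bridge and H-bond counts recovered exactly
    from seeded toy complexes."""
    ic = {"cc": 2, "cp": 1, "ca": 2, "pp": 1, "pa": 1, "aa": 2}
    spec = ComplexSpec(n_residues_a=15, n_residues_b=15, planted_ic=dict(ic),
                       planted_salt_bridges=1, planted_hbonds=3, seed=seed)
    st, ledger = build_toy_complex(spec)
    view = ComplexView(st, frozenset("A"), frozenset("B"))
    desc = interface_report(view)
    assert desc.ic == ic
    assert desc.n_salt_bridges == 1
    assert desc.n_hbonds == 3
    assert desc.interface_residues_a == ledger.interface_residues_a
    assert desc.interface_residues_b == ledger.interface_residues_b


def test_group_swap_symmetry(standard_view):
    """Swapping receptor/ligand roles leaves every symmetric descriptor field
    unchanged and swaps the per-side residue sets."""
    d1 = interface_report(standard_view)
    d2 = interface_report(standard_view.swapped())
    assert d1.ic == d2.ic
    assert d1.n_hbonds == d2.n_hbonds
    assert d1.n_salt_bridges == d2.n_salt_bridges
    assert d1.bsa == pytest.approx(d2.bsa, abs=1e-9)
    assert (d1.nis_charged_pct, d1.nis_apolar_pct, d1.nis_polar_pct) == \
           (d2.nis_charged_pct, d2.nis_apolar_pct, d2.nis_polar_pct)
    assert d1.interface_residues_a == d2.interface_residues_b
    assert d1.interface_residues_b == d2.interface_residues_a


def test_cutoff_monotonicity(standard_view):
    prev_total = -1
    prev_res = frozenset()
    for cutoff in (4.0, 5.5, 7.0, 9.0):
        crit = ContactCriteria(heavy_atom_cutoff=cutoff)
        ra, rb, pairs = find_interface(standard_view, crit)
        assert len(pairs) >= prev_total
        assert prev_res <= (ra | rb)
        prev_total = len(pairs)
        prev_res = ra | rb


def test_descriptor_determinism(standard_view):
    d1 = interface_report(standard_view)
    d2 = interface_report(standard_view)
    assert d1 == d2
    assert d1.bsa == d2.bsa  # bit-identical, not approximately


def test_descriptor_json_round_trip(standard_view, tmp_path):
    desc = interface_report(standard_view)
    path = tmp_path / "desc.json"
    desc.to_json(path)
    back = InterfaceDescriptor.from_json(path)
    assert back == desc


def test_class_map_missing_entry_is_configuration_error():
    from impscan.interface import ConfigurationError
    crit = ContactCriteria(class_map={"K": "charged"})
    view = _two_chain(
        [_res("K", 1, {"N": (0, 9, 0), "CA": (0, 0, 0), "C": (0, -9, 0)})],
        [_res("L", 1, {"N": (5, 9, 0), "CA": (5, 0, 0), "C": (5, -9, 0)})])
    with pytest.raises(ConfigurationError):
        classify_contacts(view, crit)
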