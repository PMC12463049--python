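"""Mutant construction, folding surrogate, pair nomination, 19x19 scan and
the dual selection filter."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_filter
from impscan.constants import CHI_ATOMS
from impscan.geometry import build_sidechain, structure_from_chain
from impscan.mutscan import (CLASH_CUTOFF, Mutation, PairNominationParams,
                             ROTAMER_GRID, SelectionCriteria,
                             StabilityScorerParams, evaluate_mutant,
                             filter_candidates, mutate_residue,
                             nominate_interface_pairs, read_heatmap,
                             scan_pair, score_folding_change,
                             write_candidates_tsv, write_heatmap)
from impscan.structure import (Atom, Chain, ComplexView, PoseEnsemble,
                               Residue, Structure, StructureError)
from impscan.synth import ComplexSpec, build_peptide, build_pose_ensemble, \
    build_toy_complex


# ---------------------------------------------------------------------------
# mutant construction

def test_identity_mutation_preserves_coordinates(standard_complex):
    st, _ = standard_complex
    mut = mutate_residue(st, Mutation("B", 1, st.get_chain("B").residues[0].aa,
                                      st.get_chain("B").residues[0].aa))
    for (c1, r1), (c2, r2) in zip(st.iter_residues(), mut.iter_residues()):
        for a1, a2 in zip(r1.atoms, r2.atoms):
            assert np.array_equal(a1.coords, a2.coords)


def test_glycine_truncation():
    st = structure_from_chain(build_peptide("ARA", chain_id="B"))
    mut = mutate_residue(st, Mutation("B", 2, "R", "G"))
    res = mut.get_chain("B").residues[1]
    assert res.aa == "G"
    assert sorted(a.name for a in res.atoms) == ["C", "CA", "N", "O"]


def test_wild_type_mismatch_rejected(standard_complex):
    st, _ = standard_complex
    aa = st.get_chain("B").residues[0].aa
    wrong = "A" if aa != "A" else "G"
    with pytest.raises(StructureError, match="mismatch"):
        mutate_residue(st, Mutation("B", 1, wrong, "T"))


def test_rotamer_choice_matches_brute_force_oracle():
    """K->R in a pocket with deliberate obstacles: the chosen rotamer equals
    exhaustive enumeration over the full chi grid by the same objective."""
    chain = build_peptide("AKA", chain_id="B")
    stx = structure_from_chain(chain)
    res = stx.get_chain("B").residues[1]
    n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
    # obstacles near some rotamer exits
    obstacles = []
    for k, combo in enumerate(itertools.product(ROTAMER_GRID, repeat=4)):
        if k % 7:
            continue
        side = build_sidechain(n, ca, c, "R", combo)
        obstacles.append(side[-1][2])  # near NH2 of that rotamer
    extra = Chain("C", [Residue("G", i + 1, atoms=[
        Atom("CA", "C", np.asarray(p))]) for i, p in enumerate(obstacles)])
    stx.chains.append(extra)

    mut = mutate_residue(stx, Mutation("B", 2, "K", "R"))
    got = {a.name: a.coords for a in mut.get_chain("B").residues[1].atoms}

    env = np.array([a.coords for cid, r in stx.iter_residues()
                    if not (cid == "B" and r.author_number == 2)
                    for a in r.heavy_atoms()])
    best = None
    for combo in itertools.product(ROTAMER_GRID, repeat=len(CHI_ATOMS["R"])):
        side = build_sidechain(n, ca, c, "R", combo)
        coords = np.array([xyz for _, _, xyz in side])
        d = np.linalg.norm(coords[:, None] - env[None, :], axis=2)
        clashes = int((d < CLASH_CUTOFF).sum())
        if best is None or clashes < best[0]:
            best = (clashes, side)
    assert best[0] > 0, "fixture should actually constrain the rotamer choice"
    for name, _, xyz in best[1]:
        np.testing.assert_allclose(got[name], xyz, atol=1e-9)


# ---------------------------------------------------------------------------
# folding surrogate

def _ser_residue(num, origin):
    ox, oy, oz = origin
    return Residue("S", num, atoms=[
        Atom("N", "N", np.array([ox, oy + 1.4, oz])),
        Atom("CA", "C", np.array([ox, oy, oz])),
        Atom("C", "C", np.array([ox + 1.4, oy, oz])),
        Atom("O", "O", np.array([ox + 2.0, oy + 1.0, oz])),
        Atom("CB", "C", np.array([ox - 1.2, oy - 0.8, oz])),
        Atom("OG", "O", np.array([ox - 2.2, oy - 1.6, oz])),
    ])


def test_identity_gives_exact_zero(standard_complex):
    st, _ = standard_complex
    assert score_folding_change(st, st.copy(), chain_scope={"B"}) == 0.0


def test_two_clashes_cost_two_kcal():
    """A mutant whose only change is two new heavy-atom clashes scores
    exactly w_clash * 2 = 2.0 under default weights."""
    wt = Structure(chains=[Chain("B", [_ser_residue(1, (0, 0, 0)),
                                       _ser_residue(2, (20, 0, 0))])])
    mut = wt.copy()
    cb = mut.get_chain("B").residues[1].get_atom("CB")
    # place residue 2's CB 2.40 A from residue 1's CA and C and > 2.6 A from
    # everything else (2 clashes, carbons only, so no H-bond/bridge change;
    # serine is polar, so no burial term)
    cb.coords = np.array([0.7, 0.0, 2.3])
    assert score_folding_change(wt, mut, chain_scope={"B"}) == pytest.approx(
        2.0, abs=1e-12)


def test_folding_score_matches_term_oracle(standard_complex):
    """Weighted-sum recomposition from independently recounted terms."""
    st, _ = standard_complex
    mut = mutate_residue(st, Mutation("B", 1, st.get_chain("B").residues[0].aa,
                                      "W"))
    params = StabilityScorerParams(w_clash=1.3, w_lost_hbond=0.7,
                                   w_lost_bridge=0.9, w_burial=0.02)
    from impscan.mutscan import _stability_terms
    t_wt = _stability_terms(st, {"B"})
    t_mut = _stability_terms(mut, {"B"})
    expected = (params.w_clash * (t_mut["n_clash"] - t_wt["n_clash"])
                + params.w_lost_hbond * max(0.0, t_wt["n_hbond"] - t_mut["n_hbond"])
                + params.w_lost_bridge * max(0.0, t_wt["n_bridge"] - t_mut["n_bridge"])
                + params.w_burial * max(0.0, t_wt["buried_apolar"]
                                        - t_mut["buried_apolar"]))
    got = score_folding_change(st, mut, params, {"B"})
    assert got == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# evaluate_mutant

def test_empty_mutation_list_is_zero_zero(standard_view, default_params):
    assert evaluate_mutant(standard_view, [],
                           affinity_params=default_params) == (0.0, 0.0)


def test_wt_to_wt_is_exactly_zero(standard_view, default_params):
    aa = standard_view.structure.get_chain("B").residues[0].aa
    ddb, ddf = evaluate_mutant(standard_view, [Mutation("B", 1, aa, aa)],
                               affinity_params=default_params)
    assert (ddb, ddf) == (0.0, 0.0)


def test_duplicate_sites_rejected(standard_view, default_params):
    aa = standard_view.structure.get_chain("B").residues[0].aa
    with pytest.raises(StructureError, match="duplicate"):
        evaluate_mutant(standard_view,
                        [Mutation("B", 1, aa, "T"), Mutation("B", 1, aa, "S")],
                        affinity_params=default_params)


def test_mutations_must_stay_on_one_side(standard_view, default_params):
    aa_b = standard_view.structure.get_chain("B").residues[0].aa
    aa_a = standard_view.structure.get_chain("A").residues[0].aa
    with pytest.raises(StructureError, match="one side"):
        evaluate_mutant(standard_view,
                        [Mutation("B", 1, aa_b, "T"),
                         Mutation("A", 1, aa_a, "T")],
                        affinity_params=default_params)


def test_planted_mutation_reproduces_weight_difference(default_params):
    """On a backbone-anchored cc contact, mutating the ligand Arg to Thr
    converts cc to cp; the binding ddG is exactly w_cp - w_cc."""
    spec = ComplexSpec(n_residues_a=14, n_residues_b=14,
                       planted_ic={"cc": 2}, backbone_anchored=True, seed=7)
    stx, _ = build_toy_complex(spec)
    view = ComplexView(stx, frozenset("A"), frozenset("B"))
    ddb, _ = evaluate_mutant(view, [Mutation("B", 1, "R", "T")],
                             affinity_params=default_params)
    predicted = default_params.w_ic["cp"] - default_params.w_ic["cc"]
    assert ddb == pytest.approx(predicted, abs=1e-9)


# ---------------------------------------------------------------------------
# pair nomination

def test_single_pose_adjacent_pair_nominated():
    spec = ComplexSpec(n_residues_a=8, n_residues_b=8, planted_ic={"ca": 2},
                       contact_positions=[0.0, 6.0], seed=1)
    stx, _ = build_toy_complex(spec)
    view = ComplexView(stx, frozenset("A"), frozenset("B"))
    ensemble = PoseEnsemble(poses=[view])
    pairs, occupancy = nominate_interface_pairs(ensemble, "B")
    assert pairs == [(("B", 1, ""), ("B", 2, ""))]
    assert occupancy[("B", 1, "")] == 1.0


def test_never_interfacial_residue_in_no_pair():
    spec = ComplexSpec(n_residues_a=8, n_residues_b=8, planted_ic={"ca": 2},
                       contact_positions=[0.0, 6.0], seed=1)
    stx, _ = build_toy_complex(spec)
    view = ComplexView(stx, frozenset("A"), frozenset("B"))
    ensemble, _ = build_pose_ensemble(view, 10, seed=2)
    pairs, occupancy = nominate_interface_pairs(ensemble, "B")
    nominated = {k for pair in pairs for k in pair}
    fillers = {("B", n, "") for n in range(3, 9)}
    assert occupancy.keys().isdisjoint(fillers)
    assert nominated.isdisjoint(fillers)


def test_planted_hot_pair_uniquely_nominated():
    """0.9/0.85-occupancy pair 6 A apart among 0.25-occupancy decoys is the
    unique nomination at default parameters."""
    spec = ComplexSpec(n_residues_a=12, n_residues_b=12, planted_ic={"ca": 5},
                       contact_positions=[0.0, 6.0, 30.0, 44.0, 58.0], seed=3)
    stx, _ = build_toy_complex(spec)
    view = ComplexView(stx, frozenset("A"), frozenset("B"))
    ensemble, ledger = build_pose_ensemble(
        view, 20, hot_residues=[("B", 1, ""), ("B", 2, "")],
        hot_occupancies=[0.9, 0.85], decoy_occupancy=0.25, seed=4)
    pairs, _ = nominate_interface_pairs(ensemble, "B")
    assert pairs == [(("B", 1, ""), ("B", 2, ""))]


# ---------------------------------------------------------------------------
# 19x19 scan

def test_scan_matrix_shape_and_axis_order(scan_results, scan_view):
    view, _ = scan_view
    mat = scan_results["mat"]
    wt_a = view.structure.get_chain("B").residues[0].aa
    wt_b = view.structure.get_chain("B").residues[1].aa
    assert mat.ddg_binding.shape == (19, 19)
    assert mat.ddg_folding.shape == (19, 19)
    assert wt_a not in mat.subs_a and wt_b not in mat.subs_b
    assert list(mat.subs_a) == sorted(mat.subs_a)


def test_scan_determinism_bit_identical(scan_results):
    assert np.array_equal(scan_results["mat"].ddg_binding,
                          scan_results["again"].ddg_binding)
    assert np.array_equal(scan_results["mat"].ddg_folding,
                          scan_results["again"].ddg_folding)


def test_scan_transpose_symmetry(scan_results):
    np.testing.assert_array_equal(scan_results["swapped"].ddg_binding,
                                  scan_results["mat"].ddg_binding.T)
    np.testing.assert_array_equal(scan_results["swapped"].ddg_folding,
                                  scan_results["mat"].ddg_folding.T)


def test_scan_rejects_receptor_site(scan_view, default_params):
    view, _ = scan_view
    with pytest.raises(StructureError, match="receptor"):
        scan_pair(view, ("A", 1, ""), ("B", 1, ""),
                  affinity_params=default_params)


def test_heatmap_tsv_round_trip(scan_results, tmp_path):
    mat = scan_results["mat"]
    for channel, grid in (("binding", mat.ddg_binding),
                          ("folding", mat.ddg_folding)):
        path = tmp_path / f"{channel}.tsv"
        write_heatmap(mat, path, channel)
        lines = path.read_text().splitlines()
        assert len(lines) == 20 and len(lines[0].split("\t")) == 20
        back = read_heatmap(path)
        np.testing.assert_allclose(back, grid, atol=1e-6)


def test_filter_channel_matches_filter_candidates(scan_results, tmp_path):
    mat = scan_results["mat"]
    path = tmp_path / "filter.tsv"
    write_heatmap(mat, path, "filter")
    ones = int(read_heatmap(path).sum())
    retained = filter_candidates(
        [(lbl, b, f) for lbl, b, f, _ in mat.candidates()], mat.criteria)
    assert ones == len(retained)
    cand_path = tmp_path / "cand.tsv"
    write_candidates_tsv(mat, cand_path)
    rows = cand_path.read_text().splitlines()[1:]
    assert sum(1 for r in rows if r.endswith("\t1")) == ones


# ---------------------------------------------------------------------------
# dual filter

FOUR_REPORTED_MUTANTS = [
    ("R1518T-D1522G", 1.40, 0.0),
    ("R1518T-D1522A", 1.40, 0.0),
    ("R1518T-H1519G", 1.4, -0.79),
    ("R1518T-H1519G-D1522G", 1.50, 0.0),
]


def test_reported_mutants_all_retained():
    """The four double/triple mutants with their printed ddG values all pass
    the inclusive >=0.8 / <=0.05 kcal/mol dual criterion."""
    retained = filter_candidates(FOUR_REPORTED_MUTANTS)
    assert [r[0] for r in retained] == [m[0] for m in FOUR_REPORTED_MUTANTS]


def test_boundary_semantics_inclusive():
    assert filter_candidates([("boundary", 0.8, 0.05)])
    assert not filter_candidates([("null", 0.0, 0.0)])
    assert not filter_candidates([("binding_short", 0.7999, 0.0)])
    assert not filter_candidates([("folding_over", 1.0, 0.0501)])


def test_stabilizing_fold_change_passes():
    assert filter_candidates([("stabilized", 1.4, -0.79)])


def test_random_entries_match_brute_force(rng):
    entries = [(f"m{i}", float(rng.normal(0.8, 0.6)),
                float(rng.normal(0.0, 0.4))) for i in range(361)]
    ours = filter_candidates(entries)
    oracle = brute_force_filter(entries, 0.8, 0.05)
    assert ours == oracle


@settings(max_examples=30, derandomize=True, deadline=None)
@given(bmin=st.floats(0.1, 3.0), fmax=st.floats(-1.0, 1.0),
       bmin2=st.floats(0.0, 2.0), fmax2=st.floats(0.0, 2.0))
def test_filter_monotonicity(bmin, fmax, bmin2, fmax2):
    """Raising the binding threshold or lowering the folding threshold never
    enlarges the retained set."""
    rng = np.random.default_rng(42)
    entries = [(f"m{i}", float(rng.normal(1.0, 1.0)),
                float(rng.normal(0.0, 1.0))) for i in range(100)]
    loose = set(x[0] for x in filter_candidates(
        entries, SelectionCriteria(bmin, fmax)))
    tight = set(x[0] for x in filter_candidates(
        entries, SelectionCriteria(bmin + bmin2, fmax - fmax2)))
    assert tight <= loose


def test_nomination_params_validation():
    with pytest.raises(Exception):
        PairNominationParams(occupancy_min=0.0)
    with pytest.raises(Exception):
        PairNominationParams(proximity_cutoff=-1.0)
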