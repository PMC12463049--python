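"""Elastic-network sampling and FG-motif exposure/cluster selection."""

import numpy as np
import pytest

from _oracles import brute_force_max_clique
from impscan.fg import (FgClusterCriteria, build_anm, ca_rmsd, fg_exposure,
                        find_fg_motifs, max_mutual_cluster, sample_conformers,
                        select_fg_clustered_conformers, spring_energy)
from impscan.geometry import structure_from_chain
from impscan.sasa import compute_sasa, relative_sasa
from impscan.structure import StructureError
from impscan.synth import build_buried_phe, build_fg_fixture, build_peptide


@pytest.fixture(scope="module")
def helix_model():
    st = structure_from_chain(build_peptide("A" * 100, "helix"))
    return st, build_anm(st, cutoff=15.0)


# ---------------------------------------------------------------------------
# ANM

def test_six_zero_modes_and_orthonormal_modes(helix_model):
    _, model = helix_model
    assert model.n_zero_modes() == 6
    V = model.eigenvectors
    np.testing.assert_allclose(V.T @ V, np.eye(V.shape[0]), atol=1e-8)
    assert np.all(np.diff(model.eigenvalues) >= -1e-10)


def test_hessian_matches_spring_energy_quadratic_form(helix_model):
    """The eigendecomposition reproduces the spring-network energy of a
    small random displacement (finite-difference check)."""
    _, model = helix_model
    rng = np.random.default_rng(1)
    V, lam = model.eigenvectors, model.eigenvalues
    x0 = model.node_coords.reshape(-1)
    v = rng.standard_normal(len(x0))
    v /= np.linalg.norm(v)
    eps = 1e-4
    e_direct = spring_energy(model, (x0 + eps * v).reshape(-1, 3))
    e_quad = 0.5 * eps ** 2 * float((V.T @ v) ** 2 @ lam)
    assert e_direct == pytest.approx(e_quad, rel=1e-5, abs=1e-14)


def test_too_few_nodes_rejected():
    st = structure_from_chain(build_peptide("AAAAA"))
    with pytest.raises(StructureError):
        build_anm(st)


def test_disconnected_network_warns(helix_model):
    st, _ = helix_model
    far = st.copy()
    for res in far.chains[0].residues[50:]:
        for a in res.atoms:
            a.coords = a.coords + np.array([500.0, 0.0, 0.0])
    with pytest.warns(UserWarning, match="disconnected"):
        build_anm(far)


# ---------------------------------------------------------------------------
# conformer sampling

def test_rmsd_control(helix_model):
    st, model = helix_model
    ens = sample_conformers(model, st, 25, target_rmsd=2.0, n_modes=10, seed=3)
    for conf in ens.conformers:
        assert 1.8 <= ca_rmsd(st, conf) <= 2.2


def test_zero_target_rmsd_is_identity(helix_model):
    st, model = helix_model
    ens = sample_conformers(model, st, 3, target_rmsd=0.0, n_modes=10, seed=3)
    for conf in ens.conformers:
        assert ca_rmsd(st, conf) == 0.0


def test_sampling_determinism(helix_model):
    st, model = helix_model
    e1 = sample_conformers(model, st, 5, 1.5, 8, seed=9)
    e2 = sample_conformers(model, st, 5, 1.5, 8, seed=9)
    for c1, c2 in zip(e1.conformers, e2.conformers):
        for (_, r1), (_, r2) in zip(c1.iter_residues(), c2.iter_residues()):
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert np.array_equal(a1.coords, a2.coords)


# ---------------------------------------------------------------------------
# FG motifs

@pytest.mark.parametrize("seq,expected", [
    ("NFGQ", [2]),
    ("FGFG", [1, 3]),
    ("FFGG", [2]),
    ("AAAA", []),
])
def test_fg_dipeptide_positions(seq, expected):
    assert find_fg_motifs(seq) == expected


def test_fixture_sequence_carries_22_motifs():
    ens, ledger = build_fg_fixture(n_conformers=3, sequence_length=130,
                                   n_fg=22, planted=(1, 3, 30.0), seed=2)
    seq = ens.conformers[0].chains[0].sequence
    assert find_fg_motifs(seq) == ledger.fg["positions"]
    assert len(ledger.fg["positions"]) == 22


def test_buried_phe_not_exposed():
    st, pos = build_buried_phe()
    sasa = compute_sasa(st)
    rel = relative_sasa(sasa, ("R", 1, ""))
    assert rel < 0.25
    assert fg_exposure(st, [], FgClusterCriteria()) == []


def test_isolated_phe_exposed_and_zero_threshold_degenerate():
    ens, _ = build_fg_fixture(n_conformers=2, sequence_length=40, n_fg=4,
                              planted=(0, 2, 30.0), seed=5)
    conf = ens.conformers[1]
    positions = find_fg_motifs(conf.chains[0].sequence)
    exposed = fg_exposure(conf, positions, FgClusterCriteria())
    assert exposed == positions
    all_exposed = fg_exposure(conf, positions,
                              FgClusterCriteria(exposure_threshold=0.0))
    assert all_exposed == positions


# ---------------------------------------------------------------------------
# clique selection

def test_max_clique_matches_brute_force_on_random_graphs(rng):
    """Exact clique search equals exhaustive subset enumeration for up to
    12 motifs on 50 random point sets."""
    for _ in range(50):
        n = int(rng.integers(3, 13))
        pts = rng.uniform(0, 60, (n, 3))
        cutoff = float(rng.uniform(15, 45))
        ours = max_mutual_cluster(pts, cutoff)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        assert all(d[i, j] <= cutoff
                   for k, i in enumerate(ours) for j in ours[k + 1:])
        assert len(ours) == brute_force_max_clique(d, cutoff)


def test_selection_monotone_in_distance_cutoff():
    ens, _ = build_fg_fixture(n_conformers=4, sequence_length=80, n_fg=8,
                              planted=(2, 4, 30.0), seed=6)
    sizes_prev = None
    for cutoff in (20.0, 30.0, 45.0, 80.0):
        hits = select_fg_clustered_conformers(
            ens, FgClusterCriteria(1, cutoff, 0.25))
        sizes = {i: a["cluster_size"] for i, a in hits}
        if sizes_prev is not None:
            for i, s in sizes_prev.items():
                assert sizes.get(i, 0) >= s
        sizes_prev = sizes


def test_planted_conformer_uniquely_selected():
    """Only the conformer with 5 exposed motifs mutually within 30 A is
    selected among decoys capped at 4."""
    ens, ledger = build_fg_fixture(n_conformers=12, sequence_length=130,
                                   n_fg=22, planted=(7, 5, 30.0), seed=8)
    hits = select_fg_clustered_conformers(
        ens, FgClusterCriteria(min_exposed_motifs=5,
                               mutual_distance_cutoff=30.0))
    assert [i for i, _ in hits] == [7]
    assert hits[0][1]["cluster_size"] == 5
    assert ledger.fg["cluster_sizes"][7] == 5
    assert max(s for i, s in enumerate(ledger.fg["cluster_sizes"])
               if i != 7) <= 4


def test_below_threshold_planting_yields_empty_selection():
    ens, _ = build_fg_fixture(n_conformers=6, sequence_length=80, n_fg=8,
                              planted=(3, 4, 30.0), seed=10)
    hits = select_fg_clustered_conformers(
        ens, FgClusterCriteria(min_exposed_motifs=5,
                               mutual_distance_cutoff=30.0))
    assert hits == []
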