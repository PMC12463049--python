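import numpy as np
import pytest

from impscan.affinity import load_model_params
from impscan.mutscan import scan_pair
from impscan.structure import ComplexView
from impscan.synth import ComplexSpec, build_toy_complex

STANDARD_IC = {"cc": 2, "cp": 1, "ca": 3, "pp": 2, "pa": 1, "aa": 4}


@pytest.fixture(scope="session")
def standard_complex():
    """Mixed-class toy complex: 13 contacts, 2 salt bridges, 3 H-bonds."""
    spec = ComplexSpec(n_residues_a=20, n_residues_b=20,
                       planted_ic=dict(STANDARD_IC),
                       planted_salt_bridges=2, planted_hbonds=3, seed=11)
    return build_toy_complex(spec)


@pytest.fixture(scope="session")
def standard_view(standard_complex):
    st, _ = standard_complex
    return ComplexView(st, frozenset("A"), frozenset("B"))


@pytest.fixture(scope="session")
def paper_scale_complex():
    """Interface at the scale reported for the NLS-importin-alpha complex:
    24 contacts hosting 24 H-bonds, 4 of them salt bridges."""
    spec = ComplexSpec(n_residues_a=33, n_residues_b=33,
                       planted_ic={"cc": 6, "cp": 4, "ca": 4, "pp": 4,
                                   "pa": 3, "aa": 3},
                       planted_salt_bridges=4, planted_hbonds=24, seed=24)
    return build_toy_complex(spec)


@pytest.fixture(scope="session")
def default_params():
    return load_model_params()


@pytest.fixture(scope="session")
def scan_view():
    """60-residue two-chain complex used by all 19x19 scan tests."""
    spec = ComplexSpec(n_residues_a=30, n_residues_b=30,
                       planted_ic={"cc": 3, "cp": 2, "ca": 2, "pp": 2,
                                   "pa": 1, "aa": 2},
                       planted_salt_bridges=2, planted_hbonds=4, seed=9)
    st, ledger = build_toy_complex(spec)
    return ComplexView(st, frozenset("A"), frozenset("B")), ledger


@pytest.fixture(scope="session")
def scan_results(scan_view, default_params):
    """One set of scan matrices shared by shape/transpose/determinism tests:
    the same two-site scan run twice plus the site-swapped scan."""
    view, _ = scan_view
    site_a, site_b = ("B", 1, ""), ("B", 2, "")
    mat = scan_pair(view, site_a, site_b, affinity_params=default_params,
                    seed=7)
    mat_again = scan_pair(view, site_a, site_b,
                          affinity_params=default_params, seed=7)
    mat_swapped = scan_pair(view, site_b, site_a,
                            affinity_params=default_params, seed=7)
    return {"mat": mat, "again": mat_again, "swapped": mat_swapped}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
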