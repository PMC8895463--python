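"""Structure handling: parsing, desalting, descriptors, fingerprints, Tanimoto."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypscreen.chemstruct import (
    Fingerprint,
    FingerprintConfig,
    InorganicError,
    MoleculeParseError,
    compute_descriptors,
    desalt,
    fingerprint,
    parse_and_canonicalize,
    tanimoto_distance,
)
from cypscreen.synthetic_data import generate_library


class TestParsing:
    def test_simple_molecule(self):
        mol = parse_and_canonicalize("CCO", "ethanol")
        assert mol.n_fragments_input == 1
        assert mol.rdmol.GetNumHeavyAtoms() == 3

    @pytest.mark.parametrize("bad", ["C(", "", "   ", "not_smiles("])
    def test_malformed_input_raises_with_id(self, bad):
        with pytest.raises(MoleculeParseError) as exc:
            parse_and_canonicalize(bad, "x17")
        assert exc.value.compound_id == "x17"

    def test_dot_disconnected_fragment_count(self):
        mol = parse_and_canonicalize("[Na+].CC(=O)[O-]", "na-acetate")
        assert mol.n_fragments_input == 2

    def test_canonicalization_idempotent_and_input_invariant(self):
        a = parse_and_canonicalize("c1ccccc1O", "a")
        b = parse_and_canonicalize("Oc1ccccc1", "b")
        assert a.smiles_canonical == b.smiles_canonical
        again = parse_and_canonicalize(a.smiles_canonical, "a2")
        assert again.smiles_canonical == a.smiles_canonical

    def test_canonicalization_idempotent_over_synthetic_library(self):
        lib = generate_library(150, seed=3)
        for mol in lib.molecules:
            assert parse_and_canonicalize(mol.smiles_canonical, mol.id).smiles_canonical \
                == mol.smiles_canonical


class TestDesalt:
    def test_keeps_larger_organic_fragment(self):
        mol = desalt(parse_and_canonicalize("[Na+].CC(=O)[O-]", "s"))
        assert mol.smiles_canonical == parse_and_canonicalize("CC(=O)[O-]", "f").smiles_canonical

    def test_single_fragment_unchanged(self):
        mol = parse_and_canonicalize("CCO", "e")
        assert desalt(mol).smiles_canonical == mol.smiles_canonical

    def test_inorganic_salt_raises(self):
        with pytest.raises(InorganicError):
            desalt(parse_and_canonicalize("[Na+].[Cl-]", "nacl"))

    def test_idempotence(self):
        mol = parse_and_canonicalize("CCN.Cl", "amine-hcl")
        once = desalt(mol)
        assert desalt(once).smiles_canonical == once.smiles_canonical


# hand-listed molecules with hand-counted formulas; the oracle sums standard
# atomic masses independently of any cheminformatics library
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999}
HAND_LISTED = [
    ("C", dict(C=1, H=4)),                 # methane
    ("CC", dict(C=2, H=6)),                # ethane
    ("CCO", dict(C=2, H=6, O=1)),          # ethanol
    ("CO", dict(C=1, H=4, O=1)),           # methanol
    ("C=O", dict(C=1, H=2, O=1)),          # formaldehyde
    ("CC(=O)O", dict(C=2, H=4, O=2)),      # acetic acid
    ("c1ccccc1", dict(C=6, H=6)),          # benzene
    ("Cc1ccccc1", dict(C=7, H=8)),         # toluene
    ("c1ccncc1", dict(C=5, H=5, N=1)),     # pyridine
    ("CN", dict(C=1, H=5, N=1)),           # methylamine
    ("N", dict(N=1, H=3)),                 # ammonia
    ("O", dict(O=1, H=2)),                 # water
    ("C#N", dict(C=1, H=1, N=1)),          # hydrogen cyanide
    ("CC(C)C", dict(C=4, H=10)),           # isobutane
    ("OCC(O)CO", dict(C=3, H=8, O=3)),     # glycerol
    ("CC(=O)C", dict(C=3, H=6, O=1)),      # acetone
    ("NC(=O)N", dict(C=1, H=4, N=2, O=1)), # urea
    ("C1CCCCC1", dict(C=6, H=12)),         # cyclohexane
    ("OC(=O)c1ccccc1", dict(C=7, H=6, O=2)),  # benzoic acid
    ("Nc1ccccc1", dict(C=6, H=7, N=1)),    # aniline
]


class TestDescriptors:
    @pytest.mark.parametrize("smiles,formula", HAND_LISTED)
    def test_mw_agrees_with_atomic_mass_oracle(self, smiles, formula):
        expected = sum(ATOMIC_MASS[el] * n for el, n in formula.items())
        d = compute_descriptors(parse_and_canonicalize(smiles, smiles))
        assert d.mw == pytest.approx(expected, abs=0.01)

    def test_piperine_matches_printed_values(self):
        # CAS 94-62-2
        mol = parse_and_canonicalize("O=C(/C=C/C=C/c1ccc2OCOc2c1)N1CCCCC1", "piperine")
        d = compute_descriptors(mol)
        assert d.mw == pytest.approx(285.3, abs=0.2)
        assert d.hbd == 0

    def test_ethanol_donor_acceptor_convention(self):
        d = compute_descriptors(parse_and_canonicalize("CCO", "ethanol"))
        assert d.mw == pytest.approx(46.07, abs=0.01)
        assert (d.hbd, d.hba) == (1, 1)

    def test_methane_has_no_polar_counts(self):
        d = compute_descriptors(parse_and_canonicalize("C", "methane"))
        assert d.mw == pytest.approx(16.04, abs=0.01)
        assert (d.hbd, d.hba) == (0, 0)

    def test_all_fields_finite_and_positive_mw(self):
        lib = generate_library(60, seed=5)
        for mol in lib.molecules:
            d = compute_descriptors(desalt(mol)) if mol.n_fragments_input == 1 else None
            if d is not None:
                assert d.mw > 0 and np.isfinite([d.mw, d.logp]).all()
                assert d.hbd >= 0 and d.hba >= 0


class TestFingerprint:
    def test_deterministic(self):
        a = fingerprint(parse_and_canonicalize("c1ccccc1", "b1"))
        b = fingerprint(parse_and_canonicalize("c1ccccc1", "b2"))
        assert a.bits == b.bits

    def test_benzene_nonempty_and_differs_from_cyclohexane(self):
        a = fingerprint(parse_and_canonicalize("c1ccccc1", "bz"))
        b = fingerprint(parse_and_canonicalize("C1CCCCC1", "ch"))
        assert a.bits
        assert a.bits != b.bits
        assert tanimoto_distance(a, b) > 0

    def test_path_fingerprint_config(self):
        cfg = FingerprintConfig(kind="path", n_bits=1024)
        fp = fingerprint(parse_and_canonicalize("CCO", "e"), cfg)
        assert fp.length == 1024 and fp.bits


class TestTanimoto:
    def test_identity_and_disjoint(self):
        a = Fingerprint(frozenset({1, 2, 3}), 16)
        b = Fingerprint(frozenset({4, 5}), 16)
        assert tanimoto_distance(a, a) == 0.0
        assert tanimoto_distance(a, b) == 1.0

    def test_worked_example(self):
        a = Fingerprint(frozenset({1, 2, 3}), 16)
        b = Fingerprint(frozenset({2, 3, 4}), 16)
        assert tanimoto_distance(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_as_zero(self):
        e = Fingerprint(frozenset(), 16)
        assert tanimoto_distance(e, e) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto_distance(Fingerprint(frozenset({1}), 8), Fingerprint(frozenset({1}), 16))

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.frozensets(st.integers(0, 63), max_size=40),
        b=st.frozensets(st.integers(0, 63), max_size=40),
    )
    def test_symmetry_and_range(self, a, b):
        fa, fb = Fingerprint(a, 64), Fingerprint(b, 64)
        d_ab = tanimoto_distance(fa, fb)
        assert d_ab == tanimoto_distance(fb, fa)
        assert 0.0 <= d_ab <= 1.0
        assert (d_ab == 0.0) == (a == b)
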