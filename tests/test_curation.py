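"""Labeling rules, duplicate resolution, stratified splitting, library cleanup."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypscreen.chemstruct import Molecule
from cypscreen.curation import (
    BioassayRecord,
    CurationLog,
    LabeledCompound,
    SplitError,
    curate_library,
    label_records,
    resolve_duplicates,
    stratified_split,
)


def rec(cid, smiles="CCO", curve_class=-1.1, efficacy=90.0, potency=None):
    return BioassayRecord(cid, smiles, curve_class, efficacy, potency)


def fake_compound(cid, label):
    """A labeled compound with a unique synthetic structure; no parsing needed."""
    mol = Molecule(id=cid, smiles_input=cid, smiles_canonical=cid, n_fragments_input=1)
    return LabeledCompound(molecule=mol, label=label, source_record_ids=[cid])


class TestLabeling:
    def test_full_curve_high_efficacy_is_active(self):
        out = label_records([rec("a", curve_class=-1.1, efficacy=85)])
        assert [c.label for c in out] == ["active"]

    def test_inactive_curve_class(self):
        out = label_records([rec("a", curve_class=4.0, efficacy=None)])
        assert [c.label for c in out] == ["inactive"]

    def test_other_curve_classes_excluded_as_inconclusive(self):
        log = CurationLog()
        out = label_records([rec("a", curve_class=-2.2, efficacy=85)], log=log)
        assert out == []
        assert log.counts["inconclusive_curve_class"] == 1

    def test_low_efficacy_active_curve_rejected(self):
        out = label_records([rec("a", curve_class=-1.1, efficacy=60)])
        assert out == []

    def test_missing_curve_class_rejected_with_reason(self):
        log = CurationLog()
        label_records([rec("a", curve_class=None)], log=log)
        assert log.rejected == [("a", "missing_curve_class")]

    def test_multiorganic_mixture_removed_but_salt_kept(self):
        log = CurationLog()
        out = label_records(
            [rec("mix", smiles="CCO.CCN"), rec("salt", smiles="[Na+].CC(=O)[O-]")],
            log=log,
        )
        assert [c.molecule.id for c in out] == ["salt"]
        assert log.counts["fragmented_mixture"] == 1


class TestDuplicates:
    def test_same_label_collapses_keeping_smallest_id(self):
        out = resolve_duplicates(
            label_records([rec("b2"), rec("a1")])
        )
        assert len(out) == 1
        assert out[0].molecule.id == "a1"
        assert out[0].source_record_ids == ["a1", "b2"]

    def test_conflicting_labels_removed_entirely(self):
        out = resolve_duplicates(
            label_records([rec("a", curve_class=-1.1), rec("b", curve_class=4.0)])
        )
        assert out == []

    def test_distinct_structures_both_retained(self):
        out = resolve_duplicates(
            label_records([rec("a", smiles="CCO"), rec("b", smiles="CCN", curve_class=4.0)])
        )
        assert len(out) == 2

    def test_idempotent_on_own_output(self):
        candidates = label_records([rec("a"), rec("b"), rec("c", smiles="CCN")])
        once = resolve_duplicates(candidates)
        twice = resolve_duplicates(once)
        assert [(c.molecule.id, c.label) for c in once] == [
            (c.molecule.id, c.label) for c in twice
        ]


class TestStratifiedSplit:
    def test_printed_class_sizes_give_printed_train_counts(self):
        # 1760 actives / 8893 inactives at 75 % -> 1320 / 6670 in training
        dataset = [fake_compound(f"a{i}", "active") for i in range(1760)] + [
            fake_compound(f"i{i}", "inactive") for i in range(8893)
        ]
        split = stratified_split(dataset, fraction_train=0.75, seed=1)
        train_active = sum(c.label == "active" for c in split.train)
        train_inactive = sum(c.label == "inactive" for c in split.train)
        assert (train_active, train_inactive) == (1320, 6670)
        assert len(split.validation) == 1760 + 8893 - 1320 - 6670

    def test_same_seed_identical_membership(self):
        dataset = [fake_compound(f"a{i}", "active") for i in range(9)] + [
            fake_compound(f"i{i}", "inactive") for i in range(40)
        ]
        s1 = stratified_split(dataset, seed=5)
        s2 = stratified_split(dataset, seed=5)
        assert [c.molecule.id for c in s1.train] == [c.molecule.id for c in s2.train]

    def test_degenerate_fraction_rejected(self):
        dataset = [fake_compound("a", "active"), fake_compound("a2", "active"),
                   fake_compound("i", "inactive"), fake_compound("i2", "inactive")]
        with pytest.raises(SplitError):
            stratified_split(dataset, fraction_train=1.0)

    def test_single_class_rejected(self):
        with pytest.raises(SplitError):
            stratified_split([fake_compound("a", "active"), fake_compound("b", "active")])

    @settings(derandomize=True, max_examples=50)
    @given(
        n_active=st.integers(4, 60),
        n_inactive=st.integers(4, 200),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_class_ratio_and_disjointness(self, n_active, n_inactive, seed):
        dataset = [fake_compound(f"a{i}", "active") for i in range(n_active)] + [
            fake_compound(f"i{i}", "inactive") for i in range(n_inactive)
        ]
        split = stratified_split(dataset, fraction_train=0.75, seed=seed)
        train_ids = {c.molecule.id for c in split.train}
        val_ids = {c.molecule.id for c in split.validation}
        assert not train_ids & val_ids
        assert len(train_ids | val_ids) == len(dataset)
        for label, n in (("active", n_active), ("inactive", n_inactive)):
            in_train = sum(c.label == label for c in split.train)
            assert in_train == int(np.floor(0.75 * n + 0.5))

    def test_no_inconclusive_record_reaches_a_split(self):
        records = [rec(f"c{i}", smiles="C" * (i + 1)) for i in range(8)]
        records += [rec(f"x{i}", smiles="CCO", curve_class=-2.2) for i in range(4)]
        records += [rec(f"n{i}", smiles="N" + "C" * (i + 1), curve_class=4.0, efficacy=None)
                    for i in range(8)]
        labeled = resolve_duplicates(label_records(records))
        split = stratified_split(labeled, seed=0)
        all_ids = {c.molecule.id for c in split.train + split.validation}
        assert not {f"x{i}" for i in range(4)} & all_ids


class TestCurateLibrary:
    def test_constructed_fixture_bookkeeping(self):
        # 85 unique alkanes + 10 duplicates + 5 inorganics = 100 rows;
        # 3 exclusion-list members -> 82 survivors
        rows = [(f"u{i}", "C" * (i + 1)) for i in range(85)]
        rows += [(f"d{i}", "C" * (i + 1)) for i in range(10)]
        rows += [(f"q{i}", s) for i, s in enumerate(
            ["[Na+].[Cl-]", "O", "[K+].[Br-]", "N", "OS(=O)(=O)O"])]
        assert len(rows) == 100
        exclusion = ["C" * 30, "C" * 31, "C" * 32]
        lib = curate_library(rows, exclusion_list=exclusion)
        assert len(lib.molecules) == 82
        assert lib.log.counts == dict(inorganic=5, duplicate=10, exclusion_list=3)

    def test_duplicate_by_canonical_structure(self):
        lib = curate_library([("a", "OCC"), ("b", "CCO")])
        assert [m.id for m in lib.molecules] == ["a"]

    def test_exclusion_by_registry_id(self):
        lib = curate_library([("cas-50-00-0", "C=O"), ("ok", "CCO")],
                             exclusion_list=["cas-50-00-0"])
        assert [m.id for m in lib.molecules] == ["ok"]
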