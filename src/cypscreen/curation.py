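"""Bioassay curation: labels, duplicates, stratified split, library cleanup.

Dose-response bioassay records (PubChem-style curve classes) become binary
active/inactive labels:

* active   — curve class -1.1 (full, high-efficacy inhibition curve) with
  efficacy >= 80 % of control,
* inactive — curve class 4.0,
* every other curve class is inconclusive and excluded.

Mixtures that still contain more than one organic fragment after desalting
are removed. Duplicates are resolved on the canonical desalted structure:
same-label duplicates collapse to one entry, conflicting labels remove the
compound entirely. The curated set is then split 75/25 per class with the
active:inactive ratio preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .chemstruct import (
    InorganicError,
    Molecule,
    MoleculeParseError,
    desalt,
    n_organic_fragments,
    parse_and_canonicalize,
)

ACTIVE_CURVE_CLASS = -1.1
INACTIVE_CURVE_CLASS = 4.0
DEFAULT_EFFICACY_THRESHOLD = 80.0

# Potency range observed among curated actives; recorded as metadata only,
# never applied as a filter (labeling is by curve class).
ACTIVE_POTENCY_RANGE_UM = (0.032, 15.85)


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class BioassayRecord:
    """One compound's dose-response outcome before labeling."""

    compound_id: str
    smiles: str
    curve_class: Optional[float]
    efficacy: Optional[float] = None   # percent of control
    potency: Optional[float] = None    # uM


@dataclass
class LabeledCompound:
    molecule: Molecule
    label: str                         # "active" | "inactive"
    source_record_ids: List[str] = field(default_factory=list)


@dataclass
class CurationLog:
    """Row-level removal bookkeeping; reasons -> counts plus rejected ids."""

    counts: Dict[str, int] = field(default_factory=dict)
    rejected: List[Tuple[str, str]] = field(default_factory=list)

    def note(self, compound_id: str, reason: str) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1
        self.rejected.append((compound_id, reason))


@dataclass
class DatasetSplit:
    train: List[LabeledCompound]
    validation: List[LabeledCompound]
    seed: int
    fraction_train: float


def label_records(
    records: Iterable[BioassayRecord],
    efficacy_threshold: float = DEFAULT_EFFICACY_THRESHOLD,
    log: Optional[CurationLog] = None,
) -> List[LabeledCompound]:
    """Assign active/inactive labels by curve class; drop everything else.

    Returned candidates carry canonical desalted structures; duplicate
    resolution is a separate pass (:func:`resolve_duplicates`).
    """
    log = log if log is not None else CurationLog()
    out: List[LabeledCompound] = []
    for rec in records:
        if rec.curve_class is None or (
            isinstance(rec.curve_class, float) and math.isnan(rec.curve_class)
        ):
            log.note(rec.compound_id, "missing_curve_class")
            continue
        if rec.curve_class == ACTIVE_CURVE_CLASS:
            if rec.efficacy is None or rec.efficacy < efficacy_threshold:
                log.note(rec.compound_id, "low_efficacy")
                continue
            label = "active"
        elif rec.curve_class == INACTIVE_CURVE_CLASS:
            label = "inactive"
        else:
            log.note(rec.compound_id, "inconclusive_curve_class")
            continue
        try:
            mol = parse_and_canonicalize(rec.smiles, rec.compound_id)
        except MoleculeParseError:
            log.note(rec.compound_id, "unparsable")
            continue
        if n_organic_fragments(mol) > 1:
            log.note(rec.compound_id, "fragmented_mixture")
            continue
        try:
            mol = desalt(mol)
        except InorganicError:
            log.note(rec.compound_id, "inorganic")
            continue
        out.append(LabeledCompound(molecule=mol, label=label,
                                   source_record_ids=[rec.compound_id]))
    return out


def resolve_duplicates(candidates: Sequence[LabeledCompound]) -> List[LabeledCompound]:
    """Collapse same-label duplicates, discard conflicting-label ones.

    The duplicate key is the canonical desalted structure. Same-label groups
    keep a single entry whose id is the lexicographically smallest source id
    (all source ids are retained in ``source_record_ids``).
    """
    by_structure: Dict[str, List[LabeledCompound]] = {}
    order: List[str] = []
    for cand in candidates:
        key = cand.molecule.smiles_canonical
        if key not in by_structure:
            order.append(key)
        by_structure.setdefault(key, []).append(cand)

    out: List[LabeledCompound] = []
    for key in order:
        group = by_structure[key]
        labels = {c.label for c in group}
        if len(labels) > 1:
            continue  # conflicting activities: drop the compound entirely
        ids = sorted(i for c in group for i in c.source_record_ids)
        keeper = min(group, key=lambda c: min(c.source_record_ids))
        out.append(
            LabeledCompound(molecule=keeper.molecule, label=keeper.label,
                            source_record_ids=ids)
        )
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    dataset: Sequence[LabeledCompound],
    fraction_train: float = 0.75,
    seed: int = 0,
) -> DatasetSplit:
    """Per-class shuffled split preserving the active:inactive ratio.

    Per-class training counts are round(fraction * class size), half-up, so
    the rounding remainder goes to the training side. Reproducible for a
    fixed seed.
    """
    if not 0 < fraction_train < 1:
        raise SplitError("fraction_train must be in (0, 1)")
    by_label: Dict[str, List[LabeledCompound]] = {}
    for c in dataset:
        by_label.setdefault(c.label, []).append(c)
    if len(by_label) < 2:
        raise SplitError("both classes must be present")
    rng = np.random.default_rng(seed)
    train: List[LabeledCompound] = []
    validation: List[LabeledCompound] = []
    for label in sorted(by_label):
        members = by_label[label]
        if len(members) < 2:
            raise SplitError(f"class {label!r} has fewer than 2 members")
        idx = rng.permutation(len(members))
        n_train = _round_half_up(fraction_train * len(members))
        if n_train == 0 or n_train == len(members):
            raise SplitError(f"degenerate split for class {label!r}")
        train.extend(members[i] for i in idx[:n_train])
        validation.extend(members[i] for i in idx[n_train:])
    return DatasetSplit(train=train, validation=validation, seed=seed,
                        fraction_train=fraction_train)


@dataclass
class CuratedLibrary:
    molecules: List[Molecule]
    log: CurationLog


def curate_library(
    compounds: Iterable,
    exclusion_list: Iterable[str] = (),
    log: Optional[CurationLog] = None,
) -> CuratedLibrary:
    """Prepare a screening library: desalt, deduplicate, drop inorganics and
    exclusion-list members.

    ``compounds`` may hold :class:`Molecule` objects or ``(id, smiles)``
    pairs. Exclusion entries that parse as SMILES match on the canonical
    desalted structure; anything else matches on the compound id (e.g. a
    registry number). The first occurrence of each canonical structure wins.
    """
    log = log if log is not None else CurationLog()
    excl_structures: Set[str] = set()
    excl_ids: Set[str] = set()
    for entry in exclusion_list:
        entry = str(entry).strip()
        if not entry:
            continue
        try:
            mol = desalt(parse_and_canonicalize(entry, entry))
            excl_structures.add(mol.smiles_canonical)
        except (MoleculeParseError, InorganicError):
            excl_ids.add(entry)

    seen: Set[str] = set()
    kept: List[Molecule] = []
    for item in compounds:
        if isinstance(item, Molecule):
            mol_in = item
        else:
            cid, smiles = item
            try:
                mol_in = parse_and_canonicalize(str(smiles), str(cid))
            except MoleculeParseError:
                log.note(str(cid), "unparsable")
                continue
        try:
            mol = desalt(mol_in)
        except InorganicError:
            log.note(mol_in.id, "inorganic")
            continue
        if mol.id in excl_ids or mol.smiles_canonical in excl_structures:
            log.note(mol.id, "exclusion_list")
            continue
        if mol.smiles_canonical in seen:
            log.note(mol.id, "duplicate")
            continue
        seen.add(mol.smiles_canonical)
        kept.append(mol)
    return CuratedLibrary(molecules=kept, log=log)


# ---------------------------------------------------------------------------
# I/O

BIOASSAY_COLUMNS = ("compound_id", "smiles", "curve_class", "efficacy", "potency")


def read_bioassay_csv(path) -> List[BioassayRecord]:
    """CSV schema: compound_id, smiles, curve_class, efficacy, potency."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        def _opt(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        records.append(
            BioassayRecord(
                compound_id=str(row["compound_id"]),
                smiles=str(row["smiles"]),
                curve_class=_opt("curve_class"),
                efficacy=_opt("efficacy"),
                potency=_opt("potency"),
            )
        )
    return records


def write_labeled_csv(dataset: Sequence[LabeledCompound], path) -> pd.DataFrame:
    df = pd.DataFrame(
        dict(
            compound_id=[c.molecule.id for c in dataset],
            smiles_canonical=[c.molecule.smiles_canonical for c in dataset],
            label=[c.label for c in dataset],
            source_record_ids=[";".join(c.source_record_ids) for c in dataset],
        )
    )
    df.to_csv(path, index=False)
    return df


def write_split_manifest(split: DatasetSplit, path) -> pd.DataFrame:
    rows = []
    for part, members in (("train", split.train), ("validation", split.validation)):
        for c in members:
            rows.append(dict(compound_id=c.molecule.id, label=c.label, subset=part))
    df = pd.DataFrame(rows)
    df.attrs["seed"] = split.seed
    with open(path, "w") as fh:
        fh.write(f"# seed={split.seed} fraction_train={split.fraction_train}\n")
        df.to_csv(fh, index=False)
    return df
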