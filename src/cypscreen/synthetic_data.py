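"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the three data sources the pipeline consumes:

* :func:`generate_library` assembles valid SMILES from a small fragment
  grammar (ring scaffolds x decorating substituents), optionally salting
  entries, planting exact duplicates, and mixing in inorganic rows so the
  curation stage has something to remove.
* :func:`plant_bioassay` turns a library into dose-response bioassay
  records under a planted structure-activity rule: compounds carrying the
  methylenedioxyphenyl (benzodioxole) motif are active with high
  probability, the background is almost all inactive, and the resulting
  class imbalance matches the roughly 1:5 active:inactive ratio of curated
  public CYP3A4 bioassay data.
* :func:`simulate_curve` samples noisy 4PL inhibition curves at the
  seven-point 3-fold dilution series used by the in vitro assay.

All generators are reproducible from (seed, config) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .chemstruct import Molecule, parse_and_canonicalize
from .curation import ACTIVE_POTENCY_RANGE_UM, BioassayRecord
from .dose_response import DEFAULT_CONCENTRATIONS_UM, InhibitionCurve, four_pl

# --------------------------------------------------------------------------
# fragment grammar
#
# Scaffold templates carry one or two branch slots written ({a}) / ({b}) or
# trailing {a} / {b}; empty substituents remove the branch. Substituents are
# plain fragments whose first atom is the attachment point. None of the
# substituents can complete a fused OCO ring, so the benzodioxole motif is
# present exactly when a motif scaffold was chosen — the planted rule is
# unambiguous.

PLAIN_SCAFFOLDS = (
    "c1cc({a})cc({b})c1",
    "c1cc({a})ccc1{b}",
    "c1cc({a})cnc1{b}",
    "c1cc({a})ncc1{b}",
    "c1cc({a})oc1{b}",
    "c1cc({a})sc1{b}",
    "C1CC({a})CCC1{b}",
    "C1CC({a})NCC1{b}",
    "C1CC({a})OCC1{b}",
    "c1ccc2ccc({a})cc2c1{b}",
    "c1cc2cccnc2c({a})c1{b}",
    "O=c1ccc2ccc({a})cc2o1",
    "O=C1CCC({a})CC1{b}",
    "c1cc({a})c(O)cc1{b}",
)

MOTIF_SCAFFOLDS = (
    "c1cc2OCOc2cc1{a}",
    "c1cc2OCOc2c({b})c1{a}",
    "O=C({a})/C=C/c1ccc2OCOc2c1",
    "C({a})c1ccc2OCOc2c1",
)

# substituent ring closures use digit 3 so they never collide with the
# scaffold's ring numbering (1 and 2)
SUBSTITUENTS = (
    "", "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "Cl", "F", "Br", "C#N", "C(=O)O", "C(=O)OC", "C(=O)N", "C(=O)C", "CO",
    "CCO", "OC(C)=O", "S(C)(=O)=O", "[N+](=O)[O-]", "C(F)(F)F", "c3ccccc3",
    "Cc3ccccc3", "Oc3ccccc3", "OCc3ccccc3", "C=C", "C#C", "NS(C)(=O)=O",
    "OC(F)F", "C3CC3", "N3CCCC3", "N3CCOCC3", "C(=O)N3CCCCC3",
    "/C=C/C(N)=O", "SC",
)

SALT_SUFFIXES = (".Cl", ".[Na+]", ".OS(=O)(=O)O")

INORGANIC_SMILES = ("[Na+].[Cl-]", "[K+].[Br-]", "O", "OS(=O)(=O)O", "N")

ACTIVE_MOTIF_SMARTS = "c1ccc2c(c1)OCO2"  # methylenedioxyphenyl


def _fill(template: str, a: str, b: str) -> str:
    t = template
    t = t.replace("({a})", f"({a})" if a else "")
    t = t.replace("({b})", f"({b})" if b else "")
    t = t.replace("{a}", a).replace("{b}", b)
    return t


@dataclass(frozen=True)
class GrammarConfig:
    motif_fraction: float = 0.17        # share of entries on a motif scaffold
    salt_fraction: float = 0.0          # share emitted as a salt form
    duplicate_fraction: float = 0.0     # share that duplicates an earlier entry
    inorganic_fraction: float = 0.0     # share of inorganic rows


@dataclass(frozen=True)
class SarGroundTruth:
    """The planted structure-activity rule for bioassay generation."""

    active_substructure: str = ACTIVE_MOTIF_SMARTS
    activation_probability: float = 0.95
    background_active_probability: float = 0.005
    label_noise: float = 0.0
    seed: int = 0


@dataclass
class SyntheticLibrary:
    molecules: List[Molecule]
    manifest: Dict = field(default_factory=dict)


def generate_library(
    n: int,
    seed: int,
    grammar_config: GrammarConfig = GrammarConfig(),
) -> SyntheticLibrary:
    """Emit ``n`` library entries; every structure parses.

    The manifest records, per entry, whether it sits on a motif scaffold,
    its salt form, and planted duplicate pairs (duplicate id -> original id).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = grammar_config
    rng = np.random.default_rng(seed)

    n_inorganic = int(round(cfg.inorganic_fraction * n))
    n_dup = int(round(cfg.duplicate_fraction * n))
    n_fresh = n - n_inorganic - n_dup
    if n_fresh < 1:
        raise ValueError("inorganic + duplicate fractions leave no fresh entries")
    if n_dup > n_fresh:
        raise ValueError("more duplicates requested than fresh entries")

    molecules: List[Molecule] = []
    entries: Dict[str, Dict] = {}
    fresh_ids: List[str] = []
    for i in range(n_fresh):
        cid = f"SYN{i:06d}"
        on_motif = rng.random() < cfg.motif_fraction
        scaffolds = MOTIF_SCAFFOLDS if on_motif else PLAIN_SCAFFOLDS
        template = scaffolds[rng.integers(len(scaffolds))]
        a = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        b = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        smiles = _fill(template, a, b)
        salted = rng.random() < cfg.salt_fraction
        if salted:
            smiles = smiles + SALT_SUFFIXES[rng.integers(len(SALT_SUFFIXES))]
        mol = parse_and_canonicalize(smiles, cid)
        molecules.append(mol)
        fresh_ids.append(cid)
        entries[cid] = dict(motif=bool(on_motif), salt=bool(salted),
                            inorganic=False, duplicate_of=None)

    duplicate_pairs: List[Tuple[str, str]] = []
    if n_dup:
        originals = rng.choice(len(fresh_ids), size=n_dup, replace=False)
        for j, orig_idx in enumerate(originals):
            orig = molecules[orig_idx]
            cid = f"SYNDUP{j:05d}"
            mol = parse_and_canonicalize(orig.smiles_input, cid)
            molecules.append(mol)
            entries[cid] = dict(motif=entries[orig.id]["motif"], salt=entries[orig.id]["salt"],
                                inorganic=False, duplicate_of=orig.id)
            duplicate_pairs.append((cid, orig.id))

    for j in range(n_inorganic):
        cid = f"SYNINORG{j:05d}"
        smiles = INORGANIC_SMILES[rng.integers(len(INORGANIC_SMILES))]
        molecules.append(parse_and_canonicalize(smiles, cid))
        entries[cid] = dict(motif=False, salt=False, inorganic=True, duplicate_of=None)

    order = rng.permutation(len(molecules))
    molecules = [molecules[i] for i in order]

    return SyntheticLibrary(
        molecules=molecules,
        manifest=dict(
            seed=seed,
            config=cfg,
            entries=entries,
            duplicate_pairs=duplicate_pairs,
            n_inorganic=n_inorganic,
        ),
    )


def plant_bioassay(
    library: SyntheticLibrary,
    truth: SarGroundTruth,
    inconclusive_fraction: float = 0.0,
) -> Tuple[List[BioassayRecord], Dict[str, bool]]:
    """Bioassay records under the planted rule, plus the true labels.

    Actives get curve class -1.1 with efficacy uniform in [80, 100] and
    potency log-uniform over the curated active potency range; everything
    else gets curve class 4.0. A configurable fraction is reassigned an
    inconclusive curve class (excluded downstream). The returned mapping
    id -> bool is the generator's ground truth, independent of any noise
    applied to the records.
    """
    rng = np.random.default_rng(truth.seed)
    motif = Chem.MolFromSmarts(truth.active_substructure)
    inconclusive_codes = (-2.1, 1.1, 2.1, 3.0)
    lo, hi = ACTIVE_POTENCY_RANGE_UM

    records: List[BioassayRecord] = []
    true_labels: Dict[str, bool] = {}
    for mol in library.molecules:
        has_motif = mol.rdmol is not None and mol.rdmol.HasSubstructMatch(motif)
        p = truth.activation_probability if has_motif else truth.background_active_probability
        active = bool(rng.random() < p)
        true_labels[mol.id] = active
        label = active
        if truth.label_noise and rng.random() < truth.label_noise:
            label = not label
        if rng.random() < inconclusive_fraction:
            curve_class = float(inconclusive_codes[rng.integers(len(inconclusive_codes))])
            efficacy = float(rng.uniform(0, 80))
            potency = None
        elif label:
            curve_class = -1.1
            efficacy = float(rng.uniform(80, 100))
            potency = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            curve_class = 4.0
            efficacy = float(rng.uniform(0, 20))
            potency = None
        records.append(
            BioassayRecord(
                compound_id=mol.id,
                smiles=mol.smiles_input,
                curve_class=curve_class,
                efficacy=efficacy,
                potency=potency,
            )
        )
    return records, true_labels


def simulate_curve(
    ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    noise_sd: float = 5.0,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS_UM,
    replicates: int = 3,
    seed: int = 0,
) -> InhibitionCurve:
    """Noisy 4PL inhibition curve at the assay's dilution series."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    clean = four_pl(conc, np.log(ic50), hill, bottom, top - bottom)
    if noise_sd > 0:
        activity = clean[:, None] + rng.normal(0.0, noise_sd, size=(len(conc), replicates))
    else:
        activity = np.tile(clean[:, None], (1, replicates))
    return InhibitionCurve(concentrations=conc, activity=activity)
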