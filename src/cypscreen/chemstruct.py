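"""Molecular structure handling.

Everything downstream of raw SMILES flows through this module: parsing and
canonicalization, desalting (largest organic fragment), physicochemical
descriptors (MW, logP, HBD, HBA), hashed fingerprints, and the Tanimoto
distance used by the applicability domain.

Descriptor conventions
----------------------
* MW: exact molecular weight from standard atomic masses (average isotopic
  composition).
* logP: Crippen atom-contribution octanol/water partition coefficient.
* HBD: number of N-H and O-H hydrogens (Lipinski donor count).
* HBA: Lipinski acceptor count (N and O, excluding e.g. amide nitrogens and
  pyrrole-type aromatic nitrogens per the RDKit definition).

One convention is used throughout a run; it is never mixed with others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the offending id."""

    def __init__(self, compound_id: str, smiles: str):
        self.compound_id = compound_id
        self.smiles = smiles
        super().__init__(f"unparsable structure for {compound_id!r}: {smiles!r}")


class InorganicError(ValueError):
    """Raised when desalting finds no carbon-containing fragment."""


@dataclass(frozen=True)
class DescriptorSet:
    """The four Lipinski-relevant descriptors of a single-fragment molecule."""

    mw: float      # g/mol
    logp: float    # unitless, Crippen atom contributions
    hbd: int       # H-bond donors
    hba: int       # H-bond acceptors


@dataclass(frozen=True)
class FingerprintConfig:
    """Hashed-fingerprint settings, fixed per run.

    kind='morgan' is the circular (ECFP-like) fingerprint, the standard
    choice for Tanimoto-based applicability domains; kind='path' selects the
    RDKit path-based (Daylight-like) fingerprint.
    """

    kind: str = "morgan"
    radius: int = 2
    n_bits: int = 2048

    def generator(self):
        if self.kind == "morgan":
            return rdFingerprintGenerator.GetMorganGenerator(
                radius=self.radius, fpSize=self.n_bits
            )
        if self.kind == "path":
            return rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=self.n_bits)
        raise ValueError(f"unknown fingerprint kind {self.kind!r}")


@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset
    length: int

    def __post_init__(self):
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.length):
            raise ValueError("bit positions outside [0, length)")


@dataclass
class Molecule:
    """A parsed compound: raw input, canonical form, and lazy annotations."""

    id: str
    smiles_input: str
    smiles_canonical: str
    n_fragments_input: int
    descriptors: Optional[DescriptorSet] = None
    fingerprint: Optional[Fingerprint] = None
    _rdmol: object = field(default=None, repr=False, compare=False)

    @property
    def rdmol(self):
        if self._rdmol is None:
            self._rdmol = Chem.MolFromSmiles(self.smiles_canonical)
        return self._rdmol


def parse_and_canonicalize(smiles: str, id: str = "") -> Molecule:
    """Parse a SMILES string and store its canonical form.

    Raises :class:`MoleculeParseError` for malformed input; callers that
    stream libraries catch it and log the offending id rather than dropping
    rows silently.
    """
    if not smiles or not smiles.strip():
        raise MoleculeParseError(id, smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(id, smiles)
    n_frags = len(Chem.GetMolFrags(mol))
    return Molecule(
        id=id,
        smiles_input=smiles,
        smiles_canonical=Chem.MolToSmiles(mol),
        n_fragments_input=n_frags,
        _rdmol=mol,
    )


def n_organic_fragments(mol: Molecule) -> int:
    """Number of carbon-containing fragments in the (possibly multi-part) input."""
    frags = Chem.GetMolFrags(mol.rdmol, asMols=True, sanitizeFrags=False)
    return sum(
        1
        for f in frags
        if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
    )


def desalt(mol: Molecule) -> Molecule:
    """Keep the largest organic fragment of a multi-fragment structure.

    The retained fragment is the carbon-containing one with the most heavy
    atoms; ties break on the lexicographically smallest canonical SMILES so
    the choice is deterministic. Single-fragment input is returned unchanged.
    """
    if mol.n_fragments_input == 1:
        frag = mol.rdmol
        if not any(a.GetAtomicNum() == 6 for a in frag.GetAtoms()):
            raise InorganicError(f"{mol.id!r}: no carbon-containing fragment")
        return mol
    frags = Chem.GetMolFrags(mol.rdmol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        raise InorganicError(f"{mol.id!r}: no carbon-containing fragment")
    # max heavy-atom count; tie-break on canonical text, ascending
    keyed = sorted(
        ((-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)) for f in organic)
    )
    best_smiles = keyed[0][1]
    kept = Chem.MolFromSmiles(best_smiles)
    return Molecule(
        id=mol.id,
        smiles_input=mol.smiles_input,
        smiles_canonical=Chem.MolToSmiles(kept),
        n_fragments_input=mol.n_fragments_input,
        _rdmol=kept,
    )


def compute_descriptors(mol: Molecule) -> DescriptorSet:
    """MW/logP/HBD/HBA for a desalted, single-fragment molecule."""
    m = mol.rdmol
    d = DescriptorSet(
        mw=float(Descriptors.MolWt(m)),
        logp=float(Crippen.MolLogP(m)),
        hbd=int(Lipinski.NumHDonors(m)),
        hba=int(Lipinski.NumHAcceptors(m)),
    )
    mol.descriptors = d
    return d


def fingerprint(mol: Molecule, config: FingerprintConfig = FingerprintConfig()) -> Fingerprint:
    """Hashed fingerprint of the canonical structure; deterministic per config."""
    gen = config.generator()
    bv = gen.GetFingerprint(mol.rdmol)
    fp = Fingerprint(bits=frozenset(bv.GetOnBits()), length=config.n_bits)
    mol.fingerprint = fp
    return fp


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """1 - |a & b| / |a | b|.

    Symmetric, in [0, 1], zero iff the bit sets are identical. Two empty
    fingerprints are defined to be at distance 0 (identical bit sets).
    """
    if a.length != b.length:
        raise ValueError("fingerprint lengths differ")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    inter = len(a.bits & b.bits)
    return 1.0 - inter / union


def fingerprint_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Stack fingerprints into a boolean (n, length) matrix for bulk math."""
    if not fps:
        raise ValueError("no fingerprints")
    length = fps[0].length
    out = np.zeros((len(fps), length), dtype=bool)
    for i, fp in enumerate(fps):
        if fp.length != length:
            raise ValueError("fingerprint lengths differ")
        if fp.bits:
            out[i, sorted(fp.bits)] = True
    return out


# ---------------------------------------------------------------------------
# readers / writers

def read_smiles_file(path) -> Iterator[Molecule]:
    """Whitespace-separated SMILES-per-line files, with an optional second
    column taken as the compound id."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"line{lineno}"
            yield parse_and_canonicalize(smiles, cid)


def read_csv_library(path, smiles_col: str = "smiles", id_col: str = "compound_id"):
    """Read a CSV compound library.

    Returns ``(molecules, failures)`` where failures is a list of
    (row id, reason) pairs — rows that fail to parse are reported, never
    silently dropped. All remaining columns are attached per molecule id in
    the returned DataFrame-backed ``extras``.
    """
    df = pd.read_csv(path)
    molecules, failures = [], []
    for _, row in df.iterrows():
        cid = str(row.get(id_col, ""))
        try:
            molecules.append(parse_and_canonicalize(str(row[smiles_col]), cid))
        except MoleculeParseError as exc:
            failures.append((cid, str(exc)))
    return molecules, failures


def read_sdf_library(path):
    """Read an SDF file; returns (molecules, n_failed)."""
    molecules, n_failed = [], 0
    supplier = Chem.SDMolSupplier(str(path))
    for i, m in enumerate(supplier):
        if m is None:
            n_failed += 1
            continue
        cid = m.GetProp("_Name") if m.HasProp("_Name") else f"sdf{i}"
        smiles = Chem.MolToSmiles(m)
        molecules.append(parse_and_canonicalize(smiles, cid))
    return molecules, n_failed


def write_library_csv(molecules: Iterable[Molecule], path,
                      config: FingerprintConfig = FingerprintConfig()) -> pd.DataFrame:
    """Write canonical structures + descriptors + fingerprint density to CSV."""
    rows = []
    for mol in molecules:
        d = mol.descriptors or compute_descriptors(mol)
        fp = mol.fingerprint or fingerprint(mol, config)
        rows.append(
            dict(
                compound_id=mol.id,
                smiles_canonical=mol.smiles_canonical,
                mw=round(d.mw, 2),
                logp=round(d.logp, 2),
                hbd=d.hbd,
                hba=d.hba,
                fp_density=len(fp.bits) / fp.length,
            )
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
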