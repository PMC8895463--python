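"""Virtual-screen orchestration and the intestinal non-permeability filter.

A screened compound becomes a hit when its prediction is reliable (inside
the applicability domain), its prediction index reaches the threshold
(default 0.7), and it is not on the exclusion list. Hits violating two or
more parts of Lipinski's Rule of five (LRO5) — MW > 500, logP > 5, HBD > 5,
HBA > 10, all strict inequalities — have a low probability of crossing the
intestinal epithelium and are flagged as candidate intestine-local
inhibitors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .activity_model import DEFAULT_THRESHOLD, TrainedClassifier, predict_indices
from .applicability_domain import ApdModel, in_domain_bulk
from .chemstruct import (
    DescriptorSet,
    Molecule,
    compute_descriptors,
    fingerprint,
)

LRO5_LIMITS = dict(mw=500.0, logp=5.0, hbd=5, hba=10)
INTESTINAL_MIN_VIOLATIONS = 2


class FilterError(ValueError):
    pass


class ScreenError(ValueError):
    pass


@dataclass
class HitRecord:
    molecule: Optional[Molecule]
    compound_id: str
    name: str
    prediction_index: float
    reliable: bool
    nn_distance: float
    descriptors: Optional[DescriptorSet]
    descriptor_source: str = "computed"     # "computed" | "supplied"
    lro5_violations: int = 0
    is_hit: bool = False
    is_intestinal_candidate: bool = False
    exclusion_reason: Optional[str] = None


def lro5_violations(d) -> int:
    """Count of strict LRO5 violations (MW>500, logP>5, HBD>5, HBA>10).

    ``d`` may be a :class:`DescriptorSet`, a mapping, or any object with
    mw/logp/hbd/hba attributes. A missing or non-finite field raises
    :class:`FilterError` naming it.
    """
    values = {}
    for name in ("mw", "logp", "hbd", "hba"):
        if isinstance(d, Mapping):
            v = d.get(name)
        else:
            v = getattr(d, name, None)
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            raise FilterError(f"missing descriptor: {name}")
        values[name] = v
    return sum(int(values[k] > LRO5_LIMITS[k]) for k in LRO5_LIMITS)


def lro5_violations_frame(df: pd.DataFrame,
                          columns: Mapping[str, str] = None) -> pd.Series:
    """Vectorized violation counts for a descriptor table.

    ``columns`` maps descriptor names (mw/logp/hbd/hba) to column names;
    defaults to mw/alogp/hbd/hba as printed in screening reports.
    """
    cols = dict(mw="mw", logp="alogp", hbd="hbd", hba="hba")
    if columns:
        cols.update(columns)
    for key, col in cols.items():
        if col not in df.columns:
            raise FilterError(f"missing descriptor: {key}")
    out = (
        (df[cols["mw"]] > LRO5_LIMITS["mw"]).astype(int)
        + (df[cols["logp"]] > LRO5_LIMITS["logp"]).astype(int)
        + (df[cols["hbd"]] > LRO5_LIMITS["hbd"]).astype(int)
        + (df[cols["hba"]] > LRO5_LIMITS["hba"]).astype(int)
    )
    return out.rename("lro5_violations")


def intestinal_filter(hits: Sequence[HitRecord]) -> List[HitRecord]:
    """Hits with >= 2 LRO5 violations, marked as intestinal candidates."""
    out = []
    for h in hits:
        if h.lro5_violations >= INTESTINAL_MIN_VIOLATIONS:
            h.is_intestinal_candidate = True
            out.append(h)
    return out


@dataclass
class ScreenReport:
    records: List[HitRecord]
    funnel: Dict[str, int] = field(default_factory=dict)

    @property
    def hits(self) -> List[HitRecord]:
        return [r for r in self.records if r.is_hit]

    @property
    def intestinal_candidates(self) -> List[HitRecord]:
        return [r for r in self.records if r.is_intestinal_candidate]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = r.descriptors
            rows.append(
                dict(
                    compound_id=r.compound_id,
                    name=r.name,
                    smiles_canonical=r.molecule.smiles_canonical if r.molecule else "",
                    index=r.prediction_index,
                    nn_distance=r.nn_distance,
                    reliable=r.reliable,
                    mw=d.mw if d else None,
                    logp=d.logp if d else None,
                    hbd=d.hbd if d else None,
                    hba=d.hba if d else None,
                    descriptor_source=r.descriptor_source,
                    lro5_violations=r.lro5_violations,
                    is_hit=r.is_hit,
                    is_intestinal_candidate=r.is_intestinal_candidate,
                    exclusion_reason=r.exclusion_reason or "",
                )
            )
        return pd.DataFrame(rows)


def run_screen(
    library: Sequence[Molecule],
    model: TrainedClassifier,
    apd_model: ApdModel,
    threshold: float = DEFAULT_THRESHOLD,
    exclusion_list: Iterable[str] = (),
    supplied_descriptors: Optional[Mapping[str, DescriptorSet]] = None,
    names: Optional[Mapping[str, str]] = None,
) -> ScreenReport:
    """Screen a curated library: predict, APD-gate, threshold, exclude, LRO5.

    Every library compound receives a :class:`HitRecord`; the report is
    sorted by descending prediction index (ties on compound id) and is
    deterministic given model, APD, and config. ``supplied_descriptors``
    overrides computed descriptors per compound id — used when a library
    ships authoritative descriptor columns.
    """
    if model.fingerprint_config != apd_model.fingerprint_config:
        raise ScreenError(
            "fingerprint configuration differs between classifier and APD model"
        )
    supplied = supplied_descriptors or {}
    names = names or {}
    exclusions = {str(e) for e in exclusion_list}

    mols = list(library)
    for m in mols:
        if m.fingerprint is None or m.fingerprint.length != model.fingerprint_config.n_bits:
            fingerprint(m, model.fingerprint_config)
    indices = predict_indices(model, mols)
    reliable, nn = in_domain_bulk(apd_model, [m.fingerprint for m in mols])

    records: List[HitRecord] = []
    funnel = dict(input=len(mols), in_domain=0, above_threshold=0,
                  post_exclusion=0, intestinal=0)
    for m, idx, ok, d_nn in zip(mols, indices, reliable, nn):
        if m.id in supplied:
            desc, source = supplied[m.id], "supplied"
        else:
            desc, source = (m.descriptors or compute_descriptors(m)), "computed"
        excl = None
        if m.id in exclusions or m.smiles_canonical in exclusions:
            excl = "exclusion_list"
        rec = HitRecord(
            molecule=m,
            compound_id=m.id,
            name=names.get(m.id, m.id),
            prediction_index=float(idx),
            reliable=bool(ok),
            nn_distance=float(d_nn),
            descriptors=desc,
            descriptor_source=source,
            lro5_violations=lro5_violations(desc),
            exclusion_reason=excl,
        )
        rec.is_hit = bool(ok) and idx >= threshold and excl is None
        records.append(rec)
        if ok:
            funnel["in_domain"] += 1
            if idx >= threshold:
                funnel["above_threshold"] += 1
                if excl is None:
                    funnel["post_exclusion"] += 1

    intestinal_filter([r for r in records if r.is_hit])
    funnel["intestinal"] = sum(r.is_intestinal_candidate for r in records)

    records.sort(key=lambda r: (-r.prediction_index, r.compound_id))
    return ScreenReport(records=records, funnel=funnel)
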