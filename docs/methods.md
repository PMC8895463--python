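# Methods

## Scope and model of the problem

`cypscreen` re-implements a ligand-based virtual-screening workflow for
dietary CYP3A4 inhibitors as an open, tested pipeline. The workflow's
substance is (i) curation of high-throughput dose-response bioassay records
into binary activity labels, (ii) a fingerprint classifier with a
probability-like prediction index, (iii) a Tanimoto-distance applicability
domain gating which predictions count, (iv) a Lipinski-based
non-permeability filter marking candidate intestine-local inhibitors, and
(v) four-parameter-logistic IC50 estimation from in vitro dose-response
data. The original study's training data (PubChem bioassays AID884/AID1851)
and screening library (FooDB) are external downloads and its classifier was
a closed commercial module; this package therefore ships a synthetic-data
generator that emulates all three inputs with known ground truth, and
bundles the study's published 115-compound hit table (printed descriptors
and literature annotations) as data, so the downstream arithmetic is
reproducible without network access.

## Structure handling

Parsing, canonicalization, descriptors, and fingerprints stand on RDKit.
Desalting keeps the carbon-containing fragment with the most heavy atoms;
equal-sized fragments tie-break on the lexicographically smallest canonical
SMILES so the operation is deterministic and idempotent. A structure with
no carbon fragment is inorganic and rejected. Entries that still contain
two or more organic fragments are true mixtures and are removed during
bioassay curation rather than desalted.

Descriptor conventions (fixed per run, never mixed): molecular weight from
standard atomic masses; logP by the Crippen atom-contribution scheme; HBD
and HBA by the RDKit Lipinski definitions (N–H/O–H hydrogens; N/O acceptors
excluding amide-type nitrogens). Published AlogP/HBA columns from other
software disagree with any open implementation in detail, which is why the
Lipinski filter consumes supplied descriptor columns when a library
provides them (recorded per row as `descriptor_source="supplied"`) and
computes them otherwise.

Fingerprints default to circular (Morgan) radius 2, 2048 bits — the
standard representation for Tanimoto-based applicability domains; a
path-based (Daylight-like) fingerprint is selectable since the upstream
choice of "a chemistry development kit" fingerprint is ambiguous between
the two. Tanimoto distance is 1 − |a∩b|/|a∪b|, with two empty fingerprints
defined to be at distance 0.

## Curation rules

* Active ⇔ curve class −1.1 and efficacy ≥ 80 % of control (threshold
  configurable); inactive ⇔ curve class 4.0; all other curve classes are
  inconclusive and excluded. The potency range observed among curated
  actives (0.032–15.85 μM) is metadata, not a filter.
* Duplicate key = canonical desalted structure. Same-label duplicates
  collapse to one entry (lexicographically smallest source id kept);
  conflicting-label duplicates are removed entirely.
* Stratified split: per-class shuffle under a seed; training count per
  class is round-half-up of fraction × class size, so the rounding
  remainder lands in training (1760/8893 at 75 % → 1320/6670).
* Screening-library curation additionally drops inorganics and
  exclusion-list members (the upstream study removed pesticides and drugs
  by hand; that list is irreproducible, so exclusion is a user-supplied
  mechanism, default empty).

## Classifier

A feed-forward network (scikit-learn `MLPClassifier`) over fingerprint
bits: two hidden layers, default 256/64, ReLU, Adam, cross-entropy.
Training is capped at 20 epochs by default — an epoch budget replaces the
upstream wall-clock cap so runs are hardware-independent — and is
deterministic under a fixed seed. Class imbalance (~1:5 active:inactive
after curation) is handled by deterministic integer replication of the
minority class to approximate inverse-class-frequency loss weights;
`MLPClassifier` accepts neither class nor sample weights, and replication
keeps training rng-free apart from the seeded weight initialization and
batch shuffling. The decision threshold is inclusive (index ≥ 0.7 ⇒
predicted inhibitor): the upstream text uses "above 0.7" and "≥ 0.7"
interchangeably and the hit with index exactly 0.70 appears in its hit
list, so ≥ is the reading consistent with the published table.

The original classifier's architecture, featurization, and hyperparameters
are unpublished; any open replacement is an approximation by construction.
Its published validation scores are therefore covered by the planted-rule
benchmark below rather than asserted.

## Evaluation

SE, SP, MCC are the standard confusion-matrix definitions. The enrichment
factor is precision over prevalence, EF = [TP/(TP+FP)] / [(TP+FN)/N]; the
upstream formula is not legible in the source material, but this standard
screening definition reproduces its printed EF (5.871) from its printed
SE/SP and split sizes within rounding, so it is adopted and documented as
inferred. Degenerate denominators flag the metric as undefined; MCC falls
back to 0 by convention. ROC-AUC is the rank-based Mann–Whitney statistic
with midranks for ties, cross-checked in the tests against scikit-learn's
independent implementation.

The literature-consistency check classifies hits with literature IC50
annotations as confirmed (≤ 20 μM) or refuted (> 20 μM), adds confirmations
from supplied assay measurements, and reports TP/FP. The bundled hit table
carries both the raw printed IC50 values and the publication's own
potent/weak grouping (`lit_class`); the two differ for exactly one
borderline row (obacunone, 20.9 μM, grouped as potent upstream). The
published-calls route reproduces the published arithmetic (25/8 → 3.1); the
numeric route applies the stated cutoff strictly (24/9 ≈ 2.7). Both are
implemented; the published grouping is what the acceptance report uses,
since it is part of the published record.

## Applicability domain

Over all n(n−1)/2 unordered training pairs, let d_all be the mean Tanimoto
distance; d̄ and σ are the mean and population standard deviation of the
strictly-below-mean subset, and APD = d̄ + Zσ. "Lower than the average" is
read as strict inequality; when every pairwise distance is equal the subset
would be empty, so the degenerate case uses the full set (σ = 0, APD =
d_all). Z is not stated upstream; the method it cites conventionally uses
Z = 0.5, which is the default here, mandatory in config and recorded in
output provenance. A query is reliable iff the distance to its nearest
training neighbor is ≤ APD. Enumeration is exact O(n²) over packed bit
matrices (desk-scale n); no approximate nearest neighbor.

## Screening

Every library compound receives a record with index, nearest-neighbor
distance, reliability flag, descriptors, Lipinski violation count, and
exclusion reason. A hit requires reliable ∧ index ≥ threshold ∧ not
excluded; the APD gate is applied before thresholding (the funnel counts
depend on the order, the final set does not). Lipinski violations are
strict comparisons (MW > 500, logP > 5, HBD > 5, HBA > 10), so MW = 500.0
or HBD = 5 does not violate; hits with ≥ 2 violations are flagged
intestinal candidates. Reports are sorted by descending index with id
tie-break, making them invariant to input order.

## Dose-response

Activity is 100 × (sample T20 − T0)/(control T20 − T0); a non-positive
control delta is an assay failure. The 4PL is fit in log concentration by
least squares over every replicate point (measurements are performed in
triplicate and fit as points, not means). Asymptotes are free by default,
parameterized as (bottom, span ≥ 0) with both bounded by 120 % so the
ordering constraint 0 ≤ bottom ≤ top reduces to a box; a fixed 100/0
variant is selectable (whether the upstream analysis constrained asymptotes
is unstated). Initialization: top/bottom from the extreme-concentration
means, hill = 1, IC50 from the interpolated 50 % crossing.

The reported IC50 is the *absolute* IC50 — the concentration where the
fitted curve crosses 50 % of control, mid·((top−50)/(50−bottom))^(1/hill) —
matching the assay's definition of IC50 as a 50 % reduction relative to
control. The curve midpoint (inflection) is retained as a diagnostic field;
the two coincide under fixed 100/0 asymptotes. When the fitted asymptotes
do not straddle 50 % the midpoint is reported and the fit flagged
`extrapolated`. A curve whose mean activity spans less than 10 percentage
points has no identifiable dose response and is reported non-converged with
a message, never a silent number.

## Synthetic-data generator

The grammar combines 18 ring scaffolds (14 plain, 4 containing the fused
methylenedioxyphenyl/benzodioxole motif) with 39 decorating substituents;
substituent ring closures are renumbered so any scaffold × substituent
combination is valid SMILES, and no substituent can complete the motif, so
motif presence — the planted activity rule — is controlled solely by
scaffold choice and verified by substructure match, not by a construction
flag. Configurable fractions of salt forms, exact duplicates, and inorganic
rows exercise the curation stage; a manifest records ground truth for all
of them.

Bioassay planting: motif compounds become active with probability 0.95,
background compounds with probability 0.005, giving an expected active
fraction of ≈ 0.165 at the default motif fraction 0.17 — matching the
1760:8893 imbalance of the curated public dataset, so specificity-heavy
thresholds behave as in the emulated regime. Actives receive curve class
−1.1, efficacy uniform in [80, 100] and potency log-uniform over
0.032–15.85 μM; others curve class 4.0; an optional fraction is reassigned
inconclusive curve classes. Dose-response simulation samples the 4PL with
Gaussian noise at the assay's seven-point 3-fold dilution series
(125…0.17 μM), default three replicates.

What the generator does **not** emulate: real medicinal-chemistry space
(the grammar spans ~10⁴ distinct structures), activity cliffs, assay
artifacts beyond i.i.d. Gaussian noise, or inter-laboratory variation in
literature IC50s. Passing the planted-rule benchmark shows the pipeline's
machinery recovers a real signal at realistic imbalance; it does not bound
performance on experimental bioassay data, where the published
sensitivity/specificity cannot be reproduced without the original data and
model.

## Benchmark problem sizes

The planted-rule benchmark trains on libraries of 2000 entries (≈ 1650
unique labeled compounds after curation) over five seeds and screens fresh
500-entry libraries, sizes at which the grammar still yields a diverse
set while the full suite runs in well under a minute; the APD oracle check
uses 50-train/20-query sets over ten seeds, and IC50 recovery uses 200
simulated curves with IC50 log-uniform in 0.3–50 μM at 5 %-of-control
noise. Measured results on these conditions (recomputed by
`scripts/acceptance.py`): mean validation AUC ≈ 0.96–0.98, mean screening
enrichment ≈ 6–7× over prevalence, APD oracle agreement 1.0, noise-free
IC50 recovery exact to the reporting precision, and noisy median relative
error ≈ 5–6 %.

## Known limitations

* Protonation states are used as drawn; the upstream pH 7.4 assignment
  used commercial software and is skipped (documented divergence).
* Open descriptor implementations (Crippen logP, RDKit HBA) need not match
  the printed AlogP/HBA of other vendors row-for-row; the published
  descriptor table is therefore consumed as data where exact reproduction
  matters.
* The 136 → 115 post-screen manual curation of the published hit list is
  irreproducible; the exclusion-list mechanism is the supported analogue.
* The classifier is an open stand-in for an unpublished commercial model;
  published validation scores on the real data are out of reach by
  construction and are covered by synthetic property checks instead.
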