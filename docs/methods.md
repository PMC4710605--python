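# Methods

## Problem setting

A high-throughput *in vitro* assay for a molecular initiating event
(MIE) — acetylcholinesterase (AChE) inhibition in the packaged case
study — yields a list of active and inactive chemicals. Activity in a
cell-free assay is neither necessary nor sufficient for *in vivo*
toxicity: an active chemical nobody is exposed to, or one that cannot
be absorbed or cross the blood–brain barrier (BBB), will never trigger
the MIE; an inactive chemical may be the parent of an active metabolite
formed only in the body. `admetriage` implements both refinements as a
deterministic, auditable pipeline.

## Structure standardisation ("washing")

Input SMILES are often salt forms. Washing keeps the largest fragment
by heavy-atom count (ties broken by molecular weight, then by
canonical-SMILES order), applies a fixed table of neutralisation
transformations (protonating carboxylate/phenolate/thiolate-type
anions, deprotonating protonated amines), and emits RDKit's canonical
SMILES. Permanent charges — quaternary ammoniums, nitro group oxygens —
are chemically non-removable and left intact. Inorganic and
organometallic species (e.g. mercuric chloride) are retained and
flagged `is_organic = false`; their downstream descriptors carry a
`low_confidence` flag instead of erroring, because annotation-driven
triage must still cover them. Washing is idempotent and invariant to
the input atom ordering; both properties are tested on fixture and
generated structures.

Deliberately out of scope: tautomer canonicalisation, stereochemistry
normalisation beyond what canonical SMILES provides, and 3D conformer
generation (no downstream step consumes coordinates).

## Descriptors and gate rules

Descriptors are computed from the washed fragment with RDKit: molecular
weight, Crippen atom-contribution logP (an open, deterministic estimate
of log K_ow), Lipinski H-bond donor/acceptor counts, rotatable bonds,
topological polar surface area (TPSA), and net formal charge.

**Absorption (extended Rule-of-5).** Violations: MW > 500 g/mol,
logP > 5, donors > 5, acceptors > 10, rotatable bonds > 10,
TPSA > 140 Å². All thresholds are strict: a value exactly at a limit is
compliant. No violation ⇒ class "Yes"; one or more ⇒ "Limited". The
predictor never emits "Negligible" — that class is reserved for curated
annotations, mirroring how the reference annotations distinguish only
Yes/Limited with NA for ungated rows. Route-specific absorption (oral
vs dermal) is not modelled; it does not change the class.

**Distribution (BBB).** A conjunction of rules, each individually
configurable or disableable via YAML: TPSA ≤ 90 Å², MW ≤ 450,
1 ≤ logP ≤ 4, donors ≤ 3, net formal charge ≥ 0. These capture the
physicochemical consensus for CNS permeation: small, moderately
lipophilic, low-polarity, non-anionic. The reference calls in the
packaged fixture came from a proprietary trained classifier, so exact
rule-level agreement is not expected or forced: the two clearly
non-permeant demoted chemicals (raloxifene, pentamidine free bases) are
reproduced and asserted, the overall agreement on the annotated rows is
measured in the test suite (documented, not gated — anthralin, for
example, passes simple physicochemical rules but was annotated
non-permeant, plausibly on sequestration grounds a rule set cannot
see). In triage, annotations always take precedence over predictions,
so fixture results do not depend on the rule set.

## Decision trees

The parent-compound path evaluates exposure → absorption →
distribution, stopping at the first demotion:

| gate | demotes on | note |
|---|---|---|
| exposure | category 4 (low/no likelihood) | categories 1–3 pass; 3 ("unknown") passes by design — insufficient evidence never demotes |
| absorption | annotated "Negligible" only | "Limited" passes with a `limited_absorption` ranking note |
| distribution | "No" | "Yes"/"NA"/unknown pass |

A priority call is "low" iff its reason list is non-empty; every gate
evaluation is recorded in an ordered trace with its input source
(annotation / predicted / absent), making each decision auditable and
letting tests assert annotation precedence directly.

An exposure-unannotated active is treated by the gate itself as
"insufficient evidence → continue", but the workflow entry point
rejects such records by default (`require_exposure=True`): a curated
exposure call is a mandatory input for real triage, while the full
factorial grid used to verify the logic legitimately contains the
unannotated level.

The metabolite path: a metabolite with its own environmental exposure
(category 1–3) is judged exactly like a parent compound. Otherwise it
exists only if its parent is encountered and absorbed, so the parent's
exposure and absorption gates apply, followed by the metabolite's own
distribution gate. Metabolism codes (activating, detoxifying, mixed,
same-toxicity, excreted unchanged, unknown) are carried as ranking
notes only; quantitative rate-based ranking is explicitly not
implemented.

## Fingerprints and false-negative detection

Fingerprints are the 166 public MDL MACCS keys (RDKit's generator emits
167 bits with bit 0 permanently unset; the public vector drops it).
Similarity is the Tanimoto coefficient over set bits. Two all-zero
fingerprints score 0, not 1: an empty key profile is absence of
evidence, not identity, and the case is logged as a warning.

Nearest-active-neighbor search is exhaustive. Similarities are compared
as exact rationals (cross-multiplied integer counts), so ties are
detected without floating-point artefacts; ties are broken by lowest
AC50 (most potent active) and then lexicographic id, with all tied ids
reported. This matters in practice: in the packaged fixture, malaoxon's
nearest active is an exact 21/37 tie between mevinphos and
bis(2-ethylhexyl) decanedioate, resolved to the far more potent
mevinphos.

The flag threshold is **inclusive** (T ≥ 0.75 by default, configurable).
A flagged inactive whose nearest neighbor is low priority inherits that
status (reason `inherited_from_low_priority_neighbor`); the remaining
flagged inactives are the possible-false-negative list. Propagation
uses the single nearest neighbor only.

**Dialect caveat.** MACCS key definitions differ slightly between
toolkits. Against similarity percentages computed elsewhere, the open
dialect used here agrees to within a few hundredths on the coefficient
for the worked pesticide pairs (e.g. chlorpyrifos/chlorpyrifos-oxon
0.8958 here vs 0.91 reported from a commercial dialect), and all
threshold classifications at 0.75 and 0.60 agree. One borderline pair
does not: zamifenacin–raloxifene scores 0.679 here against a reported
0.76, so at the 0.75 threshold this package does not flag zamifenacin;
at 0.60 it is flagged and inherits raloxifene's low priority as
expected.

## Promiscuity flagging

Some actives signal through assay interference (dye absorption, redox
cycling) rather than target binding. A pluggable alert stage matches
SMARTS substructure patterns — defaults cover triarylmethane dye
cations, N-benzyl azinium salts, azo dyes, quinones and rhodanines —
with per-record boolean overrides taking precedence in both directions.
In the packaged fixture the two known promiscuous actives (gentian
violet, 1-benzylquinolinium) both carry overrides *and* match default
alerts. Flags annotate (`promiscuity_suspect` ranking note) without
changing priority; the `demote_promiscuous` config switch enables the
stricter reading, reported alongside as `n_high_non_promiscuous`
(18 vs 20 on the fixture).

## Packaged fixtures

`data/table1_actives.csv` holds the 30 assay actives with their curated
exposure categories, absorption/distribution annotations, metabolism
codes and AC50 values (µM, strictly increasing); structures are
standard registry structures for the named chemicals, each row citing
its CAS number. Nine failed pharmaceuticals have no public structure
and carry empty SMILES: they triage on annotations (all are
exposure-gated or annotation-complete) and are skipped, with an
explicit note, by fingerprint screening.
`data/discussion_inactives.csv` holds the eight worked inactives with
parent links where known (dichlorvos ← naled; chlorpyrifos is the
parent of the top active, chlorpyrifos oxon). File integrity is pinned
by checksum in the test suite.

## Synthetic libraries

The generator builds screening sets with ground truth known by
construction, standing in for a full screening inventory that cannot be
shipped:

- **scaffolds** — carbamate/organophosphate cores of the chemistry the
  case-study assay responds to, with randomized gate annotations and
  AC50 values;
- **planted analogs** — 1–2 random edits from a fixed vocabulary
  (halogen swap, methyl addition, O↔S swap, terminal chain extension),
  accepted only if the analog's MACCS Tanimoto to its scaffold reaches
  the threshold (rejection sampling re-checked with the package's own
  fingerprint code);
- **decoys** — drawn from a packaged pool of 55 structurally diverse
  molecules (sugars, steroids, amino acids, simple aromatics), accepted
  only below the threshold against every scaffold.

Because both guarantees are enforced at generation time, a screen at
the generation threshold must flag exactly the planted analogs — an
exact property, asserted across 20 seeds. All randomness flows from one
explicit integer seed; no global state. Default library sizes (3–4
scaffolds, 2 analogs each, 15–25 decoys) keep the guaranteed-exact
property cheap to verify many times over; the generators scale to
larger libraries by argument. What the synthetic data does **not**
emulate: the real chemical-space density of a screening inventory,
activity cliffs, or assay noise — passing the planted-recovery suite
shows the screen's bookkeeping is exact, not that 0.75 is the right
threshold for any particular library.

## Determinism and numerical choices

Everything downstream of parsing is deterministic: canonical SMILES,
integer bit counts, exact rational tie-breaks, seeded generators. Two
runs with identical inputs, config and seed produce byte-identical
outputs (asserted in the CLI tests). Similarities are stored at full
precision and rounded to 4 decimals only for display. The effective
configuration — thresholds, rule bounds, alert set — is echoed verbatim
into every report.

## Known limitations

- Absorption/distribution predictions are coarse rule sets, not trained
  ADMET models; they exist to make triage runnable without annotations,
  and curated annotations always win.
- The BBB rules cannot capture tissue sequestration or transporter
  effects (the anthralin case).
- Only MACCS/Tanimoto similarity is implemented; no ECFP, no 3D or
  pharmacophore similarity.
- Metabolite handling requires explicit parent links and
  metabolite-specific exposure annotations; metabolite structure
  prediction is out of scope.
- Replicating a full-inventory screen (a thousand-odd inactives)
  requires the user to supply that inventory; the package ships only
  the worked discussion subset with packaged ground truth.
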