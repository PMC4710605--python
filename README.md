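# admetriage

Exposure/ADME triage of adverse-outcome-pathway (AOP) screening hits,
with MACCS-fingerprint detection of possible *in vitro* false negatives.

High-throughput *in vitro* assays report whether a chemical triggers a
molecular initiating event — here, inhibition of acetylcholinesterase
(AChE) — but say nothing about whether the chemical could ever reach
that target *in vivo*. `admetriage` is for toxicologists and risk
assessors who need to refine such hit lists: it demotes assay-active
chemicals that cannot plausibly reach the target, and flags
assay-inactive chemicals that are structurally so close to an active
that they may act *in vivo* (directly, or through an active metabolite).

## The method

**Priority gates.** Each active chemical passes, in order, through
three gates; the first failure demotes it to *low priority*, and
missing or uncertain evidence never demotes:

1. **Exposure** — a literature-derived category: 1 widespread,
   2 occupational/special-case, 3 unknown, 4 low/no likelihood.
   Category 4 demotes (`no_exposure`).
2. **Absorption** — the extended Rule-of-5 over the washed structure:
   violations are MW > 500, logP > 5, H-bond donors > 5, acceptors > 10,
   rotatable bonds > 10, TPSA > 140 Å². No violation ⇒ "Yes"; any ⇒
   "Limited" (kept, with a ranking note); only an annotated
   "Negligible" demotes.
3. **Distribution** — a rule-based blood–brain-barrier (BBB) screen
   (defaults: TPSA ≤ 90 Å², MW ≤ 450, 1 ≤ logP ≤ 4, donors ≤ 3, net
   charge ≥ 0). A "No" demotes (`no_bbb_distribution`), since brain
   AChE is behind the BBB.

A known metabolite with no environmental exposure of its own is judged
through its parent's exposure and absorption, then its own distribution.
Curated annotations always take precedence over predicted calls.

**False-negative screen.** Every inactive chemical is compared to every
active by the Tanimoto coefficient

&nbsp;&nbsp;&nbsp;&nbsp;*T(A,B) = |A ∩ B| / |A ∪ B|*

over 166-bit public MDL MACCS key fingerprints. An inactive whose
nearest active neighbor reaches *T* ≥ 0.75 (inclusive, configurable) is
flagged; flagged chemicals inherit *low* priority when that neighbor is
itself low priority, and the rest are reported as possible false
negatives. Promiscuity alerts (dye chromophores, interfering motifs,
plus per-record overrides) annotate — and optionally demote —
suspicious actives.

## Worked example

The package ships the case study as fixtures: 30 AChE-assay actives
with curated exposure/ADME annotations, and 8 discussion inactives
(organophosphate and carbamate pesticides plus two drugs).

```sh
admetriage fixtures --out fx
admetriage run --actives fx/table1_actives.csv \
               --inactives fx/discussion_inactives.csv --out out
```

prints

```text
30 actives: 20 high / 10 low priority; 6 flagged inactives, 6 possible false negatives
```

Ten of the 30 actives are demoted — 7 at the exposure gate (failed
pharmaceuticals nobody is exposed to), 3 at the BBB gate (anthralin,
raloxifene, pentamidine) — leaving 20 high-priority chemicals.
Of the discussion inactives, six are flagged at the 0.75 threshold,
among them chlorpyrifos (Tanimoto 0.8958 to its oxon metabolite, the
most potent active in the assay) and aldicarb (0.8824 to methomyl):
classic cases of chemicals inactive in a cell-free assay yet
AChE-inhibiting *in vivo*. Malaoxon stays below threshold (0.5676 to
mevinphos) even at 0.60. `out/report.csv` carries the per-chemical
calls with machine-readable reason codes, `out/hits.csv` the similarity
pairs, and `out/effective-config.yaml` the exact rule set used.

The same pipeline is available as a library:

```python
from admetriage import load_table1_fixture, run_workflow, RunConfig

fx = load_table1_fixture()
report = run_workflow(fx.all_records, RunConfig(threshold=0.75))
print(report.summary.n_low)   # 10
```

Synthetic screening libraries with known ground truth (planted
high-similarity analogs, guaranteed-dissimilar decoys) come from
`admetriage synth --seed 7 --out lib`.

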