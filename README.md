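# rxmatch

Automated double-check of medication selection during outpatient pharmacy
processing of electronic prescriptions.

When a pharmacy transcribes an e-prescription into its dispensing software,
staff select a concrete drug product — identified by its National Drug Code
(NDC) — to fulfil the prescribed one. That selection step is error-prone,
and today a pharmacist catches mistakes with a manual double-check.
`rxmatch` performs that double-check automatically: it resolves the
prescribed NDC and the dispensed NDC to *semantic clinical drug* (SCD)
concepts in a drug terminology and alerts when they disagree. It is aimed
at pharmacy informaticists and medication-safety researchers who have
paired e-prescription/dispensing records and want to quantify selection
errors and the alert burden of surfacing them.

## Method

For each record pair *(NDC_rx, NDC_disp)*:

1. **Normalize** both codes to the 11-digit 5-4-2 form (zero-padding the
   short segment of 10-digit 4-4-2 / 5-3-2 / 5-4-1 codes).
2. **Resolve** each NDC to a concept (RxCUI) via a terminology backend —
   the public RxNorm-style REST interface (`ndcstatus`,
   `rxcui/{rxcui}/properties`, `rxcui/{rxcui}/related?tty=SCD`) or a local
   TSV snapshot. Branded concepts (SBD/BPCK) are resolved to their generic
   clinical counterparts; generic packs (GPCK) compare at pack level;
   obsolete codes are remapped to active concepts.
3. **Match**: pairs whose resolved SCD sets intersect agree; disjoint sets
   are mismatches; pairs with an unresolvable side form the missing-RxCUI
   stream and are excluded from evaluation.
4. **Classify** each mismatch by its most harmful difference:
   ingredient → strength → pack quantity → dose form → qualitative
   distinction (concepts outside the terminology's curated scope are
   screened first).
5. **Label and score**: ingredient/strength mismatches are clinically
   significant alerts (TP), the rest are nuisance alerts (FP), agreeing
   pairs are TN; a match over truly non-equivalent products (a terminology
   mapping defect, observable only with synthetic ground truth) is FN. From
   the error matrix the usual panel follows —

   accuracy = (TP+TN)/n, sensitivity = TP/(TP+FN), FPR = FP/(FP+TN),
   specificity = TN/(FP+TN), precision = TP/(TP+FP),
   F1 = 2·P·R/(P+R)

   — computed twice: over **total** pairs (a static alerting policy that
   fires every time) and over **unique** ordered NDC pairs (a learning
   policy that suppresses repeats of an adjudicated mismatch). The *alert
   budget* (TP+FP)/TP is the number of alerts issued per clinically
   significant one.

A synthetic module generates mini terminologies and record streams with
configurable per-category error rates and exact ground truth, so the whole
pipeline is testable end to end without access to proprietary dispensing
data.

## Worked example

The package bundles a small real-drug snapshot containing the method's
canonical demonstration: a prescription for diltiazem (NDC 00093-5117-98,
SCD 830845) dispensed as Protonix (NDC 00008-0841-81 → SBD 284400 → SCD
314200) — a detectable selection error — plus one exemplar pair per
mismatch category.

```sh
rxmatch synth --out demo --seed 7          # or bring your own records
python - <<'EOF'
from rxmatch.examples import worked_example, worked_example_frames
from rxmatch.ingest import write_pairs
from rxmatch.terminology import write_tables
_, pairs, _ = worked_example()
write_tables(worked_example_frames(), "demo/terminology")
write_pairs(pairs, "demo/pairs.csv")
EOF
rxmatch check --input demo/pairs.csv --backend fixture \
    --fixture-dir demo/terminology --out demo/out
```

prints (abridged):

```
## Mismatch categories
DIFFERENT_INGREDIENT       2
DIFFERENT_STRENGTH         1
DIFFERENT_PACK_QUANTITY    1
DIFFERENT_FORM             1
OUTSIDE_RXNORM             1
OTHER_QUALITATIVE          1

## Error matrix (total pairs, n=8)
TP=3  FP=4  FN=0  TN=1
accuracy             0.50000
sensitivity          1.00000
...
```

Reading: of the 8 pairs, 1 agreed (the same clinical drug reached through
two different NDCs) and 7 mismatched; the diltiazem/Protonix pair and the
venlafaxine/levothyroxine pair are different-ingredient selections and the
pancrelipase pair a different-strength selection (3 TP), while pack-size,
dose-form, outside-terminology and osmotic-release differences are nuisance
alerts (4 FP). Sensitivity is 1 because a selection error can only be
missed if the terminology itself maps two different products to one
concept. `rxmatch resolve <NDC...>` inspects individual codes the same way.

## Layout

- `rxmatch.ndc` — NDC validation / 11-digit normalization
- `rxmatch.terminology` — concept model + TSV fixture store
- `rxmatch.rxnorm_api` — REST client with caching and record/replay
- `rxmatch.ingest` — record loading and the cleaning funnel
- `rxmatch.matcher` — matching, mismatch taxonomy, error-matrix labels
- `rxmatch.metrics` — matrices, metric panels, alert budgets, frequency table
- `rxmatch.synthetic` — synthetic terminology/stream generator with ground truth
- `rxmatch.examples` — the bundled worked example
- `rxmatch.cli` — `rxmatch check | synth | resolve`

See `docs/methods.md` for modeling choices and limitations.
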