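# Methods

## The check

The unit of analysis is a record pair: the representative NDC conveyed by
an e-prescription and the NDC of the product the pharmacy recorded as
dispensed. Both are only product identifiers; the clinical question —
*is this the same medicine?* — is answered at the level of the semantic
clinical drug (SCD), the terminology concept naming ingredient(s),
strength(s) and dose form. The pipeline is: clean the stream, resolve each
NDC to clinical-level concepts, compare the two concept sets, classify
disagreements, and aggregate into an error matrix and metric panels.

The check is deliberately one-sided: it can prove two NDCs denote
different clinical drugs, but a concept-level match cannot prove the
products equivalent if the terminology's NDC→concept mapping is itself
wrong. False negatives are therefore invisible in observational use; the
synthetic generator makes them measurable by injecting mapping corruptions
with ground truth.

## Cleaning

Pairs are removed when either free-text name contains a signal word
(default list: duplicate, cancel, wrong, denied — case-insensitive
substring, so inflections like "CANCELLED" match), or when an NDC is
missing on either side. Malformed NDCs (e.g. 4-5-2 segmentations that fit
no standard dialect) are *retained* by default and fall into the
missing-RxCUI stream at resolution time, because real streams contain
vendor-invented codes for supplies and compounds that are legitimate
records despite being unresolvable; `strict_ndc` drops them during
cleaning instead. The funnel report conserves counts by construction.

## NDC normalization

Hyphenated 10-digit codes are disambiguated by their segment lengths
(4-4-2 pads the labeler, 5-3-2 the product, 5-4-1 the package) and
zero-filled to 5-4-2; 11-digit and hyphenated 5-4-2 inputs pass through.
Unhyphenated 10-digit codes are rejected with a distinct error code rather
than guessed — the dropped zero's position is unknowable — unless the
caller supplies a dialect. No check-digit or labeler-registry validation
is attempted.

## Resolution

`ndcstatus`-style lookup returns the concept for active and obsolete NDCs;
retired concepts are followed through their remapping chain to the active
concept before any comparison, so stale codes do not masquerade as
mismatches. Term types resolve to clinical level as follows:

- SCD → itself;
- SBD → its related SCDs (the brand/generic distinction is not a
  dispensing error);
- GPCK → **itself**, and BPCK → its related GPCKs. Packs deliberately
  compare at pack level rather than being expanded to their component
  tablets: two pack sizes of the same tablet are different dispensed
  products, and expanding both to the shared component SCD would make
  every pack-quantity selection error an undetectable match. This is the
  one place where "resolve to SCD" is read as "resolve to the clinical
  comparison unit".
- Uncurated concepts (present in the terminology but sourced from an
  external vocabulary, with no structured attributes) resolve to
  themselves and are flagged; any mismatch touching one is categorized
  as outside-scope.

A non-clinical concept with no related clinical concept is a resolution
error; the pair joins the missing-RxCUI stream.

## Mismatch taxonomy

Matching is set intersection over resolved concept sets — the lenient
reading appropriate for multi-component packs. A mismatch is named by the
first difference in a severity-ordered cascade: outside-scope → ingredient
→ strength → pack quantity → dose form → other qualitative. The ordering
makes the most harmful difference the category when several attributes
differ at once (a compound ingredient+form error reads as ingredient).
When a side resolved to several clinical concepts, the lexicographically
smallest rxcui represents it — a deterministic, auditable tie-break.
Strength comparison is exact per-ingredient (value, unit) equality after
unit canonicalization (trim + case-fold); no unit conversion is performed,
mirroring name-level comparison ("5 mg" ≠ "0.005 g" — such pairs surface
as strength differences for human review rather than being silently
reconciled).

Ingredient and strength mismatches are labeled TP (clinically
significant); pack-quantity, form, outside-scope and qualitative
mismatches FP; matches TN; ground-truth-contradicted matches FN. With an
error-free terminology snapshot no FN can occur, so sensitivity is
structurally 1 — the empirical content of the evaluation lies in the FP
side.

## Metrics and alert budget

Metrics are kept at full precision internally and printed at 5 decimals;
zero-denominator metrics are reported as undefined rather than raised.
Unique-pair ("learning") mode deduplicates on the *ordered* normalized NDC
pair — (A,B) and (B,A) are different dispensing situations — keeping first
occurrences; missing-RxCUI pairs are excluded from both denominators. The
alert budget (TP+FP)/TP is rounded half-up to an integer, the convention
under which the published 137.5 and 23.5 print as 138 and 24. Frequency
tables report matched clinical drugs descending, percent of all analyzed
pairs at 2 decimals, ties broken by rxcui.

## Terminology backends

The fixture store is a pure function of four TSV tables (concepts, NDC
map, clinical-drug attributes, related-concept links). The REST client
implements the same contract over the public endpoints with a persistent
JSON response cache (mandatory politeness at the ~10⁶-lookup scale of a
real run), bounded request rate, and retry/backoff that distinguishes
transport failure (`BackendUnavailable`) from the data outcome "this NDC
has no concept". Because the REST interface does not serve structured
attributes whole, the client assembles them from the ingredient and
dose-form relations, the AVAILABLE_STRENGTH attribute (parts listed in
alphabetical-ingredient order, split on " / " so units like mg/mL
survive), a leading "N (" pattern in pack names, and a small lexicon of
qualitative name qualifiers (osmotic, sugar-free, 24 hr, 12 hr). The two
backends are property-tested for equivalence over snapshots served through
a recorded transport; that equivalence holds when concept names follow the
terminology's naming convention, which both the worked example and the
generator observe.

## Synthetic data: what it emulates, and what it does not

The generator lays clinical drugs on an ingredient × strength × form grid
(each with an osmotic-release twin), adds brands for a subset, generic
pack families in two sizes, an uncurated concept pair, an obsolete NDC
with a remapping chain, unmappable NDCs, several NDCs per concept (the
one-to-many relation), and — for the FN channel — corrupt NDCs of truly
different drugs mapped to the target concept. Each record pair draws one
kind from a categorical distribution; error kinds mutate exactly one
attribute, so detection and generation are coupled through the same
terminology and per-category detected counts equal the ground-truth draws
exactly. Default rates encode the observed study conditions: per-category
mismatch rates equal to the published frequencies over 527,009 checked
pairs (3 ingredient, 1 strength, 285 pack-quantity, 67 form, 40 outside,
159 qualitative), total cleaning removals of 9,829/537,710 split evenly
between signal words and missing NDCs (the published funnel does not break
the split down), and zero mapping corruption (no FN was observed).

What passing synthetic tests shows: the plumbing is lossless — every
injected error of every category is detected and categorized correctly,
and only injected corruptions produce FNs. What it does not show: real
free-text names are messier than generated ones, real NDC dialect mixtures
and terminology edge cases (multi-source concepts, reused NDCs, tie cases
in NDC→concept mapping) are richer than the fixture's, and the real
category mix depends on pharmacy workflow, not on a categorical draw.
Synthetic NDCs use the reserved labeler 99999 so fixture provenance is
self-evident.

## Problem sizes and numerical choices

The bundled evaluation runs 20 synthetic streams of 10,000 pairs each —
large enough that pooled per-category counts are informative at the
published rates while keeping the full suite fast on one CPU. Statistical
recovery is asserted two ways: exact per-seed equality of detected and
drawn category counts (a determinism property, not a statistical one), and
pooled counts inside the central 99% binomial interval of the configured
rates. Metric identities are property-tested over random matrices;
reported rounding (5 decimals for metrics, 2 for percentages, half-up
integers for budgets) is centralized so printed tables are reproducible
byte-for-byte for fixed inputs and seeds.

## Known limitations

- Attribute assembly from the live REST interface is heuristic where the
  interface is unstructured (qualifier lexicon, pack-size regex,
  strength/ingredient order pairing); a terminology release file would be
  authoritative but is out of scope.
- No unit conversion in strength comparison, by design; equivalent
  strengths expressed in different units alert as strength mismatches.
- The curated/uncurated distinction is binary and source-based; it does
  not model partially curated concepts.
- Only ordered-NDC-pair learning is modeled; a deployed learning system
  might generalize adjudications across NDCs of the same concept pair.
- The check evaluates recorded data after the fact; it does not model
  real-time interruption of the dispensing workflow.
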