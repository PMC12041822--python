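# Methods

## Scope and data model

`oncofed` implements the logic of a multi-hospital oncology data pipeline at
desk scale. Real deployments of this pattern move data through message
brokers between containerized services and use networked pseudonymization
(gPAS/entici-style) and federated-analysis servers (DataSHIELD/OPAL).
Here every transport is a folder contract with the same message granularity
(one report / one bundle / one row per case), the pseudonymization service
is an in-process keyed-hash provider behind a swappable interface, and the
federated client/server protocol is a pair of pure functions
(`aggregate_site`, `combine`). The privacy-relevant semantics — what leaves
a site, and in what form — are preserved exactly; the infrastructure is not.

One oBDS report is one cancer case. Multiple reports may share a
`patient_id` (representable, and pseudonymization preserves that
linkability), but cases are counted per report throughout. The XML dialect
carries only the fields the analysis consumes: patient identifier,
administrative gender (M/W/D/U), ICD-10-GM code and catalog year, diagnosis
date, schema version, plus an optional synthetic quasi-identifier whose only
purpose is to give the deidentification rules something to strip. The full
oBDS schema (therapy, TNM, histology, UICC staging) is out of scope; UICC
stage in particular is deliberately not modelled because it is typically
incomplete in registry XML exports.

### Version gate

The pipeline accepts schema versions from a configurable set (default
`{2.2.2}`). A collection with any other version aborts the decompose stage
with an error naming the version — newer schema revisions silently parsed
by an older mapping are a documented failure mode of this class of
pipeline, so the gate is fatal rather than advisory. Invalid *reports*
(bad gender code, malformed ICD-10, future or unparsable date, duplicate or
empty report id), by contrast, are quarantined individually with a reason
code and never silently dropped.

## Entity grouping

The 24-group ICD-10 map (`entity_groups_default.yaml`) is an editable
reconstruction of common registry reporting groups: breast (C50, D05),
prostate (C61), melanoma (C43), lung (C33–C34), lip/oral cavity/pharynx
(C00–C14), colorectum (C18–C21), non-Hodgkin lymphoma (C82–C88), cervix
(C53, D06), pancreas (C25), thyroid (C73), larynx, esophagus, bladder
(C67, D09.0), liver, kidney, stomach, leukemia (C91–C95), uterus (C54–C55),
ovary, testis, Hodgkin lymphoma, brain/CNS (C70–C72), multiple myeloma,
biliary (C23–C24), with everything else in an explicit fallback group.
Matching is first-match-wins in file order; a bare category matches all of
its subcodes, a dotted spec only its own subtree. The fallback share is
computable per table so silent growth of "other" is visible. Exact group
boundaries (whether C21 or D09 belong, etc.) are a judgment call; analyses
that depend on them should ship their own map, which is why the map is
plain YAML and a constructor argument everywhere.

## Pseudonymization

`HashingPseudonymProvider` derives tokens as HMAC-SHA256(secret,
domain ⟂ value), base64-url encoded and truncated to 32 characters.
Determinism per (domain, value) preserves within-domain linkability;
distinct domains give unlinkable tokens for the same value; without the
secret the map is one-way. Truncation to 128+ bits keeps collisions
negligible at any realistic corpus size (tested at 10⁴ values). As a
belt-and-braces guarantee the provider re-derives (with a counter) in the
astronomically unlikely event a token shares a ≥4-character substring with
its input, so corpus scans for original identifiers cannot hit token
fragments.

Deidentification is rule-driven (`deident_default.yaml`): pseudonymize
`Patient.identifier` in the `patient` domain, remove the quasi-identifier,
keep gender/code/onset. Rules referencing unknown field paths, removals of
structural fields, or pseudonymize rules without a domain all fail at
config load, not per bundle. Onset dates stay at full precision through the
bundle stages; generalization to year happens at the flattening boundary,
which also *hard-fails* on any bundle not flagged deidentified.

## Disclosure control

`DisclosurePolicy.min_cell` defaults to 5, a common registry small-cell
rule; it is configurable and nothing in the code depends on its value.
Suppression applies to cells and marginals independently: a cell with
0 < n < min_cell exports as `SUPPRESSED`, while its entity marginal — if
itself ≥ min_cell — exports exactly. Totals (`total_cases`,
`combined_total`) are never reduced by suppression; consequently a
federation-wide marginal can sometimes be recovered by subtraction (the
worked example's 3 other-gender cases are identifiable as
17,885 − 7969 − 9913). That residual disclosure is inherent to publishing
exact totals and is accepted here, as it is in the deployments this
emulates; protecting against it would require rounding or perturbation,
which is explicitly out of scope.

True zeros are reported as absent/zero rather than suppressed — absence of
a combination reveals only absence. `strict_zeros=True` switches to the
conservative alternative in which a cell missing at any site makes the
combined cell non-publishable. Combination marks a federated cell
`SUPPRESSED` whenever any contributing site suppressed it ("poisoning"),
since its exact sum is unknowable from the exports. Every serialized
aggregate passes `assert_nondisclosive`, a recursive guard that refuses to
write any count in (0, min_cell).

## Q1/Q2 estimators and rounding

Q1 shares are percentages of the (never-reduced) scope total, so reported
shares sum to ≤ 100% with the gap equal to the suppressed/fallback share.
Q2 is emitted under both estimators side by side. The default is
`mean_of_sites` — the unweighted arithmetic mean of site-level shares,
matching the "mean across sites" convention of federated frameworks, with
a site excluded from an entity's mean (and countable via
`q2_excluded_sites`) when any of its gender cells is suppressed. The
`pooled` estimator divides combined cells by the sum of *reported* combined
cells of the entity, so reported genders always sum to 100%; when nothing
is suppressed this equals the textbook cell/marginal ratio, verified in
tests against a centralized recount oracle. Whether a real federation's
"mean" is site-weighted is a judgment call; unweighted is the documented
default here. All percentages are rounded half-up to one decimal for
reporting; full precision is retained internally.

## Validation metric

The deviation for entity *i* is |ŷᵢ − yᵢ| / yᵢ with ŷ the federated count
and y the gold-standard (tumor-documentation) count; the MAPE is the
unweighted mean over entities with y > 0. Zero-gold entities are excluded
with a warning rather than mapped to infinity — this keeps the mean finite
and the exclusion auditable in the report. MAPE is formatted to one decimal
except below 2%, where two decimals are kept. The metric is exercised
against a brute-force recomputation (equality to 1e-12 over random table
pairs) and through `perturb_gold`, which emulates retrospectively
documented cases: extra cases present in the documentation system but
absent from the export, so gold ≥ pipeline per entity and MAPE grows
monotonically with the injection count. Production per-site deviations
require protected hospital data and are intentionally not reproduced.

## Synthetic-data generator

A `SiteProfile` fixes one site's entity × gender cell counts for one
diagnosis year. *Exact* mode emits precisely those counts — this is the
backbone of the worked example, making every downstream aggregate a known
constant. *Multinomial* mode treats the cells as weights for a seeded
multinomial draw of a given total, emulating year-to-year sampling
variability (validated against binomial standard errors over 100 seeds).
Within a cell, codes are drawn uniformly from the group's configured code
list, half the time with a random subcode digit so category matching is
exercised; dates are uniform over the year; identifiers are zero-padded
per-site counters. Identical profile + seed yields byte-identical XML.

The packaged `paper_federation.yaml` (six sites, 17,885 cases; 7969 female,
9913 male, 3 other; prostate 2476, breast 2006, melanoma 1921, lung 1415,
lip/oral/pharynx 1329, colorectum 1187, NHL 801, cervix 719, pancreas 644,
thyroid 700, fourteen further groups filling the total; site 5 with 2045
cases of which 500 melanoma; site 6 documented for 2021, the rest for 2022)
pins the combined margins; the split across sites 1–4 and 6 is arbitrary
(weighted largest-remainder) and carries deliberate structure: site 4 has
no breast/uterus cases, site 5 has thinned gynecology/urology counts, and
the 3 other-gender cases sit in a single below-threshold cell so the
suppression path is exercised. All per-site cells other than that one are
≥ 5 by construction, so exact-mode runs reproduce the combined margins
bit-exactly under the default policy.

What the generator does **not** emulate: duplicate or corrected reports,
cross-site patients, documentation delay, missing fields, realistic
subcode frequencies, or within-year date structure. Passing tests therefore
demonstrate the pipeline's *logic* (conservation, privacy, estimator
correctness), not robustness to real-world data quality — the quarantine
path is tested with synthetic invalid reports instead.

## Numerical and procedural choices

* Rounding: half-up via `decimal` (never banker's rounding), one decimal
  for percentages.
* Diagnosis year is the calendar year of the diagnosis date; the default
  year filter is {2021, 2022} to match a federation in which one site's
  most recent complete documentation year lags the others.
* Manifests hash file contents (SHA-256, truncated) and the run config
  (minus key material); re-running a stage with unchanged inputs reproduces
  the manifest byte-for-byte, and generated == flattened + filtered +
  rejected is reconcilable across manifests.
* Problem sizes: the end-to-end suite runs the full 17,885-case federation
  once (a few seconds) and uses 100-seed/100-federation/1000-pair batches
  for the stochastic and oracle checks.

## Known limitations

* No networked operation: folder hand-offs and in-process aggregation
  model, but do not implement, broker- or DataSHIELD-compatible protocols.
* Disclosure control is cell suppression only — no rounding, perturbation
  or complementary-suppression against differencing attacks (see above).
* The entity map and deidentification rule set are documented
  reconstructions, not authoritative registry artifacts.
* One report = one case: deduplication/correction semantics of real
  registry feeds are not modelled beyond rejecting duplicate ids per file.
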