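# Methods

## Problem setting

An oncology information system (OIS) export arrives as three raw tables:
referrals (patient id, ICD-10 diagnosis, treatment intent, referral start
date), appointments (unique appointment id, patient id, task, date) for the
pre-treatment tasks mould, CT at two sites, MRI, PET, QA and treatment
planning (TP), and delivered fractions (patient id, date). Raw exports are
contaminated — duplicated rows, blank lines, rows whose key content field is
NULL, and corrupted entries — and a substantial share of referrals lacks a
treatment intent. Downstream applications need a cleaned dataset structured
into diagnosis–intent groups with per-group resource counts.

## Cleaning model

Each raw row receives exactly one class, with precedence
`blank_row > null_key_field > irrelevant > valid`:

* **blank_row** — every field empty or whitespace;
* **null_key_field** — the table's key content field is empty: diagnosis for
  referrals, task or appointment id for appointments, patient id for
  fractions;
* **irrelevant** — unrecognised format or corrupted content: a diagnosis
  failing ICD-10 category validation (`letter + two digits + optional dotted
  subcode`), an unrecognised task token, or an unparseable date;
* **valid** — everything else. A referral with an empty *intent* is valid:
  missing intent is handled by substitution, not removal.

Duplicates are all-but-first occurrences under a per-table identity key:
`(patient_id, diagnosis, intent, referral_date)` for referrals, the unique
`appointment_id` alone for appointments, `(patient_id, fraction_date)` for
fractions. The keys are configurable. Deduplication runs among the rows
classified valid, after the date-window filter; rows outside the window are
excluded before any accounting and reported separately. Each removal is
counted exactly once, giving the conservation invariant
`initial = duplicates + Σ invalid + final` on every table.

Percentages in the cleaning report are rendered relative to the initial
count, rounded half-up to integers, with `"<1"` for strictly positive values
below 0.5 % and `"N/A"` for a zero denominator. Half-up rounding (half away
from zero for signed values) is used for every rendered percentage in the
package; it is the convention that matches the verification tables the
defaults encode.

## Intent substitution

With per-diagnosis known counts (C_d, P_d) and u_d unknowns, the four
strategies assign, per diagnosis d:

1. **all-curative** — all u_d to curative;
2. **all-palliative** — all u_d to palliative;
3. **50–50** — largest-remainder apportionment with weights (1, 1);
4. **ratio** — largest-remainder apportionment with weights (C_d, P_d).

Two-party largest-remainder apportionment gives each side the floor of its
exact share u·w/(w_C+w_P); the at-most-one leftover unit goes to the larger
remainder, ties toward curative. The allocation is therefore always within
one record of the exact proportion. Whether an *individual* unknown record
becomes curative is decided by ascending patient id within the diagnosis
(source order breaking ties), so the whole operation is deterministic — a
requirement, since group orderings are compared across runs. A diagnosis
with no known intents falls back to the global known ratio, then to 50–50
(configurable hook; basing the fallback on historical data is possible but
not implemented). Counts are conserved per diagnosis under every strategy,
and curative counts are monotone: all-curative ≥ ratio ≥ all-palliative.

## Group statistics

Diagnoses are pooled to ICD-10 categories; by default the secondary-
malignancy categories C77–C79 merge into one "C77-79" group (configurable).
A patient with several in-window referrals is attributed to the (group,
intent) of their earliest referral; appointments and fractions follow the
patient via patient id, and records whose patient has no in-window referral
are pooled into "Other" — so every cleaned record lands in exactly one cell.
Group tables are ranked by descending patient count with lexicographic
tie-breaks; top-N coverage (default N = 20, typically ≈ 80 % of patients) is
reported, not enforced. Appointment counts are per appointment (CT pools
both sites; PET is carried as an optional column), fractions per delivered
fraction. Monthly inflow buckets referrals by calendar month, zero-filled
across the window.

## Comparison report

Reference-vs-tool comparison aligns the union of groups (absent side = 0)
on the reference's largest N groups. Cells report `diff = det − ref` and the
half-up integer percent difference, `N/A` when the reference count is zero.
The per-variable **median absolute percent difference** over the top N
groups is computed from the unrounded ratios |det−ref|/ref (zero-reference
pairs excluded, even counts averaging the middle two) and rounded half-up
at the end — medians of pre-rounded cells would differ.

## Synthetic data

No deposited OIS export exists, so fixtures are generated:

* **Exact-marginal mode** plants `clean + duplicate + null_key + blank +
  irrelevant` rows per table and shuffles them by seed. Duplicates are exact
  copies of seeded-chosen clean rows; clean rows are constructed unique
  under the identity key, so the planted counts are exactly recoverable.
  The default suite encodes the 2015–16 study conditions: referrals
  3916 = 3310 + 28 + 103 + 107 + 368 with intents 2030 curative / 907
  palliative / 373 unknown; mould 1662 = 1560 + 36 + 66; CT-site1
  3735 = 3642 + 41 + 52; MRI 684 = 654 + 13 + 17; QA 1285 = 946 + 304 + 35;
  fractions 58 228 = 58 224 + 4. Malformed diagnosis tokens come from a
  fixed pool of format violations (digit-first, symbols, truncated codes).
* **Cohort mode** draws patients from a case-mix weight table (breast,
  prostate, lung dominating; C77/C79 overwhelmingly palliative), a global
  curative share of 0.69 with per-diagnosis overrides, 11.3 % intent
  missingness, Poisson per-task appointment counts (means per patient:
  mould 0.47, CT-site1 0.95, CT-site2 0.15, MRI 0.20, PET 0.06, TP 1.18,
  QA 0.29), and Poisson fraction counts with intent-dependent means
  (curative 22, palliative 8 — protracted vs short palliative courses).
  Referral dates follow monthly weights with a mild summer dip
  (June–August: 0.85/0.70/0.80); the weights are configuration, not a
  claim about any particular year. A ledger records the true per-(diagnosis,
  observed intent) counts; attribution is deterministic given the data, so
  the computed statistics must equal the ledger exactly.

What the generator does **not** emulate: per-diagnosis missingness
structure (missingness is uniform), patients with multiple referrals,
cross-table inconsistencies beyond the planted classes, or any real
department's exact per-diagnosis distribution. Passing tests therefore
demonstrate correctness of the accounting, apportionment and attribution
machinery under the stated contamination model — not robustness to every
failure mode of a live OIS.

## Numerical and design choices

* Rounding: half-up everywhere (`decimal.ROUND_HALF_UP` on the repr of the
  float), chosen over banker's rounding to match the rendered verification
  percentages; signed percent differences round half away from zero.
* Window: both endpoints inclusive; appointments and fractions are filtered
  by their own dates, independent of referral dates. Fraction courses in
  cohort mode may straddle the window end — batch runs log, and do not
  correct, such straddling.
* Unknown-intent share is reported over the total; curative/palliative
  shares over known referrals only, as the shares feed the ratio strategy.
* CSV in/out uses verbatim strings for raw tables (no NA coercion, so the
  blank/NULL distinction survives parsing); dates render ISO-8601; written
  bundles are byte-deterministic for identical inputs.
* Problem sizes in the test suite: the exact-marginal suite at its default
  (~69 000 raw rows over six tables) runs in a few seconds; cohort-based
  property tests use 200–10 000 patients, the larger size only where a
  binomial sampling-error bound needs it.

## Limitations

* The ratio strategy is estimated from the selected time frame only; for
  small cohorts the per-diagnosis ratios are noisy (the fallback hook is the
  mitigation point).
* Strategy-specific top-20 totals of a real dataset depend on its
  unpublished per-diagnosis unknown distribution; synthetic cohorts
  reproduce such results only qualitatively.
* No fuzzy duplicate matching and no back-filling from electronic medical
  records; a row is either exactly duplicated or it is kept.
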