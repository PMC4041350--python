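# Methods

## Setting and scope

`hdsslink` models record linkage between two person-level sources in a
rural southern-African surveillance setting: an HDSS register of a
geographically defined population, and the patient register of a local
health facility. Identifiers available in both are first name, surname,
sex, day/month/year of birth, village, another household member's first
name and surname, national ID number and telephone number. The register
side is essentially complete on these fields; the clinic side is not
(village ≈ 81%, household-member names ≈ 77%, national ID ≈ 1.6%,
telephone ≈ 27% complete). Because no public gold standard exists for
such data, a synthetic generator with known pair-level truth stands in
for the fingerprint-matched evaluation sets used in practice.

## Fellegi–Sunter core

Per candidate pair and linking field *i* the comparison outcome is
agree/disagree/missing. Agreement weights log2(m_i/u_i) and disagreement
weights log2((1−m_i)/(1−u_i)) are summed over non-missing fields into the
matching score (bits). Date parts are compared as three separate exact
fields; village exactly; name fields under the scenario's rule.

**Missing-field policy.** A missing outcome contributes zero weight —
neither reward nor penalty. With the clinic side missing entire fields
for ~20–98% of records, a disagreement penalty would systematically
depress scores of incomplete records rather than reflect evidence about
match status.

**EM estimation.** m, u and the match proportion p are estimated per
blocking scheme on that scheme's candidate pairs, by EM for a two-class
mixture under conditional independence given match status. Comparison
vectors are collapsed to unique patterns with counts, so each iteration
is O(patterns × fields). Missing outcomes are excluded from a field's
update counts. Parameters are clamped to [1e-6, 1−1e-6]; defaults
m=0.9, u=0.1, p=0.01; convergence when the largest absolute parameter
change falls below 1e-6, at most 1000 iterations (non-convergence sets a
flag, never an error). The observed-data log-likelihood is recorded per
iteration and is non-decreasing. If the converged solution has the
"match" class agreeing less often on average than the "non-match" class,
the classes are relabelled (p ← 1−p).

**Threshold.** Following the estimated-match-count approach, M =
round(p̂·n) among the block's n candidate pairs, and the threshold is the
M-th largest score; pairs scoring ≥ threshold (closed boundary) are
accepted. M = 0 yields +∞ (nothing accepted automatically).

**Degenerate-block guard.** A genuine match class agrees *at least* as
often as chance on every identifier, so m_i ≥ u_i is an a-priori property
of the model. When a block's fitted parameters violate this strictly
(m_i < u_i on some field), the fitted "match" class is an artifact of
correlated chance agreement — typically name-pool collisions among
records with no true counterpart — and the block is declared
non-identifiable: its parameters are reported for audit but it
contributes no automatic links. The case arises in practice when the
deterministic stage has already removed every true match from a block
(e.g. complete, unique national IDs), leaving a match-free remainder;
without the guard the rank threshold would fabricate round(p̂·n) false
links there. Fields made constant by blocking (e.g. birth year inside a
sex×birth-year block) fit m = u at the clamp and are unaffected by the
strict inequality.

## Blocking and combination

Three schemes: BS1 = exact sex and birth year; BS2 = exact sex and
village; BS3 = equal first letters of first name and surname with age
difference ≤ 10 years (age = reference_year − birth_year; reference_year
is a run parameter, default 2010). A record missing a blocking variable
yields no pairs under that scheme. Linkage (EM, scoring, threshold) runs
within each scheme and the *linked* pairs are unioned afterwards —
parameters are per-block because u in particular depends strongly on the
blocking variable. Duplicate pairs keep their maximum score; a clinic
record linked to several registry records keeps only the highest-scoring
pair, ties broken by lexicographically smallest registry id. The
one-to-one rule is applied after the union.

## Deterministic stage and clerical review

The deterministic stage links exact agreement on national ID, or on
telephone together with first name (phones normalized by stripping
non-digits and a leading 27/0027 country code; IDs by stripping
whitespace). A value occurring on multiple records of one side is a
collision: flagged, never linked. Deterministically linked records are
accepted unconditionally and removed from the probabilistic stage's
input. Removing them slightly perturbs the per-block EM fits, so the
hybrid scenario's sensitivity is not guaranteed to dominate its purely
probabilistic core on every seed — it does in the median and on most
seeds, and its deterministic links are always true when IDs are unique.

Clerical review targets the scored pairs nearest the acceptance
threshold: with fraction f of the n scored candidate pairs, ceil(f·n/2)
pairs are taken from each side of the threshold by rank (topping up from
the other side if one runs short), ordered by |score − threshold|. The
review base is all scored candidate pairs of the scenario, and the
scenario-level threshold is the minimum accepted score over blocks (the
effective boundary of the combined accept region) — with per-block
thresholds there is no single printed cut-off, and this choice makes
"nearest the threshold" well defined on the combined set. Reviewers are
simulated: two independent reviewers report the true status flipped with
probability ε, a third adjudicates disagreements under the same model,
so the final decision errs with probability 3ε² − 2ε³. Review decisions
suspend the automatic classification of queued pairs and take precedence
in the final one-to-one resolution.

## Scenario grid

S1–S6 use the routine identifiers (first name, surname, day/month/year
of birth, village) with name rules exact, JW ≥ 0.7, JW ≥ 0.9, Double
Metaphone, Soundex, and "JW ≥ 0.9 or DM or Soundex". S7–S12 add another
household member's first name; S13–S15 add the household member's
surname (JW ≥ 0.9 / DM / Soundex only). S16 prepends the deterministic
stage to S12's settings; S17–S20 add clerical review of 5/10/15/20% of
near-threshold pairs.

## String comparators

All comparisons case-fold, strip accents (NFKD) and trim whitespace.
Jaro–Winkler uses the standard prefix boost (scale 0.1 over at most 4
characters). Soundex is the classic American code (initial letter + 3
digits, H/W transparent, vowels separating repeated codes). Double
Metaphone follows the published rule set with codes capped at 4
characters; the alternate code falls back to the primary when no
alternative pronunciation exists, and phonetic agreement means primary
codes equal or either primary equals the other's alternate. Missing
values form a third outcome state rather than a disagreement.

## Synthetic data generator

The generator emulates the statistical structure the linkage problem
depends on, not any real population:

- **Registry.** Persons are grouped into households (Poisson-distributed
  size, mean 5, floored at 2 so the household-member fields always have a
  referent) sharing surname and village; the household-member fields cite
  the oldest other member. Adult ages follow a decreasing band structure
  (54% aged 18–34, 20% 35–49, 14% 50–64, 12% 65+). Names come from small
  bundled pools (synthetic southern-African given names and surnames);
  national IDs are 13-digit strings and phones 10-digit strings, unique
  per person.
- **Clinic.** A configurable fraction (default 0.6) of clinic records are
  corrupted copies of distinct registry persons (the ground truth); the
  rest are novel walk-ins drawn from the same name pools, which is what
  creates realistic false-positive opportunities. IDs of walk-ins come
  from a disjoint numeric range so spurious deterministic links cannot
  occur by construction.
- **Corruption.** Name typos (one random character edit) at rate 0.25,
  phonetically plausible spelling rewrites (PH↔F, C↔K, doubled letters,
  I↔Y, …) at rate 0.30, female surname change (marriage) at 0.20,
  misreporting of one date-of-birth component at 0.30, and residential
  village change at 0.15. These defaults were set so that desk-scale
  linkage difficulty mirrors the qualitative behaviour observed in real
  HDSS↔clinic linkage — exact name comparison clearly trails phonetic
  rules, the household-member name adds sensitivity, and PPV stays below
  1 — while absolute sensitivities remain higher than in field data
  because a 5,000-person register offers a far smaller confusion space
  than a real one.
- **Covariate effects.** Corruption rates scale with age (×(1 + 0.5 per
  decade above 50)), and name corruption is ×1.75 for persons of
  non-local ethnicity (emulating less consistent transcription of
  unfamiliar names). Jointly with the female surname-change rule these
  produce the linkage-bias signature the evaluation module is designed to
  detect: lower matching odds for women, the elderly and minorities.
- **Missingness.** Per-field, per-source completeness probabilities;
  defaults follow the observed completeness of each identifier in the two
  sources (e.g. national ID 67.14% registry / 1.55% clinic, village 100%
  / 81.17%, household-member first name 98.48% / 77.29%). Missing is a
  dedicated sentinel (`None` in memory, empty CSV cell), never the empty
  string.
- **Background covariates** (ethnicity, residence status, education,
  employment, wealth quintile) are drawn from fixed marginals with an RNG
  keyed on (seed, record id), so any stage can recompute them; wealth
  quintiles are assigned directly rather than derived from an asset
  model.

Everything is a deterministic function of (config, seed): identical
inputs give byte-identical datasets.

**What the generator does not model:** real name frequency
distributions, correlated field errors (a clerk mishearing a name does
not also misreport the village), duplicate registry entries, circular
labour migration, or clinic patients re-registering under different
identities. Passing tests therefore demonstrate the pipeline's internal
correctness and its qualitative behaviour under realistic noise — not
field-level performance.

## The overlap fraction

The true overlap between a register and a clinic population is never
observed in practice. The default 0.6 is a design choice: large enough
that every block contains a solid match class for EM, small enough that
walk-ins dominate no block. It is a plain config parameter.

## Evaluation

Sensitivity = TP/(TP+FN) and PPV = TP/(TP+FP) are the primary indices.
Specificity and NPV are computed only against an explicit candidate-pair
universe and labelled with it; with millions of easy non-matches they sit
near 1 by construction and carry little information. Undefined indices
(zero denominator) are reported as not-available, never 0.

The bias regression is a multivariable logistic model of match success on
sex, age group, ethnicity, residence, education, employment and wealth
quintile (reference categories: female, 18–34, other ethnicity,
permanent, no education, not working, lowest quintile), fit by maximum
likelihood with Wald CIs, McFadden pseudo-R² and an overall Wald χ² on
the slope coefficients; covariates causing separation are dropped with a
warning. Match success is reported both strictly (the true pair was
recovered) and loosely (the clinic record was linked to someone), since
the two denominators answer different questions.

The distribution comparison applies Pearson χ² (no continuity
correction) to the k×2 table of category counts in the full
gold-standard set versus the linked subset, treating the columns as
independent samples. The linked subset is nested in the gold set, so
these p-values are conservative descriptive summaries rather than exact
tests; they are used this way deliberately, matching how such
comparisons are conventionally reported.

## Problem sizes and tolerances in the test suite

Module tests run at 1,200×400 records; the scenario-ordering suite at
5,000×1,000 over 10 seeds; EM recovery at 20,000 vectors × 20 seeds
(mean absolute error ≤ 0.02 for m and u, ≤ 0.01 for p, consistent with
binomial error at these counts); the clean-data perfect-recovery limit at
1,000×300 for all twenty scenarios. Chi-squared recomputations from the
bundled published counts match their published p-values to ±0.005.
Monte-Carlo checks (corruption rate, reviewer error) use ±1–2 percentage
points at n = 10,000.

## Known limitations

- Conditional independence is assumed by EM but mildly violated in the
  generator (household structure correlates surname, village and the
  household-member fields); the rank threshold partly absorbs the
  resulting miscalibration of p̂.
- u-probabilities are global per field, not value-specific; rare names
  carry no extra weight.
- The greedy max-score one-to-one rule is not an optimal assignment.
- The clerical-review base (all scored candidate pairs) and the
  scenario-level threshold are documented conventions; other
  implementations count only pairs inside the review window differently.
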