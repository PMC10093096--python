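# Methods

## Model

`ihcdx` treats panel-based IHC diagnosis as posterior inference over a
finite set of disease entities.  The knowledge base stores, for entity
*d* and marker *j*, an ordinal grade describing what fraction of cases
of *d* stain positive for *j*:

| grade | positivity interval | representative frequency f |
|-------|---------------------|----------------------------|
| `++`  | 75–100 %            | 0.875 |
| `+`   | 50–74 %             | 0.62  |
| `+/-` | 30–49 %             | 0.395 |
| `-/+` | 10–29 %             | 0.195 |
| `-`   | 0–9 %               | 0.045 |

Printed interval brackets are integers; on the continuous percentage
scale the bands are taken half-open — [0, 10), [10, 30), [30, 50),
[50, 75), [75, 100] — which agrees with the integer endpoints everywhere
and leaves no fractional value unassigned.  The representative frequency
is the midpoint of the printed bracket rescaled to [0, 1].  Grades are
what pathology references actually record; a point probability is needed
for inference, and the midpoint is the least-informative choice inside
the band.  The whole mapping lives in one `GradeTable` object so an
alternative calibration (e.g. empirical frequencies) is a single change.

Scoring is naive Bayes: conditional independence of marker results given
the disease, with

* P(positive | d, j) = f(grade(d, j)), P(negative | d, j) = 1 − f;
* markers the KB does not grade for *d* contribute the neutral
  likelihood 0.5 (unknown ≠ negative);
* markers absent from the KB registry entirely are skipped with a
  warning — penalising every candidate identically would only rescale
  the posterior, whereas the per-disease gaps above are meaningful;
* all likelihoods are clamped to [0.01, 0.99].  Grade-derived values
  already lie inside this range; the clamp guards user-supplied numeric
  frequencies of 0 or 1, so that one atypical result can never zero out
  the true diagnosis.

Conditional independence is clearly wrong in detail (CD4/CD8, lineage
programmes), but it is the minimal model expressible over a
grade-table knowledge base, and the validation harness measures exactly
how far it carries.

Products are accumulated in log space and normalised over the full
candidate set.  The top-k view (k = 10 by default, matching how such
differentials are presented to users) truncates without renormalising:
displayed percentages remain posteriors over all candidates and sum to
less than 100 %.  The default prior is uniform over KB entities; an
incidence-weighted prior can be supplied as a mapping.  Marker terms are
accumulated in sorted-marker order, making the posterior bit-identical
regardless of how the panel was entered; remaining exact ties (entities
with identical restricted profiles) are broken by canonical name, so all
output is deterministic.

## Validation harness

Case filters mirror archival-study practice, applied in order with the
first applicable reason recorded: duplicate case id; fewer than three
usable (performed) markers; panels whose usable markers all carry the
`prognostic_only` role tag (e.g. p53, EGFR — they say nothing about
tumour origin); and, where ground truth is required, absence of an
original diagnosis.  Result tokens outside the recognised vocabulary are
flagged as inconclusive on the case rather than silently dropped, and
are treated as not-done.

A **strict hit** means the alias-normalised original diagnosis appears
in the top-k differential.  An **inclusive hit** additionally accepts a
top-k entry that shares the truth's lineage and has an identical grade
on every marker graded for *both* entities, differing at most in site
class — operationalising "indistinguishable immunophenotype, different
location" (nodal vs extranodal marginal zone lymphoma being the type
case).  Restricting the comparison to jointly graded markers is the only
computable reading when profiles have different marker coverage.  If the
truth is missing from the KB the inclusive outcome is flagged
undeterminable and counted as a miss.

Percentages print half-up to one decimal via exact decimal arithmetic
(`rate(570, 602) == 94.7` to the digit).  Source tables in this
literature occasionally round the same ratio both ways; the harness
reproduces each ratio from its own numerator and denominator and leaves
the convention documented rather than adjudicated.

Accuracy across dataset groups is compared with a Pearson chi-square
test on the g × 2 table of (accurate, error) counts, df = g − 1, no
continuity correction (the comparison is across g groups, not a 2 × 2
design); p-values come from the chi-square survival function.

## Synthetic data

The generator emulates the structure of a nationwide archival lymphoma
validation: many candidate entities, modest per-case panels, profiles
that partially overlap between entities, and occasional atypical
results.  Defaults (chosen once as study conditions):

| parameter | default | rationale |
|-----------|---------|-----------|
| `n_diseases` | 150 | order of the number of recognised lymphoid-neoplasm types |
| `n_markers` | 60 | a realistic lymphoma-relevant antibody menu |
| `panel_size` | 8 | archival panels average ~8 stains per case |
| `cases_per_disease` | 20 | ~3000-case cohort spread over 150 entities |
| `overlap` | 0.2 | moderate profile sharing between entities |
| `atypical_rate` | 0.05 | small probability a result is flipped |
| `specific_fraction` | 0.0 | pathognomonic markers only when asked for |

Knowledge bases: one template profile with grades uniform over the five
labels; each disease copies the template and resamples
⌈(1 − overlap)·n⌉ randomly chosen positions, so overlap 1 yields
identical profiles and overlap 0 independent ones (pairwise shared-grade
fraction ≈ 1/5 by chance).  A configurable fraction of markers is
instead designated disease-specific — `++` for exactly one entity,
`-` elsewhere — recreating the contrast between entities with
near-pathognomonic stains (TdT, CD56, EBER) and marker-poor ones.
Cases sample `panel_size` markers uniformly without replacement and draw
each result Bernoulli(f) with an `atypical_rate` chance of flipping.
All stages draw from independent streams spawned from one integer seed
(`SeedSequence([seed, stage])`), so partial runs reproduce exactly.

What the generator does **not** emulate: marker–marker correlation
within a case, site- or treatment-dependent expression shifts,
pathologist-directed panel selection (real panels are chosen to probe
the suspected entity, not at random), inter-observer read variability,
and mixed/composite tumours.  Passing synthetic recovery therefore shows
the engine is a correct and well-calibrated Bayes ranker for the stated
generative model — not that real-world hit rates will match.

### Experiments

`recovery_experiment` scores a generated cohort against its own
generating KB and reports the strict top-k hit rate.  Under separable
conditions (20 entities, overlap 0, no atypicality, panels of 8, 50
cases per entity) the measured hit rate is ≈ 97–99 % per seed, not
100 %: with grades uniform over five levels, mid-grade markers carry
weak evidence, and a few per cent of cases draw panels atypical enough
for their own profile that ten or more competitors legitimately
out-score the truth under the exact posterior.  An independent
Monte-Carlo of the generative model (outside the package) reproduces
this ~2 % miss floor, so it is a property of the model, not of the
implementation.  With overlap 1 all profiles are identical, the
posterior is uniform, and deterministic alphabetical tie-breaking makes
the top-10-of-20 hit rate exactly k/n = 50 %.

`atypical_flip_experiment` reproduces the documented real-world failure
mode — a tumour negative for its pathognomonic marker (the
cyclin-D1-negative mantle-cell scenario).  It requires a KB in which
disease-specific markers exist (`specific_fraction` > 0), samples a case
from the disease's own profile with its most disease-specific `++`
marker observed positive, flips that one result to negative, and checks
whether the true diagnosis's rank strictly worsens.  Under the canonical
configuration (20 entities, 40 markers, half of them pathognomonic,
panels of 8) the demotion fraction is ≈ 98–100 %; without pathognomonic
markers demotion is rarer (~90 %) because no single marker's loss is
decisive enough for a competitor to overtake a truth that leads on the
rest of its panel.

## Numerical choices and degenerate inputs

* Posterior normalisation is exact to 1e-9 by construction
  (max-subtraction before exponentiation).
* `top_k` on fewer than k candidates returns all of them; k < 1 is
  rejected.
* An empty knowledge base, a case with no usable results, and a prior
  that does not sum to 1 over the KB are rejected with specific errors.
* Differential tables allow 0 × M and N × 0 shapes (removing the last
  row/column is valid).
* Serialisation: JSON round-trips the full KB (grade table, registry,
  aliases) identically; the long-format CSV carries profiles only and is
  intended for hand authoring.

## Known limitations

* The naive-Bayes likelihood ignores marker correlations and staining
  intensity; results are positive/negative only.
* The neutral-0.5 treatment of ungraded markers favours sparsely
  profiled entities when panels stray outside their graded markers
  (visible in the demo KB when unusual co-positivities are entered).
* The curated demo KB is a two-dozen-entity teaching set with
  entity-level textbook grades, not a calibrated clinical database.
* Prior weighting by disease or site incidence is supported but no
  incidence table ships.
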