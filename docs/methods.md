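# Methods

## Model structure

The network has three layers. Disorder roots are binary with prevalence
priors; a `PopulationContext` selects the clinical or the general-population
column. Symptom variables are children of exactly the disorders with an
elicited probability in their table row; there are no disorder–disorder
edges (comorbidity is mediated by shared symptoms, e.g. three DSM antisocial
criteria are also borderline arcs) and no symptom–symptom edges (correlated
symptoms were excluded at the variable-selection stage, and a clamped
finding is unaffected by incoming arcs anyway). The distress layer holds
binary nodes, one per symptom cluster plus one general node, so that
clusters of maladaptive symptoms remain visible when every categorical
diagnosis is negative.

State spaces: DSM criteria and defense mechanisms are binary
(absent/present); LPF scales and trait variables are graded low/medium/high.
For LPF the neutral state is *low* (scales measure impairment); for FFM and
biosocial variables it is *medium* (an extreme score on either side can be
deviant).

## Elicited parameters

The packaged tables carry, per symptom row: the probability that the
symptom is present when each related disorder is present alone (one column
per disorder, on the 0–100 scale, one decimal), the probability of the
symptom absent any personality disorder ("norm", the leak/baseline), and
the probability that the symptom alone causes clinically significant
psychological distress ("pd"). Percentages are converted to fractions at
load; display rendering reverses the conversion (one decimal for
probabilities, two for likelihood ratios).

Reading choices where the printed tables underdetermine the model:

* The FFM table prints a single norm value per trait even when arcs point
  at both tails; it is used as the baseline of *both* tails. This reading
  reproduces the published likelihood-ratio values (e.g. Compliance under
  ATS).
* The biosocial table prints separate ↑/↓ baselines; where the ↓ value is
  missing ("Active", "Other") it defaults to the printed ↑ value. No arc
  targets those low tails, so the choice is inert for inference; it is
  recorded only to keep every graded variable fully parameterized.
* The LPF elicited probability is taken to refer to the *high* state alone
  (not "medium-or-high"); this choice exactly reproduces the published LPF
  likelihood-ratio rows (e.g. Empathy 85/15 → 5.67).
* Symptom ids are normalized to `FRAMEWORK-Name` slugs; a lookup accepts
  the printed spellings ("DSM - BDL 03", "MD - Acting out").

## Canonical CPT models

All three models assume independence of causal influence and are calibrated
with `c = (q − l)/(1 − l)`. This is the unique calibration that makes the
all-absent row equal the baseline *and* every single-cause row equal its
elicited `q` — the two facts the elicitation actually measured — and it is
required for the likelihood-ratio tables to be self-consistent with the
CPTs. Single-cause calibration holds to 1e-12 across all 179 arcs (checked
by the acceptance suite).

**Leaky noisy-OR** (binary): standard.

**Leaky noisy-MAX** (LPF): the tables carry one number per arc, so a full
per-state effect distribution is not available. Each cause's graded effect
is two-point — mass `c_i` on high, the remainder on low — and the child is
the ordinal maximum of the effects and the leak. Under this reading the MAX
reduces to a noisy-OR on the top state and the medium state gets zero
conditional mass. A `medium_split` parameter (default 0) moves a fraction
of each effect's non-high mass to medium for users who want a softer scale;
the high-state calibration is invariant to it.

**Evidence-weighting model** (FFM, biosocial): the published description —
multi-state symptoms whose causes weigh evidence for and against, against a
population baseline — is reconstructed as additive log-odds evidence:
per-arc weight `w_i = logit(q_i) − logit(b_tail)`, tail scores
`logit(b_tail) ± Σw` mapped back through the inverse link, medium taking
the remainder. An active ↓ arc subtracts its weight from the ↑ tail score
and vice versa (opposing evidence). A probit link is provided as an option,
since a latent-normal threshold is the other natural reading of a
"logistic-Gaussian" construction; single-cause calibration holds under
either, and the logit link is the default. When many strong causes are
simultaneously present the two tail scores can overflow; tails are then
rescaled proportionally onto `1 − ε` with the medium floor `ε = 0.01`
keeping the distribution proper. Whether the original model rescaled or
floored the neutral state is unknowable from the published description;
flooring was chosen because it never perturbs single-cause rows.

## Distress layer

Distress nodes are leak-free noisy-OR children: the link strength of a
symptom is exactly its elicited "pd" probability, so a single deviant
symptom alone provokes distress with exactly that probability and an
all-neutral group has distress probability zero. No spontaneous-distress
baseline was elicited, hence leak 0. Graded parents activate their link
from any deviant state some arc targets (both tails for traits with arcs to
both tails; only *high* for LPF scales). Grouping: the five DSM clusters by
criterion family; FFM traits by their NEO domain, openness excluded (its
three retained traits have no distress entry); LPF as
{identity, self-direction} / {empathy} / {intimacy} — the LPFS
self/interpersonal split, with the published count (3) fixing the number
but not the partition, which is configurable. The general node takes the
five disorder nodes as parents with the disorder-level "pd" strengths; the
alternative (aggregating the 13 group nodes) has no elicited parameters and
is rejected.

## Inference

Exact, by enumeration of the 2^5 disorder configurations. Given a
configuration the symptoms are conditionally independent, so the evidence
likelihood factors per observed symptom; an observed distress node
contributes `1 − ∏(1 − pd_i · P(trigger_i | config, clamps))` in closed
form, marginalizing unobserved symptom parents without enumeration.
Weights accumulate in log space (86 factors can underflow) with one final
normalization. Symptom targets that are parents of observed distress nodes
are handled by re-evaluating those distress factors with the target
clamped. Contradictory findings (total weight zero) raise an error rather
than returning NaNs. Networks re-imported from XMLBIF lose the closed-form
distress decomposition and fall back to explicit marginalization over the
distress CPT.

The engine is cross-checked against an independent dense joint-table oracle
(tensor product of all CPTs) on seeded synthetic networks of ≤ 12 nodes;
agreement is at 1e-9 or better.

## Diagnostics and sensitivity

Likelihood ratios are computed from the stored fractions and rounded only
for display; panel thresholding uses unrounded values with inclusive
boundaries (two borderline rows sit at 5.01 unrounded and are printed as
5.00). Recomputing the published screening panel from the raw tables admits
one member the published column omits — DSM-BDL-06, LR− 0.174 ≤ 0.2 — which
the tests document as a surplus; its rounded value (0.17) ties two printed
rows. Panel ties order by (strength, symptom id) for determinism.

Arc strength is defined explicitly (the published analysis leaned on a GUI
tool whose metric is undocumented): per configuration of the child's other
parents, the maximum pairwise distance between the child's conditionals
across the arc parent's states; distances euclidean (default), absolute
(Chebyshev) or Hellinger; aggregation unweighted average (default) or
maximum. Finding impact ranks candidate observables by the largest
posterior shift they can induce on a target, on top of current evidence —
the therapeutic-target ranking. Parameter-perturbation sensitivity
(derivatives w.r.t. CPT entries) is out of scope.

## Delphi module

Sample (n−1) standard deviation — with seven experts the distinction from
the population SD matters and the elicitation description does not specify;
sample SD is the statistical default. The consensus bound is inclusive
(exactly one SD away still counts), reading "more than one standard
deviation away" literally. Missing responses are excluded per item, not
imputed. The monotone consensus property is stated against the *round-1*
band (mean ± SD as shown to the experts): moving dissenters toward the mean
provably cannot lower that rate, whereas the recomputed rate may fall
because the recomputed SD shrinks as answers regress to the mean — the
published elicitation observed precisely this friction. The historical
inter-round consensus percentages cannot be reproduced without the raw
expert matrices, which were never published; the module is validated on
seeded synthetic rounds instead (generating-mean recovery within three
standard errors).

## Synthetic fixtures

`generate_fixture` emulates the *shape* of the real knowledge base — mixed
binary/graded frameworks, strict arc-over-baseline margins (≥ 5 points),
values on the 0.1% elicitation grid, distress groups, clinical > general
prevalence — at sizes (default 2 disorders, ≤ 7 symptoms) where the dense
joint oracle is affordable. It does not emulate the real tables'
correlation structure, their heavy sharing of symptoms across disorders, or
realistic prevalence magnitudes; passing the oracle-equivalence and
round-trip properties on fixtures therefore validates the *algorithms*,
not clinical behaviour. Acceptance runs use 100 fixture seeds.

## Known limitations

* The parameters are expert consensus, not patient data; the model has not
  been validated against a clinical sample, and posteriors should be read
  comparatively (ranking disorders) rather than as calibrated risks.
* The evidence-weighting model's functional form is a reconstruction
  constrained by single-cause calibration; multi-cause rows are a modelling
  choice, not published data.
* No CPT learning from data, no approximate inference (the exact scheme
  covers this model class), no comorbidity edges, no GUI.
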