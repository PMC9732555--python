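# clusterbn

A Bayesian diagnostic network for the dramatic/emotional (cluster-B)
personality disorders — antisocial (ATS), borderline (BDL), narcissistic
(NAR), histrionic (HST) and passive-aggressive (PAG) — built entirely from
expert-elicited probabilities.

Personality disorders are hard to assess: traditional instruments lean on a
single framework (usually the DSM criteria), inter-evaluator agreement is
poor, and empirical datasets suitable for learning a statistical model are
scarce. `clusterbn` takes the knowledge-engineering route instead: it ships
an elicited knowledge base covering 86 psychological variables from five
diagnostic frameworks — DSM criteria, defense mechanisms, the Level of
Personality Functioning (LPF) scales, Five-Factor Model (FFM) traits, and
Millon's biosocial polarities — and assembles them into a three-layer
probabilistic graphical model for screening, differential diagnosis and
therapeutic-target ranking. The package is aimed at researchers in
computational psychiatry and at anyone building decision-support or teaching
tools on top of diagnostic Bayesian networks.

## The model

The network is an *augmented BN2O* model with three layers and 105 nodes:

* **5 disorder roots** `D_x`, binary, with priors from prevalence tables
  (clinical or general population);
* **86 symptom nodes** `S_y` — binary (DSM, defense mechanisms) or graded
  low/medium/high (LPF, FFM, biosocial) — children of exactly the disorders
  that influence them;
* **14 psychological-distress nodes** `PD_z` aggregating symptom clusters
  (5 DSM groups, 4 FFM domains, 3 LPF clusters, 1 defense-mechanism group)
  plus a general distress node fed by the disorders themselves. The distress
  layer flags clusters of maladaptive, distress-causing symptoms even when
  every categorical diagnosis is negative.

The joint distribution factorizes as usual,
`P(X1..Xn) = ∏ P(Xi | pa(Xi))`, and all CPTs come from *canonical models*
under independence of causal influence, so table size grows linearly in the
number of parents. With elicited single-cause probability `q_i`, baseline
(leak) `l`, and calibrated link `c_i = (q_i − l)/(1 − l)`:

* **leaky noisy-OR** (binary symptoms):
  `P(S=present | config) = 1 − (1−l) ∏_{i present} (1 − c_i)`;
* **leaky noisy-MAX** (LPF scales, neutral state lowest): each cause
  contributes an independent graded effect and the child takes their
  ordinal maximum;
* **evidence-weighting model** (FFM traits and biosocial polarities,
  neutral state *medium*, causes may push either tail): each active arc adds
  log-odds weight `w_i = logit(q_i) − logit(b_tail)` for its target tail and
  against the opposite one,
  `p_high = σ( logit(b_high) + Σ w_↑ − Σ w_↓ )`, symmetrically for the low
  tail, medium taking the remainder.

All three models reproduce the elicited tables exactly: the all-absent row
equals the baseline and every single-disorder row equals its `q`.

From the same raw probabilities the package derives each symptom's
diagnostic likelihood ratios, `LR+ = q/l` and `LR− = (1−q)/(1−l)`, builds
confirmatory panels (`LR+ ≥ 5`) and screening panels (`LR− ≤ 0.2`), and
updates pre-test to post-test probabilities through the odds form of Bayes'
rule. A Delphi module implements the consensus machinery used to produce
the parameters (per-item mean/SD aggregation, the ±1-SD consensus rule,
second-round construction, last-round means as final values).

## Worked example

```python
import clusterbn as cb

ps = cb.builtin_cluster_b()            # the packaged elicitation tables
model = cb.build_network(ps, "clinical")

ev = {"DSM-BDL-03": "present",         # identity disturbance
      "DSM-BDL-04": "present",         # impulsivity
      "LPF-Identity": "high"}          # impaired identity functioning
rep = cb.posterior_marginals(model, ev, ["ATS", "BDL", "NAR", "HST", "PAG"])
for d in cb.DISORDERS:
    print(d, f"{100 * rep.prob(d, 'present'):.1f}")
```

```
ATS 13.6
BDL 95.7
NAR 13.0
HST 14.8
PAG 10.0
```

Three findings lift the borderline posterior from its 19.3% clinical prior
to 95.7% while the other disorders barely move — the three observed
variables sit in the borderline confirmatory panel (LR+ 7.77, 5.01, 5.86).
The distress profile ranks therapeutic targets under the same evidence:

```python
profile = cb.distress_profile(model, ev)
print(f"{100 * profile.prob('PD-DSM-BDL', 'present'):.1f}")   # 99.9
print(f"{100 * profile.prob('PD-General', 'present'):.1f}")   # 89.4
```

For screening in the general population, the odds update gives the
post-test probability directly: a positive on DSM-BDL-09 (LR+ 6.36) moves
the 3.5% general-population prior to 18.7%:

```python
print(f"{100 * cb.posttest_probability(0.035, 6.36):.1f}")    # 18.7
```

The same operations are available from a shell:

```sh
clusterbn panel --mode confirmatory      # Table-style LR+ ≥ 5 panels
clusterbn query --evidence ev.tsv        # posterior of the five disorders
clusterbn export --out model.xmlbif      # hand the network to other tools
```

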