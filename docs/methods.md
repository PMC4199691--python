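# Methods

## The mechanism model

All etiologies are expressed as relative survivals of the male path, with
daughters as the reference class (survival 1). For a given cross, the
probability that a zygote is female at syngamy is

    phi = a + (1 − a) · 0.5 / (0.5 + 0.5·s_Y)

where `s_Y` is the survival/functionality of Y-bearing sperm from a
driver-carrying, drive-expressing sire and `a` is the asexual-daughter
fraction of an endosymbiont-infected dam. Male zygotes then survive to the
embryo census with probability `s_son_embryo` (paternal effect) and from the
embryo census to the subadult census with probability
`s_son_post · v_male · sk_son_survival` — the paternal-effect SA-ZD
component, constitutive viability, and endosymbiont son-killing. Expected
percent-female at a census is the pooled ratio of expected counts, mixing
drive-expressing and inert sires by the penetrance.

Assumptions the model makes explicit:

- **Multiplicative composition.** Co-occurring mechanisms multiply on male
  survival; sperm killing acts first, so SD and SA-ZD compose as
  `s_Y · s_son_post` — sequentially, with the zygotic component operating on
  the male pool already diminished by sperm killing. Independence is the
  minimal assumption and reproduces the stage-wise arithmetic of the
  estimators exactly (`expected_subadult_pf(s_Y=a, s_son_post=b)` equals
  `expected_embryo_pf(s_Y=a·b)`, a tested identity).
- **Stage placement.** Endosymbiont killing, viability and the SA-ZD
  component act after the embryo census; `s_son_embryo` is the only
  pre-census mortality channel. This is the configuration the decision key
  is designed around (step 1 compares the embryo and subadult censuses); an
  endosymbiont that kills before embryos are sexed would surface at step 1
  instead and terminate the screen leftward, which is conservative.
- **Penetrance per sire.** A driver-carrying sire either expresses drive
  fully or is inert, drawn once per sire (one sire per vial in all
  designs) — not per gamete.
- **Viability scope.** `v_male` is either recessive to the focal line's
  autosomal background (applies only when the offspring's autosomal
  complement derives entirely from that line) or Y-linked
  (`v_male_scope="y_linked"`, following the Y's line of origin). These are
  the two offspring-genotype killer archetypes the key must discriminate.
- **Suppressors** are named alleles carried on an X, a Y, or the autosomes;
  each restores a declared set of mechanism parameters to 1, acting either
  in the sire (e.g. an autosomal dominant suppressor of sperm killing, or a
  Y that silences the driver in the sire's germline) or in the offspring
  (e.g. a Y that rescues sons from endosymbiont killing). Suppression is
  applied before survivals and is idempotent.
- **Feminization** (`p_fem_cyto/x/y`) reclassifies XY zygotes as phenotypic
  females at census time when sexing is phenotype-based (the default,
  matching protein-marker sexing of embryos) and not at all when
  karyotype-based; mortality follows the karyotype.
- Compound-X dams transmit the double-X to daughters and their Y to sons,
  so sons take their X from the sire — used to move drivers and suppressor
  Y's between backgrounds in the linkage and suppressor stocks.

## The simulator

Per vial: drive expression is drawn once; zygote sexes are binomial at
`phi`; each male-survival stage is a per-individual Bernoulli death whose
vial-level probability is drawn from a beta distribution with the stage's
mean and intra-class correlation `rho` (`rho = 0` collapses to pure binomial
sampling; increasing `rho` inflates between-vial variance without moving the
pooled expectation — a tested property). An optional sex-neutral background
egg-to-subadult survival (default 0.9 in the screen design) gives realistic
hatch rates for the mortality-sufficiency check without affecting any
percent-female expectation, since it multiplies both sexes.

The seven-cross screen design defaults emulate the study scale: 40
single-sire vials per cross culled to 150 eggs each (~5,000–6,000 subadults
per cross, matching the reported 4,307–7,013), embryo sexing and egg counts
only in the focal parental cross, `rho = 0.01` as modest vial
heterogeneity. What the generator does **not** emulate: development-time or
density effects, sperm competition, multi-locus autosomal genetics beyond
suppressor flags and the focal-line dose, or partial suppression gradations.
Passing tests therefore show the *inference logic* is sound under
beta-binomial count noise, not that real fly data are this well behaved.

## Estimators and intervals

- `survival_m_rel_f(E, F) = (100·E/F − E)/(100 − E)` and
  `survival_Y_rel_X(E) = (100·50/E − 50)/50` are exact inverses of
  `%F = 100/(1 + s)`; round-trip identities are tested to machine
  precision. `F < E` is flagged (males survived better than sisters) and
  clamped to 1; `E < 50` (drive against the X) is out of scope and raises.
- Percent-female intervals: intercept-only beta-binomial ML across vials
  (parameterized by mean and intra-class correlation), profile-likelihood
  interval on the mean. A single vial, a pooled estimate at 0 or 1, or a
  fitted correlation below 1e-6 degenerate to the exact Clopper–Pearson
  interval on the pooled counts. Chosen over a quasi-likelihood GLM because
  the design is intercept-only and the profile interval is exact-likelihood;
  no installed package provides this interval directly.
- Survival point estimates are propagated through the key as points; the
  mortality-sufficiency check instead uses interval endpoints (lower bound
  of F against the percent-female cap `100·0.5/s` evaluated at the lower
  bound of total egg-to-subadult survival), mirroring how the two kinds of
  conclusion are drawn.
- The map-distance bound is the one-sided exact (Clopper–Pearson) upper
  limit on the null-class proportion divided by the detectability fraction
  (1/2: only the neither-driver recombinant class is phenotypically
  visible). For 0/354 this gives 1.69 cM. A commonly quoted value for this
  design is 2.0 cM, which the exact method reproduces only at n = 298; the
  exact bound is reported as computed and is the more conservative claim
  (smaller upper bound ⇔ larger n; the discrepancy is documented rather
  than matched). Point estimates at or beyond 50 cM are capped and flagged
  unlinked.

## The decision key

Thresholds are explicit because the key's "≫/≪" are qualitative in the
field's usage:

- **Significance** is confidence-interval exclusion at the estimates' own
  `alpha` (step 1 passes iff the lower bound of F exceeds the upper bound of
  E). CI separation was chosen over a two-proportion test because the
  estimates already carry beta-binomial intervals; it is conservative, and
  the choice is flagged in the report. No multiple-testing correction is
  applied across steps: the key is sequential with early stopping.
- **Magnitude**: ">> 50" additionally requires
  `(pf − 50)/(top − 50) > tau` with `top` the step-2a prediction
  `100/(1 + survival_m_rel_f)` (or F itself at step 3c, which has no
  prediction); "<< F" requires `(F − pf)/(F − 50) > tau`. Default
  `tau = 0.5` operationalizes "most of the maximum possible deviation".
  "≈" is the negation of the corresponding "≪" test, preserving the key's
  binary structure.
- Missing estimates terminate the screen with an `incomplete` verdict
  naming the first missing cross; the trail records every evaluated step
  exactly once.

Known limitations, by construction: the key cannot see SA-ZD when the
control line carries suppressors of the paternal effect (the simulated
false-negative scenario), and with a modest SA-ZD component the suppressed
step-2b deviation can stay below `tau`, so weak suppressed SA-ZD may still
navigate to the base — `tau` trades false negatives against diagnostic
specificity and is deliberately configurable. The false-positive rate of
the full pipeline is dominated by the step-1 CI-separation event under
SD-only truth (≈0.3% per screen at `alpha = 0.05`), measured at ≤5% over
200 simulated screens across the four non-SA-ZD ground truths.

## The linkage assay

Primary families and grandson families are tested by the same one-sided
exact binomial test for female bias. The rescue decision for a
primary-negative sire is Bonferroni-corrected across his grandson families
(per-family level `alpha/k`): at a flat per-family `alpha = 0.05`, ~40% of
truly driver-free sires would be falsely rescued by one of 10 families,
biasing the map-distance point estimate downward by nearly half at
r = 0.2. Rescue power for true carriers is unaffected (a drive-expressing
grandson family's p-value is many orders of magnitude below the corrected
level). Sires with empty families are excluded from the informative count;
a configurable post-hoc size filter (`min_grandson_offspring`, default 0)
mirrors the practice of scoring only large grandson families. Simulator
defaults: 400 sires × 2 dams, 80 offspring per dam, driver strengths
`s_Y = 0.307` (focal) and `0.218` (reference driver, multiplicative when
co-carried), penetrance 0.9.

## Problem sizes and determinism

Unit and property tests run at 10–700 vials per call; the acceptance script
simulates 800 vials × 150 eggs (120,000 zygotes) per stage at `rho = 0` and
evaluates the closed-form targets exactly. All randomness flows through
numpy Generators seeded from the caller; identical seeds reproduce
bit-identical brood tables and artifacts (hypothesis property tests run
derandomized).
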