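# sazdscreen

A female-biased brood sex ratio in an XY species can have many causes:
X-linked meiotic drive (segregation distortion, SD) that kills Y-bearing
sperm, maternally transmitted endosymbionts that kill sons (SK), sex-biased
viability genes, feminization of XY zygotes, asexual production of
daughters — or **sexually antagonistic zygotic drive (SA-ZD)**: a paternal
effect of the sire's X chromosome that kills his sons *after*
fertilization. SA-ZD is easy to confuse with every one of the others, and
no single cross distinguishes it. `sazdscreen` implements the
process-of-elimination screen that does, for geneticists working with
sex-ratio-distorting lines (the motivating system is an X-linked driver in
*Drosophila simulans*).

## What the package computes

**Survival estimators.** With `E` and `F` the percent-female among embryos
and subadults of the focal (SR × SR) cross, the post-embryonic survival of
males relative to their sisters is

    survival_m_rel_f = (100·E/F − E) / (100 − E)

and the survival of Y- relative to X-bearing sperm is

    survival_Y_rel_X = (100·50/E − 50) / 50.

Both invert the forward model `%F = 100/(1 + s)`. Percent-female
confidence intervals treat the vial as the replicate and assume
beta-binomial errors (maximum likelihood with a profile-likelihood
interval, degenerating to exact Clopper–Pearson for a single vial).

**The decision key.** Six ordered comparisons over seven crosses — embryo
vs subadult sex ratio in the focal line, an even-line control, both
reciprocal F1 crosses, and three backcrosses with F1 sires — eliminate SK,
recessive autosomal killers, Y-suppressed SK, latent distorters in the
control line, and Y-linked/epistatic killing in turn. Reaching the base of
the key demonstrates that some of the post-embryonic male mortality is
SA-ZD. "Much greater/less" comparisons require both confidence-interval
separation and that more than a fraction `tau` (default 0.5) of the maximum
possible deviation is realized.

**The linkage assay.** For two X-linked drivers in repulsion, the fraction
of G2 sires carrying neither driver estimates half the recombination
fraction; sires with non-significant families are rescued through a
grandson follow-up (a heterozygous daughter transmits a driver to each
grandson with probability 1/2, so 10 grandsons miss it with probability
2⁻¹⁰ < 0.001). An exact one-sided binomial bound on the null-class
proportion yields a map-distance upper bound in centimorgans.

**The simulator.** A seeded forward simulator generates per-vial brood
counts for arbitrary crosses and for the full seven-cross and linkage
designs under every etiology above (with vial-level beta-binomial
overdispersion and incomplete driver penetrance), so the screen's claimed
behavior — in particular that it produces essentially no SA-ZD false
positives — is verifiable without fly data.

## Worked example

```python
from sazdscreen import survival_m_rel_f, survival_Y_rel_X, predicted_pf

E, F = 76.5, 83.9   # percent-female in embryos and subadults, focal cross
s_mf = survival_m_rel_f(E, F)
s_yx = survival_Y_rel_X(E)
print(f"extra post-embryonic male mortality: {100 * (1 - s_mf):.1f}%")
print(f"extra Y-sperm mortality/incapacitation: {100 * (1 - s_yx):.1f}%")
print(f"ratio: {(1 - s_mf) / (1 - s_yx):.2f}")
print(f"%F predicted from male survival alone: {predicted_pf(s_mf):.1f}")
```

prints

```
extra post-embryonic male mortality: 37.5%
extra Y-sperm mortality/incapacitation: 69.3%
ratio: 0.54
%F predicted from male survival alone: 61.6
```

i.e. the zygotic (post-embryonic) component is about half as strong a male
mortality agent as the gametic one, and on its own would produce only a
~62%-female brood — the embryo bias requires sperm killing.

End-to-end from the shell:

```sh
sazdscreen simulate --scenario sa-zd --seed 5 --out-dir run/
sazdscreen screen --broods run/broods.tsv --out run/verdict.json
# ... step-by-step trail, then:
# VERDICT: SA-ZD-present
sazdscreen linkage --seed 2 --r 0.0 --n-sires 354
# map distance: point 0.00 cM, 95% upper bound 1.69 cM
```

The same pipeline is available as library calls
(`simulate_screen_dataset` → `screen_inputs_from_broods` → `run_screen`).

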