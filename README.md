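# neoxy

Transmission genetics of the neo-XY sex chromosome system of the mandarin
vole, *Lasiopodomys mandarinus vinogradovi*.

This subspecies segregates four sex-chromosome karyomorphs built from two
autosome-to-sex-chromosome translocations: KI males
(neo-X1/neo-X3/neo-X3/neo-Y, 2n = 48) and three female forms — KII
(neo-X1/neo-X2/neo-X3), KIII (neo-X2/neo-X3/neo-Y) and the rare KIV
(neo-X1/neo-X1/neo-X3/neo-X3). Under the textbook rule "neo-Y present ⇒
male", KIII animals should be male and KIII dams should produce only KII
daughters; the breeding data contradict both predictions. `neoxy` packages
the quantitative machinery needed to make — and test — that argument:

* **karyomorph algebra** (`neoxy.karyotype`): sex-chromosome complements
  as multisets of the four elements, karyomorph classification,
  X-euchromatin/autosomal-block dosage, genotype→sex maps for the
  standard rule and three XY-female mechanisms (neo-X2 suppressor of a
  neo-Y trigger; neo-X1 complement of a neo-Y trigger; neo-X1-borne
  trigger inactive in double dose), and zygote viability models;
* **cross models** (`neoxy.meiosis`): balanced trivalent segregation in
  dams, fertilization-stage sperm selection (w_Y : w_X1 per dam
  karyomorph), and exact offspring distributions for every dam × KI cross;
* **exact statistics** (`neoxy.exact_stats`): Pearson goodness-of-fit
  (no continuity correction), Fisher 2×2 and r×c tests by complete
  enumeration, exact binomial, two-sample t;
* **likelihood inference** (`neoxy.inference`): binomial × multinomial
  likelihood of progeny counts, deterministic grid-refinement MLE with
  profile-likelihood intervals, AIC hypothesis ranking;
* **population dynamics** (`neoxy.popsim`): deterministic and seeded
  stochastic recursions of the karyomorph frequencies, equilibria;
* **synthetic colonies** (`neoxy.synthetic`): a generator matching the
  real breeding design (38 dams, ≈327 offspring, a third of daughters
  karyotyped) for parameter-recovery experiments;
* **I/O and CLI** (`neoxy.io`, `neoxy.cli`): progeny TSV format, the
  published count tables as packaged fixtures, and a `neoxy` command with
  `cross`, `test`, `fit`, `compare`, `simulate` and `popsim` subcommands.

## The model in brief

A dam's trivalent resolves by alternate segregation into two balanced
gamete classes (KII: {X1, X3} vs {X2}; KIII: {X2} vs {X3, Y}; KIV: {X1,
X3} only), and KI sires make {X1, X3} and {Y, X3} sperm. For a dam of
karyomorph *d*, Y-bearing sperm succeed with relative weight
*w*<sub>Y</sub>(*d*) against *w*<sub>X1</sub>(*d*) = 1. Zygotes without
X euchromatin (neo-Y/neo-Y) die; neo-X1/neo-X1 zygotes survive with
relative viability *v*<sub>X1X1</sub>. With defaults (*w* = 1, *v* = 1)
a KII × KI cross yields KIV♀ : KI♂ : KII♀ : KIII♀ at 25% each, and a
KIII × KI cross yields KII♀ : KIII♀ : KI♂ at 1/3 each after the lethal
quarter is removed. The observed counts are scored by

log L(θ) = Σ<sub>d</sub> [ log Binom(sons<sub>d</sub> | n<sub>d</sub>, p<sub>♂</sub>(d; θ)) + log Multinom(karyotyped daughters<sub>d</sub> | π(d; θ)) ]

and hypotheses are ranked by AIC.

## Worked example

```python
import neoxy as nx
from neoxy import Hypothesis, Karyomorph

counts = nx.observed_progeny_counts()          # packaged colony counts
print(nx.compare_hypotheses(counts, list(Hypothesis)))
```

```
hypothesis  log_likelihood  n_params       aic  rejected                               note
    mech_a      -37.133133         0 74.266266     False
    mech_b      -37.133133         0 74.266266     False
    mech_c      -37.133133         0 74.266266     False
  standard            -inf         0       inf      True rejected by impossible observation
```

The standard rule is impossible on the data — it gives the 6 KIII
daughters observed from KIII dams probability zero — while the three
XY-female mechanisms fit equally well (they induce the same sex map on
every viable genotype these crosses can produce, so the data cannot
separate them). Fitting the sperm-selection weight for KII dams:

```python
fit = nx.fit_parameters(counts, Hypothesis.MECH_A, ["wY_KII"])
print(fit.estimates, fit.intervals)
# {'wY_KII': 3.51}  {'wY_KII': (2.09, 6.46)}
```

Y-bearing sperm are favored roughly 3.5 : 1 in KII dams — the excess of
KI sons and KIII daughters in their litters. Finally, the maintenance
question: with full KIV viability the deterministic recursion drives the
double-X1 karyomorph to fixation, but

```python
eq, ok, _ = nx.deterministic_equilibrium(params=nx.CrossParameters(v_x1x1=0.2))
# {KII: 0.4706, KIII: 0.4706, KIV: 0.0588}
```

a double-X1 viability of 0.2 stabilizes the female pool at
47.1 : 47.1 : 5.9% — essentially the frequencies seen among 163 wild and
colony females (47 : 47 : 6%).

The same analyses are available from the shell, e.g.

```sh
neoxy cross --dam KII --hypothesis mech_a
neoxy test --method fisher --input daughters.tsv
neoxy simulate --seed 42 --out progeny.tsv
neoxy compare --input progeny.tsv
```

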