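# Methods

## The genetic system being modeled

Four chromosomes participate in the mandarin vole sex complex. Two carry
X euchromatin: the large metacentric neo-X1 (X material plus an
autosomal block homologous to field-vole chromosome MAG13, called A1
here) and the submetacentric neo-X2 (X material plus a block homologous
to MAG17/19, called A2). Two carry none: the small acrocentric neo-X3
(an A2 homolog) and the putative neo-Y (an A1 homolog whose apparent
X-signal in hybridization is repetitive sequence — chromosome sequencing
finds only MAG13-block synteny). Dosage accounting therefore counts the
neo-Y as zero X. The four observed karyomorphs are KI males
(X1/X3/X3/Y, 2n = 48), KII females (X1/X2/X3, 2n = 47), KIII females
(X2/X3/Y, 2n = 47) and KIV females (X1/X1/X3/X3, 2n = 48). KIII females
are thus X-monosomic and Y-bearing — the crux of the sex-determination
question.

## Genotype → sex maps

Four rules are implemented as total functions on complements:

* `STANDARD` — male iff neo-Y present;
* `MECH_A` — an epistatic locus on neo-X2 suppresses a dominant male
  trigger on neo-Y: male iff Y present and X2 absent;
* `MECH_B` — a locus on neo-X1 complements the neo-Y trigger (the
  wood-lemming-like deletion scenario): male iff Y and X1 both present;
* `MECH_C` — the trigger sits on neo-X1 itself and is inactive in double
  dose or suppressed by neo-X2: male iff exactly one X1 and no X2.

All three XY-female mechanisms assign KI male and KII/KIII/KIV female;
they disagree with each other only on genotypes that are lethal (e.g.
neo-Y/neo-Y) or unreachable from the implemented crosses, which is why
the likelihood cannot separate them and the comparison table shows them
tied. `STANDARD` assigns male to KIII — the discriminating disagreement.

Viability: under the XY-female regime the single lethal class is a
zygote without X euchromatin (neither X1 nor X2). Under the standard
regime the lethal set is the one that rule needs to explain the missing
karyomorphs: no-X zygotes, X2+Y zygotes, and monosomic "/0" zygotes
(X1/0, Y/0). Note the standard lethal set is *defined* on zygotes; a
KIII dam (X2/0 in standard bookkeeping) is treated as alive because the
regime tracks her gametes, not her own viability — the internal tension
of that hypothesis is the point, not a bug. A separate weight
`v_x1x1 ∈ [0, 1]` (default 1) scales the viability of X1/X1 zygotes in
both regimes.

## Gametes and crosses

Female trivalents resolve by strictly alternate (balanced) segregation
into exactly two gamete classes: KII dams make {X1, X3} (probability
`s_kii`, default 0.5) or {X2}; KIII dams make {X2} (`s_kiii`) or
{X3, Y}; KIV dams make {X1, X3} only. This is the unique two-class rule
that regenerates all four observed offspring karyomorphs from a KI sire
(gametes {X1, X3} and {Y, X3}) without invoking nondisjunction, which
the XY-female reading explicitly avoids. Under the standard regime the
small acrocentrics are unidentifiable and gametes carry only the
recognized sex chromosomes, with nullo gametes written "0".

Transmission-ratio distortion is applied at fertilization, not in sire
meiosis: sperm classes are reweighted `(w_x1[dam], w_y[dam])`,
conditioned on the dam's karyomorph, because the data pattern is that
the same male's Y-sperm succeed differently in different female
karyomorphs. Only the ratio `w_y / w_x1` is identifiable; the pair is
kept so the rescaling invariance is a testable property. Zygotes are
multiset unions of gametes; the offspring table carries raw
probabilities (summing to 1), viability weights, and probabilities
renormalized over live classes. The autosomal background (22 pairs) is
ignored throughout.

The cross engine reports, per dam × KI cross: expected son fraction
among live offspring, lethal-zygote fraction (raw mass), and the
karyomorph distribution of live daughters. Defaults reproduce the
analytic benchmarks: KII × KI → four classes at 25%; KIII × KI → 1/3
sons; standard-regime lethal fractions 3/4 (KIII dams) and 1/4 (KII
dams).

## Likelihood and fitting

Counts per dam karyomorph are (sons, daughters) for all sexed offspring
and karyomorph counts for a karyotyped subsample of daughters. Because
only a subsample (64 of ~196 daughters in the real colony) was
karyotyped, the likelihood factorizes as a binomial for the son count
times a multinomial for the karyotyped daughters conditional on being
karyotyped; the pieces are summed over dam karyomorphs. An observed
class with model probability zero yields −∞ — the computational form of
"the standard rule predicts only KII daughters from KIII dams".

Free parameters (any subset of `wY_KII/KIII/KIV`, `v_x1x1`, `s_kii`,
`s_kiii`) are fitted by deterministic successive grid refinement: sperm
weights log-spaced on [1e−3, 1e3], unit-interval parameters linear; 9
points per axis, 6 shrink iterations. Determinism was preferred over
speed at this problem size (each likelihood evaluation is three 4–8-row
cross tables). Flat likelihoods are flagged in metadata
(`identifiable: False`), not raised. Intervals are profile-likelihood at
the χ²₁ 95% cutoff (drop of 1.921): a coarse scan over the bounds (41
points plus the MLE), re-optimizing the other free parameters at each
point, with the two crossing edges sharpened by 20 bisection steps.
Hypotheses are ranked by AIC (= 2k − 2 log L with k the number of
fitted parameters; 0 when defaults are used); −∞ rows are flagged
"rejected by impossible observation" and sorted last. AIC was chosen
because the mechanism hypotheses are not nested in the standard rule;
for nested comparisons the log-likelihoods themselves are in the table.

## Exact tests

All built from first principles because the published analysis depends
on their exact form: Pearson goodness-of-fit without continuity
correction (recomputing the printed sex-ratio statistics gives 11.28 vs
printed 11.2 and 5.62 vs 5.66 — the uncorrected statistic is clearly
what was used, and is treated as authoritative); Fisher 2×2 and r×c by
complete enumeration of margin-preserving tables under the
(multivariate) hypergeometric, with probabilities accumulated in log
space (safe at n ≈ 300) and a relative tie tolerance of 1e−7 in the
probability-ordering two-sided rule; exact binomial by the same
ordering rule; pooled-Student and Welch t. The r×c enumerator refuses
more than 10⁷ candidate tables and offers a seeded permutation Monte
Carlo fallback instead. p-values within 1e−9 of 1 are snapped to 1
(complete-support sums). The published p = 0.070 for the 7/7 all-son
KIV litter is not reproducible as an exact binomial (2 × 0.5⁷ =
0.015625) and the construction behind it is unstated; the package
reports its own exact value.

## Population dynamics

Non-overlapping generations; every dam mates a KI male (the only live
male genotype under XY-female rules — asserted each generation); equal
male mating success; a dam's expected output is proportional to her
cross's viable-zygote mass times an optional per-karyomorph fecundity
multiplier (KIV subfertility — 0 of 4 KIV dams bred in the cohort —
is expressible there rather than as a separate mechanism). The
deterministic mode iterates the expectation map on female karyomorph
frequencies (the fixed-point solver precomputes the daughter-mass
matrix once and iterates a 3-vector, so bisection sweeps over
parameters are cheap). The stochastic mode draws Poisson litters and
multinomial class counts from a single `numpy` Generator; one integer
seed fully determines a run, and an optional population cap subsamples
offspring by multivariate hypergeometric draw. Means over seeded
replicates of one stochastic generation agree with the deterministic
map within Monte-Carlo error (tested at 1000 replicates).

Key dynamical facts the tests pin down: with defaults the KIV frequency
is non-decreasing and approaches fixation (double-X1 dams waste no
zygotes and produce only KIV daughters), so the observed ~6% KIV
requires selection; `v_x1x1 = 0.2` gives a stable interior equilibrium
at 47.1 : 47.1 : 5.9% (KII : KIII : KIV), essentially the observed
47 : 47 : 6; and any population with KII or KIII dams has a
female-biased birth sex ratio at default weights.

## Synthetic colonies

The generator emulates the real breeding design: dams per karyomorph
(default 17/18/3), negative-binomial offspring totals per dam (mean 8.6
≈ 327/38; dispersion 20 — mild overdispersion, since per-litter data
are not printed), offspring classes i.i.d. from the cross model's
live-offspring distribution, and a per-dam simple random subsample of
daughters karyotyped (default fraction 0.33 ≈ 64/196). What it does not
emulate: litter structure and within-litter correlation, parental age
or environment effects, sex-differential postnatal survival, and any
misclassification in sexing or karyotyping. Passing recovery tests
therefore show the inference machinery is correct and well-calibrated
for the stated sampling model, not that real colony data are free of
those complications.

## Numerical choices and limitations

Gamete/zygote probabilities are exact rational arithmetic in floating
point (sums checked to 1e−12). Complement strings serialize in the
fixed element order X1 < X2 < X3 < Y. Degenerate inputs are policy, not
errors, where a convention exists (zero-margin Fisher tables → p = 1;
empty populations → flagged extinct; empty count sets → log L = 0) and
validation errors where none does (copy number > 2, probabilities
outside [0, 1], karyotyped counts exceeding daughters). Problem sizes
in the tests — 250 dams per karyomorph (~2000 offspring per cross) for
recovery, 1000 replicates for stochastic/deterministic agreement, 200
generations for trajectories — were chosen as the smallest sizes at
which the targeted effects are decisively resolved.

Out of scope by design: recombination within the neo-sex chromosomes
and pachytene pairing geometry; molecular identity of the trigger and
suppressor loci; dosage compensation (unexplored in this species);
evolution of the distortion weights themselves; and the sequencing
pipeline behind the element composition, which enters only as the fixed
element table. One genuine ambiguity is preserved rather than resolved:
the all-son KIV litters can be explained either by sperm selection
(`wY_KIV`) or by reduced double-X1 zygote viability (`v_x1x1`); both
parameters are exposed so either account can be fitted, and on the
printed counts they are confounded.
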