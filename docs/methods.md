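# Methods

## Model and procedure

### Dated species tree

All dating happens on a rooted ultrametric species tree with node ages in
million years (MY), leaves at age 0. The default is an 8-taxon vertebrate
tree (*H. sapiens* focal, *P. troglodytes*, *M. musculus*, *R. norvegicus*,
*B. taurus*, *G. gallus*, *X. tropicalis*, *D. rerio*) with TimeTree-style
divergence times: vertebrate root 435 MY, amphibian split 352 MY, amniote
split 312 MY, mammal MRCA 96 MY, primate–rodent split 90 MY, mouse–rat
20.9 MY, human–chimp 6.7 MY. Trees are read from Newick with branch
lengths in MY; ultrametricity is enforced within 1e-6 MY and violations
are reported naming the offending leaf. When an ortholog family lacks some
species the tree is restricted to the species present, suppressing unary
nodes and preserving node ages, so branch durations keep their absolute
meaning.

### Ancestral reconstruction

Ancestral states are reconstructed per alignment column by unweighted
parsimony. We compute, for every node, the set of states attainable in at
least one minimum-mutation labelling (the MPR final sets of Fitch
parsimony) with a two-pass unit-cost dynamic program: a postorder pass
accumulates subtree costs per state, a preorder pass accumulates
outside-subtree costs, and a node's final set is the states whose total
equals the global minimum. This is exact on arbitrary rooted trees,
including the multifurcation-free restrictions above, and is verified in
the test suite against exhaustive enumeration of all internal labelings on
every rooted binary shape with up to 6 leaves.

Choices worth stating:

* **Parsimony, not likelihood.** A maximum-likelihood reconstruction with
  branch lengths would weight changes by time; parsimony is deterministic,
  dependency-free, and sufficient for dating the presence/absence of an
  acceptor residue. The method tag is stored per reconstruction so an ML
  backend could be added; downstream code depends only on state sets.
* **Gap is a 21st state.** A gap→serine event is a genuine appearance.
  Treating gaps as missing data would let absent sequence vote for
  ancestral presence and inflate ages.
* **Unit cost for all state pairs.** No exchangeability matrix; a
  documented simplification.

### Emergence dating and age groups

A site's acceptor is its own residue type: a phosphoserine tracks serine
only, and an ancestral S→T switch interrupts presence (a pooled-S/T mode is
a flag). A node "has" the acceptor when the residue is in its final state
set; ambiguity therefore counts as presence, which makes dating
conservative toward older ages. The emergence node is the oldest node of
the maximal *uninterrupted* acceptor stretch on the root→focal-leaf path
ending at the focal leaf, so a gain–loss–regain column dates from the most
recent regain; an `earliest` mode reporting the oldest appearance at all is
available behind a flag. Age groups:

* **old** — emergence age ≥ 435 MY *and* (strict mode, default) the
  acceptor present in every non-gap extant leaf;
* **young** — emergence age < 96 MY (presence at the mammal-MRCA node
  itself implies a gain on the branch into it, hence median);
* **median** — everything else. The three bins partition all dated sites.

Families enter dating only with strictly more than 4 ortholog sequences.
The ancestral origin of a site is the final state of the emergence node's
parent: a singleton set gives that residue, a tie gives `ambiguous`, and
root emergence gives `unknown` (old-group origins are unknowable by
construction). Disorder scores in [0, 1] classify a site as disordered
when strictly above 0.5.

### Origin enrichment

Controls are S/T/Y sites not known to be phosphorylated, from the same
proteins as the phosphosites, dated with the same pipeline and restricted
to the median and young groups; sites flagged in the PTM-database analogue
or with predicted kinase score > 2 are excluded as likely unannotated
phosphosites. Each of B = 1000 bootstrap rounds draws, with replacement,
exactly the phosphosite set's per-stratum counts from the control pool,
stratified on structure class and (by default) residue type, so every
draw's disordered:ordered composition matches the phosphosite set's
exactly. Ambiguous/unknown origins are excluded before fractions are
computed. Per amino acid: ratio = observed fraction / bootstrap-mean
control fraction; one-sided empirical p with +1 correction,
`p = (1 + #{f_b ≥ f_obs}) / (B + 1)`. Depletion shows as ratio < 1 without
a second test; no multiple-testing correction by default (Bonferroni over
20 amino acids behind a flag).

### Cohort statistics

Pearson chi-squared without Yates correction throughout; when an expected
count falls below 1 an exact conditional test on the same margins
(multivariate hypergeometric enumeration) is substituted and noted.
Fisher's exact test (two-sided) for the young-group BFM/VFM functionality
2×2. The evolutionary-rate proxy for a column is the fraction of non-gap
ortholog residues differing from the focal residue — monotone in
substitution count and sufficient for directional module comparisons; it
is a proxy, not a rate estimator. The Wilcoxon rank-sum test uses
mid-ranks for ties, exact enumeration of all arrangements when both
samples have ≤ 8 observations, and otherwise a normal approximation with
tie correction and continuity correction; all-tied input returns p = 1
with a warning.

### Tissue quantification

Per site: maximum phosphorylation level across the nine tissues and
breadth = number of tissues with level > 0 (the missingness convention of
typical atlases). Young-vs-old comparisons use the rank-sum test, with
protein abundance as a negative control. The covariate ANOVA fits
`breadth ~ protein_breadth + C(age_group)` by sequential (type-I) sums of
squares, covariate first, and reports the F-test of the group term; a
constant covariate reduces it to one-way ANOVA. Stepwise selection is
forward, on an OLS of the ordinal age coding (young 0, median 1, old 2),
entering the predictor with the best AIC improvement until none improves.
"Low" in the low-low analysis means the pooled empirical CDF value is at
most the configured quantile (bottom tertile by default) for both level and
breadth; the ECDF definition makes a quantile of 0 an empty set, exercising
the documented skip path.

## Synthetic data generator

The generator is the package's test harness and defines its study
conditions. Root sequences are uniform over the 20 residues and evolve
down the tree with independent per-site, per-branch substitution
probability 0.05 (uniform target residue, no indels, no rate heterogeneity
beyond a per-module multiplier). Planted sites force the root→focal path:
the drawn origin residue above the gain node, the acceptor from the gain
node down; with probability 0.9 (`conservation_p`) all descendants of the
gain node retain the acceptor, and old-group plants are always fully
conserved so their planted labels satisfy the old definition. Gains are
restricted to the root→focal path so every planted site is datable, and
every plant keeps a truth record (gain branch, interval, origin, group).

Default conditions, chosen once:

| knob | default | rationale |
| --- | --- | --- |
| group mixture (phospho) | 1/3 old, 1/3 median, 1/3 young | balanced power across bins |
| control group mixture | 1/2 median, 1/2 young | old-group origins are unusable as controls |
| acceptor mix | S 0.75, T 0.20, Y 0.05 | serine-dominated catalogues |
| phospho origin weights | median D4/E4/K2, young D2/E2/K2 over uniform | plants the phosphomimetic D/E excess, stronger in median |
| control origin weights | uniform | neutral background |
| disordered fraction | 0.75 | phosphosites concentrate in disorder |
| functional flag p | 0.30 / 0.15 / 0.05 (old/median/young) | functionality rises with age |
| polymorphic flag p | 0.05 / 0.10 / 0.20 | polymorphism falls with age |
| module mixture; VFM rate | 50/50; 0.5× substitution | VFM proteins more constrained |
| quant level μ (log) | 1.0 / 0.65 / 0.3 | old ≈ 2× young median level |
| quant breadth α (logit) | 0.8 / 0.4 / 0.0 | breadth rises with age |
| latent coupling β, γ, σ | 1.0, 0.7, 0.6 | calibrated once to pooled level–breadth r ≈ 0.46, then frozen |

Quantification draws a per-site latent severity z ~ N(0,1) driving both
breadth ~ Binomial(9, logistic(α_g + βz)) and max level =
exp(μ_g + γz + σε); the maximum is assigned to one detected tissue and the
remaining detected tissues get Uniform(0, max) levels, so max level is 0
iff breadth is 0 and zero coupling makes level independent of breadth
among detected sites. Protein abundance is lognormal, independent of age;
protein breadth is weakly coupled to z. A correlation target above 0.95 is
rejected as infeasible for a 0–9 breadth.

What the generator does **not** emulate: indels and alignment error,
kinase-motif sequence context, site-rate heterogeneity, phylogenetic
correlation of annotations, tissue-specific biology, and any BFM/VFM
difference in age-group composition (the module knob affects substitution
rate only). Passing tests therefore validate the pipeline's inferential
machinery under known truth, not the biological conclusions on real data;
module-by-age comparisons are null under default conditions, and the
module conservation contrast is strongest on background (non-planted)
columns because planted acceptors are conservation-enforced.

## Numerical and design notes

* All randomness flows from one master seed through per-stage
  `SeedSequence`-derived streams; identical seeds reproduce every table
  byte-for-byte (manifest paths are stored relative to the run directory).
* Ortholog-count filter is strict (> 4); kinase-score filter is strict
  (> 2 excluded); disorder threshold is strict (> 0.5).
* The bootstrap p-value's +1 correction keeps p in (0, 1]; the enrichment
  ratio's denominator is the bootstrap-mean control fraction, with ∞
  reported when the pool never produces an origin the phosphosites show.
* Bootstrap calibration is a large-pool property: resampling treats the
  control pool as the population, so with a pool of size m the effective
  variance of `f_obs − mean(f_b)` is inflated by (1 + n/m) and the test is
  mildly anti-conservative for pools comparable to the phosphosite set
  (about 0.06 at m = 4n instead of 0.05). The calibration test therefore
  uses m = 20n; real analyses should prefer the largest available pool.
* Forward-AIC selection admits a null predictor with probability
  P(χ²₁ > 2) ≈ 0.157 per candidate; that spurious-retention rate is
  inherent to the AIC criterion and reflected in the tests.
* Exact conditional contingency tests are enumerated only for table totals
  ≤ 400; beyond that the chi-squared approximation is reliable anyway.
* Problem sizes in the test suite (e.g. 1000 planted sites for recovery,
  200 replicates for calibration checks, n = 2000 for correlation
  recovery) were chosen to give the quoted binomial/Kolmogorov bounds
  adequate resolution while keeping a laptop-scale runtime.

## Known limitations

* Parsimony underestimates changes on long branches; ages are upper bounds
  on phosphorylation age in any case, since acceptor presence precedes
  phosphorylation.
* The conservation proxy ignores phylogeny (each ortholog counts equally).
* The control pool is matched on protein, age group, structure and residue
  type, not on sequence context or kinase motif.
* Stepwise selection on an ordinal age coding is the simplest model of
  "contribution compensated by the other predictor"; a logistic
  young-vs-old variant is a flag.
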