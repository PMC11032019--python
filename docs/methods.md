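# Methods

This note documents the statistical model, the defaults and the design
choices behind `omeconcord`, in the order the pipeline runs them.

## Study design assumed

Two tissues (leaf, root) x two conditions (nutrient-deficient, replete),
five biological replicates per tissue x condition. Three omes enter the
analysis at different points:

* **transcriptome** — differential tables arrive precomputed from an
  external count-based DE pipeline (the DE model itself is out of scope);
  they are only thresholded here, at adjusted p < 0.05;
* **proteome** — label-free peptide ion-current abundances on the log2
  scale, carried through normalization, roll-up and Welch t tests with a
  raw p < 0.01 retention rule;
* **metabolome** — a sample x metabolite abundance matrix with missing
  values, carried through detection filtering, mean-centering and Welch
  t tests with BH adjustment at adjusted p < 0.05.

All thresholds are strict inequalities. No fold-change cutoff is applied
anywhere. Missing values are first-class (never imputed as zero); every
statistic defines its own missing-data handling. Feature identifiers are
exact, case-sensitive strings.

## Preprocessing

**Metabolome.** Samples detecting fewer than 100 metabolites (strictly
fewer; a sample at exactly 100 is kept) are excluded before any statistic
is computed — such samples indicate failed runs rather than biology. Each
metabolite is then centered by subtracting its mean over non-missing
values; features with no observed value are dropped with a log entry.

**Proteome.** Log2 abundances are normalized per sample by *central
tendency*: each sample's median over non-missing values is subtracted and
the grand median of the original per-sample medians is added back, so all
samples share a median and the global location is untouched. The median
(not the mean) is used: it is robust to missingness and is the
conventional reading of central-tendency normalization in label-free
proteomics; the choice is recorded in the run metadata. The operation is
idempotent and removes any per-sample additive offset exactly (up to one
global constant), regardless of the missingness pattern, because the
per-sample median absorbs the offset.

**Peptide-to-protein roll-up** follows the Rrollup family of algorithms:
per protein, the *reference peptide* is the one observed in the most
samples, ties broken by higher median abundance and then lexicographic
peptide id (determinism); every other peptide is shifted by the median of
(reference − peptide) over samples where both are observed, provided at
least `min_overlap = 3` shared samples (otherwise the peptide enters
unshifted); the protein abundance per sample is the median of the shifted
peptide values present there. The reference tie-breaks and the overlap
default are this package's choices — the algorithm family fixes only the
median-scaling idea. Single-peptide proteins are retained (no one-hit
filter at this stage). The roll-up is invariant to peptide input order and
equivariant to constant shifts.

## Differential calling

The two-group test is Welch's unequal-variance t (Satterthwaite df); a
pooled-variance alternative is available behind `--pooled-t`. Welch is
used for the metabolome as well as the proteome, for consistency and
robustness to heteroscedasticity; "two-tailed t test" does not pin the
variance assumption, so the choice is declared here. The metabolome log2
fold change is mean(deficient) − mean(replete) on the working
(post-normalization) scale, recorded in the run metadata.

Degenerate contrasts: both groups constant and equal gives t = 0, p = 1;
both constant but different is untestable by t and the feature is skipped
with a log entry. Features with fewer than two non-missing values in
either group are likewise skipped. The BH family is exactly the set of
features actually tested within one tissue x ome — skipped features are
outside it.

## Enrichment model

Annotation terms are flat sets as annotated (no ontology propagation; if a
user wants ancestor-propagated GO sets they must be propagated before
input). The universe is, by default, the union of all annotated features;
an explicit universe file can widen it (e.g. to a whole genome including
unannotated genes). `n` counts SDE features *present in the universe*, not
all SDE features, so k/n and K/N are drawn from the same background.

* Per-tissue: `p = P(X >= k)`, `X ~ Hypergeom(N, K, n)`, exact (scipy's
  survival function; verified against rational-arithmetic enumeration to
  ~1e-16). Terms with fewer than `min_term_size = 2` SDE members are not
  tested. BH families are one per (tissue, namespace).
* Directionality: `p_pos = P(X <= k_up)`, `X ~ Binomial(n_dir, pi)`, where
  `n_dir` counts the term's SDE members that carry a direction (features
  with log2FC exactly 0 carry none) and `pi` is the background up-fraction
  among the tissue's directed SDE features. The lower-tail convention lets
  the printed cutoffs act directly: `p_pos > 0.95` is an up call,
  `p_pos < 0.05` a down call. `pi` is estimated from the SDE background by
  default; `--pi 0.5` fixes it, which is advisable when the SDE set is
  small (tens of features) or itself dominated by the terms under test.
* `p_both`: the term's hypergeometric enrichment within the intersection
  of the two tissues' SDE sets, against the same universe — the most
  direct formalization of "differential in both tissues at the same
  time". An alternative (Fisher combination of the two marginal p-values)
  sits behind `--p-both-method fisher`; it answers a weaker question
  (enrichment *somewhere* in both margins) and is not the default. With an
  empty intersection every `p_both` is 1 (warned). BH is applied over all
  reported terms per namespace.
* `p_same`: when both tissues' direction calls agree, the product of the
  two concordant binomial tail probabilities (upper tails for both-up,
  lower for both-down), else 1. Under independence of tissues this is the
  probability of both tissues being at least as concordantly extreme as
  observed; under positive dependence between tissues it is
  anti-conservative, which is why it is gated behind the `p_both`
  significance test rather than used alone.
* Final label: `both-up` / `both-down` require `p_both_adj < 0.05`,
  agreeing calls and `p_same < 0.05`; `any-direction` marks joint
  enrichment without directional agreement; everything else is `none`,
  with tissue-specific significance readable from the per-tissue columns.

**Discreteness of the direction calls.** The strict `>0.95` / `<0.05`
cutoffs act on a discrete CDF, so globally flipping every fold change maps
up calls to down calls only up to the binomial point mass at `k_up`: a
`p_pos` lying within one point mass of a cutoff can lose its call under
the flip. All enrichment p-values are exactly invariant under the flip;
in the validation study the planted-term recovery rate is the same (>= 90%)
in both orientations, with roughly one boundary replicate per hundred.

## Cross-tissue summaries

Feature-level Venn counts are computed for three classes — all SDE, up,
down — where a shared up (down) feature must be up (down) in *both*
tissues; an up/down-discordant feature contributes to the "all" overlap
only. The shared fraction's denominator is the union of the class across
tissues by default (`--denominator` offers per-tissue alternatives); the
choice is recorded in output metadata.

Term-level Venn counts populate the "both" cell from the joint statistic
(`p_both_adj < 0.05`; for the up/down classes, a concordant call), never
from naive intersection of the marginal significant sets. Because that
cell is not necessarily a subset of a tissue's marginal set, each tissue's
total is defined as (marginally significant terms) ∪ (both-cell terms),
which preserves the additive identity total = unique + shared.

## Synthetic data

The generators are pure functions of (parameters, seed) and return a truth
ledger of everything planted.

* **Universe**: 500 features, 40 terms, term sizes log-uniform in 5–50 by
  default — term-size dispersion matching flat GO/KEGG slices at desk
  scale; membership sampled without replacement per term.
* **Differential tables**: background features are SDE with probability
  0.1 per tissue and up with probability 0.5; a planted term's members are
  SDE with probability min(1, 0.1 x factor) and up with the planted
  probability, in the designated tissues. Emitted tables carry p_adj 0.001
  (SDE) or 0.5, log2FC ±1 — the generator emits post-DE summary tables
  because the pipeline's contract starts there.
* **Metabolome**: feature means ~ Normal(10, 1), unit residual sd, so the
  default planted shift of 3 is a 3σ effect at n = 5 per group; 10%
  missingness; deliberately sparse samples are thinned to exactly 80
  present features, safely below the 100-feature filter.
* **Peptidome**: protein base levels ~ Normal(20, 2) on log2; per-peptide
  ionization offsets ~ Normal(0, 1); user-supplied per-sample loading
  offsets; measurement noise ~ Normal(0, 0.25) (standard deviation);
  planted proteins shifted by 2 log2 units in the deficient group. At
  these scales a planted fold is essentially always recoverable at n = 5,
  which is the point: failures then indicate pipeline defects, not power.

What the generators do *not* emulate: correlated features (co-regulation),
heavy-tailed abundance distributions, intensity-dependent missingness
(censoring), shared peptides, or between-tissue dependence of the
background. Passing the validation study therefore demonstrates
correctness of the machinery under its own assumptions, not performance on
real data — in particular `p_same`'s independence assumption is granted by
construction here and must be kept in mind on real tissues.

## Validation study sizes

The shipped validation (tests and `scripts/acceptance.py`) uses: exhaustive
tail enumeration for N ≤ 20, n ≤ 12; 200 null replicates of the
500-feature / 40-term two-tissue design for calibration; 100 replicates
with one planted 30-member term (factor 10, up probability 0.95) for
recovery; 100 seeds of the 60-protein peptidome for detection power; 200
null metabolome replicates for the type-I rate. These sizes give binomial
standard errors comfortably inside the asserted bands while keeping the
whole study at desk scale.

## Known limitations

* Flat term sets only; no GO DAG propagation.
* `p_same` assumes independence across tissues (see above).
* The hypergeometric test is conservative for small terms (discreteness),
  so null false-positive fractions sit slightly below nominal.
* Transcriptome DE quality is inherited, not checked: the pipeline trusts
  the adjusted p-values it is given.
* The run-metadata file records thresholds, flags, seed and version, and
  is sufficient to reproduce a run byte-for-byte; it does not capture the
  provenance of external input tables.
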