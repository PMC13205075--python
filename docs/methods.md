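# Methods

This note documents the models, estimators and design choices behind
`cernascreen`, in the order the pipeline applies them, together with the
simulator's generative model and what passing tests do and do not show.

## Study design and data model

The screen targets a two-group bulk RNA-seq design: a treatment group
(cold exposure) and a control group, three biological replicates each,
with counts quantified separately for four RNA classes — mRNA, lncRNA,
miRNA and circRNA. Counts are modeled as negative binomial with
$\mathrm{Var}(X) = \mu + \alpha \mu^2$, where $\alpha$ is the dispersion.
All fold changes are **base-10** logarithms of the treatment/control
ratio; the conventional volcano threshold $|\log_{10}\mathrm{FC}| \ge 0.6$
corresponds to about a four-fold change ($10^{0.6} \approx 3.98$).

Missing values are illegal in counts; there is no imputation. Genomic
coordinates are 0-based half-open throughout, including any exported
BED-like files. The internal sequence alphabet is RNA (A, C, G, U, N);
DNA input is converted on read.

## Normalization

Median-of-ratios size factors: for each feature with nonzero counts in
every sample, divide its count in sample $j$ by its geometric mean across
samples; the size factor $s_j$ is the median of those ratios (taken in
linear space). Factors are rescaled to geometric mean 1, which fixes the
otherwise arbitrary global scale. Consequence of that convention:
multiplying one sample's counts by $c$ multiplies *all* normalized counts
by $c^{1/n}$, so test statistics are invariant to library-size changes
only up to the pseudocount's influence on weakly expressed features (the
test suite checks the tight version of this invariance on features whose
group means dominate the pseudocount).

If no feature is positive in every sample the estimator is undefined and
the pipeline stops with an error rather than silently switching reference.

## Dispersion

Per feature, a method-of-moments estimate on normalized counts:
$\hat\alpha = \max\!\big(0, (s^2 - \bar m)/\bar m^2\big)$, with $\bar m$
the grand mean and $s^2$ the pooled within-group variance (denominator
$n - G$), floored at $10^{-8}$. Features with all-zero counts get an
undefined dispersion and are excluded from testing.

With three replicates per group this estimator has four residual degrees
of freedom and is very noisy; plugging it straight into a Wald statistic
is anticonservative (measured null fraction $p<0.05$ of ≈ 0.10 at a true
$\alpha = 0.1$). The pipeline therefore applies empirical-Bayes
moderation,
$\tilde\alpha_i = \frac{d\,\hat\alpha_i + d_0\,\bar\alpha}{d + d_0}$,
with residual df $d$, prior df $d_0 = 10$ (the classic tag-wise default)
and $\bar\alpha$ the mean of the finite per-feature estimates — the mean
rather than the median because the per-feature estimator is right-skewed
and the mean is nearly unbiased for a shared dispersion. After moderation
the measured null fraction is 0.045–0.050. The raw estimator remains
available (`estimate_dispersion`); moderation strength is a config knob
(`dispersion_prior_df`, set 0 to disable).

## Wald test and classification

With group means $m_1$ (control), $m_2$ (treatment) of normalized counts
and pseudocount $c = 0.5$:

$$\log_{10}\mathrm{FC} = \log_{10}\frac{m_2 + c}{m_1 + c}, \qquad
z = \frac{\ln\left((m_2+c)/(m_1+c)\right)}{\sqrt{\frac{1}{n_1}\left(\frac{1}{m_1+c}+\alpha\right) + \frac{1}{n_2}\left(\frac{1}{m_2+c}+\alpha\right)}}$$

The SE is the delta-method variance of the log of an NB group mean; the
two-sided p comes from the standard normal. The pseudocount guards zero
means and is configurable. This is intentionally a direct Wald test, not
an IRLS GLM: with a two-group design the GLM collapses to group means,
and the simple estimator is transparent and fast. Its operating
characteristics are established by simulation (type-I calibration,
power), not by equivalence to any particular GLM implementation.

Classification uses **raw** p-values with class-specific cutoffs —
0.05 for mRNA and lncRNA, 0.01 for miRNA and circRNA — and the fold-change
bound $|\log_{10}\mathrm{FC}| \ge 0.6$, *inclusive* at the boundary
(p strictly below its cutoff). BH adjustment is computed and reported but
does not gate classification; it does gate nothing in enrichment either
except the reported `p_adj` (within namespace).

PCA is computed on $\log_{10}(\text{normalized}+1)$, feature-centered,
via SVD; component signs are fixed by making each component's
largest-magnitude loading positive, so results are deterministic.

## Targeting

Seed sites follow the canonical taxonomy. With the miRNA written 5'→3',
the 6-mer core on the target is the reverse complement of miRNA positions
2–7. Each core occurrence is classified once, with its strongest type:
8mer (m8 match before the core and A after it), 7mer-m8, 7mer-A1, 6mer.
Overlapping occurrences are reported independently. circRNAs are scanned
as linear strings by default; an optional flag extends the scan across
the back-splice junction by appending the first seven nucleotides.

Interactions aggregate sites per (miRNA, target) pair. The screening
pipeline's evidence bar defaults to `min_site_type = "7mer-A1"` — bare
6mers are excluded, the usual convention, because a 6-mer occurs by
chance roughly every 4 kb of sequence and contributes mostly noise to
network assembly. `build_interactions` itself defaults to keeping all
canonical classes.

lncRNA→mRNA relations: *cis* = same chromosome with gap distance (0 if
overlapping) at most 100 kb (configurable; the common convention for cis
target screens); *trans* = $|r| \ge 0.9$ Pearson correlation of
log-normalized expression across all samples (configurable; with only six
samples this is permissive and should be read as a co-expression filter,
not causal evidence).

## Triad assembly

The direction-consistency rules: for a differential mRNA $m$, a
differential miRNA $\mu$ of **opposite** direction with an interaction
$\mu \to m$, and a differential sponge $s$ of the **same** direction as
$m$ with an interaction $\mu \to s$, emit the triad $(m, \mu, s)$. circRNA
sponges need only the seed-site evidence; lncRNA sponges must additionally
appear as a cis or trans partner of $m$ (cis takes precedence in the
reported mode when both hold). The requirement that $\mu$ targets the
core mRNA — not only the sponge — reflects using the mRNA as the search
core. Output is deduplicated and sorted; an optional post-filter keeps
triads whose core mRNA belongs to a term set of interest (e.g. a
lipid-storage annotation), off by default. Direct lncRNA–mRNA edges
without a miRNA (mechanism uncertain) can be exported as annotated extra
edges in the network files, never as triads.

## Enrichment

Hypergeometric upper tail $P(X \ge k)$ for a term with $K$ in-universe
members, selected set of size $n$, universe $N$, overlap $k$. The
universe is the set of tested features of the relevant class (not the
whole annotation), the defensible default. Terms with $k = 0$ are
dropped before BH (they carry $p = 1$ and only dilute); BH runs within
namespace. Reporting ranks by gene ratio $k/n$ descending (ties: smaller
p, then term id), truncated to 10 per GO category and 20 for pathways.

## Marker normalization

For a focal gene whose bulk-tissue signal may reflect cell composition
rather than regulation (an adipocyte-secreted gene in muscle that is
accumulating adipocytes), the per-sample normalized value is

$$x_{\mathrm{target},j} \big/ \sqrt{x_{\mathrm{markA},j}\, x_{\mathrm{markB},j}}$$

on normalized counts. The geometric-mean denominator is the default: it
is units-consistent (both numerator and denominator scale linearly with
marker-cell content, so the ratio is composition-free) and invariant to
common per-sample scaling. A plain-product denominator
$x/(x_A x_B)$ is available behind a config switch for comparability with
formulations that omit the root; the two differ by a factor
$\sqrt{x_A x_B}$ and the group comparison can differ. Group difference is
assessed with a two-sided pooled-variance Student t-test; with zero pooled
variance the test returns $t=0, p=1$ for equal means and errors otherwise.

## The simulator

`simulate_experiment` draws, per feature, a baseline mean $10^{U(0.5,\,3.5)}$
(log-uniform, spanning weak to strong expressors) and NB counts with a
single global dispersion (default 0.1, a realistic bulk value; the
observed mean–dispersion trend of real data is deliberately not modeled —
a constant is the simplest faithful stand-in and is what the moderated
estimator assumes).

Planted differential features receive group means
$\text{base} \cdot 10^{\pm\mathrm{fc}/2}$, i.e. the effect is split
symmetrically around the baseline. The group-mean *ratio* is exactly
$10^{\pm\mathrm{fc}}$, while each feature's average expression stays at
its drawn baseline — this keeps down-regulated features as detectable as
up-regulated ones instead of pushing them toward zero counts.

Planted triads alternate two patterns, (mRNA↑, miRNA↓, circRNA↑) and
(mRNA↓, miRNA↑, lncRNA↓); lncRNA sponges are placed in cis (same
chromosome, 1–50 kb downstream) of their core mRNA. Each triad's miRNA
gets one planted 8mer site in its mRNA and one in its sponge. Sequences:
miRNAs are 22 nt with pairwise-unambiguous seeds (no miRNA's core occurs
inside another's 8mer site string — otherwise a planted site for one
miRNA would be an accidental site for another and the truth would be
ill-defined); targets default to 500 nt, rejection-sampled/locally
repaired so that **no planted-differential miRNA** has an accidental
canonical site anywhere. Non-differential miRNAs are not scrubbed —
global avoidance is infeasible — so background matches exist for them;
they do not enter the screen because only differential miRNAs are
scanned. Two high-baseline mRNAs act as adipocyte markers with planted up
effects (markers are anchored in the top quarter of the baseline range:
marker genes are strongly expressed, and the normalization divides by
them); the focal normalization target is the first planted-down triad
mRNA. One term in the synthetic catalogue ("lipid storage" analogue)
draws ~70 % of its members from planted-up mRNAs.

Randomness is split per component — design, counts, sequences, terms,
power — from the master seed by the fixed rule
`SeedSequence([seed, component_index])`; generating or skipping one
component never perturbs another's stream (tested).

**What the simulation does not emulate:** feature–feature count
correlation, a mean–dispersion trend, GC/length biases, isoform
ambiguity, miRNA-family shared seeds, non-canonical or 3'-compensatory
sites, and real GO/KEGG structure. Passing recovery tests therefore shows
the screen implements its stated rules correctly and is calibrated under
its model — not that it would achieve the same operating characteristics
on real tissue data.

## Problem sizes used in validation

Recovery is validated at 2000 mRNA / 300 lncRNA / 150 miRNA / 500 circRNA
features, 3 vs 3 samples, dispersion 0.1, 20 planted triads at
$|\log_{10}\mathrm{FC}| = 1.0$, ten replicates (measured: mean recall
0.97–0.99, precision 1.0 — residual misses are planted features drawn at
the lowest baselines, where a 3-replicate design genuinely lacks power).
Type-I calibration uses a 20,000-feature null simulation. Unit tests use
smaller instances of the same generator.

## Numerical choices and degenerate inputs

- p-values are clipped to $[10^{-300}, 1]$; BH enforces monotonicity and
  caps at 1.
- Dispersion floor $10^{-8}$; all-zero features are excluded from testing
  with a flag rather than an error.
- Zero-variance features are excluded from trans-correlation with a
  warning, not an error.
- Constant matrices make PCA fail loudly (no variance to decompose).
- Tie-breaks are always deterministic and documented at the operation
  (enrichment ordering, top-term ranking, triad sorting, PCA sign fix).
- The hypergeometric tail is delegated to `scipy.stats.hypergeom.sf`
  (log-space stable) and cross-checked against exact combinatorial
  enumeration for all universes up to $N = 12$.

## Known limitations

- The Wald test's normal reference is approximate at $n = 3$; calibration
  is demonstrated for the simulator's NB model, not proven generally.
- Seed-match prediction carries no thermodynamics, conservation or
  AGO-CLIP weighting; it is the minimal canonical model.
- With six samples the trans-correlation threshold of 0.9 still admits
  many chance pairs; cis evidence is the stronger lncRNA filter.
- The marker-normalization t-test treats per-sample ratios as
  approximately normal; with three replicates per group this is a coarse
  approximation (the simulator's planted effects are strong enough that
  the conclusion is insensitive to it).
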