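# Methods

This note documents the models and procedures implemented in `contextflux`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic study conditions do and do not show.

## Expression preprocessing

**Normalization.** Samples from different platforms are put on a common
location by a per-sample median shift onto the global median of sample
medians. This is deliberately the weakest transformation that makes merged
log2 data comparable: it is rank-preserving within samples and idempotent.
It does not correct scale differences between platforms; those are absorbed
by the batch model below. All-zero samples are left untouched (warned), since
shifting them would fabricate signal.

**Batch correction** follows the parametric empirical-Bayes location/scale
model (Johnson, Li & Rabinovic 2007). Per gene, data are standardized
against a design containing the batch indicators *and* the biological
condition, so condition effects are estimated and added back unchanged —
the correction can remove batch structure but never naive/primed signal.
Per-batch location (γ) and scale (δ²) deviations get normal and
inverse-gamma priors with method-of-moments hyperparameters, solved by the
standard fixed-point iteration to a relative tolerance of 1e-4. Degenerate
cases (too few genes for a scale prior, zero residual variance) fall back to
the unshrunk estimates with variance floors, which makes the exact
symmetric two-batch case come out exactly equal. The implementation agrees
with Bioconductor `sva::ComBat` (parametric, condition in `mod`) to ~1e-6 on
shared fixtures; that agreement is enforced by a test that shells out to
`Rscript` when available.

A batch whose samples all carry one condition *and* make the joint design
rank-deficient is rejected by name: its batch effect is not estimable
separately from the condition effect.

**Differential expression** is per-gene Welch's *t* on log2 values with
logFC = mean(naive) − mean(primed) and Benjamini–Hochberg adjustment. This
replaces count-based models on purpose: the pipeline's contribution is
downstream of DE, and the simulator produces microarray-like log2 data for
which a two-group location test is the appropriate, fully specifiable
choice. Genes with zero variance in both groups get p = 1 and a
`degenerate` flag rather than NaNs.

**Diagnostics.** PCA is computed on gene-centered values (scikit-learn,
full SVD); k-means (50 seeded restarts) reports mean silhouette and the
adjusted Rand index against protocol labels. A mean silhouette below 0.25
is read as "no major heterogeneity"; the threshold is a package convention
(the underlying judgment is visual in the literature), exposed as a
parameter.

## Reaction scoring and confidence tiers

Gene-level mean log2 expression is pushed through GPR rules with AND → min
(complex limited by its scarcest subunit) and OR → max (isozymes). Genes in
the model but absent from the data score 0 ("not expressed"); genes in the
data but not the model are ignored. Reactions without a GPR stay unscored.

Tiers are assigned over *scored* reactions only: top ⌈10%⌉ by score high,
bottom ⌈10%⌉ negative, everything else — including all unscored reactions —
medium. Scored-only percentiles were chosen because spontaneous and
orphan reactions carry no expression evidence either way; leaving them
medium lets network topology decide their inclusion. Ties at a cutoff break
lexicographically by reaction id, which makes tier counts exact and the
assignment deterministic.

## Context-specific extraction

The extractor is a deterministic variant of CORDA-style dependency
assessment. On the split (all-forward) network, for each high-confidence
reaction a single LP

    min Σ cost_i · v_i   s.t.   S·v = 0,  bounds,  v_target ≥ τ

is solved (scipy HiGHS), with medium candidates at cost 1, negative at cost
100, and high at cost 0. τ defaults to 1.0 mmol/gDW/h, clipped per target
to its maximum feasible flux (a pre-solve maximization), so low-capacity
reactions are not declared unsupportable merely by scaling. Candidates
active above 1e-6 at the optimum form the target's support.

Promotion proceeds in passes: (1) every medium reaction in any support is
promoted; negative reactions are promoted when they support at least
`nc_promotion_min = 2` high targets; (2) a *rescue* pass promotes the
assessed support of any high reaction still blocked in the promoted core —
a negative reaction that is the unique route feeding a high reaction is
therefore always included, regardless of its tally; (3) promoted medium
reactions may pull in further negative reactions they strictly require.
The deterministic costs replace the original algorithm's noise-perturbed
repeated solves; the tally plays the role of its occurrence counts. This
trades the stochastic robustness heuristic for exact reproducibility, which
the test suite depends on.

Finally the submodel (high ∪ promoted) is pruned to flux consistency:
blocked reactions (unable to carry |v| ≥ 1e-6 at steady state, detected via
COBRApy's blocked-reaction FVA) are removed iteratively. High reactions are
never pruned; a blocked high reaction aborts extraction with its name. The
invariant that every retained reaction can carry flux is asserted by tests.

In the pipeline, the objective (biomass) reaction is forced into the high
tier before extraction: growth is the demand that defines the context, and
without it the dependency assessment has no anchor.

## Condition submodels and differential flux capacity

Genes down-regulated in a condition beyond each of three logFC thresholds
(1.00, 0.85, 0.70; BH-adjusted p < 0.05) are silenced; a reaction is
zero-bounded only when its GPR evaluates false with those genes off and all
others on, so isozyme-redundant reactions survive (standard gene-deletion
semantics). An `any-association` mode that zeroes every touching reaction
exists behind a flag for comparison. Using three thresholds and keeping only
status calls identical in tendency across all of them guards against the
sensitivity of FVA results to the removal cutoff; intersection (not union)
is the default combination rule.

FVA runs at an objective floor of 90% of each submodel's own optimum — a
conventional figure, configurable; note that a submodel whose biomass is
blocked (optimum 0) degrades gracefully to bounds-only variability. The
interval pair (N = [a_n, b_n], P = [a_p, b_p]) is classified with tolerance
1e-6:

* **F** all four endpoints ≈ 0 (inactive in both);
* **A** a_n > b_p (disjoint, naive above), **B** symmetric for primed;
* **C** both naive endpoints ≥ their primed counterparts with at least one
  strictly greater (shifted up in naive), **D** symmetric;
* **E** otherwise (identical or mutually covering intervals).

The classifier is a total function (exactly one status per reaction) and
antisymmetric under swapping the two models (A↔B, C↔D, E and F fixed),
both verified exhaustively over endpoint orderings. Reactions absent from
one submodel are exactly interval (0, 0) there, since removal is
bound-zeroing. Signed intervals are classified as-is; reactions forced to
strictly opposite signs in the two conditions are additionally flagged
`direction_flip`, because a single status letter cannot express a direction
reversal.

## Reporter metabolites

Neighborhoods are 1-step and compartment-specific: the genes of all
reactions producing or consuming the metabolite. No currency-metabolite
exclusion is applied by default — highly connected cofactors (NAD among
them) are legitimate reporters here — but an exclusion list is accepted.

Per gene, z = Φ⁻¹(1 − p) with p clamped to [1e-15, 1 − 1e-15]; per
metabolite Z_raw = Σz/√k. The background for each size k is 10,000 random
k-subsets drawn without replacement from the full set of DE-tested genes
(not only genes adjacent to metabolites: the wider universe gives a stabler
null and matches the statistic's usual practice), giving
Z_corrected = (Z_raw − μ_k)/σ_k and a one-tailed normal p, BH-adjusted
across metabolites. One permutation pass serves all k via cumulative sums,
so the background costs O(n_background · k_max).

Degenerate backgrounds are resolved by a case split: if σ_k = 0 because
every gene carries identical evidence *and* k is smaller than the universe,
the neighborhood is exactly at background level (Z_corrected = 0, p = 0.5);
if k spans the whole universe the background carries no information and the
metabolite is flagged and excluded. Direction (mean sign of neighborhood
logFCs) is reported separately — the z-aggregate measures significance, not
direction.

## Enrichment

Over-representation uses the hypergeometric upper tail with BH adjustment,
with set sizes taken after intersection with the stated universe. This
stands in for both ranked gene-set enrichment and modified-Fisher web
services: the pipeline's contribution is the input gene lists, and an exact,
dependency-free test keeps the stage verifiable (the suite checks it against
direct combinatorial enumeration for universes ≤ 30). Only BH-adjusted
p-values are reported; permutation-based FDR q-values are out of scope.

## Synthetic study conditions

The toy network (37 reactions, 41 genes by default) couples a glucose →
pyruvate chain, a carrier-regenerating TCA-like cycle with an anaplerotic
filler, an OXPHOS-like ATP producer, and a tryptophan → kynurenine → NAD
branch with one dedicated gene per step (rate-limiting first step included).
Biomass consumes ATP, a sugar precursor, a TCA-derived precursor, and NAD;
since the branch is the only NAD source, silencing it abolishes growth —
the planted causal chain connecting transcription to flux. The biomass
drain of the TCA carrier is what keeps the anaplerotic step flux-consistent.
Flux-consistent "extra" detour reactions pad the network so 10% tiers are
non-degenerate; dead-end fixtures used in tests are constructed explicitly
and are not part of the default model.

Expression is simulated on the log2 scale (microarray-like):
x = μ_g + Δ_g·1[naive] + γ_{g,b} + φ_{g,b}·ε with baselines μ ~ N(7, 1.5),
additive batch shifts γ ~ N(m_b, σ_batch) around per-batch means
m_b ~ N(0, σ_batch), multiplicative noise scales φ ~ U(0.8, 1.25), and
ε ~ N(0, 0.5). Defaults (2000 genes, 3 batches, 20 samples per condition
per batch, batch shift SD 1; shift SD 2 in the batch-recovery scenario;
planted |logFC| = 2 for marker/power scenarios and −1.5 for the pathway
scenario) are the study conditions of the test suite and acceptance script.
Counts, library sizes, gene length effects, and single-cell structure are
deliberately not modeled — passing tests show the pipeline recovers planted
log-scale structure, not that it handles RNA-seq count noise; with real
count data, upstream normalization is the user's responsibility.

Problem sizes in the suite (2000–2200 genes, 40–120 samples, ≤ 50-reaction
networks, 100 null replicates, 10,000-draw backgrounds) were chosen so every
statistical check has comfortable power while the whole pipeline runs in
seconds on one CPU.

## Numerical conventions

LPs: GLPK via COBRApy for FBA/FVA, HiGHS via scipy for dependency
assessment; both are exact simplex-type solvers and cross-checked against
each other in tests to 1e-6. Flux tolerance 1e-6 throughout; ComBat
iteration tolerance 1e-4; reporter p clamp 1e-15. Tie-breaks are
lexicographic by identifier wherever an ordering is needed. All randomness
flows from one root seed split per stage (simulation, k-means, reporter
background), so identical configs produce byte-identical outputs.

## Known limitations

* The extraction is faithful in spirit to CORDA but not a reimplementation:
  deterministic costs and tally/rescue promotion replace randomized repeated
  assessments, so inclusion sets can differ from the original algorithm's on
  the margins.
* Reporter p-values assume the normal tail of the sampled background; for
  very small universes the background is coarse and the BH step is applied
  over few metabolites.
* The six-status classification compares flux *capacity* (FVA intervals),
  not realized flux; statuses C/D in particular state interval dominance,
  not a measured rate difference.
* Thermodynamic (loopless) constraints, flux sampling, and alternative
  extraction algorithms (GIMME, iMAT, FASTCORE, mCADRE) are out of scope.
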