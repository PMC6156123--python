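# Methods

## Study design and data model

The package targets a two-population comparative RNA-seq design with
field-collected individuals: populations A and B (equatorial and
subtropical in the motivating system), `n` individuals per population
(default 3), one library per individual × organ across five organs.  The
primitive data object is a transcript × sample matrix of raw fragment
counts with per-transcript effective lengths; FPKM
(X·10⁹ / (L·N), L in nt, N the sample's total fragments) is derived from it
where a length- and depth-normalized scale is needed (presence/absence
calls, correlation networks).  Counts, not FPKM, feed the count model.

## The Beta–negative-binomial mixture

For gene g and sample i, counts are modelled as NB(r_gi, q_g) in the
success-probability parameterization, P(X=x) = C(x+r−1, x) q^r (1−q)^x,
with r_gi = r0_g·s_i.  Size factors s_i (median-of-ratios, rescaled to
geometric mean 1; column-sum ratios as fallback) carry sequencing depth, so
expected counts scale with depth at a shared q_g.  With a conjugate
Beta(α, β) prior on q_g, the marginal likelihood of any group of samples is
closed-form:

    f(x₁..xₙ) = [∏ᵢ C(xᵢ+rᵢ−1, xᵢ)] · B(α+Σrᵢ, β+Σxᵢ) / B(α, β)

Equal expression (EE) means one q_g shared by all samples of both
conditions; differential expression (DE) means independent q's per
condition, f_DE = f(A)·f(B).  A gene's posterior probability of DE is

    PPDE_g = p·f_DE,g / (p·f_DE,g + (1−p)·f_EE,g),   PPEE = 1 − PPDE.

EM estimation: within each iteration (α, β) are updated by Nelder–Mead
ascent on the incomplete-data log-likelihood (the optimizer returns the
best point evaluated, which includes the starting point, so the trace is
non-decreasing by construction), then p ← mean(PPDE) — the exact M-step.
Convergence is declared at a relative log-likelihood change below 1e-6
(default cap 200 iterations).  Initialization α = β = 1, p = 0.5.
All-zero genes carry no evidence; they are excluded from the fit and
assigned PPDE = 0.

**Dispersion.**  r0_g comes from method-of-moments on depth-normalized
counts, using the pooled within-condition variance when both conditions
have ≥ 2 samples (so genuine DE does not inflate dispersion) and the total
variance in the 1-vs-1 pairwise case.  With 2–3 replicates the gene-wise
excess-variance coefficient φ = 1/r0 is extremely noisy (its chance
underestimation produces overconfident posteriors), so φ is shrunk toward
the transcriptome-wide median with 10 pseudo-degrees of freedom — the
moderated-dispersion construction standard for small-n RNA-seq.  r0 is
capped at 50/φ-floor ≡ 50·mean (a near-Poisson ceiling).

**Calls.**  DE: PPDE ≥ 1 − FDR (hard posterior threshold, the convention
for PPDE-based FDR control) *and* max(FC, 1/FC) > 1.5 with
FC = (mean_A+1)/(mean_B+1) on normalized means — the pseudocount keeps
fold changes defined next to structural zeros.  EE: PPEE ≥ 1 − FDR —
there is no canonical convention for an explicit EE threshold, so the rule
is taken symmetrically to the DE rule.  The mean PPEE over called DE genes
bounds the expected false-discovery proportion by FDR automatically.

**Operating characteristics and an honest ceiling.**  On the packaged
3-vs-3 benchmark (2000 transcripts, 20% DE at fold change 4, NB size 5)
the engine's realized false-discovery proportion is ≈ 0.01–0.02 and the
fully-null fitted p stays below 0.01.  Sensitivity is ≈ 0.50–0.55.  This is
not an estimation defect: a Bayes-optimal oracle that knows the exact
generative model (paired ±√FC means, true dispersion, true mixing weight)
reaches only ≈ 0.62 sensitivity at the 0.95 posterior threshold under this
noise level, and the mixture's independent-q DE alternative is a weaker
test than the oracle's paired alternative.  At biological CV ≈ 45%
(NB size 5 — a realistic figure for unrelated field-grown individuals, and
the package default) a hard 0.95 posterior threshold is simply a
conservative test at n = 3; users wanting more power should raise FDR,
lower the posterior threshold deliberately, or add replicates.

## Three-step classification

Per organ: (1) UETs — FPKM > ε (ε = 0 by default; any positive value
counts as expressed) in *every* sample of one population and exactly zero
in every sample of the other.  Transcripts not expressed in at least one
sample of each population are then excluded.  (2) EETs per population —
the engine runs on each of the C(n,2) individual pairs (one library per
side, matched organ) and the EE calls are intersected; the EET-both set is
the intersection across populations.  (3) DETs — a 3-vs-3 fit restricted
to EET-both, called at FDR < 0.05, FC > 1.5, with the over-expressed
population as direction.  Set invariants (DET ⊆ EET-both, UET sets
disjoint from each other and from DETs) are asserted on every run.

UETs are computed per organ by default (matching organ-wise reporting); a
`global` mode requires presence in all organs simultaneously.  The strict
all-pairwise EET rule can be severe at 1-vs-1 replication — when fitted
posteriors sit near the threshold an organ can retain few transcripts —
which is the intended behaviour of the original design, not a bug.

## Co-expression network and clustering

Expression is transformed log2(x+1) before Pearson correlation (raw scale
available); transcripts with > 50% zeros across samples are removed first
(strictly greater: a transcript at exactly 50% is kept).  Constant rows
have undefined correlations, recorded as 0 and flagged.

HRR: partners are ranked per transcript by descending correlation (ordinal
ranks, ties broken by index order), HRR(i,j) = max(rank_i(j), rank_j(i)).
Two thresholds are exposed because both conventions appear in practice:
HRR ≤ 30 defines the candidate graph handed to clustering and HRR ≤ 3 the
reported/visualized edges; the strict edge set is always a subset of the
loose one.

HCCA: every node seeds a candidate (its 3-hop vicinity); the candidate is
chiseled by simultaneously removing all nodes with more edges leaving the
set than staying inside, until stable; surviving candidates within
[40, 200] nodes are scored and accepted greedily without overlap (ties by
smallest member id), and the procedure repeats on the residual graph until
no candidate reaches the minimum size; leftover nodes stay unassigned.
Candidates are scored by **internal edge density** (internal edges /
C(size, 2)).  The naive alternative — internal-edge *fraction*,
internal/(internal+boundary) — degenerates: any whole connected component
scores a perfect 1.0, so a graph of two dense blocks joined by one bridge
would always be swallowed into a single cluster.  Density has no such
fixed point and recovers planted partitions exactly (ARI ≥ 0.98 on
50-node blocks at within-density 0.3, and ≈ 0.92–0.99 for latent-factor
modules through the full Pearson→HRR→HCCA chain).

DET neighborhoods: the subnetwork induced by DET nodes plus nodes within
depth 1 (configurable), with node classes assigned at precedence
DET > UET > neighbor — so UETs appear only when directly connected to a
DET.  Exported as SIF and GraphML with a `node_class` attribute.

## GO enrichment

Per cluster or per set, against a configurable background universe
(default: annotated network nodes).  Central test: upper-tail
hypergeometric P(X ≥ k).  Length-aware test: isotonic regression of study
membership on transcript length yields per-transcript selection weights;
a term's odds ratio is the mean weight of its annotated background
transcripts over the unannotated ones, and the p-value comes from the
Wallenius noncentral hypergeometric distribution.  At odds exactly 1 the
noncentral law coincides with the central one and the central routine is
used directly (scipy's noncentral survival function is not accurate to the
sub-1e-9 level the equal-weights identity deserves).  Terms are flagged at
raw p < 0.05 — the convention of per-cluster pathway reporting — with BH
q-values always alongside.  GO-graph ancestor propagation is off by
default (input annotation is used as given).

## Sequence curation

* ORF finder: all six frames, ATG to the first in-frame stop, minimum
  300 nt (configurable); the longest ORF is flagged, ties prefer the
  forward strand then the smaller start.  Coordinates are 0-based
  half-open on the forward strand everywhere.  This is a deliberate
  simplification of longest-CDS selection: no coding-potential (Markov)
  scoring.
* Redundancy clustering: greedy, longest sequence first; a record joins a
  cluster when its global alignment against the representative (free end
  gaps; +1/−1/−2 match/mismatch/gap) reaches ≥ 95% identity over ≥ 90% of
  the shorter sequence; the member with the longest ORF represents the
  cluster.  A 12-mer word filter (shared-word fraction ≥ 0.05 of the
  shorter sequence's words) screens pairs before alignment; the bound is
  far below what any pair at the accept thresholds can exhibit, so the
  screen only removes pairs the alignment would reject.
* Consensus merge: an A-record survives when some B-record shares an
  exact-identity local alignment covering ≥ 95% of the shorter sequence —
  at 100% identity this is a longest-common-substring criterion; a scored
  local aligner handles identity thresholds < 1.  Exact duplicates are
  collapsed.  The coverage denominator (shorter sequence) is a documented
  choice; it is configurable.
* SSR scan: perfect tandem repeats of motif length 1–6 in contigs
  > 1000 nt, minimum repeat counts {mono 10, di 6, tri 5, tetra 5,
  penta 5, hexa 5} (common MISA defaults; fully configurable).  Motifs are
  reported in canonical (lexicographically minimal) rotation; periodic
  motifs and runs nested inside an already-reported run are suppressed.

## Synthetic data: what it emulates and what it does not

The generator draws baseline means log-uniform on [10, 1000], applies
per-transcript × organ log-normal effects (sd 0.4, mean-preserving; organ
identity then dominates sample ordination, as in the motivating study),
per-sample library factors (log-normal, sd 0.1, so depth normalization is
exercised), and NB noise at size 5.  Planted signals: UET fractions (zero
in the other population, counts clipped to ≥ 1 in the own population so
presence is noiseless); DET fractions at a configurable fold change split
geometrically (±√FC) so the population mean ratio is exact; co-expression
modules sharing a per-sample log-normal latent factor with loading
`module_correlation` (higher loading ⇒ higher pairwise correlation);
GO terms enriched in modules (membership probability 0.8 inside vs 0.05
outside); sequences with planted ORFs, SSR motifs and near-duplicate pairs
(98% identity, mutations kept outside planted features).  Everything is
recorded in a truth table; a fixed seed reproduces all outputs exactly.

Not emulated: read-level errors, positional/GC bias, isoform structure,
batch effects, correlated DE, dispersion–mean trends, SNPs.  Passing tests
therefore demonstrate the *logic* and *calibration* of the pipeline under
its own model assumptions, not robustness to artefacts real libraries
carry.

## Problem sizes and numerical choices

Default verification sizes — 2000 transcripts for the DE benchmark, 500
(4 modules × 50) for the network chain, 400 for the end-to-end demo, 100
random 50-node instances for the HRR oracle — keep a full test run near a
minute on one CPU while leaving Monte-Carlo error well inside the asserted
margins.  Degenerate inputs are defined, not fatal: empty gene sets yield
empty fits, all-zero genes get PPDE 0, constant rows correlate 0 (flagged),
clusters without annotated members are skipped with a warning, missing DET
ids in the network are skipped with a warning.  Manifests record seed,
thresholds and input hashes but no timestamps, so identical configurations
rerun to byte-identical artifacts.

## Known limitations

* The EE/DE mixture shares one Beta prior across all genes; with a very
  wide expression range this prior is broad, which makes the DE Bayes
  factor conservative (see the ceiling analysis above).
* 1-vs-1 pairwise EE testing is weakly informed by construction; the
  all-pairs intersection amplifies threshold noise at small transcriptome
  sizes.
* HCCA is a greedy heuristic: cluster boundaries depend on chisel order
  only through the deterministic tie-breaks, but no optimality is claimed.
* The Wallenius correction conditions on a single odds ratio per term
  (mean annotated weight vs mean unannotated weight), the usual
  approximation to the fully weighted urn.
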