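# Methods

## Model and assumptions

`gwaspath` treats a GWAS result not as a list of significant hits but as a
genome-wide ranking of gene effects, and tests whether the genes of a
predefined pathway concentrate in one tail of that ranking.  The chain of
inference is:

SNP–trait associations → LD-pruned tagSNPs → gene effects → pathway
enrichment.

The key assumptions are:

* **Biallelic markers.** Markers with more or fewer than two allele-effect
  rows are discarded, as are markers lacking an association R².  The two
  allele rows carry one free effect (the other allele is the reference), so
  the marker's signed effect is taken from the first allele row with a
  nonzero effect, in file order.  This convention is a deliberate choice;
  association tools that report one effect per marker are unaffected.
* **LD is precomputed.** The package never touches genotypes; linkage is
  whatever the upstream LD table says.  Pairs spanning different loci are
  dropped.  "Exceeds the cutoff" is strict (`r² > cutoff`), so a pair
  sitting exactly at the cutoff is *not* linked.
* **Linkage groups are connected components.** Blocks are described in the
  field as several SNPs linked to one SNP in common (a star).  Overlapping
  stars and chains are not stars; we therefore define a block as any
  connected component of size ≥ 3 in the thresholded LD graph, with the
  "common" SNP being the member of highest degree (ties broken by smallest
  position).  On an actual star this reduces to the star definition; on any
  graph it is order-independent and unambiguous.
* **One effect per group, one effect per gene.** The tagSNP election and
  gene-resolution rules are sign-majority votes with fully specified
  tie-breaks (see below); zero effects count as neither sign.  Where every
  stated rule ties, the smallest genomic position wins — a final tie-break
  the election needed that costs nothing when it never fires.

## TagSNP election and gene transfer

Pairs: same effect sign → larger |effect|; equal effects → the downstream
SNP; opposite signs → smaller p; opposite signs *and* equal p → the pair is
"problematic", elects no tagSNP, and both SNPs leave the analysis (counted
and logged — in real data this is rare).

Blocks: count positive vs negative effects.  Majority positive → largest
positive effect; majority negative → most negative effect; tie → the sign
of the block's common SNP decides which extreme is taken; common SNP with
zero effect → largest |effect| overall.

Genes: every gene within `window` bp of a tagSNP (distance zero inside the
gene, otherwise gap to the nearest gene boundary; strand ignored) inherits
that tagSNP's effect and p.  A gene reached by several groups resolves by
the same majority-sign logic — most negative effect if negatives dominate,
largest positive if positives dominate, lowest p among equal extremes,
greatest |effect| on a tie of counts (then lower p, then the positive
effect) — and its linked-SNP count is the *sum* over contributing groups.

## Enrichment statistic

With N ranked genes and a pathway hit set H (N_H = |H|), the running sum
steps are `+|e_i|/Σ_H|e|` at hits and `−1/(N−N_H)` at misses — the
weighted Kolmogorov–Smirnov form with weight exponent 1 used across the
GSEA family.  Both step families sum to one, so S_N = 0 identically; the
ES is `max_i S_i`, *not* floored at zero, so a pathway whose members all
sit at the bottom still gets a well-defined (possibly ≤ 0) score and the
null normalization stays meaningful.  If every hit effect is zero the hit
steps fall back to uniform `1/N_H` (logged).

The null resamples the observed effect vector **with replacement**
(a bootstrap; `null_mode="permutation"` offers the without-replacement
variant for sensitivity analysis), reassigns the drawn effects to the gene
labels in a fixed (sorted) order, re-ranks, and recomputes every pathway's
ES.  Then z = (ES − mean)/sd with the sample (N−1) standard deviation and
p = 1 − Φ(z).  A degenerate null (sd = 0, e.g. all effects identical) sets
p to 1 when the ES does not exceed the null mean and to the smallest
positive float otherwise, with a flag on the result.

q-values: with ≥ 100 pathways, Storey's smoother estimate of π₀ (cubic
polynomial through π₀(λ) over λ = 0.05…0.95, evaluated at λ = 0.95) scales
the Benjamini–Hochberg step-up; with fewer pathways, or when the estimate
leaves (0, 1], π₀ = 1 and the procedure is exactly BH.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `r2_cutoff` | 0.8 | LD r² above which two SNPs are linked (strict >). Conventional block threshold; raise for long-LD inbreeders. |
| `window` | 1000 bp | maximum SNP-to-gene-boundary distance for transfer. |
| `min_genes` | 5 | minimum pathway genes present in the ranking; guards the null against small-sample bias. |
| `n_perm` | 1000 | null replicates; 200 is enough for screening, 1000 for calibrated tails. |
| `direction` | increase | which trait tail is "best"; run both to test increase and decrease separately. |
| `seed` | 0 | master seed; every replicate draws from its own spawned substream, so results are bit-identical for any `workers` count. |

## Synthetic data

`gwaspath.synthetic` generates complete input sets: genes spaced along a
few chromosomes, one causal SNP inside each gene, extra intergenic SNPs in
LD blocks, and disjoint pathways over the genes.  Null effects are
N(0, σ); a planted pathway's gene SNPs draw from N(μ_shift·σ, σ) (default
shift 2σ — a moderate polygenic signal).  p-values are a monotone
decreasing map of |effect| (the normal upper tail) with small
multiplicative jitter, so effect magnitude and significance agree; explicit
per-marker overrides let tests force the tie-break branches.  Within-block
LD r² is Uniform(lo, hi) and between-block Uniform(0, lo) with lo defaulting
to the 0.8 cutoff, so the strict threshold recovers the constructed blocks
exactly (almost surely) and the ground-truth manifest can be asserted
against.

The generator does **not** emulate population structure, allele-frequency
spectra, LD decay with distance, genotyping error, or overlapping
pathways.  Green tests demonstrate correct bookkeeping and statistical
behaviour under exchangeability — not robustness to confounded real data.

## Numerical choices

* Running-sum closure is exact to ~1e-15; tests assert 1e-9.
* Gene ranking ties break lexicographically by gene id; the null re-ranking
  uses a stable sort over the same fixed gene order, so tie-breaking is
  identical for observed and resampled rankings (this is what makes z
  exactly invariant to rescaling all effects by a positive constant).
* Tables are written with `repr`-round-trip floats; readers parse via
  Python's exact `float()`, so write→read is bit-faithful.
* Parallel nulls partition replicates, never streams: replicate i always
  uses substream i of the master seed.

## Known limitations

* The normal approximation p = 1 − Φ(z) is mildly anti-conservative: the
  null ES is the maximum of a random walk and is right-skewed, so the true
  upper tail is heavier than normal.  Measured on signal-free synthetic
  data, the rejection rate at p < 0.05 is ≈ 0.06–0.07 rather than 0.05
  (closer to nominal at 1000 replicates than at 200).  This is inherent to
  the z-normalization; an empirical-tail p-value would fix it but would
  change the method.  Treat borderline p-values accordingly; q-values
  inherit the same bias.
* Very long LD blocks (inbreeders, polyploids) can span several genes, and
  the window-based transfer will assign one tagSNP to all of them.
* A pathway covering the entire ranked universe has no miss step and is
  skipped with a warning.
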