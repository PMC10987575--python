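# Methods

This note records the models and procedures implemented in `pamg`, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Viral screening and curation

Contigs strictly longer than 10,000 bp enter screening ("longer than 10 kb"
is read as a strict bound; the cutoff is a parameter).  For each contig the
profile counts genes with a KO term, a non-empty Pfam set, and a viral
protein family (VOG) hit, with the full gene count as denominator (whether
the source protocol divides by all genes or annotated genes is ambiguous;
all-genes is the implemented and documented choice).  The three curation
criteria all require at least five viral-family hits; boundary semantics
follow the wording they paraphrase: the KO (<20%), Pfam (<40%) and c1 viral
(>10%) bounds are strict, the c3 viral fraction ("at least 60%") and the
five-hit floor are inclusive.  A contig is a *validated phage* when manual
curation and two external tool verdicts (supplied as data, since running
those tools is out of scope) all agree; absent verdicts count as negative.

## Auxiliary scores, flags and acceptance

The auxiliary score of a candidate gene is derived from the best viral-gene
class within a 10-gene window on each side (window configurable): hallmark
on both sides → 1, hallmark plus viral-like → 2, viral-like on both → 3,
viral evidence on exactly one side → 4, none → 5.  The nine flank-class
combinations are enumerated in tests against an independently stated table.

Flags: `M` — KO in the P-gene catalog (or a configurable metabolic KO set);
`V` — the gene itself hits a viral family; `T`/`A`/`P` — transposase /
attachment / peptidase annotations supplied on the gene; `B` — membership
in a maximal run of ≥3 adjacent metabolic, virus-free genes; `F` — no viral
hit and within two genes of a contig end.  The upstream scorer's exact `F`
and `T` semantics are not public; these definitions are explicit,
documented stand-ins and are configurable (`end_margin`).

Acceptance: score ≤3 with `M` and/or `F`, none of `V`/`A`/`P`, and no `T`;
or score ≤3 with `T` on a validated phage contig; or score 4 inside a *pst*
cluster (≥3 distinct kinds of *pstS/C/A/B* adjacent, any order — three
tolerates an operon truncated at a contig edge) on a validated contig.
Genes that are themselves viral/structural (`V`, `A`, `P`) are not auxiliary
metabolic genes, hence the disqualification.  Accepted calls therefore have
score ≤4, and score 4 only via the cluster rescue.

## Alignment and clustering

One identity engine serves all thresholds: optimal global alignment with
free end gaps (semi-global), so fragment-versus-full-length comparisons are
not penalized for overhangs.  Identity is identical positions over the
shorter sequence and coverage is each sequence's non-end-gap aligned span
over its length — the conventions of the dereplication tools this stands in
for.  Defaults: BLOSUM62 with gap open 11 / extend 1 for proteins; match 2,
mismatch −3, gap 5/2 for nucleotides.  Clustering is greedy over sequences
sorted by decreasing length (ties by id): each sequence joins the first
representative meeting the identity and coverage thresholds, else founds a
cluster, making every representative the longest member and the outcome
independent of input order.  Coverage mode is "shorter" for 95/90
dereplication and "both" for the 70/70 pre-clustering ("over at least 70%
of their lengths" is read as both sequences); for species-like contig
clustering at 95/85 the alignment fraction refers to the shorter contig.
No k-mer prefilter is implemented; the all-pairs cost is acceptable at the
problem sizes used here (tens of sequences).

## Abundance and ecology

Mean depth is mapped read-bases over contig length.  Normalization divides
each sample column by its read count and multiplies by the mean read count
across samples, making the table invariant to a global rescaling of
sequencing effort; the proportional table rescales each sample to sum to
100, with all-zero samples left at zero and flagged rather than dropped.
An AMG's relative abundance is that of its carrier viral unit (pass-
through), avoiding read recruitment from homologous host genes.  Detection
is any strictly positive normalized depth by default — the source protocol
states no threshold, so the threshold is exposed as a sensitivity knob.
Habitat comparisons use Kruskal–Wallis followed, only in interpretation,
by pairwise two-sided Mann–Whitney tests Holm-corrected within the family
of 10 habitat pairs; correlations are Pearson product-moment.

## dN/dS (NG86)

Sites: per codon position, the fraction of single-nucleotide changes that
are synonymous, among changes not producing a stop codon, renormalized per
position; mutations to stops are likewise excluded from pathway counts.
(Classic NG86 counts stop-producing changes as nonsynonymous; exclusion is
the convention of common modern implementations and is mirrored by the
enumeration oracle in the tests.)  Codon pairs differing at k positions
average difference counts over the k! single-step pathways, equally
weighted, skipping pathways through stops; in the degenerate case where
every ordering crosses a stop, all pathways are used.  Proportions are
corrected with Jukes–Cantor, d = −(3/4)ln(1 − 4p/3), raising a typed error
at saturation (p ≥ 3/4).  ω is undefined (reported as null, not dropped)
when dS = 0, keeping pair counts auditable.  Within each gene kind,
proteins are pre-clustered at 70/70 and all within-cluster pairs scored;
single-sequence kinds are skipped with a report entry.  Bacterial/archaeal
translation table 11 throughout.

## Phage–host linkage and transcript ratios

Gene trees are built by Saitou–Nei neighbor joining over Poisson-corrected
protein distances, d = −ln(1 − p), from the same alignment engine — a
self-contained stand-in for the external aligner/ML-tree step, which is out
of scope.  Tie-breaks in the join selection are deterministic (by label);
negative branch-length estimates are clamped to zero with the deficit moved
to the sibling branch, preserving the joined pair's distance.  The host
counterpart of a phage gene is the bacterial leaf at minimal patristic
distance (ties lexicographic); sister-clade proximity would be an
alternative reading, and patristic was chosen as the implemented default.
Expression is RPKM; a pair's ratio is phage/host RPKM, ∞ when only the
phage copy is transcribed, and *not recorded* when neither is — so summary
denominators count transcribed pairs only, and ratios exactly 1 are not
"greater than one".

## Aggregated boosted trees

"Aggregated" is realized as bagging over B bootstrap replicates of a
stagewise least-squares gradient-boosted ensemble of depth-limited trees
(shrinkage and per-iteration row subsampling inside each replicate); the
underlying booster is scikit-learn's `GradientBoostingRegressor`.  Defaults
B = 25, 500 trees, depth 3, shrinkage 0.01, bag fraction 0.5 —
conventional boosted-regression-tree settings for a few hundred rows; the
source analysis names the approach but not its hyperparameters.  Relative
influence sums each predictor's split squared-error reductions over all
trees and replicates (unnormalized per replicate, so replicates weigh by
their actual gain) and normalizes to percent.  Categorical predictors
(site, habitat) are one-hot encoded and their column influences summed back
to one number per predictor.  Squared-error loss only: the response
(available P) is continuous.

## Synthetic data: what it emulates, and what it does not

The generators mirror the study design constants: 111 sites × 3 replicate
samples across five habitat types (29 farmland, 27 forest, 9 grassland,
4 Gobi desert, 42 mine wasteland; 333 samples).  Planted AMG contexts place
five hallmark genes at the contig start (outside the scoring window) so
contigs pass curation, and realize each target score exactly by
construction; the closed-loop tests require exact recovery of every planted
accept/reject label.  Codon families evolve from a random stop-free
ancestor by uniform point-mutation proposals — synonymous proposals always
fix, nonsynonymous fix with probability ω, stop-producing proposals are
discarded — so the realized rate ratio matches the target under the same
stop-exclusion convention the estimator uses.  Coverage depths are
lognormal with explicit drop-outs whose probability decreases with total P
(`zero_rate` is exact at its endpoints), linking detection counts to
phosphorus as the ecology stage expects.  Environment tables plant
AP = Σβ·x + site effect + noise over standardized predictors with TP
dominant by default (β = 3.0 vs 0.5/0.3/0.2, noise SD 0.5, site SD 0.3).
Transcript counts are Poisson around RPKM-consistent means, with a
configurable per-kind phage:host rate ratio and a fraction of silent pairs.

None of this reproduces real metagenomes: no read-level simulation, no
assembly artifacts, no taxonomic structure, no gene-length variation within
pairs, independence between samples beyond the site effect.  Passing tests
therefore demonstrate that the *operations* are correct and that the
estimators recover known ground truth under their own model assumptions —
not that the study's field numbers would be reproduced, which would require
the original 333 metagenomes.

## Problem sizes and determinism

Default analysis sizes — 9 planted contigs of 20 genes, three codon
families of 6 × 200 codons, 40 viral units × 333 samples, 8
metatranscriptome samples per pair — were chosen so the full pipeline and
its recovery checks run comfortably on one CPU while every statistic
remains well-determined; ω-recovery checks use 8 × 300-codon families
(28 pairs).  All randomness flows from explicit seeds through
`numpy.random.default_rng`; `run_all` derives fixed small offsets from the
run seed per stage, and rerunning any configuration reproduces its summary
byte for byte.

## Known limitations

* The greedy clusterer is quadratic; it is not meant for genome-scale
  dereplication.
* NG86 with equal pathway weights underestimates ω when transition/
  transversion bias is strong; no ML codon model is provided.
* NJ trees with Poisson distances are a deliberate simplification of the
  MAFFT/ML-tree step they replace; host pairing quality on real data
  depends on that step's accuracy.
* The external phage-validation verdicts (VIBRANT, the VirSorter2/CheckV
  protocol) enter as booleans; this package never runs those tools.
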