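# Methods

## Signature models and data representation

Two parameterizations of mutational signatures are supported. The
*Alexandrov* model is the joint distribution over the 96 pyrimidine-centered
trinucleotide mutation categories, stored as a vector in canonical COSMIC
order (substitution class slowest — C>A, C>G, C>T, T>A, T>C, T>G — then the
5' base, then the 3' base, each over A, C, G, T). The *Shiraishi* model
treats the substitution class, each flanking position and optionally the
transcription strand as independent features, each with its own categorical
distribution; a context of f₅ + f₃ flanking bases with a strand feature has
P = 6 + 4·(f₅+f₃) + 2 parameters (14 for a triplet without strand, 24 for a
quintet with strand).

A Shiraishi signature is stored as a rectangular matrix with 6 columns:
one row per feature, in the fixed order *change, −f₅ … −1, +1 … +f₃,
strand*, with flanking rows padded by two hard zeros and the strand row by
four. The padding makes Frobenius distances and file I/O well defined on a
single rectangular object; because the pads are zero in both operands they
never contribute to a distance. Note that this row order is a deliberate,
documented convention (reading order of a printed probability table);
other toolchains order the rows differently, so flat files from elsewhere
must be checked before mixing.

Tumor catalogs (`GenomeProfile`) use the identical representation: each
feature row is the empirical frequency of that feature across the tumor's
usable SNVs. Probability rows must sum to 1 within 1e−10 for in-memory
constructions; file readers relax this to 1e−4 because published tables
are rounded, and expose an opt-in `renormalize` flag (off by default, so
rounded inputs are preserved as printed).

## Featurization

Variants are read from VCF 4.x (via pysam, genotype-aware: a variant
counts for every sample whose GT carries the alternate allele; files
without genotype columns are a single tumor) or from MPF, a tab-separated
`sample chrom pos ref alt` dialect with 1-based positions; an optional
header line is auto-detected. Only single-nucleotide A/C/G/T variants are
kept; multi-allelic sites are split; skipped records are counted and
logged. Flanking context always comes from the reference FASTA, never from
the variant file, and a disagreement between the stated ref allele and the
reference base is an error by default (silent mismatches corrupt
signatures; `on_mismatch="skip"` downgrades them to counted exclusions).
Contexts containing N are excluded and counted.

Each SNV is pyrimidine-normalized: purine refs are complemented and their
context reverse-complemented, so the mutated base is always C or T. The
strand feature compares the pyrimidine-carrying reference strand σ with the
transcript strand τ of a BED6 annotation (0-based half-open on disk,
1-based inclusive internally): *plus* when σ = τ, *minus* otherwise,
*undefined* for uncovered positions or positions covered by transcripts on
both strands. When the model uses the strand feature, undefined-strand
mutations are excluded from the profile (and counted); this restricts the
catalog to regions with a defined transcription strand. The σ = τ
convention only fixes the order of the two strand entries; profiles and
signatures built with the same convention are mutually consistent.

## The refitting quadratic program

Exposures minimize ‖g − S·w‖² over the probability simplex. The solver
works on the equivalent form −gᵀS·w + ½·wᵀ(SᵀS)·w. Because SᵀS can be
singular (duplicate or linearly dependent signatures), it is first replaced
by its nearest positive definite matrix: eigenvalues below a floor of
1e−8 × the spectral norm are clipped to that floor and the matrix
reassembled (with a growing diagonal jitter in the — never yet observed —
event that Cholesky still fails). A matrix already positive definite is
returned *unchanged*, which is why the correction is exactly zero for
full-rank signature sets. The correction is a numerical device only: the
reported residual sum of squares and explained variance are always
evaluated against the original, uncorrected S.

The strictly convex QP is then reduced to non-negative least squares:
with L the Cholesky factor of the corrected Gram matrix and z = L⁻¹Sᵀg,
minimizing ‖Lᵀw − z‖² over w ≥ 0 reproduces the quadratic form, and the
simplex equality is enforced by appending the row λ·1ᵀw = λ with weight
λ = 1e4. The active-set NNLS solve (scipy) is exact for the penalized
problem; the equality-constraint bias is O(λ⁻²) ≈ 1e−8 and removed by a
final renormalization. Weights below 1e−8 are clamped to zero (active-set
solvers return tiny values at active constraints) and the vector
renormalized to sum exactly to 1. The solver was validated against a
brute-force simplex-grid oracle (step 1e−3, agreement within 2e−3 per
weight on random instances) and recovers exact in-span mixtures to
better than 1e−6.

## Explained variance and subset selection

R² = 1 − Σᵢ(gᵢ−ĝᵢ)² / Σᵢ(gᵢ−refᵢ)², with ĝ = S·w. The baseline ref is the
*flat genome*: for the Alexandrov model the uniform 1/96 vector, which
equals the mean of g (so this is the textbook coefficient of
determination); for the Shiraishi model the mean is not a valid baseline
because the features have different state counts, so the flat genome with
1/6, 1/4 and 1/2 per state replaces it. A profile equal to the flat genome
makes the denominator zero and is rejected explicitly. R² can be negative
when the fit is worse than the flat baseline.

Subset selection enumerates all C(K, k) subsets for k from
`min_num_signatures` (default 2) to `max_num_signatures` (default K),
refits each, and stops at the first k where the best subset reaches the
requested explained variance — returning, at that k, the subset with the
highest R² (the choice among threshold-reaching subsets is otherwise
underdetermined; ties broken by lexicographic signature order for
determinism). If no subset reaches the threshold the overall best result is
returned flagged `threshold_reached=False`. The per-size best R² curve is
monotone non-decreasing in k, since any subset embeds in a superset with
zero weights. Exhaustive enumeration is capped at 200,000 combinations per
size (K = 30 at mid-range k is astronomically larger); past the cap the
caller must opt into greedy forward selection, which is a heuristic and may
miss the optimal subset.

## Distances and set mapping

Signature distances operate on identically-shaped representations:
Frobenius (Euclidean on the flattened parameters), L1 and cosine distance.
Mapping one signature set onto another offers *nearest* (independent
argmin, many-to-one allowed), *one_to_one* (injective assignment minimizing
the total distance, solved as an optimal linear assignment via the
Hungarian algorithm — chosen over greedy sequential matching because
"minimum distance" alone does not prescribe a tie-handling order), and
*greedy* for reproducing sequential matchers. Pairwise distance summaries
report the unbiased (n−1) standard deviation.

## Simulated genomes

A simulated tumor of n mutations draws each mutation's signature from the
exposure vector and then the mutation's features from that signature; for
the independent-feature model each feature row is sampled independently,
exactly as the model assumes (no attempt is made to emulate within-genome
feature linkage, which the factorized model cannot represent anyway). The
implementation aggregates the draws as nested multinomials — per-signature
assignment counts, then per-row feature counts — which is distributionally
identical to per-mutation sampling and fast at any n. Simulated profiles
are refit against the full signature set and the absolute deviations of
fitted from true exposures summarized by median/90th/99th percentiles,
split into driving and non-driving signatures.

The default study conditions mirror the standard recovery experiment: 15
signatures over a quintet-plus-strand context; one driving signature at
exposure 0.8 with the remaining 0.2 uniform over the other 14 (multi-driver
designs at 0.5/0.3, 0.4/0.25/0.15 and 0.3/0.2/0.1/0.1 are available through
`make_exposures`); mutation counts of 100, 200, 770 and 2334 per genome;
1000 genomes per driving signature. The reference signature sets such
experiments were originally run on came from de novo inference over large
tumor cohorts and are not published as tables, so the harness substitutes
random well-separated signatures: each feature row is drawn from a sparse
symmetric Dirichlet (concentration 0.5, favouring the peaked rows real
signatures have), and the set is redrawn until all pairwise Frobenius
distances exceed 0.4 — comparable to the spread of real converted
catalogs, whose mean pairwise distance is around 0.8. Recovery results on
these synthetic sets therefore test the method's error envelope under
realistic separation, not the exposures of any real cohort; profiles built
from real tumors additionally face off-model variation (feature linkage,
catalogs not in the signatures' span) that the simulation deliberately
omits. At the 2334-mutation condition the acceptance script uses 200
genomes per driver instead of 1000, a problem size chosen to keep the full
four-quantity recomputation in seconds at unchanged Monte-Carlo stability
of a median over 3000 genomes.

Reproducibility: one global seed; each genome uses the independent
substream `default_rng([seed, condition, genome_index])`, so any single
genome can be regenerated in isolation.

## Synthetic fixtures

The fixture generator produces random A/C/G/T reference sequences and SNV
records whose ref alleles are read from that reference (alt uniform over
the other three bases, positions kept clear of sequence ends so context is
always available), written as matching VCF and MPF files; random stranded
BED6 annotations complete the inputs. These fixtures exercise every parser
and the featurization path without external downloads; they make no claim
to realistic mutation spacing, trinucleotide composition bias, or
transcript structure.

## Known limitations

* De novo signature inference is out of scope; the package refits known
  signatures only.
* Indels, MNVs and structural variants are ignored everywhere.
* Exposures come without uncertainty estimates (no bootstrap or
  posterior); deviations reported by the simulation harness are the only
  calibration aid.
* The greedy subset fallback is a heuristic; exhaustive search beyond the
  combinatorial cap is refused rather than silently approximated.
* The COSMIC v2 conversion-distance check requires the external COSMIC
  probability table (see README); everything else runs self-contained.
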