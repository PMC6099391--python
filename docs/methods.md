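# Methods

This note records, in one place, the statistical and algorithmic choices the
package makes. Modules are referenced by name; every default named here is a
plain keyword argument that can be overridden.

## 1. Peak statistics (`chromatogram`)

A Sanger trace is modelled as an `(L, 4)` array of per-position channel
intensities (A, C, G, T) plus the base calls, where each call must be the
argmax of its row. At a query site, three intensities are read:

- `I1` — the tallest channel at the site (the called base);
- `I2` — the second-tallest channel at the site (the putative additive base);
- `I0` — the background level, estimated as the mean of the *second-tallest*
  channel over a window of ±5 positions around the site, with the query site
  itself excluded.

From these, two ratios are formed:

- **S-value** `= I2 / (I1 + I2)` — the relative weight of the secondary peak;
- **N-value** `= I0 / (I0 + I1)` — the relative weight of ordinary baseline
  noise at a peak of the same height.

Both are scale-invariant (multiplying all intensities by a constant leaves
them unchanged) and bounded: `S ≤ 0.5` because `I1 ≥ I2` by construction.
Excluding the query site from the `I0` window matters: at a genuinely
additive site the secondary channel is elevated, and including it would
inflate the noise estimate exactly where the comparison must be sharpest.

## 2. Additivity decision (`additivity`)

A site with a visible secondary peak is accepted as carrying a real additive
nucleotide (a heterozygous double peak) by a two-branch rule over `n`
replicate sequencing runs:

1. **Direct confirmation** — the replicate mean S reaches 0.15. At this level
   the double peak is unmistakable and no test is needed.
2. **Confirmation by test** — a two-group one-way ANOVA of the replicate
   S-values against the replicate N-values is significant at `alpha = 0.01`
   *and* the mean S exceeds the mean N. With two groups the ANOVA is
   identical to the pooled-variance t-test (`F = t²`); the directional guard
   is required because the test is two-sided, while only an S *above* the
   noise band can indicate an additive base.

Anything else is `not_confirmed`. Two identical zero-variance groups are
assigned `p = 1` by convention (constancy detected by range, not by floating
`std`, which is nonzero for constant inputs like `[0.1, 0.1, 0.1]`).

Before any testing, a position must pass a **two-strand candidate screen**:
its per-position secondary ratio must exceed `min_secondary = 0.13` on both
the forward and the reverse trace of the same region. Under the packaged
noise model the per-position secondary ratio of a pure-template trace is
about 0.107 ± 0.007, so 0.13 sits more than 3 noise SDs above the baseline
while staying below the smallest hybrid ratio the panel reports (16.47%).
Requiring both strands suppresses strand-specific artefacts.

## 3. Mixed-template calibration and detection limit

The simulator (`synthetic_data.simulate_sn_replicates`) draws replicate
(S, N) pairs at a chosen minor-template fraction `f` from truncated normal
distributions on [0, 1] with

- `E[S] = 0.905 · f + 0.025` (replicate SD 0.015),
- `E[N] = 0.0991` (replicate SD 0.011),

moments fitted to a six-point calibration series at
f ∈ {10, 15, 20, 30, 40, 50}%. `calibration_table` applies the decision rule
(5 replicates, `alpha = 0.01`) at each fraction; the **detection limit** is
the smallest significant fraction. A single run is seed-dependent near the
boundary, so `detection_limit_over_seeds` reports the majority verdict over
≥ 20 independent seeds; the stable answer is **15%**, with 10% remaining
indistinguishable from noise.

The S-value of a confirmed peak, in percent, is the **hybrid ratio**: the
share of the minor repeat type in the specimen's rDNA array. Ratios are
summarised as replicate mean ± sample SD (`ddof = 1`), and per-type averages
over the 46-specimen panel are plain group means at sites 122 and 226.

## 4. Sequence model and genotyping (`synthetic_data`, `genotyping`)

All sequences live on a 655-nt ITS coordinate system: ITS1 (1–257),
5.8S (258–420), ITS2 (421–655). Four boundary motifs (`TCGAA` at the start,
`TCCGACC` at the end, `AAACGACTCT` / `CGTCACGC` delimiting 5.8S) let
`its_regions.extract_regions` recover the regions from any flanked read.
The packaged reference is the homozygous baseline haplotype: 655 nt, exactly
397 G+C (60.61%), with fixed alleles C/G/C/G at the four variable sites
122/135/226/500; the remaining positions are seeded filler generated under a
G+C rejection sampler, so the reference is deterministic per seed.

The thirteen named ITS types are defined entirely by their genotypes at the
four variable sites. Four are homozygous pure lines; nine are cultivar types
carrying one or two heterozygous (two-base) sites, written with IUPAC codes
plus, where known, the major/minor peak orientation (e.g. `Y(T>C)`: C→T
polymorphism with T under the taller peak). G+C of a rendered type sequence
counts ambiguity codes as **neither** G nor C; this single convention
reproduces every published per-type value (e.g. 60.31% and 60.46% for the
two types differing from baseline by one and two ambiguous sites).

`assign_type` matches a four-site genotype within a species context,
comparing orientation only where both sides define it; no match returns
`"novel"`, and a genotype compatible with several types (possible for
double-heterozygotes typed without orientation) raises rather than guesses.

## 5. Parental-lineage inference

A cross between two (possibly heterozygous) parents can produce a target
type if, at every variable site independently, one base from each parent's
composition reproduces the target composition. `infer_single_cross`
enumerates all unordered pure-line pairs (self-pairs included) against this
rule and is verified in the tests against a brute-force gamete-product
oracle. `enumerate_two_step` chains two generations
(line × line → intermediate, intermediate × line → target); a homozygous
target needs no hybridization and yields no chains.
`hypothetical_missing_parent` solves for the minimal unsampled homozygous
partner when no sampled pair works, and its output is always labelled
hypothetical.

## 6. Phylogeny (`phylogeny`)

Distances are IUPAC-aware p-distances: the per-site mismatch between codes
with allele sets `A`, `B` is `1 − |A ∩ B| / max(|A|, |B|)` (so `C` vs `Y`
counts ½), averaged over the alignment; a Jukes–Cantor correction is
optional. Trees are built with neighbor joining (negative branch lengths
clamped to zero); the implementation is validated by exact recovery of 200
random additive trees. Bootstrap support resamples alignment columns via a
precomputed per-site mismatch tensor, so 1000 replicates over 13 × 655
sequences run in under a second; supports annotate the internal nodes of the
full-data tree. Note that NJ topology is only unique when the Q-criterion is
tie-free; the 13-type matrix contains ties, so only tie-robust features
(such as the two-type cherry of the outgroup species, supported at ~71%)
are asserted.

`clade_partition` cuts the single internal edge that best isolates a
reference label set (smallest side containing all references, with a
logged best-agreement fallback). On the 13-type tree, partitioning on the
two outgroup-species types cleanly splits them from the other eleven
haplotypes — the two-clade structure of the analysis.

## 7. Reproducibility

Every stochastic routine takes an explicit seed or `numpy` Generator; the
pipeline driver (`report.run_pipeline`) derives all randomness from one root
seed and writes only text artefacts (TSV, FASTA, Newick, PHYLIP, YAML),
byte-identical across reruns of the same configuration. Derived seeds are
kept below 2³¹ for portability.
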