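# Methods

## Coordinate frame

Every transcript is handled in a local, 1-based coordinate frame whose +1
is the annotated transcription start site (the cap nucleotide). A fixed
upstream extension (default 100 nt, positions −100…−1) absorbs cap sites
that fall upstream of the annotation; position 0 does not exist, and all
nucleotide arithmetic (offsets, windows) steps over it. The frame is
enforced once, at file-reading time — downstream code never sees an illegal
position. The four analysis regions partition the frame exactly: upstream
[−ext, −1], 5′UTR [1, u₅], CDS [u₅+1, L−u₃], 3′UTR (L−u₃, L]; a transcript
with u₅ = 0 starts its CDS at +1.

## Normalization and MaxSeqs

Raw tag counts are scaled to TP20M, `a = c · 2×10⁷ / N`, where `N` is the
**manifest** depth of the library, not the sum of profiled counts — depth
includes tags mapping to transcripts outside the analysis set, which is how
degradome libraries are normalized in practice. The MaxSeq of a
(library, transcript) pair is the argmax of its sparse profile; ties break
to the 5′-most position, making the result deterministic and independent of
map iteration order (exact ties are a measure-zero event on real data). An
empty profile yields no MaxSeq rather than a zero-abundance placeholder.

## Cap sites

C-PARE profiles are summed position-wise across all C-PARE libraries
(genotypes pooled — cap-site architecture is a property of the transcript,
not the decay genotype; a per-genotype comparability check is available by
calling with a library subset). The summed-profile MaxSeq is the cap site.
The offset from the annotated TSS is classified precise (0), within +25 nt,
upstream (< 0) or other (> 25). The minimum-evidence rule is an explicit
parameter; by default a call needs the TP20M equivalent of 5 raw tags in
the smallest C-PARE library, which forbids single-tag cap calls while
adapting to library depth.

## Substrate callers

All three callers are per-mutant threshold rules with a WT fold-change
denominator, followed by intersection across the two mutant alleles.

* **WT reference.** The denominator is the mean TP20M of the two WT
  replicate libraries of the same polyA fraction at the position (or
  window), floored at the mean TP20M equivalent of one raw tag per
  replicate. The floor makes division by zero impossible and means "absent
  in WT" is treated as "at most ~1 tag deep", a deliberately conservative
  choice for fold changes.
* **Decapped intermediates**: mutant MaxSeq exactly equal (integer
  equality, no tolerance) to the cap position, abundance ≥ 10 TP20M, fold
  ≥ 5. The ±25-nt window applies only to cap-vs-annotation offsets, never
  to MaxSeq-vs-cap matching. Transcripts without a cap-site call are not
  evaluated and are counted separately in the diagnostics.
* **3′ fragments**: mutant MaxSeq in CDS or 3′UTR and not at the cap,
  abundance ≥ 20 TP20M, fold ≥ 2; restricted to polyA+ libraries by
  default, where essentially all such fragments are observed. Mutant
  intersection requires the identical site in both alleles.
* **Cleavage sites**: abundance is the TP20M **sum** over site ± w
  (default w = 1 nt; sum rather than max, because the sum is monotone in
  window width and w = 0 degenerates to the exact-position rule), compared
  against the same-window WT reference; thresholds ≥ 10 TP20M and
  ≥ 1.5-fold.

Raising any threshold can only remove calls (the callers are antitone in
every threshold field); this is asserted by property tests over random
datasets. polyA+ and polyA− call sets are computed and reported separately,
never merged implicitly.

## Overlap statistics

The Monte-Carlo overlap test draws, per permutation, two fresh uniform
random subsets of the universe matching the observed set sizes, and records
their intersection. Re-sampling both sets (rather than fixing one) matches
the symmetric description of the null; either way the null mean is the
hypergeometric expectation |A||B|/N, which the test suite uses as an
independent oracle. The z-score is (observed − mean)/sd of the permutation
distribution (undefined when the sd is 0, e.g. saturated overlaps), and the
empirical p-value uses the add-one rule (1 + #{perm ≥ obs})/(n + 1), so it
is conservative and never exactly zero. Default 10,000 permutations.
Elements outside the stated universe are dropped with a warning — the
universe is an explicit argument because enrichment conclusions depend on
it (e.g. restricting to transcripts with cap-site information).

## Half-lives and assay formulas

Decay fits are OLS of ln(abundance) on time after renormalizing to the
t = 0 point (so raw band or qPCR intensities are acceptable inputs).
`k = −slope`; `t½ = ln 2 / k` using full-precision ln 2 (the familiar
0.693 is the rounded constant; the difference is far below any tolerance
used here). Non-positive abundances are excluded before the log transform;
fewer than three usable points refuses the fit with a diagnostic rather
than returning a degenerate estimate, and the number of points used is
reported. A non-positive fitted k yields an infinite half-life, never a
negative one. Stabilization against a reference condition is classified
only for transcripts with reference t½ ≤ 240 min (shutoff courses are
uninformative for very stable RNAs) and requires a ≥ 1.5× longer test t½.

Chlorophyll content is the closed form (22.12·OD₆₅₂ + 2.71·OD₆₆₅) ·
dilution, normalized per g fresh weight; relative qPCR quantification is
2^−ΔΔCt.

## Synthetic data: what it emulates and what it does not

The generator emits the full study layout: two WT replicates and two
mutant alleles in both polyA fractions (8 PARE libraries), two C-PARE
libraries, a manifest, planted cleavage sites and a truth table. Per
transcript it plants, by class: an amplified cap peak in the mutant
alleles (decapped substrates, routed to polyA− with probability 0.6 and
polyA+ otherwise), a CDS cleavage-site peak or a 3′UTR fragment peak
amplified in mutants in polyA+ only, over a low exonucleolytic background
ladder; every transcript gets a dominant C-PARE cap peak. Counts are
negative binomial (gamma-mixed Poisson) with configurable dispersion;
manifest totals are the profiled counts plus a 10% unprofiled remainder so
TP20M normalization against manifest depth is genuinely exercised.

Default scenario sizes: 2,000 transcripts, ≈ 5×10⁵ profiled tags per
library, 8-fold cap-peak amplification, 40 expected WT tags at a planted
substrate's cap, dispersion θ = 200. The WT peak depth and dispersion were
set by a power calculation: under TP20M normalization the mutant libraries
are ~11% deeper than WT (they contain the amplified peaks), so the
realized fold of a planted 8-fold effect is ~7.2, and the per-mutant
probability of falling below the 5-fold threshold must be kept ≪ 1% for the
scenario to behave as a strong-effect benchmark. θ = 200 corresponds to
mild overdispersion near the sequencing-sampling limit for counts at a
fixed site; heavier biological dispersion can be configured, at the cost of
recall at fixed effect size. These sizes also keep the full pipeline under
two minutes on one CPU.

The generator does **not** emulate: sequence-level reads (the input
boundary is tag counts), multi-mapping ambiguity, positional biases of
library construction, correlated biological replicate structure beyond the
shared planted means, alternative TSS heterogeneity within a transcript, or
secondary cap peaks. Passing the planted-truth tests therefore shows the
rules and plumbing are correct under the stated noise model, not that the
thresholds are optimal for any particular real library.

Decay time courses are exp(−kt) with multiplicative lognormal noise of
unit mean and given CV, sampled at 0/15/30/60 min by default.

## Numerical and design choices

* Tie-breaks: all argmax operations choose the 5′-most position.
* The WT pseudocount floor is expressed in raw tags (default 1) and
  converted per replicate, so it adapts to library depth.
* Cap-site calling pools C-PARE genotypes by default (one cap per
  transcript; secondary peaks are out of scope).
* Intersections: decapped and cleavage calls intersect by transcript
  (their positions are shared by construction); fragments by exact site.
* Whether the minimum-abundance rule should be evaluated per mutant
  library (as here) or against pooled WT is exposed through the caller
  inputs: callers accept any MaxSeq map, so replicate-merged variants can
  be supplied via `merge_replicates`.
* All pipeline outputs are sorted and written with fixed float formatting;
  no timestamps — reruns with the same config and seed are byte-identical.

## Known limitations

* One cap site per transcript; transcripts with genuinely heterogeneous
  TSS usage are summarized by their dominant C-PARE peak.
* Multi-transcript attribution of tags is delegated to the upstream
  counting (the profile table is the input boundary).
* The half-life fit assumes single-exponential decay; biphasic decay is
  summarized by the best single rate, visible as reduced R².
* Overlap tests report per-comparison p-values without multiplicity
  correction, matching the per-comparison star convention used in this
  kind of analysis.
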