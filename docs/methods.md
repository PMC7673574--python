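# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, and what the synthetic data do and do not establish.

## Distances

Distances are raw (uncorrected) proportions of differing sites — the "p
distance" — with **pairwise deletion**: a column contributes to a pair only
when both sequences carry an unambiguous `A/C/G/T` there. IUPAC ambiguity
codes are treated as missing alongside `-`, `N` and `?`, because the
barcode analysis turns on exact identity calls and an ambiguous base can
neither confirm nor refute identity. No substitution-model correction is
applied anywhere: the quantity of interest is "zero differences observed",
and model corrections are monotone in the raw distance, so they could only
rescale, never reorder, the minima.

A pair is **undefined** when fewer than `min_overlap` sites could be
compared (default 100). The default guards against spurious zero distances
between barely-overlapping partial sequences; with ~1.3 kb sequences whose
partial reads cover one half, real overlaps are either 0 or several hundred
sites, so any cutoff in between behaves identically. Undefined pairs are
stored as NaN and excluded from minima — never silently zeroed. Distances
are exact rationals (`int / int` evaluated in double precision), so the
failure test `D_min == 0` involves no epsilon.

A site is parsimony-informative iff at least two distinct unambiguous bases
each occur in at least two sequences at that column.

## Barcode gap

The scoring unit is the **terminal taxon** (species or infraspecific
terminal). For taxa with several specimens the minimum is taken over all
cross-taxon specimen pairs, not over centroids; conspecific pairs are never
considered. Nearest-taxon ties are broken lexicographically and all tied
names are retained. Taxa whose every interspecific pair is undefined are
flagged unscorable and excluded from the failure-rate denominator.
Non-native taxa can be excluded before scoring, mirroring survey practice
of restricting barcode evaluation to the native flora.

For multi-flora comparisons the distance matrix is computed once on the
combined alignment; because pairwise deletion makes each pair's distance a
function of that pair alone, subsetting the matrix to one flora's
specimens is exactly equivalent to rebuilding it from a subset alignment
(a property the tests assert). Floras with fewer than two taxa are skipped
with a warning.

The histogram of minima uses left-closed bins (default width 0.005) with
zero-distance taxa reported as their own category, since "exactly zero" is
a qualitatively different event from "small".

## Richness

Estimation is incidence-based throughout (Hill number q = 0 only); the
sampling unit is the collection day. Interpolation uses the exact
hypergeometric expectation

S(t) = S_obs − Σ_i C(T−Y_i, t) / C(T, t),

evaluated with exact integer binomials. Chao2 uses the bias-corrected form
with the (T−1)/T factor. Extrapolation is
S(T+t*) = S_obs + Q0_hat · [1 − (1 − Q1/(Q1 + T·Q0_hat))^{t*}], flat at
S_obs when Q1 = 0. The curve is evaluated at integer knots, default every
unit to endpoint 2T (the common rarefaction/extrapolation plotting
convention); the asymptote is reported separately.

Confidence intervals are a **unit-resampling percentile bootstrap**
(default B = 1000, level 0.95): days are resampled with replacement,
species undetected in a replicate are dropped, and the full curve plus the
Chao2 asymptote are recomputed per replicate. This is deliberately simple
and deterministic for a fixed seed; it is *not* the analytic
bootstrap-variance construction some richness software uses, so interval
widths are not comparable across implementations even when the point
estimates agree exactly.

## Tree and monophyly

Neighbor joining follows Saitou–Nei with the Q-criterion. Two conventions
make topologies reproducible on matrices full of identical sequences: ties
on Q are resolved toward the lexicographically smallest cluster-label pair
(a cluster is labelled by its smallest leaf id), and negative branch
lengths are clamped to zero with the deficit moved to the sister edge so
the pair's summed length is preserved. Zero-length internal edges are kept,
not collapsed: monophyly is read off the resolved binary tree. Midpoint
rooting breaks ties on the longest leaf-to-leaf path toward the
lexicographically smallest leaf pair; an all-zero-length tree is rooted on
its first internal edge with a warning.

The screen classifies single-specimen taxa as `trivial` and a
multi-specimen taxon as monophyletic iff its specimens' smallest containing
clade holds no other taxon's specimen. This is a *screen on a distance
tree*: it carries no support values, and taxa separated by a handful of
substitutions can legitimately interleave on such a tree even when a
likelihood analysis with support thresholds would withhold judgement.
Specimens that cannot be placed (undefined distances from opposite-half
partial reads) are pruned greedily — fewest removals, deterministic
tie-break — before tree building, and the pipeline then assesses monophyly
over the specimens present.

## Synthetic floras

The generator emulates the statistical structure the analyses assume:

- **Species tree**: a Yule (pure-birth) tree, rescaled so the root-to-tip
  depth equals `subst_rate` expected substitutions/site (default 0.08,
  giving mean pairwise distances of a few percent to ~15%, the range seen
  in plastid barcodes of a diverse fern flora).
- **Sequences**: Jukes–Cantor evolution over 1,309 bp (the *rbcL* barcode
  length). Equal rates and uniform base composition are deliberate: the
  generator's job is to produce identical-versus-distinct haplotypes with
  controlled structure, not realistic codon evolution. No indels are
  simulated; partial sequences (default 1.5% of specimens) are represented
  by masking the 5' or 3' half.
- **Failures**: `n_failure_pairs` (default 15) designated taxon pairs have
  the second taxon's haplotype overwritten by the first's — the
  maternally inherited plastid of a hybrid. The designated pairs are the
  truth set; any *accidental* identical cross-taxon pair triggers a
  re-draw, so `failure set == truth set` is a generator contract (with a
  bounded retry and an explicit error when the configuration cannot
  satisfy it, e.g. too many species on too few sites).
- **Specimens**: one specimen with probability 0.8, else 2–5; the first
  specimen carries the exact haplotype, extras at most one private
  mutation.
- **Incidence**: each species' daily detection probability is drawn from
  Beta(2, 2) and days are independent Bernoulli trials over T = 37.
  Species never detected are dropped from the alignment, checklist and
  incidence matrix — the survey sees only observed species — but remain in
  the truth record's true richness, which is what makes the Chao2 recovery
  test meaningful. Designated failure taxa are conditioned on detection so
  the truth set always survives into the outputs.
- **Defaults** mirror the target survey's shape: 176 species, 37 days,
  ~260 specimens, ~17% failure rate.

`simulate_three_floras` draws three floras from one shared pool tree so
cross-flora distances are on a common scale. Tip selection is biased per
flora: *island* takes tips with the largest nearest-neighbour patristic
distance (immigrant lineages that diverged elsewhere), *continental* takes
shallow cherry pairs (in-situ radiation), *mainland/none* samples at
random; per-flora hybrid pairs are injected among private species. Here
extra natural zero-distance pairs are allowed — they are the island/
continental signal itself — so only the designated pairs are guaranteed,
not exclusive.

What passing tests on synthetic data do **not** show: robustness to real
alignment pathologies (misalignment, chimeric contigs, heterogeneous
missing-data patterns), rate variation across sites and lineages, base
compositional bias, or the behaviour of the monophyly screen relative to a
supported likelihood tree.

## Reporting conventions

Rounding is half-up and happens only at the presentation layer: one
decimal for percentages, two for species per hectare. Habit percentages
are per-terminal-taxon counts over the terminal total, so multi-habit taxa
push the column sum past 100%. The fern/lycophyte split reports
species-level counts with the percentage likewise taken over the terminal
total — the convention of the survey tables this module reproduces, where
varieties are few and the species/terminal distinction is noted in the
caption; both species- and terminal-level counts are stored. Lycophytes
are recognised by family membership (Lycopodiaceae, Selaginellaceae,
Isoetaceae).

The pipeline writes machine-readable TSV/JSON only (plot-ready, no
figures), plus a manifest with the package version, seed, parameters and
SHA-256 input checksums; outputs contain no timestamps, so identical
inputs and seed reproduce byte-identical reports.

## Test and acceptance problem sizes

Property checks run against independent oracles at sizes chosen for a
fast, deterministic suite: 1,000 random fixtures for the p-distance and
parsimony-informative brute-force comparisons; exhaustive subset
enumeration for rarefaction at T ≤ 8 (tolerance 1e-9); 10 random additive
trees for NJ recovery; 50 random labelled trees for the monophyly oracle;
100 seeded replicates (30 species × 800 bp) for the failure-set truth
check; 200 incidence replicates at the survey scale (250 species, T = 37,
Beta(2, 2) detection) for Chao2 recovery; 50 replicates of the three-flora
contrast. The acceptance script runs the full synthetic survey at the
default scale with a 200-replicate bootstrap.
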