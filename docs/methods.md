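# Methods

This note documents the models, numerical policies and design choices
behind `supersage`, and what the simulator does and does not emulate.

## The counting model

A SuperSAGE library is a multiset of 26-nt tags anchored at the 3'-most
NlaIII site (`CATG`) of each transcript. Two libraries — W (wounded) and
F (elicitor-treated) — of unequal depths `N1`, `N2` are compared tag by
tag. All inference is *relative*: a library only measures each
transcript's share of the total, so normalized counts (copies per
million, or per 100,000) are compositional. This matters below.

Terminology: a tag seen exactly once across both libraries combined is a
**singleton**; a tag seen at least twice is a **UniTag**. Singletons are
kept in the library totals and in normalization but excluded from
differential testing — a single observation carries no comparative
information and is very often a sequencing artifact. Abundance classes
partition copies-per-million at 100 / 1,000 / 5,000 into low / mid /
high / very high. The class boundary convention is "≤ 100 is low": where
a report's row label and its running text disagree on `<` vs `≤`, the
inclusive reading is used consistently here.

## The Audic–Claverie test

For a tag with counts `x` (of `N1`) and `y` (of `N2`), both counts are
modeled as Poisson with a shared underlying rate; integrating the rate
out gives the conditional mass

    p(y | x) = r^y (x+y)! / ( x! y! (1+r)^(x+y+1) ),   r = N2/N1,

a negative binomial in `y` with `x+1` successes and success probability
`1/(1+r)`. Implementation policy:

* all factorial terms go through `scipy.special.gammaln`; nothing
  overflows at any library depth;
* the lower tail `P(Y ≤ y | x)` is a log-sum-exp over `y+1` terms
  (exact to machine precision);
* the upper tail is taken as `1 − P(Y ≤ y−1)` when that complement is
  large, and otherwise summed directly term by term — successive term
  ratios converge to `r/(1+r) < 1`, so the remaining mass is bounded by
  a geometric series and summation stops when that bound falls below
  1e-12 of the accumulated sum. This keeps *relative* accuracy in the
  minor tail, which is the one that decides the p-value;
* the two-sided p-value is `min(1, 2·min(lower, upper))`; one-sided
  variants (`sided="less"/"greater"`) are exposed;
* p-values are clamped into `(0, 1]` (floor 1e-300) so volcano
  coordinates stay finite.

Against an exact rational-arithmetic oracle (`fractions.Fraction`,
recurrence `p(k+1|x) = p(k|x)·q·(x+k+1)/(k+1)`), the log-space
implementation agrees to ~1e-12 relative error over the full grid
`x, y ≤ 50` at depth ratios from 1:1 to the reference libraries' ratio.

Two properties worth knowing:

* **The doubled-tail p-value is not exchange-symmetric.** Swapping
  `(x, N1) ↔ (y, N2)` changes the conditioning variable; at the pmf
  level the swap multiplies the mass by `r`, and the doubled-minimum-
  tail p-values differ (e.g. `x=2, y=0, N1=N2` gives 0.25 one way and
  0.50 the other). The package fixes the convention: `x` is always the
  W count, `y` the F count. At the symmetric point `x=y, N1=N2` both
  tails hold at least half the mass and the p-value is 1.
* **The test is discrete and therefore conservative at small counts.**
  With `x+y = 6` and `N1=N2` the most extreme split (6:0) has a
  two-sided p of 0.089 — significance at 0.05 is unreachable. On null
  simulations where the average UniTag carries ~6 combined counts
  (5,000 UniTags over 31,200 tags) the realized size is ~0.01, far
  below the nominal 0.05. This is a property of exact tests on tiny
  counts, not an implementation artifact; the acceptance suite records
  it. At the counts of a full-scale run (~28 per UniTag) the size
  approaches the nominal level.

No multiple-testing correction is applied by default (matching the raw
95% confidence convention of classic SAGE analyses); a Benjamini–
Hochberg option (`bh=True`, cross-checked against statsmodels) is
available.

**Fold change** is computed on the per-100,000 scale as F/W with any
zero replaced by 1 before division — the classic rule that keeps
presence/absence tags finite at the cost of making their fold change
depth-dependent. Calls require both significance and a fold-change
threshold (defaults 2.5 up / 0.4 down), applied jointly.

**Candidate selection** flags tags meeting at least two of: a
significant strong fold change; abundance below 1,000 copies per
million in *both* libraries (regulators are low-abundant — "both" is
this package's reading of the abundance criterion); an annotation as a
known regulatory component (tags without a flag count as
non-regulatory).

## Tag extraction

Read layout (simulator and extractor agree by construction):
`left_linker(8) + tag_a(26) + revcomp(tag_b)(26) + right_linker(8)`,
68 nt total. The linker pairs are fixed package constants per library
(`extraction.LINKERS`); the original read architecture was never
published, so this layout is an explicit stand-in, not a
reconstruction. Filtering rules:

* length below 68 → `incomplete`;
* exact linker match only; a single substitution in a linker →
  `missing_linker` (the filter demands *complete* linkers);
* interior must be exactly 52 nt and split into two CATG-anchored,
  N-free tags (the second reverse-complemented) → otherwise
  `incomplete`;
* within each library, ditags sharing a canonical key — the
  lexicographic minimum of the interior and its reverse complement —
  are collapsed to the first occurrence (`twin_ditag`). Deduplicating
  within library (rather than before demultiplexing) is a documented
  choice; the removal is idempotent.

Every read ends as exactly one retained ditag or one rejection record,
so `reads = retained + Σ rejections` holds on every run and is recorded
in the pipeline manifest.

## The simulator

`synthetic` generates what the analysis needs and nothing more:

* **Transcriptome** — random sequences whose final 26 nt are a planted
  `CATG` + 22 nt tag, with no downstream CATG, so the 3'-most anchor
  always yields a full tag; tags are unique across transcripts.
* **Abundance** — transcripts are allocated to the four abundance
  classes by the configured mixture (largest-remainder rounding);
  within a class, copies-per-million values are drawn log-uniformly
  between the class bounds and water-filled to the class copy budget,
  so each library column sums to exactly 10^6. Default mixture
  (88.4 / 10.2 / 1.2 / 0.2%) and copy budgets (19.8 / 33.2 / 23.6 /
  23.4%) emulate the reference experiment at its full diversity
  (~12,800 transcripts). A mixture is only feasible if the class
  bounds times the class counts can bracket 10^6 — at desk scale
  (~1,000 transcripts) the average transcript must be more abundant,
  so scaled-down runs use `DESK_SCALE_MIXTURE` (60 / 30 / 8 / 2%);
  infeasible combinations fail with an explicit message rather than
  silently distorting classes.
* **Differential expression** — a `de_fraction` of low/mid transcripts
  (where, empirically, essentially all differential expression lives)
  receives fold changes drawn log-uniformly above `de_up_min` (default
  2.5) or below `de_down_max` (default 0.4), the up/down split
  defaulting to 79/21. The F column is then renormalized to 10^6.
  Renormalization is the compositional reality of count libraries: it
  shifts *every* tag's realized ratio by a common factor, so truth
  status (`up`/`down`/`null`) is assigned from the final ratio against
  the thresholds — a drawn fold change near the threshold can end up
  `null`, and null tags share a common true ratio slightly off 1. With
  strong, mostly-up regulation this factor is substantial, and the
  exact test *correctly* detects the resulting relative down-shift of
  unregulated tags; scoring treats those as false positives. This is a
  property of relative counting, not of the test.
* **Reads** — per library, `depth` tag draws (rounded up to even) come
  from one multinomial over the truth means, are paired into ditags and
  wrapped in linkers. Pairing avoids repeating an unordered tag pair
  whenever possible: chance ditag re-occurrence is a real feature of
  deep libraries, but the twin filter would silently discard those
  genuine draws and break exact count conservation, which the test
  suite relies on. In high-concentration regimes (very-high-class tags
  at full depth) some repeats are unavoidable and are then filtered as
  twins — matching the known bias of the twin rule against abundant
  tags.
* **Artifacts** — injected after pairing: PCR twins (duplicate read
  appended, default rate 0.05), incomplete reads (uniform truncation
  below 68 nt, default 0.05), substitution errors (default 0.001/base,
  uniform). Defaults are plausible for 454-era chemistry; homopolymer
  errors, read-length variation and quality decay are deliberately not
  modeled.

One seeded `numpy` generator per simulation call; identical
configurations are bitwise identical, and the pipeline manifest digests
prove it.

What passing simulation tests does **not** show about real data: no
3'-UTR polymorphism between the sample and the annotation database, no
non-uniform error profile, no library-construction biases (PCR
selection, digestion efficiency), and chance twin collisions are
avoided rather than modeled. Recovery numbers from the simulator are
upper bounds for a real run of equal depth.

## Annotation

Each tag is compared ungapped, full length, against every 26-nt window
of every reference on both strands — an exact scan, not a heuristic.
Windows are packed 4 bits per base into two 64-bit words; mismatch
counts are XOR + popcount, so a full scan is a few vector operations
per tag. Hits are tiered 26/26 … 23/26 (0–3 mismatches) and `extended`
(4–6). Reverse-strand hits carry the `minus` prefix on the reference id
and report the forward-strand window offset (0-based). All co-optimal
hits are reported, joined with `" or "` in reference input order.

The original analysis used BLASTN; for a self-contained artifact the
ungapped Hamming scan is used instead, which is the dominant regime of
those BLAST settings for 26-nt queries at ≤ 3 mismatches. Gapped
alignments and e-values are out of scope. The "minimum of 20 nt
matched" rule is ambiguous between *total* agreeing positions (≥ 20 of
26, i.e. ≤ 6 mismatches — the default) and a *contiguous* exact run of
≥ 20 nt (`min_match_mode="contiguous"`); both are implemented, neither
is asserted to be the original's reading. N or other unknown bases in
references encode to a pattern that mismatches every base.

## Comparative ΔCt (qPCR)

Within each sample, ΔCt = Ct(target) − Ct(reference gene); against the
*mean* calibrator ΔCt (samples at the calibrator timepoint, default 0),
ΔΔCt = ΔCt − mean ΔCt(calibrators) and fold = 2^(−ΔΔCt).
Amplification efficiency is fixed at 2, the comparative method's
assumption; efficiency correction is out of scope. Averaging calibrator
ΔCts on the cycle (log) scale makes the *geometric* mean calibrator
fold exactly 1; with identical calibrator replicates every calibrator
fold is exactly 1. Replicate summaries report mean and standard error
(ddof=1) and refuse groups of fewer than two replicates. Using the mean
calibrator ΔCt (rather than pairing each replicate with its own
calibrator) is a documented choice.

## Pipeline and reproducibility

`run_pipeline` chains simulate/parse → extract → count → classify →
normalize → test → annotate → select → report, writing every
intermediate as TSV plus a JSON manifest with the seed, per-stage record
counts (the read → ditag → tag → UniTag accounting) and SHA-256 digests
of all outputs. A stage failure aborts with the stage name. Reruns with
the same configuration are bit-identical.

## Problem sizes used in validation

The validation suite scales the experiment down so the whole suite runs
in minutes: transcriptomes of 300–5,500 transcripts and depths of a few
thousand to 312,000 tags, chosen so that each check runs in its
cleanest regime — statistical checks (test size, recovery) use low/mid-
only mixtures where ditag pairing is collision-free and expected counts
meet the check's assumptions; conservation checks use artifact-free
configurations; the oracle comparisons (exact-rational p-values,
exhaustive annotation scan) run on exhaustive small grids and 1,000
randomized fixtures. The null-size check reports the realized size of
the discrete test at shallow depth (~0.01 at a nominal 0.05; see the
conservatism note above).

## Known limitations

* Replicate-free testing: the Poisson model ignores biological
  overdispersion; calls on real libraries are anticonservative in the
  presence of biological variability (the reason modern designs use
  negative-binomial GLMs with replicates — out of scope here).
* Compositional fold changes: normalized ratios shift globally when
  regulation is asymmetric; no compositional correction is applied.
* The zero→1 fold-change rule makes presence/absence fold changes
  depend on library depth.
* Annotation is ungapped: an indel in the reference shifts the frame
  and can demote a hit that BLAST would recover.
* Linkers and read layout are package conventions, not the original
  instrument's.
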