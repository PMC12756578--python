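# Methods

## Scope and data model

All cistrome statistics operate on a single shared set of fixed-width
(default 400 bp) consensus windows on which both factors (GR, RELA, and
optionally RNAP2) are quantified under every condition (unstimulated `ns`,
glucocorticoid `bud`, cytokine `il1b`, combination `co`). "Overlap" between
cistromes therefore means identity of window id, which makes partition
arithmetic exact; a general ≥1-bp interval mode is deliberately out of the
core path because the partition percentages are only well defined on a
shared window set. Coordinates are 0-based half-open in memory; BED
dialects are honored on disk, and the narrowPeak 10th column is converted
to an absolute summit (offset −1 → absent).

Classification rules are inclusive at every stated boundary: significance
(intensity ≥ 4, log2fc ≥ 1, FDR ≤ 0.05), trend (Δ ≤ −0.5 / ≥ +0.5), DEGs
(|b| ≥ 1, FDR ≤ 0.05), deltas (±1), proximity (≤ 30 kb). These are the
conventions under which the published count identities close exactly, and
they are asserted in tests rather than assumed.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions all calibration suites run under.

**Cistromes.** Windows are placed without overlap, uniformly within each
chromosome (250 kb margins), chromosome chosen proportional to usable
length. Each window carries a joint (GR status, RELA status) label drawn
from a count table — by default a proportional scaling of the
worked-example table in `cistroshift.datasets` to `n_windows` (default
3,000 on a 600 Mb four-chromosome genome; large genome so that TSS–region
distances beyond 30 kb exist at realistic window densities). Statuses are
realized by truncated-normal intensity draws on the appropriate side of the
significance floor — "lost" windows literally move below the threshold on
co-treatment rather than disappearing. Binding intensities and expression
effects carry Gaussian noise on the log2 scale (the conventional surrogate;
no empirical noise model is available). Significant blocks get log2fc and
FDR draws that pass the rule; insignificant blocks fail it through the
intensity floor regardless of their other columns.

**Coupling.** On maintained windows, the co-treatment shift of one factor
is `noise + slope × (other factor's co-treatment intensity, centered)`
(defaults: slope 0.3 each way, noise sd 0.35). The two directions are
built sequentially — GR conditioned on the uncoupled RELA draw, RELA then
on the realized GR co intensities — which is exact whenever one slope is
zero (the configuration the analytic recovery tests use: Pearson r =
s·σx / √(s²σx² + σe²)) and a documented approximation when both are
nonzero. Co intensities of maintained windows are clipped at the
significance floor to preserve planted statuses; recovery tests raise the
occupied-intensity mean so the clip is rare.

**Summits.** A GR anchor near the window center (jitter sd 15 bp) and a
RELA anchor offset by a Laplace(0, 40 bp) displacement, plus small
per-condition jitter; only significant blocks carry summits.

**Expression.** 800 genes, 600 planted mono-upregulated DEGs, five time
points (1–24 h). DEGs get a truncated-normal peak b ≥ 1.1 (mean 2.0, sd
0.5) with FDR ≤ 0.05 at the peak time; the co-treatment b is mono b − 1.5
(baseline repression) + 1.0 if the TSS is within 30 kb of a partner region
+ N(0, 0.5) — the exact near/far distributions N(−0.5, 0.5) vs N(−1.5, 0.5)
the protection-test power analysis assumes. The near indicator is computed
with the pipeline's own nearest-distance routine on the *actual* placement,
so the planted effect and the analysis split always agree even when a gene
aimed far lands near another region. Half the DEG TSSs are aimed within
0.8 × 30 kb of a random partner region and half at 1.5–5 × 30 kb. A
configurable fraction (default 0.15) of genes is independently upregulated
by the other mono-treatment, feeding the exclusion filter.

**Sequences.** Per-window i.i.d. background at a configurable base
composition (uniform default); each window draws one of four categories
(default mix 40/30/20/10% GRE only / NF-κB only / both / neither) and gets
instances sampled from the family PWM embedded at recorded offsets and
strands, non-overlapping. The FASTA uses one record per window id, keeping
sequence size proportional to windows rather than the genome.

**Spots.** Square nuclear mask (4 × 4 µm), per-channel homogeneous Poisson
at 5e-5 spots/nm² (≈ 800 spots/channel, a realistic nuclear STED density);
in paired mode a configured fraction of B spots is planted at a
folded-normal offset from random A spots. Placement is rejection sampling
inside the mask, so arbitrary mask polygons work.

Everything is deterministic under (config, seed); each stage uses
`default_rng([seed, stage])` so stages are independently reproducible.

What the generator does *not* emulate: chromatin background and fragment
pileup shape, replicate structure, dispersion estimation, overdispersed
counts, correlated motif background (i.i.d. only), spot clustering beyond
planted pairing, 3D imaging. Passing tests demonstrate the statistics and
their calibration, not robustness to those real-data features.

## Numerical choices

* **Exact PWM p-values.** Log-odds (log2, pseudocount 0.01 × background)
  are rounded to a 1e-3-bit lattice; position distributions are convolved
  to the full pmf of a background word's score. Scanning uses the *same*
  integer lattice matrix, so scanned scores coincide with the DP support
  and the survival function is exact for every reported hit — verified
  against exhaustive enumeration for widths ≤ 6. Reverse-complement scans
  use a separately calibrated distribution (relevant for asymmetric
  backgrounds). Track score = min(1000, round(−100·log10 p)); the hit
  threshold works in lattice units (smallest score with p ≤ 10^−(t−0.5)/100).
* **Bundled PWMs.** The two shipped motif models are synthetic, built from
  the canonical family consensus (AGAACAnnnTGTTCT; GGGACTTTCC) with 0.97
  consensus-base probability and deliberately unequal off-base
  probabilities, so the score distribution is fine-grained near p = 1e-4
  like an empirical matrix instead of a degenerate consensus filter.
  Database matrices can be supplied in JASPAR format.
* **Nearest distances.** Sorted arrays + binary search with a running
  maximum of interval ends (correct for overlapping regions); the
  `bedtools closest -d` distance convention, cross-checked against
  bedtools itself and an O(n·m) oracle in tests.
* **Summit mode.** The modal short-range separation uses an 8-bp histogram
  over (0, 400] (numpy half-open bins, center reported). The bin width is a
  declared package default — fine enough to separate the ~56 vs ~32 bp
  regimes, coarse enough to smooth single-bp noise — and is recorded in the
  summary output.
* **Rank tests.** Mann-Whitney U two-sided throughout; group-comparison
  tables carry raw p plus Benjamini-Hochberg. The RNAP2-by-trend-group
  comparison is a Kruskal-Wallis omnibus followed by pairwise Mann-Whitney
  with BH (Dunn-style), labeled as such in the output.
* **Co-regulation enrichment** is an exact hypergeometric over the
  expressed-gene universe, reporting both tails; equality with a pmf-sum
  oracle is tested for |U| ≤ 200.
* **Degenerate inputs.** Genes on chromosomes without partner regions
  cannot be "close": they join the far group of the protection split but
  are excluded from mean-distance summaries. Empty protection groups leave
  the test undefined while still reporting group sizes. Percentages of
  empty parent sets are `None`, never 0. Undefined statistics are reported
  as such rather than imputed.

## Design decisions that were genuinely open

* The published "141 RBRs (4.5%)" is ambiguous between denominators
  (141/1,163 = 12.1%, 141/3,106 = 4.5%); the overlap partition reports
  both and adjudicates neither.
* The delta used by the protection test is evaluated at the gene's
  mono-treatment peak time by default (per-time evaluation is available),
  and peak time is argmax-b among significant times with earliest-time
  ties — declared choices where the source procedure is unstated.
* Random regions are count-matched and width-matched to the real set by
  default.
* The randomization null re-places spots under full CSR inside the mask
  (whether the original randomization preserved clustering is unknowable
  from the text); excluded low-density nuclear areas are handled by the
  mask supplied at read time.
* The CLI (`cistroshift simulate|classify|overlap|summits|motifs|degs|
  proximity|protect|coloc|run`) is a thin layer over the library; the
  pipeline report is a single versioned JSON schema with fractions
  emitted raw and 1-decimal rounded.

## Calibration results the suites compute

The acceptance suite re-derives (not asserts from constants): the
worked-example partition arithmetic; protection-test power (≥95/100 seeds
at p < 0.01 under the planted +1 effect), effect recovery (mean near−far
median difference within ±0.15), and type-I error (≤ 0.06 at nominal 0.05
over 200 null seeds); CSR touching fractions within 3 binomial SE of
1 − exp(−λπr²) in ≥ 48/50 seeds with mean standardized deviation below one
SE; motif category mixtures within 3 SE of the planted mix and an empirical
per-position false-hit rate within a factor of two of 1e-4 at track score
400; and byte-identical simulator output under a fixed seed. Problem sizes
(3,000 windows, 800 genes, 50–200 seed batches, 800–2,000 scanned windows)
are the package's chosen defaults for these suites.

## Known limitations

Only linear nearest-feature gene–region assignment (no contact-based
linking); presence/absence motif categories (one best hit per family; no
affinity aggregation); 2D spot analysis; sequential (not simultaneous)
bidirectional intensity coupling; no replicate-level variance modeling —
upstream differential tools own that.
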