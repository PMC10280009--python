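# Methods

## The detection problem

A large introgression — a chromosomal segment transferred from a donor
species (rye, *Thinopyrum*, …) or another homoeologous chromosome into a
crop genome — changes how sequencing reads of a carrier map against the
host reference assembly. Reads from the introgressed segment diverge from
the reference and fail to map there, producing a *deficit* in coverage over
the replaced interval; in a substitution, those reads instead pile onto the
most similar remaining homoeologue, producing a paired *excess*. At the
chromosome scale these signatures are visible even in data far too shallow
for variant calling: genotyping-by-sequencing (GBS) or ultra-low-coverage
WGS at 0.005–0.3× genome coverage.

`introscan` works entirely on **breadth of coverage**: for every fixed-size
window (default 1 Mb) of every chromosome, the fraction of reference
positions overlapped by at least one retained aligned base. Breadth
saturates at 1 regardless of depth, so duplicated reads and uneven library
sizes perturb it far less than depth does. Alignments are filtered with the
SAM FLAG mask 2308 (unmapped + secondary + supplementary) before counting;
CIGAR M/=/X operations cover positions, D/N consume reference without
covering, and MAPQ is deliberately not filtered. Trailing partial windows
are kept and normalised by their actual length, so telomeric ends remain
callable.

## The four-step caller

Let `v_i` be the breadth of window `i` of a sample.

**Step 1 — initial calling.**

* *WGS mode.* Compute the genome-wide median `m` and the median absolute
  deviation over all non-donor windows. A window is seeded when
  `|v_i − m| > k · MAD`, with multiplier `k = 1.5`; the sign of `v_i − m`
  decides between a deficit (LOW) and an excess (HIGH) seed. The MAD is
  scaled by the usual consistency constant 1.4826 by default (so `k·MAD`
  approximates 1.5 standard deviations under normal noise); the constant is
  a parameter, with 1.0 as the documented alternative.
* *GBS mode.* Methylation-sensitive restriction enzymes make GBS capture
  efficiency strongly window-dependent (telomeric/centromeric depletion), so
  a sample cannot be compared with its own genome-wide median. Instead both
  the sample and an external GBS profile of the reference genotype itself
  are normalised by their own median breadth (`s_i = v_i / median(v)`,
  `r_i = u_i / median(u)`), and the relative deviation
  `d_i = (s_i − r_i) / r_i` is thresholded at 20% in magnitude. Windows
  where the reference has zero breadth are uncallable: they are masked,
  never labeled, and break runs. The median normalisation cancels library
  size, and the shared capture-efficiency pattern cancels in the ratio —
  the invariance the simulator's shared-field test verifies.

**Step 2 — seed denoising.** Maximal same-label runs shorter than 5
windows are erased.

**Step 3 — gap filling.** The gap between two neighbouring surviving runs
with the same label is relabeled iff *every* gap window's step-1 deviation
already has the matching sign (sub-threshold but consistent evidence).
Zero or undefined deviations block filling. Note the rule is applied to
the raw step-1 values, not the thresholded labels.

**Step 4 — size pruning.** Maximal labeled runs shorter than 25 windows
are erased; at 1-Mb windows only introgressions of at least 25 Mb survive.
Each surviving run is emitted as one call.

Runs never cross chromosome boundaries at any step, all thresholds use
strict inequalities, and every threshold is a named parameter
(`CallerParams`). The steps are individually idempotent, the composition is
deterministic, and the call set is invariant to multiplying a profile by any
positive constant (median and MAD scale together in WGS mode; the
normalisation absorbs it in GBS mode).

Two deliberate design extensions of the basic procedure: donor chromosomes
of a concatenated reference are excluded from calling entirely (not only
from the median/MAD), since a "call" on a donor chromosome would not be a
host introgression; and the sign conventions of the two modes are unified
into semantic labels LOW/HIGH instead of ±1.

## Downstream analyses

**Donor inference.** Against a concatenated host+donor reference, reads
from an introgressed segment map to the appended donor chromosomes. The
signal for donor chromosome `D` is `median(breadth over D's windows) /
median(breadth over non-donor windows)`. Each LOW call is assigned the
donor chromosome of its homoeologous group (leading digits of the name,
overridable by an explicit map) with the highest signal, if that signal
exceeds 0.2; otherwise "unknown". Donor attribution is usually done by
visual inspection of such profiles; this rule is a reproducible
formalisation of that practice, and reports carry the numeric signal
alongside the verdict so the evidence stays visible. HIGH calls are
reported as host-like duplication candidates and get no donor.

**Missing-subgenome screen.** Per-subgenome medians of breadth; a
subgenome whose median falls below 0.25× the best subgenome's median marks
the sample as lacking that genome (e.g. tetraploid material in a hexaploid
wheat collection). The 0.25 ratio is a calibration point with no canonical
value and is exposed as a parameter.

**Group enrichment.** For each window, samples of two groups are
cross-tabulated by whether any call overlaps the window, and a one-sided
Fisher exact test (hypergeometric survival function, no asymptotic
approximation) asks whether group 1 carries introgressions there more
often. Multiple testing is controlled by Benjamini–Hochberg at α = 0.05 by
default (Bonferroni and none offered); the choice is explicit and recorded
in output. Significant
windows are merged into regions per chromosome, allowing a configurable
number of gap windows (default 0); testing at the window level with
post-hoc merging makes the otherwise vague notion of an "enriched region"
fully reproducible.

**Pair screening.** The distance between two samples' final call tracks is
the per-chromosome count of windows with unequal labels (partial windows
weighted by actual length). A pair is heterogeneous when any single
chromosome differs by ≥ 100 Mb (configurable). Any label mismatch counts,
not only call-present-versus-absent windows — the stricter of the two
plausible readings of "differing profiles". This is a Hamming distance,
hence symmetric with a triangle bound — both property-tested.

## The simulator

Two tiers, both deterministic given a seed:

* **Profile level** — `value = clip(baseline · efficiency · factor +
  ε, 0, 1)` with truncated-Gaussian noise ε. Defaults: baseline breadth
  0.10 (typical of the low-pass regimes targeted), noise σ = 0.01, toy
  genome of 3 subgenomes × 2 chromosomes × 100 windows of 10 kb. LOW
  segments use `factor = similarity` (a donor retaining 30% sequence
  identity-by-mapping leaves 30% of baseline breadth); HIGH segments
  `factor = min(1/similarity, 1/baseline)` so the noise-free value never
  exceeds saturation; a substitution implants LOW plus HIGH on a designated
  homoeologue. In GBS mode a matched reference shares the per-window
  capture-efficiency field (restriction-site landscape is a property of the
  genome, not the sample) but draws independent noise. The efficiency
  field model is cosine-shaped telomere/centromere dips with log-normal
  jitter.
* **Read level** — toy SAM text with packed non-overlapping primary reads
  realising per-window breadth targets to one read-length quantum, plus
  secondary/supplementary decoys that a correct FLAG filter must ignore;
  and a uniform primary-read subsampler.

What the simulator does *not* emulate: read errors, GC and mappability
bias, real repeat structure, alignment ambiguity between homoeologues, and
donor-sequence divergence at base level. Tests passing on simulated data
therefore validate the segmentation machinery and its invariances, not the
mapping behaviour of any particular reference or library protocol.

## Depth titration

The question "how many reads are needed to see an introgression?" is
answered on a read-level simulation: a 40-Mb toy genome (4 chromosomes ×
100 windows of 100 kb), a substitution spanning 50 windows of chromosome
1A whose reads re-map to homoeologue 1B with weight `1 + (1 −
similarity)`, and 100-bp reads placed by weighted sampling. For each
budget in a ladder from 2 000 to 1 024 000 reads, breadth is computed, the
WGS caller runs, and detection means a LOW call covering at least half of
the implanted interval. Each budget uses an independently derived seed.

The windows here are 100 kb (not the 10-kb toy default) so that a
similarity-0.9 deficit — about 4% of breadth at its optimum near 1× read
coverage — stands above per-window read-sampling noise; the segment is
chromosome-arm-scale because that is the size class the titration question
concerns. A distant donor (similarity 0.3) is typically detected from
~4 000–8 000 reads; a very similar donor (0.9) needs two orders of
magnitude more, and in a few percent of replicates a single
positive-noise window inside the segment blocks gap filling and splits the
call below the 25-window minimum even at the highest budget — a real
operating characteristic of the strict all-signs gap rule, not a simulator
artifact.

## Numerical and edge-case choices

* Coordinates are 0-based half-open internally and in BED; window grids
  keep trailing partial windows.
* MAD = 0 with outliers still calls them (any nonzero deviation exceeds
  `k·0`); an entirely constant profile yields no calls.
* A zero-median profile in GBS mode is rejected as unusable rather than
  producing infinities.
* Profile/track TSVs round-trip at full float precision
  (`float_precision="round_trip"` on read).
* Merging and distances treat partial windows by actual base length.
* Fisher p-values come from the vectorised hypergeometric survival
  function and are verified against exact integer enumeration for every
  table with row margins ≤ 30.

## Problem sizes used by the test suite

The default suite and the acceptance script run on toy genomes (hundreds
of windows, kilobase-scale) chosen so that the full pipeline — simulation,
calling, enrichment, titration — completes in minutes on one CPU. The
calling algorithm is window-size-agnostic: nothing in it depends on the
absolute window size, only on window counts, which the toy scales preserve
(5-window seeds, 25-window minimum calls).
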