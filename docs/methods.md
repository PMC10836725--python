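# Methods

This note documents the models, algorithms, defaults and numerical choices
behind each module, what the synthetic generators do and do not emulate,
and the known limitations.

## Coordinates and tiling

All fragment coordinates are 1-based and inclusive, matching how minigene
fragments are conventionally labelled (a "612–1011" fragment is 400
residues). Internally intervals are manipulated as integer pairs; every
`FragmentSpec` carries its sequence and is validated against the interval
length on construction.

`tile_protein(protein, window, min_overlap)` produces the *minimum* number
of fragments of length ≤ `window` covering the protein with adjacent
overlaps ≥ `min_overlap`:

    n = 1                                          if L ≤ window
    n = ⌈(L − window)/(window − min_overlap)⌉ + 1  otherwise

When the leftover `L − window` does not divide evenly over the `n − 1`
junctions, the inter-start steps are `⌊·⌋`/`⌈·⌉` of the average with the
larger steps placed first — i.e. extra overlap is spread as evenly as
possible and the layout is deterministic. All fragments have the full
window length (the alternative — shrinking terminal fragments — would
reduce epitope multiplexing for no benefit). Defaults follow the standard
screen geometry of 400-aa minigenes with 30-aa overlaps, which keeps every
≤ 30-residue epitope intact in at least one fragment.

`refine_fragment` re-applies the same tiling machinery inside a parent
interval with window `⌈(len + (n_children−1)·min_overlap)/n_children⌉`.
Defaults for hierarchical scanning: binary splits, 15-aa overlap at
sub-100-aa levels, 20-aa minimum fragment — the 15-aa overlap preserves
any class II-sized epitope across junctions. When children would fall
below `min_length` the function raises a refinement-exhausted signal and
the caller stops recursing. `epitope_interval` intersects the positive
intervals at the deepest tested level; an empty intersection raises an
inconsistency signal rather than guessing, because disjoint positives
usually mean the parent fragment carries two distinct epitopes and each
branch should be refined separately.

## Constrained backtranslation

The backtranslator is a two-phase sampler/repairer:

1. **Sampling.** Each residue independently draws a codon with probability
   proportional to its relative usage in the codon table (codons below
   `min_codon_frequency` are excluded and the remainder renormalized; the
   default threshold 0 keeps all codons). The packaged table is standard
   human relative codon usage, normalized per amino acid at load.
2. **Repair.** The candidate is scanned exhaustively (`validate_dna`,
   which is also the public validator and shares no bookkeeping with the
   sampler): forbidden motifs on both strands, homopolymer runs, GC and
   pyrimidine fractions in sliding windows of the configured sizes with
   step 1. Only complete windows are evaluated, so sequences shorter than
   a window are unconstrained by it. While violations remain, the earliest
   one is localized; every synonymous single-codon swap overlapping the
   offending span is scored by the number of violations left in a context
   widened by one window on each side, and the best strictly-improving
   swap is applied (ties: higher codon frequency, then alphabetical codon,
   then position). If no single swap improves, the span is resampled from
   the usage distribution to escape the local minimum. The loop is
   deterministic given the seed; if `max_repair_iterations` (default
   2000) is exhausted the function raises an unsatisfiable-constraints
   error naming the stuck window — it never returns a non-compliant
   sequence.

Defaults: GC ∈ [0.40, 0.60] per 50-nt window (the lower bound doubles as
the AT-rich-stretch filter), homopolymer runs ≤ 5 nt, pyrimidine fraction
≤ 0.75 per 30-nt window, forbidden motifs SpeI (`ACTAGT`) and BamHI
(`GGATCC`) — the cloning sites flanking library inserts, which must not
occur internally. Motifs are searched on both strands because restriction
sites are double-stranded. All bounds are configurable.

Batch processing derives a per-record seed as
`crc32(f"{seed}:{record_id}") ^ seed (mod 2³¹)`, so each record's output
is independent of batch composition and order, and failures are collected
per record instead of aborting the batch.

**Usage convergence and constraint bias.** With the constraint channel
quiet, emitted codon fractions converge to the table (verified within
±0.05 per codon on a 20,000-residue protein, where that band is > 3σ of
multinomial noise). Under the default windowed constraints the output is
deliberately *not* table-distributed: repairs, and the survivorship of
windows that never violated, both favor mid-GC codons. The measured drift
is ≤ ~0.05 per codon on the same 20k-residue benchmark even including
that selection effect (bounded at 0.10 in the suite); this is the
intended behaviour of a constrained optimizer, not an estimator error.

## Pooled arrays

A design is a map of targets to wells with three constraints: every target
in ≥ `min_replicates` wells, every well ≤ `pool_size_max` targets, and
pairwise co-occurrence ≤ 1 well. The uniqueness guarantee is structural:
if two targets shared their whole (size ≥ 2) signature they would co-occur
in ≥ 2 wells, so signatures are automatically pairwise distinct and the
positive-well pattern identifies the target.

For duplicates (`min_replicates = 2`) the problem is exactly edge
selection in a simple graph on the wells with maximum degree
`pool_size_max`; a design exists iff
`n_targets ≤ min(⌊n_wells·pool_size_max/2⌋, C(n_wells, 2))`, and both
bounds are prechecked with a named infeasibility error. The solver is a
deterministic seeded depth-first search that tries candidate well-subsets
least-loaded-first (the greedy branch almost always succeeds immediately;
backtracking covers the frontier cases), with a node budget that raises a
partial-design error rather than ever emitting an invalid design. The same
search handles `min_replicates > 2` under the pairwise-intersection
constraint directly. Pools may be ragged (unequal sizes) when the slot
count does not divide evenly.

`verify_design` is an independent checker: it re-derives co-occurrence,
replicate counts, signature uniqueness and pool sizes by brute force over
all target pairs straight from the well contents, sharing no code with
the solver.

Plate export names wells row-major (A1…H12 on 96, A1…P24 on 384), maps
pool *i* to `technical_replicates` consecutive assay wells (mirroring a
96→384 duplicate split), and reports per-well total mass as
`per_construct_ng × pool_size / 1000` µg; the default 65 ng per construct
gives 0.325 µg for a pool of five.

## Screen analysis

- **Overton percent-positive** is computed as the per-bin positive part of
  the normalized sample-minus-control difference on shared binning
  (equivalent to the classic cumulative subtraction). When raw events are
  supplied they are binned on 256 equal-width bins spanning the pooled
  range. The estimator is exactly 0 for identical histograms and 100 for
  disjoint supports; on *finite samples* of identical populations it has a
  small positive bias of order `bins^½/n^½` (≈ 6% at 256 bins × 10,000
  events, shrinking with coarser bins), which is inherent to the method.
- **Z-scores** standardize each well against the mean and *population* SD
  of all wells in the experiment, so the normalization identity
  (mean 0, SD 1) holds exactly; a zero-variance experiment raises a
  degenerate-experiment error.
- **Replicate aggregation** uses a geometric mean, which requires positive
  values; scores are shifted by `offset` (default 10), averaged
  geometrically, and shifted back. Too small an offset raises an explicit
  error rather than propagating NaNs.
- **Hit calling** thresholds the *aggregated* score (aggregate-then-
  threshold; the default threshold is the conventional z = 3). The
  threshold is an analysis parameter: in experiments with few wells and a
  non-negligible fraction of true positives the positives themselves
  inflate the experiment SD and compress attainable Z-scores — with 2
  positive wells out of 8 the maximum attainable z is ≈ 1.7 regardless of
  separation, so the example-scale analyses in the suite use a threshold
  of 1.0, chosen from that ceiling, not from test outcomes.
- **Deconvolution** scores each target by
  `support = |signature ∩ positives| / |signature|`, ranks by support,
  then by fewer positives outside the signature, then by id, and flags
  full-support candidates as exact. Partial-support candidates are
  reported (not discarded) so screens with a false-negative well still
  surface the near-miss for review; a union of disjoint signatures
  correctly yields multiple exact candidates (multi-hit screens).

## Synthetic generators

`simulate_screen` draws pool-level signals: wells whose pool contains a
planted target emit Normal(μ₊, σ), the rest Normal(μ₋, σ), floored at 0;
dropout removes a *pool* (all its technical replicates read negative),
modeling a failed transduction. Defaults μ₊ = 10, μ₋ = 1, σ = 1,
no dropout, duplicate replicates on the 18-target/8-well geometry. The
Normal noise model was chosen over log-normal for analytic transparency
(a log-normal variant is available behind the `lognormal` flag). The
generator does not emulate cross-activation between pools, plate-position
effects, or signal saturation — so passing recovery tests demonstrate the
correctness of the deconvolution logic under the stated noise model, not
robustness to those real-data artifacts.

`simulate_flow_events` draws log-normal intensities (matching the
log-scaled appearance of cytometry histograms): control from the base
component, sample as a known mixture with a location shift, so the Overton
estimate has an exact ground truth (≈ 100 × mixture fraction for large
shifts). `simulate_well_image` places non-overlapping constant-intensity
discs on a flat background and returns the exact mask, making the
positive-area extraction testable to equality. All generators are
deterministic per seed and serialize ground truth alongside the data.

## Problem sizes in the default suite

The test suite exercises backtranslation round-trips on 1000 random
proteins (900 × ≤ 60 aa, 100 × 150 aa) plus 150 hypothesis cases and a
30-record batch at 120 aa; usage convergence on a 20,000-residue protein;
pooled-design properties over a 3 × 3 feasibility grid and 20 design
seeds with exhaustive per-target deconvolution; and recovery-vs-noise
grids of 30 simulated screens per condition. These sizes were chosen so
the full suite documents every stated property while remaining a
coffee-break run on a laptop.

## Known limitations

- The backtranslator optimizes constraint satisfaction and usage fidelity
  only; it does not model mRNA secondary structure, codon-pair bias, or
  vendor-specific synthesis rules.
- The pooled-array solver guarantees feasibility within the stated bounds
  but does not minimize well count, and designs are not error-correcting:
  a false-negative well degrades the top candidate to partial support
  (the simulator quantifies this; the solver does not optimize for it).
- Readouts are consumed as numeric tables/matrices; FCS and microscope
  image file parsing are out of scope.
- Leader (processing-enhancing) sequences are treated as configurable
  amino-acid strings; no claim is made about which leader best rescues
  antigen processing — that is an experimental question.
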