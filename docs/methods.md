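# Methods

`foxscreen` implements a transcription-factor downstream target-discovery
screen for a knockout-contrast experiment (a parental tumour line versus a
transcription-factor-null derivative, e.g. a ccRCC line and its FOXD1
knockout), together with the quantifications used to validate candidate
compounds phenotypically. This note records the models, the defaults and
why, and what the synthetic data does and does not establish.

## Selection funnel

**DE classification.** A differential-expression table (per-gene fold
change, log2 fold change, raw and adjusted p) is partitioned into
*differential* (adjusted p ≤ α, boundary inclusive; default α = 0.05),
*uninterpretable* (adjusted p missing — these rows are excluded from every
downstream stage), and *equal*. Fold-change orientation is stored as
parental over knockout, so lfc > 0 means "down in the knockout", the genes
a compound panel would inhibit. Rows with a raw p but no adjusted p count
as uninterpretable: the adjusted p is the only quantity the cutoff uses.
The top k (default 100) genes per direction are ranked by |log2 fold
change|; ties break by smaller adjusted p, then gene id, so ranking is
deterministic. Ranking by raw fold-change magnitude is available
(`metric="raw"`); the boundary between the two is only visible when ties
occur at the cut.

**Motif scanning.** A position frequency matrix (JASPAR text format) is
converted to log-odds with per-cell pseudocount (default 0.5) against a
configurable background. A window is a hit iff (a) every *core* position —
information content ≥ 1 bit against a uniform background, threshold
configurable — matches the consensus base exactly, and (b) the
range-normalised deficit (S_max − S)/(S_max − S_min) is ≤ the cutoff
(default 0.15). The deficit is a score-monotone operationalisation of "15%
mismatch tolerance outside the core"; published scanners do not document
an exact formula, so the scanner is specified by this contract and proven
against a brute-force per-window rescoring oracle in the tests. Both
strands are scanned by default; reverse-strand hits carry forward
coordinates; windows containing N are skipped; overlapping hits are all
retained. Promoter windows are 1.5 kb upstream / 0.5 kb downstream of the
TSS, 0-based half-open, truncated (with a warning) at the sequence start.

**Clustered motifs.** Hits from one promoter chain by single linkage:
consecutive starts within the cluster window (default 100 bp, inclusive)
join; chains of ≥ 2 are clusters. Start-to-start distance is the default
measure; an edge-to-edge (gap) measure is available because the two differ
for adjacent hits and published phrasing ("within 100 bases") does not
disambiguate.

**Candidate scoring.** Candidates are cross-referenced against four
phenotype databases — mitotic G2-G2/M phases, the human kinome, the
matrisome, cell adhesion — with additive weights +2, +1, +0.5, +0.5 and a
selection threshold of 2. Clustered-motif genes bypass the threshold
(the high-stringency arm of the funnel). Pools are merged by union with
deduplication, the clustered tag surviving any collapse; this is the only
arithmetic-consistent reading of a funnel in which top-ranked and
clustered lists overlap. Matching is exact string after uppercasing — the
original cross-referencing was manual, and alias resolution would add a
dependency on an identifier-mapping snapshot. The bundled GMT files are
small *synthetic* example snapshots for tests and examples; real analyses
must supply current database exports, which drift over time.

**Actionability.** The manual compound searches (inhibitor/antagonist
search, secretion check, recombinant availability, activator/agonist
search) enter as boolean annotations, making the decision tree total and
testable: lfc > 0 → inhibit via small molecule or antibody if an
inhibitor exists, else via an available recombinant (ligand saturation of
an inhibitory receptor); lfc < 0 → activate via recombinant if secreted
and available, else agonist. Refinement removes secreted growth factors,
ECM components, targets with known/contradictory effects, and targets
with no modality. A bundled fixture encodes the published 18-compound
panel (12 inhibit / 6 activate); its fold-change magnitudes are
placeholders — only the sign enters the tree.

## Phenotype validation

**Dose-response.** Percent growth is the treated mean well count over the
vehicle mean (×100); inhibition is its complement; viability is the mean
dead-negative count over the mean total. Toxicity is a one-sided test for
an *increase* in per-well dead fraction versus vehicle at α = 0.05 — the
screen seeks proliferation delay without cell death, so only increases
matter. Welch's unequal-variance t-test is the default wherever a
two-sample t-test is called for (count data rarely share variances across
doses); a pooled-variance switch exists for exact replication. No
multiple-testing correction is applied across doses or compounds by
default, matching the source analysis; a Bonferroni option exists. The
optimal dose is the greatest inhibition among significant non-toxic doses
(ties favour the lower dose); it is never a toxic dose, and is undefined
(None, with a warning) when nothing qualifies. Growth-curve comparisons
are two-sided endpoint t-tests on final-day replicates.

**Cell-cycle gating.** The G1 gate is anchored on a synchronized control
in which all cells are in G1: the dominant histogram mode seeds a local
Gaussian fit (mean/sd within ±25% of the mode, refined twice at ±3σ). A
comparably tall, well-separated second mode (≥ 50% of the main peak)
raises an error — the control was not synchronized. The G2/M gate centre
is exactly 2× the fitted G1 centre for any input, and its width is twice
the G1 width (constant stain CV); S is the open interval between. Events
below G1 (sub-G1 debris) or above G2/M are excluded rather than assigned,
since counting debris as G1 would bias every fraction. Gate half-width is
k·σ with k = 2.5 by default (the doubling rule fixes the centres but not
the widths; k is configurable and gates error out if 3kσ ≥ μ).

Hard interval gates are biased for a broad S phase: with k = 2.5 and
cv = 0.03 they swallow ~7.5% of a uniform S component into the G1 gate and
~15% into the G2/M gate, errors of up to ~0.03–0.04 on realistic
mixtures. `gate_phases` therefore applies a uniform-S spill-over
correction by default: the S density estimated on the open inter-gate
interval is extrapolated across the full (μ, 2μ) span, and the expected S
counts inside the G1 and G2/M gates are reassigned to S. This is the same
idea as the polynomial-S background in classical DNA-content models,
restricted to a uniform S (full mixture-model fitting is out of scope).
With the correction, (0.6/0.2/0.2) mixtures at n = 10⁴ and cv = 0.03 are
recovered with per-phase mean absolute error < 0.02 over 100 seeds; raw
gate counts remain available via `s_correction=False`. Arm comparisons
are t-tests on per-replicate G2/M fractions, flagging significant
increases.

**Imaging.** Channel order is Hoechst / Calcein / EthD1. "Threshold tool"
→ Otsu (the standard automatic stand-in for an interactive threshold),
with a contrast guard: if the foreground/background mean separation is
under 4 background SDs the channel is treated as blank, so pure-noise
fields do not shatter into spurious objects. "Despeckle" → 3×3 median
filter (the documented behaviour of that tool). Nuclei are separated by
watershed on the smoothed distance transform with markers at distance
peaks ≥ `min_distance` (default 5 px) apart. Colonies are connected
components of the binarized Calcein channel ≥ `min_colony_area` (default
100 px²); a colony is dead when ≥ 50% of its pixels are EthD1-positive
(the published rule names the markers but not an overlap fraction).
Nuclei require ≥ `min_nucleus_area` = 8 px² — deliberately below the
fragment-size range (~12–30 px² at default nucleus sizes), because a
filter that removes nuclear fragments would blind the module to the
fragmentation phenotype it exists to measure.

A colony is *anuclear* when no nucleus centroid falls inside its mask. A
nucleus is *fragmented* when its area is below 0.3× the vehicle median
area — a configurable operationalisation of a call originally made by
eye, reported alongside every result. Count-derived percentages are
rounded to whole percent (half away from zero), matching how such counts
are conventionally reported. Condition comparisons use two-sample
z-tests on mean areas (falling back to Welch's t with a warning below 30
objects per arm) and a standardized-count z-test, z = (n₁−n₂)/√(n₁+n₂),
for colony counts; size results use a signed-fold convention (ratio if
≥ 1, else −1/ratio).

## Synthetic data

Every generator is seeded (`numpy.random.default_rng`), byte-reproducible,
and emits a truth table sufficient to score its analysis stage without
re-deriving labels. Defaults are chosen to mirror the scale of the
assays they emulate; where the underlying study publishes no
distributional information (its images, plates, and event files are not
deposited), generator defaults are free parameters of this package, not
estimates of that study's data.

* **DE tables** place adjusted p-values on the correct side of α by
  construction, with an exact `round(frac_missing · n)` count of missing
  adjusted p rows; differential genes have |lfc| ≥ 0.25 so direction is
  always defined.
* **Promoters** are i.i.d. background with configurable GC (no repeat
  structure — the simplest null); planted sites are matrix consensus
  (deficit 0) unless a non-core mutation rate is requested.
* **Cytometry** events are Normal(μ, cv·μ) for G1, Normal(2μ, 2cv·μ) for
  G2/M (constant CV, as for DNA stains), uniform on (μ, 2μ) for S, with
  multinomial phase counts.
* **Plates** draw Poisson well totals around a Hill-curve expectation
  `vehicle_mean · (1 − emax·dʰ/(dʰ+ec50ʰ))` and binomial dead counts
  (flat base death rate, optionally Hill-shaped for genuinely toxic
  compounds); triplicate wells by default.
* **Images** (512×512, 16-bit, 3 channels) draw ~10 colonies of ~42 px
  radius with Poisson(7) nuclei each, lognormal nucleus areas (mean
  120 px², sd 35), 5% fragmented (2–3 disks each at 10–25% of the parent
  area, inside 1.5× the parent footprint), 5% anuclear (Calcein blob, no
  Hoechst), 10% dead (EthD1 overlay); Gaussian blur (σ = 1 px) then
  Poisson noise. Nucleus centres are sampled uniformly *within* the
  colony disk with retries, so placement acceptance is independent of
  nucleus size — a box-sample-then-reject scheme would truncate the size
  distribution and bias fold-change estimates. Fragment areas are drawn
  at 10–25% of the parent, clearly below both the 30%-of-parent envelope
  and the fragmentation cutoff, so the generator's truth labels remain
  recoverable by the stated classifier. The reference evaluation
  configuration uses 10 fields of view per condition (~60–70 drawn
  nuclei each), yielding well over 500 nuclei per condition — the
  per-condition scale of the assays being emulated.

**What passing on synthetic data shows.** Recovery on these generators
demonstrates internal consistency — the analysis inverts the stated
forward model at desk scale — not performance on real data. Real
promoters have repeat structure and composition bias the i.i.d. null
lacks; real DNA-content histograms have doublets and aggregation the
mixture model lacks; real 3D-culture images have out-of-focus light,
touching colonies and intensity gradients the disk model lacks. The
headline counts of the source analysis (thousands of DE genes and
motif-bearing promoters) additionally depend on a specific genome build,
annotation, and an external scanner's exact scoring, and are not
reproducible from this package's inputs.

## Numerical choices

Coordinates are 0-based half-open throughout. Deficit comparisons use a
1e−12 absolute slack so boundary hits are kept under either rounding.
Degenerate matrices (S_max = S_min) score deficit 0 everywhere. Gate
fractions sum to 1 within 1e−9 by construction. Degenerate t-tests on
identical samples (nan p) are reported as p = 1 ("no evidence") rather
than propagating nan into significance flags. The pipeline derives all
stage seeds from one root seed via `numpy.random.SeedSequence`, writes
SHA-256 hashes of every output into its manifest, and contains no hidden
state: replaying the stages by hand from the written intermediates
reproduces the candidate list exactly (tested).

## Known limitations

* No identifier alias resolution; gene matching is exact (uppercased).
* The scanner models one matrix at a time; genome-wide TSS lookup from
  annotation is out of scope (promoter FASTA is the interface).
* The cell-cycle model excludes doublet discrimination and full
  Dean–Jett–Fox/Watson fitting; the S spill-over correction assumes a
  uniform S.
* Image analysis is 2D single-plane; no volumetric segmentation,
  tracking, or shape-based invasiveness classification.
* EC50/IC50 curve fitting is deliberately absent: doses are selected
  from supplied summaries, not fitted.
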