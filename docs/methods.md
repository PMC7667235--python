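# Methods

This note documents the models, decision rules, numerical choices and known
limitations of the `c4origins` pipeline, stage by stage.

## Isotope pathway classification

Leaf δ13C separates the photosynthetic pathways because PEP carboxylase
fractionates 13C far less than Rubisco: C4 tissue sits near −9…−16‰, C3
tissue near −22…−32‰, and C3–C4 intermediates that run a strong C4 cycle
("C4-like") in between. The survey literature quotes these as three
disjoint windows, which leaves gaps (−16…−10 vs −23…−32) and is contradicted
at the edges by real species means (a fully C4 genus reaching −9.4‰; a C3
call at −22.6‰). The classifier therefore uses half-open boundaries:

* C4: δ ≥ −16
* C4-like: −22 ≤ δ < −16
* C3: δ < −22, flagged `borderline_c3` when δ > −24 (arid-zone C3 species
  with high water-use efficiency reach such values without any C4 cycle)
* `out_of_range` flag outside (−35, −8), a plausibility window for leaf
  tissue.

This rule is total (every finite value gets exactly one label), monotone in
δ, and reproduces every published species call we transcribe. All
thresholds are config-overridable (`IsotopeThresholds`). Genus-level
semantics: a genus is "C4" when every sampled species mean classifies C4,
matching surveys in which C4 genera contain only C4 species. Species means
are plain arithmetic means over replicate specimens keyed by
(genus, species).

## Gas exchange

An A/Ci curve is the stepped response of net CO2 assimilation *A*
(μmol m⁻² s⁻¹) to intercellular CO2 *C*ᵢ (μmol mol⁻¹). Derived statistics:

* **Initial slope (carboxylation efficiency)** — OLS of *A* on *C*ᵢ over
  steps with *C*ᵢ below 100 μmol mol⁻¹ (cutoff configurable); the μmol/μmol
  units give the slope directly in mol m⁻² s⁻¹. At least two qualifying
  steps are required.
* **Γ (CO2 compensation point)** — the x-intercept −intercept/slope of that
  regression, floored at 0 with a `clamped` flag. The estimation method for
  Γ is genuinely open (measurement protocols only say CO2 was "reduced to
  near the compensation point"); the x-intercept of the low-Ci line is the
  default, with a bracketing-interpolation alternative
  (`method="interpolation"`).
* **A₄₀₀, A₁₂₀₀, A₄₀₀/A₁₂₀₀** — read at the ambient-CO2 steps nearest 400
  and 1200 μmol mol⁻¹ (±25 tolerance, else an error). The ratio is computed
  per curve and averaged across replicates (mean of ratios), which is why a
  table mean can differ slightly from the ratio of table means.
* **Normalized carboxylation efficiency** — initial slope / A₁₂₀₀, an
  identity maintained exactly (`norm_ce * a1200 == initial_slope`).
* **Intrinsic WUE** — A/gₛ at the 400 step, reported on the numeric scale
  conventional for such tables.

## Enzyme and pigment arithmetic

Chlorophyll from 80%-acetone absorbances at 645/663 nm uses the standard
two-wavelength equations (mg/L): chl a = 12.7·A663 − 2.69·A645,
chl b = 22.9·A645 − 4.68·A663, converted to mmol m⁻² with molar masses
893.5/907.5 g mol⁻¹ and the extract volume per leaf area. A negative
computed concentration raises an error (the usual cause is swapped
wavelengths). The a/b ratio is molar.

Enzyme activity from NAD(P)(H) kinetics at 340 nm:
|dA340/dt| / (ε·path) gives mM min⁻¹ in the cuvette (ε = 6.22 mM⁻¹ cm⁻¹),
scaled by assay volume to μmol min⁻¹, by extract/aliquot to the whole
extract, divided by leaf area (m²) and 60 to μmol m⁻² s⁻¹.

**Subtype call.** The dominant decarboxylase per leaf area decides between
NADP-ME and NAD-ME, gated by whether it can sustain the measured A₄₀₀:
robust at ≥ 1.0·A₄₀₀; called with a warning flag between 0.2·A₄₀₀ and
A₄₀₀ (the 0.2–0.5 band still yields a call, with the same warning — the
decision rule has no silent gap); "none" (C3-consistent) when both
decarboxylases fall below 0.2·A₄₀₀. There is deliberately no PCK branch:
this panel never assays PEP carboxykinase, so the rule cannot claim to
detect it.

**One-tailed comparisons** use Welch's unequal-variance t test, one-tailed
in the direction of the observed difference (the test identity is not fixed
by convention here; Welch is the default and the function is swappable).
Identical groups return the symmetric-null p = 0.5.

**Ultrastructure summaries** aggregate per cell → per plant → per species
(coverage = Σ organelle areas / cell area × 100, averaged per plant first),
with group letters from one-way ANOVA + Tukey HSD at α = 0.05 on per-plant
means (statsmodels `pairwise_tukeyhsd`; letters via a standard insert-absorb
compact letter display). Species measured in a single plant get metrics but
no letters.

## Supermatrix construction

* **Longest ORF**: all six frames are scanned; an ORF runs from the first
  in-frame ATG after a stop (or the sequence edge) to the next stop or
  edge; the longest protein wins, ties broken by frame order (+0, +1, +2,
  −0, −1, −2) then 5′-most start. Whether the original practice required
  ATG starts is not recoverable, so a stop-to-stop mode
  (`require_start=False`) is also provided. Coordinates are 0-based
  half-open on the forward strand.
* **Overlap** is computed on aligned coordinates: shared non-gap columns
  divided by the shorter row's non-gap length. (Overlap is only meaningful
  post-alignment; the aligned-coordinate choice is flagged here because an
  unaligned convention would differ.)
* **Fragment/paralog resolution**: if every pairwise overlap ≤ 0.10 the
  copies are merged column-wise (fragments ordered by first non-gap column;
  a doubly-covered column takes the earlier-starting fragment's residue),
  otherwise all copies for that species are dropped from the orthogroup.
* **Filter order**: resolution runs before presence counting, so merged
  fragments count as present — the rescue of fragmented assemblies is the
  point of the merge rule. Then, in order: presence (≥ ceil(fraction ×
  roster), default 40/53 expressed as a fraction so it generalizes; an
  absolute count is also accepted), multicopy fraction (species multicopy
  *before* resolution / roster ≤ 0.10), alignment length (≥ 100 aa). The
  first failing rule is recorded per orthogroup.
* **Back-translation** maps each residue column to its codon ("---" for
  gaps), strips a trailing stop, and verifies the CDS translation against
  the aligned residues, reporting the sequence and 1-based residue position
  on mismatch.
* **Trimming** removes whole codons whose non-gap fraction falls below the
  0.5 gap threshold (boundary inclusive). Removing nucleotide columns
  individually would break reading frame, so the codon is the unit; the
  threshold semantics are the conventional per-column gap score. Trimming
  is idempotent and returns the original codon indices kept.
* **Concatenation** orders orthogroups by id, pads absent species with
  gaps, and emits one partition per orthogroup (1-based inclusive
  coordinates in the partition file; 0-based half-open everywhere
  internally).

## Parsimony origin scenarios

Unit-cost small parsimony (Sankoff dynamic program, valid on polytomies;
equal to Fitch counts on binary trees) gives the minimum number of C3↔C4
changes, with a witness labeling recovered top-down (root ties break toward
C3 and are flagged; child ties prefer no change). Gains are 0→1 edges on
the rooted tree — the raw count is rooting-invariant but the gain/loss
decomposition is not, so unrooted input should be rooted on an outgroup
first.

The constrained search (`constrained_min_changes`) minimizes total changes
subject to the number of gain edges equaling *k*, via a DP over
(node, state, gains-in-subtree) with a backtracked witness. The root state
is pinned to C3 by default: origin scenarios are counted from a C3
ancestor, and without that pin "zero gains" would be trivially satisfiable
by an all-C4 history. `root_state=None` lifts the pin. An exhaustive
enumeration mode (≤ 20 internal nodes) provides an in-package cross-check;
equally costly alternative labelings can be enumerated rather than assuming
the witness is unique.

The packaged newick + tip-state fixture encodes the study clade (two C4
tip groups separated by C3 lineages, rooted through C3 outgroups), so the
published "2 changes vs 3 changes" comparison is a one-command
reproduction.

## Expression and convergence

RPKM uses total *sequenced* reads as the library-size denominator (the
variant appropriate when reads were mapped to selected references only, so
total mapped reads would overstate depth). The functional-copy rule picks
the highest-RPKM copy per species × family; the dominance ratio
(top/second) and a co-expression flag (second ≥ 0.5 × top) qualify the
call. The 0.5 factor is a documented, configurable choice: it flags the
case of two decarboxylase transcripts at 0.87 relative expression while
leaving a 2/8563 runner-up silent. Expression evidence alone can mislead —
high transcript level of a second decarboxylase with zero measured enzyme
activity is expected to be resolved in favor of the assayed activity — so
the flag marks exactly the cases needing biochemical confirmation.

Convergence scoring anchors all site numbers on the maize PEPC reference
coordinate system. The packaged catalog carries the 19 printed
positively-selected positions with their grass C4 residue sets, C3
reference residues and posterior-probability classes; the source catalog of
grass switches counts 21 sites, so the fraction denominator is configurable
(19 printed, 21 cited; the acceptance script reports /21). Scoring rules:
consensus ∈ grass set AND ∉ C3 sister consensus → convergent;
sister ∩ grass ≠ ∅ → `ancestral_shared`, never counted; clade polymorphic
with a matching member → `partial`, excluded from the strict count by
default (`mode="any_member"` includes it). On the packaged observations
this yields 5 strict convergent sites (+1 partial) for the larger C4 clade
and 4 for the other, preserving the published ordering. The published
naming of the main decarboxylase copy in one clade is internally
inconsistent in the source (NADP-ME1 vs NADP-ME2); the packaged expression
table is treated as authoritative and the copy with the dominant RPKM is
what the assignment returns.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of config + seed (bitwise reproducible)
and attach ground-truth labels consistent with the emitted data.

* **Isotope survey** — per-species replicate draws from genus-level C3/C4
  normal modes (defaults C3 −27.0 ± 1.5‰, C4 −12.5 ± 1.2‰, consistent with
  published per-genus ranges), truncated to [−32, −9]. The default design
  mirrors the published sampling effort (21 genera, 3 fully C4). The modes
  are > 4σ apart, so species-level classification accuracy is 100% by
  construction — passing that check validates the plumbing, not the
  difficulty of real intermediate-value calls.
* **A/Ci curves** — Ci = ratio × Ca per step (defaults 0.33 C4-like, 0.60
  C3-like), noiseless A from a non-rectangular hyperbola of the CO2-limited
  line v = slope·(Ci − Γ) and ceiling a_max, clamped to the line below Γ.
  The default curvature θ = 1 is the piecewise-linear-saturating (Blackman)
  limit, matching the response shape the pipeline's slope estimator
  assumes; θ < 1 produces a bent transition and is available for stressing
  model mismatch. gs is derived from A via the 1.6 diffusivity ratio with a
  floor — generator plumbing, not a stomatal model. Default step ladder:
  13 steps from 1200 down to 20 μmol mol⁻¹.
* **Gene families** — a master protein per family (length 80–300 aa),
  mutated per species (2% substitutions); fragment cases split the copy
  into two rows separated by ≥ 5 all-gap columns (overlap exactly 0);
  paralog cases add a second, more-diverged full-length copy (aligned
  overlap 1.0, unambiguously above the 0.10 merge threshold; the generator
  does not synthesize partially-overlapping paralogs). CDS back-translate
  each row through a fixed codon choice per amino acid. No substitution
  model or indel realism is attempted — the families exist to exercise the
  resolution/filter logic, not to resemble real evolution.
* **Expression counts** — Poisson draws around RPKM-implied expectations.
  Poisson (not negative binomial) because only the RPKM arithmetic is
  consumed downstream; no dispersion is inferred.
* **Convergence alignments** — a reference with known numbering (optional
  planted leading gap columns to exercise the coordinate map), clade
  members carrying designed residues at catalog columns plus background
  substitutions elsewhere.

Consequently, green tests demonstrate correctness of the arithmetic and
decision rules under the stated statistical structure; they do not
demonstrate robustness to real-data pathologies (alignment error, partial
assemblies with residual overlap, isotope values in the C4-like gap,
dispersed read counts).

## Problem sizes and determinism

The test and acceptance workloads are desk-scale by design: 200 random
trees of ≤ 12 leaves against exhaustive enumeration, 500 synthetic gene
families for resolution recovery, 200 seeds for the noisy-slope bias check,
~480-record synthetic surveys. All randomness flows through
`numpy.random.default_rng` seeded from the config or the acceptance
script's `--seed`.

## Known limitations

* No mechanistic photosynthesis model (FvCB / enzyme-limited C4) is fitted;
  the A/Ci statistics are the descriptive ones.
* Orthology inference, multiple sequence alignment, tree search and
  bootstrap are out of scope — the pipeline consumes their standard output
  formats.
* The parsimony module does not perform likelihood-based ancestral state
  reconstruction or divergence dating.
* The convergence catalog is an input, not a result: positive-selection
  testing (dN/dS, branch-site models) is not implemented.
* Isotope mixing models and post-photosynthetic fractionation corrections
  are not applied.
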