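# Methods

## Problem and data model

`ith-ihc` analyses intratumoral heterogeneity (ITH) in multi-region
immunohistochemistry (IHC) data. Each tumor is sampled as a small number
of spatially separated foci on a tissue microarray; each focus is scored
for a panel of nuclear markers (default: the SWI/SNF subunits PBRM1,
ARID1A, BRG1, BRM and the methyltransferase SETD2) on a three-level
ordinal scale:

- **2** — more than `t1` (default 50%) of tumor cells stain positive;
- **1** — between `t0` and `t1` positive (weak, still counted as retained);
- **0** — at most `t0` (default 5%) positive: *loss of expression*.

The loss boundary is inclusive (`f <= 0.05` is a loss) and the weak/strong
boundary exclusive (`f <= 0.50` is weak). Both thresholds are exposed as
configuration because published scoring rules vary in whether the 5%
boundary is itself a loss; the inclusive reading is the default here.
Missing cells are *non-evaluable* — a failed core is evidence of nothing,
so it never enters a numerator or denominator and is never imputed.

Tumor-level calls follow the single-biopsy convention: a tumor has lost a
marker iff **any** evaluable focus scores 0. This makes tumor-level
prevalence systematically at least as high as focus-level prevalence.
That dominance is exact when all tumors contribute the same number of
foci; with unequal focus counts the pooled focus denominator re-weights
tumors and the inequality can fail by O(1/total foci). The default study
design (one 2-focus tumor among 159 4-focus tumors) keeps the effect
negligible; the property test therefore uses equal focus counts.

Two-pathologist consensus scoring is modelled as already-resolved input:
the package accepts one score per cell and performs no automatic
adjudication, since disagreement resolution is a human step.

## Clonal ordering and tree construction

A marker's *support set* is the set of foci in which it is lost. Clonal
ordering rests on a perfect-phylogeny reading of the support sets:

1. **Events.** Markers with identical support within a tumor are grouped
   into one loss event (`extract_events`); they are indistinguishable as
   separate clones from a binary matrix.
2. **Laminarity.** A family of supports in which every pair is nested or
   disjoint is exactly the family representable as a rooted tree.
   Overlapping-but-non-nested supports are a compatibility conflict and
   indicate convergent (parallel) loss.
3. **Conflict policy.** `strict` rejects conflicted tumors; the default
   `split` interprets the conflicting event as parallel occurrences:
   processing events in deterministic order (descending support size,
   then the fixed marker order PBRM1, ARID1A, SETD2, BRG1, BRM), a
   conflicting event is split into its intersection with and difference
   from the largest already-placed conflicting set, recursively, and
   pieces with identical support are re-merged. Per insertion this
   greedy rule attains the minimum number of laminar pieces (verified by
   partition enumeration in the tests). Every split is logged.
4. **Tree.** Each event's parent is the event with the smallest support
   strictly containing its own, else the loss-free founder WT whose
   support is the tumor's evaluable foci. Sibling order follows the
   same deterministic key, so trees are bit-reproducible.

**Truncal vs branch.** An event attached to the root is truncal iff its
support covers at least `tau` (default 0.75) of the denominator foci;
all deeper events are branch. The default denominator is all evaluable
foci; `any-loss` restricts it to foci carrying at least one loss, which
matters when trailing loss-free foci are plausibly non-evaluable. With
four foci, `tau = 0.75` makes a three-focus trunk truncal under either
convention. A root-attached event below the threshold is labelled branch
and flagged (`flagged_trunk`), since a minority-support trunk is
structurally a trunk but temporally late.

**Shape taxonomy.** `NO_LOSS` (root only); `MULTI_TRUNK` (root has >= 2
children); otherwise `BIFURCATED` if any node has >= 2 children;
otherwise `TRUNK_ONLY` for a depth-1 chain and `BRANCHED` for a deeper
chain. The trunk-only/branched distinction is depth-based by design.

**Newick.** Node labels are marker names joined by `+` in the fixed
marker order, root labelled `WT`, no branch lengths:
`((PBRM1+BRG1)ARID1A+BRM)WT;`. The writer is deliberately minimal; tests
round-trip topology through an independent Newick parser.

## Co-loss statistics

For every unordered marker pair a 2x2 table of joint loss/retention is
tallied at tumor level and at focus level (foci pooled across tumors;
this ignores within-tumor correlation and is kept deliberately, as the
standard TMA tally — focus-level p values are descriptive). Units
non-evaluable for either marker are excluded.

The two-sided Fisher exact test is implemented from log-factorials with
the point-probability definition: p is the sum of hypergeometric
probabilities of all tables sharing the observed margins whose
probability is at most the observed one, with a 1e-7 relative tolerance
on the comparison to absorb floating-point ties. Two-sided exact tests
have competing definitions; this one matches the mainstream
implementations and is validated against full enumeration (to 1e-12 on
all tables with total <= 40) and against an independent library
implementation. Tables with a degenerate margin (a marker constant in
the stratum) return p = 1 by convention, with a warning.

Odds ratios use the cross-product formula, optionally with the Haldane
correction (+0.5 per cell). Benjamini–Hochberg q-values are computed
over the full set of pair tests as a supplement; raw p values remain the
primary replication quantity because the reference analysis reported raw
p only.

## Synthetic cohorts

`simulate_cohort` plants a clone tree per tumor and emits scores:

- **Design defaults** mirror the replicated study: 4 stages x 40 tumors,
  4 foci each, one 2-focus tumor, 5 markers.
- **Events.** Candidate events are marker bundles with per-tumor
  occurrence probabilities; the default bundles {PBRM1, ARID1A} and
  {BRG1, BRM} generate co-loss enrichment, and singleton events cover
  marker-specific losses. Defaults were set once so the implied
  cohort-average tumor-level prevalences approximate 31/51/14/15/38% for
  PBRM1/ARID1A/SETD2/BRG1/BRM; per-stage multipliers follow the
  direction (not the exact values) of the observed stage trends. Each
  marker is lost by at most one event per tumor (a second event touching
  an already-lost marker is suppressed).
- **Tree.** Occurring events are truncal with probability `p_truncal`
  (default 0.30). All truncal markers collapse into a single trunk node
  supported by every focus — separate all-foci events cannot be
  distinguished from a binary matrix, so the model does not plant them.
  Branch events attach to the trunk, or with probability `p_nest`
  (default 0.25) below an existing branch clone; their supports are
  proper subsets of the parent's free foci with sizes drawn from
  `branch_support_sizes` (default {1, 2} of 4 — a minority of foci,
  consistent with the truncal threshold). Supports are laminar, sibling-
  disjoint and pairwise distinct by construction, and every planted
  clone occupies at least one focus. Consequently, with zero score noise
  and zero missing cells the analysis pipeline recovers every planted
  tree and label exactly — identifiability is a property of the model.
  If a branch event finds no free focus under its parent it simply does
  not occur (rare at default rates).
- **Noise.** Retained cells score 2, or 1 with probability `score_noise`
  (default 0.10, emulating weak/spotty staining); cells are blanked to
  non-evaluable with probability `missing_rate` (default 0.01). Score
  noise never flips loss status; missing cells can hide planted events,
  which the recovery report counts as sampling misses, not errors.
- **Not modelled:** spatial autocorrelation between neighbouring foci,
  clone mixtures within a focus, growth dynamics, and cross-tumor
  correlation of distinct events. The last omission makes the simulated
  any-loss fraction (~75%) run above typical observed cohorts
  (~58–75%), because real tumors concentrate multiple events in the
  same cases; passing recovery tests therefore demonstrate correctness
  of the inference on laminar loss patterns, not realism of the
  marginal any-loss rate. Likewise, only bundled pairs show co-loss
  enrichment, so the simulated maximum pair-test p is near 1 while
  cohorts with global co-loss structure can have all pairs significant.

`recovery_report` compares pipeline output against planted truth per
tumor: exact label-preserving tree isomorphism, truncal/branch label
accuracy over recovered markers, mean per-marker support Jaccard, and
the number of unobservable planted events.

## Numerical and procedural choices

- All randomness flows through one `numpy` generator seeded from the
  config; identical config implies byte-identical cohorts.
- All orderings (events, siblings, output rows, file names) are
  deterministic, so repeated pipeline runs are bit-reproducible.
- Degenerate inputs: empty score tables are hard errors; single-focus
  tumors are retained with a warning; empty strata yield denominator 0
  and NaN proportions, flagged rather than dropped.
- Problem sizes in the validation experiments: exhaustive oracle checks
  cover all 2x2 tables with total <= 40 and all binary matrices up to
  4 foci x 4 markers; parameter recovery uses 500 noiseless tumors; test
  calibration uses 1000 replicates of 160 units. These sizes make the
  exhaustive checks complete while keeping the default validation run
  in the tens of seconds.

## Known limitations

- The laminar/split machinery is exact for the small focus counts TMAs
  use; for many regions per tumor the greedy split is per-insertion
  minimal but not proven globally minimal.
- Focus-level inference treats foci as independent; no
  cluster-correction is attempted.
- The `reproduce_study` comparison requires the original study's
  focus-level score spreadsheet, which is not redistributed with the
  package; without it the command reports where to obtain the file.
- Survival/outcome modelling and any image analysis are out of scope;
  scoring begins at fractions or ordinal scores.
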