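# Methods

## The prediction problem

Transcription factors (TFs) act in the nucleus, frequently as physical
complexes, so knowing which TF pairs can bind each other is central to
understanding combinatorial gene regulation. Experimentally confirmed TF–TF
interactions are scarce, and the usual negative-set trick for general
protein–protein interaction (PPI) prediction — pairing proteins from
different cellular compartments — is unavailable: every TF lives in the
same compartment and participates in the same process. `tfinteract`
implements a deliberately simple predictor for this setting that uses
primary sequence only: physicochemical summary features, a quadratic
discriminant classifier, and a greedy wrapper to pick a small feature
subset under cross-validation.

## Feature representation

Let *s* be an amino-acid sequence of length *L* and *p* a per-residue
property scale (one of the P complete scales retained from an AAIndex1
file). The sequence is split into an N-terminal section (first
`t = floor(0.2 L)` residues), a C-terminal section (last `t`), and the
middle (`L − 2t`); the 20/60/20 split lets the model see terminal regions,
which carry distinct biology (degradation signals, disordered activation
domains), separately from the core. Each section contributes the mean of
every scale over its residues, with the unknown residue `X` and
selenocysteine `U` excluded from numerator and denominator alike. A
protein therefore maps to a vector of length 3P regardless of its length,
and a pair to the 6P-long concatenation of its two members.

Because an interaction is unordered, the pair encoding must not depend on
which member is written first: the member with the smaller molecular
weight (average residue masses plus one water; `X` weighs 0, `U` uses the
selenocysteine residue mass; exact ties broken by identifier) always comes
first. Only the ordering consistency matters, so the mass convention is a
recorded model tag rather than a tunable; a saved model refuses to score
pairs prepared under a different convention or property table.

Sequences shorter than 5 residues are rejected (a terminal section would
be empty), as are ambiguity codes other than `X`/`U` (silently skipping
`B`, `Z`, `J`, `O` would change feature values without notice).

## Dataset construction

Positive pairs are read from a tab-separated table and filtered to
evidence types that can support complex formation (PSI-MI codes MI:0195
covalent binding, MI:0407 direct interaction, MI:0915 physical
association; rows without a code are dropped when the filter is active).

Negatives are sampled in three classes of increasing difficulty, defined
by the partner map of the input universe: *absolute* (neither member has
any known partner), *partial* (exactly one does), and *PPI* (both do, but
not with each other). Classes are sampled without overlap, self-pairs are
excluded, and no sampled pair may coincide with a positive. Requesting
more pairs than exist raises a capacity error naming the achievable
maximum.

Close homologs often share binding partners, which leaks information
between cross-validation folds. The redundancy filter aligns every pair of
positive-set proteins that share a partner (other pairs cannot trigger a
removal, so they are not aligned) with a Smith–Waterman local aligner
under BLAST-default scoring (BLOSUM62, gap open 11, extend 1); identity is
identical positions over alignment length, gap columns included. Whenever
identity exceeds the threshold (default 0.8) and the two proteins share a
partner B, only the interaction of the lexicographically smaller protein
with B is kept. The keep-rule makes the filter deterministic, idempotent
and independent of record order; every exclusion is written to an audit
table with its identity and the shared partner.

## Classifier

Each class *k* is a multivariate Gaussian with its own mean and
covariance. A point is scored by

    score_k(x) = −½ log det Σ_k − ½ (x − μ_k)ᵀ Σ_k⁻¹ (x − μ_k) + log π_k

and assigned to the argmax (exact ties to the earlier class in sorted
label order). Priors π_k are empirical class frequencies. Covariances are
unbiased sample covariances plus a relative ridge `ridge · tr(Σ̂)/d` on
the diagonal; the default `1e−6` exists because a cross-validation fold
with ~350 samples and tens of features can be near-singular, and it is
small enough not to move well-conditioned decisions. `ridge = 0` is
honoured exactly and raises a singularity error naming the class when a
covariance is not positive definite. Scores go through a Cholesky
factorization and triangular solves — never an explicit inverse — and are
tested to match direct log-density evaluation to 1e−8 relative.

## Cross-validation and feature selection

Folds are stratified: within every class, samples are dealt to folds as
evenly as possible (remainders to the currently smallest folds), so fold
sizes differ by at most one overall and per class, and the assignment is a
deterministic function of (labels, k, seed).

The wrapper grows a feature list greedily. At each step, every unselected
candidate is appended in turn, the classifier is refit per fold on the
out-of-fold samples and scored on the held-out fold, and the candidate
with the best mean criterion (accuracy by default; F-measure available)
joins the list. The *same* fold partition is used for every candidate at
every step — each recorded step carries a hash of the assignment as an
internal check — so scores are comparable across the whole search. Ties
break to the lowest feature index; a candidate whose fit fails is logged
and skipped (it could never win a step anyway); step *t* costs
`|pool| − t + 1` cross-validated fits, so a restricted candidate pool
keeps the loop tractable at any scale. The final subset is the shortest
trace prefix attaining the maximal mean criterion.

The end-to-end pipeline splits the data into k + 1 stratified groups:
groups 1..k are the cross-validation folds used for selection and the
final fit, group k + 1 is never touched until the end and yields the blind
performance estimate.

## Performance measures

Precision, sensitivity, specificity, false-discovery rate, accuracy and
F-measure are computed from the binary confusion matrix on the percentage
scale and reported to two decimals (full precision kept internally). A
measure whose denominator is zero is carried as an explicit undefined
marker — never substituted by 0 — and excluded from cross-fold means with
a warning, because coercing it would silently bias wrapper selection.

## Synthetic studies with planted ground truth

Real interaction snapshots are neither redistributable nor stable, so the
test bed is a generator that emits the package's own input formats (FASTA,
AAIndex1, pair TSV) plus a ground-truth JSON naming the pair-vector
features that carry class signal. Signal is planted at the
residue-composition level — not by emitting feature vectors — so every
pipeline stage (parsing, segmentation, averaging, canonical ordering) is
exercised.

Proteins fall into three pools: interaction-prone proteins (positives are
drawn among them), promiscuous proteins whose known partners are outside
the study (they populate the hardest negative class), and isolated
proteins. The three negative classes follow their definitions against
this partner map: absolute = isolated × isolated, partial =
(prone ∪ promiscuous) × isolated, PPI = promiscuous × promiscuous.
Partial negatives may therefore contain one signal-bearing protein, which
keeps the learning problem non-degenerate.

Each interaction-prone protein's composition is tilted additively along
per-property directions. Every direction sums to zero (it stays on the
composition simplex), moves its own property by one unit, and is exactly
invisible to every other scale in the table; the directions are found by
one linear programme that maximises the worst property's response while
the *summed* tilt keeps every residue coordinate nonnegative. Per-protein
random direction weights (uniform 0.8–1.2) make each informative property
carry partly independent evidence, and the tilt is confined to the middle
section of the sequence, emulating a central interaction domain — the
signal-bearing features are the two members' mid-segment means of the
informative properties. Positivity binds per protein: each protein is
tilted by the requested strength or 98% of its own bound, whichever is
smaller.

The effect size is defined on the pair-level mid-section mean of each
informative property and calibrated by bisection so the weakest property
sits exactly at the target, in standard deviations of the pure
within-class noise (positives and absolute negatives; the partial-negative
mixture spread is signal, not noise). An unreachable effect raises a
feasibility error reporting the largest attainable value.

Default study conditions: 13 property scales, 1,000 proteins (so a
protein appears in roughly one pair, matching the ratio of a realistic
TF study — reusing few proteins across many pairs lets the classifier
fingerprint individual proteins across folds), lengths 350–750 aa,
Dirichlet(700) baseline compositions, 200 positives plus 67 negatives per
class (~400 pairs), 5 informative properties, effect 2.5 sd. The property
table is treated as external reference data with its own seed (default
fixed), the way a real scale database is a fixed snapshot: re-running with
a new study seed redraws proteins, pairs and noise against the same
scales. Informative properties default to generator-selected — the five
scales whose joint planted shift can be largest under the shared
positivity budget (greedy growth of the LP optimum) — because a random
table may contain scales nearly collinear with the rest, for which no
meaningful effect is reachable.

What the generator does *not* emulate: TF family structure and
phylogenetic correlation (sequences are independent draws), domain
architecture, real AAIndex scale correlations, and database noise
(mislabeled positives). Passing tests therefore demonstrate that the
pipeline recovers planted composition-level signal under honest
cross-validation — not that real TF interactions are predictable at any
particular accuracy.

## Numerical and reproducibility choices

All randomness flows from one root seed through named substreams
(properties, pools, compositions, sequences); residue draws reuse one
fixed set of uniforms across calibration steps, so a study is a bitwise-
deterministic function of its spec. Alignments canonicalize argument
order before aligning because tied optimal local alignments may otherwise
report different identities for (a, b) and (b, a). Property values are
stored at full printed precision and never normalised (the classifier is
affine-equivariant). Every pipeline run writes its effective
configuration, including all seeds, next to its outputs; two runs from
the same configuration are file-identical.

Problem sizes used by the shipped tests and the reproduction script —
~400 pairs, a 50-feature candidate pool, 10 selection steps, 10 folds —
are the package's desk-scale defaults; the full loop at publication scale
(3,186 candidates, 150 steps) uses the identical code path via the same
entry points.

## Known limitations

- The wrapper is greedy; it does not revisit earlier choices (no floating
  or backward steps), matching the simplicity of the original procedure.
- Hard labels only: QDA scores are exposed, but no probability
  calibration or ROC analysis is provided.
- The redundancy filter's common-partner restriction means two
  near-identical proteins with disjoint partners are both retained by
  design; whether that is desirable depends on the downstream use.
- Identity is computed from one optimal local alignment; near-threshold
  decisions (identity within ~1% of the cutoff) could differ from another
  aligner's report.
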