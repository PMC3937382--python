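# Methods

This note documents the models, algorithms, parameter choices and known
limitations of kinscan, in the order the pipeline runs them.

## Profile model and scoring

Profiles are per-column log-odds matrices in bits (a PSSM), not full
profile HMMs. Columns are estimated from a seed alignment with
background-proportional pseudocounts,
`S(c,a) = log2(((n_ca + α·q_a)/(N_c + α))/q_a)`, gaps and `X` excluded
from the counts. The pseudocount weight α defaults to 1.0; as α → 0 a
single-seed profile scores its consensus residue at log2 20 ≈ 4.32 bits
per column, and a column whose empirical distribution equals the
background scores 0 for every α — both limits are asserted in the tests.
No sequence weighting is applied: the seed sets this package is designed
for are small (a handful to a few dozen members) and near-equidistant.

Scoring is optimal local alignment (Smith–Waterman over profile columns)
with affine gaps: a gap of length L costs `gap_open + (L−1)·gap_extend`,
defaults 11/1 bits, conventional BLOSUM-era magnitudes; there is no
biological calibration behind them and they are configurable everywhere.
The unknown residue `X` scores exactly 0 bits at every column
(background-neutral). The DP is the three-state Gotoh recursion,
row-vectorised with numpy; the in-row gap state is solved with a running
prefix-maximum. Tie-breaking in the traceback is deterministic — match
over profile-gap over sequence-gap, then the smallest sequence index —
so the column map is reproducible bit-for-bit across runs. Equality with
an independently written cell-by-cell DP is asserted to 1e-9 (double
precision; the two implementations associate additions differently, so
exact bitwise equality is not the right notion). The reported score always
equals the matched log-odds minus gap penalties recomputed from the trace
to 1e-6.

The PSSM-plus-affine-gaps choice, rather than a profile HMM with forward
scoring, is deliberate: it is deterministic, exactly oracle-testable, and
sufficient for best-match classification. Bit scores here are **not**
numerically comparable to HMMER bit scores; the default acceptance cutoff
of 20 bits carries over the conventional working threshold as a same-named
knob, not as a claim of equivalence. E-values are out of scope.

## Alignment trimming

`trim_columns` keeps exactly the columns whose gap fraction is ≤ a
threshold (default 0.5) and remaps subdomain annotation onto the surviving
columns. This replaces two-pass slope-based trimming heuristics with a
single testable rule that serves the same role (removing gap-dominated
columns before profile building and distance computation); it is
idempotent at a fixed threshold.

## Best-match classification and iterative refinement

`classify_best_match` scores a sequence against every profile in the
library and assigns the argmax group if its score reaches the cutoff,
with ties broken by library order. `iterative_refine` mirrors a
seed-and-extend lineage search: the seed alignment's columns are the fixed
coordinate template; each iteration builds a profile from the current
member set, re-classifies the corpus, and folds newly accepted members
back in by projecting them onto the template columns through their
local-alignment trace (residues matched to a column fill it, skipped
columns become gaps, insertions are dropped). Re-running a full multiple
alignment per iteration would be more faithful to practice but
non-deterministic across alignment tools; the projection keeps the loop
exactly reproducible. Acceptance is cumulative — once in, a member stays —
which guarantees termination at a fixpoint in at most `max_iter`
iterations on any finite corpus. The refined profile supplements the
library rather than replacing the generic profiles.

## Subdomain anchoring and TK diagnostics

A reference profile carrying Hanks subdomain column intervals (I–XI) maps
those intervals onto a hit through the alignment column map; subdomains
with no matched column are reported absent, and sequences scoring below
the cutoff are "unanchorable" rather than silently skipped. Motifs are
searched only inside their subdomain window widened by a slack of 5
residues (anchoring on diverged sequences is locally imprecise by a few
positions; a larger slack would start admitting spurious matches from
neighbouring subdomains).

Each diagnostic rule carries a motif and key residue positions. When the
full motif fails, the site is re-located with the key positions wildcarded
so the report can say *which* key residue diverged (e.g. the lineage-
diagnostic P where TKs have M/L) instead of just "not found". Verdict
logic: any required subdomain window absent → `indeterminate` (truncation
takes precedence over failure, so truncated members are never called
non-TK on missing evidence); all motifs found with all keys passing →
`TK-like`; otherwise `non-TK`. An `X` in the sequence never satisfies a
fixed or allowed-set element — an unknown residue cannot confirm a
diagnostic residue — but wildcards accept it.

The catalytic-loop key residues are interpreted as the degenerate
consensus positions 3–6 of `DL(R/A)A(A/R)N` (element 3 ∈ {R,A}, 4 = A,
5 ∈ {A,R}, 6 = N) rather than the literal string "AARN", which is one
admissible instance; a literal reading would reject consensus-conformant
TKs. The `(M/L)` set at motif-3 position 4 is taken as authoritative for
that rule. The `CW(X)6RPXF` motif is parseable and searchable but not part
of the default rules, because it is shared between TKs and TKLs and hence
not diagnostic.

## Logo statistics and motif discovery

Per-column information content is `IC = log2 20 − H` bits, with H the
Shannon entropy of the (optionally pseudocounted) column distribution and
an optional small-sample correction `e = 19/(2·ln2·N)`, clamped at 0.
All-gap columns are reported as undefined rather than 0.

Group-specific motif discovery compares two alignments sharing one column
coordinate system. For each window of w columns, the candidate element per
column is the smallest residue set covering ≥ `f_cons` (default 0.7) of
the target group's residues, capped at `k = 2` residues (matching the
two-residue degeneracies like `(M/L)` typical of these motifs) and
otherwise wildcarded. A candidate is *specific* when its match fraction is
≥ `f_in = 0.8` in the target group and ≤ `f_out = 0.2` in the background
group; overlapping specific windows are merged keeping the longest. The
thresholds make an algorithm out of what is otherwise a visual logo
comparison; they are parameters, not estimates.

## Distance trees and clade logic

Likelihood and Bayesian tree inference are deliberately out of scope; the
only downstream consumers of the tree are clade questions (monophyly,
sister group), which are agnostic to the inference method. The package
therefore uses p-distances (or Poisson-corrected, `−ln(1−p)`) over
template-anchored alignments and neighbor joining with the standard
Q-criterion. NJ pair selection is deterministic (lowest Q, ties by sorted
cluster labels) and negative branch-length estimates are clamped to 0.
NJ is exact on additive matrices — topology and path lengths are recovered
to 1e-9 on simulated trees — which is the regime the synthetic benchmarks
approximate. There is no analog of branch supports; none is invented.

Rooting places the root at the midpoint of the single edge separating the
outgroup; an outgroup not separable by one edge is an error, not a guess.
The pipeline's tree stage drops candidates whose template coverage is
below `min_domain_coverage` (default 0.5): sporadic decoys that clear the
bit-score cutoff do so on ~10–20 matched columns, and such fragments
carry no usable phylogenetic signal (in the worst case they share no
columns with another leaf). This mirrors the domain-confirmation step that
kinome pipelines run between profile search and phylogenetics.

## Synthetic benchmark

The generator emulates the statistical structure the analysis assumes,
not real evolution. A single synthetic 290-residue kinase-like scaffold
carries the canonical subdomain landmarks (Gly-rich loop, VAIK, HRD-type
catalytic loop, DFG, APE) with annotated I–XI intervals fixed once in the
source. Three group templates share the scaffold and differ at the
diagnostic motif slots — TK carries `DLRAAN` / `APIKWTAPE` / `GARM`, TKL a
Ser/Thr-style loop without the motif-2 proline or the motif-3 signature,
FslK diverged loop keys, no proline, and `GARP` — plus fixed lineage
"drift" substitutions outside the slots (FslK ~15, TKL ~40, outgroup ~90
positions). The drift reflects that real kinase groups are deeply diverged
families, and it is what gives the benchmark its tree geometry (FslK
closest to TK, outgroup far); with diagnostic-site differences alone,
between-group distances would sit below the pairwise p-distance noise at
the benchmark's 15 % substitution rate and no clade structure would be
recoverable by any method. A `CW(X)6RPXF`-instance is planted in all
templates, providing the shared (non-specific) motif for discovery tests.

Members are sampled per group by independent point substitutions
(replacement uniform over the 19 alternatives, so expected mismatch
fraction equals the rate) and geometric-length indels; motif positions are
deliberately *not* protected, so diagnostics must tolerate decayed motifs.
Defaults: 50 members per group at substitution 0.15 and indel 0.01 (mean
length 2), 50 i.i.d.-uniform decoys of 80–400 residues, no truncation.
Truncation, when enabled, cuts a member at a uniform position and flags
it; it is a separate event from indels so the two failure modes stay
separable. Species labels are drawn from a skewed weight table (two
dominant species, a tail, six species with weight 0), emulating the
uneven per-species distribution such lineages show. Every sequence has
its own seeded substream keyed by (group, replicate), so changing the
decoy count never perturbs the group members, and ids are assigned after
a seeded shuffle so they encode nothing about the truth.

The iterative-refinement corpus is a staged-search scenario: a lineage
template drifts twice at rate 0.15 (template → mid → far) with members
sampled at 0.02 around each tier, and the seed alignment holds three
near-template members. The suggested detection cutoff is defined by the
construction as 60 bits above the remote tier's best score against the
seed-only profile — below both the near/remote tier gap (≥ ~120 bits) and
the score gain refinement confers on the remote tier (≥ ~110 bits across
realizations), so near members are detectable from the seed alone while
remote members are reached only after the profile absorbs the mid-tier
drift. This is the mechanism the refinement loop exists to exercise.

### What passing on synthetic data does and does not show

The generator's i.i.d. substitution model has no rate heterogeneity,
no indel hotspots, no compositional bias, and decoys are uniform-random
rather than low-complexity protein sequence; real proteomes are harder on
all counts. Benchmark results certify the algorithms' correctness and the
pipeline's wiring, not expected performance on real kinomes. Note also
that on 15 %-mutated single sequences the three-motif verdict decays
roughly binomially (≈19 diagnostic positions × 0.85 retention ⇒ only a
few percent of true TK members keep every key residue), which is why the
verdict criteria are stated on clean template sequences; on real data the
diagnosis is meant for curated members or group consensus patterns, as in
the workflow this package re-creates.

## Problem sizes and numerical conventions

Default problem sizes — 290-column profiles, 200-sequence benchmarks,
≤ 70-leaf trees, 100–200 random oracle instances — were chosen so the full
test suite runs in well under a minute and the acceptance script in a few
seconds on one CPU, while every stage still operates in its intended
regime. Coordinates are 0-based half-open everywhere; tables are
tab-separated with a single header row; JSON reports carry a schema tag;
profile files are a versioned plain-text format whose reader rejects
unknown versions. All stages are deterministic given their config and
seed, and re-running a stage with identical inputs is byte-identical on
all outputs.

## Known limitations

- Bit scores are not HMMER-comparable and there is no E-value calibration;
  the 20-bit default cutoff is a working convention.
- Refinement projects members onto fixed seed columns; columns absent from
  the seed alignment can never be recovered.
- NJ trees carry no support values; clade answers are point estimates.
- The FASTA header rule (id up to first whitespace or `|`, species after
  the first `|`) is one convention covering the common provider dialects;
  exotic header schemes need a custom reader.
- Motif discovery reports ungapped window patterns only.
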