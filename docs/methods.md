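# Methods

## Grammars and parsing

Grammars are deterministic context-free rule sets ⟨V, Σ, s, P⟩ in a plain
text format (one rule per line, `lhs <- item ...`, quoted items are
tokens).  Two rule kinds exist: *expansions* over internal symbols (a
quoted literal such as `'('` may appear inline and becomes a single-token
terminal slot) and *acceptance* rules mapping an internal symbol to a
terminal class of one or more tokens.  Rule indices are 1-based in file
order and identify weight layers in the per-rule sharing mode.

Determinism is operationalised as a conflict-free canonical LR(1) ACTION
table (`ngn.lr`), built at load time; LR(1) accepts every LALR(1)-clean
grammar, so the check is conservative in the right direction.  Conflicts
are reported as data (shift/reduce, reduce/reduce, and a token-dispatch
class for the case where two terminal classes admitting the same text are
shiftable in one state); loading a conflicted grammar fails unless
`allow_conflicts` is set, in which case parsing prefers shifts and the
first-listed rule.  The tokenizer is a greedy longest-match scanner
(`Cl`/`Br` must beat `C`/`B`); when a token text belongs to several
terminal classes (`-` is a bond between atoms but a charge sign inside a
bracket atom) the parser resolves the class from its LR state.  Character
offsets are 0-based.

Three grammars ship with the package: `smiles_subset`, the 10-rule
teaching fragment over branched C/O chains; `smiles_extended`, a practical
organic-subset SMILES (aromatic lowercase atoms, bond symbols `- = # / \`,
single-digit ring closures, branches, bracket atoms with optional isotope,
chirality `@`/`@@`, H-count and charge); and `inchi_basic`, which covers
the InChI header, formula layer and the `/c` and `/h` layers as opaque
token sequences.  The extended SMILES rule set is this package's own
design: it is validated as deterministic and accepts standard organic
SMILES, but it is a syntax, not a chemistry — valence, aromaticity
perception and stereochemical meaning are never checked.  `inchi_basic`
has one known lexical coarseness: the version token `1S` is preferred by
longest match, so a formula containing the literal character pair `1S`
(e.g. `C11S...`) mislexes; full InChI is explicitly out of scope.

## Network

Weight layers are keyed, by default, to (lhs symbol, child slot) of the
symbol's *child signature* — the union over the symbol's productions of
their right-hand slots in first-appearance order, with all acceptance
rules of an lhs merged into one terminal slot whose one-hot width is the
union of their tokens.  Layers are therefore shared across productions
with the same lhs; slots a given production does not fill are recorded as
zero-flushed.  A `per_rule` mode keys layers by (rule, position) instead;
the two modes are not expected to give identical results and both are
tested.

Feedforward computes, children before parents,
`α_u = L(Σ_present w_(u,slot) α_child + b_(u,slot))`.  Two conventions the
formulation leaves open are fixed as follows and matter for exactness:

* **Bias placement.**  Each slot's layer carries its own bias and all
  present slots' biases are summed at the parent.
* **Zero-flushed slots contribute nothing** — not even their bias.
  Feeding a zero vector through the weight matrix vanishes either way;
  excluding the bias as well is the only reading under which an unused
  layer is genuinely "not updated given the current string", which the
  update rule then guarantees structurally (unused keys keep weights,
  biases and momentum buffers untouched).

The output head is a dedicated one-unit trainable layer above the start
symbol; targets are scalars in the configured output scale (0.2, 0.8), so
classification uses 0.8/0.2 as class targets and a 0.5 decision threshold
(the scale midpoint).

Backpropagation through structure uses the sum-of-squares deltas
(δ_out = (y−ŷ)ŷ(1−ŷ); hidden deltas fold the logistic derivative with the
single parent connection).  Every occurrence of a shared key records its
own delta group; the applied update is their *sum*, plus momentum
α·ΔW(t−1) applied per exemplar (the "previous time step" is the previous
exemplar that used the layer).  The learning rate η is folded into the
per-instantiation deltas — equivalent to applying it after summation by
linearity, fixed for bit-reproducibility.  The sign convention is pinned
by a central-finite-difference oracle: every delta must descend the
squared error.

Training is online: per exemplar, feedforward → backprop → update, in an
order reshuffled each epoch from the run seed.  Epoch RMSE is computed
from the outputs as encountered during the epoch; RMSE below the threshold
means convergence.  Exhausting `max_epochs` triggers re-initialization
from a seed derived via `SeedSequence([seed, attempt])`, up to
`max_restarts` (default 3, a bound the procedure needs but the design
leaves open).  Initial weights and biases are drawn uniformly from the
two-band range [−hi, −lo] ∪ [lo, hi], band chosen equiprobably per entry.

Two implementations exist: an object-level numpy reference
(`assemble`/`feedforward`/`backprop`/`apply_updates`) and a flattened
numba kernel (`ngn.engine`) that `train` uses.  They perform the same
per-exemplar update; a test pins their trained libraries against each
other to 1e-10.  Only the accumulation order of one key's instantiation
deltas differs (float-rounding level).  Determinism: identical (dataset
order, seed, config, engine) gives a bit-identical library.

## Parameter presets

| preset | η | α | RMSE | epochs | init bands | hidden | scale |
| --- | --- | --- | --- | --- | --- | --- | --- |
| classification | 0.60 | 0.90 | 0.05 | 5000 | [1.0, 1.6] | 8 | (0.2, 0.8) |
| regression_cv | 0.30 | 0.10 | 0.03 | 7500 | [1.0, 1.6] | 8 | (0.2, 0.8) |
| regression_designed | 0.33 | 0.66 | 0.04 | 7500 | [0.4, 1.2] | 8 | (0.2, 0.8) |
| toxicology_ngn | 0.30 | 0.30 | 0.05 | 10000 | [1.0, 1.6] | 12 | (0.2, 0.8) |

The toxicology design distinguishes a training threshold (0.05) from a
stricter convergence pre-test (0.03); both are separate config fields.
Hidden size may also be set per internal symbol.  η is the online learning
rate; α the momentum coefficient (fraction of the previous applied delta
carried over); the init bands keep initial weights away from zero, which
shortens convergence without hurting accuracy.

## Evaluation statistics

Q = (tp+tn)/n, SE = tp/(tp+fn), SP = tn/(tn+fp);
MCC = (tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn)), defined as 0 when a
factor vanishes.  Predictions at or above the threshold count positive.
q² = 1 − PRESS/SD with PRESS = Σ(tᵢ−pᵢ)² and SD = Σ(tᵢ−t̄)² computed on the
test set only; undefined for constant test targets.  Epsilon is the
per-trial *sum* of absolute residuals (absolute values make "Epsilon → 0 ⇔
small residuals" literally true; a signed mode exists behind a flag), its
SD is the sample standard deviation of the absolute residuals (0 for a
single pair).  Targets are min-max normalized into (0.2, 0.8) as a convex
combination `lo·(1−u) + hi·u`, so the dataset extremes land on the
endpoints exactly in floating point.

The Wilcoxon signed-rank test drops zero differences, average-ranks ties,
enumerates the null distribution of W+ exactly over all 2ⁿ sign patterns
for n ≤ 12 (valid with ties, and symmetric about its mean, which gives the
two-sided p), and uses the tie-corrected normal approximation with
continuity correction above.  Method comparison pairs trials, tests the
one-sided alternative in the observed direction, and declares a winner
below p = 0.05; with three trials the exact floor (1/8) already exceeds
that, so small comparisons cannot produce a winner.

## Cross-validation designs

Leave-20%-Out: 5 near-equal folds, each fold the test set 10 times → 50
trials.  Leave-5%-Out: 20 folds, one trial each → 20 trials.  Designed:
an explicit test split, 10 repetitions.  Grouped five-fold: sort by
target, deal round-robin into 5 clusters (each spans the output range);
random five-fold: a fresh random fifth per trial.  Per trial the library
is re-seeded from (plan seed, trial index); non-converged trials are
flagged and excluded from the mean ± sample-SD aggregates, and the ±
spread is across trials.

The baseline for paired comparisons is a plain 3-layer logistic network
(2 hidden units, η 0.9, momentum 0.3, init U(−0.3, 0.3), 50 000-epoch cap)
over transparent, string-computable token-count descriptors (per-element
counts, branch openings, ring-closure digits, per-bond counts, total
tokens), min-max scaled per feature on the training set.  The point of the
baseline is the protocol — identical convergence/restart contract and
paired statistics — not descriptor sophistication; by construction it
discards token order, which is exactly what the grammar-structured network
keeps.

## Synthetic data

The generator performs stochastic leftmost derivation: at each internal
symbol it draws uniformly among the productions whose minimal completion
depth fits the remaining budget, so sampling always terminates and every
string parses under the generating grammar.  Label rules: token presence,
substring presence, token-count threshold (classification, resampled to a
50/50 balance; the minority class of a presence rule is exponentially rare
under uniform choice, hence a generous rejection budget), and scaled token
count (regression; raw count plus optional Gaussian noise, min-max
normalized into (0.2, 0.8)).  Duplicate strings are dropped so no string
carries two targets, which would bound training RMSE away from zero.

What these datasets emulate is the *shape* of QSAR data — grammar-valid
strings with labels tied to structural features at realistic sample sizes
(n = 150–200).  What they do not emulate: chemical plausibility (no
valence), label noise structure of assay data, activity cliffs, or the
scaffold redundancy of curated datasets.  Passing learnability benchmarks
therefore demonstrates that the machinery optimizes and generalizes on
structured string tasks at these sizes, not that any particular accuracy
carries over to real assay data.

Benchmark problem sizes used by the test suite: contains-oxygen
classification, n = 200, 10 seeded runs over Leave-20%-Out folds under the
classification preset; scaled-C-count regression, n = 150, 5 held-out
fifths under the cross-validation regression preset.

## Numerical and design notes

* Logistic activations keep outputs strictly inside (0, 1); target scale
  endpoints 0.2/0.8 avoid the saturated tails.
* Finite-difference gradient checks use central differences with step
  1e-5 and a 1e-10 absolute floor: below that, fd rounding noise dominates
  the relative comparison on near-zero derivatives.
* Ties in classification (prediction exactly at threshold) count as
  positive; activity exactly at a labeling threshold is positive, with a
  direction flag to invert.
* The model archive is versioned JSON holding the grammar text, the full
  configuration and every layer's weights, biases and momentum buffers —
  the library *is* the accumulated training, so it round-trips exactly.
* Known limitations: signal attenuation down deep parse chains (long
  molecules train more slowly and less reliably); the network recognizes
  local syntactic context, not token distances or run lengths; grammars
  with empty right-hand sides are not supported by the file format; the
  per-rule/per-symbol sharing choice changes the parameterization, and
  results are comparable only within one mode.
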