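# ngn — Neural Grammar Networks for QSAR

`ngn` predicts biological activity of molecules (the QSAR problem —
quantitative structure–activity relationships) directly from their string
notation, with no hand-designed descriptor vectors.  A molecular string
(SMILES, or a simplified InChI) is parsed with a deterministic context-free
grammar; the unique parse tree becomes the topology of a per-molecule
neural network assembled from a *finite library of shared weight layers*,
one per grammar binding.  Training is backpropagation through structure:
because the same layer is instantiated wherever its production applies, a
finite model processes molecules of unbounded size, and what it learns is
tied to syntax — *where* in a traversal a feature occurs, not just how
often.

## The model

A grammar is a four-tuple G = ⟨V, Σ, s, P⟩.  A string s(t) has a unique
parse tree T(t) under an unambiguous (LR(1)-clean) grammar.  Each child
slot of an internal symbol carries a weight layer W = (w, b) shared across
all of its occurrences.  Leaves are one-hot token vectors (1.0 at the
matched token); absent slots of a production are zero-flushed.  With
logistic L(x) = 1/(1+e⁻ˣ), a node u with children v computes

    α_u = L( Σ_v  w_(u,v) α_v + b_(u,v) )

and a one-unit output head above the start symbol yields ŷ ∈ (0,1).
Gradients use the standard sum-of-squares deltas,
δ_out = (y − ŷ)·ŷ·(1−ŷ) and δ_v = α_v(1−α_v)·Σ_i w_ij δ_u,i; the update of
a layer instantiated k times in one molecule is the **sum of its k
per-instantiation deltas** plus a momentum term α·ΔW(t−1).  Training is
online per exemplar, to an epoch-RMSE threshold, with seeded restarts.

Evaluation statistics: concordance Q, sensitivity SE, specificity SP,
Matthews correlation MCC for classification; q² = 1 − PRESS/SD for
regression; Epsilon (per-trial summed absolute residual), its standard
deviation, Pearson CC, and an exact/small-sample Wilcoxon signed-rank test
for paired method comparison.  Cross-validation designs include
Leave-20%-Out (5 folds × 10 reps), Leave-5%-Out (20 folds), explicit
designed splits, and grouped/random five-fold.  A token-count descriptor
ANN baseline is included for paired comparisons.

## Worked example

Isopentanol is `CC(C)CCO`.  Its leftmost derivation under the built-in
10-rule SMILES fragment (`smiles_subset`):

```bash
$ ngn parse --grammar smiles_subset "CC(C)CCO"
1 3 5 4 5 7 8 9 2 5 10 3 5 3 5 2 6      # 17 rule applications (one per line)

$ ngn parse --grammar smiles_subset "CC(C)CCO" --show counts
...  2 2   3 3   5 5  ...               # rules 2, 3, 5 used 2, 3, 5 times
```

so the shared layers bound to rules 2, 3 and 5 are instantiated 2, 3 and 5
times in the assembled network.  Fitting the model object on a synthetic
contains-oxygen task:

```python
from ngn import NeuralGrammarNetwork, TrainingConfig
from ngn.grammar import builtin_grammar
from ngn.synthetic import SynthTask, make_dataset

g = builtin_grammar("smiles_subset")
task = SynthTask(kind="classification", label_rule="contains_token",
                 param="O", n=60, max_depth=12, seed=11)
data = make_dataset(task, g)
model = NeuralGrammarNetwork([s for s, _ in data],
                             labels=[y for _, y in data],
                             grammar="smiles_subset",
                             config=TrainingConfig(max_epochs=2000))
res = model.fit(seed=0)
print(res.summary())
```

```
Neural Grammar Network fit
============================================
grammar:        smiles_subset (10 rules)
task:           classification
n exemplars:    60
sharing mode:   per_symbol_pair
library size:   12 weight layers
hidden size:    8
eta / momentum: 0.6 / 0.9
seed:           0
--------------------------------------------
converged:      True (epochs=29, restarts=0)
final RMSE:     0.0186 (threshold 0.05)
Q:              1.0000
SE:             1.0000
SP:             1.0000
MCC:            1.0000
```

Training converged after 29 epochs; Q/SE/SP/MCC = 1 means every training
molecule is classified correctly at the 0.5 decision threshold.
`res.predict(["CC(C)CCO"])` returns 0.773 — above 0.5, so isopentanol is
(correctly) called oxygen-containing.  `res.plot_convergence()` draws the
per-epoch RMSE; `res.save(path)` writes a versioned model archive.

The CLI also provides `ngn synth`, `ngn train`, `ngn predict`, `ngn eval`
and `ngn crossval`; see `ngn --help`.

## Layout

| module | contents |
| --- | --- |
| `ngn.grammar` | grammar model, file format, LR determinism check, built-ins |
| `ngn.lr` | canonical LR(1) table construction |
| `ngn.parse` | tokenizer, shift-reduce parser, derivations |
| `ngn.network` | weight-layer library, assembly, feedforward/backprop, training |
| `ngn.engine` | flattened numba training kernels |
| `ngn.model` | `NeuralGrammarNetwork` / `NGNResults` front end |
| `ngn.metrics` | Q/SE/SP/MCC, q², Epsilon, CC, Wilcoxon, normalization |
| `ngn.experiments` | fold plans, trial runner, descriptor-ANN baseline |
| `ngn.synthetic` | grammar-valid dataset generation |
| `ngn.io` / `ngn.cli` | .smi/CSV/config/model-archive I/O and the `ngn` CLI |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
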