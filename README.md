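# mvgat — multi-view graph attention for node classification

Real networks rarely come as a single relation.  The same proteins appear
in a physical-interaction view, a co-expression view and a text-mined
view; the same papers appear in a citation view and a text-similarity
view.  `mvgat` classifies the nodes of such *multi-view networks*: one
shared node set with features and (partially observed) labels, plus k
edge sets, one per relation.

The model encodes every view with multi-head neighbourhood attention

> α_ij = softmax_{j∈N_i} LeakyReLU( aᵀ[W x_i ‖ W x_j] ),  x_i′ = Σ_j α_ij W x_j ,

concatenating heads in hidden layers and averaging them at the output,
then fuses the per-view representations X⁽¹⁾..X⁽ᵏ⁾ with a second,
view-level attention

> β_ij(v) = softmax_j LeakyReLU( bᵀ[T x_v⁽ⁱ⁾ ‖ T x_v⁽ʲ⁾] ),  Z_v = Σ_j w_j(v) x_v⁽ʲ⁾ ,

so each node weights the views by how informative they are *for that
node*.  Training is full-batch Adam on masked cross-entropy, and the
reported labels come from the iteration with the lowest selection loss.
The whole computation is scheduled as a coupled membrane (P) system —
k+4 cells with audited communication channels, the k view sub-cells
running under an order-independence contract — which makes every run
bitwise reproducible and the parallel structure explicit.  Everything is
pure numpy, including a small gradient-checked reverse-mode autodiff
engine; there is no deep-learning-framework dependency.

A planted-community (stochastic block model) generator with per-view
informativeness, Gaussian-blob features and stratified splits makes every
stage testable without downloads, and loaders read the standard
two-column edge-list and `id  features…  label` table dialects.

## Worked example

```python
from mvgat import MultiViewNodeClassifier, informative_plus_noise_benchmark

net = informative_plus_noise_benchmark(seed=0)   # 120 nodes, 3 classes,
                                                 # 1 informative + 1 noise view
res = MultiViewNodeClassifier(net, seed=0).fit()
print(res.summary())
```

```
Multi-view graph attention node classifier
==========================================================
nodes: 120   views: 2   classes: 3   features: 10
layers: 2 (hidden 8, heads 8)   fusion: attention/per_node
iterations: 200   lr: 0.005   dropout: 0.6   seed: 0
best iteration: 199   selection loss: 2.2937
mean fusion weights: view 0: 0.789, view 1: 0.211
----------------------------------------------------------
split     accuracy  precision   recall       f1
train       1.0000     1.0000   1.0000   1.0000
val         1.0000     1.0000   1.0000   1.0000
test        1.0000     1.0000   1.0000   1.0000
==========================================================
```

The fusion weights are the interesting part: the model learned to put
0.789 of its weight on the informative view (uniform would be 0.5), and
the selected iteration classifies every held-out node correctly.
Training the noise view alone drops test accuracy to ≈0.4.

The same pipeline is available from the shell:

```sh
mvgat generate --out data/ --seed 7          # write a synthetic network
mvgat train --config config.yaml --out run/  # predictions, trace, metrics
mvgat ablate --config config.yaml --variant mmv
mvgat sweep --config config.yaml --heads 4,8 --lr 0.001,0.005
```

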