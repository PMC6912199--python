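# Methods

## Problem and model

`miralink` predicts which microRNAs (miRNAs) are associated with which
diseases. The input is a *bilayer* network: a bipartite disease–miRNA
association network (the known links), a disease–disease similarity layer
and a miRNA–miRNA similarity layer. Two complementary feature families are
extracted per (disease, miRNA) pair and classified by two deep-forest
models whose probability scores are fused linearly.

### Disease similarity (DS)

Diseases are compared through their associated gene sets on a functional
gene network whose edges carry log-likelihood scores (LLS). For diseases
$d_i, d_j$ with gene sets $S(d_i), S(d_j)$:

$$
DS(d_i,d_j) = \frac{\sum_{g_1\in S(d_i)} LLS(g_1, S(d_j)) +
              \sum_{g_2\in S(d_j)} LLS(g_2, S(d_i))}{|S(d_i)|+|S(d_j)|}
$$

and $DS = 0$ when both sets are empty. $LLS(g, S)$ — the score between a
gene and a gene *set* — is not a standard primitive; we aggregate as the
**sum** of the network edge scores from $g$ into $S$ (zero when no edge
exists), which matches the additive structure of the outer sums; `max`
aggregation is available as a configuration alternative. The full dense
$m\times m$ matrix is kept (no thresholding), so at $m=336$ the disease
layer has $336^2 = 112{,}896$ entries. The diagonal is computed by the
same formula rather than pinned to a constant; it only ever enters as a
feature coordinate.

### miRNA similarity (RS)

Four components are combined elementwise:

$$RS = \alpha\,RST + \beta\,RSF + \gamma\,RSC + \delta\,RSD,\qquad
(\alpha,\beta,\gamma,\delta) = (0.2, 0.1, 0.2, 0.5).$$

* **RST** — shared-target counts. Raw counts are unbounded while the other
  components live in $[0,1]$, so by default RST is normalised by its
  global maximum off-diagonal count (raw mode is a flag); the diagonal is
  forced to 0.
* **RSF / RSC** — binary family / cluster co-membership (1 if any shared
  group). The diagonal is 1 for annotated miRNAs and 0 otherwise.
* **RSD** — a precomputed disease-derived miRNA similarity matrix supplied
  as input (in real use, a MISIM-style matrix).

### Topology features (random-walk embedding)

DeepWalk-style embedding of the bipartite association network only (the
similarity layers are not walked): $\gamma = 10$ truncated random walks of
length $t = 40$ start at every node, stepping to uniformly random
neighbours; isolated nodes yield singleton walks and keep their
initialised embedding. SkipGram then maximises the likelihood of the
nodes within a window $w = 5$ of each walk position. The softmax over the
node vocabulary is factorised by a Huffman tree built on corpus
frequencies (ties broken by node ID for determinism): the probability of
a context node is the product of sigmoid branch factors
$\sigma(\pm\,\Phi(v_i)\cdot\Psi(b_l))$ along its root-to-leaf path, which
sums to 1 over leaves by construction. $\Phi$ is initialised uniformly in
$[-0.5/n, 0.5/n]$ (seeded), $\Psi$ at zero; the learning rate decays
linearly from 0.025 to $10^{-4}$; 5 epochs by default. The SGD inner loop
is JIT-compiled (numba) with a fixed update order, so training is
bit-reproducible. Default dimension $n = 128$.

### Pair vectors and the autoencoder

* similarity-based: $[DS\text{ row of }d \,\|\, RS\text{ row of }r]$,
  length $m+h$ (913 at the 336/577 scale), compressed by a symmetric
  autoencoder (encoder widths input–512–256, decoder mirrored; ReLU
  hidden, linear output, MSE loss, Adam, inputs min-max scaled per
  coordinate). The autoencoder is fitted **per CV fold on training pairs
  only** and then applied to test pairs, so no information flows from
  held-out pairs through the encoder. Input scaling and the training
  subset are design choices of this package.
* topology-based: $[\Phi(d) \,\|\, \Phi(r)]$, length $2n$ (256 at
  $n=128$).

### Deep forest

Each 256-d pair vector is classified by a deep forest: stride-1
multi-grained scanning with a single window (default 100), where every
window slice is scored by two small forests and the class-probability
vectors are concatenated; then a cascade whose layers hold four forests
(two random forests, two completely-random forests — `max_features=1`
extra-trees, the gcForest convention). Layer augmentation features are
produced by internal 3-fold cross-validation on the training set
(leak-free, also the early-stopping signal); growth stops when internal
accuracy stops improving or `max_layers` is hit. The final score is the
mean positive-class probability of the last layer's four forests. The
same configuration is used for both feature families, giving scores
$s_1$ (similarity) and $s_2$ (topology), fused as

$$s = \lambda s_1 + (1-\lambda) s_2, \qquad \lambda = 0.5.$$

Scanning is applied to the *post-encoder* 256-d similarity vector, not
the raw 913-d vector, following the pipeline ordering (encode first,
classify second).

## Sampling and cross-validation

With $m$ diseases and $h$ miRNAs the grid has $m\times h$ cells; known
associations are positives and everything else is unlabeled (at the
curated-data scale: $193{,}872 = 6{,}441 + 187{,}431$, a 1:29 ratio).
Assuming unknown true associations are of the same order as known ones,
they are diluted enough that negatives are drawn **uniformly without
replacement** from the unlabeled cells at a 1:1 ratio to the positives —
no degree matching or reliable-negative heuristics.

Per-disease five-fold CV: each disease's positives are shuffled (seeded)
and dealt round-robin into five folds. The five per-disease plans are
merged into five global training runs — fold $f$ removes the union of
every disease's fold-$f$ edges from the network before walk generation,
feature building and training; training everything separately per disease
would multiply cost by the disease count for no statistical benefit.
Negatives are resampled per fold (fresh derived seed) and drawn from the
pairs unlabeled in the *full* network, so a held-out positive can never
be sampled as a negative. Test candidates for disease $d$ are all miRNAs
not linked to $d$ in the training network; the held-out positives against
the remaining candidates give the per-disease ROC AUC (Mann–Whitney
concordance, ties ½) and top-$k$ precision/recall at
$k = 10, 20, \dots, 100$. Ranking ties break lexicographically by miRNA
ID so top-$k$ metrics are reproducible.

## Synthetic data generator

The generator emulates curated-database-style inputs with a
planted-partition (block) model, because the method's premise —
functionally similar genes tend to be associated with similar diseases,
so similar diseases share miRNAs — *is* a block-structure assumption.
Diseases, miRNAs, genes and targets are split into `n_blocks` contiguous
blocks; same-block disease–miRNA pairs associate with probability
`within_block_edge_prob` (default 0.5), cross-block pairs with
`cross_block_edge_prob` (default 0.02). Disease gene sets and miRNA
target sets draw mostly (`gene_overlap_strength = 0.8`) from their
block's pool; LLS edges are denser within block pools (0.3 vs 0.01,
weights uniform on [0.5, 2]); families (~4 miRNAs) and clusters (~6) are
within-block chunks; the precomputed miRNA similarity matrix is 0.8
within block / 0.1 across, plus symmetric N(0, 0.1) noise clipped to
[0, 1]. Setting within == cross removes the signal (the null fixture uses
0.2/0.2, keeping edge density moderate so every disease still has
positives to hold out).

The default scale — 30 diseases × 50 miRNAs, 3 blocks — exercises every
code path (including the window-vs-length guards) while keeping a full
5-fold pipeline run around a minute. What the fixture does **not**
emulate: real degree heterogeneity (HMDD-style hub diseases), miRBase
nomenclature, overlapping disease modules, or annotation noise that is
uncorrelated with the association structure. Passing the planted-signal
recovery check therefore demonstrates that the pipeline's machinery
recovers block-structured signal end to end, not that real-data AUC
levels would be reproduced.

## Operating points

Paper-scale defaults (`PipelineConfig()`): $n = 128$, autoencoder
input–512–256, scan window 100, 100 trees per cascade forest. For the
30×50 fixture the similarity vector has only 80 coordinates, so the
compact operating point (`PipelineConfig.compact()`) scales the geometry
down proportionally: embedding $n = 32$, autoencoder hidden 48 / latent
32, scan window 16, 60-tree cascade forests (20-tree scan forests), at
most 2 cascade layers. Tests and the acceptance script use the compact
point; all structural contracts (four forests per layer, two-class
probabilities, fold protocol) are identical at both scales.

## Numerical choices and edge cases

* All randomness flows from one seed through a multiplicative derivation
  (values kept below $2^{31}$); forests, walks, SGD and sampling are all
  seeded, making two runs with the same seed byte-identical.
* Symmetry of every similarity matrix is enforced at construction
  (tolerance $10^{-9}$); non-finite entries are rejected.
* RST normalisation guards the all-zero case (no division by zero).
* A degenerate fold (disease with no held-out positive, or a single-class
  candidate set) is skipped in the metrics for that fold; diseases with
  no positives at all are skipped with a warning.
* The internal-CV fold count is capped by the minority-class size
  (floor 2) so tiny training sets do not crash stratified splitting.
* Loss tracking for the SkipGram trainer restarts the linear
  learning-rate schedule each epoch (it is meant for diagnostics on small
  corpora, not as the production training path).

## Known limitations

* The deep forest's probability outputs are not calibrated; only the
  ranking matters for the reported metrics.
* The scale of RST relative to RSD is a normalisation choice; the exact
  combined RS values of any particular external dataset are therefore not
  recoverable, only their structure.
* DeepWalk is re-run per fold (the held-out edges must not shape the
  walks), so embeddings are fold-specific; no attempt is made to align
  embedding spaces across folds.
* Real-data evaluation (HMDD/HumanNet/miRTarBase/MISIM downloads,
  literature case studies, comparison against other predictors) is out of
  scope; the synthetic fixtures are the test bed.
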