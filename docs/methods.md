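# Methods

## Model and procedure

`linkdrp` treats cell-line-to-tumor drug response transfer as a link
prediction problem: the unit of representation is not a single expression
profile but a *pair* — the profile and a synthetic partner interpolated
toward a nearest neighbor — concatenated into one feature vector. The
underlying assumption is the standard transfer premise: tumors whose
(paired) expression representation resembles that of a cell line are
expected to show a drug response close to that cell line's IC50.

Three pipelines share one contract (training matrix + responses + test
matrix in, one predicted IC50-scale score per tumor out):

- **B** fits the final learner directly on the raw matrices.
- **A1** adds paired feature construction and link filtering.
- **A2** adds leverage-score column selection on top of A1.

### Paired feature construction

For each sample g_i, find its k′ nearest neighbors by Euclidean distance
*within the same set* (training samples pair with training samples,
tumors with tumors), excluding the sample itself — self-pairing would
reduce the construction to feature duplication. The synthetic partner is
g_b = g_i + (g* − g_i)·λ. The output has exactly 2n columns; training
rows carry their response unchanged, encoding that the original and
synthetic profile are linked by a shared response.

With the default k′ = 1 the construction is fully deterministic (distance
ties break toward the lower row index). For k′ > 1 one partner is drawn
uniformly from the k′ neighbors under a seeded generator, keeping one row
per sample. Test-set neighbors are deliberately searched within the test
set, not the training set: the pairing should capture local geometry of
the cohort being scored.

### Link filtering

The weight w_i of training row i is its minimum Euclidean distance to any
test row in the paired space — a transductive quantity that uses only
unlabeled test geometry, never test outcomes. The median of w splits the
training set into a test-proximal half X (w ≤ med) and a distal half Z
(w ≥ med); with continuous features ties have probability zero, and exact
median ties place a row in both halves (numpy's even-p median is the
midpoint of the two central order statistics, so both halves then hold
p/2 rows).

A ridge seed model trained on each half predicts the other half's
responses; each side is scored by the mean squared error over its own
prediction set. Using each side's own mean (rather than a shared
denominator) is the only reading that stays defined when weight ties make
the halves unequal, and it reduces to a shared denominator when they
match. The side whose model incurred the **larger** error becomes the
labeled pool S (ties go to X). This follows the selection formulas as
stated, although the surrounding intuition could be read as preferring
the smaller-error side; `assign_seed_set(..., rule="inverted")` exposes
the opposite convention for sensitivity analysis, and the default stays
with the formulas.

The relaxed query-by-committee loop then runs k″ = 5 iterations: fit the
committee (SVR linear / degree-5 polynomial / sigmoid, weights ⅓ each) on
S, score every U row by the weighted prediction variance
Σ_i w′_i (f_i(g) − f′(g))² about the weighted ensemble mean f′, and move
the argmax row (ties to lowest index) with its stored training response
into S. "Querying the label" is a lookup — U rows are training rows whose
responses are known. Consequently |S_final| = ⌈p/2⌉ + k″ whenever weights
are distinct, which is exactly the selected-set arithmetic the benchmark
tables exhibit (e.g. 482 → 246, 269 → 140); the count does not depend on
the gene count.

### Leverage-score column selection

Columns of the *filtered* training matrix (filtering precedes feature
selection) are ranked by normalized statistical leverage
π_j = (1/l)·Σ_{ξ≤l}(v_j^ξ)² over the top-l right singular vectors,
computed by a deterministic full SVD — no randomized sketching, so the
ranking is seed-free. Orthonormality of the singular vectors makes the
scores nonnegative and sum to one. Only the ranking is used; the explicit
C, U, R factors of a CUR approximation are never formed. The top-k
columns (ties to lowest index, returned in descending-score order) are
applied identically to training and test, preserving pairwise column
identity. Columns from the original and synthetic halves compete
independently; pairs are not kept intact.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ (`lam`) | 0.3 | interpolation fraction toward the neighbor; 0 duplicates, 1 lands on the neighbor |
| k′ (`k_prime`) | 1 | neighbors considered when drawing the synthetic partner |
| k″ (`k_doubleprime`) | 5 | rows transferred by the QBC loop |
| committee | SVR linear / poly-5 / sigmoid, weights ⅓ | disagreement voters |
| seed learner | ridge, α = 1 | cross-partition error scorer |
| SVR defaults | C = 1, ε = 0.1, γ = 1/#features, coef0 = 0 | libsvm conventions; the kernels are prescribed, the hyperparameters are not, so reproducible defaults are used with full override hooks |
| ridge α | 1.0 | penalty on coefficients only; the intercept is never penalized |
| `cur_rank` (l) | min(rows, cols, 100) | SVD rank for leverage scores; the external CUR implementation this mirrors does not document a portable default, so the rank is explicit |
| `top_k_genes` (k) | required for A2 | number of columns kept; dataset-specific, no silent default |
| `standardize` | off | optional z-scoring using final-training-subset statistics |

Predictions are raw response-scale scores; no calibration is applied
because evaluation is rank-based.

## Evaluation protocol

AUC uses the Mann–Whitney rank formulation with half credit for ties;
the resistant/non-responder class (label 1) is the positive class,
expected to receive higher predicted IC50. MAUC is the arithmetic mean
over runs of a strictly decreasing, nested training-size schedule;
which samples are dropped at each step is uniform random under the
schedule seed (the removal rule is otherwise unspecified).

The pairwise algorithm comparison is a two-tailed Wilcoxon signed-rank
test on per-run AUCs pooled across datasets. The default is the plain
normal approximation — no continuity correction and no tie variance
adjustment — because that is the variant consistent with the published
pairwise p-values for this protocol (an all-positive n = 10 comparison
with two midrank ties gives p = 0.0051 under this variant, 0.0050 with
tie correction, and ≈ 0.002 exactly); `method="exact"` (full sign-pattern
enumeration) and `method="approx-cc"` are available. Clinical groups are
compared by Welch's t-test by default (`equal_var=True` for the pooled
Student's form); the t-test variant is unstated in the protocol this
mirrors, and Welch is the safer default under unequal group sizes.

## Synthetic data

The generator emulates exactly the statistical structure the method
consumes: continuous expression features (i.i.d. standard normal), a
continuous response y = Xβ + ε with β nonzero on a small informative
gene set and ε ~ N(0, noise_sd²), and test tumors from the same model
whose binary label thresholds the same latent response at a quantile.
Gaussian marginals are used deliberately: every stage consumes only
distances, inner products and singular vectors, none of which require
heavy-tailed microarray realism for correctness testing. Continuity also
guarantees pairwise-distinct weights almost surely, which pins down the
selected-set arithmetic.

What the generator does **not** emulate: batch effects, cross-platform
homogenization artifacts, heterogeneous cell-line quality, or any
systematic train/test distribution shift. That last omission matters for
interpretation: on this synthetic family the training and test cohorts
are exchangeable, so discarding roughly half the training rows carries a
real information cost and the direct baseline can outscore the filtered
pipelines. Passing tests therefore demonstrate that each stage computes
what it claims (counts, widths, rankings, scores) — not that filtering
improves transfer on real clinical cohorts, which is precisely the regime
(quality gaps between cell lines and tumors) the synthetic model leaves
out.

Problem sizes in the test suite and acceptance script are chosen for
desk-scale runs: cohort-sized sample counts where the measured quantity
depends on p (the selected-set counts at p = 482, 473, 280, 269, with 50
genes, since the counts are n-independent), the study's gene counts where
it depends on n (paired widths at n = 6538 and 9114, with 12 samples),
and a 120 × 60-gene cohort for the end-to-end benchmark.

## Numerical choices and degenerate inputs

- All argmax/neighbor ties break toward the lowest index; selections are
  therefore deterministic and permutation-equivariant up to ties.
- Leverage scores reject l beyond the numerical rank (tolerance
  max(dim)·eps·σ₁) with a message recommending a smaller l.
- Seed fitting rejects partitions whose features are all-constant, naming
  the offending side.
- An all-zero paired column gets exactly zero leverage and can never be
  selected while k does not exceed the number of nonzero columns.
- Degenerate Wilcoxon pairings (all differences zero) return p = 1 with a
  warning rather than an error, so benchmark tables stay total.
- File parsing is strict: ragged rows, non-numeric cells and literal
  `NA` raise naming the line or cell; no imputation. Matrices round-trip
  through write/read bit-exactly (shortest-repr formatting on write,
  correctly rounded parsing on read).

## Limitations

- Real microarray preprocessing/homogenization is out of scope; inputs
  are assumed already comparable across the cell-line and tumor cohorts.
- The committee and seed-learner hyperparameters are conventions, not
  tuned values; no internal cross-validation is performed by design.
- With k′ > 1 the paired construction is randomized; all published-count
  guarantees are stated for the deterministic k′ = 1 default.
- Absolute AUCs on real clinical cohorts are not reproducible from this
  package alone, since they depend on external accession data; the
  reproducible surface is structural (set sizes, widths, score
  arithmetic, test statistics) plus synthetic end-to-end behavior.
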