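# tricgen

**tricgen** generates three-way synthetic datasets — observations × features ×
contexts grids, numeric or symbolic — with *planted, ground-truth triclusters*,
for benchmarking triclustering algorithms.

Triclustering is subspace clustering of three-way data: given a dataset
`D` with `n` observations, `m` features and `p` contexts (contexts are often
time points, as in gene–sample–time expression data or patient–feature–time
clinical records), the task is to find subspaces `T = (I, J, K)` whose cells
are coherent across all three dimensions. Real datasets carry no ground
truth, so algorithm comparisons are limited to intrinsic quality scores.
tricgen closes that gap: it plants triclusters with known location, pattern
and quality into a configurable background and emits the solution alongside
the data, enabling extrinsic evaluation (match scores, recovery rates)
against a known answer.

## The model

Every cell of a planted tricluster follows one of four coherence models:

* **constant** — `a_ijk = c`;
* **additive** — `a_ijk = c + α_i + β_j + γ_k`, one factor per row, column
  and context (a constant dimension has all factors 0);
* **multiplicative** — `a_ijk = c · α_i · β_j · γ_k` (a constant dimension
  has all factors 1);
* **order-preserving** — a single permutation `π` of one dimension such that
  every fiber along it, read in `π` order, is non-decreasing; the ordering
  is shared across the other two dimensions. On the context dimension the
  profile can be monotonically increasing, decreasing, or random.

A pattern triple `(P_row, P_col, P_ctx)` assigns one pattern per dimension,
drawn from {order-preserving, constant, additive, multiplicative, none};
admissibility rules leave 24 triples for numeric datasets and 10 for
symbolic ones.

Cells shared by overlapping triclusters combine under a **plaid** coherency:
`a_ijk = c + Σ_t θ_ijkt ρ_it κ_jt τ_kt` (additive), the analogous product
(multiplicative), the average (interpoled), or the last-generated
tricluster's value (none). Overlap is governed by four quotas: the fraction
of overlapping triclusters, the maximum group size `k`, the maximum shared
elements `⌊O_elements · min(|T_1|, |T_2|)⌋`, and per-dimension caps.

Data **quality** is controlled separately for background and triclusters:
missing values, noise and errors. Background percentages are exact counts;
tricluster percentages are per-tricluster maxima drawn uniformly. The noise
deviation `N_dev` separates noise (`|v − v'| ≤ N_dev`) from errors
(`|v − v'| > N_dev`), with rank distance on symbolic alphabets.

## Worked example

A 10×10×10 integer dataset with one planted 4×5×5 constant tricluster
(100 cells, so the background holds 900 cells) and exact background
degradation of 50% missing, 30% noise, 10% errors:

```yaml
# demo.yaml
dataset:
  dtype: integer
  dims: [10, 10, 10]
  alphabet: {min: 0, max: 9}
triclusters:
  n: 1
  rows: {dist: uniform, a: 4, b: 4}
  cols: {dist: uniform, a: 5, b: 5}
  ctxs: {dist: uniform, a: 5, b: 5}
  patterns: constant
quality:
  missing_background: 50
  noise_background: 30
  error_background: 10
  noise_deviation: 2
```

```
$ tricgen generate --config demo.yaml --seed 42 --out demo
wrote demo_data.tsv, demo_trics.txt, demo_trics.json
1 triclusters, coverage 0.1, missing 45%, noise 27%, errors 9%
```

The dataset-level percentages are over all 1000 cells: 900 × 50% = 450
missing cells is 45% of the dataset, 270 noisy cells 27%, 90 errors 9%.
Coverage 0.1 is the planted 100 cells over 1000. `demo_data.tsv` holds ten
tab-separated 10×10 slices (one `# context k` block per context; missing
cells are empty fields), and `demo_trics.json` is the ground truth — the
tricluster's rows/cols/ctxs, its pattern triple, and the degradation planted
inside it — validating against `src/tricgen/schemas/solution.schema.json`.

The same pipeline is available as a library:

```python
from tricgen import load_preset, generate
result = generate(load_preset("base/R"), seed=1)
result.report.n_triclusters   # 12
result.dataset.values.shape   # (1000, 100, 10)
```

Presets cover five real-data mimics (`real/dataset1..5`), the clean base
datasets (`base/R|S|B|C`), scalability (`scal/S1..S3`, 10⁷–10⁹ cells),
overlap and quality stress suites, per-pattern suites, and `rich/*`
combinations; `tricgen preset --list` enumerates them.

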