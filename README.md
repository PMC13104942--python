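# atlasmap

Reference-guided mapping of T-cell states for immune-checkpoint-inhibitor
(ICI) response analysis.

Single-cell studies of ICI response usually define T-cell states de novo
within each cohort, which makes reported "response markers" sensitive to
cohort composition and clustering choices. `atlasmap` implements the
alternative: query scRNA-seq cells are projected into a *frozen* reference
atlas embedding and interpreted entirely in that shared coordinate system.
It provides, end to end:

1. **Reference model fitting** — highly variable genes, per-gene scaling
   statistics and a PCA embedding (default d = 20) fitted once on an
   annotated reference atlas and then frozen.
2. **Query projection** — feature alignment (reference genes missing from the
   query are zero-imputed, query-only genes dropped), library-size
   normalization (ln(1 + 10⁴·x/total)), optional cell-cycle correction
   (the Tirosh S-minus-G2M module-score difference regressed out of every
   gene), standardization with the *reference* statistics, and projection
   through the stored loadings.
3. **k-NN consensus label transfer** — each query cell's k = 10 nearest
   reference cells vote; a state is assigned only if at least
   `min_votes` = 5 neighbours agree (and the maximum is unique), otherwise
   the cell is left **NA** rather than forced into a state.
4. **Identifiability** — per assigned cell,
   I(q) = (1/k) Σ_{a∈N_k(q)} 1{L(a) = L(q)}, the fraction of nearest atlas
   neighbours sharing the transferred label; a confidence score used to
   gate candidate response states (`prioritize_states`).
5. **Compositional response modelling** — per-sample cell-state proportion
   vectors (cohort labels, atlas labels including NA, or their granular
   `cohort|atlas` intersection), unpenalized logistic regression with
   deterministic collinear-column dropping (proportions sum to 1, so the
   design is exactly rank-deficient), ROC AUC, pair-based cross-validation
   (every responder/non-responder pair held out once), feature-subsampling
   stability grids (50–90% inclusion × 10 iterations × stratified 5-fold CV)
   and a per-principal-component information-gain decomposition.
6. **Synthetic data** — a generator producing a reference atlas with known
   discrete states, a cell-cycle confound, and batch-shifted query cohorts
   whose sample compositions differ by response status, with a deliberately
   coarsened "cohort" labelling — so the whole pipeline is testable with no
   external downloads.

The core is organised as scikit-learn-style estimators
(`ReferenceMapper.fit/transform`, `KNNConsensusClassifier.fit/predict`,
`CompositionalLogisticRegression.fit/predict_proba`); the module-level
functions (`fit_reference`, `project_query`, `knn_consensus`, ...) are thin
wrappers over them.

## Worked example

Simulate a study at its default scale (4,000 reference cells over 8 T-cell
states, 20 responders + 20 non-responders at 1,200 CD8 cells per sample,
with a mean response-state proportion shift of ≈ 0.10 on t-Teff), then map
and evaluate:

```bash
atlasmap --seed 1 simulate --out demo/data
atlasmap build-ref --counts demo/data/reference \
    --labels demo/data/reference_labels.tsv --dims 20 --out demo/model
atlasmap --seed 1 map --model demo/model --query-counts demo/data/query \
    --regress-cc --cc-genes demo/data/cc_genes.tsv --out demo/annotations.tsv
atlasmap features --annotations demo/annotations.tsv \
    --cell-meta demo/data/cell_meta.tsv --sample-meta demo/data/sample_meta.tsv \
    --scheme atlas --out demo/features.csv
atlasmap --seed 1 predict --features demo/features.csv --cv pair --out demo/predict.json
```

which prints (abridged):

```
wrote synthetic reference (4000 cells) and query (48000 cells) to demo/data
reference model: 1500 genes, 1500 HVGs, d=20, 4000 cells -> demo/model
mapped 48000 cells: 39981 assigned, 8019 NA -> demo/annotations.tsv
40 samples x 9 atlas features -> demo/features.csv
pair CV mean AUC = 0.840 -> demo/predict.json
```

About 17% of query cells fail the 5-of-10 consensus and stay NA — these are
cells whose batch-shifted profiles land between atlas states. The atlas-level
proportion features discriminate responders from non-responders with
pair-CV AUC 0.840; rebuilding the features with `--scheme cohort` (the
coarse simulated cohort labels, which bury the response state inside a mixed
"Non-exhausted" cluster) drops this to 0.524 on the same cells — the
resolution loss the atlas mapping is designed to undo. The annotation table
itself carries the per-cell confidence:

```
cell_id     assigned_label  n_match  identifiability
R01_c0001   Trm             7        0.7
R01_c0002   Teff            7        0.7
```

The same pipeline is available as library calls (`simulate_reference`,
`fit_reference`, `project_query`, `knn_consensus`, `aggregate_features`,
`pair_cv`).

## Input formats

* counts: 10x-style MTX triplet (`matrix.mtx(.gz)` + `features.tsv(.gz)` +
  `barcodes.tsv(.gz)`, genes as rows) or a dense delimited cells × genes
  table;
* metadata: TSV/CSV with headers (`cell_id`, `sample_id`, `cohort_label`;
  `sample_id`, `response` in {R, NR, anything-else → unknown});
* gene sets: two-column TSV (`set_name`, `gene_id`). The canonical Tirosh
  S/G2M cell-cycle lists ship with the package and are used when no
  `--cc-genes` file is given.

See `docs/methods.md` for the model details, parameter defaults, and what
the synthetic benchmark does and does not demonstrate.
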