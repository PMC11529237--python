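# tiab-screen

Semi-automated title–abstract (TIAB) screening for systematic reviews.

The package turns a citation export table (CSV with title, abstract and —
for screened rows — a human include/exclude decision) into screening
decisions and a workload report:

1. **corpus_io** — read/validate citation CSVs (configurable column
   dialects), filter records without abstracts, split train/test.
2. **text_processing** — lowercase → tokenize (letters only) → lemmatize →
   Porter-stem → dictionary filter (fill words out, stems absent from a
   reference English wordlist out). The Porter stemmer and a rule-based
   lemmatizer are implemented in-package; both wordlists are replaceable
   plain-text assets.
3. **features** — document-term count matrix (docs × stems, the p > n
   table), removal of terms appearing only once, and elastic-net logistic
   regression (penalty chosen by internal CV) whose nonzero coefficients
   are the selected features. A `LeakageGuard` enforces that selection only
   ever sees training rows.
4. **classifiers** — SVM (RBF), logistic regression, random forest
   (probability = tree vote share) and histogram gradient-boosted trees,
   tuned by grid search with stratified 5-fold CV on AUC.
5. **evaluation** — Mann–Whitney AUC, percentile-bootstrap confidence
   intervals, and the growing-training-set learning curve (nested batches,
   full chain re-run at every step).
6. **thresholding** — cross-validated cutoff selection: per fold, the
   smallest predicted inclusion probability among the fold's gold includes;
   aggregated by min (default), median or mean. Decision rule is inclusive
   (probability ≥ cutoff ⇒ forward to full-text screening).
7. **workflow** — ML-vs-human disagreement detection and the abstract-read
   / minutes-saved accounting for the semi-automated workflow.
8. **synthetic_corpus** — generator for labeled corpora with the assumed
   structure (class imbalance, short documents, sparse enriched signal
   terms, matching wordlist), plus a fixed hand-traced 8-document worked
   example used as an exact regression oracle.

## CLI

One directory per run; each stage writes its outputs, a log and its
resolved configuration:

```bash
tiab-screen simulate   --config config.yaml --out run/   # synthetic corpus
tiab-screen preprocess --config config.yaml --out run/   # text chain + DTM
tiab-screen train      --config config.yaml --out run/   # selection + tuned model
tiab-screen curve      --config config.yaml --out run/   # learning curve CSV
tiab-screen cutoff     --config config.yaml --out run/   # CV cutoff JSON
tiab-screen screen     --config config.yaml --out run/ --input new.csv
tiab-screen workload   --out run/ --n-total 4460 --n-train 1788 \
                       --n-test 2672 --n-disagreement 1358
```

Minimal `config.yaml`:

```yaml
seed: 1
input_csv: citations.csv        # omit when using `simulate`
dialect: {id_column: id, title_column: title, abstract_column: abstract,
          label_column: label}
text: {wordlist_file: wordlist.txt}   # defaults to the packaged starter list
classifier: {method: random_forest}
cutoff: {n_folds: 5, rule: min}
```

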