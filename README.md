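# phenorec

Collaborative filtering over binary phenotype profiles for rare-disease
diagnostic recommendation, with heterogeneous EMR–literature data fusion.

## The problem

The first step in diagnosing a rare disease is stratifying patients by
phenotypic similarity: a patient whose phenotype profile closely resembles
previously diagnosed patients probably shares their diagnosis.  `phenorec`
treats this as user-based collaborative filtering — diagnosing a patient
from similar patients' diagnoses the way a shop recommends products from
similar customers' purchases.  Evidence can come from two heterogeneous
sources: patient records (each patient contributes a binary set of
phenotype terms plus one confirmed rare-disease label) and literature
(subject–predicate–object predications asserting phenotype–disease
associations, merged into one pseudo-patient per disease).

The package is aimed at clinical-informatics researchers studying how
data-fusion strategies interact with neighborhood recommenders; it runs
entirely on synthetic corpora with planted disease signatures, so every
claim it makes is testable against known ground truth.

## The model

For patients *m*, *n* with phenotype sets `P_m`, `P_n` and
`c = |P_m ∩ P_n|`, four similarity coefficients are supported:

| token | name | formula |
|---|---|---|
| `tani` | Tanimoto | `c / (|P_m| + |P_n| − c)` |
| `ol` | overlap | `c / min(|P_m|, |P_n|)` |
| `fmg` | Fager & McGowan | `c / √(|P_m|·|P_n|) − 1 / (2·√max(|P_m|, |P_n|))` |
| `ll` | log-likelihood ratio | `1 − 1/(1 + G²)` with Dunning's G² of the 2×2 co-occurrence table over a phenotype universe of size N |

Neighborhoods are selected from the sorted similarity score map either as
the top *k* (KNN) or as all neighbors with similarity strictly above a
threshold *t* (TPN); *k* and *t* are tuned by leave-one-out RMSE over
rating predictions with sampled negative diseases.  Selected neighbors
cast similarity-weighted votes for their disease labels, normalized into
a probability-like score vector; the ranked vector is the recommendation.

Three fusion strategies prepare the training table: `emr` (patients
only), `emr_l` (patients mixed with per-disease merged literature
documents), and `emr_pl` (the same after pruning every literature
phenotype–disease pair that does not also occur in the EMR).  Evaluation
uses pooled precision–recall curves with PRAUC, mean average precision,
and per-disease precision/recall/F with macro-averaged F, each under
three increasingly relaxed disease-equivalence criteria: exact name
(`string`), shared semantic concept key (`concept`), shared disease
category (`category`).

## Worked example

```python
from phenorec import SimConfig, simulate_corpus, split_table, NeighborhoodRecommender

cfg = SimConfig(signature_overlap=0.5, phenotype_dropout=0.3,
                noise_phenotypes_per_patient=2, seed=11)
corpus = simulate_corpus(cfg)
train, test = split_table(corpus.emr, 0.2, seed=0)

model = NeighborhoodRecommender(measure="ll", neighborhood="knn", k=5).fit_table(train)
query = test[test.entity_ids[0]]
print("query patient:", query.entity_id, "true disease:", query.disease)
for disease, score in model.recommend(query.phenotypes, top_n=3).ranked:
    print(f"{disease}\t{score:.4f}")
acc = model.score([p.phenotypes for p in test], [p.disease for p in test])
print(f"held-out top-1 accuracy: {acc:.3f}")
```

prints

```
query patient: PAT00005 true disease: RD:0000
RD:0000	1.0000
held-out top-1 accuracy: 0.975
```

The corpus plants 10 diseases whose 8-phenotype signatures overlap 50%
with their neighbors, then corrupts each patient (30% phenotype dropout,
2 noise phenotypes).  All five nearest neighbors of this query carry its
true label, so the vote is unanimous (score 1.0); across the held-out
20% split the recommender still recovers the planted disease for 97.5%
of patients despite the signature overlap.

The same workflow is scriptable from the shell:

```sh
phenorec simulate --seed 11 -o corpus/
phenorec fuse --strategy emr_pl --emr corpus/profiles.tsv \
    --predications corpus/predications.tsv \
    --phenotypes corpus/phenotypes.tsv --diseases corpus/diseases.tsv \
    --seed 0 -o fused.tsv
phenorec tune --profiles fused.tsv --neighborhood knn --grid 1,3,5,7
phenorec recommend --profiles fused.tsv --query "HP:0000000|HP:0000001" --k 5
phenorec sweep --seed 0 -o sweep.json     # all 24 measure x rule x strategy groups
```

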