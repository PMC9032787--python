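# gcmed

Graph Code indexing, relevance filtering, query-by-example, reasoning and
natural-language explanation for medical multimedia feature fusion.

## The problem

A patient's record is a heterogeneous multimedia object: X-ray images,
DICOM headers, lab panels, doctors' letters. Once feature extraction has
turned each asset into a **multimedia feature graph** (MMFG) of vocabulary
terms and typed relationships, two problems remain for retrieval and
diagnosis support:

1. graph traversal does not scale as the level of detail grows, and
2. most extracted terms (name, date of birth, scanner model, ...) occur in
   every asset and carry no retrieval signal.

`gcmed` implements the **Graph Code** answer to both. A Graph Code is the
2D adjacency-matrix projection of an MMFG: an ordered dictionary
*dict_GC* of feature vocabulary terms plus a square matrix whose cell
*m(i,j)* holds the directed relationship row-term → column-term. Cells are
tagged: term presence (diagonal), a relationship-type code, a **discrete
value** *D(x)* for quantitative measurements, or — in query codes only — an
inclusive **value range** *D(a–b)*. Matrix operations replace graph
traversal, so similarity, union, difference and filtering are linear in the
dictionary.

On top of the index, the package provides:

* **Set algebra** — a patient's cumulative code `GC_P(t) = ⋃ GC_P(i)`,
  subtraction of whole terms with their rows/columns, and change-sets
  between two timed codes ("what happened between January and July?").
* **Relevance** — an adapted TF-IDF. Since a dictionary holds unique terms,
  term frequency is replaced by the discrimination weight `M_DIS` (the
  count of non-empty off-diagonal cells in the term's row, floored at 1):
  `tfidf(t, GC) = max(rw(t), 1) · ln(N / df(t))`. Terms with zero collection
  relevance (exactly the ubiquitous ones) form the stop code `SGC_STOP`;
  subtracting it yields the **Feature Relevant Graph Code**
  `FRSGC = SGC − SGC_STOP`, an aboutness score `M_ABT`, and the
  emerging-entity surface over patient histories.
* **Similarity & queries** — the metric triple `(M_F, M_FR, M_RT)` over
  vocabulary overlap, relationship positions and relationship values, with
  `IN (a, b)` / `EQUALS x` predicates that match numeric discrete cells
  against inclusive ranges.
* **Reasoning** — knowledge validity `KV(vt_i, vt_j) = s/p` (supporting
  codes over co-occurring codes) splits observed relationships into a
  Poole-style default theory `T = (F, D)`; a forward chainer over binary
  Horn rules (e.g. transitivity of "above") grows `F` to its fixpoint.
* **Explanation** — audience profiles map terms to labels (LBL) and cell
  contents to phrases (PHR); every non-empty off-diagonal cell of an
  explaining code expands through `m(i,j) ≠ 0 → LBL PHR LBL`, and clauses
  within the small English lexicon get a full PS-tree derivation
  (`S → NP VP`, `VP → V PP`, `NP → DET N`, `PP → PR NP`).

## Worked example

```python
from gcmed import *
from gcmed.synthetic_data import CollectionSpec, TimelineSpec, make_collection, make_timeline

# --- encode a face-landmark feature graph -------------------------------
g = MultimediaFeatureGraph(asset_id="faces")
for n in ("Face 1", "Face 2", "Eye Distance"):
    g.add_node(n)
g.add_edge("Face 1", "Eye Distance", value=27.21)
g.add_edge("Face 2", "Eye Distance", value=18.14)
print(encode(g).to_frame())
#              Face 1 Face 2 Eye Distance
# Face 1            1      0     D(27.21)
# Face 2            0      1     D(18.14)
# Eye Distance      0      0            1

# --- range query: which face has eye distance in [27.10, 27.25]? --------
q = build_query([parse_predicate("Eye Distance IN (27.10, 27.25)")])
# per-face codes built from the rows above, then:
# rank(coll, q) -> [("face-1", (1.0, 1.0, 1.0)), ("face-2", (1.0, 1.0, 0.0))]
# face-1 matches on value (27.21 lies inside the inclusive range), face-2
# shares the vocabulary and the cell position but fails the value test.

# --- stop-code compression ----------------------------------------------
coll = make_collection(CollectionSpec(6, 24, 12, density=0.3, seed=7))
report = build_stop_code(coll, threshold_fraction=0.0)
fr = feature_relevant(coll.codes[0], report.stop_code)
print(len(coll.codes[0].dictionary), coll.codes[0].n_cells, "->",
      len(fr.dictionary), fr.n_cells)
# 36 1296 -> 12 144        (the 24 collection-wide terms are removed:
#                           an 88% reduction of the matrix)

# --- timeline explanation -----------------------------------------------
tl = make_timeline(TimelineSpec("P1", events=(
    ("January", "blood-pressure", 140), ("July", "blood-pressure", 155))))
d = diff(tl.snapshots[0][1], tl.snapshots[1][1], labels=("January", "July"))
print(render(ExplanationPlan(source=d, mode="timeline_diff", audience=MEDICAL_PROFILE)))
# between January and July, the blood pressure increased from 140 to 155.
print(render(ExplanationPlan(source=d, mode="timeline_diff", audience=PATIENT_PROFILE)))
# between January and July, your blood pressure increased from 140 to 155.
```

The same workflows are available from the shell via the `gcmed` command
(`encode`, `union`, `diff`, `relevance`, `stopwords`, `query`, `explain`,
`simulate`, `reason`), e.g.

```sh
gcmed simulate collection --spec spec.json --out coll/
gcmed query --collection coll/ --where "Eye Distance IN (27.10, 27.25)" --top 5
gcmed diff --earlier jan.json --later jul.json --labels January July \
      --explain --audience patient
```

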