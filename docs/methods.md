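# Methods

## The index model

A Graph Code is an ordered dictionary of unique feature vocabulary terms
plus a square matrix of tagged cells over that dictionary. Cell (i, j)
describes the *directed* relation row-term → column-term; the matrix is not
required to be symmetric. Cell contents are a tagged union:

| tag      | meaning                                   | where legal        |
|----------|-------------------------------------------|--------------------|
| empty    | no relationship                           | anywhere           |
| presence | the term exists (printed as 1)            | diagonal only      |
| rel_type | relationship-type code (integer > 1)      | off-diagonal       |
| discrete | a measured value `D(x)`, number or text   | anywhere           |
| range    | inclusive numeric bounds `D(a–b)`         | query codes only   |

One cell holds one tagged value; a term pair never carries both a type code
and a discrete value. The registered type-code table is 1 = presence,
2 = generic association, 3 = belongs-to/part-of, 4 = is-a, 5 = spatial
"above"; further codes are registrable at run time
(`register_relationship_type`). Dictionary order is insertion order and is
stored explicitly in both serializations (sparse JSON and the CSV matrix
table), so code equality is well defined; `structurally_equal` additionally
offers order-free comparison.

Quantitative measurements are stored as discrete cell values rather than as
vocabulary terms of their own. This keeps the dictionary finite: a
value-as-term encoding adds one row and column per distinct measured value.
Three placement conventions coexist in practice and are all supported:
attribute edges (face → eye-distance carrying `D(27.21)`), diagonal cells
(one database row mapped column-by-column), and key-value metadata edges
(tag → asset root). Term labels are normalized by trimming and collapsing
whitespace only; case is preserved because clinical vocabulary is
case-meaningful (BMI vs. bmi).

## Algebra over timed codes

A patient is modeled as a multimedia object accumulating snapshots; the
cumulative code at time t is the left fold of cell-wise union over all
snapshots up to t. Union keeps a's dictionary order, appends b's unseen
terms, and resolves conflicting non-empty cells in favor of the *newer*
operand with a logged warning — a timeline must surface the latest
measurement, while history stays in the snapshot store. Under this
rightmost-non-empty-wins policy union is idempotent and associative
(property-tested).

Subtraction removes whole terms: every dictionary term of the subtrahend is
dropped from the minuend together with its matrix row and column, so a
d-term code with k removed terms shrinks from d² to (d−k)² cells.

The difference of two timed codes is represented as a change-set
(`DiffResult`): terms added, terms removed, and, over shared terms, cell
pairs whose values differ with both the old and the new value retained (the
explanation layer needs both ends of "increased from 140 to 155").
Change-sets also record the later code's cells that touch added terms, so
`apply_diff(earlier, diff(earlier, later))` reconstructs `later` exactly —
the patch round-trip is a property test. A plain-code projection
(`project_diff`) exposes the change-set to the metric layer. A literal
set-algebra reading of "union then intersect with the earlier code" would
collapse to the earlier code itself, so the change-set semantics is used
deliberately.

Timestamps are opaque strings. Snapshot order as given is authoritative;
strict increase is enforced only for duplicate labels, because clinically
natural labels ("Jan", "Jul") do not sort lexicographically. Lookups accept
either an exact snapshot label or an ISO-8601-comparable bound.

## Relevance

A Graph Code dictionary contains each term once, so classical term
frequency is unavailable. The discrimination weight of a term — the number
of non-empty off-diagonal cells in its matrix row — takes its place:

    tfidf(t, GC)  = max(rw(t, GC), 1) · ln(N / df(t))
    tfidf_coll(t) = Σ_{GC ∋ t} tfidf(t, GC)

with N the collection size and df(t) the number of codes whose dictionary
contains t. The floor at 1 prevents a structurally isolated but present
term from being auto-eliminated; the natural logarithm is a documented
constant (base choice only rescales every score). With the floor,
`tfidf_coll(t) = 0 ⇔ df(t) = N`: the stop code at threshold 0 contains all
and only the collection-ubiquitous terms. A threshold fraction additionally
stops the lowest `floor(fraction · remaining)` terms ordered by
(tfidf, label) — the lexicographic tie-break makes stop-code construction
deterministic. The computed stop code can be edited (terms added or
protected) before use.

Derived quantities:

* `M_DIS(i, j)` = rw(i) − rw(j), antisymmetric; rankings use |M_DIS|.
* `M_REL(i, j)` = tfidf_coll(i) − tfidf_coll(j).
* `FRSGC = SGC − SGC_STOP` via the algebra's subtraction; idempotent.
* `M_ABT(GC, SGC_STOP-ED)` = fraction of the code's vocabulary surviving
  subtraction of the *edited* stop code, in [0, 1]. Of the two readings of
  "distance to the topical domain", the surviving-vocabulary fraction was
  chosen because it directly supports the filtering use case (drop an asset
  whose aboutness falls below a cutoff); the scalar is deliberately simple
  and can be replaced by a metric-triple-based distance without touching the
  module surface.
* History relevance (`frsgc_hist`): per patient, the projection of the
  change-set between the cumulative codes at the window's ends; the
  per-patient projections form the baseline collection for a relevance
  table. Emergence is read off the document frequency across patients — a
  term newly appearing in *every* patient's window has tfidf 0 in this
  baseline by construction, so df, not tfidf, is the emergence signal.
* Per-patient and application-wide relevance baselines are the same
  mechanism applied to different collections (one patient's snapshots vs.
  all patients' codes); no separate code path exists.

## Similarity and queries

The metric triple is containment-style, normalized on the query side:

* `M_F`  = |dict_Q ∩ dict_C| / |dict_Q|;
* `M_FR` = fraction of the query's *queried* cells (all non-presence cells)
  that land on a non-empty candidate position;
* `M_RT` = fraction of queried cells whose candidate value also matches:
  equal type code, equal discrete value, or a numeric discrete value inside
  the query's inclusive range.

Value matching implies position matching, so `M_RT ≤ M_FR`, and
self-similarity is (1, 1, 1). `EQUALS x` on numeric x is compiled to the
degenerate range [x, x]; on text it is discrete equality. A value predicate
that names only one term is placed on the query's diagonal and is checked
against every candidate cell incident to that term (row, column or
diagonal), which makes one query form work across all three value-placement
conventions. Vacuous cases are pinned: an empty query matches everything at
(1, 1, 1); a query with terms but no queried cells scores M_FR = M_RT = 1
when its whole vocabulary occurs in the candidate and 0 otherwise (so
disjoint dictionaries give (0, 0, 0)). Ranking is descending lexicographic
on the triple — vocabulary overlap dominant — with asset-id tie-break; a
weighted-sum mode is available where a scalar score is preferred.
Widening a range predicate can only grow the set of matching values, so
M_RT is monotone in range width (property-tested).

## Reasoning

Knowledge validity of a typed relationship (i, j, type) is the support
ratio s/p, where p counts collection codes containing both terms and s
those whose (i, j) cell carries exactly that type. The score is kept on the
natural [0, 1] scale so that a "90% validity" threshold reads directly; a
logarithmic variant (ln s/p, range (−∞, 0]) is available behind
`log_scale=True` for callers who transform thresholds accordingly.
`extend_facts` enumerates only relationships observed in at least one code
(the type space is unbounded, so never-observed triples are not
hypothesized) and splits them into facts (kv ≥ threshold, provenance
recorded) and scored hypotheses; it is monotone in the threshold. The rule
engine is intentionally minimal: binary Horn rules chaining two typed
relationships through a shared middle term, of which per-type transitivity
is the canonical instance. Forward chaining terminates because the fact
universe over known terms and types is finite, and is idempotent at the
fixpoint. Richer rule languages are out of scope by design; the module's
JSON rule format is the extension point.

## Explanation

Audience profiles are data, not code: a JSON object with term → label (LBL)
and cell → phrase (PHR, keyed by type code or "D" for discrete values)
mappings, a change-sentence template, and direction words. Two profiles are
built in — "medical" (terse: PHR_D = "has a value of") and "patient"
(didactic labels, second person: PHR_D = "Your value is") — plus a neutral
"generic" profile. Missing labels fall back to the raw term with a logged
warning, so profile lookup is total.

An explaining code is the subtraction of two codes (result minus query, or
result minus result) and thus carries only distinguishing content. Each
non-empty off-diagonal cell emits exactly one clause `LBL(row) PHR LBL(col)`
(for discrete cells the value itself takes the object slot), in dictionary
row-major order; an empty explaining code renders the profile's fixed
no-difference sentence. Timeline change-sets render through the change
template, direction chosen by comparing old and new numeric payloads
("increased" / "decreased", "changed" for non-numeric). Sentences are
terminated with "." and newline-joined; rendering is deterministic for a
fixed plan and profile, and swapping the profile changes surface text only,
never which cells are explained.

Every cell clause is derivable from the declared productions: the
Graph-Code production `m(i,j) ≠ 0 → LBL PHR LBL` always applies (the
renderer keeps clauses segmented, so generate-then-parse is closed), and
when every token of a clause belongs to the English lexicon the full
PS-tree under `S → NP VP, VP → V PP, NP → DET N, PP → PR NP` is produced
instead, with parse errors naming the first unmatched symbol. Template
change sentences are surface text outside the clause grammar; they are not
given derivations.

## Synthetic data

The collection generator emulates the structure of a "mostly similar
assets" test collection: every element's dictionary is the shared
vocabulary (n_shared_terms) plus its own unique terms
(n_unique_per_element); off-diagonal typed relationships are sampled
i.i.d. at the configured density from the registered type codes, via
`numpy.random.default_rng(seed)` — global random state is never read, and
equal seeds give byte-identical serializations. By construction df(shared
term) = n_elements and df(unique term) = 1, which is the regime the
relevance layer's zero-threshold guarantee addresses; the reference
configuration used in tests and in the acceptance script is 6 elements × 36
terms (24 shared, 12 unique) at density 0.3, reproducing the 1296 → 144
cell compression. What the generator does *not* emulate: real extractor
noise (near-duplicate terms, partially shared vocabulary with intermediate
df), discrete measurement values inside collection elements, and semantic
concept annotations. Passing tests therefore demonstrate the algebraic and
statistical machinery, not extraction quality on real imagery.

The timeline generator replays scripted (timestamp, term, value) events
into cumulative snapshots (later values of a term override earlier ones),
storing measurements as discrete payloads on term → patient-root edges.
The two-snapshot blood-pressure script (140 in January, 155 in July) is the
reference fixture for the explanation layer.

## Numerical and degenerate-input choices

* Range bounds are inclusive at both ends; en dash and hyphen are both
  accepted in `D(a–b)` literals; a literal with low > high is rejected.
* Numeric comparison of discrete values is exact float equality (values
  come from printed/stored literals, not computation); a range matched
  against a text payload is a no-match, never an error.
* Empty codes: union of an empty sequence, aboutness of an empty code and
  similarity ranking over an empty collection are errors; subtracting an
  empty stop code and diffing a code with itself are identities.
* `float` payloads that are whole numbers print without the trailing ".0"
  in explanations (so "140", not "140.0").
* All test and acceptance problem sizes (collections of ≤ 6 codes × 36
  terms, timelines of ≤ 4 events, random graphs of ≤ 10 nodes) were chosen
  as the smallest sizes at which every structural property is non-trivial;
  the whole suite runs in seconds.

## Known limitations

* Feature *extraction* is out of scope: inputs are already-structured text
  (JSON graphs, key-value headers, CSV rows), never pixels or binary DICOM.
* The metric triple's exact formulas are containment-style definitions
  chosen for this artifact (maximal self-similarity, query-side
  normalization); other normalizations exist in the literature.
* The stop-code threshold uses a global tfidf order; per-asset or
  concept-aware stopping is not implemented.
* The reasoner has no retraction machinery beyond the fact/hypothesis
  split, and no external rule-engine bridge.
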