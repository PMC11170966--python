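# Methods

`sideroscreen` triages molecule libraries for candidate siderophores —
microbial secondary metabolites that chelate ferric iron — and places
known siderophores in the chemical space of natural products. This note
records the model, the parameter choices, and the limits of what the
packaged tests demonstrate.

## The screening rule

Siderophores coordinate Fe(III) through a small repertoire of bidentate
donor moieties. The screen is existence-based: a molecule is a candidate
iff it contains **at least one of 15 searchable iron-coordinating
functional groups**, contains **none of 8 modified (blocked) groups**,
and is **not an exact known structure**. Formally, with `T` the set of
searchable groups matched, `V` the vetoes matched, and `K` the known set:

```
candidate(m)  ⇔  T(m) ≠ ∅  ∧  V(m) = ∅  ∧  canon(m) ∉ K
```

Each group is a SMARTS query evaluated with RDKit's default aromaticity
model; matches that cover the identical atom set (automorphic symmetry
images) are counted once. Searchable patterns demand a free donor
hydroxyl (`[OX2H1]`) wherever the chelating chemistry requires one, so a
veto pattern — an O-alkylated or O-acylated donor oxygen, which cannot
form a coordination bond — can never co-count as its intact parent on
the same atoms.

### Registry composition

The searchable set covers the four major siderophore chemistries and the
established rarer donors: hydroxamate, catecholate, phenolate (the
salicyl-type ortho-hydroxyphenyl carbonyl/azoline site, with the
catechol case carved out so one site is not read twice),
carboxylate-in-citrate, alpha-hydroxycarboxylate-in-citrate,
alpha-aminocarboxylate, hydroxyphenyloxazoline, hydroxyphenylthiazoline,
hydroxyphenylthiazolidine, alpha-hydroxyimidazole
(beta-hydroxyhistidine-type), diazeniumdiolate (graminine),
2-nitrosophenol, 1-hydroxy-2-pyridinone, 3-hydroxy-4-pyridinone, and
beta-hydroxyaspartate. Every pattern carries the name of a literature
exemplar (desferrioxamine B, enterobactin, pyochelin, cepabactin, ...)
so the transcription can be audited against a published structure:
`sideroscreen patterns --out patterns.tsv` dumps the registry.

Two deliberate design points:

* **Free carboxylate and free alpha-hydroxycarboxylate are profiled but
  never trigger** (`common_excluded`). Both moieties do bind iron, but
  they are ubiquitous in ordinary metabolites — counting them as
  triggers would flag every fatty acid and hydroxy-acid. They still
  appear in match profiles and count matrices for composition
  statistics.
* **Citrate-context groups require an amidated citrate arm.** A citrate
  motif incorporated into a siderophore (aerobactin, rhizoferrin,
  staphyloferrin A, schizokinen) always carries at least one amide-linked
  arm; free citric acid carries none and is therefore not a candidate,
  consistent with its exclusion as a ubiquitous metabolite.
* **1-hydroxy-2-pyridinone is its own group**, not an instance of
  hydroxamate, although it is chemically a cyclic aromatic hydroxamate;
  the acyclic hydroxamate pattern is restricted to non-aromatic atoms.

The veto is **global** by default: one blocked group anywhere rejects
the molecule even if intact groups remain elsewhere. A `per-site` mode
(reject only when no intact searchable group survives) is available but
off, because the blocked variant signals a biosynthetic or curation
context in which the remaining sites are suspect too.

## Canonicalization and deduplication

Structure identity is canonical-SMILES string equality (RDKit canonical
algorithm). Before canonicalization: the largest covalent fragment is
kept (counter-ions logged and dropped) and simple protonation states are
neutralized, so acid/anion spellings collapse. Stereochemistry is
retained — stereoisomeric siderophores are distinct records — with an
`ignore_stereo` switch for sensitivity analysis. Different toolkits (and
different stereo/tautomer conventions) can shift unique-structure counts
by a few on a ~900-record library; any reproduction should state the
convention, as done here.

Merging keeps the first-seen record's id and name and appends duplicate
names to `other_names` (an order-independent lexicographic tie-break is
available); a duplicate with a known biosynthetic type fills in an
`unknown` representative.

## Similarity, novelty, chemical-space clustering

Fingerprints are circular substructure bit-vectors (Morgan, radius 2,
2048 bits) — the standard choice for Tanimoto screening. Similarity is
Tanimoto `|A∩B|/|A∪B|`; `1 − Tanimoto` is the edge weight everywhere.
A minhash/TMAP layout scheme is not provided; only the tree topology is
in scope here, and the MST of the kNN graph fixes that topology.

* **Novelty**: a candidate is novel when its exhaustive maximum Tanimoto
  similarity to the known set is ≤ 0.60. The threshold is the
  conventional "same chemotype" cut-off and is configurable.
* **Joint graph**: known + background molecules, each node linked to its
  k = 20 most similar neighbours (k balances connectivity against cost;
  configurable). If the kNN graph is disconnected, components are joined
  by their cheapest cross edge (counted and logged) so a spanning tree
  exists.
* **MST**: computed with scipy's sparse-graph routine restricted to kNN
  edges; zero distances (identical fingerprints) are preserved by a
  constant weight offset, which cannot change which tree is minimal.
* **Clusters**: delete background nodes from the MST; the connected
  components of the surviving known-set nodes are the clusters —
  background molecules act as separators between siderophore islands.
  Indexes are 1-based, size-ranked descending; equal sizes break ties by
  the smallest member id, so output is deterministic.
* **Groups**: within a cluster, connected components of the pairwise
  similarity graph at ≥ 0.60 (same coefficient as novelty; overridable).
  Group indexes are size-ranked within the cluster.
* **IDs**: every structure gets `x.y.z` — cluster, group, record within
  group in input order — injective and append-stable: adding records
  creates fresh `z` values without renaming existing ones.
* **Biosynthetic inference**: a group's route (NRPS, NIS, ...) is the
  majority vote of members with known types; `is_mixed` flags groups
  spanning ≥ 2 known types; all-unknown groups stay unknown.

## Fixture bed: what it emulates and what it does not

The packaged fixtures replace downloaded libraries so every operation is
testable offline: 13 literature-standard siderophores spanning
catecholate, hydroxamate, citrate/carboxylate and
phenolate/oxazoline-thiazoline chemistries (SMILES transcribed from the
primary literature without stereo descriptors, since both the rules and
the fingerprints used here are stereo-agnostic); 20 natural-product-like
decoys with no searchable group; 4 veto constructs built by O-methylating
the chelating oxygens of references (each stays a > 0.60 near analog of
its parent — V2 methylates only the 2-OH of each enterobactin catechol
for exactly this reason). The seeded generator mixes these into
byte-reproducible libraries.

Passing fixtures demonstrates rule correctness, determinism, and
MST/metric correctness. It does **not** demonstrate performance on a
real natural-product library: real libraries contain borderline
chemistry (flavonoids and other ortho-hydroxy-ketones genuinely match
chelation patterns), far larger scale, and curation noise. Reproduction
of published library-level counts additionally depends on the curated
deposit and on the background library's release, which this repository
does not ship; the acceptance tests for those reproductions state the
expected file locations (`data/deposit/`).

## Numerical and degenerate-input choices

* Tie-breaks are everywhere lexicographic/stable (argsort with stable
  kind, sorted component members), making all outputs order- and
  platform-deterministic; the one RNG (fixture generator, layout seeds)
  takes an explicit seed, default 42, recorded in output metadata.
* C/N and C/O element ratios are undefined (`None`), never 0, when the
  denominator element is absent.
* Tanimoto on two empty fingerprints is 1 by RDKit convention (identical
  empty feature sets).
* Empty libraries yield empty tables/reports, not errors; an empty known
  set makes the novelty query an error (maximum over nothing).
* Problem sizes in tests and the acceptance script (≤ 8-node graphs for
  exhaustive spanning-tree enumeration, 100 seeded graphs, 34-record
  end-to-end libraries) are chosen so exhaustive oracles stay exact.

## Known limitations

* The pattern registry is a faithful-chemistry reconstruction audited
  via exemplars, not a transcription of a published SMARTS table; group
  boundary conventions (e.g. phenolate vs catecholate adjacency) follow
  the depicted exemplar structures.
* Denticity, iron-affinity constants and 3-D coordination geometry are
  out of scope; the rule is existence-based.
* Exact known-structure exclusion is identity-based; a salt or stereo
  variant of a known siderophore counts as known only after
  canonicalization collapses it.
* `alpha-aminocarboxylate` intentionally matches free amino acids — they
  are weak iron binders and the rule is existence-based; downstream users
  should treat single-amino-acid candidates accordingly.
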