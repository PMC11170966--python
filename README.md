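# sideroscreen

Rule-based discovery of candidate **siderophores** — the iron-chelating
secondary metabolites microbes secrete to scavenge Fe(III) — in molecule
libraries, plus tools for organizing known siderophores in chemical
space. Intended for natural-product and microbiology researchers triaging
SMILES libraries for iron-binding chemistry.

## The method

A molecule *m* is a **potential siderophore** iff

```
candidate(m) ⇔ T(m) ≠ ∅ ∧ V(m) = ∅ ∧ canon(m) ∉ K
```

* `T(m)` — matches among **15 searchable iron-coordinating functional
  groups** (hydroxamate, catecholate, phenolate, citrate-context
  carboxylates, salicyl-oxazoline/thiazoline, diazeniumdiolate, ...),
  each a SMARTS query requiring free donor hydroxyls;
* `V(m)` — matches among **8 modified groups** whose donor oxygens are
  O-alkylated/acylated and cannot coordinate iron (global veto);
* `K` — known structures, excluded by exact canonical-SMILES identity.

Free carboxylate and free α-hydroxycarboxylate are profiled but never
trigger: they chelate iron yet are ubiquitous in ordinary metabolites.

Around the rule the package provides: canonical-SMILES deduplication
(salt stripping, charge neutralization, stereo retained); **novelty** as
the exhaustive maximum Tanimoto similarity (Morgan radius-2, 2048-bit
fingerprints) to the known set, with > 0.60 meaning "near a known
chemotype"; and **chemical-space clustering** — known + background
molecules form a k-nearest-neighbour graph under Tanimoto distance, its
minimum spanning tree is taken, background nodes are deleted, and the
surviving components of known molecules are size-ranked clusters.
Within-cluster groups form at similarity ≥ 0.60 and every structure gets
a stable hierarchical ID `x.y.z` (cluster.group.record); a group's
biosynthetic route (NRPS / NIS / ...) is inferred by majority vote of
its typed members. See `docs/methods.md` for details and limitations.

## Worked example

The package ships a download-free fixture bed: 13 literature siderophores
(enterobactin, desferrioxamine B, aerobactin, yersiniabactin, ...), 20
decoys, and 4 O-methylated "blocked" constructs.

```bash
sideroscreen fixtures dump --out fx
sideroscreen screen --library fx/mixed_library.csv --out decisions.csv
# INFO sideroscreen: screen summary: {'n_records': 34, 'n_candidates': 10,
#   'n_vetoed': 4, 'n_known_excluded': 0, 'n_no_trigger': 23}
```

Of the 34 molecules in the seeded mixed library, exactly the 10 planted
siderophores are candidates; the 4 O-methylated constructs are vetoed
(`decisions.csv` names the vetoing group, e.g.
`mod2_V2,False,,O-alkyl-catecholate|O-alkyl-phenolate,False`) and the 20
decoys match nothing. Passing `--known fx/references.csv` additionally
excludes exact known structures (`n_known_excluded: 10`,
`n_candidates: 0`).

Novelty of the blocked constructs against the reference set:

```bash
sideroscreen novelty --library fx/veto_constructs.csv \
    --known fx/references.csv --out novelty.csv
# INFO sideroscreen: novel: 0 / 4 (threshold 0.60)
```

`novelty.csv` shows each construct is most similar to its own parent and
above the 0.60 chemotype threshold — e.g. `V1,F3,0.630,False`
(tri-O-methyl desferrioxamine B vs desferrioxamine B) — so none counts
as novel chemistry.

Clustering the references against the decoy background:

```bash
sideroscreen cluster --library fx/references.csv \
    --background fx/decoys.csv --knn-k 5 --out clusters.csv
# INFO sideroscreen: 1 clusters, 11 groups, 13 records
```

All 13 references stay in one cluster (the small decoy background never
separates them on the tree) and split into 11 groups at the 0.60
coefficient; `clusters.csv` lists the `x.y.z` IDs, e.g. the three
citrate-type siderophores schizokinen, rhizoferrin and staphyloferrin A
form group `1.1` (`F7,1,1,1` / `F8,1,1,2` / `F9,1,1,3`).

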