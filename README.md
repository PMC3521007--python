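# hgtscan

Detection of **inter-kingdom horizontal gene transfers (HGT)** in protein
gene families by taxonomy-aware tree screening and multi-method
phylogenetic confirmation.

Large gene-family trees (e.g. Pfam full trees) occasionally show leaves
whose taxonomic kingdom contradicts their placement: a plant protein
nested deep inside the bacterial branches, or a cluster of bacterial genes
inside the archaeal clade. `hgtscan` turns the screening-and-confirmation
procedure behind such findings into a tested, reusable pipeline:

1. **Screen** a reference gene-family tree for *foreign leaves* — leaves
   (or maximal same-kingdom groups) wrapped inside another kingdom's
   branches — using lineage-based kingdom labels from a taxonomy table,
   then drop dubious candidates with aligned fragments < 300 aa.
2. **Select the best alignment** from an ensemble of alternative
   alignments of the same sequences by the multiple overlap score
   (MOS), and keep only high-confidence columns (ensemble agreement
   ≥ 0.93 by default).
3. **Infer trees** by neighbor joining on Poisson-corrected protein
   distances, d = −ln(1 − p), and by maximum parsimony (Fitch scoring
   with a close-neighbor-interchange search), each with a 100-replicate
   column bootstrap. An externally computed maximum-likelihood tree can
   be supplied as a third method.
4. **Combine** the per-method trees into a consensus containing exactly
   the branches supported by *all* methods (strict bipartition
   intersection; contested edges collapse into polytomies), annotated
   with each method's bootstrap value.
5. **Call HGT events**: candidates still wrapped in the same host
   kingdom on the combined tree are confirmed, grouped into transfer
   events (one event per maximal confirmed foreign clade), and reported
   with per-candidate statuses and per-kingdom-pair totals.

A first-class synthetic-data generator evolves kingdom-labelled protein
families with transfers planted as subtree-prune-regraft moves and an
answer key, so the whole pipeline is testable without any downloads.

## Worked example

Simulate a two-kingdom family of 24 proteins (400 aa) with two planted
Plantae→Bacteria transfers and a four-member alignment ensemble, then run
the full pipeline:

```bash
hgtscan simulate --out family --leaves-per-kingdom 12 --events 2 \
    --event-size 3,4 --length 400 --seed 7
hgtscan run-all --tree family/tree.nwk --taxonomy family/taxonomy.tsv \
    --alignment family/alignment_0.fasta --alignment family/alignment_1.fasta \
    --alignment family/alignment_2.fasta --alignment family/alignment_3.fasta \
    --out run --seed 7
```

which logs

```
[hgtscan.pipeline] screen: 7 candidate leaves
[hgtscan.pipeline] alignments: MOS-best index 0, 295/400 columns kept
confirmed=7 rejected=0 unresolved=0 events=2
```

The screen found the 7 planted foreign leaves; the true alignment won the
MOS comparison and 295 of 400 columns survived the 0.93 agreement filter;
all 7 candidates were re-detected on the NJ∩MP consensus tree and grouped
into the two planted events. `run/events.tsv` shows their membership:

```
members                      source   host      size  ancient
pla001;pla002;pla009;pla010  Plantae  Bacteria  4     False
pla005;pla008;pla011         Plantae  Bacteria  3     False
```

matching `family/truth.json` exactly. `run/` also holds the per-method and
combined Newick trees, MOS and column-score tables, the candidates table
with statuses, and a machine-readable `report.json`.

Each stage is also available separately (`hgtscan screen`,
`score-alignments`, `infer`, `combine`, `call`) and as a Python API
(`hgtscan.detect_foreign_leaves`, `hgtscan.mos_scores`,
`hgtscan.bootstrap`, `hgtscan.combine_method_trees`, ...).

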