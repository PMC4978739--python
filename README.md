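# nlr-evolkit

Genome-wide analysis of plant **NLR (NB-LRR) resistance genes** from
annotated gene sets: identification and architecture typing by NB-ARC
motif scanning, subgroup classification by integrating Markov clustering
with a bootstrapped NB-domain phylogeny, physical (tandem/proximal)
cluster calling on genome coordinates, and duplication dating from
synonymous substitution rates (Ks) with a post-speciation enrichment test.

NLRs are the intracellular immune receptors of effector-triggered
immunity.  Surveys of Solanaceae genomes (pepper, tomato, potato) show the
family expanding through lineage-specific tandem duplication after
speciation, with expansion concentrated in particular CNL subgroups.  This
package implements that survey workflow as a reusable, fully tested
library and CLI for anyone with a protein FASTA, matching CDS FASTA and
GFF3 per species — plus a truth-labeled synthetic-genome generator so
every stage is verifiable end-to-end without external downloads.

## The method in brief

* **Typing.**  PSSM scans (null-calibrated cutoffs) for the NB-ARC motifs
  (P-loop, RNBS-A, kinase-2, RNBS-B, RNBS-C, GLPL, RNBS-D, MHDV), the TIR
  core and LRR units; Lupas-style heptad scoring for coiled-coils
  (probability ≥ 0.9).  Genes fall into eight classes — TNL, CNL, NL_tir,
  NL_cc, TN, CN, N_tir, N_cc — and are *full-type* when the NB span is
  ≥ 160 aa with ≥ 3 major and ≥ 3 minor motifs.
* **Subgroups.**  All-by-all Smith–Waterman similarity (coverage ≥ 50%)
  → MCL at inflation 1.5; neighbor-joining tree of full-type NB domains
  under JTT distances with bootstrap supports (branches < 50% collapsed);
  clusters sharing a supported clade (≥ 70%) merge; leftovers are placed
  by best hit or `none-grouping`.
* **Physical clusters.**  Adjacent NLRs chain when < 200 kb apart with
  fewer than 8 genes between them; clusters are maximal chains of ≥ 2.
* **Ks dating.**  Protein-guided codon alignment; Ks by pairwise ML under
  a GY94/F3×4 codon model (NG86 as cross-check); Ks > 2 discarded as
  saturated; single-linkage families deduplicated to n−1 UPGMA join
  heights; per-subgroup chi-square for duplication excess after
  speciation (Ks < 0.3 ≈ 19.1 Mya).

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

Simulate a three-species genome with five planted subgroups and run the
whole pipeline:

```sh
nlr-evolkit simulate --seed 2 --out sim/
nlr-evolkit run \
  --proteins pepper sim/pepper.faa --cds pepper sim/pepper.fna --gff pepper sim/pepper.gff3 \
  --proteins tomato sim/tomato.faa --cds tomato sim/tomato.fna --gff tomato sim/tomato.gff3 \
  --proteins potato sim/potato.faa --cds potato sim/potato.fna --gff potato sim/potato.gff3 \
  --bootstrap-reps 100 --out out/
```

prints the per-species type summary:

```
species  total  NLR-type  NB-type  TIR%
pepper   24     20        4        16.7
tomato   17     14        3        23.5
potato   17     14        3        23.5
```

`total` is the number of NB-encoding genes detected; `NLR-type` counts
genes that also carry an LRR (TNL+CNL+NL), `NB-type` those that do not
(TN+CN+N); `TIR%` is the share of the TIR lineage.  `out/subgroups.tsv`
carries the per-gene subgroup assignment with provenance
(`tree`/`cluster`/`best-hit`/`none`):

```
gene_id          type_label  full_type  subgroup  provenance
pepper_CNL-A_1   CNL         1          G1        tree
pepper_CNL-A_2   CNL         1          G1        tree
```

and `out/tree.nwk` the bootstrapped NB-domain tree.  On this noise-free
genome the pipeline recovers the five planted subgroups exactly (Rand
index 1.0), every planted physical cluster, and n−1 duplication ages per
family.

From the library, the Ks clock anchored at the pepper–tomato/potato
divergence (Ks 0.3 ↔ 19.1 Mya):

```python
>>> from nlr_evolkit import ks_to_time
>>> ks_to_time(0.3)
19.1
>>> ks_to_time(0.15)
9.55
```

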