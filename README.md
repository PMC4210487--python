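# seldscope

Comparative genomics of the archaeal **SelD / SelD-like** family.

Selenophosphate synthetase (SelD) activates selenide with ATP to produce
selenophosphate, the selenium donor required by every known selenium
utilization trait — selenocysteine (Sec) decoding, 2-selenouridine (SeU)
tRNA modification, and the Se-containing molybdenum-hydroxylase cofactor.
In archaea, Se utilization is rare, and two orders of hyperthermophilic,
sulfur-reducing Crenarchaeota (Sulfolobales and Thermoproteales) instead
carry a *distant* SelD homolog ("SelD-like") that retains the catalytic
Cys-X-X-Lys active site but is thought to act in sulfur metabolism.

`seldscope` is a desk-scale, fully deterministic toolkit for the analyses
that characterise such a family:

* **Homology search** — exact Smith–Waterman local alignment (BLOSUM62,
  affine gaps 11/1) with Karlin–Altschul statistics
  `E = K·m·n·e^(−λS)` (λ = 0.267, K = 0.041), identity and query-coverage
  filters in BLAST conventions.
* **Orthology** — bidirectional best hits (BBH) with optional domain-label
  agreement.
* **Trait classification** — per-genome marker calls (SelD, SelA/SecS,
  SelB, YbbB, YqeB, YqeC, SelD-like) and trait rules
  `Sec = SelD ∧ (SelA ∨ SecS) ∧ SelB`, `SeU = SelD ∧ YbbB`,
  `SeCofactor = SelD ∧ YqeB ∧ YqeC`, with orphan-SelD flagging and clade
  summaries.
* **Gene neighborhoods** — all loci within a ±10,000 nt window of an anchor
  gene, shared-neighbor counting across genomes, and domain-fusion
  detection on single proteins.
* **Exclusive co-occurrence screen** — a reference proteome profiled across
  positive and negative genome sets under strict criteria
  (E < 1e−07, alignment over half the query length, identity ≥ 30%);
  candidates must be present in *all* positives and absent from *all*
  negatives, then annotated with outgroup occurrence (all/some/none).
* **Conservation** — mapping catalytic residues and motifs (e.g. the
  Sec/Cys-X-X-Lys active site) through a multiple alignment.
* **Phylogenetics** — p-distances, Saitou–Nei neighbor joining, seeded
  column-bootstrap supports, majority-rule consensus, monophyly tests.
* **Synthetic data** — a generator that plants all of the above (marker
  genes, an exclusively co-occurring gene, neighborhood clusters, domain
  fusions, diverged families) into genome sets with machine-checkable
  ground truth, so the entire pipeline is testable without downloads.

## Worked example

Run the end-to-end synthetic study — 9 SelD-like-positive and 3
SelD-like-negative Thermoproteales (the first positive is the reference
genome), a Sulfolobales outgroup, Se-trait clades, 50 background families:

```sh
$ seldscope run-study --seed 1 --out study/
screen candidates: ['TP01_p0026', 'TP01_p0027', 'TP01_p0028', 'TP01_p0054']
expected (planted): ['TP01_p0026', 'TP01_p0027', 'TP01_p0028', 'TP01_p0054']
SelD-like clade monophyletic: True
```

The co-occurrence screen recovered exactly the four planted genes: the
SelD-like anchor itself, its two planted neighborhood partners (SirA-like
and Prx-like), and the exclusively co-occurring gene — no false positives
among the 50 background families. `study/screen_report.tsv` has the
occurrence-table shape of the original analysis:

```
# seldscope 0.1.0 stage=profile seed=1 criteria=E<1e-07,cover>0.5,id>=0.3
protein_id   annotation                      domains                         occurrence_Sulfolobales ...
TP01_p0026   SirA-like protein               SirA-like                       all
TP01_p0027   SelD-like protein               SelD-like;acylphosphatase-like  all
TP01_p0028   Prx-like protein                Prx-like                        all
TP01_p0054   exclusively co-occurring protein                                none
```

and `study/clade_summary.tsv` the per-clade trait distribution:

```
clade            n_genomes  n_SelD  n_Sec  n_SeU  n_SeCofactor  n_orphan_SelD  n_SelD_like  pct_SelD
Halobacteriales  2          2       0      0      2             0              0            100.0
Methanococcales  3          3       3      3      0             0              0            100.0
Sulfolobales     4          0       0      0      0             0              4            0.0
Thermoproteales  12         0       0      0      0             0              9            0.0
```

Other subcommands (`simulate`, `search`, `orthologs`, `neighborhood`,
`tree`, `conserve`) expose the individual stages; the same functionality is
available as a library (`import seldscope`).

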