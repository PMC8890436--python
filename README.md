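# latsplice

Most human introns contain intronic GT dinucleotides that look like 5'
splice-donor sites but are never used under normal growth.  Use of such a
**latent 5' splice site (LSS)** would extend the upstream exon into the
intron and, for the large class of sites with an in-frame STOP codon in the
extension, put a premature termination codon (PTC) into the mRNA.  The
*suppression of splicing* (SOS) hypothesis holds that a nuclear
quality-control mechanism keeps these sites silent, and that knocking down
the responsible factors re-activates them — detectable in RNA-seq as split
reads joining the latent donor to the downstream acceptor.

`latsplice` is a tested, reusable implementation of the computational side
of that experiment, for genomicists who want to annotate latent donors and
measure their activation in their own case/control RNA-seq designs:

* **Donor scoring** (`latsplice.scoring`) — a maximum-entropy model over
  donor 9-mers (3 exonic + 6 intronic nt).  The model is the distribution
  `p*` of maximal entropy whose low-order marginals match the training
  donors, fitted by iterative scaling over the enumerated 4^9 table; a
  sequence is scored as `log2(p*(s) / q(s))` against a background `q`.  A
  PWM (independence) model is available as a baseline; the two coincide
  when only single-position marginals are constrained.
* **Catalog** (`latsplice.catalog`) — scans within-CDS introns of
  multi-exon coding transcripts for candidate GTs that would extend the
  upstream exon by at most 1000 nt while leaving at least 20 nt of intron,
  drops annotated donors, applies a score threshold (default 0, inclusive),
  and classifies each candidate by continuing the reading frame of the
  upstream exon through the extension:
  `LSS` (in-frame STOP in the extension), `adSS_3n` (no STOP, length
  divisible by 3 — no PTC), `adSS_fs` (no STOP, frame shift — PTC
  downstream).
* **Quantification** (`latsplice.junctions`) — split-read junction counts
  from SAM alignments (N CIGAR operations) or junction tables; normalized
  latent usage `u = reads_latent / reads_canonical`; per-base coverage
  profiles of exon extensions from bedGraph.
* **Activation calling** (`latsplice.activation`) — 2-case/2-control
  criteria (one replicate with >= 4 latent reads and >= 1.5-fold usage
  increase, the other with >= 1 read and any increase; the stringent
  variant imposes 4 reads / 1.5-fold on both), coverage-profile screening,
  one-sided Fisher's exact tests per replicate combined by Fisher's method,
  geometric-mean fold ranking, label-switch negative controls, and
  composite median fold profiles with order-statistic confidence bands.
* **Class statistics** (`latsplice.stats`) — one-sided Fisher tests for
  class bias (are PTC-introducing classes preferentially activated under
  true labels?), hypergeometric gene-set enrichment against user-supplied
  GMT collections with collection-level and global Bonferroni correction,
  Spearman correlation.
* **Synthetic data** (`latsplice.simulate`) — a seeded generator of toy
  genomes with planted sites of all three classes and of negative-binomial
  / Poisson split-read experiments with known activation truth, so the
  whole pipeline is testable without any downloads.

## Worked example

Simulate a small experiment, build the catalog, and call activated sites:

```bash
latsplice simulate --seed 3 --outdir sim
latsplice catalog --genome sim/ref.fa --gtf sim/genes.gtf --threshold 0 --out sim/catalog.tsv
latsplice call --catalog sim/catalog.tsv \
    --case sim/j1.tsv --case sim/j2.tsv \
    --control sim/j3.tsv --control sim/j4.tsv \
    --out sim/calls.tsv
```

which prints

```
reference (14 planted sites) and experiment -> sim
catalog: 134 sites -> sim/catalog.tsv
9 activated sites -> sim/calls.tsv
```

The catalog holds the 14 planted donors plus chance GT candidates that pass
the score threshold.  The ranked calls table starts with

```
chrom  strand  gt_start  parent5ss  gene   site_class  extension_len  score  ...  combined_p    fold_geomean  stringent
chrS   -       10898     10931      gene8  LSS         33             3.73   ...  1.46e-09      5.21          True
chrS   -       2598      2664       gene2  LSS         66             10.94  ...  1.10e-07      5.91          True
```

i.e. a latent donor 33 nt into the intron of `gene8` whose usage rose about
5-fold in the knockdown samples, with the two replicates' one-sided Fisher
tests combining to p ≈ 1.5e-9.  The same objects are available as a library
(`generate_reference`, `build_catalog`, `call_activated`, `label_switch`,
`rank_calls`, `class_bias`, ...), which is the more convenient surface for
analysis notebooks.

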