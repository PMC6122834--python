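# splicedm

Differential alternative-splicing and expression analysis for two-condition
bulk RNA-seq with few biological replicates — the setting of a
mutant-vs-control embryo experiment with two replicates per genotype.

Given a gene annotation (GTF) and uniquely mapped read alignments (or a
precomputed count table), `splicedm`:

1. merges transcripts into strand-specific **gene clusters**, flattens each
   cluster into numbered **exonic parts**, and enumerates two-path splicing
   events of seven types — exon skipping (ES), alternative 5'/3' splice
   site (A5SS/A3SS), mutually exclusive exons (ME), intron retention (IR),
   and alternative first/last exon (AFE/ALE);
2. counts, per sample, the reads supporting each path through the features
   *exclusive* to that path (exonic parts and exact-match exon–exon
   junctions);
3. models the replicate path counts with a two-category
   **Dirichlet-multinomial** (beta-binomial) and tests each event with a
   1-df **likelihood-ratio test**, with **Benjamini–Hochberg** q-values
   pooled across all event types;
4. reports **PSI** (percent spliced in) per condition and
   ΔΨ = Ψ(mutant) − Ψ(control), calling an event significant when
   **|ΔΨ| > 0.03 and q < 0.25** (both strict);
5. computes per-gene **RPKM** and 2-fold up/down regulation calls, and
   Venn-style overlaps of significant events between two mutants.

A synthetic-data module generates toy annotations, Dirichlet-multinomial
counts with known ground truth, and gapped synthetic reads, so the entire
chain is testable without external data.

## The model

For an event with path counts (x₁, x₂), n = x₁ + x₂, the replicate-level
path-1 proportion is Beta(s·π, s·(1−π)) distributed, giving

    P(x₁ | n, π, s) = C(n, x₁) · B(x₁ + s·π, x₂ + s·(1−π)) / B(s·π, s·(1−π))

where π is the population proportion and s the precision (overdispersion
vanishes as s → ∞). The null model shares π across conditions; the
alternative gives each condition its own π with a shared s, so
Λ = 2(ℓ_alt − ℓ_null) is referred to χ²(1). Because a precision
re-estimated from four samples per event biases the test, the pipeline
estimates one s shared across all events by a method of moments on
within-condition replicate scatter and holds it fixed while profiling the
proportions (see `docs/methods.md`).

PSI is the alternative-model MLE of the numerator path's proportion: the
*longer* isoform for ES/A5SS/A3SS/ME/IR, the *proximal* terminal exon for
AFE/ALE. Log-odds are natural logs, `ln(π/(1−π))`, with the log-odds-ratio
mutant − control.

## Worked example

```bash
python examples/03_differential_splicing.py
```

simulates 140 events (two conditions × two replicates, depth ~200,
precision 30) of which 35 carry a true splicing shift of 0.3, and prints:

```
pooled precision estimate s = 32.8 (true 30)
tested 140 events, 43 significant at |dPSI|>0.03 & q<0.25

strongest five events:
      event_id event_type  psi_mut  psi_ctrl  delta_psi      pval      qval
SIM:A3SS:00002       A3SS   0.7693    0.2589     0.5105 3.823e-09 5.352e-07
  SIM:ES:00014         ES   0.7395    0.2926     0.4469 3.883e-07 2.718e-05
...
sensitivity on true changes: 0.97; false calls among nulls: 9
```

The precision estimate recovers the generating value, the recovered
ΔΨ ≈ psi_mut − psi_ctrl tracks the simulated 0.3 shift (plus sampling
noise), and at the q < 0.25 operating point most true changes are found
while false calls stay within the FDR budget. The other example scripts
cover event enumeration (`01`), read counting (`02`), RPKM calls (`04`)
and two-mutant overlap (`05`).

The same stages are available as a CLI for shell pipelines:

```bash
splicedm simulate --n-events-per-type 10 --delta-psi 0.3 --seed 3 --out-dir sim
splicedm test --counts sim/event_counts.tsv --out-dir out
splicedm events --annotation sim/annotation.gtf --out events.tsv
splicedm report --results-a outA/results.tsv --results-b outB/results.tsv
```

Result tables follow the schema `event_id event_type path1 path2
logodds_mut logodds_ctrl logoddsratio pval qval psi_mut psi_ctrl delta_psi
significant favored_path` (a flag switches the column names to the
published supplementary-table style). Every run writes a manifest (inputs,
thresholds, seed, annotation hash) sufficient to reproduce it bit for bit.

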