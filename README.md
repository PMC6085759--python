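# isolimits

**What limits isoform-level analysis in single-cell RNA-seq?** Library
preparation decides how much of each transcript is sequenced (UMI-tagged
protocols read only a 3′ or 5′ end window; Smart-based protocols cover the
full length), and long-read platforms trade sequencing depth per cell against
the number of cells on a flow-cell. `isolimits` is a simulation framework
that quantifies how these choices bound (i) the number of isoforms per
multi-isoform gene (MIG) that short reads can resolve and (ii) the number of
dominant-isoform switches between two cell types that long reads can detect.
It is aimed at people designing single-cell isoform experiments or building
isoform-quantification methods who want an error-free, fully controlled
test-bed with known ground truth.

## What it does

1. **Synthetic transcriptome** — ~7000 non-overlapping gene loci on a random
   genome; 45% are MIGs whose extra isoforms are derived from a reference
   isoform by a single event: exon skipping, intron retention, alternative
   5′/3′ splice site, alternative TSS or TTS (~13,000 transcripts in total).
   Serialised as GTF + FASTA.
2. **Expression** — two cell-type profiles (NSC-like and
   oligodendrocyte-like) in TPM with log-normal gene abundance, one strictly
   dominant isoform per MIG, and exactly round(14% of MIGs) switching their
   dominant isoform between the cell types.
3. **Short-read workflow** — templates trimmed to 3′/5′ windows
   w ∈ {100, 200, 300, 500, 1000} nt (read length growing with the window:
   25/50/100 nt single-end; full length uses 250 nt paired-end), one million
   reads allocated multinomially with p_i = TPM_i/10⁶, splice-aware
   read↔isoform compatibility computed exactly (no aligner, no errors),
   equivalence classes quantified per gene by maximum-likelihood EM
   (responsibilities ∝ θ_i/ℓ_i), and per-MIG resolution
   `100 · n_detected / n_reference` summarised in 0–25 / 25–50 / 50–75 /
   75–100 % bins.
4. **Long-read workflow** — a one-million-read full-length budget split over
   2–20 cells (half per cell type), one read = one transcript; per-cell MIG
   detection and dominant-isoform switch recovery against the noiseless
   references, plus MinION flow-cell budgeting (4 cells per flow-cell).

## Worked example

```python
import isolimits as il

cfg = il.neural_emulation()                       # the default preset
tx, profiles = il.generate_inputs(cfg, seed=1)
print(tx.n_genes, tx.n_isoforms, len(tx.migs))    # 7000 13039 3150

res = il.run_longread_experiment(cfg, seed=1, tx=tx, profiles=profiles)
print(res.report.table[["n_cells", "mean_migs_per_cell", "mean_switches"]])
```

prints (seed 1):

```
   n_cells  mean_migs_per_cell  mean_switches
0        2            2013.000     293.000000
1        6            1473.000     234.111111
2       10            1197.700     196.720000
3       16             966.625     168.406250
4       20             865.450     150.620000
```

Against noiseless references of 3150 detectable MIGs and 441 switches: with
only two cells (500,000 reads each) about two-thirds of the true switches are
recovered, and by 20 cells (50,000 reads per cell) only ~151 (about a third)
survive — deeper sequencing of fewer cells preserves switch detection.

The short-read counterpart (`il.run_shortread_experiment`) reports, per
protocol, the fraction of MIGs in each resolution bin; on the same inputs
the mean resolution against the annotated isoform complement rises from
35.5% (100 nt 3′ window) to 51.5% (1000 nt) and reaches 61.0% for full-length
Smart-seq — partial end-sequencing, not depth, is what caps isoform
resolution.

The same workflows are scriptable from a shell:

```bash
isolimits generate  --seed 1 --outdir out/        # GTF + FASTA + expression
isolimits shortread --seed 1 --outdir out/
isolimits longread  --seed 1 --outdir out/
isolimits report    --outdir out/                 # stacked-bin + decay plots
```

## Layout

| module | role |
| --- | --- |
| `transcriptome.py` / `annotation.py` | event-based isoform generator; GTF/FASTA I/O |
| `expression.py` | two-cell-type TPM profiles with dominance and switches |
| `protocols.py` | UMI3/UMI5/SMART/LONGREAD coverage templates and read specs |
| `readsim.py` | read simulation and exact splice-aware equivalence classes |
| `em.py` | per-gene ML-EM quantification and detection calls |
| `resolution.py` | per-MIG resolution percentages and 4-bin summaries |
| `tradeoff.py` | long-read downsampling, switch recovery, flow-cell math |
| `config.py` / `pipeline.py` / `cli.py` | presets, seeded orchestration, CLI |

See `docs/methods.md` for the model, its assumptions, parameter defaults and
known limitations.
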