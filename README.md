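# clockko

Transcriptome analysis for multi-knockout epistasis studies of the
circadian repressors REV-ERBα/β (genes *NR1D1*/*NR1D2*), plus cosinor
quantification of circadian reporter rhythms.

Given a genes × samples TPM matrix over four genotypes — wild type (WT),
the single knockouts N1KO (*NR1D1*-null) and N2KO (*NR1D2*-null), and the
double knockout NDKO — `clockko`:

1. **Filters** to the significantly detected transcripts (top 25% by mean
   TPM by default).
2. **Calls DEGs** per mutant genotype against WT: fold change on mean TPM
   with a two-sided pooled Student's *t* on log2(TPM + 1); a gene is a DEG
   when FC > 1.5 (or < 1/1.5) and *p* < 0.05.
3. **Classifies** every NDKO DEG, per direction, into `ndko_exclusive`
   (DEG in neither single mutant — redundant/compensatory regulation),
   `alpha_dominant` (also a DEG in N1KO while N2KO changes less than
   1.3-fold), `beta_dominant` (the mirror image), or `shared`; and tabulates
   the three-way Venn cells of the per-genotype DEG sets.
4. **Scores gene-set overrepresentation** of any DEG list against GMT
   libraries with the one-sided Fisher/hypergeometric tail
   p = P(X ≥ k), X ~ Hypergeom(N, K, n), plus Benjamini–Hochberg *q*-values,
   using the expressed-gene set as the background universe.
5. **Quantifies reporter rhythms** by least-squares cosinor
   y = M + bt + β_c cos(2πt/τ) + β_s sin(2πt/τ), reporting mesor M,
   amplitude A = √(β_c² + β_s²), acrophase φ, relative amplitude 100·A/M
   (the “% of mesor” readout), and an F-test of rhythmicity; a
   moving-average detrend and an optional damped-envelope fit are included.
   Dual-luciferase endpoint assays are normalized firefly/renilla with the
   WT mean set to 1, and qPCR Ct tables are quantified by the comparative
   (ΔΔCt) method, 2^(−ΔΔCt).

A synthetic-data module plants ground-truth gene classes (null,
NDKO-exclusive, additive, α-dominant, β-dominant, each up/down) and
damped-cosine reporter traces, so every stage is verifiable end to end
without any external data.

## Worked example

```python
import clockko as ck

# 2000 genes, 4 replicates/genotype, planted 3-fold effects, log2-noise 0.1
study, truth = ck.simulate_expression(ck.SimConfig(n_genes=2000, replicate_sd=0.1, seed=42))
contrasts = ck.contrast_all(study)

print(ck.venn_summary(contrasts)[["n_NDKO", "only_NDKO", "ndko_exclusive_pct"]])
#            n_NDKO  only_NDKO  ndko_exclusive_pct
# direction
# up            300        100               33.33
# down          300        100               33.33

classes = ck.classify(contrasts)
print(classes.groupby(["direction", "label"]).size())
# down       alpha_dominant     70
#            beta_dominant      70
#            ndko_exclusive    100
#            shared             60
# up         alpha_dominant     70
#            ...
```

Each genotype carries 300 planted NDKO DEGs per direction (100
NDKO-exclusive, 70 α-dominant, 70 β-dominant, 60 additive); the classifier
recovers them exactly at this noise level — the 60 additive genes land in
`shared` because both single mutants move significantly. The
`ndko_exclusive_pct` column is the percentage of NDKO DEGs seen in neither
single mutant; on real knockout data this fraction is the headline measure
of isoform redundancy. The same arithmetic applied to published Venn
counts, e.g. `ck.exclusive_pct(757, 1033)`, prints `73.28`.

A rhythm example:

```python
trace = ck.simulate_bioluminescence(
    ck.BiolumSimConfig(noise_sd=1.0, damping_rate=0.01, seed=42))
fit = ck.cosinor_fit(trace["time_h"].to_numpy(), trace["signal"].to_numpy(), damped=True)
# mesor=99.98 amplitude=19.90 acrophase=6.02 rel_amp=19.9% p=1.56e-285
```

The fit recovers the planted mesor 100, amplitude 20 and acrophase 6 h
from a noisy, damped 96-h trace sampled every 20 min; `rel_amp` is the
amplitude as a percentage of the mesor.

## Command line

```sh
clockko simulate --n-genes 2000 --seed 1 --outdir sim/
clockko deg --matrix sim/tpm.tsv --design sim/design.tsv --out contrasts.tsv
clockko classify --contrasts contrasts.tsv
clockko enrich --query degs.txt --gmt kegg.gmt --universe expressed.txt
clockko cosinor --trace biolum.csv --damped
clockko qpcr --table ct.tsv --control-group WT
clockko run --config pipeline.yaml          # end-to-end, writes a manifest
```

All tables are TSV with `#`-prefixed metadata lines; `clockko run` writes a
`manifest.json` with parameters, seed and SHA-256 checksums, and re-running
with the same config reproduces byte-identical outputs.

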