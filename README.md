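# rpg-regulon

Analysis toolkit for the regulatory program of ribosomal protein genes
(RPGs): promoter motif content, transcription-factor occupancy at the TSS,
spike-in-normalized expression changes after a knockdown, ribosome content
by label-free proteomics, and translation by polysome profiling.

Mammalian cells coordinate the expression of the ~80 canonical ribosomal
proteins (plus ~10 paralogs) through promoter elements that differ from the
yeast and *Drosophila* systems. A subset of human RPG promoters carries the
palindromic element **TCTCGCGAGA** close to the TSS and recruits the protein
kinase DYRK1A there; knocking the kinase down lowers RPG mRNAs globally,
reduces ribosomal protein (RP) levels and ribosome mass, and shifts the
polysome:monosome balance toward monosomes. This package implements the
complete computational workflow needed to carry out — and to validate on
synthetic data with known ground truth — every quantitative step of such a
study.

## What it computes

- **Motif scanning with exact p-values** (`rpg_regulon.motif`). A PWM is
  built from an IUPAC consensus or aligned sites; a window score is the
  log-odds `S = Σᵢ log₂(pᵢ(bᵢ)/q(bᵢ))` in bits, and its p-value
  `P(S ≥ s)` under the i.i.d. background `q` is computed *exactly* by
  dynamic programming over a discretized score lattice (1e-4 bit
  granularity), equivalent to enumerating all 4^L sequences. Promoters are
  tiered as *bona fide* (p < 1e-4), *poorly conserved* (1e-4 ≤ p < 3e-4)
  or *absent*. A CentriMo-style binomial test over a fixed ladder of
  central windows ({50,…,250} bp, Bonferroni-corrected) quantifies how
  centrally the best site sits inside equal-width peaks, and the
  polypyrimidine TCT initiator (YC⁺¹TYTYY) is matched around annotated
  TSSs.
- **ChIP occupancy** (`rpg_regulon.chip`). Reads are binned by 5′ end
  (RPM-normalizable); per-bin significance is `−log₁₀ P(X ≥ k | λ)` with
  `λ = max(λ_global, λ_local)` (MACS-style floor, 10 kb local window);
  TSS-anchored metagene profiles span ±3 kb with strand flipping; a gene
  is called *bound* when the maximum significance within ±500 bp of its
  TSS reaches θ = 5 (p ≤ 1e-5). Binding matrices are clustered with seeded
  k-means on log(1+x) rows, call sets are intersected across datasets, and
  divergent (bidirectional) promoter pairs are detected within 500 bp.
- **Spike-in differential expression** (`rpg_regulon.expression`).
  Size factors come from median-of-ratios restricted to exogenous spike-in
  genes, so a genuine global shift of the endogenous transcriptome remains
  visible. After a >10 average-CPM filter, a minimal per-gene
  negative-binomial Wald test (method-of-moments dispersion with
  empirical-Bayes moderation, moderated-t reference) yields log₂FC and p;
  genes are *up*/*down* at |log₂FC| > 0.7 and p ≤ 0.05 (BH-adjusted
  optionally). Mann–Whitney / Wilcoxon comparisons stratify any per-gene
  metric by occupancy.
- **TOP3 riboproteomics** (`rpg_regulon.proteome`). Protein abundance per
  replicate is the mean of its three most intense peptide areas; a
  replicate correction factor (sum of TOP3 over mean of sums, applied
  within condition) equalizes loading; proteins quantified in ≥3
  replicates of a condition are *detected*. Downstream: differential
  abundance (t or Mann–Whitney behind a Shapiro–Wilk gate), RP mass
  fraction `Σ_RP TOP3 / Σ_all TOP3`, per-RP stoichiometry (share of total
  RP intensity), and protein/mRNA log-ratios with Spearman correlations.
- **Polysome profiles** (`rpg_regulon.polysome`). A254 traces are
  baseline-corrected, smoothed and segmented at valleys; the first three
  peaks are 40S/60S/80S and everything past the 80S boundary is the
  polysome region; the P:M ratio is the polysome area over the 80S area.
- **Exact small-sample statistics** (`rpg_regulon.stats`). Tie-aware
  exact Mann–Whitney and Wilcoxon signed-rank p-values via DP over the
  midrank lattice, Spearman ρ, Benjamini–Hochberg, Shapiro–Wilk gate.
- **Synthetic data with ground truth** (`rpg_regulon.simulate`). Seeded
  generators for every input: promoters with planted motifs, ChIP reads
  with planted bound promoters, negative-binomial count matrices with
  spike-ins and a planted global RPG shift, log-normal peptide tables with
  a planted RP reduction, and Gaussian-mixture A254 traces with analytic
  areas. Truth sidecars make every stage testable offline.

## Worked example

Run the full synthetic study (90-gene RPG catalog on a toy genome, 25% of
promoters carrying the planted motif and bound in the ChIP simulation, a
−1 log₂FC knockdown shift on all RPGs, a 30% RP reduction in the peptide
table, and a 4-peak polysome trace):

```bash
rpg-regulon run --seed 1 -o results/demo
```

which logs, per stage:

```
[motif] classified 90 promoters
[chip] 23 promoters called bound
[crosstab] Fisher p = 1.52e-20
[de] 82 genes down
[proteome] median RP mass fraction 0.717
[polysome] P:M ratio 3.247
```

Reading the output: 23/90 promoters are called DYRK1A-bound and the
occupancy-by-motif contingency table (`occupancy_by_motif.tsv`) shows the
planted bound ⇔ bona-fide association (23 bound promoters all bona fide,
one bona-fide promoter missed; Fisher p ≈ 1.5e-20). 82 of the 90 RPGs are
called down at the |log₂FC| > 0.7, p ≤ 0.05 thresholds after spike-in
normalization. The RP mass fraction across samples has median 0.717 —
between the planted control share (0.75) and the knockdown share reduced
by 30% — and the polysome:monosome ratio 3.247 is within 3% of the
analytic truth for the simulated trace. Each stage also runs standalone
(`rpg-regulon motif scan`, `chip occupancy`, `de run`, `prot top3`,
`polysome quantify`, `simulate …`) on user-supplied FASTA/BED/TSV inputs.

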