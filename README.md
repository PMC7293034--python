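# unwrapseq

Fragment-level analysis of **nucleosome unwrapping states** from
MNase-X-ChIP-seq paired-end data.

Nucleosomes are not static: histone–DNA contacts can be partially lost, so a
nucleosome protects fewer than the canonical ~147 bp from MNase digestion.
With crosslinking, ChIP for a histone (e.g. the variant H2A.Z, or canonical
H2A/H3) and paired-end sequencing *without size selection*, the distribution
of protected fragment lengths becomes a readout of unwrapping: intact cores
near 147 bp, hexasome-like intermediates around 120–140 bp, further unwrapped
states near 105/91 bp, and tetrasome/factor-scale protections below 80 bp.
`unwrapseq` implements the fragment-level statistics of that readout for
computational epigenomicists working with aligned fragment intervals (BED or
BEDPE): no alignment, peak calling or nucleosome-center calling is done here —
those are consumed as inputs.

## What it computes

- **FLP** — the fragment length profile: per-bp histogram of fragment lengths
  over 0–200 bp, with summit/sub-peak calling (moving-average smoothing +
  prominence threshold).
- **V-plots** — strand-oriented matrices of fragment-*center* density around
  reference points (TSS, CTCF binding sites, nucleosome centers), normalized
  to centers per billion read pairs: `CPB = raw × 1e9 / total_pairs`;
  group-aggregated meta-profiles; and **difference-V-plots** (cell-for-cell
  CPB difference between conditions, e.g. knockdown − wild type).
- **Fragment groups** — the five-way length partition G80 (30–80 bp),
  G100 (81–100), G120 (101–120), G140 (121–140), G168 (141–168); per-window
  counts/ratios, per-group 10-bp RPM genome tracks, and Venn-style interval
  overlap.
- **+1 nucleosome analysis** — strand-aware selection of nucleosome centers
  50–200 bp downstream of TSSs; per-+1 group ratios; median/MAD scaling per
  group; hierarchical clustering into five unwrapping classes labelled A–E
  (A over-represents G80 … E over-represents G168, assigned by unique
  maximum-weight matching); Spearman correlation of ratios with expression.
- **CBS orientation** — exact scanning of the directional CTCF consensus
  5'-CCACNAGGTGGCAG-3' on both strands to center and orient binding sites
  for motif-frame V-plots.
- **Synthetic data** — a ground-truth generator (state mixtures, phased
  arrays with an NDR, CTCF footprints, edge-retained sub-nucleosomal
  placement, expression-linked unwrapping, knockdown weight shifts) so the
  whole pipeline is testable without any sequencing data.

## Worked example

```python
import unwrapseq as uw

# 1. FLP of a simulated canonical-histone library (long digestion)
frags = uw.simulate_histone_sample(uw.CANONICAL_LONGMN, n=200_000, seed=1)
profile = uw.compute_flp(frags)
for peak in uw.find_peaks(profile):
    tag = "summit" if peak.is_summit else "sub-peak"
    print(f"{tag:8s} {peak.length:3d} bp  freq={peak.height:.4f}")

# 2. Unwrapping-state clustering of +1 nucleosomes on a promoter landscape
land = uw.simulate_tss_landscape(uw.LandscapeSpec(n_refpoints=2500,
                                                  n_downstream=1, seed=1))
plus1 = [p for p in land.nuc_centers if p.name.endswith("_nuc1")]
windows = uw.windows_from_points(plus1, 100)
windows["window_id"] = [p.name.rsplit("_", 1)[0] for p in plus1]
table = uw.window_group_ratios(land.fragments, windows)
scaled = uw.scale_ratios(table)
result = uw.label_clusters(uw.hcluster(scaled, k=5), scaled)
report = uw.correlate_ratios_expression(table, land.truth[["gene_id", "expression"]])
print(result.to_dataframe()["label"].value_counts().sort_index().to_dict())
print(report.round(3))
```

Output:

```
summit   147 bp  freq=0.0542
sub-peak 127 bp  freq=0.0236
sub-peak 105 bp  freq=0.0179
sub-peak  91 bp  freq=0.0142
sub-peak  69 bp  freq=0.0094
{'A': 498, 'B': 494, 'C': 509, 'D': 501, 'E': 498}
         rho  pvalue     n
group
G80   -0.294   0.000  2500
G100  -0.010   0.629  2500
G120   0.028   0.155  2500
G140   0.242   0.000  2500
G168   0.204   0.000  2500
```

The peak caller finds the intact-core summit at 147 bp and the four planted
unwrapping sub-peaks (127/105/91/69 bp). The clustering recovers the five
planted ~500-gene unwrapping classes, and the short-fragment (G80) ratio of
+1 nucleosomes is negatively rank-correlated with expression while the
long-fragment ratios (G140/G168) correlate positively — the expected
direction for unwrapped versus intact +1 nucleosomes.

The same pipeline is available from the shell:

```sh
unwrapseq simulate --kind tss --n 500 --seed 1 --outdir sim/
unwrapseq plus1 --centers sim/tss_nuc_centers.bed --tss sim/tss_tss.bed --out plus1.bed
unwrapseq groups --fragments sim/tss_fragments.bed --refs plus1.bed --out ratios.tsv
unwrapseq cluster --ratios ratios.tsv --expression sim/tss_expression.tsv --out clusters.tsv
```

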