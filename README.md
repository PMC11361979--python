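# sdrscan

Discovering sex chromosomes from pooled resequencing of males and females.

Many fishes (and other vertebrates) carry *homomorphic* sex chromosomes:
karyotypically invisible, differentiated only across a region that can be
narrower than a megabase. A cheap and effective way to find such a
sex-determining region (SDR) is **pool-seq**: sequence one DNA pool per
sex and look for sites where the two pools' allele frequencies separate
in the pattern a sex-linked allele must produce. `sdrscan` implements
that scan as a reusable, tested pipeline for researchers mapping sex
determination in non-model species, together with a simulator that
generates realistic pooled sex-contrast datasets with a planted SDR so
every stage can be validated end to end.

## The method

Given per-site read counts for a male pool and a female pool (sync
format, `A:T:C:G:N:del` per pool, or any table of pooled counts):

1. **Per-site differentiation.** Each biallelic site gets the fixation
   index between the sex pools,

   F_ST = (H_T − H_S) / H_T,  H_T = 2p̄(1−p̄),  H_S = [2p_m(1−p_m) + 2p_f(1−p_f)]/2,

   with p_m, p_f the pools' variant-allele frequencies and p̄ their mean.

2. **Sex-patterned SNP classification.** A site is **XY-patterned** when
   the allele is effectively fixed in females (frequency < 0.1, or > 0.9
   for the complement) and polymorphic in males (0.3 ≤ p_m ≤ 0.7) — the
   signature of an allele on every Y and no X, since each XY male is
   heterozygous. **ZW-patterned** is the mirror image. Depth filters
   (default: ≥ 10 reads per pool, ≤ 3× the mean depth) and a
   third-allele noise threshold are applied first.

3. **Window scan.** Patterned SNPs are counted in non-overlapping 100-kb
   windows; each window gets log2((n_XY + 1)/(n_ZW + 1)); the top 1% of
   anchored windows by patterned-SNP count are selected (ceiling rule:
   1% of 7,800 windows is exactly 78).

4. **Chromosome-level tests.** A tie-corrected Kruskal–Wallis test asks
   whether window log2 ratios differ among chromosomes; when it does,
   Dunn's rank-based pairwise comparisons with Benjamini–Hochberg
   correction localize the chromosomes involved.

5. **Candidate regions.** Selected windows on one chromosome merge
   (bridging ≤ 1 unselected window) into ranked candidate regions with
   an XY/ZW system call.

6. **Protein changes.** For genes inside a candidate region, a labeled
   protein alignment (X and Y haplotypes plus ≥ 2 outgroup species,
   isoforms grouped per species) is classified column by column against
   the outgroup consensus: changes shared by X and Y, X-specific
   changes, Y-specific changes, and run-merged indel events, each scored
   conservative vs non-conserved by BLOSUM62 (score ≥ 0 is
   conservative).

## Worked example

Simulate a small three-chromosome genome (2 Mb each) with an XY system
whose 400-kb SDR sits on LG02, then run the scan:

```bash
cat > sim.yaml <<'YAML'
seed: 5
chrom_lengths: {LG01: 2000000, LG02: 2000000, LG03: 2000000}
system: XY
sdr_chrom: LG02
sdr_interval: [800000, 1200000]
YAML

sdrscan simulate --config sim.yaml --out-prefix demo
# wrote 12006 sites to demo.sync (XY system)

sdrscan scan --sync demo.sync --out demo.sites.tsv
# 12006 sites: 250 XY-patterned, 23 ZW-patterned

sdrscan windows --classified demo.sites.tsv \
    --chrom-lengths demo.chrom_lengths.tsv --out-prefix demo
# 60 windows, 1 selected (pseudocount=1.0)

sdrscan test --windows-bed demo.windows.bed --out-prefix demo
# KW H=13.160 p=0.00139; 2 Dunn pairs at adjusted p<0.05

sdrscan report --windows-bed demo.windows.bed --out demo.regions.bed
# LG02:900000-1000000  call=XY  windows=1  XY=64 ZW=0
```

The 250 XY-patterned SNPs against 23 ZW-patterned ones, the significant
Kruskal–Wallis test, and the single top-ranked XY region inside the
planted 800 kb–1.2 Mb interval together recover the simulated ground
truth: an XY system on LG02. The same library calls are available in
Python via `sdrscan.analyze(sites, chrom_lengths)`.

Protein-level calling works from an aligned FASTA plus a role map:

```bash
sdrscan protein --aln rin3.faa --roles rin3.roles.tsv --out rin3.calls.tsv
# {"shared": ["—"], "x": ["—"], "y": ["P76S", "P87S"]}
```

listing non-conserved changes per haplotype (here two Y-specific
proline→serine substitutions).

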