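# sncatlas

Spatiotemporal analysis of sperm small non-coding RNAs (sncRNAs) along the
male reproductive tract.

Sperm acquire and shed small RNAs as they travel from the testis through the
epididymis to ejaculation, and the resulting cargo — miRNAs, PIWI-interacting
RNAs (piRNAs), tRNA-derived fragments (tsRNAs) and rRNA-derived fragments
(rsRNAs) — is a candidate carrier of paternal epigenetic information.
`sncatlas` implements the full desk-scale analysis chain for a five-region
bovine design (testis parenchyma **PAR**, epididymis caput **CAP**, corpus
**COR**, cauda **CAU**, ejaculated sperm **SPZ**, three bulls each):

1. **Synthetic study generator** — reference bundles (miRNA / piRNA / tRNA /
   rRNA sets plus a circular mitochondrial genome with a feature table) and
   UMI-tagged FASTQ libraries with per-read ground truth, emulating the
   region-specific class mixtures, piRNA 5'-U / 10-A biases and length modes,
   tsRNA subtype mixes and rRNA species mixes of the real tract.
2. **UMI preprocessing** — adapter/UMI extraction, collapse of identical
   (insert, UMI) reads to one exemplar carrying per-position mean quality,
   then length (≥ 17 nt) and quality (every base ≥ Q25) filtering, and
   stacking by unique sequence into a tag table.
3. **Hierarchical classification** — exact reference matching in priority
   order (miRNA > tsRNA > rsRNA > piRNA), tsRNA fragment typing against the
   anticodon loop (tRF5, tRF3, 5'-tRH, 3'-tRH, i-tRF), rRNA species labels,
   piRBase-style piRNA target categories, and isomiR grouping (5' offset
   ≤ 2 nt, 3' offset ≤ 5 nt from the canonical mature ends).
4. **piRNA signatures** — positional nucleotide frequencies (positions
   1–35), expression-weighted U1/V1 and A10/B10 shares, length
   distributions, and perfect full-length matching to the circular
   mitochondrial genome on both strands with feature assignment.
5. **Quantification** — median-of-ratios (RLE) size factors
   `s_j = median_i ( K_ij / (prod_v K_iv)^(1/m) )` over features with
   all-positive counts; per-region composition shares; a simplified
   negative-binomial Wald screen per region pair (method-of-moments
   dispersion, Benjamini–Hochberg correction, significant ⇔ adjusted
   p < 0.05 and fold > 2.5).
6. **Profiling** — replicate-averaged, row-standardized five-point region
   profiles; multi-start Lloyd K-means (default 100 random starts, 1000
   iterations) with the elbow statistic betweenss/totss ("information
   retained") scanned over k = 2…25; per-cluster composition, length and
   U1/A10 summaries; and between-class analysis (BCA) of samples, ratio =
   between-class inertia / total inertia.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a simulated
study (15 libraries × 20,000 reads) and write their tables under `results/`:

```bash
cd analysis
python 01_simulate_study.py            # study + truth under results/study
python 02_preprocess.py                # tag table
python 03_annotate.py                  # class/subtype assignments
python 04_composition_signatures.py    # per-region shares, U1/A10, mt-piRNAs
python 05_differential_expression.py   # pairwise NB screen
python 06_cluster_profiles.py          # K-means profiles + BCA
```

`04_composition_signatures.py` prints the recovered composition (percent of
each region's expression; compare the planted 78% piRNA at PAR falling to
13% at CAU, and miRNA rising to 38% at SPZ):

```
class share (%) of each region's total expression:
              PAR   CAP   COR   CAU   SPZ
miRNA         1.0   4.9  12.8  26.5  37.4
piRNA        75.9  55.7  19.5  12.9  17.7
rsRNA        16.6  27.1  44.9  30.6  25.2
tsRNA         2.0   7.9  18.3  25.6  15.4

piRNA U1 / A10 expression shares per region:
region  u1_share  a10_share
   PAR     0.801      0.252
   CAP     0.803      0.250
   COR     0.360      0.596
   CAU     0.396      0.258
   SPZ     0.553      0.251
```

U1 piRNAs (primary pathway) dominate PAR/CAP, while COR is dominated by
non-U1, A10-enriched (ping-pong-like) piRNAs — the planted signature.
`05_differential_expression.py` shows the number of differentially expressed
sncRNAs growing with anatomical distance (1,204 for PAR vs CAP down to 0 for
CAU vs SPZ at this scale, 99% of PAR-vs-SPZ calls under-expressed in
ejaculated sperm, 98.6% of them piRNAs), and `06_cluster_profiles.py` reports
the elbow trace, each cluster's peak region and class make-up, and per-family
BCA ratios (0.31–0.79 here).

The same chain is available as a CLI (`sncatlas simulate|preprocess|annotate|
quantify|signatures|cluster|report|all --config cfg.json --seed 1`), which
writes a machine-readable `report.json` with per-stage counts and artifact
checksums; identical config and seed give a byte-identical report.

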