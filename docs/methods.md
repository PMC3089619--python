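# Methods

This note records the models behind `protoseq`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data
experiments can and cannot show about real data.

## Read accounting and normalization

Reads are located by their 5′ genomic position only; read length never
enters. Coordinates are 0-based half-open throughout (GFF3 is converted on
load). A read is assigned to the collapsed locus whose exon contains its
5′ position on the same strand; when exons of several loci contain it the
lexicographically smallest locus id wins — a deterministic stand-in for a
multi-mapping policy, which real pipelines resolve with alignment scores.
Reads that hit no exon stay in the per-channel non-ribo/mito total, so the
genomic-bin stage can see them and so the RPM denominator reflects *all*
usable reads, assigned or not. Consequently an RPM column sums to
10⁶ × (assigned / all non-ribo/mito reads), with equality at 10⁶ only when
every usable read was assigned.

Collapsed loci merge same-strand transcripts with overlapping genomic
spans into an exon-union model. The locus representative length is the
median of member representative lengths (equal to spliced lengths for
freshly loaded transcripts); using the member *median_length* rather than
re-deriving from the union keeps collapsing idempotent.

RPM divides by the per-sample non-ribosomal/non-mitochondrial read total;
ribosomal and mitochondrial transcripts are excluded from both the matrix
rows and the denominator. Channels combined into one sample are summed as
raw counts *before* normalization (summing RPM values would weight
channels by their sequencing depth incorrectly). RPKM exists only for
spike-in analysis and the length-artifact experiment.

## Gating, correlation, strata

Presence gating is a strict inequality (value > threshold, default 5 RPM)
and is recomputed per compared pair with "any of the compared samples"
scope. Spearman correlation uses average ranks for ties; a constant vector
yields NaN rather than a misleading 0. Expression strata follow the
boundary convention [5,10], (10,50], (50,100], (100,10³], (10³,10⁴],
(10⁴,∞): the printed style "5–10" vs ">10–50" forces 10 into the first
stratum, and values below 5 RPM are not counted as expressed.

## Differential expression

Welch (unequal-variance) two-sided t-tests run per transcript on
per-channel RPM, each channel normalized by its own denominator. The
multiple-testing correction divides the significance threshold by the
number of gated transcripts (p < α/N, Bonferroni); α defaults to 0.05.
Welch is used because protocol groups carry no variance-equality
guarantee; with 4 + 4 channels the difference from the pooled test is
small. Degenerate rows (zero variance in both groups) get p = 1 when the
means agree and p = 0 otherwise. Fold changes are reported
larger÷smaller with a direction flag; a zero smaller mean yields an
infinite fold rather than a pseudocount-adjusted ratio, so printed-style
ratios are never silently altered.

Length-binned summaries sort gated transcripts by representative length
(ids break ties, for determinism) and chunk them into consecutive bins of
400; the last bin may be short and is excluded from trend statistics. The
per-bin expression summary is the median over members of the mean RPM
pooled across all channels of both conditions.

## Genomic bins

The genome is tiled with 100-bp half-open bins (last bin of a chromosome
may be short). Counting ignores strand. Bin RPM uses the *library-level*
non-ribo/mito denominator — the same denominator as transcript RPM — so an
RPM floor translates directly into a raw-read floor in the shallowest
library (0.95 RPM ↔ 3 reads at a 3.16M-read library). A bin is eligible
for the differential comparison when either sample reaches the floor
(choosing "either" keeps the rule symmetric and maximizes sensitivity; the
alternative readings are "the named shallowest sample" or "both").
Classification is exonic > intronic > intergenic with ≥1 bp overlap and no
majority rule; strand is ignored because tag protocols report both
orientations over a locus.

## The sampling simulator

The generator emulates the composition of human total RNA:

* lengths log-normal, median 2,000 nt, σ(log₁₀) = 0.4 — the scale of
  annotated transcript-length catalogs;
* molar abundances log-normal, σ(log₁₀) = 1.0 (≈4 decades within ±2σ),
  drawn independently of length;
* a small ribosomal set (8 species) rescaled to carry exactly 85% of
  total-RNA sampling mass, matching the ">80% of aligned reads" regime,
  and a mitochondrial set (15 species, polyadenylated) carrying 5%;
* the remaining loci split 70% coding polyA+, 20% non-coding polyA−,
  5% histone polyA−, 5% non-coding polyA+ by count;
* loci tiled onto synthetic chromosomes with ≥1 kb gaps and 1–5 exons, so
  bin-level analyses have realistic exon/intron/intergenic structure.

Sampling weights: multi-read RNA-Seq uses w = m·L (random-hexamer priming
gives long molecules proportionally more priming sites); DGE uses w = m
for polyadenylated transcripts and 0 otherwise (one 3′-anchored read per
molecule). Protocol multipliers:

| parameter | default | meaning |
|---|---|---|
| `rrna_residual` | 0.2 | fraction of rRNA weight surviving depletion; chosen so the simulated rRNA read share lands in the 47–77% band observed for probe-depleted libraries |
| `capture` | 0.9 | polyA+ weight retained per selection round |
| `polya_carryover` | 0.02 | polyA− weight surviving one selection round (squared for two rounds); no measured value exists, this is a stated parameter |
| `frag_scale` λ | 400 nt | fragmentation retention r(L) = L/(L+λ); the functional form is a modeling choice, and λ = 400 puts the unfragmented/fragmented median ratio for sub-kb transcripts near 1.3 |
| `sp_rrna_residual`, `sp_short_penalty` | 0.1, 0.1 | selected-primer multipliers for rRNA and for species < 200 nt |
| `rt_stop_rate` | 1/4000 per nt | DGE reverse transcription terminates geometrically from the 3′ end; the read sits max(L − extension, 0) from the 5′ end, so most sub-2-kb molecules read exactly at the 5′ end |

Counts per channel are one multinomial draw of the configured depth over
normalized weights, so channel totals are exact and category shares equal
weight shares in expectation. Per-channel seeds derive from one master
seed by the counter scheme `SeedSequence([master, index])`; everything is
reproducible from a single integer.

Under these defaults the simulated rRNA read share is ordered total >
depleted > polyA×1 > polyA×2 while the mitochondrial share rises along the
same ordering — the qualitative fingerprint of increasing polyA selection,
since mitochondrial transcripts are polyadenylated.

What the simulator does **not** model: GC and secondary-structure priming
bias, amplification (the modeled platform is amplification-free), sequence
content and alignment error, positional coverage bias other than the 5′
tag displacement, between-replicate biological variation (replicate
channels differ only by counting noise), and any length–abundance
dependence. Passing tests therefore demonstrate the *arithmetic and
statistical* behavior of the pipeline under controlled sampling, not
robustness to those real-data effects.

## Experiment design and problem sizes

All experiments live in `protoseq.experiments` and are driven by one seed.
Expression-only experiments (power, null, fragmentation, artifact) use a
preset without ribosomal/mitochondrial mass so sequencing depth is spent
on the transcripts under test.

* **Replicate reproducibility** — two polyA channels of 10⁶ reads from a
  5,000-locus transcriptome; gated Spearman measures pure counting-noise
  reproducibility. At this scale the >5 RPM gate admits transcripts with
  only a handful of reads, whose rank noise caps the correlation near
  0.95–0.97; published replicate libraries carried several million usable
  reads each, so their 5 RPM gate corresponded to ~40 reads and supported
  correlations above 0.99. The experiment reports the measured value; the
  gap is a depth effect, not a pipeline property.
* **Length-dependent power** — per repeat: a fresh 4,400-locus
  transcriptome (abundance σ(log₁₀) = 0.5 so the power transition spans
  the length range instead of saturating), 2-fold changes injected into
  20% of loci, 4 vs 4 channels of 10⁶ reads, Welch tests, fractions
  significant per 400-transcript length bin. The trend statistic is the
  Spearman correlation of (bin index, fraction significant) pooled over 10
  repeats: under multi-read sampling power rises with length (trend
  ≈ 0.93); under DGE it is length-free, and pooling keeps the no-trend
  statistic honest — a single 10-bin curve of noisy fractions would give a
  scale-free Spearman whose null |ρ| exceeds 0.3 about a third of the
  time, whereas the pooled statistic's null sd is ≈ (10·repeats)^(−1/2).
* **Length-correction artifact** — four independent channels of 10⁶ reads
  from one transcriptome with length ⊥ abundance; mean pairwise Spearman
  under RPM, RPKM, and ten fresh shared random-length divisions. Any gain
  of permuted-length over RPM is arithmetic, not biological. Full depth is
  used because at shallow depth the rank noise of barely-gated transcripts
  swamps the shared-divisor effect and can invert the direction.
* **Null family-wise error** — 200 repeats of 4 vs 4 channels drawn from
  one unchanged 2,200-locus transcriptome; FWER is the fraction of repeats
  with any Bonferroni-significant call, checked against
  α + 3·√(α/200); first-repeat p-values are KS-compared to U(0,1).
* **Fragmentation** — one unfragmented and one fragmented (λ = 400)
  channel of 10⁶ reads, 3,000 loci. With retention r(L) the expected
  unfragmented/fragmented RPM ratio is C·(L+λ)/L with C the
  weight-averaged retention, so sub-kb transcripts sit ~1.3–1.4× high and
  >2 kb transcripts just below 1; the per-length-bin medians (fixed
  boundaries 0–250–500–1000–2000–4000–∞ nt) fall monotonically and the
  ratio–log-length Spearman is negative.
* **Spike-ins** — seven species spanning three decades of concentration,
  including one short (325 nt) spike at the lowest concentration, sampled
  ∝ concentration × length at 10⁵ reads; 100 repeats count how often the
  length-adjusted abundances rank exactly like the concentrations
  (Spearman ≥ 0.99 over seven points requires a perfect ranking).
* **Genomic bins end-to-end** — 300-locus genome, 2×10⁵ reads per
  condition with per-read positions. With annotation matching the
  simulator truth, every differential bin is exonic (reads are emitted
  only from exons). Adding one 30-kb transcript absent from the annotation
  to one condition produces an unbroken ~300-bin run of intergenic
  differential bins — the annotation-free detection of an unannotated
  expressed region.

These sizes keep the full suite and the acceptance script in the tens of
seconds on one CPU while leaving every statistic far from its decision
boundary (except the replicate bound discussed above).

## Known limitations

* The locus-collapse rule (span-overlap union) is one plausible
  construction of a collapsed annotation; real catalogs use curated
  clustering.
* The multi-mapping tie-break is deterministic but arbitrary.
* No FDR control, count-model (negative-binomial) testing, or paired
  designs; the t-test-on-RPM design is intentionally simple.
* Spike linearity and fragmentation conclusions are exact only under the
  simulator's proportional-sampling assumptions.
* TSV count tables store category totals as reserved rows; per-transcript
  categories ride in a header comment, so foreign tables without it are
  treated as all-"other".
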