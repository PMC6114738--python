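# Methods

## Scope and data model

`hairmeth` compares two groups of whole-genome bisulfite methylomes —
three biological replicates each of "anagen" and "telogen" skin — starting
from per-cytosine count tables (chrom, 1-based position, strand, context,
methylated reads, total reads). Alignment and base calling are upstream of
the package; a bisulfite genome converter (C→T / G→A) is provided for
building aligner indexes, but read mapping itself is out of scope.

All internal coordinates are 0-based half-open. Site tables are 1-based on
disk to match common methylation-extractor dialects; BED stays 0-based
half-open and GTF 1-based inclusive, with the readers doing the shifts.
The central container is a sites × samples count matrix
(`MethylomeMatrix`) holding strand-resolved cytosines with their CG/CHG/CHH
context.

## Read-level QC

Reads are removed whole (never trimmed) by three ordered rules: the 3'
adapter as an exact substring; an N fraction strictly above 10%; and a
low-quality rule that removes reads where at least half the bases are at
PHRED ≤ 5. Q20/Q30/GC are computed on survivors (GC over non-N bases).
Duplicates are marked by the (chrom, start, strand) alignment key, keeping
the first read per key.

## Methylated-cytosine calling

The unmethylated lambda spike-in measures the conversion failure rate
ε = Σm/Σt over its cytosines (rate = 1 − ε). No published operational rule
exists for counting a cytosine as methylated, so the package adopts the
field's convention: a one-sided binomial test of the methylated count
against ε, Benjamini–Hochberg corrected per sample over all covered sites
at α = 0.05. Region levels pool counts (Σm/Σt) rather than averaging site
levels — coverage-robust, and configurable. Sites below a coverage floor
(default 4 reads) are excluded from level-based analyses.

Context classification reads 3'-ward on the cytosine's own strand and is
strand-symmetric by construction; a site within 2 bp of a contig end with
insufficient context is deterministically classified CHH (negligible
count, but every site gets a label).

## DMR procedure

1. **Smoothing.** Degree-1 local regression per sample along each
   chromosome, weights = tricube(distance / h) × coverage with
   h = 500 bp, windows widened to the nearest 10 sites where CpGs are
   sparse. Degree 0 (a weighted local mean) is available; smoothing never
   crosses chromosome boundaries. The fit is evaluated at the site and
   clipped to [0, 1].
2. **Window testing.** Windows of 1000 bp advanced by 100 bp. Each
   sample's summary is its mean smoothed level over the window's sites
   (windows with < 3 sites skipped). Welch's *t* (safer than pooled-
   variance Student at n = 3 per group, and identical under equal
   variances) compares the groups; BH correction runs over all tested
   windows genome-wide.
3. **Site flagging.** The FDR rule binds to windows, the effect-size rule
   to sites: a cytosine is differential iff it lies in ≥ 1 window with
   q < 0.05 and its own pooled between-group difference is > 0.25 in
   absolute value (both groups pooled-covered ≥ 4 reads).
4. **Merging.** Maximal same-sign runs with consecutive gaps ≤ 300 bp and
   ≥ 3 sites become DMRs (the gap criterion acts as a split rule — sites
   farther apart than 300 bp never co-merge). The DMR span runs from the
   first to one past the last supporting site, so the step phase of the
   window grid cannot move DMR edges. Direction is hyper (telogen-higher)
   iff the pooled region difference is positive; DMR q is the minimum over
   supporting windows.

DMR calling defaults to the CG context; other contexts run behind a flag
without calibration claims.

## Profiles and correlations

Window densities pool counts in non-overlapping tiling windows (default
300 kb) per context and group. Meta-profiles orient gene-linked features
5'→3' (minus-strand genes flipped), scale bodies/exons/introns/CGIs to 50
bins and bin promoters/flanks/shores at 100 bp; promoters are defined as
the 2 kb upstream of the TSS (the common convention; configurable), CGI
shores as the 2 kb flanking an island minus any island overlap. CpG o/e
uses the Gardiner–Garden form (N_CG · L)/(N_C · N_G). Chromosome-level
correlations are Pearson r of the per-chromosome pooled level against
length, CpG count, CpG o/e, gene count and repeat count (computed on
per-chromosome means; a per-window variant is available through
`window_density`). Sample correlations are Pearson r over per-site levels
restricted to sites covered ≥ 4 reads in both samples of a pair.

## Synthetic data generator

The generator emulates the structure the pipeline is meant to detect, not
any particular genome. Defaults (the study conditions): two 1-Mb
chromosomes plus a 48.5-kb lambda contig; background GC 42% with 85% of
background CpG dinucleotides mutated away so CpG o/e is low outside and
high inside the 60 GC-rich CpG islands; 80 non-overlapping genes of
3–8 kb with 2–5 exons; expected CG levels 0.75 in gene bodies, 0.70
intergenic, 0.15 in promoters, 0.10 in islands, with a Gaussian TSS dip
(depth 0.12, σ 400 bp); CHG/CHH at 0.02/0.01 with +0.03 at islands and
shores; a +0.03 telogen CG offset; conversion error 0.005; coverage
negative-binomial around 20× (dispersion 10); and a beta-distributed
replicate wobble (concentration 300, mean-preserving) so the window
*t*-test sees honest within-group variance (per-sample window-mean SD
≈ 0.03 at mid levels).

Planted DMRs are realized as an explicit per-group level pair: the local
baseline is clipped so that both levels fit in [0.02, 0.98] and the groups
are set at centre ± Δ/2. Simply adding Δ to a 0.75 baseline would clamp
at 1 and silently shrink the realized effect below the 0.25 site filter;
the centred construction keeps the planted between-group difference
exactly Δ. The telogen offset is not applied inside planted regions.

Planted DEGs draw |log₂FC| ∈ (1.5, 3) and q ≤ 0.05; all other genes draw
q > 0.05 so they can never pass the DEG filter. A configurable subset of
DEG genes (default 5) also carries an intragenic planted DMR; the
remaining planted DMRs avoid DEG gene spans ± 2 kb so the expected
DMG × DEG overlap is exactly that subset.

Presets: `small` (defaults above — all contexts, 20 DMRs, 20 DEGs),
`null` (1 Mb, CG only, identical generative parameters in both groups),
`recovery` (2 Mb, CG only, 50 DMRs of 1–3 kb at Δ = 0.3). Problem sizes
were chosen so a full preset runs in seconds on a single core while
leaving tens of thousands of CG sites for calibration. Every draw flows
from one integer seed through separate, fixed-jump generator streams, so
the whole bundle is reproducible byte for byte.

What the generator does *not* emulate: read-level errors and mapping
bias, hemimethylation and strand asymmetry, copy-number or repeat-driven
coverage artifacts, spatially correlated biological noise beyond the
smoothing scale, and realistic gene/isoform structure. Passing tests
therefore demonstrate the procedure's internal correctness and its
calibration under the stated generative model — not performance on real
tissue libraries.

## Numerical choices and degenerate inputs

* Local-regression denominators near zero (collinear or single-site
  windows) fall back to the weighted mean; windows with zero total weight
  give NaN, and smoothed values are clipped to [0, 1].
* Welch windows with zero variance in both groups give t = 0, p = 1 when
  the means agree and p = 0 otherwise; windows where either group has
  fewer than two summaries are skipped and counted.
* Empty regions yield NaN sentinels, never zero levels; zero-coverage
  spike-ins and zero-call proportion requests raise errors.
* BH q-values can tie below their raw p (step-up minimum), so no
  q ≥ p invariant is asserted anywhere.
* The merger asserts that a same-sign run cannot have a pooled difference
  of exactly zero.

## Known limitations

* The binomial mC-calling rule is a stated stand-in for an unspecified
  upstream convention; inventory-style counts (e.g. proportions of mC by
  context) depend on it.
* DMG membership uses ≥ 1 bp overlap with the gene span or its 2-kb
  promoter; both the promoter inclusion and the overlap rule are
  configurable, and reported DMG counts depend on them.
* CHG/CHH DMR calling is mechanically available but uncalibrated.
* The adapter rule is exact substring matching; partial 3' adapter
  overlap detection is left to upstream trimmers.
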