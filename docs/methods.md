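# Methods

## The quantification model

Each TP73/TP63 isoform decision — which promoter a transcript used, which
C-terminal splice it took, which exon-8 donor form — is evidenced by reads
spanning one diagnostic exon–exon junction. The package treats each decision
point as a *level* of competing junctions and allocates percentage mass
hierarchically: the root level divides 100 % in proportion to its junction
counts; every deeper level divides its parent label's percentage in
proportion to its own counts. Because each level is a within-sample count
ratio, the result is invariant to rescaling all counts by a constant, so CPM
normalization affects only cross-sample displays, never the fractions.
N- and C-terminal ends are quantified independently; no joint (full-length)
isoform deconvolution is attempted, and none is implied by the outputs.

Assumptions: (i) competing junctions at one level are sampled with equal
efficiency, so count ratios estimate molar transcript ratios; (ii) every
transcript contributing to a level carries exactly one of its junctions;
(iii) junction counts are uniquely-mapping reads (multi-mapped reads are
ambiguous at paralog-rich loci and are never used).

Known limitation shared with the underlying junction-count approach: TP73 γ
and ε cannot be separated from junction data (identical E10–E12 evidence;
downstream structure re-uses the E12–E13/E12–E14 junctions that discriminate
α from β), so they are reported as a single tandem leaf `gamma+epsilon` and
the simulator does not attribute post-E12 junctions to the tandem
transcript. In real libraries, γ/ε transcripts do contribute reads to the
α/β-discriminating junctions; the α/β split is therefore conditional on the
α+β pool, exactly as the count-based method defines it.

### NA and partial semantics

A terminus with zero root-level counts is undefined: all leaves NA. If a
deeper level has zero counts while its parent still carries mass, only that
subtree is NA and the row is flagged `partial` (non-NA leaves then sum to
less than 100). A parent with 0 % mass propagates 0 to its children
regardless of their local counts. Tissue aggregation is the complete-case
mean over samples (NA samples skipped per leaf, `n_samples` reported); a
tissue is NA only when all its samples are.

## The 5′-depletion ratio

`ratio_pct = 100 × Σ(5′-junction CPM) / mean(body-junction CPM)`, with the
5′ set {E3–E4, E3′–E4} and the body set the five consecutive junctions
E5–E6 … E9–E10. The five body terms are grouped by exon pair, so for TP63
the E8–E9 term sums the full-length and shortened-donor (E8s) variants —
both carry mass shared by all C-terminal forms, and dropping E8s would
understate the denominator. On noise-free counts with no coverage bias the
ratio is exactly 100 %; an internal transcript providing fraction *f* of
body coverage gives (1 − f) × 100; 3′ coverage bias depresses the ratio
monotonically because both 5′ junctions lie farther from the poly-A end than
any body junction. The testis/TP73 pair is excluded: the testis-specific I3a
product (E3a + E4 only) breaks the assumption that body junctions measure
the same transcript pool as the 5′ junctions. `depletion_flag` defaults to
calling ratios below 40 % "depleted" — the midpoint between the two regimes
the statistic is designed to separate (~10 % under a strong internal TSS
vs ~70 % under 3′ bias alone); the threshold is a parameter, not a fitted
quantity.

## Gene models

Models are declarative YAML-serializable configurations (exons, junctions,
terminal isoform segments, cascade levels, ratio junction sets), so the
machinery is generic over genes. The shipped TP73/TP63 models use schematic
coordinates (plausible exon lengths laid along the chromosome with fixed
2-kb introns): every computation depends only on junction identity and exon
length, so absolute positions are placeholders by design. Users matching
real aligner output must supply a config with annotation-exact intron
coordinates, since file matching is by exact
(chromosome, intron_start, intron_end). TP63's E8s donor is modelled as a
60-bp shortening of E8. Junctions for TP63 exon-4 skipping and the 216-bp
intron-4/5 cryptic exon are deliberately absent (no tissue-specific signal);
likewise the rare TP73 N-terminal splice forms (Δex2, Δex2/3, ΔN′) are
representable as isoform segments but feed no cascade, because junction
quantifications do not report their distinguishing junctions.

## Synthetic data generator

The generator emulates what the analysis consumes, not raw reads: it draws
per-junction and per-exon counts for a known transcript mixture.

- **Mixture**: weights over full transcripts (N-choice × C-choice, plus the
  complete products I3a and E4p73), summing to 1. The expected count of a
  junction is the summed weight of transcripts carrying it, times a bias
  weight, rescaled so total junction reads equal `depth`.
- **Depth** (default 10⁵ junction-spanning reads for the gene): large enough
  that level denominators are in the thousands; Poisson counting error on a
  leaf percentage is then a few tenths of a point.
- **Noise**: independent Poisson per junction/exon — junction counts are
  count data and no overdispersion structure is imposed; a negative-binomial
  option (`nb_dispersion`, variance μ + dμ²) exists but is off by default.
- **3′ bias** (`bias_decay_bp`): a single-exponential weight
  exp(−d / decay) in transcript coordinates, d being the distance from the
  junction (or exon base, integrated analytically) to the 3′ end. This is
  the simplest monotone stand-in for poly-A-capture coverage decay — a
  qualitative model, not an estimate of any cohort's empirical bias; RNA
  degradation is emulated by shortening the decay scale, not by a separate
  mechanism. Default is no bias.
- **E8s share** (TP63, default 0.30): the fraction of E8→E9 mass routed
  through the shortened donor, matching the ~70/30 split observed across
  tissues. It feeds the E8-variant split and the E8–E9 body term only; the
  C cascade never sees it. It is a separate dial because the E8 choice is
  orthogonal to the N/C mixture vocabulary.
- **E4p73**: simulated as E4→E14 with α splicing; it carries all shared body
  junctions and no N-terminal junction, which is what makes it invisible to
  the N cascade and visible to the depletion ratio.

`truth_fractions` is the independent oracle: it walks every transcript down
each cascade by junction membership (pure per-transcript bookkeeping, no
count arithmetic), normalizing over the transcripts that reach the cascade
root. On noise-free, bias-free expected counts the quantifier reproduces it
to floating-point precision; with finite bias, root-level C fractions remain
exact whenever competing branches lead into equal-length tails (all
transcripts sharing one suffix), and shift otherwise — the generator makes
that deviation measurable rather than hiding it.

What the generator does *not* emulate: fragment-length and GC effects,
mappability, multi-mapping, junction-overhang filters, cross-sample library
variation. Passing recovery tests therefore demonstrates the correctness of
the count-to-fraction algebra under the stated noise model, not robustness
to every artifact of real libraries.

## Atlas summaries

Tissues are classified at mean TPM ≥ 2 per gene into four groups
(p73High_p63High, p73High, p63High, LowLow); exactly 2.0 counts as High so
the boundary is assigned. Spearman correlation uses average ranks with the
two-sided t-approximation p-value for all n (the exact small-sample
permutation p of R's `cor.test` is not implemented; for the tissue-scale n
this package targets, the approximation is standard). Scatter displays use
log2(TPM + 0.1); exon profiles use log2(normalized count + 0.01).

## Numerical choices

- Percentages are exact rational operations on floats; no iterative fitting
  anywhere, hence no initialisation or convergence concerns.
- Ties need no tie-breaking: fractions are continuous in the counts.
- Sum-to-100 holds to 1e-6 on fully defined rows; oracle agreement is
  asserted at 1e-9; written tables round to 2 decimals (documented maximum
  round-trip drift 0.005).
- Problem sizes in tests and the acceptance script — 100 random mixtures per
  gene, 1000 random count vectors per cascade, 200 Poisson samples at depth
  10⁵, a 10-point bias grid — were chosen as the package's standard
  verification conditions; each runs in seconds.
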