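# Methods

## Coordinates and input conventions

All internal coordinates are 0-based half-open, for residues, CDS
nucleotides and genomic bp alike; interval arithmetic then needs no ±1
bookkeeping. GFF3 and every TSV dialect (gene loci, domains, genetic
map, centromeres) are 1-based inclusive on disk and converted exactly
once, in the reader. Strand is stored but ignored by every analysis —
all statistics here are strand-agnostic. Protein and CDS records pair by
exact id; a CDS must be 3L or 3L+3 nucleotides for an L-residue protein
(optional stop codon). Mismatches are excluded from G+C analyses with a
warning rather than aborting, because real proteome releases contain
annotation glitches. `N` bases count as non-GC; `X` residues take
whatever disorder call the prediction gives them. Genes with multiple
transcripts must be pre-collapsed to one protein per gene upstream; the
package does not arbitrate between isoforms.

## Disordered segments and domain-relative classification

A disordered segment is a maximal run of true per-residue calls; run
boundaries come from the 0/1 transitions of the padded call vector, so
maximality is structural, not checked after the fact. Downstream
statistics keep segments of L ≥ 30 residues, the conventional threshold
separating functional long disorder from short loops; the threshold is a
parameter (`min_seg_len`) everywhere.

For the in/outside-domain accounting, overlapping domain hits on a
protein are merged (union) first so no residue is counted twice. Every
disordered residue is then labelled: inside a merged domain; N-terminal
to the first domain; C-terminal past the last; linker otherwise. The
cohort summary applies a double normalization: in-domain and
outside-domain percentages are taken over all disordered residues, while
linker/N-term/C-term percentages are taken over outside-domain
disordered residues only, so each group sums to 100 on its own — this is
the internal arithmetic of the classical percentage tables for this
analysis. Classification is per-residue, not per-segment: a segment
straddling a domain boundary contributes residues to both classes. By
default all disordered residues are counted here (the L ≥ 30 filter
applies to window and conservation statistics); a `min_seg_len` argument
switches to the segments-only reading, since published tables do not
state which was used. Proteins without domain annotations are excluded:
the contrast is undefined for them.

## Paralogue conservation and location classes

A pair conserves its disorder content when the two members' long-segment
counts are exactly equal (`--count-tolerance` relaxes this; default 0 is
the only reading the definition "conserve the number of segments"
supports). Pairs missing a mask are skipped and tallied, never silently
dropped.

Location stratification uses the anchor member (`id_a`): class A when
the gene midpoint lies within a centromeric window (radius 250 kb,
i.e. a 0.5 Mb window, configurable); outside it the arm runs from the
window edge to the telomere, class B covering the proximal 25% of the
arm and class C the rest. The 25% boundary is a package choice — the A/B/C
scheme is qualitative in its source and gives no quantitative B/C
geometry — and is exposed as `--proximal-fraction`. Centromere positions
are a required input; no default is assumed.

## G+C partitioning

Three per-gene quantities: GC_total over the whole CDS; GC_disordered
over nucleotides whose residue (⌊i/3⌋) lies in a long segment; and
GC_ordered = GC_total − GC_disordered, an exact integer identity checked
by construction. The GC_disordered *frequency* divides by total CDS
nucleotide length (the natural denominator for a base count; the
alternative — disordered-region length — is available as the per-region
percentage). A trailing stop codon encodes no residue and is ordered.

The enrichment test contrasts per-gene disordered-region G+C % with
ordered-region G+C %. Both regions come from the same gene, so a paired
Student's t test is the default (`--unpaired` selects the two-sample
version). Genes lacking either region are dropped; at least 3 usable
genes are required. A Shapiro–Wilk statistic of the tested values is
reported alongside as a normality check but never gates the test. The
degenerate all-equal case follows the convention t = 0, p = 1.

## Windows

Fixed mode tiles each chromosome with half-open windows (0.5 Mb
default), truncating the last; map mode adopts the genetic-map fragments
verbatim, carrying their cM. Genes attach to the unique window
containing their midpoint (⌊(start+end)/2⌋) — midpoint assignment avoids
double-counting boundary-spanning genes; a midpoint exactly on a
boundary belongs to the upper window by half-openness. Genes in map
gaps are tallied as unassigned. Windows with zero genes yield NaN
frequencies and are excluded from correlations and regressions rather
than imputed as zero: 0/0 is undefined, and imputation would
manufacture signal at gene-poor regions.

Per window: segments-per-ORF (long segments over member genes);
disordered-residue frequency (residues inside long segments over all
residues of member proteins); GC_disordered frequency (pooled
GC_disordered over pooled gene length); recombination rate cM/Mb.
Both disorder statistics are first-class because the segment form drives
the correlation analyses while the residue form is the regression
response (it shares units with windowed G+C).

## Statistical layer

*Pearson:* r by the product-moment formula; p from
t = r·√((n−2)/(1−r²)) on Student's t with n−2 df (scipy's beta-based
p is the independent cross-check in the tests). Star bands follow the
figure-legend convention — *** p < 0.005, ** p < 0.01, * p < 0.05,
strict inequalities, so p = 0.005 earns **.

*Dispersion:* the index of dispersion is the sample-variance (ddof = 1)
to mean ratio of counts of disorder-containing genes per fixed 0.5 Mb
window, computed per chromosome — the standard VMR test of spatial
randomness (1 under Poisson, >1 clustered). The literal phrase
"variance to the mean physical location" admits a reading in bp
coordinates, which is dimensionally unusable; the count reading is
implemented.

*Regression:* OLS of disordered-residue frequency on GC_disordered
frequency and cM/Mb via statsmodels, with multiple R², sequential
(type I) ANOVA p per term, a Breusch–Pagan heteroscedasticity statistic
and Shapiro–Wilk on residuals. Diagnostics are reported, never used to
drop observations.

*Enrichment:* one-sided hypergeometric upper-tail p per term over all
terms annotating the population, corrected by Bonferroni (default, the
conservative choice when the correction method is unspecified) or
Benjamini–Hochberg.

Window non-independence (spatial autocorrelation) is ignored, as in the
analyses this package reproduces; p-values at the window level are
therefore optimistic and should be read comparatively.

## Synthetic genomes

The generator emits a complete input bundle — protein FASTA, CDS FASTA,
mask FASTA, domain TSV, GFF3 loci with `##sequence-region` pragmas, map
TSV, pair TSV, centromere TSV — plus a ground-truth record, fully
determined by the seed. Default conditions: one 12 Mb chromosome in 24
half-Mb windows; 1200 genes of mean length 400 residues placed with
Dirichlet-weighted regional density (α = 50, giving the mild gene
clustering real chromosomes show); window recombination rates
Gamma(2, 2) cM/Mb (mean 4, within the empirical range of plant
chromosomes) with two 5× hotspot windows; per-gene long-segment counts
Poisson(λ₀ + β_rec·rate) with λ₀ = 0.8 and β_rec = 0.5 segments per
cM/Mb; segment lengths 30 + Geometric(mean 20) placed without touching;
additional short (<30) disordered runs (Poisson mean 1 per protein) that
never merge with long segments, so the L ≥ 30 filter has real work;
600 paralogue pairs whose partners copy the anchor's protein length and
conserve its segment count with probability 0.85/0.66/0.64 for location
classes A/B/C (the centromere-vs-arm contrast), else gain or lose
exactly one segment.

Sequences couple G+C to disorder mechanistically: disordered residues
are drawn, with probability p_rgap = 0.055, from Arg/Gly/Ala/Pro with
fully-G+C codons (all others, and all ordered residues, take a uniform
amino acid and uniform synonymous codon). This yields a true
disordered-region G+C increment of δ_gc = p_rgap·(1 − m₀) ≈ +2.9
percentage points (m₀ ≈ 0.47 is the uniform-codon G+C mean), the
magnitude reported for monocot coding sequences. A per-gene synonymous
G+C bias (SD 0.08 on the probability of choosing the most/least G+C-rich
synonymous codon) adds disorder-independent gene-to-gene G+C variation.

What the generator does **not** emulate: introns and UTRs (gene span =
CDS span), alternative transcripts, overlapping genes being forbidden
(placements may overlap), sequence evolution within pairs (partner
sequences are resampled, not mutated), domain–disorder anticorrelation
(domains land uniformly), and realistic proteome-wide disorder levels —
the default genome is disorder-enriched (~40% of residues) because the
coupling regime is kept strong enough for power at 24 windows. Passing
recovery tests therefore demonstrate correctness of the estimators under
the assumed generative structure, not predictive validity on real
proteomes.

Two estimator caveats, visible in the recovery report: the fitted
segments-per-ORF slope on cM/Mb underestimates β_rec, because segment
counts are capped by protein capacity and pair partners inherit the
anchor's count rather than their own window's rate; and with G+C in the
model the recombination term of the window regression carries little
independent information (windowed GC_disordered frequency is nearly
collinear with disordered-residue frequency by construction — it counts
bases inside the same segments), so its partial sign is unstable. Both
mirror the behaviour of the real-data analysis, where G+C dominates the
regression.

## Numerical and scale choices

Ensemble tests (power and null calibration) run 100 seeds of the default
genome with sequence emission disabled — masks, map and loci suffice for
the disorder–recombination correlation, and skipping codon sampling
keeps the whole suite under a minute. Conservation recovery uses a
10 000-gene / 5000-pair genome with a uniform 0.64 conservation
probability, where the binomial standard error (≈0.7 points) sits well
inside the ±2-point check. The acceptance script mirrors these sizes.
Permutation cross-checks of the correlation p-value use 10⁵ replicates
at n = 10 with a tolerance of 0.01, about three Monte-Carlo standard
errors at the p-values exercised.

The region-level worked example (r = 0.693 and r = 0.881 with **/***
bands) runs on a synthetic stand-in table: region pairs constructed by
Gram–Schmidt to carry exactly the published correlation structure at
n = 13 fragments, since the original per-region table is not
redistributable with the package. It validates the correlation and
banding machinery on data with a known answer, not the original
measurements.
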