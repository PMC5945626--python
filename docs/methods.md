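# Methods

This note documents the models, conventions and parameter choices behind
the package, the way the synthetic-data generator emulates real screen
data, and what the tests do and do not establish about real data.

## Coordinate frame and cut-site model

All analysis runs in cDNA space: a coding transcript is a cDNA string plus
the 1-based positions of the first and last CDS base. Public coordinates
are 1-based closed throughout, matching HGVS; `c.1` is the A of the start
codon and residue r = ⌊(c − 1)/3⌋ + 1.

Guides are located on the transcript by exact 20-nt protospacer match with
an adjacent NGG PAM on either strand (NAG sites are ignored; the libraries
this models are NGG designs). Every exact match is reported; downstream
proximity statistics use the minimum distance over all sites. The predicted
cut is the SpCas9 blunt cut between protospacer bases 17 and 18 (3 bp 5′ of
the PAM on the guide strand), reported as the sense-strand base immediately
5′ of the cut. The source screens speak only of distance to a "predicted
target site"; placing the point at the canonical blunt cut is this
package's documented choice, motivated by SpCas9 biochemistry, and the
5-bp proximity window is interpreted relative to that point.

## Alignment

Amplicon reads are subsequences of the cDNA, so alignment is semi-global:
the read is aligned end to end (end gaps penalised) while the reference
ends are free. Scoring is affine — match +1, mismatch −2, gap open −5, gap
extend −1 per base, so a length-L gap costs 5 + L. These defaults favour
one contiguous CRISPR indel over scattered mismatches, which matches the
NHEJ mutation spectrum the screens produce. The dynamic programme is
Biopython's `PairwiseAligner` in this configuration; the op-level
representation, tie handling and normalisation are the package's. Among
co-optimal alignments the aligner's first enumerated path is taken — this
is deterministic for fixed inputs — and indel placement is then fixed by
the mandatory 3′-shift: every indel in a repetitive context is slid to its
3′-most equivalent position (score-preserving, idempotent, and verified
property-based never to change the implied read sequence). Calls therefore
follow the HGVS 3′ rule regardless of where the aligner first placed a gap.

Reads shorter than 20 nt or more than 50% N are rejected. Reads are not
quality-trimmed: the modelled assays did not specify quality handling, and
an explicit minimum-read / minimum-fraction allele filter downstream is the
error-suppression mechanism instead. Externally aligned reads can enter
through SAM (`M/X/=/I/D/S` CIGARs; soft clips trimmed; unmapped and
secondary records skipped with counts logged).

## Variant calling and nomenclature

Mismatch runs become per-base substitutions and indel ops become
deletions/insertions; a deletion immediately adjacent to an insertion is
merged into a delins. A deletion adjacent to a substitution is *not*
merged — resistance tables report such alleles as phased compound variants
(`c.[127_129delATG;130T>A]`), and the bracketed multi-variant form keeps
that structure. Insertions use the flanking convention `c.(n)_(n+1)ins`.
Variants wholly outside the CDS are dropped (counted); a variant straddling
a CDS edge marks the allele `boundary`, which is excluded from frame
statistics — such alleles (e.g. splice-acceptor-spanning deletions) are
biologically uninterpretable in a pure cDNA frame. Intron-offset HGVS
coordinates (`c.121-4…`) are for the same reason outside this package's
coordinate space.

Frame classification: `wild_type` (no variants), `frameshift` (net length
change ≢ 0 mod 3), `nonsense` (frame preserved but a premature stop
introduced), else `in_frame`. For the enrichment statistic "in-frame"
means frame-preserving AND not nonsense: the tag-sorted screen selects for
full-length protein, so nonsense alleles are pooled with frameshifts as
disruptive.

Protein annotation works by editing the coding sequence (plus the
downstream cDNA tail, so frameshifts can find a stop in the 3′ UTR),
translating, and diffing the peptides with a maximal-common-prefix-first
placement, which reproduces the 3′-most (most C-terminal) HGVS placement
at protein level. Two renderings are emitted: canonical three-letter HGVS
(`p.Met43del`, `p.Lys119_Ser120del`, `p.Phe44IlefsTer50`) and the compact
style of resistance tables (`p.43delM`, `p.119_120delKS`, `p.44F>fs49*`).
The compact frameshift count fsN\* is the number of *novel* residues after
the last reference-matching residue, excluding the stop — one less than
the canonical fsTer index, matching how screen tables count "different
amino-acid residues". A frameshift that runs off the transcript without
reaching a stop is flagged `no_stop_found` with a null count.

## Screen statistics

**In-frame enrichment.** Exact one-sided binomial test of k in-frame among
n mutant alleles, alternative p > p₀ with p₀ = 1/3: an indel of uniformly
random length preserves frame one time in three, which is also the
empirical limit of the simulator's uniform(1..30) length distribution. The
95% interval is one-sided exact (Clopper–Pearson lower bound
Beta⁻¹(0.05; k, n−k+1); upper bound 1). The default counting unit is
unique alleles, with a read-weighted option: read counts in a
post-selection population are clonally inflated, so allele counting is the
conservative default, while the read-weighted figure describes the
population composition. Both are computed.

**Cut-site proximity.** The observed statistic is the fraction of unique
indels whose 3′-shifted start lies within window_bp (default 5) of the
nearest predicted cut; a read-weighted companion figure is reported. The
null draws the same number of positions uniformly over the assayed coding
interval — not the whole CDS, because only assayed bases can yield observed
indels — and the p-value uses the add-one estimator
(1 + #{null ≥ observed})/(1 + N), which can never be zero. N ≥ 1000 is
enforced; the default is 10⁴. Using the 3′-shifted start is a documented
convention: shifting changes distances in repeats, and consistency with
the calling convention matters more than the (unknowable) physical break
position. Seeds are explicit parameters of every stochastic operation.

**Tiling density.** Per coding base, m = summed read count of in-frame
alleles whose variants affect the base (deletions: every deleted base;
insertions: both flanking bases; substitutions/delins: the replaced bases);
density d = m/C × 1000 with coverage C. Bases pass the report filter only
with C strictly greater than 500 reads. Whether non-in-frame alleles count
is a switch (`inframe_only`, default true — the tag-sorted population is
dominated by in-frame alleles and the in-frame restriction matches the
screen's question). Residue scores are the *sum* of the codon's three base
densities (a mean is available) — summing weights multi-base events
naturally; bases failing the filter contribute 0, and a residue whose
three bases all fail is emitted with a null score. The B-factor writer
touches only columns 61–66 of matching ATOM records and requires an
explicit transcript-to-structure residue offset; it never guesses
numbering.

**Minimal mutation.** The intersection of affected residues across an
in-frame allele family; non-empty cores are labelled compactly
(`119_120delKS` when every allele is a deletion), an empty intersection
returns the modal affected residue flagged `no_common_core`. The family
should share a mutated region (one target site); the focused-screen driver
builds the family from alleles overlapping the cut-site codon
neighbourhood of the relevant guide.

**Copy number.** Allele fractions of an N-copy locus quantise to multiples
of 1/N; the estimator returns the N in 1..max_copies minimising the maximum
absolute deviation of each fraction from its nearest grid multiple, ties
toward smaller N. Input fractions must sum to ~1 (a wild-type remainder is
appended when they fall short).

**Recruitment curves.** Background-subtracted signal scaled so its maximum
is 1; a series with no positive corrected signal is returned all-zero and
flagged `no_signal` rather than divided by a non-positive maximum.

## Synthetic data

No external sequence or read data ships with the package. The transcript
is a deterministic synthetic PARP1-like cDNA (seeded codon draw from the
61 non-stop codons; 1014 codons plus stop, 24-nt 5′ UTR, 180-nt 3′ UTR)
with the literature's key residues planted at their canonical indices
(M43/F44/D45, K119/S120, N329, R591, H742/D743, Y848/K849/P850/F851,
A925), so nomenclature worked examples carry the familiar labels. Guide
libraries are derived by scanning it for NGG protospacers: a 29-guide
focused library in six positional pools, and a dense tiling library of all
~400 candidate sites (the synthetic sequence's NGG density sets that
count).

The read simulator emulates the statistical structure of screen amplicon
sequencing: each read spans the amplicon of a uniformly chosen guide
(halfwidth 70 nt); with probability `edit_probability` an indel is planted
at cut + round(Normal(0, sd)) with sd defaulting to 1.5 bp — the knob that
recreates the "nearly all indels within 5 bp of a target site" signature —
resampled (and counted) if it would leave the amplicon interior; lengths
come from uniform(1..30) by default (the 1/3 in-frame null) or are
frame-stratified when a target in-frame fraction is requested (the
post-selection regime); deletions:insertions default 80:20, a typical
SpCas9 NHEJ split; substitution errors are flat per-base. What it does
*not* model: platform-specific error structure (e.g. homopolymer errors),
PCR jackpotting/chimeras, microhomology-biased deletion spectra, or
multi-cut alleles. Passing tests therefore demonstrate correctness of the
statistics and calling machinery under a faithful statistical null, not
robustness to every real-platform artefact; the SAM import path exists so
real, externally aligned data can be brought in unchanged.

Clone-table simulation gives each clone Poisson(λ)+1 distinct guides,
forces a rotating hit-gene design (so the hit gene is multi-design by
construction), and plants sister pairs by duplicating the guide set of a
clone that carries at least one passenger — sisters are only detectable
through shared passengers, so planting them from single-guide clones would
plant undetectable truth. Recruitment curves are background + amplitude ·
(t/t_peak)² e^{2(1−t/t_peak)} (unit peak at t_peak) with slow exponential
decay after the peak and Gaussian noise.

## Clone attribution

A gene is a credible screen hit when carried by ≥ 2 distinct guide designs
across resistant clones; a single design recurring can be a jackpot clone.
Sister clones share ≥ 2 identical integrated designs (high confidence,
merged by transitive closure); exactly one shared design is reported as a
candidate link but never merged — confirming single-shared-guide
sisterhood needs genomic indel identity, which is outside this package's
inputs. Clones in a high-confidence group with exactly one attributed
cause inherit it. "ND" genotyping failures stay in the table
unattributed. One consequence, visible in the packaged mouse ES table, is
that a clone pair the original analysts called clonal on one shared guide
plus indel evidence appears here as a candidate link only.

## Problem sizes and numerics

Defaults used by the drivers and tests: 29-guide focused library at a few
hundred reads per pool, dense library at 4000 reads with a ×5 depth factor
applied to counts (so the strict >500-coverage filter is exercised while
keeping the number of alignments desk-scale); Monte-Carlo proximity at 10⁴
iterations. These sizes are the package's chosen desk-scale study
conditions; all statistics scale to larger inputs unchanged. Monte-Carlo
assertions in the tests compare seed-averaged estimates against analytic
tails at 3 standard errors. Binomial p-values and Clopper–Pearson bounds
come from scipy (`binomtest`, `beta.ppf`) and are exact, not normal
approximations. Floating-point comparison in the proximity null uses a
1e-12 tolerance on the ≥ comparison so equal fractions count as extreme.

## Known limitations

* cDNA-only coordinates: no genomic (g.) nomenclature, no intron offsets,
  no splice modelling; boundary-spanning alleles are flagged, not
  interpreted.
* The aligner's single-indel preference means complex multi-indel alleles
  separated by short matches may be represented differently from a
  minimum-edit human annotation, though always score-optimally and
  3′-normalised.
* Copy-number inference assumes equal per-copy amplification; allelic PCR
  bias is not modelled.
* The enrichment test treats alleles as independent; residual clonal
  structure among unique alleles (sister alleles from one editing event)
  would make it anti-conservative.
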