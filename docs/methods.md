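# Methods

This note documents the models and procedures implemented in `cnvsweep`,
the parameters that matter, and the design choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and data model

All intervals are 0-based half-open internally; VCF and GFF3 (1-based
inclusive) are converted at the I/O boundary and BED is written natively.
Phased genotypes live in a `HaplotypeMatrix` (rows = haplotypes, columns =
biallelic SNP sites; positions keep their 1-based VCF coordinate).
Multiallelic sites, indels and unphased or missing genotypes are skipped at
read time and counted, never imputed: EHH/iHS are defined only on phased
biallelic data. Derived-allele polarity comes from an `AA` (ancestral
allele) INFO annotation when present; otherwise ALT is treated as derived
with a logged warning — with an outgroup-free data set this is the only
available convention, and it affects iHS sign and the CLR spectrum but not
π, *D* or *F*<sub>ST</sub>.

## SNP selection statistics

**Windows.** One generator serves all scans: windows of `size` (default
50,000 bp) starting every `step` (default 20,000 bp) for every start below
the chromosome length, with trailing windows clipped (vcftools-like; the
end-of-chromosome convention is a choice, not a given).

**π and Tajima's D.** Per-site heterozygosity 2c(n−c)/(n(n−1)) summed over
window sites and divided by window length; *D* uses the canonical Tajima
(1989) constants, reported as 0 with a flag when S = 0.

**F<sub>ST</sub>.** Weir–Cockerham (1984) with haploid (haplotype-level)
observations: the within-individual term vanishes (h̄ = 0, c = 0) and
r = 2. Windows aggregate as ratio of sums Σa / Σ(a+b+c) — the "weighted"
vcftools variant — and negative estimates are reported as computed;
truncation at 0 is a presentation choice left to the caller.

**EHH / iHS.** EHH at distance x from a core allele is the probability
that two random carriers are identical from the core to x; extension stops
below a cutoff (default 0.05, the common tool default) and iHH is the
trapezoidal integral of EHH against physical distance (no recombination
map is assumed), summed over both directions. iHS = ln(iHH_A / iHH_D).
Sites whose EHH still exceeds the cutoff at a chromosome end are flagged
and dropped by default; sites below a minor-frequency bound (default 0.05)
are skipped. Standardization uses 50 equal-width derived-frequency bins
over [0, 1] (bins with < 2 records or zero spread yield flagged missing
scores); window-level aggregation takes the mean |standardized iHS| of the
sites in each window. The alternative reading of "normalization windows"
as physical windows was rejected: frequency-bin standardization is what
makes iHS comparable across frequencies.

**CLR.** The sweep model follows the classic composite-likelihood
construction: at distance d from a putative sweep position, each of the n
sampled lineages escapes the sweep independently with
p_e = 1 − exp(−α·d). Conditional on k escapees, the pre-sweep derived
count of the escaped sub-sample of size k+1 (k escapees plus one lineage
representing the entire swept class) is obtained by hypergeometric
downsampling of the background spectrum, and the swept-class lineage
contributes its allele as n−k copies; k = n reproduces the background
exactly. The background spectrum is the chromosome-wide empirical
distribution of derived counts over polymorphic classes 1..n−1 (invariant
and fixed-derived classes excluded), and per-site sweep likelihoods are
conditioned on polymorphism. CLR = 2(log L_sweep − log L_background)
maximized over a fixed geometric α grid (default 40 points spanning
1e−7…1e−2 per bp — escape negligible within ~1 Mb at the low end, certain
beyond ~1 kb at the high end — plus the exact background limit α = ∞), so
the maximized CLR is ≥ 0 by construction and the search is deterministic.
Grid positions default to one per 50 kb starting at 0. The α-grid
resolution matters: the likelihood peak in α is narrow, and a coarse grid
understates CLR.

**Determinism.** No randomness anywhere in the statistics; ranking ties
break by (chrom, start).

## CNV consensus chain

Filtering keeps calls that are precise (no IMPRECISE flag), pass the
caller's own quality filter, have length ≥ 50 bp and ≥ 4 supporting reads;
thresholds are inclusive because the removal rules are exclusive
("shorter than", "less than"). Per sample, transitively overlapping
same-type calls from ≥ 2 distinct callers form a consensus call on the
intersection interval (conservative breakpoints); any read-depth copy
number present must agree in direction, with a neutrality band
[1.75, 2.25] treated as contradicting evidence. Consensus calls from ≥ 2
animals merge transitively (≥ 1 bp overlap; a reciprocal-overlap fraction
is exposed but defaults off) into CNVRs spanning the union of members —
inclusive region definition — typed deletion/duplication/both from member
types, and placed in genomic context with precedence exon > intron >
intergenic.

Normalized copy number per CNVR and sample is the consensus call's CN
annotation when present, else inferred from the caller genotype
(homozygous DEL → 0, heterozygous DEL → 1, hom DUP → 4, het DUP → 3),
else the diploid 2 for samples without a call — absence of a call is
treated as evidence of the reference state, which V_ST requires since it
needs complete vectors.

## V_ST and outlier rules

V_ST = (V_T − V_S)/V_T with V_T the variance of copy number across all
individuals and V_S the group-size-weighted mean within-group variance.
Both use the population denominator (ddof = 0; exposed as a parameter
since the convention is not universal — V_ST itself is invariant to the
choice only when applied consistently). V_T = 0 yields a flagged missing
value. Scans return the top ceil(fraction·N_defined) items (V_ST: 2%,
F_ST and single-statistic selection scans: 1%) with deterministic
(chrom, start) tie-breaking; adjacent selected windows merge into regions
(bookended merge). PSGs are genes covered by the top windows of at least
two of the π (low tail), CLR and iHS scans. QTL overlap emits every ≥ 1 bp
(item, QTL) pair with both records; because a reciprocal-fraction flag
without an overlap fraction is not meaningful, reciprocity is an optional
parameter defaulting to off, and both the pair count and the distinct-QTL
count are reported since the two conventions differ.

## Synthetic data

The generator provides the study conditions the pipeline is tested under;
its defaults are fixed and are not tuning knobs.

**Forward Wright–Fisher.** Discrete generations, N diploids (default 200),
random mating with multinomial parent sampling, additive fitness
1 : 1+s : 1+2s at the sweep site, Poisson crossovers (rate r·L per
meiosis), Poisson mutations under infinite sites on integer positions
(collisions re-drawn). A forward simulator was chosen over a coalescent
because explicit selection is then trivial and desk scale (N ≤ a few
hundred, L ≤ 1 Mb) keeps it fast; burn-in is 10N generations from a
monomorphic start. Sweeps are conditioned on fixation by restarting from
the saved pre-sweep state on loss (retry cap 500); sampling happens at the
fixation generation, when the footprint is deepest.

**Scale calibration.** N = 200 and L = 500 kb are a desk-size rescaling of
a cattle resequencing study. The mutation rate (1.5e−6/bp/gen) is set so
equilibrium diversity matches cattle autosomes, θ = 4Nμ ≈ 1.2e−3/bp; the
recombination rate (5e−7/bp/gen, ρ = 4Nr = 4e−4/bp) is set so the hard
sweep footprint at s = 0.05, roughly s/(r·ln 2Ns) ≈ 27 kb half-width,
is commensurate with one 50 kb analysis window — mirroring real cattle
sweeps, whose footprints are at or above window scale. Samples are 30
diploids split 14/16 into two groups.

A known desk-scale limitation follows from these conditions: with
2Ns = 40, conditioned fixation takes on the order of 0.4·2N generations,
so the swept window retains roughly 40% of background diversity rather
than approaching zero, and with only ~23 neutral 50 kb windows on the
chromosome the single lowest-π window is a noisy localizer — the minimum
frequently lands one window-step off the selected site. Tajima's D in the
trough and the CLR contrast are more robust at this scale. Real
genome-scale scans (thousands of windows, Ne in the thousands, 2Ns in the
hundreds) do not face this ceiling; passing or failing the desk-scale
localization check accordingly says little about the statistics on real
data, which is why the oracle-equivalence tests (exact agreement with
brute-force definitions) carry the correctness burden.

**Two-group scenario.** A neutral shared background plus one inserted site
whose allele frequencies are independent Bernoulli draws per haplotype at
(f1, f2) per group; (0, 1) produces a fixed difference with per-site
F_ST = 1.

**CNV truth and pseudo-callers.** Neutral regions (default 100) get 2–8
carriers chosen independently of group with integer copy numbers (0/1 for
deletions, 3/4 for duplications); the differentiated scenario plants a
deletion with CN 0 in every sample of one group and half of the other,
matching a fully penetrant group-differentiated event. Three pseudo-callers
emulate distinct caller families: two breakpoint callers that genotype
(hom/het) but do not annotate CN, and one read-depth caller that annotates
CN (truth + Gaussian noise, sd 0.15) but does not genotype. Shared error
model: per-carrier false-negative rate 0.05, breakpoint jitter sd 30 bp,
support reads Poisson(10) (so ~1% of true calls fall under the 4-read
filter), 10% flagged IMPRECISE, false positives Poisson(0.02 per sample per
caller). These rates are deliberately on the conservative side for
kb-scale events at 25× coverage; they exercise every filter branch, and
they imply per-carrier consensus survival of ~94%, so recovery of the
planted deletion through the full chain is high but not certain on every
seed. The generator does not model demography, LD-calibrated haplotype
structure, read-level artifacts, or caller-correlated errors — passing
tests therefore demonstrate the pipeline's rules and arithmetic, not
performance on real sequencing data.

**Fixtures.** Gene models (2–8 exons inside a random span) and QTL records
(trait classes, P ≤ 0.05 after filtering) are drawn seed-reproducibly and
round-trip through the package's own readers.

**Reproducibility.** Every generator is a pure function of its seed; the
CLI writes its resolved configuration beside the outputs and re-runs are
byte-identical.

## Problem sizes used in the checks

The recovery experiments run 20 sweep replicates (N = 200, L = 500 kb,
s = 0.05, 30 sampled diploids) and 10 CNV-scenario seeds (100 neutral
regions, 30 samples), chosen to keep a full run within minutes on one CPU
while leaving the per-replicate conditions at the stated study scale.
Oracle comparisons use ≤ 500-element random fixtures at tolerance 1e−10
(1e−8 for iHS integrals, which accumulate trapezoid round-off).
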