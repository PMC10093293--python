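# Methods

## Assay model

The package models a ligation-dependent probe assay for targeted
splicing analysis.  A *panel* fixes, per gene, an ordered set of exons
(ordinals in 5′→3′ transcript order) and up to two junction probes per
exon: an acceptor-side probe at the 5′ boundary and a donor-side probe
at the 3′ boundary.  Terminal exons carry a single inward-facing probe.
Alternative boundaries within an exon (labels with a `p`/`q` suffix,
e.g. `5q` for the distal part of exon 5) are modelled as separate exon
records with ordinals offset ±0.5 from the parent, so every
classification decision reduces to one ordinal comparison.

A sequenced ligation product reads as `UMI ++ left-probe ++ right-probe
(++ barcode)`.  Classification of the probe pair is a pure function of
the panel:

1. any intronic probe → `intronic_control` (genomic-DNA signal);
2. any SNP-allele probe → `snp_allele`;
3. left probe not donor-side, right probe not acceptor-side, or genes
   differing → `artifact` (cross-gene pairs would be fusion candidates,
   deliberately out of scope);
4. otherwise, `ordinal(acceptor) > ordinal(donor)` → linear (canonical
   iff the pair is a reference-transcript junction), else `backsplice`.

A backsplice with `donor = last` and `acceptor = first` of a known
germline tandem duplication is linear splicing across the duplication
boundary in disguise; `annotate_pseudo_circ` flags (never removes) such
junctions, because the assay itself cannot distinguish the two — only
external germline knowledge can.  Flagged junctions stay in circRNA
tallies unless the user excludes them explicitly.

## Quantification

Molecules are counted as **distinct UMIs per (sample, probe pair)** —
not globally per sample, since two independent junctions can share a
UMI by chance without loss of information.  The per-circRNA ratio
divides a circular junction's UMIs by the *mean* linear-junction UMI
count (total linear UMIs over the number of canonical junctions of the
gene); the per-gene overall ratio divides total circular by total
linear UMIs, reported per 100.  Linear totals include alternative
(non-canonical) linear junctions while the divisor counts canonical
junctions only, following the ratio's definition; SNP and intronic
UMIs are excluded from both sides, as they measure alleles and
contamination rather than junction abundance.

With a 7-base UMI the tag space holds 4⁷ = 16 384 tags, and the
expected distinct-UMI count for *m* molecules is
`E[K] = U·(1−(1−1/U)^m)`, `U = 16384`.  Raw distinct-UMI counts are the
default unit everywhere.  An optional occupancy-corrected molecule
estimate `m̂ = −U·ln(1−k/U)` (the inverse of the expectation up to
O(1/U)) is available for settings where per-junction depth approaches
the tag space; the cohort-scale recovery analyses use it, because at
10⁵ linear-junction molecules per gene (~4×10³ per junction) raw counts
under-count the linear denominator by ~11% and would inflate the ratio
by ~0.25 per 100.

Sample QC requires 1500 distinct transcript UMIs, by default summed
over the target genes (`per-gene` mode requires each gene to pass
individually).  Detection frequencies are presence/absence calls
(`umi_count ≥ 1` after QC, configurable) with half-up rounding to two
decimals.  Allelic imbalance is an exact two-sided binomial test of
allele-A UMIs against 0.5, called when `p < 0.01` *and* the allele
fraction leaves [0.3, 0.7], with a 20-UMI floor; the thresholds are
package decisions — the readout is qualitative in practice.

## Read processing

The read structure is positionally rigid, so probe identification is
fixed-offset Hamming comparison (default tolerance 2 substitutions,
barcodes 1) rather than alignment; indels are out of scope.  The best
match must be unique — a tie yields status `ambiguous`.  Barcode
demultiplexing is unambiguous whenever the panel's barcode set keeps
pairwise Hamming distance ≥ 2·tolerance + 1, which panel validation
enforces.  UMI collapse is exact by default; an optional directional
merge absorbs a Hamming-1 neighbour when the parent's read count is at
least twice the child's minus one (standard practice for
sequencing-error UMIs), off by default since the reported counts are
raw.

## Synthetic data

The simulator is first-class, tested code and defines the study
conditions.  Each canonical-transcript molecule emits one ligation
product per canonical junction of its gene (capture efficiency 1.0 by
default; a configurable thinning in (0,1] preserves ratios in
expectation).  Alternative and backsplice molecules emit one product at
their junction.  By default circRNA molecules do *not* emit their
internal linear junctions (`circ_internal_linear=False`), matching the
implicit accounting of the ratio definitions; the flag exists so the
resulting bias can be studied.  Products receive independent uniform
7-base UMIs; PCR duplicates (default 3 reads per molecule) share their
molecule's UMI — that is precisely what UMI collapse removes.
Substitution errors are independent per base per read (quality scores
are constant; indels and chimeric ligations are not modelled).  SNP
products pair an allele-specific probe with its shared partner, with a
per-SNP molecule count and allele-A fraction; genomic-DNA contaminants
pair intronic probes.  Ground truth (per-junction molecule and
distinct-UMI counts) is emitted alongside the reads, and identical
seeds give byte-identical FASTQ output.

The cohort scenario mirrors the reference study structure: 38 normal
and 90 tumor samples, two genes, 10⁵ linear-junction molecules per
sample-gene, per-sample true overall ratios drawn from a Normal
recentred to the exact group means (1.89/1.14 per 100 for BRCA1,
0.51/0.23 for BRCA2), floored at 0.02.  Dispersions are 0.5 (BRCA1)
and 0.1 (BRCA2) per 100 — comparable coefficients of variation, keeping
ratios positive.  Circular molecules are spread over the reference
21-junction repertoire by a multinomial with the tabulated
group-specific relative proportions as weights.  At this scale the
scenario is evaluated at the molecule-count level: distinct-UMI counts
are drawn from the exact same tag-occupancy process the read simulator
realises, without materialising ~10⁷ reads per cohort.  Problem sizes
(10⁴-read oracle runs, 100 replicate cohorts, 20-seed occupancy checks)
were chosen so the full analysis reruns comfortably on a laptop.

What passing tests show — and do not.  The simulator reproduces the
assay's counting statistics (UMI occupancy, PCR duplication,
substitution noise, barcode structure) but not capture-efficiency
variation across probes, ligase sequence bias, FFPE fragmentation
profiles, or cellularity differences between tissues.  Recovery results
therefore validate the *computational* pipeline — that the method
measures what it defines, unbiasedly, at realistic depths — not the
wet-lab accuracy of any particular panel.

## Numerical and design choices

* Ratio denominators: zero linear UMIs raise an error (`no mRNA
  signal`) rather than returning NaN; zero circular UMIs give ratio 0
  and an empty proportion map.
* Anomaly detection normalises by the mean canonical-junction UMI count
  of the gene-sample (the same per-junction denominator as the
  per-circRNA ratio) and reports non-canonical junctions at relative
  abundance ≥ 1% by default — the sensitivity the 1500-UMI QC threshold
  guarantees for alternative transcripts.
* Group comparison defaults to the Welch t-test (group sizes and
  variances differ in the motivating design); `pooled` reproduces the
  classical Student test.  No multiple-testing correction is applied by
  default across subgroup panels.
* Profile rendering scales arc heights by √UMI by default (linear and
  log available); junctions below 0.1% of the mean canonical UMI are
  suppressed from the drawing but always listed in a sidecar table.
  Output is deterministic SVG (fixed ordering, no timestamps).
* Fixture probe sequences are synthetic random placeholders satisfying
  the panel invariants (uniqueness, 20–30 nt, no prefix ambiguity);
  `scripts/make_panel_fixture.py` regenerates them deterministically.
* The packaged QC pass-count table stores raw counts; two of its
  percentage entries as originally reported (86%, 66.5%) disagree
  slightly with their own count ratios (87.0%, 66.7%), and
  recomputation follows the counts.

## Known limitations

Fusion transcripts (cross-gene ligations) are tallied as artifacts, not
called.  Intron exonization is only indirectly visible as
canonical-junction depression.  The directional UMI merge is O(k²) per
junction — fine for amplicon-scale UMI sets, not for millions.  The
allele-imbalance test assumes the two allele probes capture with equal
efficiency.  Saturation correction breaks down as counts approach the
full tag space (k → 16384), where the assay itself stops being
quantitative.
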