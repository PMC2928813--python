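# Methods

## Problem setting

In an isolated, multiply consanguineous family segregating an
autosomal-recessive trait, all affected individuals are expected to be
homozygous by descent for one ancestral haplotype spanning the causal gene.
Classical parametric linkage is unattractive here: the pedigree's loops make
likelihood computation fragile and reliable marker allele frequencies for a
small founder population are unobtainable.  The package therefore implements
two frequency-free scans over AB-coded SNP-array genotypes, plus the
downstream consequence annotation for a splice-acceptor point mutation, and a
simulator that generates panels with known ground truth.

## Genotype representation

Calls are AA/AB/BB/missing in platform-neutral AB coding (integers 0/1/2/−1).
When reading `.ped` files with nucleotide alleles, the lexicographically
smaller observed allele at each marker maps to A; files already written in
literal A/B letters map identically so that write→read round-trips.  Any
fixed per-marker bijection suffices for run detection, since both scans
compare genotypes only within a marker.  Coordinates are 1-based and closed
throughout; BED input is converted on read.  All chromosomes are treated
uniformly (no special X handling) — a documented simplification.

## Genetic-map repair

Array annotations carry empty, zero and non-monotone cM values.  A value is
flagged invalid when it is absent, exactly zero (except a zero at the
chromosome's first marker, kept as the chromosome-start anchor), or off the
longest non-decreasing subsequence of the remaining values — the minimal set
of removals that restores monotonicity, with ties resolved in favour of
earlier markers (first-seen wins).  Flagged values are linearly interpolated
in physical position between the nearest valid flanks; beyond the outermost
anchors the repair is constant rather than linear, avoiding negative cM.
Repair is idempotent and leaves valid values untouched.

## HH screen

Per affected, the homozygosity haplotype is the ordered subset of completely
homozygous markers.  A discordance point is a marker where at least one
affected is A-homozygous and another B-homozygous.  Candidate regions are
maximal stretches of informative markers (homozygous in ≥ 1 affected) free
of discordance points; boundaries sit on the outermost concordant markers,
with the discordance points themselves excluded.  Regions are additionally
split wherever consecutive informative markers lie further apart than
`largegap_bp` (default 400,000 bp, the centromere-style gap guard raised
from 300 kb to accommodate array spacing), and only regions of genetic
length ≥ `cutoff_cm` (default 3.0 cM) are reported.  Markers heterozygous in
every affected do not anchor the gap test, consistent with the
homozygous-subset framing.  Unaffected samples play no role in this screen.
No minimum informative-SNP count is imposed beyond the cM cutoff (a
configurable floor exists, default 1).

Known-locus exclusion intersects candidate regions with named intervals on
closed bp coordinates: a locus is EXCLUDED exactly when no region touches it.

## Shared-IBS run scan

A marker conforms when every affected call is AA, or every affected call is
BB.  Maximal conforming runs of at least `min_run_snps` (default 35) markers
are reported with the inclusive size convention `end_bp − start_bp + 1`,
sorted by descending SNP count (ties by chromosome, then start).  Missing
calls break runs: the error mode the scan forgives is specifically the
false-heterozygote call, not dropout.

Bridging merges two same-chromosome runs when the markers between them
number at most `bridge_max_gap_snps` (default 1) and each fails only because
at most `bridge_max_carriers` (default 1) samples are heterozygous there —
never across an opposite-homozygote conflict or a missing call.  Merging is
transitive, and a merged region's SNP count covers its whole span, bridged
markers included.  Each merged region records, per unaffected sample, the
fraction of span markers at which that sample is homozygous for the
affecteds' shared allele; a fraction ≥ 0.95 (configurable — the scan's
definition of "carries the haplotype") flags the region NOT_SEGREGATING.
The ranking report adds each region's ratio to the next-ranked SNP count as
the outlier diagnostic; a region with no successor reports infinity.

## Splice-acceptor consequence

The model is deliberately minimal: the intron-terminal AG is the sole
acceptor determinant (no branch point, polypyrimidine tract or strength
scoring), and when a substitution destroys it the nearest downstream AG
within a 200 nt window wins — matching the splice observed in patient RNA
for this mutation class.  The aberrant junction deletes the exonic bases 5'
of the cryptic AG; the mutant CDS is translated with the standard code from
the reference start codon to the first in-frame stop.  A deletion length
≢ 0 (mod 3) is an obligatory frameshift; absence of any stop flags stop-loss.
Reported quantities: disrupted intron, deleted bases, frame status,
reference and mutant protein lengths, and the intact prefix (codons fully 5'
of the junction).  Minus-strand transcripts are reverse-complemented into a
transcript-forward frame at construction; offsets are transcript
coordinates.  Cryptic acceptors are sought inside the downstream exon only;
junctions upstream of the start codon are out of scope.  Reproducing the
exact published residue numbers (truncation after 643 of 723 residues)
requires the real transcript models, which are not shipped; the packaged toy
transcript reproduces the qualitative result (2 nt deletion, frameshift,
premature truncation).  No claim is made about protein stability or decay.

## Simulator

**Founders.**  Each founder contributes two haplotypes with independent
per-marker B-allele frequencies (default drawn once from U(0.05, 0.5), an
array-like site-frequency profile).  One designated founder haplotype
carries the causal allele.  Founder linkage disequilibrium is deliberately
absent — run detection operates on homozygosity, not haplotype frequencies,
so independent founders suffice; background sharing is therefore somewhat
more fragmented than in a real founder population.

**Transmission.**  Each meiosis's inheritance indicator is a two-state
Markov chain along the chromosome with Haldane switch probabilities
(1 − e^(−2d))/2 — no crossover interference.  Crossovers are observable
only as marker-interval switches; at default density (0.02 cM spacing) the
invisible double-crossover deficit is ≈ 2×10⁻⁴ per meiosis, negligible
against sampling error.

**Autozygosity conditioning** is exact rejection sampling, implemented in
two stages for feasibility: inheritance bits at the causal marker are
rejection-sampled (vectorised over ~10⁵ attempts per block) until every
designated affected is homozygous by descent for the causal haplotype —
an event of probability 2⁻²¹ in the demo pedigree — and the accepted
single-locus configuration is then extended left and right with the same
Markov transitions.  Because a whole-chromosome drop factorises into the
causal-locus bits times conditionally independent extensions (the chain is
stationary and reversible), this samples exactly the distribution that
naive whole-drop rejection would, at ~10⁶-fold lower cost.  An outer
rejection retries the whole drop until the realised shared IBD tract spans
at least `target_region_snps` markers (default 300); a pedigree that cannot
produce the required autozygosity exhausts `max_locus_attempts` and raises.

**Error model.**  One-directional, mirroring array behaviour: a truly
homozygous call becomes AB with `het_error_rate` (default 5×10⁻⁴); any call
becomes missing with `missing_rate`.  True heterozygotes are never converted
to homozygotes.  The default missing rate is 0: the error mode the scans
must tolerate — and the one the mapping study observed interrupting its
candidate region — is the false heterozygote, and because missing calls
break runs and are never bridged, a scenario with material missingness is a
different (and harsher) study condition, available by raising the parameter.

**Ground truth.**  The simulator records, per affected, the IBD tract (the
maximal interval where both haplotypes are the causal founder haplotype),
the tract intersection across affecteds, and that intersection's IBS-closure
— the maximal interval around the causal marker over which all affecteds
are homozygous-identical on the pre-error calls, computed inside the
simulator by direct expansion.  The closure, not the bare IBD intersection,
is what a marker-by-marker scan can recover exactly: at a tract edge the
first affected to lose IBD remains homozygous by state with probability
roughly the allele frequency, so chance IBS extends the detectable region
by a few markers per side.  With errors disabled, the scan's top region
equals the closure exactly and contains the IBD intersection.

**Demo pedigree.**  One ancestral couple, three children married to
unrelated spouses, and three first-cousin couples producing six affecteds in
three sibships plus unaffected sibs — the loop structure homozygosity
mapping exploits, at a size where conditioning stays cheap.  It approximates
the shape, not the identity, of any real family.

**What passing tests do and do not show.**  Recovery of the implanted tract
in ≥ 45/50 replicates demonstrates the scan logic, bridging and ranking
under the modelled error process; it does not certify performance on real
arrays, where LD, batch effects, CNV-driven loss of heterozygosity and
non-uniform error rates all exist and are unmodelled.

## Problem sizes and numerical choices

Default simulations use 8,000 markers (5,000 on the causal chromosome at
0.02 cM spacing, 2.5 Morgans total map) and a 23-member pedigree — dense
enough that a ≥ 300-marker tract is the norm while a full simulate+scan
replicate stays around two seconds.  The published-region reconstruction
carries the exact printed SNP counts per segment (1,366 markers).  Mbp spans
round half-up at two decimals from the simple coordinate difference
(end − start); the inclusive variant is exposed and agrees at the printed
precision.  Ranking ties break by (chromosome, start).  All randomness flows
from a single integer seed through `numpy.random.Generator`; identical seeds
give byte-identical reports.

## Known limitations

- No X-specific handling; no sex-specific genetic maps.
- No likelihood-based ROH calling (genotype-likelihood HMMs) and no
  population-frequency weighting — the method is deliberately frequency-free.
- Founder haplotypes lack LD; background run lengths are approximate.
- The splice model ignores acceptor-strength competition; it reports the
  nearest-AG outcome, which is the observed outcome for this mutation class
  but not a general splice predictor.
- Binary PLINK, VCF input and raw array intensity parsing are out of scope.
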