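# Methods

## Signal model and coordinate conventions

All positions are 0-based half-open internally; every file format keeps its
native convention (GFF3 and report tables 1-based inclusive, BED/bedGraph
0-based half-open), and the genome is a single linear chromosome —
circularity is not modelled because no stage here depends on wrap-around.

Two per-strand integer tracks drive the analysis: *read starts*
x<sub>i</sub>, the number of fragments whose 5'-most transcribed base is
position *i* (on the minus strand this is the right end of the fragment),
and *coverage* c<sub>i</sub>, the number of fragments covering base *i*.
Mate pairs are combined into single fragments spanning the outer read
extent when both mates map to the same strand within 1 kb; wider or
discordant pairs are discarded (counted), and lone mates are kept as
single-read fragments.  Two invariants are enforced everywhere: per strand,
Σc equals the total fragment length and Σx equals the fragment count.

## TSS calling

A position is a candidate when x<sub>i</sub> > T and either
x<sub>i−1</sub> = 0 or x<sub>i</sub>/x<sub>i−1</sub> > R, with "previous"
taken strand-aware (i+1 on the minus strand).  Defaults T = 14, R = 5.  A
zero previous count passes the ratio test by convention — an isolated peak
is the clearest possible start.  Note an interaction that shapes simulated
data too: of two peaks 1 nt apart, the downstream one passes the ratio test
only if it is > R-fold higher, so alternative-start pairs are detectable
only in that configuration.

Candidates within 1 nt collapse to the highest-count position (ties to the
5'-most).  Candidates assignable to rRNA/tRNA genes, or inside one in sense
orientation, are set aside as stable-RNA starts.  The published analysis
then removed false positives by manual review; here that review is codified
as a prominence filter: a candidate in scope (more than 300 nt upstream of
the nearest same-strand start codon, or inside a sense CDS with more than
100 read starts) is kept only if its count is ≥ 3× the mean signal in the
surrounding ±10 nt window.  All three scope/strength constants are
parameters, and every flagged site is written out with its prominence for
audit.  No claim is made that these defaults reproduce any manually curated
count.

Classification precedence is gene_assigned → intragenic → antisense →
intergenic.  A TSS is gene-assigned when it sits exactly on a start codon
(leaderless, UTR 0) or at most 500 nt upstream of the nearest same-strand
start codon; choosing the *nearest* start codon makes the
no-intervening-start condition automatic.  The 500-nt cap must exceed the
300-nt false-positive scope boundary to be coherent; both are parameters.
The ledger — detected = retained + merged + stable-RNA + false-positive —
is recomputed and asserted when the report is written.

## Gene-start refinement

For a TSS inside a gene body: if it lies on a start codon (ATG/GTG/CTG/TTG)
in frame with the annotated stop, the gene is re-annotated leaderless with
its start at the TSS.  Otherwise the 5'-most in-frame start codon strictly
downstream of the TSS that can still reach the annotated stop is proposed
(an internal in-frame stop voids earlier candidates), and the remaining
candidates are listed for audit.  "5'-most" is a documented convention —
the choice among candidate starts is genuinely open.  ORF scanning reports,
per stop-bounded frame segment, the ORF from its 5'-most start plus every
internal alternative start; it is verified against a brute-force
enumeration on random sequences.

## 5'-UTRs and RBS statistics

UTR length is the strand-aware TSS→TLS distance; 0 defines a leaderless
mRNA.  For genes with several TSSs the "unique UTR" used by the RBS and
purine analyses is the one from the TSS with the most read starts
(configurable to shortest/longest; the underlying selection rule is not
derivable from the data).  The purine profile uses unique UTRs of length
≥ 20 trimmed to their final 20 nt.  RBS spacers count the bases strictly
between the motif's 3' end and the first base of the start codon.

Externally predicted cis-regulatory regions (riboswitches, RNA
thermometers) are matched against observed transcript/5'-UTR intervals by
same-strand overlap.  The default demands any strictly positive overlap:
on the packaged 16-region reference table, two regions match their
observation by only 16 % and 30 % of the predicted span, so any threshold
above ~16 % would contradict the recorded observed/not-observed calls.  The
threshold is exposed as `min_overlap_frac` for stricter use.

## Motif discovery

Motifs are fixed-width PWMs learned by ZOOPS EM: each sequence contains at
most one site; the likelihood mixes a no-site background term (1−γ) with
uniform site positions (γ/m).  Pseudocount 0.25 per cell acts as a
Dirichlet prior, so the quantity guaranteed monotone (and asserted every
iteration) is the penalized objective, log-likelihood + prior.  Ten
restarts are seeded from randomly chosen data windows; after the best
restart converges, ±1-column phase shifts are attempted and kept when they
improve the objective — without this move the EM frequently converges to
the planted motif shifted by one column.  Background is a 0-order model
estimated from the searched windows.  Determinism: same seed, same model.

Positional constraints implement the anchored searches.  The −10 search
runs the EM on the spacer-admissible tail of each 60-nt upstream window
(motif 3' end 3–11 nt before the +1): in an unconstrained window the EM
locks onto the most informative upstream element — typically the −35, which
has five defined consensus positions against the −10's three — after which
every hit fails the spacer filter.  The −35 search then runs on the 9-nt
sub-window 16–19 nt upstream of each accepted −10.  RBS motifs (width 5)
are searched in unique UTRs of length ≥ 14 trimmed to 20 nt.  Hits are
retained per sequence when the posterior probability of site presence is
≥ 0.5 and the spacer constraint holds.

Two caveats measured during development and reflected in the tests: on
uniform random sequences this EM family still fits a diffuse junk motif
with mean information content ≈ 0.4–0.6 bits (null and planted cases are
separated by IC, not by IC ≈ 0); and with few sequences a degenerate
3-position motif can be beaten by a spurious one with genuinely higher
likelihood, so consensus-level recovery guarantees are stated for
50-sequence panels, while on the default toy architecture (~23 promoters)
the −10 is asserted as hit rate plus its TA…T signature.

## Operons

For every pair of same-strand neighbours (adjacent in the same-strand gene
ordering, with no distance cap), junction support is the number of
fragments overlapping both gene bodies by ≥ 1 nt.  Chains with support
≥ 15 form primary operons; a chain whose first gene lacks an assigned TSS
is kept and flagged rather than dropped.  Unchained genes are monocistronic
when their mean gene-body coverage is ≥ 1, otherwise unassigned.  Stable
RNA and ncRNA genes participate in chains.  Each gene-assigned TSS on a
non-first gene starts a sub-operon — the suffix of the chain from that
gene; duplicates collapse.  Raising the junction threshold can only split
chains, never merge them.

## Novel transcripts and 3' ends

Novel transcripts are maximal runs of c > T (reusing T = 14; the coverage
threshold is configurable and recorded) that do not overlap a same-strand
annotated gene, of length ≥ 50 nt.  Classification: intragenic (5' end
inside a sense gene) → antisense (overlapping an opposite-strand gene) →
intergenic.  Novel TSSs without a coverage call seed `tss_derived` calls
extended 3' while c > 5; these ends are approximate and marked by their
source.  Intragenic 3' ends are not reported — the signal merges with the
host gene's transcript.  Intergenic calls get their longest ORF (≥ 30 nt,
same codon sets as refinement) and a log-odds RBS score over the 20 nt
upstream of the ORF start, skipped (and flagged leaderless) when the ORF
begins at the transcript 5' end.

Terminator predictions are consumed as a table of stem1/loop/stem2/tail
genomic sub-spans, contiguous in transcription direction with equal stems;
only terminators trailing monocistronic genes or the last gene of a primary
operon are evaluated.  With u the mean coverage of the 5 bases 5' of stem1:
u < 11 → insufficient coverage; otherwise the transcript end is the first
base b (5'→3', configurable to last) with u / max(c<sub>b</sub>, 1) ≥ 5,
attributed to the sub-element containing it; no such base → gradual
decrease.  The max(·, 1) keeps the ratio finite at zero coverage.
Bidirectional terminators are simply two predictions, one per strand.

## Synthetic data: what it emulates, and what it does not

The generator lays out transcription units left to right with 550–800 nt
gaps: eight operons (2–4 genes, internal TSSs in alternating operons),
eleven monocistronic genes, a tRNA and an rRNA unit, an intergenic novel
transcript, an antisense transcript inside a host gene, an intragenic TSS,
an alternative-TSS satellite 1 nt 5' of one primary peak, and one
processing-site plateau that the false-positive filter should flag.  Gene
bodies are non-stop codons between a start (ATG 79 % / GTG 21 % for
leaderless genes) and a stop; −10/−35/RBS consensus strings are planted at
spacers drawn from their documented ranges with per-base identity 0.9 (so
motif discovery is non-trivial); terminator stems are reverse-complement
palindromes with a T-tail.  Defaults: 50-kb genome, 28 planted TSSs, ~34
genes; an end-to-end run takes well under a second.

The 5' library is Poisson: rate 60 at planted TSSs over rate 0.2
background.  The whole-transcriptome library samples per-transcript
fragment counts at 0.2 per transcribed nt, lengths uniform in 200–500 nt,
with fragment extents clipped to the transcript — emulating hydrolysis of
full-length transcripts — so coverage is plateau-shaped with sharp edges at
the TSS and at the planted 3' end (a drop placed in stem1/loop/stem2/tail
at 72/18/8/2 %).  A genome-wide background fragment rate of 0.01/nt models
unassigned transcription.

Deliberately not modelled: sequencing errors and base qualities, rRNA
contamination, expression-level heterogeneity between transcripts,
condition-dependent starts, RNA processing and 5'-end degradation, and the
gradual 3' tapering of real fragmentation libraries.  Passing recovery
tests therefore demonstrates the correctness of the inference rules under
their own signal model — clean peaks and plateaus — not robustness to the
full noise structure of real libraries.

## Problem sizes and numerical choices

Tests and the acceptance script run the default toy scale: 10–20
simulated datasets for recovery rates, 200 random 300-mers for the ORF
oracle, 50-sequence motif panels over 20 seeds, a 1000-terminator panel for
end-region fractions, and 500 planted spacers for the spacing statistic —
sizes chosen so every estimate's sampling error is small against its
tolerance while the whole suite stays fast.  EM: tolerance 1e−6 on the
penalized objective, ≤ 200 iterations, 10 restarts.  Ties: 5'-most wins
(TSS merging); first qualifying base wins (3'-end scan).  Degenerate
inputs: empty tracks raise; empty UTR sets yield empty statistics; a
terminator outside the genome raises.
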