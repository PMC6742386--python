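# Methods

This note documents the models and conventions mirpipe implements, the
parameters that matter, what the synthetic benchmark does and does not
emulate, and the numerical choices made where the design was open.

## Read preprocessing

Reads are processed through a fixed cascade; every raw read receives
exactly one fate, so fate counts partition the raw total per library.

* **Adapter trimming.** The insert is the prefix before the left-most
  occurrence of the 3' adapter; a ≥6 nt adapter *prefix* flush with the
  read end also counts, so inserts whose adapter is truncated by the read
  length are recovered. An empty insert is an adapter dimer; no occurrence
  means the read never reached the adapter (fate `no_3_adapter`). Adapter
  default: the TruSeq small RNA 3' adapter `TGGAATTCTCGGGTGCCAAGG`.
* **Junk filter.** Low complexity is declared when one base makes up ≥80%
  of the insert, a dinucleotide tandem repeat covers ≥90%, or an ambiguous
  base is present. The two thresholds are conventions (the notion of "junk
  reads" has no standard operational definition); both are deliberately
  conservative and live in one function for easy tightening.
* **Length window.** Inserts of 15–32 nt are retained, boundaries
  inclusive. Unique tags of 18–25 nt are eligible for miRNA matching;
  shorter/longer retained tags are still counted and can only be rescued by
  the genome-mapped (novel) route.
* **Contaminant screen.** A tag occurring as an exact substring of any
  rRNA, tRNA, snRNA, snoRNA, repeat or mRNA reference is assigned the first
  matching class in that fixed order. Exact matching keeps the filter
  deterministic and oracle-checkable; quality scores are parsed but ignored
  (no quality filter is part of the protocol).

## Tolerant matching and the isomiR grammar

A tag is aligned to each annotated mature by enumerating end offsets
(left_delta, right_delta) within a tolerance E (default 4 per end;
published isomiR suffixes rarely exceed |2|) such that the shifted
reference interval has the tag's length. Extensions must copy precursor
context — an extended read that does not match its hairpin context is not
an isomiR of that mature. At most one substitution is allowed, and only
strictly inside the detected sequence (never at the first or last base).
The reported match minimises

    cost = |left_delta| + |right_delta| + 2 × substitutions,

i.e. the explanation with the fewest sequence edits wins; ties break on the
lexicographically smallest reference name, then the smallest |left_delta|.
The cost weights and tie-break are package conventions chosen for
determinism; an exhaustive-enumeration oracle in the tests guarantees the
search is exact, not heuristic.

Names append the non-zero parts in fixed order (`L±n`, `R±n`, then
`1ss<pos><Ref><Obs>` with the position 1-based on the detected sequence,
5'→3'). The grammar is parsed and inverted by `reconstruct_tag`; the
round trip name → reconstruct → tag is property-tested on 1,000 random
isomiRs. Tags placed on the precursor arm opposite the annotated mature
(exact ends, ≤1 internal substitution, placement excluded from the
annotated interval widened by E) become `-p5`/`-p3` candidates on the
precursor name.

## Hairpin validation

Candidate genomic loci are folded over the locus ±120 nt per side
(strand-aware; windows truncate at contig edges; a window shorter than
candidate +15 nt is not evaluable). "Flank 120 nt" is read as 120 nt on
each side — the alternative (120 nt total) cannot contain a candidate plus
a stem on both sides.

The fold is a Nussinov-style maximum base-pairing dynamic programme
(pairs A:T, G:C, G:T — the DNA spelling of G:U — minimum loop 3). A locus
is accepted as a hairpin when

* every paired candidate base finds its partner outside the candidate on
  one side (candidate entirely in the 5p or the 3p arm; partners on both
  sides ⇒ `spans_loop`, rejected),
* ≥60% of candidate bases are paired, and
* the stem through the candidate (pairs enclosing its innermost pair)
  involves ≥18 paired positions.

Maximum matching replaces thermodynamic folding deliberately: it is
parameter-free, exactly reproducible, and checkable against definitional
enumeration of all nested structures on small sequences. The 0.6 / 18
thresholds are declared conventions (no published acceptance criterion
exists for "within hairpins"); a thermodynamic backend (e.g. RNAfold) can
be plugged in behind the same `HairpinCall` contract. The DP kernel is
numba-jitted when numba is importable (~5 ms per 261 nt window) with an
equivalent vectorised numpy fallback.

## Group taxonomy

First matching rule wins: (i) specific mature in its arm → 1a; (ii)
opposite arm of a specific precursor → 1a as p5/p3 candidate; (iii)
selected mature whose precursor maps to the genome → 1b; (iv)/(v) selected
mature with the tag itself on the genome, with/without a hairpin →
2a / 2b; (vi)/(vii) selected mature with no genome hit → 3a (if a specific
match also exists) / 3b; (viii) no known-miRNA match but an exact genome
hit (up to 10 loci) with some hairpin locus → 4a, named `PC-<arm>-<serial>_
<count>`; contaminants → others; everything else → nohit. The precedence
between 1b and 2a/2b, and the reading of 3a, are declared conventions where
the published flow chart is ambiguous. Genome mapping of tags is exact
(both strands); the 10-locus multi-mapping cap is configurable.

## Differential expression

Counts are normalized per library to one million **clean** reads — the
retained-tag total, not the raw total — so each library's normalized mass
is exactly 10^6. The test is the classical pooled-variance two-sample
Student's t-test (Welch available as an option), two-sided, at raw
thresholds 0.05 and 0.01 with no multiple-testing correction, matching the
protocol it reimplements. Degenerate zero-variance rows: p = 1 for equal
means, p = 0 otherwise — note this makes a feature observed only in one
condition at perfectly proportional counts trivially significant; with
three replicates and CPM scaling this is rare but visible in the tails of
real outputs. log2 ratios use a pseudocount (default 0.01 on the CPM
scale) only to guard zeros.

qPCR: ΔCt = Ct_target − mean Ct_reference per condition,
ΔΔCt = mean ΔCt_treated − mean ΔCt_control, fold = 2^(−ΔΔCt) (the
comparative method's standard sign; the exponent is negative so that
earlier amplification means higher expression). The randomization test
reallocates condition labels over the pooled replicate ΔCt values with
statistic |ΔΔCt|; in exhaustive mode all C(n+m, n) relabelings are
enumerated and p = (b + 1)/(N + 1), b counting non-observed relabelings at
least as extreme; sampled mode draws seeded relabelings with the same
plus-one correction.

## Target prediction

Gapless duplexes only: position p of the miRNA (1…L from the 5' end) faces
site position L+1−p. Penalties 0 / 0.5 / 1 for Watson–Crick / G:U /
mismatch, doubled at positions 2–13 (the seed), summed into the
expectation; sites with expectation ≤ cutoff (default 3) are reported,
sorted by (expectation, transcript, position). A non-Watson–Crick pair
facing position 10 or 11 — the slicing site — flips the predicted mode
from cleavage to translational inhibition. Bulged (gapped) alignments are
out of scope in this version: at cutoff 3 they are rarely reportable and a
gapless scanner is verifiable against brute-force window enumeration,
which the tests do.

## GO enrichment

One upper-tail hypergeometric test per term present in the study set,
population = all genes with ≥1 annotation in the supplied map (the study's
own universe definition is not published; this is the most common choice).
Raw p < 0.05 defines significance; Benjamini–Hochberg is available behind
a flag but off by default to match the protocol. No GO-graph propagation:
the annotation map is taken as given.

## Promoter scanning

The promoter proxy is the 1000 bp upstream of the precursor locus in its
transcription direction (minus-strand loci use the reverse complement of
the downstream-coordinate window), truncated at contig edges. Motifs are
IUPAC consensus strings; overlapping occurrences are counted, by default
on both strands, and a palindromic consensus counts once per strand (a
documented convention, not deduplicated). The shipped default motif table
carries the standard stress/phytohormone element names with configurable
consensus stand-ins; the tests rely only on planted synthetic motifs.

## The synthetic benchmark

The generator builds a full study design with recorded truth:

* **References/genome.** Stem-loop precursors constructed as
  arm + loop + reverse-complement(arm) (arm 30 nt, loop 8 nt, mature 21 nt
  inside one arm, alternating 5p/3p), embedded in ~50 kb of random genome
  across 4 contigs on both strands. Selected-species precursors are
  locatable in the genome for a configurable subset only; contaminant sets
  are regenerated until disjoint from every planted mature. Note a planted
  stem-loop necessarily contains the mature on both strands.
* **Libraries.** Six libraries (3 control, 3 treated), default 10^5 reads
  each — a desk-scale stand-in for the ~10^7-read libraries of a real
  study, chosen so the whole suite runs in seconds while keeping counts in
  the thousands. Reads are mature ± end shifts on {−2…+2} (extensions copy
  precursor context; mean |shift| configurable, default 0.3), one internal
  substitution with probability 0.02, adapter appended, padded/truncated
  to 50 nt. Insert lengths concentrate at 21 nt within 15–32 nt. The
  contaminant compartment (default 20%) spans the six reference classes
  plus junk, adapter dimers, adapter-less reads and length outliers.
* **Condition model.** Per-miRNA base weights are log-normal; treated
  weights are multiplied by the planted fold changes while the contaminant
  mass stays fixed, so proportions follow
  p = w·fc / (Σ w·fc + contaminant). This is compositional, as sequencing
  is: a planted 4-fold change appears at slightly less than 4 after
  renormalization, and the truth table records the exact expected
  proportions as the sampling oracle. Replicate-level biological noise is
  log-normal with σ = 0.25 (~25% CV), chosen by a design-time power
  analysis as a realistic replicate variability under which a 4-fold
  change is recoverable by a 3 vs 3 t-test, consistent with the planted-DE
  recoverability the generator is specified to provide. The 50-seed power
  property runs on the generator's count-level model (identical sampling
  scheme, skipping read synthesis); the read-level path is exercised end to
  end on a fixed seed at depth 2×10^4.
* **Null calibration** uses a separate i.i.d. log-normal model
  (σ = 0.5) for 10,000 features; the pooled t-test's empirical size at
  n = 3 per group sits slightly below nominal (~0.044) because the data
  are skewed — within Monte-Carlo tolerance of 0.05.

What the benchmark does **not** emulate: sequencing quality errors beyond
the single-substitution channel, PCR duplicates, realistic quality
strings, miRNA family structure (paralogous matures differing by 1–2 nt),
true thermodynamic hairpin stability, or annotation incompleteness.
Passing the planted-truth suite therefore demonstrates the pipeline's
logic is correct under its stated tolerances, not that real-data recall
would match.

## Degenerate inputs and numerical notes

Empty FASTQ files yield empty iterators; zero-total libraries are
validation errors; promoters with zero upstream bases return an empty
sequence with a warning; hairpin windows below candidate +15 nt are "not
evaluable" (rejected); hypergeometric bounds are validated and the tail is
computed by scipy's log-space survival function; all randomness flows from
explicit integer seeds through `numpy.random.default_rng`, and identical
configurations produce byte-identical outputs.

## Known limitations

* Exact-substring contaminant screening misses divergent contaminant
  copies; real pipelines use alignment with mismatches.
* The zero-variance p = 0 rule plus no count floor lets one-condition
  singletons reach the significant list (visible in the worked example);
  a minimum-count filter is the obvious downstream guard.
* Maximum base pairing over-pairs relative to thermodynamics, so the
  hairpin criterion is permissive for structured random sequence; the
  stem and arm conditions compensate but were tuned for the constructed
  stem-loops, not for genome-wide novel discovery specificity.
* Gapped target duplexes and target-site conservation filtering are not
  implemented.
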