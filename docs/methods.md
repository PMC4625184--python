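# Methods

## Scope and model

piggytools reimplements, at desk scale and with simulated ground truth, a
complete integration-site analysis for piggyBac-like cut-and-paste
transposition. The chain is: simulate → trim/filter → split-read junction
calling against a hybrid reference → insertion-site aggregation,
classification and statistics; a parallel branch annotates ITRs in repeat
families. Every quantity reported by the test suite and
`scripts/acceptance.py` is computed by running this chain; nothing is
hard-coded.

### Integration and excision

An integration at a TTAA starting at 0-based position *p* transforms the
contig as `g[:p+4] + element + "TTAA" + g[p+4:]` — the target-site
duplication leaves one TTAA on each side of the element. The orientation
is `+` or `−` with equal probability; `−` inserts the reverse complement.
Off-target events (controlled by `ttaa_fidelity`) insert at a non-TTAA
position without duplication. Excision replaces the unique
`TTAA+element+TTAA` cassette by `TTAA`; by construction,
excision ∘ integration is the identity on the genome, which the tests
verify byte-exactly over many seeds.

### The reporter

The transposon reporter is `itr5 + cargo + itr3` with the 13-bp ITRs
`CCCTAGAAAGATA` / `TATCTTTCTAGGG` (top strand). The `mutant` variant
substitutes both terminal trinucleotides (5′ `CCC→TAT`, 3′ `GGG→ATA`),
the symmetric reading of the terminal-motif mutation that disrupts the
hairpin intermediate; the `deleted` variant is bare cargo. Whether a
mutant reporter alters one or both termini was genuinely open; mutating
both is the symmetric choice and only affects negative-control
simulations.

### Read simulation

Junction amplicons emulate anchored (FLEA-style) PCR: each event receives
~Poisson(`depth`) amplicons split at random between its two junctions; an
amplicon starts `primer_offset` (default 100 bp) inside the element,
crosses the junction, and extends a geometric length (mean
`mean_amplicon` = 600 bp, clamped to [read_length, 2000]) into the
genome. Mate 1 is the first `read_length` bases, mate 2 the reverse
complement of the last. Defaults are the study conditions: 300/300 paired
reads; 60% PCR duplicate pairs (inside the observed 56–87% range),
appended as exact copies with `duplicate_of` provenance; 5% adapter-dimer
pairs built from standard Illumina adapter sequences; substitution errors
i.i.d. at 0.005/base; base quality ≈ Q35 with a linearly decaying 3′ tail
ending in [2, 20] so that Q20 trimming is actually exercised. The
generator does not model indel errors, quality-by-cycle empirical
profiles, chimeric PCR artifacts, or biased fragment-length
distributions — so passing tests demonstrate correctness of the analysis
arithmetic on realistic error/duplication levels, not robustness to every
failure mode of real libraries.

### Trimming, filtering, deduplication

3′ quality trimming uses the running-sum rule (trim the suffix maximising
Σ(cutoff − q) from the 3′ end, cutoff Q20; among ties the longer trim
wins). A pair is excluded as an adapter dimer when either mate matches
adapter+adapter with ≤10% mismatches over ≥20 compared bases.
Deduplication collapses byte-identical `(seq1, seq2)` pairs and is on by
default; site counting is read-count-independent anyway, so the flag only
matters for support statistics.

### Junction calling

The hybrid reference is the genome plus one plasmid contig (the reporter
element). Alignment is exact k-mer seeding (default k = 21, sorted-array
index over both strands of the read) plus ungapped evaluation: a mate
yields a call iff it partitions into a prefix and suffix, one on the
plasmid and one on a genomic contig, each ≥ `min_anchor` (20) bases at
mismatch rate ≤ 0.04; the partition maximising total matches wins, ties
broken by longer transposon anchor then leftmost genome position. k = 21
(not larger) so that anchors in the 20–30 bp range can still be seeded;
random 21-mer collisions are negligible on ≤10-Mb toy genomes
(4²¹ ≈ 4·10¹²). Gapped alignment, BWT indexing and discordant-pair
evidence are deliberately out of scope.

Breakpoint resolution is reference-driven: bases compatible with both
references define a microhomology window; the junction is placed to
minimise `transposon_offset` (maximal extent on the transposon side), so
a joint exactly at the ITR terminal GGG/CCC motif reports offset 0. The
4-bp target is read on the genome forward strand — the 4 bases ending at
a 5′-side junction, or starting at a 3′-side junction — which makes both
junctions of one TSD-flanked insertion report the same `tsd_start`, and a
recovered insertion aggregates to a single site.

### Sites, classes, statistics

Sites aggregate calls by exact `(contig, tsd_start)`; `min_support`
(pipeline default 2) drops single-read sites, the standard guard against
breakpoints shifted by an isolated sequencing error. The strict class
rule is `TTAA_ITR ⇔ target == TTAA AND every supporting junction at the
ITR terminus`; a lenient TTAA-only mode is exposed because the class
definition in the source material is ambiguous on that point — strict is
the default. Fisher's exact test uses integer binomial-coefficient
weights with the common denominator C(N, n): the two-sided inclusion rule
(point probability ≤ observed) is decided on exact integers with no
floating-point tolerance, and the single final division is correctly
rounded. This is algebraically equivalent to, and in tests cross-checked
against, scipy's implementation and a rational-arithmetic enumeration
oracle. Mid-P and doubled-one-sided conventions are not used.

Logo information content is `2 − H` bits per position over offsets
−flank … 4+flank−1 relative to `tsd_start` (the TTAA occupies offsets
0–3); the optional small-sample correction subtracts `3/(2·ln2·n)` and is
off by default. Genic annotation is half-open interval membership of
`tsd_start` in a BED gene set.

### Repeat-family annotation

Members are extracted with 50-bp flanks (truncated at contig edges,
minus-strand members reverse-complemented). The multiple alignment is
centre-star — pairwise global alignments (match +1, mismatch −1, gap −2)
to the centre sequence (maximal summed pairwise score, ties to input
order), merged under "once a gap, always a gap" — chosen over an external
MSA tool because it is deterministic, dependency-free, and adequate for
hundreds of short elements; no claim of equivalence to a specific MSA
program is made. Conservation is the modal-base fraction among non-gap
rows per column; columns carried by fewer than half the rows are treated
as private insertions, not consensus positions. ITRs are the maximal
terminal runs of element-region columns with conservation ≥ 0.70
(strictly terminal: the first sub-threshold column stops the run; the
70% statistic is applied per column). On families whose interior is as
conserved as their termini (e.g. freshly planted, uniformly mutated
copies) the detected "ITR" extends over the whole element — the
classification logic is unaffected because intactness is judged by
gap-free alignment to the consensus, not by ITR length.

Intact ⇔ both element terminal regions align to their consensus without
gaps AND the 4 bp immediately flanking the element on each side read
TTAA; elements with <4 bp of captured flank are non-classifiable, and
every call carries its failure reasons. The identity matrix uses
`100 · identical aligned residues / min(len(a), len(b))` over the same
global alignment scoring; `N` never counts as identical.

## Synthetic data: what it does and does not emulate

The genome is i.i.d. with configurable GC (default 0.41, human-like),
which reproduces the expected TTAA density but none of the repeat
structure, CpG depletion or isochore organisation of real genomes; the
planted repeat families have uniform per-base divergence rather than the
age-structured divergence of real MER75/MER85 copies, and corruption is a
single 1-bp ITR indel per corrupted copy. Consequently the planted-family
truth tables are exactly recoverable at zero mutation rate — which is the
point of the test — whereas genome-wide annotation of real,
hand-curated repeat libraries would additionally face fragmented copies,
nested insertions and annotation boundary noise that the deterministic
classifier does not attempt to adjudicate.

## Problem sizes and numerical choices

The recovery benchmark uses a 5-Mb, 5-contig genome with 200
integrations at depth 20, the family benchmarks 40 copies on a 120-kb
genome — sizes chosen so the whole pipeline, including the exhaustive
Fisher-oracle comparison over all 2×2 tables with N ≤ 30, completes in
well under a minute each while keeping every per-event statistic
well-powered. Event spacing defaults to 1 kb so amplicons from adjacent
insertions do not interleave. All randomness flows from
`numpy.random.default_rng` seeded from a single global seed with fixed
per-stage offsets, making every stage independently reproducible;
identical config+seed gives byte-identical FASTA/FASTQ and identical
manifest checksums (run timestamps are excluded from checksummed files).
Alignment tie-breaks (traceback prefers diagonal, then gap-in-second),
modal-base ties (alphabetical) and site ordering (coordinate sort) are
all fixed, so outputs are stable across platforms.

## Known limitations

- Error-shifted breakpoints: a read with a substitution at the junction
  can resolve one base off, occasionally producing a low-support
  satellite site adjacent to a true site; `min_support` suppresses most
  but not all of these (they remain counted as false-positive sites in
  run summaries).
- The published p-value for the intact-reporter 2×2 comparison is not
  reproduced by the standard two-tailed Fisher computation (see the test
  suite's documented check); the implementation reports the exact value.
- The junction caller is ungapped; reads with indel sequencing errors
  (not simulated) or genuine indels at the junction would be dropped, not
  mis-called.
- Genome-scale repeat annotation against real RepeatMasker libraries and
  reproduction of published genome-wide element counts are out of scope.
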