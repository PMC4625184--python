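# piggytools

Desk-scale toolkit for analysing **piggyBac-like cut-and-paste DNA
transposition**: it simulates TTAA-targeted transposon integration and
precise excision with full ground truth, maps transposon–genome junctions
from paired amplicon reads at base-pair resolution by split-read analysis
against a hybrid genome+plasmid reference, classifies insertion sites and
tests them with the exact Fisher test, quantifies TTAA target-site
preference as sequence-logo information content, and annotates
piggyBac-like repeat families (ITR discovery, intact-element curation,
identity matrices).

## The biology and the statistics

piggyBac-superfamily transposases mobilise elements flanked by 13-bp
inverted terminal repeats (ITRs, beginning `CCC` / ending `GGG` on the top
strand). Integration targets the tetranucleotide **TTAA** and duplicates
it, so an integrated locus reads `...TTAA[element]TTAA...`; excision is
precise, restoring a single `TTAA`. The toolkit models exactly this
arithmetic:

- **Integration** at position *p* of a TTAA: `g[:p+4] + element + TTAA + g[p+4:]`.
- **Excision**: the unique `TTAA+element+TTAA` cassette collapses back to
  `TTAA`; `excise ∘ integrate` is the identity on the genome.
- **Junction evidence**: a split read whose prefix aligns to the reporter
  plasmid and suffix to the genome (or vice versa, either strand) locates
  the breakpoint; junction microhomology is assigned to the transposon
  side, so a joint exactly at the ITR terminal `GGG`/`CCC` motif has
  `transposon_offset == 0`.
- **Site classes**: `TTAA_ITR` (target tetramer TTAA *and* every
  supporting junction at the ITR terminus) versus `non_ITR`; two
  conditions form a 2×2 table tested with a two-tailed Fisher exact test
  (sum of hypergeometric point probabilities ≤ that of the observed
  table, computed in exact integer arithmetic).
- **Logo**: per-position information content `2 − H` bits, with
  `H = −Σ f_b log₂ f_b` over the base frequencies in a ±10 bp window
  around the insertion site.
- **Repeat annotation**: family members extracted with 50-bp flanks,
  centre-star multiple alignment (match +1, mismatch −1, gap −2), ITRs
  called as maximal terminal runs of columns conserved at ≥ 70%, and an
  element is *intact* iff both ITRs align gap-free to the family
  consensus and the TTAA duplication is present on both flanks. ITR
  identity = `100 · identical aligned residues / length of the shortest
  sequence`.

## Worked example

```bash
piggytools stats --table 65,14,2,10
# {"table": [[65, 14], [2, 10]], "p_value": 1.4282885753997558e-05, "odds_ratio": 23.214285714285715}
```

That is the exact two-tailed Fisher p-value for 65/79 vs 2/12 TTAA-ITR
insertion sites: transposase-expressing cells are overwhelmingly enriched
for TTAA-targeted, ITR-terminal integrations relative to control.

A full simulated run (1-Mb genome, 50 integrations, depth 20, 60% PCR
duplicates, 0.5% substitution errors):

```python
from piggytools import PipelineConfig, run_all

cfg = PipelineConfig.from_dict({
    "simulation": {"genome_length": 1_000_000, "contig_count": 2, "n_events": 50},
    "seed": 1, "outdir": "demo_run",
})
manifest = run_all(cfg)
print(manifest.counts)
# {'events': 50, 'read_pairs': 2734, 'pairs_after_trim': 2597,
#  'pairs_after_dedup': 1039, 'junction_calls': 1443, 'insertion_sites': 52}
```

`demo_run/summary.json` then reports the comparison against the simulator
ground truth:

```json
{"n_events": 50, "n_sites": 52, "n_recovered": 50, "site_recovery": 1.0,
 "false_positive_sites": 2, "ttaa_itr_fraction": 0.96}
```

All 50 planted integrations are recovered at their exact TTAA position
and classified `TTAA_ITR`; the two extra sites are one-base satellites
produced by reads carrying a sequencing error at the junction.

The CLI exposes each stage separately: `piggytools simulate
{genome,integrations,reads,family}`, `call-junctions`, `analyze-sites`,
`annotate-elements`, `stats`, and `run-all`.

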