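# introview

Build, query and visualize **introgression libraries** of near-isogenic
lines (NILs) from SNP genotype matrices.

An introgression library is a family of NILs sharing a recurrent parent and
a donor parent: each line's genome is essentially the recurrent parent's,
interrupted by one or more donor-derived segments (introgressions).  Such
libraries are the workhorse of fine mapping and of testing phenotypic
effects of specific donor regions — provided you can find the line that
carries (or lacks) an introgression at a locus of interest.  `introview`
does exactly that for people who maintain such germplasm: it determines
where each line's introgressions lie, makes them searchable, and draws
per-line graphical genotypes.

## What it computes

Inputs are four tab-delimited files: a reference genetic map (marker,
chromosome, position in cM), a relationships file (sample pedigree:
recurrent/donor parents, replicates, F1 ancestors), a raw genotype matrix
(markers × samples), and a small configuration file naming the other three.

For each NIL the engine:

1. collapses replicate genotypings of each parent (and of the line itself)
   into a consensus by strict majority vote — ties are conflicts, not
   guesses — and, when the donor was never genotyped, infers its genotype
   from an F1 by allele subtraction (recurrent *x/x* + F1 *x/y* ⇒ donor
   *y/y*);
2. classifies every mapped marker as RECURRENT, DONOR, HET, NON_PARENTAL,
   MISSING or UNINFORMATIVE;
3. segments runs of donor (or heterozygous) markers into introgression
   blocks with a marker-supported **inner span** [first, last supporting
   marker] and an estimated **outer span** extending to the midpoints
   toward the flanking recurrent markers;
4. stores everything in a single-file database that answers conjunctive
   include/exclude queries by marker name or by chromosome interval, and
   renders SVG ideograms, TSV block tables and a static HTML report.

A seeded simulator generates complete synthetic libraries (the four input
files plus ground truth) for testing and benchmarking.

## Worked example

Simulate a small library (6 NILs, 5 chromosomes × 100 markers), call its
blocks, and query it:

```sh
$ introview simulate --out demo --seed 7 --lines 6
demo/sim.cfg

$ introview build demo/sim.cfg --min-markers 2
markers: 500
samples: 12
unmapped_markers: 0
consensus_conflicts: 26
lines_called: 6
blocks_found: 11
[calling] sample 1 skipped: parent/F1 sample
[calling] sample 4 skipped: parent/F1 sample
demo/sim.iview
```

The build log says all 500 markers were on the map, 26 markers had
conflicting parental replicate calls (simulated genotyping noise), and 11
blocks of at least 2 supporting markers were found across the 6 lines.
The two parents are skipped — they are reference material, not callable
lines.  Now ask which lines carry a donor introgression between 60 and
100 cM on chromosome 5, or at one specific marker:

```sh
$ introview query demo/sim.iview --include 5:60-100
NIL003
NIL006

$ introview query demo/sim.iview --include M5_0050
NIL006
```

Two lines overlap the interval; only NIL006's block actually covers marker
M5_0050 (at 74.2 cM).  Inspect one line, or render the whole library as a
browsable report:

```sh
$ introview show demo/sim.iview NIL006 --out demo/out
$ introview report demo/sim.iview --out demo/report
demo/report/index.html
```

`NIL006.tsv` then lists rows like

```text
chromosome  state  inner_start  inner_end  outer_start  outer_end  n_support ...
5           DONOR  62.121       92.424     61.3635      100.7575   17        ...
```

meaning: a homozygous donor block supported by 17 markers from 62.1 to
92.4 cM, with an estimated extent (midpoints toward the flanking recurrent
markers) of 61.4–100.8 cM.  The SVG next to it draws each chromosome as a
gray bar with the block in red (outer span semi-transparent, inner span
solid).

The same machinery is available as a library:

```python
from introview import parse_reference_map, parse_relationships, \
    parse_raw_data, call_library

records = parse_relationships("demo/relationships.tab")
refmap = parse_reference_map("demo/ref_map.tab")
matrix = parse_raw_data("demo/raw_data.tab", {r.sample_id for r in records})
result = call_library(refmap, records, matrix, min_markers=2)
```

## Documentation

The model, its assumptions, parameter defaults and known limitations are
described in [docs/methods.md](docs/methods.md).
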