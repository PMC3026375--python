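# Methods

## Problem setting

An introgression library is a family of near-isogenic lines (NILs) sharing a
common recurrent parent and a common donor parent.  Each NIL's genome is
essentially that of the recurrent parent, interrupted by one or more donor
segments (introgressions).  Given SNP genotype calls for the parents and the
NILs, plus a reference genetic map assigning each marker a chromosome and a
centimorgan (cM) position, the engine determines where each line's
introgressions lie, stores them in a queryable single-file database, and
renders graphical genotypes.

## Parental consensus

Parents are commonly genotyped several times; replicate columns are linked
to a root sample in the relationships file.  The consensus at each marker is
the **strict majority** of the non-missing replicate calls: the winner must
exceed half of the votes, missing calls abstain, and any tie (including
one-vs-one) yields a missing consensus flagged as a conflict.  This is
deliberately conservative — discordant replicates never invent a parental
allele, they only remove a marker from consideration.  A heterozygous
consensus for an inbred parent is permitted but marked low-confidence and
renders the marker uninformative downstream, since residual heterozygosity
or a genotyping error are the plausible explanations.

When a donor parent was never genotyped but an F1 of the cross was, the
donor genotype is recovered by allele subtraction: recurrent x/x with F1 x/y
implies donor y/y; F1 equal to a homozygous recurrent parent is an
uninformative marker (donor indistinguishable); an F1 lacking the recurrent
allele, a heterozygous recurrent consensus, or missing inputs degrade to a
missing donor call with a reason flag.  A directly genotyped donor always
takes precedence over F1 inference.

## Marker classification

For each NIL and each mapped marker the call is classified by a fixed
cascade, first match wins:

1. **UNINFORMATIVE** — either parental consensus missing or heterozygous,
   or the parents identical at this marker;
2. **MISSING** — the NIL call is missing;
3. **RECURRENT** — NIL equals the recurrent consensus;
4. **DONOR** — NIL equals the donor consensus;
5. **HET** — NIL carries exactly one allele from each parent;
6. **NON_PARENTAL** — anything else (e.g. an allele absent from both
   parents).  Reported as its own state, never silently merged.

Parent informativeness is tested before the NIL's own call, so a marker at
which the parents cannot be distinguished is UNINFORMATIVE even when the
NIL call is missing.  The rule is purely deterministic; there is no error
model, imputation or probabilistic (HMM) smoothing.  Replicated NILs are
collapsed by the same strict-majority consensus before classification.

## Block segmentation

Each chromosome is scanned in map order.  Maximal runs of DONOR markers
(and, separately, of HET markers) form blocks.  Interior MISSING,
UNINFORMATIVE and NON_PARENTAL markers neither support nor break a run —
they carry no evidence for either side, and treating NON_PARENTAL as a
breaker would let isolated genotyping artifacts split real introgressions.
A RECURRENT marker, a marker of the other introgressed state, or the
chromosome end closes a run.  HET runs form their own blocks by default so
residual heterozygosity stays visible to fine-mapping users; the
`het_as_donor` switch (CLI `--het-as-introgression`) absorbs HET markers
into DONOR runs instead.

Each block carries two spans, both closed intervals in cM:

* **inner** — first to last supporting marker: the marker-backed extent;
* **outer** — extended to the midpoint toward the nearest flanking
  RECURRENT marker on each side, or to the chromosome's terminal mapped
  position when no recurrent evidence exists on that side.  The midpoint is
  the conventional point estimate for a breakpoint lying uniformly between
  the last donor and first recurrent marker.

Runs with fewer than `min_markers` supporters (default 1) are dropped and
logged; raising the threshold can only remove blocks.

## Queries

A query term is a marker name (resolved to a point on the map) or a
chromosome interval; terms are include or exclude and combine by
conjunction.  A line satisfies an include term when one of its DONOR blocks
(HET blocks too, under an option) on that chromosome has an inner span
overlapping the closed query interval; exclude is the exact negation, so
for any term the include and exclude sets partition the library.  Matching
uses the inner span by default because the outer span is an estimate —
claiming a hit with no marker evidence inside the query region would
mislead; an `outer=True` switch is available and documented.

Results persist in a single SQLite file named after the configuration's
`DB_NAME` (suffix `.iview`), an embedded replacement for a client-server
database: no credentials, trivially copyable, byte-stable for identical
inputs.

## Synthetic libraries

The simulator emulates the genetic structure the caller must recover, not
the full backcross pedigree.  Per line, the number of donor segments is
Poisson (mean 2), segment starts are uniform on the chromosome, lengths are
exponential (mean 20 cM, truncated at the chromosome end), overlapping
draws are merged, and each merged segment is heterozygous with probability
0.1 (residual heterozygosity of an unfixed region).  Defaults: 5
chromosomes of 150 cM with 100 equally spaced markers, 20 lines, parents in
triplicate, 1% genotyping error, 5% missing calls, 1% marker-wise residual
heterozygosity on truly recurrent NIL markers.  These sizes are chosen as a
small but realistic maize-like library that keeps the full pipeline fast.
Parents are simulated fully homozygous for alternate alleles at every
marker, with noise applied afterward, so the consensus/conflict code paths
are exercised by the noise channel rather than by construction.

A single seed drives one generator through a fixed draw order (marker
alleles, then per-line segments, then per-sample noise cell by cell), so
identical seeds reproduce identical files byte for byte.  Map positions are
rounded to 0.001 cM before writing so that printed and re-parsed
coordinates are bit-identical to the in-memory truth.

What the simulator does **not** model: recombination interference,
multi-generation pedigree structure, selection, segregation distortion,
marker ascertainment bias, and locus-specific error rates.  Passing the
recovery tests therefore shows the engine is exact at marker resolution
under the stated noise model, not that it is robust to every artifact of
real genotyping platforms.

`truth_blocks` converts true segments into the blocks a perfect caller must
report: the expected inner span runs from the first to the last marker
inside the segment, segments containing fewer than `min_markers` markers
are undetectable, and consecutive same-state segments with no marker in the
gap between them are merged — at marker resolution they are one block, and
an exact caller necessarily reports them as one.

Accuracy on noisy data is measured over informative markers whose observed
call is non-missing: a missing call is absence of data, not a
misclassification, so the missing rate does not mechanically cap the
accuracy statistic.

The generator's donor-genome dosage has a closed form used as a
convergence check: a segment starting uniformly on a chromosome of length
L with exponential length (mean mu) covers position x with probability
q(x) = (mu/L)(1 − e^(−x/mu)); with Poisson segment counts (mean λ/c per
chromosome over c chromosomes), P(marker at x is donor-origin) =
1 − e^(−(λ/c) q(x)).  The naive λ·mu/(c·L) overstates this by ignoring
overlap merging and edge truncation.

## Numerical and formatting choices

* Coordinates are cM throughout; physical (bp) coordinates are out of scope.
* Ties in map position keep file order (stable sort); chromosome display
  order is natural sort, so labels like "2" precede "10".
* Genotypes are canonically sorted allele pairs over A/C/G/T; "GA" and
  "AG" are the same genotype; "--" is missing; partial tokens are rejected.
* The `[Data]` sentinel of the raw-data format is matched
  case-insensitively and tolerates extra text on the line, since published
  examples of the format disagree on capitalization.
* Writers emit Unix line endings and trim trailing zeros from positions, so
  a file of integer positions round-trips byte-identically.
* SVG/HTML/PNG outputs embed no timestamps and use fixed two-decimal pixel
  formatting, making every artifact reproducible bit for bit.

## Known limitations

* Single recurrent/donor pair per line; multi-donor pedigrees are rejected
  by omission (no fields for them).
* No probabilistic ancestry inference: an isolated miscalled marker inside
  a long recurrent stretch becomes a one-marker block unless filtered by
  `min_markers`.
* Unmapped raw-data markers are excluded from calling (blocks are defined
  in map coordinates) and only surfaced through the run log.
* Query semantics are pure conjunctions; there is no OR/NOT expression
  language.
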