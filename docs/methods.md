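# Methods

## The screening model

`mitescreen` treats contamination detection as a best-hit classification
problem. A contig is called mite-derived when, and only when, it clears a
fixed sequence of eliminations:

1. **Length** — contigs longer than `max_contig_len` (default 100,000 bp)
   are discarded. The rationale is biological: mite mitochondrial genomes
   are under 25 kb and the barcode library is overwhelmingly COI, so true
   barcode-detectable contaminants are mitochondrial-scale. The boundary
   is strict-greater: a contig of exactly 100,000 bp is retained.
2. **Inclusion similarity** — the contig must hit at least one mite
   barcode. "Similarity" is operationalised as a local-alignment hit with
   E ≤ `step2_evalue_cutoff` (default 10⁻⁵). The cutoff is a package
   decision, not an external constant; it sits far above the scores
   reachable by chance between unrelated desk-scale sequences (a raw
   score ≈ 46, i.e. 23 consecutive matches, would be needed) while any
   real barcode copy at ≤ 15 % divergence exceeds it by an order of
   magnitude.
3. **Comparative screen** — the best non-mite-barcode bitscore must not
   strictly exceed the best mite-barcode bitscore. Elimination requires
   being *more* similar to the exclusion set, so ties keep the contig.
   Bitscore (not identity or E-value) is the comparison currency because
   it is length-normalised and monotone in the raw score.
4. **Reference verification** — the best-bitscore hit in the nt-like
   database must lie inside Acari-minus-Ixodida and align at
   ≥ `min_nt_identity` (default 80 %). Identity of exactly 80.0 % is
   retained (the elimination clause is "less than 80 %"). A best hit
   without a lineage entry eliminates the contig (conservative default
   for incompletely annotated databases).

Mite membership is decided purely by the presence of one of the four
order names {Trombidiformes, Sarcoptiformes, Mesostigmata, Holothyrida}
in a lineage. This name-based rule is exactly the operational definition
used to partition barcode libraries; it requires no taxonomy graph, so
synthetic lineages work identically to NCBI-derived ones. Ticks
(Ixodida) carry none of the four names and are therefore excluded by
construction.

### Misidentified reference records

Step 4 inherits the reference database's errors: a record that is itself
mite contamination, deposited under the host species' name, attracts the
contig's best hit and defeats the lineage test. Such records are
detected by searching the record against its own database: the pattern
is a top hit of exactly 100 % identity to a non-mite record carrying the
query's own source lineage (normally itself) with the second-best hit to
a mite sequence. During step 4 the detector runs automatically whenever
the best hit is non-mite at qualifying identity (results are cached per
record); a positive detection *rescues* the contig, which is kept with
`rescued_by_misid_rule=True` and reported separately rather than
silently merged.

## Alignment engine

Scoring is BLAST-like nucleotide scoring: match +2, mismatch −3, gap
open −5 (existence), gap extend −2 per residue, so a gap of length L
costs 5 + 2L. Identity is matched columns over all alignment columns
including gaps, reported to three decimals. Ambiguity codes are kept in
sequences and score as mismatches. E-values use the Karlin–Altschul form
E = K·m·n·exp(−λS) with K = 0.41, λ = 0.625 (values appropriate for this
reward/penalty ratio); bitscore = (λS − ln K)/ln 2.

Two independent routes compute the optimum:

* `smith_waterman` — a self-contained affine-gap dynamic program with
  traceback, used as the reference oracle in tests. Co-optimal end cells
  are resolved to the first optimum in row-major order (smallest query
  end, then subject end); within the traceback, diagonal moves are
  preferred, which maximises matched columns.
* `search` — the production engine: an exact k-mer seed prefilter
  followed by optimal local alignment of surviving (query, subject,
  strand) pairs via Biopython's `PairwiseAligner` (C implementation,
  identical scoring model). Both strands are searched; minus-strand hits
  are reported BLAST-style (ascending query, descending subject
  coordinates). Hits are ranked by bitscore, ties by E-value then
  subject id.

The seed length default is **k = 13**. At this package's working scale
(contigs of 0.5–3 kb against a ~33 kb barcode set) the expected number of
chance 11-mer seed matches per contig is ≈ 12, which would defeat the
prefilter; k = 13 brings it below one while a true homolog at ≤ 15 %
divergence still shares hundreds of exact 13-mers. `method="auto"`
disables seeding on small databases (≤ 100 subjects, all ≤ 2 kb), where
exhaustive alignment is cheap and guarantees score-optimality against
the oracle; the screen passes `method="seeded"` explicitly.

## Family assignment and reporting

A call is assigned the family rank of its top best-score reference hit
when the hit identity is ≥ `family_threshold`, default **91.4 %**
(inclusive), the stricter of the two published family-level thresholds
for mite barcodes; a uniform threshold is the default because that is
how the assignment is applied in practice, with a per-order option
(Sarcoptiformes 89.9 %) available via `per_order_thresholds`. Hits below
threshold, or lineages lacking a family rank, stay `unassigned`.

Contamination rates are 100 × contaminated/total over assemblies,
half-up rounded to one decimal — the printed precision of such surveys
(e.g. 461/7591 → 6.1). Family × host-class tables carry per-family row
percentages (half-up, one decimal). Krona output is the tab-delimited
text dialect, one line per family leaf with its order as the parent
rank; the count column sums to the number of assigned contigs.

**Suspect flagging.** Some mite families are obligate associates of one
host group; an assignment from a different host with near-perfect
identity to a known reference is more plausibly fortuitous contamination
of the sample (classically: human follicle mites, Demodicidae, in
non-mammal projects). A configurable watch-list maps families to
expected host classes and reference sequences; an assignment is flagged
when its family is watched, its host class falls outside the expected
group, and its identity to a watch-list reference is
≥ `suspect_identity_min` (default 96 %). Flagged contigs leave the
host-association tables but remain in raw output and still count toward
assembly contamination rates. This automates what is otherwise a manual
curation step; the default watch-list contains only
Demodicidae → Mammalia and ships without reference sequences (they are
data, not code).

## COI extraction

For phylogenetics, the region of each called contig spanned by its best
mite-barcode hit is translated with the invertebrate mitochondrial code
(NCBI table 5) on the hit strand; all three frames are tried, the
longest stop-free stretch wins (ties to the lower frame), and only
peptides strictly longer than 80 aa are exported ("more than 80 amino
acids" read as strict). This hit-guided translation deliberately
replaces full mitogenome annotation: it recovers the barcode-spanning
COI fragment that downstream alignment/tree tools consume, and nothing
else.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *decision structure* of the real inputs,
not their sequence biology:

* **Barcode families** are star phylogenies: an i.i.d. uniform founder
  per family, members mutated at `intra_family_div` (default 0.03) per
  site. Different families are unrelated (~25 % background identity),
  which makes family assignment unambiguous by construction.
* **Substitutions** are i.i.d. per site with a uniform choice among the
  three alternative bases and no indels by default, keeping
  identity ≈ 1 − divergence exact for threshold arithmetic (an indel
  option exists for robustness checks). A contaminant at divergence d
  from a barcode with an exact-copy reference record therefore lands at
  ~100(1 − d) % identity: d = 0.05 → ~95 % (assigned), and the 91.4 %
  threshold corresponds to an ~8.6 % divergence boundary.
* **The nt-like database** carries one exact-copy record per inclusion
  barcode (barcode embedded in random flanks) — mirroring the fact that
  barcoded specimens are routinely also deposited in sequence archives —
  plus unrelated non-mite records, plus (optionally) planted
  misidentified records: a mite barcode mutated at `misid_div` under an
  insect lineage.
* **Host contigs are i.i.d. random sequence.** The screen only requires
  them to be alignment-negative against the barcode library; real host
  genomes additionally contain their *own* COI, low-complexity regions
  and repeats, none of which is emulated. Passing the synthetic
  acceptance checks therefore demonstrates the pipeline's logic,
  determinism and threshold behaviour — not its false-positive rate on
  real nuclear genomes, where the exclusion set (step 3) and the
  reference lineage test (step 4) carry the discrimination burden.

Default study size: 200 assemblies × 10 contigs of 0.5–3 kb, 5 mite
families × 10 barcodes of 658 bp (the COI-5P length), contamination
probability 0.2, contaminant divergence 0.05, TSA fraction 0.34. These
sizes keep a full simulate–screen–assign–evaluate cycle to about a
minute on one CPU while leaving every decision point of the method
exercised; the host-class weights (Insecta 0.35, Magnoliopsida 0.30,
Actinopteri 0.15, Pinopsida 0.10, Anthozoa 0.10) echo the taxonomic
spread of public assembly projects.

All generators draw from `numpy` generators keyed on (stage, seed), so
every artefact is bit-reproducible from the design seed and stages are
independent of one another.

## Numerical and interface conventions

* Rounding of printed percentages is half-up (`decimal`-based), one
  decimal for rates/markers, integer for order shares.
* Hit tables are 12-column BLAST `outfmt 6`; floats are written at full
  `repr` precision so write-then-read round-trips are lossless. The raw
  score (not an outfmt-6 column) is recovered by inverting the bitscore.
* Minus-strand hits carry descending subject coordinates; readers
  recover the strand from coordinate order.
* Degenerate inputs: empty assemblies are processed with a warning and
  zero calls; an empty exclusion set disables step 3 (nothing to be more
  similar to); `percent_identity` and `contamination_rate` reject zero
  denominators; sequences must be non-empty and ids whitespace-free.
* `search` with `evalue_max=None` disables the E-value cutoff — used by
  the oracle-equivalence tests, where weak random alignments must be
  comparable.

## Known limitations

* The engine is nucleotide-only: no protein search, no composition-based
  statistics, no gapped E-value edge corrections. E-value constants are
  fixed per scheme rather than estimated.
* Misidentification rescue requires the tell-tale second-best mite hit
  to exist in the same database; a misidentified record whose mite
  relatives are entirely absent is undetectable by this rule.
* Lineages are name-based; there is no synonym resolution or taxid
  merging. Rank lookups rely on rank annotations (`family:…`,
  `class:…`), with a `-idae` suffix heuristic as fallback for family.
* The COI extractor assumes the barcode hit delimits a translatable
  region; chimeric contigs or hits spanning gene boundaries can yield
  truncated peptides.
* Desk-scale throughput (~30 ms per contig against a 50-barcode library)
  is adequate for simulation studies and modest real screens; scanning
  millions of contigs would want an external BLAST-style engine behind
  the same module surface.
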