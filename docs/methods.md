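# Methods

## The cut model

MspJI binds a methylated cytosine in a `CNNR` context and cleaves both
strands downstream of the motif: 9 nt past the motif end on the
recognized strand and 13 nt on the opposite strand, leaving a 4 nt 5′
overhang. After end repair during library construction, both strands of
a fragment extend to the far (13 nt) cut, so the model collapses each
successful recognition event to a single breakpoint in half-open genome
coordinates:

* Watson-strand mC at `p` (motif `p..p+3`): breakpoint at `p + 17`;
* Crick-strand mC indexed by the Watson coordinate `q` of its paired
  base (motif spanning `q−3..q` on Watson coordinates): breakpoint at
  `q − 16`.

For a CpG dyad (`crick_c = watson_c + 1`) in the palindromic `YNCGNR`
context, both cuts firing produces the interval
`[watson_c − 15, watson_c + 17)` — 32 bp with the 6-mer context at
offsets 13–18. For a CWG dyad (`crick_c = watson_c + 2`) the analogous
doubly-cut fragment is 31 bp, `[watson_c − 14, watson_c + 17)`; this
length is a derived consequence of the cut arithmetic rather than an
independently reported value. The 9 nt near cut and the overhang are
retained in the model as bookkeeping (the overhang length is exposed for
geometry checks) but overhang fill-in chemistry is not simulated, since
every observable — fragment intervals, the 57/32/57 and 89/57 worked
digests, the motif-13-bp-from-edge property — depends only on the far
cut.

Assumptions: every methylated site cuts independently (complete digest
with per-site efficiency; no processivity or steric interference beyond
collapsing duplicate breakpoints); 5hmC is treated as 5mC; off-target
cutting of unmethylated sites ("star activity") is a configurable
probability that defaults to 0, matching the observation that
unmethylated template is barely digested.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `efficiency_by_r` | `{G: 0.97, A: 0.80}` | per-site cut probability by the motif's downstream R base; the measured near-complete digestion of `mCGNG` sites vs insufficient digestion of `mCGNA` sites |
| `star_activity` | 0 | cut probability at unmethylated `CNNR` sites |
| `size_min..size_max` | 32..1000 | retained fragment lengths after purification (the 32-mer class plus the few-hundred-bp library smear) |
| `e_pu` | 1.0 | capture probability of exactly-32 bp fragments relative to longer ones |
| `min_dyad_coverage` | 5 | dyads covered by fewer than five classified fragments are excluded ("more than four reads") |
| hairpin `min_count` | 3 | predominant-status floor for the bisulfite oracle; ties are excluded, never guessed |
| ASM `min_coverage` | 11 | SNPs are tested only at coverage strictly larger than 10 |
| ASM `alpha` | 0.05 | a SNP is a bias-SNP iff its BH-adjusted q-value is strictly below alpha |
| conversion rate | 0.99 | probability an unmethylated C reads as T in the hairpin oracle; estimated per library from linker cytosines |

## Dyad classification

A fragment witnesses a resolvable dyad through exact integer edge
matching against the dyad's two cut offsets `L = crick_c − 16` and
`R = watson_c + 17`: `me` iff the fragment equals `[L, R)`; `hemiW`
iff it ends at `R` and starts before `L`; `hemiC` mirrored; `unme` iff it
strictly spans both offsets with neither edge matching. A fragment with
one matching edge that does not reach the partner offset proves only one
strand's methylation (`strand_only` evidence): it feeds strand-level
cytosine calls but never the four-status counts, because the partner
strand is unobservable on that molecule. Fragments shorter than the dyad
interval with no matching edge yield no call. Exact matching (no slop
window) is intentional: the simulator is exact, and handling real-data
edge wobble is out of scope.

## Normalization

The four expected-count equations (see README) are implemented exactly
as printed; note the printed form carries no single-cut efficiency on
the true hemi counts. Whether that omission is intentional is not
stated, so the package does not guess: the printed form is the default
and an `extended` mode that also scales hemi counts by their single-cut
efficiency ships clearly off by default. Inversion is per dyad, using
that dyad's own R-base classes. Negative inverted estimates (small-count
noise) clamp to zero with a per-dyad flag. Round-trip identity holds to
float tolerance; with `E_pu = 1` the forward map conserves the total
count.

## The synthetic-data generators

`make_genome` draws i.i.d. bases at a stated GC content — adequate for
geometry and statistics, but real genomes are not i.i.d. (CpG islands,
repeats, composition bias), so passing tests say nothing about mapping
artifacts, repeat collapse, or coverage non-uniformity in real data.

`plant_construct` rebuilds the 146 bp validation duplex
programmatically: an A/T-only background (no stray C/G means no stray
`CNNR` context) around the six-base context `TACGAA` at positions
70–75, placing the single resolvable dyad at Watson position 72. The
downstream R of the Watson motif is necessarily A: a G three bases after
the dyad C would itself complete a second Crick-strand `CNNR` motif,
violating the single-dyad constraint. The acceptance surface depends
only on this geometry, not on the exact oligo sequence.

`make_methylome` assigns designed statuses (deterministic 0/1 per-strand
probabilities) only to resolvable dyads whose cut offsets lie inside the
contig and that are at least 34 bp apart (greedy left-to-right
selection); closer dyads stay unmethylated and outside the truth table,
and optional CpH methylation is kept equally clear of designed dyads. A
dyad's cut offsets span `watson_c − 15 .. watson_c + 17`, so 34 bp is
the smallest spacing at which no foreign cut can coincide with a dyad's
own offsets — the condition that makes exact round-trip calling
achievable and makes the truth table a fair scoring reference.
Consequence worth knowing: long unmethylated stretches produce fragments
beyond the size-selection window, so dyads inside them lose coverage —
the same under-representation of extreme methylation deserts the real
protocol exhibits.

The hairpin oracle emits per-strand post-bisulfite base strings indexed
by Watson coordinates over windows — no FASTQ, no aligner — because its
job is cross-validating the geometry caller on molecules whose truth is
known, not read mapping. Its linker is a fixed reference sequence whose
cytosines are unmethylated by construction.

The allele model emits per-SNP count tables (maternal counts drawn
binomially at 0.95 for imprinted SNPs, 0.5 for balanced ones) plus truth
flags; `count_alleles` bridges allele-tagged fragments to the same table.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; Crick sites are indexed
  by the Watson coordinate of the paired base. BED I/O is native.
* `N` never matches any motif class; motifs truncated by a contig end
  are dropped, including strand-level `CNNR` calls near contig ends.
* Deduplication keys on (chrom, start, end, UMI) after a stable sort, so
  retention is input-order independent. An 8 nt UMI has a 65 536-key
  space: at ~10^4 identical 32-mer coordinates, birthday collisions
  would remove ~7% of genuine fragments, so simulation-scale consistency
  checks that emit no PCR duplicates run with deduplication off.
* The predominant-status rule returns the unique maximum of the four
  statuses; any tie — two-way or wider — is excluded and flagged.
* FDR control is Benjamini–Hochberg (the conventional default where only
  "FDR" is specified); the procedure is a config option. The bias rule
  is strictly `q < alpha`.
* Cluster assignment and profiles flip hemi-strand roles for `−`-oriented
  motifs, so hemi levels are always motif-strand-relative; profile
  offsets are measured along the motif strand, giving exact mirror
  symmetry under orientation flips.
* Tests and the acceptance script use deliberately modest problem sizes
  (100 kb round-trip genome with 50 molecules; 2 kb all-methylated
  genome with 10^4 molecules; 1 Mb genome for the resolvable-fraction
  scan; 1000-SNP allele models) — large enough for the stated
  statistical tolerances at 3·SE, pooled per efficiency class where many
  comparisons run at once.

## Known limitations

* Only `YNCGNR` CpG dyads (a quarter of CpGs on a uniform genome) and
  `YCWGR` CHG dyads are dyad-resolvable; everything else is strand-level.
* Alignment, trimming, BAM handling and mapping-quality logic are out of
  scope: fragment intervals are the caller's input.
* `E_pu` is modelled as a sharp exactly-32-bp effect, as the
  normalization equations imply; a smooth size-bias curve is not
  attempted.
* No sequencing-error or quality model; UMI errors are not corrected.
* 5hmC is not distinguished from 5mC.
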