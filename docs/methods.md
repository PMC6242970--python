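# Methods

## Site model

Each Cas9 species is described by its protospacer length, PAM geometry and
blunt-cut offset: SpCas9 (20 nt, `NGG`, 3 bp), SaCas9 (21 nt, `NNGRRT`,
3 bp), NmCas9 (24 nt, `NNNNGATT`, 3 bp). Genome scans enforce only the
informative, suffix-aligned core of each PAM (`NGG`, `GRRT`, `GATT`; the
expanded SpCas9 set is `NNG`/`NGN`), leaving the leading N positions
unconstrained. All coordinates are 0-based half-open; a cut junction is the
integer split point `protospacer_end − 3` (+ strand) or
`protospacer_start + 3` (− strand). Cut offsets are configurable per enzyme,
so a staggered-cut model can be substituted without touching the scan code.

Every base of a reported site (protospacer and PAM) must be A/C/G/T: an
ambiguous `N` voids the site entirely, which keeps assembly gaps from
spawning phantom targets. This is marginally stronger than only refusing to
match `N` against PAM symbols, and the in-repo brute-force oracle implements
the same convention, so the equivalence tests pin it down.

A composite site pairs one SpCas9 site with one partner site,
non-overlapping, with `spacing_x` intervening nucleotides between the
nearest edges of the two full sites (protospacer+PAM, matching the
edge-to-edge definition of the site diagrams). Orientation labels encode
(site order along the SpCas9 protospacer strand) × (relative strand):
D1 = SpCas9-first/same, D2 = SpCas9-first/opposite, D3/D4 the partner-first
mirror images. The mapping is exposed as a parameter because only the
"SpCas9 upstream" property of the active configurations is fixed by the
underlying biology; searches default to {D1, D2}. Defined this way the
labels are invariant under reverse complementation, which the suite checks.
Canonical searches use spacing 10–30 bp with the canonical PAM set; expanded
searches use 10–100 bp with the relaxed SpCas9 PAMs, so the expanded hit set
is a superset by construction. `within_functional_window` annotates pairs
whose predicted cuts lie within 200 bp — the empirical range of synergistic
fusion activity — but never filters; it is a Results-level observation, not
a search rule.

Enumeration compiles each PAM core into a regular expression with an
overlap-permitting lookahead and pairs sites with a sorted bisection window;
an exhaustive per-offset, all-pairs oracle in the test suite must agree
exactly (set equality of coordinate tuples) on random 100-kb genomes for
both partners and both parameter sets.

## Read processing

Reads are kept when mean Phred > 30 **and** minimum per-base Phred > 24,
both strict. UMIs (default 10 nt, 5′, configurable) are split off by
position; grouping is by exact UMI string — no 1-mismatch merging — because
the consolidation rule below already suppresses UMI sequencing-error
artifacts and exact matching is deterministic. A UMI group yields one
molecule only when its plurality payload sequence has at least
`min_support = 4` exact-identity observations; ties break to the
lexicographically smallest sequence, and at most one molecule is emitted per
UMI even if two sequences clear the threshold ("one read per molecule").
Rejected groups are counted, never guessed at. Per-stage counters satisfy
reads-in = kept + dropped throughout.

The mapping-quality filter of a mapper-based pipeline is replaced by a
normalized-identity floor against the best candidate reference (default
0.9), since MAPQ is mapper-specific. `large_deletion_mode` bypasses the
floor, mirroring the need to retain molecules whose deletions are so large
that any single-reference alignment scores poorly.

## Alignment and classification

Molecules are aligned globally under affine-gap scoring (match +2, mismatch
−3, gap open −5, gap extend −1; a length-L gap costs `open + L·extend`).
The reported statistics never depend on the absolute score scale — any
consistent scheme ranks the candidates identically — so the defaults are
pinned purely for reproducibility. The engine is Bio.Align's pairwise
aligner with the first optimal traceback (deterministic for fixed inputs);
an independent textbook Gotoh dynamic program in the test suite must
reproduce its scores exactly.

**Normalized identity is gap-exclusive**: identities divided by aligned base
pairs. Gaps are the *evidence* of lesions and are judged through the score
and the reported gap events; counting them against identity would push a
legitimate imprecise deletion with large junction offsets (up to ±10 nt per
end on a 200-bp amplicon) below any useful floor. Random sequences align to
the candidates at 0.66–0.79 gap-exclusive identity, so the 0.9 floor still
rejects junk molecules cleanly.

Three candidate references are derived from the wild-type amplicon and its
two predicted cut junctions: wild type, precise deletion
(`wt[:cut_a] + wt[cut_b:]`) and inversion (segment reverse-complemented in
place). The decision procedure: align to all three, keep the best score
(ties resolve WT > PRECISE > INVERSION, biasing away from lesion calls);
PRECISE-best without gap events → precise deletion, with gap events →
imprecise deletion; INVERSION-best → inversion (junction indels do not
rescind the call); WT-best with one deletion spanning both junctions →
imprecise deletion, otherwise indels are attributed to the ±`window`
(default 5 bp) around each cut — SpCas9 window only, partner window only, or
both. Substitution-only molecules are unedited; indels outside both windows
are treated as sequencing/PCR noise and leave the molecule unedited
(provided it clears the identity floor), since distal artifacts are not
nuclease products. The 5-bp window covers typical NHEJ footprints while
excluding distal artifacts. Molecules failing the floor are UNCLASSIFIED:
tallied, kept in the denominator, never forced into a class.

Identical sequences are classified once and cached, so heavily duplicated
samples cost one alignment per distinct molecule.

## Quantification

Class percentages are `100·count/total molecules` (UNCLASSIFIED included in
the denominator). Background subtraction takes the mean of the
negative-control replicates (a triplicate in the intended design) per class
— and per (frame, indel kind, position, length) for the positional catalog —
and floors at zero, because negative lesion rates are meaningless. The
precise-deletion fraction is precise% over the summed six lesion-class
percentages, NaN when the sample has no lesions. `logit_transform` clamps
at ε = 1/(2·total molecules) (half a molecule on the proportion scale)
before `ln(p/(1−p))`; `bh_adjust` delegates to the standard
Benjamini–Hochberg step-up. ANOVA and t-tests are deliberately not
re-implemented — the logit tables are exportable to any statistics
environment. GUIDE-seq peak tables are consumed as given (site, on-target
flag, unique reads); the specificity ratio is on-target unique reads over
summed off-target unique reads, with +inf when off-targets are absent and
NaN when both sides are zero.

## Synthetic data

The generator emulates a locus-specific LAM-PCR UMI library: the default
amplicon is 200 bp (GC 0.5) with cuts at 80/140, and the default outcome
mixture (20% unedited, 60% precise, 5% imprecise, 5%/5%/2.5% single/single/
double cut-site indels, 2.5% inversions) represents a strongly active dual
nuclease. Cut-site indels draw truncated-geometric lengths (p = 0.35, max
20 nt); imprecise junctions offset each end by ±1..10 nt with a nonzero net
length change. Copy counts are uniform (default 1–30), UMIs are uniform
10-mers with collisions allowed and recorded in the truth table.

**Error model.** `substitution_rate` (default 0.1%) applies once per
*template* molecule — the entity a UMI tags before amplification — so all
PCR copies inherit the same errors and consolidation recovers the template
exactly; `read_error_rate` (default 0) adds independent per-copy noise for
stress-testing. Sequencing indel errors are off by default so the closure
property stays exact. Quality strings are constant (Q37); the quality
filter is exercised separately with crafted records.

**Truth-by-construction guards.** A drawn indel is resampled when any
alignment-equivalent placement (computed by sliding the event through
repetitive context) could leave the attribution window or reach the other
cut's window, or when the planned lesion's score margin would let the wrong
candidate win under the default scoring (a single cut-site deletion of
length ℓ requires 3·(cut_b−cut_a) > 4ℓ; inward imprecise offsets shrinking
the deletion by s require cut_b−cut_a > 4s + 5). These inequalities are
derived from the scoring scheme, and they are why simulated truth is
recoverable by *any* correct classifier rather than by this one in
particular. Consequently the default geometry needs a cut separation
comfortably above 4/3 of the maximum indel length (60 bp vs 20 nt here).

Planted genomes assemble composite blocks (concrete canonical PAMs chosen so
single-base-shifted variants cannot re-match, e.g. SaCas9 `GRRT` → `GAAT`)
separated by ≥300 bp, then iteratively mutate one PAM-core base of every
accidental composite — never a planted core — and rescan until enumeration
returns exactly the planted truth. Exact-truth planting is supported for
canonical-mode queries; under the expanded SpCas9 PAM set, shifted variants
of any planted site are legitimate matches, so expanded planting is refused
rather than delivering an unreachable truth (expanded-mode correctness is
covered by the brute-force oracle on random genomes instead).

What the simulations do **not** model: realistic Illumina error profiles,
sequencing indels, PCR chimeras, amplification bias beyond the copy-count
distribution, translocations, and primer artifacts such as truncated
molecules (which the gap-exclusive identity floor would classify rather than
drop). Passing tests therefore demonstrate correctness of the algorithms
under the stated generative model, not robustness to every pathology of real
libraries.

## Problem sizes and determinism

The shipped checks run at 7 × 1,000 molecules for classifier closure, 10,000
molecules for mixture recovery, 500 molecules × 4–30 copies for the UMI
pipeline, and 100 kb for the genome-scan oracle — sizes at which the
binomial noise floor sits well inside the asserted tolerances. All
randomness flows through `numpy.random.default_rng(seed)`; a pipeline run is
a pure function of (config, seed), reports carry the config digest and seed,
and tables are written with fixed formatting so repeated runs are
byte-identical.

## Known limitations

- Inversions are detected only as full-segment inversions between the two
  cuts (with or without junction indels); partial inversions classify by
  whichever candidate scores best.
- Microhomology-mediated junctions, translocations across amplicons and
  base-editing outcomes are out of scope.
- Mismatch-tolerant off-target search is out of scope; the site scan is
  exact over IUPAC classes.
- The identity floor shares one number (0.9) between the unedited call and
  the junk filter; amplicons much shorter than ~50 bp would need it
  revisited alongside the indel-margin inequalities above.
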