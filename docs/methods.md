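# Methods

## The model

V(D)J recombination joins a D segment's 3′ end to a J segment's 5′ end
first, then a V segment to the D–J joint.  Each joining event is targeted
by a pair of recombination signal sequences (RSSs) satisfying the 12/23
rule: the 23-bp-spacer RSS upstream of the J pairs with the 12-bp-spacer
RSS downstream of the D.  An RSS is heptamer + spacer + nonamer; cell-line
substrate assays have measured how single and double substitutions in the
nonamer and heptamer, and spacer-length changes, reduce the joining
frequency relative to a consensus control.

`ighjkit` treats each IGHJ gene's relative recombination propensity as
the product of its three element efficiencies,

    w(g) = (nonamer% / 100) × (heptamer% / 100) × (spacer% / 100),

normalised over the six genes.  This is the *mechanistic* weight mode.
Because the proportionality of in-vivo usage to RSS quality is a
hypothesis rather than an established law, the simulator's default is the
*calibrated* mode: a fixed vector chosen inside the observed usage bands

    IGHJ4 0.47, IGHJ6 0.18, IGHJ3 0.16, IGHJ5 0.14, IGHJ2 0.03, IGHJ1 0.02

(high > 40 %; medium 10–20 %; low < 4 %).  The vector is a calibration,
never a measurement: the observations are bands, not point values.

## Packaged germline

Stored strand convention: nonamer consensus `CCAAAAACA`, heptamer
consensus `CACAGTG` (the complements `GGTTTTTGT` / `GTGTCAC` are derived
on demand).  Positions within an element are 1-based (`9-4G` = nonamer
position 4 → G); all string offsets reported by extraction are 0-based
half-open.

| gene  | nonamer subs | heptamer subs | spacer (bp) | coding length (aa) |
|-------|--------------|---------------|-------------|--------------------|
| IGHJ1 | 9-4 A→G      | 7-4 A→G       | 22          | 17 |
| IGHJ2 | 9-9 A→T †    | 7-6 T→C, 7-7 G→C | 22       | 17 |
| IGHJ3 | 9-4 A→C      | 7-6 T→G       | 23          | 16 |
| IGHJ4 | —            | 7-5 G→T ‡     | 23          | 15 ‡ |
| IGHJ5 | 9-6 A→G, 9-8 C→A | 7-5 G→T ‡ | 22 (alt 21) | 16 |
| IGHJ6 | —            | 7-5 G→A ‡     | 22          | 20 |

† The IGHJ2 nonamer substitution is described in the source annotation as
"position 9, C→A", which matches neither strand (position 9 is A on
`CCAAAAACA` and T on `GGTTTTTGT`).  The packaged default interprets the
printed letters on the `GGTTTTTGT` strand — T→A there, hence A→T on the
stored strand — keeping the substitution at the printed position and
recording the conflict in the gene's machine-readable `discrepancies`
field rather than resolving it silently.

‡ Alternative descriptions exist for the IGHJ4/IGHJ5 heptamer (a literal
`CAATGTG`, which implies two substitutions), for the IGHJ6 heptamer
(7-3 C→T) and for the IGHJ4 coding length (16 aa).  The packaged default
keeps one self-consistent positional substitution per gene — the variant
whose from-base matches the consensus — and records every conflicting
variant in `discrepancies`.  The single-substitution reading also keeps
the mechanistic weight ordering sensible (IGHJ4 maximal); under the
two-substitution literal, IGHJ4's heptamer penalty (0.4²) would outweigh
IGHJ6's spacer penalty, inverting the observed order.

The IGHD catalogue carries the standard 27 genes with 12-bp-spacer RSSs
on both flanks, family-typical coding lengths, and a pairing tier
(high/medium/low, relative weights 9/3/1) reflecting the observed skew:
IGHD6-13, IGHD6-19, IGHD3-22, IGHD3-10 and IGHD2-15 pair frequently;
IGHD1-20, IGHD1-7, IGHD4-11, IGHD6-25 and IGHD7-27 rarely.  Coding
nucleotide sequences for all genes are synthetic (deterministic per-gene
pseudo-random strings): the statistics in scope depend only on segment
identities and lengths, never on real coding sequence.

## Efficiency table

Quoted constants (% of control): nonamer 9-2A 2.7, 9-2T 12.9, 9-2G 61.3,
9-4G 27.3, 9-5C 10.4, double (9-3G, 9-4G) 19.3, double (9-6G, 9-7G) 26.0,
double (9-8N, 9-9A) < 0.1 (stored as 0.1 with an upper-bound flag and
used as a point value in products); heptamer 7-1G 0.0, 7-2T 0.5,
7-3G 0.6, 7-5C 5.9; 12-bp spacer length 13 → 11.0, length 11 → 7.7,
length 14 → 0.0, artificial sequence `GATCGATCGATC` → 63.0.

Declared defaults where no measurement exists:

* `moderate_default` = 40 % for any unquoted single substitution, inside
  the measured 28.5–52.0 % moderate band for non-critical heptamer
  positions; configurable.
* Unquoted multiple substitutions combine multiplicatively
  (Π vᵢ/100 · 100); only three doubles were measured, and the
  multiplicative rule is the simplest total extension.  Provenance of
  every combined value reports the weakest source used.
* 23-bp spacer length penalties: 22 or 24 bp → 50 %, 21 bp → 10 %,
  further → 1 % (one-nucleotide deviations are reported as moderately
  deleterious, larger ones severe; exact percentages were not published).

## Simulator

One record per clone.  Defaults (all stated here as the package's own
declared conditions; none are published distributions):

| parameter | default | meaning |
|-----------|---------|---------|
| n_total | 50,000 | total sequences (Σ duplicate_count, exactly) |
| j_weights | calibrated vector | J-gene choice probabilities |
| d_weights | tier weights 9/3/1 | D-gene choice probabilities |
| trim3d, trim5j | geometric, mean 2 nt | exonucleolytic trimming |
| n2 | geometric, mean 4 nt, uniform ACGT | non-templated insertion |
| expansion | geometric on {1,…}, mean 3 | clone sizes |
| complementarity_coupling | 0 | optional exp(c·score) tilt on D choice |

Frame rule: a record is in frame iff the net junction length change
(n2 − trim3d − trim5j) ≡ 0 (mod 3); stop codons are ignored, so
"productive" equals "in frame" in simulated output.  Under the default
distributions the in-frame fraction is ≈ 1/3.  Trims exceeding a
segment's length are resampled (bounded retries).  Per-gene 5′J-trim
differences are modelled as location shifts (`apply_pergene_trim_shift`),
floored at zero.  All randomness derives from one top-level seed; runs
are byte-reproducible.

The complementarity coupling exists to explore the hypothesis that
duplex pairing between the J-side and D-side nonamers favours joining;
the default of 0 reflects the absence of evidence for it.  Note that the
packaged D RSSs are all consensus, so the tilt is uniform across D genes
unless a user supplies divergent D RSSs.

### What the generator emulates — and what it does not

Emulated: banded J usage, skewed D pairing, geometric trim/insertion
junction structure, 2/3 out-of-frame geometry, clonal size structure
(U/T < 1), and convergent recombination (independent draws of the same
junction collapse into one clonotype, which slightly compresses the
usage of frequent genes relative to their generating weights — a real
feature of unique-sequence analyses).  Not emulated: somatic
hypermutation, V-segment diversity (a single schematic V), TdT base
bias, selection, sequencing error, primer bias.  Tests passing on this
generator therefore validate the statistical pipeline, not the biology
of any real cohort.

## Analysis conventions

* Filtering removes only annotator failures: "no results" and "unknown"
  (junction not identifiable) records; out-of-frame records are kept.
* Clonotype key: (j_call, d_call, junction); configurable.  Gene calls
  are normalised to subgroup level (species prefix, allele suffix and
  functionality letters stripped; first gene of a multi-gene call kept).
* Usage is computed on unique sequences; a flag allows total-sequence
  weighting.  Band labels: high > 40 %, medium 10–20 % inclusive, low
  < 4 %; anything between bands is "unbanded", never force-fit.
* U/T ratio: unique count / total count per gene; genes absent from the
  total table are reported missing, not 0.
* Group comparison: classical equal-variance one-way ANOVA; all pairwise
  t contrasts Bonferroni-adjusted (adj = min(1, raw × m)); star tiers at
  0.05 / 0.01 / 0.001.  All groups constant with unequal means raises a
  degenerate-ANOVA signal.

## Numerical and design choices

* RSS extraction scans spacer lengths nominal−2 … nominal+1 with the
  heptamer anchored at (or within a search window of) the coding edge;
  ties prefer the nominal spacer, then the shorter spacer, then the
  position nearest the coding edge; decompositions above 6 total
  mismatches are rejected.  The cap and tie-break order are configurable.
* Normalised weight vectors must sum to 1 within 1e-9; an all-zero
  weight vector raises a degenerate-model error rather than normalising.
* The acceptance script uses five simulations of 50,000 sequences —
  large enough that the band checks have wide margins (binomial σ on
  IGHJ4 at the clonotype level is ≈ 0.4 percentage points), small enough
  to run in seconds.

## Known limitations

* The mechanistic mode ranks IGHJ4 first and IGHJ1/IGHJ2/IGHJ5 low, but
  its medium-band values do not match observed usage quantitatively;
  only the calibrated mode is asserted to reproduce the bands.
* Spacer sequences of the packaged IGHJ RSSs are declared-length-only
  (the published analysis reports lengths and composition ratios, not
  full spacer strings), so spacer-sequence effects beyond length and the
  one measured artificial sequence are not modelled.
* The IMGT summary reader targets the two functionality failure
  categories by name and treats other columns permissively; it is not a
  full dialect implementation of any specific annotator version.
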