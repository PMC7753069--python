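# ighjkit

Human B-cell receptor heavy-chain repertoires use the six IGHJ genes in a
strikingly non-random and condition-independent pattern: IGHJ4 is used at
high frequency (> 40 % of unique rearrangements), IGHJ6/IGHJ3/IGHJ5 at
medium frequencies (10–20 %), and IGHJ2/IGHJ1 at low frequencies (< 4 %).
A plausible driver is the quality of each gene's recombination signal
sequence (RSS) — the nonamer / 23-bp-spacer / heptamer motif the RAG
recombinase binds during D–J joining under the 12/23 rule.

`ighjkit` is a toolkit for AIRR-seq analysts and immunogenetics modellers
that packages this line of analysis end to end:

* **Germline RSS model** — the six IGHJ RSSs expressed as consensus
  (`CCAAAAACA` nonamer, `CACAGTG` heptamer, 23 bp spacer) plus per-gene
  positional substitutions (IMGT-style `9-x`/`7-x` labels), spacer
  lengths, mismatch profiles, A-rich-core checks, spacer composition,
  RSS extraction from raw flanks, and duplex complementarity scores.
* **Efficiency model** — the measured mutation-specific relative joining
  frequencies (% of consensus control) from cell-line recombination
  assays as a total lookup table, combined multiplicatively into a
  per-gene weight:
  `w(g) = (nonamer%/100) · (heptamer%/100) · (spacer%/100)`.
* **Recombination simulator** — an RSS-weighted D–J rearrangement
  generator (gene choice ∝ weights; geometric 3′D trimming, 5′J trimming
  and N2 insertion; frame from the net junction length change mod 3;
  geometric clonal expansion) that writes AIRR Rearrangement TSVs.
* **Repertoire statistics** — AIRR and IMGT-summary readers, the
  standard no-results/unknown filter, clonotype collapsing, per-gene
  usage and band labels, unique/total (U/T) ratios, J×D pairing
  matrices, junction trim/insertion summaries, and one-way ANOVA with
  Bonferroni-corrected pairwise contrasts.

## Worked example

```python
import ighjkit as ik

germline = ik.load_germline_config()
table = ik.simulate_repertoire(params=ik.SimulationParams(n_total=50_000, seed=1))
unique = ik.collapse_unique(ik.filter_records(table))
profile = ik.ighj_usage(unique)
for gene in sorted(profile.frequencies):
    print(f"{gene}  {100 * profile.frequencies[gene]:5.2f}%  {profile.bands[gene]}")
print(f"unique rearrangements: {profile.n_unique}, total sequences: {unique.n_total}")
```

prints

```
IGHJ1   2.56%  low
IGHJ2   3.18%  low
IGHJ3  16.55%  medium
IGHJ4  44.03%  high
IGHJ5  15.00%  medium
IGHJ6  18.68%  medium
unique rearrangements: 13879, total sequences: 50000
```

50,000 simulated sequences collapse to 13,879 unique clonotypes
(geometric clonal expansion, mean clone size 3); the unique-level usage
frequencies land in the observed bands — IGHJ4 high, IGHJ3/5/6 medium,
IGHJ1/2 low.  Usage sits slightly below the generating weight for
frequent genes because independent draws of the identical rearrangement
(convergent recombination) merge during clonotype collapsing.

The same pipeline is available from a shell:

```bash
ighjkit simulate --n 50000 --seed 1 --out repertoire.tsv
ighjkit analyze --in repertoire.tsv --frame both --out analysis/
ighjkit rss-report          # per-gene RSS composition, efficiencies, weights
```

Weights come in two modes: `calibrated` (a packaged vector inside the
observed usage bands — the default for simulation) and `mechanistic`
(normalised products of the RSS element efficiencies — exploratory; it
correctly ranks IGHJ4 first but the usage-∝-RSS-quality link is a
hypothesis, not a law).

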