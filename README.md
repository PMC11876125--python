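# paleoks

Ks-peak analysis of simultaneously duplicated genes: dating plant
polyploidy events and comparing lineage evolutionary rates from collinear
paralog pairs.

## The problem

Most core eudicot plants share an ancient whole-genome triplication (the
ceWGT, ~115–130 million years ago). Every genome descended from that event
still carries thousands of paralog pairs that were all created at the same
moment, which makes them a natural starting line for measuring how fast
each lineage has evolved since: the synonymous divergence Ks of those
pairs is (approximately) neutral, so a lineage whose ceWGT pairs show a
larger Ks peak has simply accumulated substitutions faster.

`paleoks` implements that analysis as a tested pipeline for researchers in
comparative plant genomics:

1. **Ks estimation** — per-pair Ks/Ka with the Nei–Gojobori (1986)
   counting method on protein-guided codon alignments:
   `pS = Sd/S`, `Ks = −(3/4)·ln(1 − (4/3)·pS)`.
2. **Peak inference** — the median Ks of each collinear (syntenic) block
   tames the long tail of pair-level Ks; per species, block medians are
   fitted with a Gaussian mixture (one component per known polyploidy
   round, EM) and each component mean is an event peak `P_q`.
3. **Rate correction** — with a slowly evolving reference lineage (e.g.
   grapevine), each species gets a scalar `C_q = P_ref / P_q`; corrected
   values `Ks′ = Ks · C_q` place all ceWGT peaks at the same location.
4. **Event dating** — anchored: `age = T_anchor · P_event / P_ceWGT` with
   the ceWGT anchored at 115–130 Mya (invariant to `C_q`); fixed-rate:
   `age = Ks / (2r)` with `r = 7.0×10⁻⁹` substitutions/site/year.
5. **Rate comparison** — species with one polyploidy round (P1R) vs two
   or more (P2R): group means ± SD, coefficients of variation, percent
   differences, Welch t-test, Pearson correlation of peak height with
   polyploidy rounds.
6. **Functional strata** — paralog pairs in the top/bottom 20% of the Ks
   distribution define fast-/slowly evolving gene sets; their pathway
   categories form a 2×K contingency table tested with a Pearson
   chi-square.

A synthetic-data module generates every input with known ground truth
(multi-species Ks datasets with planted rate effects, codon pairs at
calibrated divergence, annotations with planted enrichment), so each stage
is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
28-species dataset (12 P1R + 16 P2R lineages, planted +5% P2R rate
elevation, seed 1):

```bash
python analysis/01_simulate.py
python analysis/02_fit_peaks.py
python analysis/03_correct_and_date.py
python analysis/04_compare_groups.py
python analysis/05_strata_pathways.py
```

which prints (seed 1):

```
fitted 28 species; ceWGT peaks span 1.6884–1.8532
correction factors span 0.9259–1.0163; corrected ceWGT peaks align to 1.7160 (max |error| = 0.00e+00)
anchored post-ceWGT event ages span 31.2–63.2 Myr
P1R: n=12 mean=1.7226±0.0154 CV=0.009
P2R: n=16 mean=1.8010±0.0277 CV=0.015
group percent difference: 4.55%
Welch t p-value: 1.13e-09; Pearson r (peak vs rounds): 0.865 (p=2.78e-09)
reference species p1r_00: 1184 fast / 1184 slow genes
chi-square = 26.365, df = 7, p = 0.000433
```

Reading: every species' ceWGT cloud is fitted to a peak; the spread of
peaks (1.69–1.85) is lineage rate variation; the correction factors rescale
each species onto the reference; the P2R group's peaks sit 4.55% above the
P1R group's — recovering the planted +5% effect (4.56% realised for this
seed) — and the planted pathway enrichment in fast-evolving genes is
detected by the chi-square test.

The same stages are available as a CLI (`paleoks --config run.toml all`,
see `paleoks --help`) and as library functions
(`paleoks.ng86.pair_ks`, `paleoks.peaks.fit_peak_model`,
`paleoks.correction.correct_all`, `paleoks.dating.date_with_anchor`,
`paleoks.compare.compare_groups`, `paleoks.strata.run_strata`).

## Layout

```
src/paleoks/        library (formats, ng86, peaks, correction, dating,
                    compare, strata, simulate, pipeline, cli)
analysis/           numbered narrative drivers over the library
scripts/acceptance.py   headline-quantity recomputation
tests/              pytest suite (unit, property and end-to-end tests)
docs/methods.md     models, assumptions, parameter choices, limitations
```
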