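# Methods

## The assay and its data

The pipeline analyzes a cell-based dual-reporter RNAi screen for modifiers
of Notch-dependent transcription. Each well of a 96-well stock plate holds
one dsRNA; four stock plates are interleaved by quadrant into one 384-well
screening plate (stock well A01 of plates 1–4 lands in screening wells
A01, A02, B01, B02 — the mapping is recorded in the plate map, never
assumed by the scoring code). RNAi-treated cells are split into three
transfection mixes, each read in duplicate:

* **con-luc** — luciferase from a constitutive viral promoter; controls
  for transfection efficiency, cell density and viability;
* **m3-luc** — luciferase from the uninduced *E(spl)m3* Notch target
  promoter; reports baseline (repressed) target transcription;
* **NΔecn > m3-luc** — the same reporter co-transfected with the
  constitutively active, membrane-tethered Notch receptor; reports
  induced target transcription.

Retests add a fourth mix, **Nicd > m3-luc**, where the reporter is induced
by the soluble intracellular domain instead; comparing the two induced
conditions separates factors acting on receptor processing at the
membrane from factors acting downstream in the nucleus.

## Screen scoring

Duplicate readings are averaged per (dsRNA, condition). The induced
signal is normalized two complementary ways — by con-luc (method
`BY_CON`) and by m3-luc (`BY_M3`) — and the log2 ratios are standardized
within each (method, stock plate) group:

    z = (log2 r − mean_group) / sd_group        (sample sd, n−1)

Grouping by the 96-well stock plate of origin absorbs per-stock-plate
batch effects (dsRNA synthesis, plate age). Hits are records with
|z| > 2.0 for `BY_CON` and |z| > 1.8 for `BY_M3` (strict inequality); the
uninduced-reporter distribution has sharper outliers, so its cutoff is
lower to select comparable tails. At the gene level the two hit lists
intersect into areas A (both methods — specific or opposing-effect
modifiers, e.g. a Su(H)-like profile), B (`BY_CON` only — genes moving
induced and uninduced transcription by similar factors) and C (`BY_M3`
only — genes acting mainly on the uninduced promoter, e.g. a
Hairless-like profile).

Three filters run **before** z-scoring so removed wells never contaminate
the group statistics:

1. **Off-target filter.** dsRNAs with more than one predicted off-target
   are removed; exactly one off-target is kept but flagged in every
   output.
2. **Viability filter.** z-scores of log2 con-luc averages over the
   genome-wide distribution; z < −2 (one-sided) marks dead or globally
   silenced wells. Log scale because luminescence is positive and
   right-skewed.
3. **Replicate-error filter.** Per-dsRNA discordance is
   |log2 r₁ − log2 r₂| over the per-copy ratios (the range, for more
   replicates); records whose error z-score exceeds 3 (one-sided,
   genome-wide per method) are removed. Note the statistic is
   folded-normal under the noise model, so the expected removal fraction
   is 2·(1−Φ(√(2/π) + 3·√(1−2/π))) ≈ 0.92%, not the naive 0.13%.

Error and viability distributions are genome-wide rather than per-plate:
the tails being estimated are rare, and pooling maximizes the sample.
Both choices, like every threshold, sit in `ThresholdConfig` and are
echoed into the filter report and run manifest.

Degenerate inputs fail loudly: stock-plate groups need ≥ 3 scored records
and nonzero spread (tolerance 1e−12 relative, to absorb float noise in
identical values); the viability filter needs ≥ 3 positive con-luc
values; non-positive ratio numerators or denominators exclude the record
with an explicit flag instead of producing infinities. Wells missing a
replicate are averaged over what remains and flagged `incomplete`, never
imputed; their replicate error is undefined and they do not enter the
error distribution.

Genes with several dsRNAs are collapsed by "any surviving dsRNA is a
hit"; the reported per-method z is the gene's most extreme one.

## Retest classification

Retests are quadruplicate in all four conditions, against a control-RNAi
treatment. Reporter readings are first normalized by the same treatment's
con-luc signal. The default pairs each reporter replicate with the
con-luc reading of the same replicate index rather than dividing by the
con-luc mean: dividing by the mean makes the normalization noise a shift
common to all four replicates, which a t-test cannot see in its
within-group variance, and the false-classification rate of true null
genes roughly triples. Pairing pushes that uncertainty into the tested
variance and keeps the per-condition tests calibrated. The mean-based
arithmetic (`con_mean`) and unnormalized values (`raw`) remain available
through the `normalization` switch.

Each condition is then compared with the control by a two-tailed
two-sample t-test (pooled variance by default — groups of four from the
same assay; Welch optional) and summarized as a signed percent deviation
100·(mean_gene − mean_control)/mean_control. Classes, evaluated in
order at significance p < α (default 0.05):

| class | NΔecn-induced | Nicd-induced | uninduced m3 | reading |
|-------|---------------|--------------|--------------|---------|
| I     | ↓ significant | ↓ significant | ↑ significant | promotes induced transcription, represses uninduced (Su(H)-like) |
| II    | ↓ significant | ↓ significant | neutral       | promotes induced transcription only |
| III   | ↓ significant | ↓ significant | ↓ significant | promotes target transcription generally |
| IV    | ↑ significant | not ↑        | —             | represses the membrane-bound receptor only |
| V     | ↑ significant | ↑ significant | —            | represses both receptor forms (nuclear-level) |
| UNCLASSIFIED | anything else | | | |

"Neutral" is operationalized as non-significance at α; no
multiple-testing correction is applied, matching the per-gene p < 0.05
convention of this assay family. Retest rates (percent positive by either
normalization contrast) are reported as integer percentages.

## Class summaries and the interaction subnetwork

Hit lists are summarized per GO class or per the five-way localization
vocabulary (extracellular, membrane, cytosolic, nuclear, unknown):
count, percent (one decimal), median z (even classes: mean of the two
central values) and the standard-normal tail percent of the median,
computed as 100·Φ(z) for z < 0 and 100·(1−Φ(z)) otherwise and rounded
only at presentation.

The network stage intersects a physical-interaction edge table with the
hits plus the core pathway nodes (N, Su(H), H, CtBP, gro): the induced
subgraph keeps an edge iff both endpoints are in that node set, drops
self-loops, and by default drops degree-0 nodes. No neighbor expansion is
performed. Exports are Cytoscape-compatible SIF and GraphML plus an
edge-list TSV, with a node-attribute table (role, overlap area, z-scores,
localization) alongside.

## The synthetic-data generator

Signals are generated as baseline × effect-multiplier × exp(N(0, σ²)):
multiplicative lognormal noise, because luminescence is positive and
right-skewed and the analysis is built on log2 ratios. The effect
multiplier is a per-gene ground truth applied identically to every
replicate (a biological effect), while noise is drawn independently per
replicate (technical); a `discordant` profile applies its effect to one
replicate only, to exercise the replicate-error filter. A single integer
seed determines everything; wells are iterated sorted by stock plate,
row, column, and spiked profiles are placed at evenly spaced well indices
independent of the noise stream.

Defaults emulate the screen's conditions: 4 stock plates × 96 wells (one
384-well screening plate), duplicate screen measurements, quadruplicate
retests, noise σ = 0.2 for the screen. Baselines (con 20 000, uninduced
m3 500, NΔecn-induced 10 000, Nicd-induced 8 000 luminescence units)
encode a strongly induced reporter over a low uninduced baseline. Spiked
effect strengths default to 4-fold — the scale of strong RNAi knockdown
phenotypes in this assay; no effect-size distribution is claimed for real
modifiers, so 2–4-fold spikes are calibration instruments, not empirical
claims. Retest simulations use σ = 0.15 (quadruplicate, hand-pipetted
retests are less noisy than robotic genome-wide plates); at 4-fold that
places induced effects ≥ 3 pooled-sd from null.

The canonical control set spikes one gene per qualitative behaviour:
Su(H)-like (induced down, uninduced up), mam-like (induced down only),
H-like (uninduced up only — a `BY_M3`-only hit), a viability profile (all
four signals down jointly — removed by the viability filter) and a decoy
with two predicted off-targets (excluded by the off-target filter no
matter how strong its effect).

What the generator does **not** model: plate spatial/edge gradients,
transfection-efficiency drift, luminescence crosstalk, heavy-tailed
outlier wells, or correlated off-target effects. Passing tests therefore
demonstrate the correctness and calibration of the analysis under its
own statistical assumptions, not robustness to those real-world
artifacts.

## Verification strategy and problem sizes

Deterministic arithmetic (percentages, tail probabilities, t-tests,
z-standardization, induced subgraphs) is checked against independent
oracles: brute-force per-group standardization, numerical integration of
the normal density, the closed-form pooled t-test via the regularized
incomplete beta, and exhaustive edge scans. Stochastic calibration uses
20-seed Monte-Carlo batches of the default 384-well screen
(≈ 7 500 scored records per method), compared with analytic tail
expectations inside binomial 99% intervals; retest calibration pools five
null genes over 20 seeds. These sizes give tight intervals while a full
suite run stays in the seconds-to-a-minute range. Membership checks with
a per-seed null-chance component (an H-like gene drifting out of area C
when its null `BY_CON` z crosses the cutoff, ~7% jointly with its
viability draw) are asserted as ≥ 15 of 20 seeds — the binomial 99.9%
floor of the analytic per-seed rate — rather than per-seed.

## Known limitations

* Replicate error generalizes to > 2 replicates as the range of per-copy
  log2 ratios; for exactly two it is the |difference| the duplicate
  design defines, but the range is a crude spread measure for many
  replicates.
* The viability and error distributions assume enough wells (hundreds)
  for stable genome-wide moments; tiny custom screens should expect
  noisy filter behaviour.
* Gene-level collapse keeps the most extreme dsRNA z; it does not model
  concordance between multiple reagents per gene.
* The epistatic rules are threshold logic on per-condition significance;
  borderline profiles flip classes near α and no effect-size band backs
  the "neutral" call of class II.
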