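# Methods

## Digestion model

Proteolysis is modeled as exact cleavage C-terminal to the protease's
target residues. `lys_c` targets K; `trypsin_p` targets K and R with no
proline restriction (a classic-`trypsin` rule with the P restriction is
also provided). Acetylation of a lysine ε-amine removes that residue from
the cleavable set for both proteases — the mechanism by which chemical
bead acetylation makes a ligand proteolytically resistant. The C-terminal
residue of a chain is never a cleavage site.

Coordinates are 0-based half-open throughout, so the zero-missed-cleavage
peptides of any digest tile the parent exactly — a property the tests
exploit. A digest with `max_missed = m` enumerates every fragment bounded
by two cleavage boundaries (termini included) spanning at most m internal
sites; a protein without sites yields itself intact.

**Two-step digestion.** Step one digests the intact protein with Lys-C.
Bead attachment is modeled as a single anchor residue index (default 0 —
the coupling chemistry and topology are not modeled further); every
step-one fragment containing the anchor is retained on the bead, the rest
are released. Step two digests each released fragment with Trypsin/P,
preserving acetyl blocks. Retained fragments never reach step two, because
beads are removed before trypsin is added. Without an anchor, everything
is released.

**Acetylation** is Bernoulli per lysine with probability p, independent
across lysines and draws. No site-specific reactivity is modeled, and
protein N-terminal amine acetylation is not modeled (lysines only). The
mapping from reagent concentration to p is deliberately left out: titration
analyses treat p itself as the independent variable.

**Ligand signal fraction.** The expected released signal at acetylation
level p, relative to p = 0, is the Monte-Carlo mean of the summed residue
length of released peptides (partition digest, `max_missed = 0`, so lengths
are not double-counted by missed-cleavage variants). Summed length is a
deterministic intensity proxy that avoids inventing ionization
efficiencies; it is documented and swappable. Degenerate case: an anchored
protein with no Lys-C site releases nothing even at p = 0; the denominator
then falls back to the intact length and a warning is emitted.

**Masses.** Monoisotopic atomic masses (H 1.007825, C 12, N 14.003074,
O 15.994915, S 31.972071, P 30.973762 Da) are hard-coded at six decimals;
peptide mass is the residue sum plus one water, plus 42.010565 Da per
carried acetyl group. The residue table is cross-checked against an
independent mass calculator in the tests.

## Quantification pipeline

Input is a protein × sample table of positive linear intensities with
missing cells encoded as absent (zeros in TSVs are read as missing). The
processing order is: filter → log2 → normalize → impute. Replicate counts
and CVs are always computed from the pre-imputation ("observed") table so
imputed draws never masquerade as measurements.

**Filtering** keeps non-contaminant proteins identified with at least 2
peptides and quantified in at least 2 replicates of at least one
condition. The operation preserves order and is idempotent.

**Mode normalization.** For each sample pair (i, j), the log2 ratios
{x·ᵢ − x·ⱼ} over co-observed proteins form a distribution whose mode
estimates the relative loading offset; the mode is taken as the argmax of
a Gaussian KDE with Silverman bandwidth on a 512-point grid spanning the
ratio range. The mode (rather than a mean or median) is robust to the
asymmetric minority of truly changing proteins — in a pull-down, the
enriched bait and interactors. Degenerate constant ratio distributions
return the constant. Pairs sharing fewer than 10 proteins are flagged;
fewer than 2 is an error. Per-sample additive factors are then solved
jointly by least squares over all pairwise modes under a zero-sum
constraint (the objective is shift-invariant, so the minimum-norm solution
is recentered; this is exact). A disconnected pair graph is singular and
rejected. Solving jointly rather than against a reference sample uses all
pairs symmetrically; factor standard errors come from the residual
variance of the mode equations (15 equations, 5 free parameters in a
6-sample design).

**Imputation.** Per sample, missing values are drawn from
N(median − d·SD, (w·SD)²) of that sample's observed log2 intensities, with
defaults d = 1.8, w = 0.3 — the standard left-censored model placing
imputed values in the low-intensity tail. Median and SD are computed from
observed values only, after normalization, so imputed values are not
re-shifted. Samples with fewer than 3 observed values are rejected (SD
unstable). Observed cells are bit-identical before and after.

**Replicate metrics.** Replicate-pair ratios compare replicate k of one
table (or condition) with replicate k of another, only where both are
observed. The median ratio is the median over proteins of per-protein mean
ratios, optionally restricted to proteins quantified in every replicate
pair. CV is SD/mean of linear-scale intensities across a condition's
replicates (log2 values are de-logged first — the standard proteomics
reading), requiring ≥ 2 observations. Quantified-protein counts per
condition exclude ligand and contaminant rows and require ≥ 2 observed
replicates.

**Ligand contamination report.** The top-5 ligand peptides are ranked by
mean linear intensity in the reference condition (missing = zero signal);
each condition reports the replicate-mean of their summed intensity
relative to the reference. `top_n = 1` reduces to the single most
prominent peptide, useful for ligands dominated by one species.

**Protein rollup.** Protein intensity is the per-sample sum of its
peptides' intensities; peptides mapping to multiple proteins (';'-joined
ids) are dropped entirely — unique-peptide summation, no razor assignment.
No statistical testing is added: the pipeline reports ratios, counts and
CVs, not p-values.

## Synthetic data generator

The generator emulates a nanobody pull-down of a GFP-tagged bait from a
yeast lysate in two conditions (tagged, untagged) × 3 replicates, with the
bead arm's acetylation probability as the treatment variable (0 = mock).
Defaults, chosen once as realistic mid-size AP-MS conditions:

| parameter | default | meaning |
|---|---|---|
| n_background_proteins | 300 | co-purifying background proteome |
| n_interactors / n_contaminants | 20 / 10 | enriched partners; flagged contaminants |
| bait_enrichment | 3.0 log2 | bait boost in the tagged condition |
| interactor_enrichment | 2.0 log2 | partner boost in the tagged condition |
| log2 abundance | N(23, 2) | protein base abundance (typical LFQ range) |
| peptides_per_protein | 5 | Dirichlet(2) intensity split across peptides |
| replicate_sd | 0.25 log2 | per-cell measurement noise |
| shift_sd | 0.5 log2 | per-sample loading offsets (centered to zero-sum) |
| missing_threshold / steepness | 18.0 / 1.0 | logistic MNAR on log2 intensity |
| acetylation_p (treated arm) | 0.95 | near-saturating chemical acetylation |
| ligand_log2_abundance | 26 | ligand dominates the mock digest |

The MNAR mechanism drops each cell with probability
sigmoid((threshold − log2 intensity)/steepness) — the left-censoring model
the downshifted imputation presumes. At the defaults this yields roughly
20% missing cells at peptide level and ~2% at protein level (protein sums
only go missing when all peptides do), with missingness concentrated in
the low-intensity tail.

Ligand peptides are not abstract draws: each sample draws an acetylation
state at the arm's p, runs the actual two-step digestion, and distributes
the ligand's abundance over the released peptides in proportion to their
length. Titration behavior is therefore mechanistic — blocked Lys-C sites
retain signal on the bead — rather than assumed.

What the generator does **not** emulate: correlated peptide detectability
across replicates (match-between-runs behavior), ionization-efficiency
differences between peptides, retention-time or spectral effects,
condition-dependent bead capacity, or interactor-specific stoichiometry.
Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and its recovery of known effects under the stated noise model,
not performance on instrument data.

## Numerical and testing choices

- The digestion engine is verified against an independent brute-force
  enumerator over all boundary pairs on random sequences (length ≤ 30,
  both proteases, random acetylation subsets, 0–2 missed cleavages).
- Normalization recovery is checked on 300-protein tables with known
  shifts, ~0.2 log2 replicate noise and 15% missingness (recovery within
  0.05 log2, fixed seed); on full generator output — where peptide dropout
  adds heavy-tailed jitter to summed protein intensities — typical maximal
  factor error at the defaults is ≈ 0.04 log2. KDE-mode estimation error,
  not the solver, dominates both.
- Monte-Carlo monotonicity checks use a conservative SE bound of
  0.5/√n per estimate (a [0,1]-bounded variable), doubled for tolerance.
- Bait-enrichment recovery is asserted within 2 standard errors of the
  replicate-pair ratio mean, with an SE floor of 0.25 log2 to keep the
  3-replicate SE estimate from collapsing by chance.
- Imputation determinism is part of the contract: a single `Generator`
  fills samples in column order, so identical seeds give identical tables.
- Problem sizes throughout (300-protein tables, 10⁴ Monte-Carlo draws,
  10⁵ imputed cells) were chosen so each property is measured well inside
  its tolerance while the whole suite stays fast.

## Known limitations

- Semi-specific and non-specific cleavage are not modeled; neither are
  reduction/alkylation chemistry, spectra or chromatograms.
- The intensity proxy (residue length) ignores peptide detectability; the
  titration curve's shape is exact only under that proxy.
- The concentration → acetylation-probability mapping of the chemical
  reagent is not modeled, so titration results are parameterized by p and
  cannot be compared numerically to reagent-concentration series.
- Factor standard errors treat pairwise modes as independent observations;
  modes sharing a sample are weakly correlated, so the errors are mildly
  optimistic.
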