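# Methods

This note documents the models and procedures implemented in
`sludgeco`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate about real
activated-sludge data.

## Table handling

The unit of analysis is an OTU table of non-negative integer counts,
taxa × samples. Singletons (total count 1 across all samples) are
removed before anything else, as sequence-quality insurance.
Rarefaction draws a multivariate-hypergeometric subsample of exactly
`depth` reads per sample (without replacement), so no count can
increase and retained column totals equal the depth exactly; samples
under the depth are dropped with a warning rather than left unrarefied,
keeping the local community size constant for the neutral model.
All ">" thresholds in the package (0.01% mean-abundance screen, 0.1%
core abundance, 80% core prevalence) are strict inequalities.
The rarefaction seed defaults to 0 and is always explicit.

## Alpha/beta diversity and PCoA

Richness counts non-zero taxa; Shannon H is in nats; Pielou evenness is
H/ln(richness) and is reported as missing for single-taxon samples.
Bray-Curtis is computed on relative abundances — after rarefaction this
equals the count-based definition, and it stays meaningful if
rarefaction is skipped. PCoA Gower-centers −D²/2 and
eigendecomposes; negative eigenvalues (present whenever the
dissimilarity is non-Euclidean, as Bray-Curtis is) are reported
unchanged rather than silently corrected away (no Lingoes/Cailliez);
coordinates use positive axes only, and proportion explained divides by
the sum of positive eigenvalues. A `collapse_rank` helper aggregates
the table to phylum (or any rank) before distance computation.

## Sloan neutral community model

For a taxon at metacommunity relative abundance p, local community size
N (reads per sample) and migration rate m, the stationary local
abundance is Beta(Nmp, Nm(1−p)) and the predicted occurrence frequency
above a detection limit d is F(p) = 1 − I_d(Nmp, Nm(1−p)). Inputs are
p_i = mean per-sample relative abundance and f_i = occupancy (fraction
of samples with count > 0); taxa never observed are excluded; d = 1/N
(one read) by default, with the alternative (minimum observed p)
exposed. m is estimated by bounded scalar minimization of
Σ(f_i − F(p_i))² on (1e−6, 1] (Brent, tolerance 1e−8); R² = 1 − SSE/SST
on the taxa directly (not on binned data — a generalized binned R² is a
recognized alternative; the per-taxon form is implemented). Bootstrap
resamples taxa — the regression's units — with replacement (1,000
replicates by default) for percentile CIs of m, Nm and R². Per-taxon
above/within/below classes compare f_i to the Wilson 95% score interval
of F(p_i) at the study's sample count; the Wilson form is a choice (the
band formula behind published figures of this kind is rarely stated).

### Known systematic bias under multinomial sequencing

The synthetic neutral generator draws each sample's composition from
Dirichlet(Nm·p) — giving exactly the model's beta marginals with exact
closure — and then N multinomial reads. Under that read layer,
detection is soft: P(detect | x) = 1 − (1−x)^N rather than a step at
d = 1/N. For a rare taxon (a = Nmp small) the realized occupancy is
≈ a·ln(1 + 1/m) while the step-threshold model predicts
≈ a·E₁(m); since roughly half the taxa of a long-tailed community sit
below the detection limit, the least-squares fit compensates by
inflating Nm by approximately ln(1+1/m)/E₁(m) — about +25% at
Nm ≈ 2,000 and +35% at Nm ≈ 5,000 for N = 25,000, essentially
independent of the metacommunity shape. Decomposition experiments
(fitting against latent-threshold occupancy x > d recovers Nm within a
few percent; swapping in count-based occupancy alone reproduces the
full bias) confirm the mechanism. Practical reading: fitted Nm values
from sequencing data of this design should be interpreted as
upper-biased by this factor, and comparisons *between* plants (which
share N and the read layer) remain meaningful. The package reports the
honest fitted values and does not correct for this effect, because the
step-threshold form is the field-standard estimator.

## Synthetic data

* **Neutral communities** — log-series metacommunity by default, shape
  0.9999, chosen so that with 3,000 taxa roughly half fall below the
  1/25,000 detection limit, mimicking the long rare tail of AS
  communities; a lognormal option exists. Generators are pure functions
  of (spec, seed).
* **Graph communities** — a sparse precision matrix with unit diagonal
  and −strength (default 0.3) on the edges of a chain/band/random
  graph; positive definiteness is checked, the latent Gaussian is
  softmax-mapped to compositions, and counts are multinomial. The true
  edge set is returned for recovery scoring. Because compositions are
  closed, CLR-transformed counts carry a uniform negative baseline
  correlation ≈ −1/p on top of the planted structure; tests account for
  it.
* **Taxonomy with planted guilds** — synthetic Silva-style lineages in
  which rounded fractions of taxa receive genuine guild genera
  (Nitrosomonas, Nitrospira, Tetrasphaera, Gordonia, …), so guild
  extraction can be scored against planted truth.
* **Reference sets** — a rounded fraction of query sequences embedded
  verbatim (half reverse-complemented, with random flanks) in
  references; the rest carry at least one substitution.

What passing tests on these fixtures do **not** show: real amplicon
data adds PCR/primer bias, chimeras, variable read depth, taxonomic
misannotation and multiple 16S copies per cell, none of which are
simulated.

## Co-occurrence networks

Spearman correlations use mid-ranks and tie-corrected two-sided
t-approximation p-values (an exact permutation option exists for n ≤
10). No multiple-testing correction is applied at the stated raw
thresholds (0.05 per plant, 0.01 before intersection); a
Benjamini-Hochberg option exists but is off by default.

The conditional-dependence route CLR-transforms counts
(ln(c+1) centered per sample) and runs per-node lasso regressions over
a log-spaced 20-value penalty path from λ_max (largest absolute
empirical covariance between CLR columns) down to 0.01·λ_max. The
penalty is selected by StARS: 50 subsamples of ⌊0.8n⌋ samples without
replacement, per-λ edge instability D(λ) = mean over pairs of
2θ̂(1−θ̂), monotonized from the sparse end, and the densest λ with
instability ≤ 0.05 is refitted on the full data with OR
symmetrization. These settings are pinned explicitly because "default"
settings of stability-selection software drift across versions.

The cross-plant consensus keeps pairs appearing with a consistent sign
in ≥ 2 plants' intersected networks with at least one endpoint core or
guild-annotated. Sign agreement and the one-endpoint (rather than
both-endpoint) rule are both configurable, since hub nodes with
non-core partners argue for the permissive reading. Modularity is
greedy agglomerative Newman Q on the unsigned graph.

## Guilds

Matching is case-insensitive with "Candidatus " prefixes stripped on
both sides. Within a guild, patterns above genus rank only fire when
the genus is unassigned or itself a member pattern — a family pattern
sweeps up unclassified members without double-counting a named foreign
genus. The packaged default definitions encode the nitrifier, PAO, BFB
and anammox taxa conventionally used for activated sludge and are
user-replaceable YAML. The AOB/NOB ratio divides group mean total
abundances; an absent NOB group is flagged rather than divided by.
Display matrices log10-transform with zeros mapped to missing, never
−inf.

## Genome-sequenced proportions

"100% alignment and 100% identity" is implemented as exact substring
containment of the query (or its reverse complement) in a reference —
equivalent to a BLAST top hit at full query coverage and identity,
without the external tool. Ambiguity codes never match (conservative).
The 97% variant aligns query-globally / reference-locally (free
reference end gaps; match +1, mismatch −1, gap −2, configurable) and
takes identity = matched columns / alignment columns excluding
reference overhangs, reporting the best-identity reference at or above
threshold. Query-relative coverage is used because genome-derived
reference 16S regions are typically longer than amplicon
representatives. P_number and P_abundance are computed overall and per
sample group, counting only taxa present in the group.

## Redundancy analysis

Responses are Hellinger-transformed by default (square root of
row-closed abundances) — abundance data in linear constrained
ordination without it over-weights abundant taxa — then column-centered;
parameters are z-standardized, with explicit errors for constant or
collinear columns. Fitted values X(XᵀX)⁻¹XᵀY are decomposed by SVD;
canonical eigenvalues are s²/(n−1); the constrained proportion is
‖Ŷ‖²/‖Y‖². Parameter importance is the marginal (single-parameter)
constrained proportion, matching the "top k parameters" reading;
forward selection is not implemented. Significance uses the pseudo-F
statistic with seeded permutation of X's rows (999 by default; the
calibration test uses 199 per replicate, which gives 1/200 p-value
granularity — sufficient to verify level 0.05).

## Pipeline and determinism

Stages run in dependency order (table → diversity → NCM → networks →
guilds → genome proportions → RDA) from a YAML config in which every
random stage has an explicit seed. Each output carries a provenance
sidecar (package version, config hash, seeds — deliberately no
timestamps), and floats are written with a fixed format, so identical
configs produce byte-identical runs. Stage failures abort naming the
stage; completed outputs are retained.

## Problem sizes used in the test suite

The suite exercises the full study design where the statistics demand
it (neutral-model recovery at 3,000 taxa × 13 samples × 25,000 reads,
20 seeds; network recovery at 50 taxa × 200 samples, 10 seeds; RDA null
calibration over 200 replicate datasets) and small constructed fixtures
everywhere a hand-checkable oracle exists. The demo pipeline uses 80
taxa per plant at 3,000 reads rarefied to 2,000 so a full six-plant
double run stays fast.

## Known limitations

* The Nm upward bias under multinomial sequencing described above.
* The mb/StARS selector is calibrated for n of order 100+; at 13
  monthly samples per plant it is usable but conservative, and the
  per-plant networks at survey scale should be read qualitatively.
* Exact matching treats any IUPAC ambiguity as a mismatch; a single N
  in a reference hides an otherwise perfect hit.
* No phylogenetic null models (βNTI/RCbray), no UniFrac (no tree), no
  PERMANOVA, no CCA.
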