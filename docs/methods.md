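# Methods

## Scope and data model

The pipeline starts from protein-level peak areas. Everything upstream —
acquisition, spectral processing, peptide-to-protein rollup, identification
FDR — is out of scope; a "peak area" here is the per-replicate sum of a
protein's unique-peptide areas, a non-negative number in arbitrary intensity
units. The experimental design is four fractions (control / cell-surface /
stripping / internalization) × up to three biological replicates × one cell
line per table.

Replicates are summarized by the arithmetic mean (SD carried alongside for
reporting). Ratios are computed between fraction *means* (ratio-of-means, not
mean-of-ratios): at equal replicate counts this is also what summing replicate
areas before dividing would give, and it is stable when a fraction has a
dropout replicate. A (protein, fraction) pair with no rows has mean 0 and is
treated as *not detected* — in this assay an absent extraction peak is
informative, not missing-at-random. A protein is "identified in a cell line"
when at least one fraction mean is positive.

### Sentinels

* surface/control with control = 0 and surface > 0 → **+∞** (classified
  cell-surface if above threshold — it is, for any finite threshold — but
  excluded from threshold derivation and binning).
* surface = control = 0 → undefined (NaN); the protein is reported with class
  `undefined` and excluded from the ratio-based stages.
* stripping efficacy with surface = 0 → undefined; such a protein can never be
  called endocytic.
* internalization/stripping with stripping = 0 and internalization > 0 → +∞
  (passes the > 2 requirement: a fully stripped protein with internal signal
  is the clearest possible case).

## Surface threshold derivation

Ratios are binned upper-inclusively on powers of two, bin $k$ covering
$(2^{k-1}, 2^k]$, so the candidate thresholds are themselves bin edges. The
threshold $T^\*$ is the smallest power of two $b \ge 2$ such that no
"Cytoplasm"-annotated protein has finite ratio $> b$. The rationale:
cytosolic proteins reach the pulldown only by contamination, so the highest
enrichment they attain estimates the upper tail of the background-enrichment
distribution; everything above it is explained by genuine biotinylation. A
`tolerance` parameter (fraction of Cytoplasm proteins allowed above $b$,
default 0) and a manual override are exposed; derivation fails loudly when no
Cytoplasm-annotated protein with finite ratio exists, rather than guessing.

The 2-fold non-specific cut and the $T^\*$ cut are applied jointly as a
three-way partition (non-specific ≤ 2 < cytosol-like ≤ $T^\*$ < cell-surface),
which makes the class counts additive to the identified total.

## Endocytosis criteria

Boundary handling is strict as stated: $E > 85$, $E > 50$, $R_{is} > 2.0$,
$\eta > 2.0$, with $\eta = 2.0$ falling to the criterion-A branch. The two
routes are mutually exclusive by the $\eta$ split. $E$ is not clamped:
$E < 0$ (stripping signal above surface) and $E = 100$ are legal, and both
fail / pass the thresholds by plain comparison. Criteria are evaluated only
for proteins already classed cell-surface; statistics ($E$, $\eta$, $R_{is}$)
are reported for every protein regardless, since they are useful diagnostics.
Methods-style "Criterion 1/2" and results-style "Criterion A/B" are the same
two objects; this package uses A/B throughout.

## Selectivity and Venn accounting

Criterion III's cross-line fold change uses the **internalization-fraction**
means: criterion III operates on the endocytic-in-both intersection, where the
internalized pool is the quantity being compared. A `fold_fraction="surface"`
switch computes the surface-fraction fold instead. The fold threshold (> 4,
strict) and the per-route definitions give mutually exclusive criteria, and
the identity |selective endocytic| = |I pre-reference| + |II pre-reference|
holds by construction because endocytic calls are a subset of surface calls.
"Identified in the comparator" means membership in the comparator's *called*
sets, not mere detection. The mean fold change over shared endocytic proteins
is reported both as arithmetic and geometric mean (they differ materially for
right-skewed folds; neither is privileged).

## Prioritization

The database stage is a staged filter — expression (FPKM strictly > 5) first,
then atlas localization — so the audit records which stage removed each
candidate. "Limited peripheral distribution" is operationalized as
`tissue_breadth`: the count of non-brain tissues with atlas detection above
"not detected". This is a deliberately threshold-free reading of a
qualitative notion — candidates are *ranked* by breadth (ascending), with
FPKM descending and then protein ID as total-order tie-breaks — rather than
cut at an arbitrary breadth. Candidates missing from a database are kept with
status `unknown` and excluded from the final ranking, never silently dropped.

## The generative model

`synthetic_data.simulate_experiment` emulates the experiment with four protein
classes: `surface_endocytic`, `surface_static`, `cytosolic`,
`nonspecific_binder` (defaults 120/180/120/80 = 500 proteins per line).
Noise-free fraction means for surface-class proteins with abundance $a$
(log-normal, median $10^5$), line multiplier $m$, stripping efficiency $s$ and
internalized ratio $i$:

    control = eps_p · a · m     surface = a · m
    stripping = a · m · (1−s)   internalization = a · m · i

with per-protein bead background $eps_p$ (median 2 % of abundance, log-normal
spread ×/÷ e^0.5). A quarter of surface proteins fall below detection in the
no-biotin control (infinite-ratio path). Contaminant classes place
`control_ratio` × control in the surface fraction — drawn in (2.2, 4] for
cytosolic proteins, so the threshold-derivation step has a genuine tail to
find, and in (0.5, 2] for bead binders — and are untouched by MESNA
(stripping = surface), with internalization ≈ surface; they therefore fail
$R_{is} > 2$ and $E > 50$ regardless of their surface call. Each expected mean
is multiplied by i.i.d. unit-mean log-normal noise per replicate (CV 20 % by
default; the CV of SWATH protein peak areas across biological replicates is
typically 10–30 %).

Planted parameters sit well inside the criterion boundaries:
criterion-A-route endocytic proteins draw $s \in [0.93, 0.99]$,
$i \in [0.3, 0.8]$; the accumulating (criterion-B) tenth draws
$s \in [0.75, 0.95]$, $i \in [3, 6]$; static proteins $s \in [0.88, 0.99]$,
$i \in [0, 0.01]$. The internalized ratio is allowed above 1 for the
accumulating route: biologically, internalized signal exceeding the labeled
surface pool arises from recycling and ongoing delivery during the warm
incubation, which is exactly the overestimation phenomenon the $\eta > 1$
flag marks. Cross-line structure: 25 % of surface proteins are target-only,
10 % comparator-only; of shared endocytic proteins, 15 % get a > 4-fold
higher target multiplier (criterion-III route) and 15 % are endocytically
inert in the comparator (criterion-II route, surface in both lines).

Annotation noise (default 5 % of proteins) is **directed**: discordant
surface-class proteins lose their terms (database incompleteness), discordant
contaminants swap to a surface-class label. Spurious "Cytoplasm" labels are
confined to low-enrichment proteins. This mirrors the empirical pattern that
makes the threshold rule usable at all — observed screens show Cytoplasm
annotation vanishing above the threshold — and keeps the generator consistent
with the phenomenon it emulates; a generator spraying Cytoplasm labels onto
high-ratio proteins would be modeling a different (and for this rule,
pathological) annotation process.

The database tables plant a prioritization funnel among the target-selective
endocytic reference proteins (7 with FPKM in [8, 40], of which 5
atlas-detected in brain microvessels, of which 2 narrowly distributed);
background FPKM is log-normal with median 1, so ~2 % of background candidates
pass the FPKM > 5 cut by chance.

**What passing on synthetic data does not show:** the generator draws
independent proteins (no shared peptides, no correlated abundances), noise is
purely multiplicative (no missingness mechanism beyond true absence, no
intensity-dependent CV), the GO annotation process is idealized, and the
cytosolic enrichment range is stipulated rather than estimated from real
pulldowns. Recovery results therefore validate the *inference logic*, not the
assay's real-world error rates.

## Problem sizes and determinism

The default simulation is 500 proteins per line with 3 replicates — the same
order of magnitude as a real single-line screen (563/399 identified proteins)
— and the full two-line pipeline on it runs in a few seconds, so tests and the
acceptance script use it directly. All randomness flows from a single
`numpy.random.default_rng(seed)`; identical config + seed gives byte-identical
output files (fixed column order, sorted JSON keys).

## Known limitations

* Exactly two cell lines; the set algebra is not generalized to k lines.
* No statistical testing of fold changes or criterion assignments — the method
  is deliberately a deterministic filter cascade, as screens of this type are.
* The threshold rule is sensitive to spurious high-ratio "Cytoplasm"
  annotations; the `tolerance` parameter is the escape hatch if a real
  annotation table behaves that way.
* `tissue_breadth` treats all peripheral tissues equally; no weighting by
  vascular density or clinical relevance.
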