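# Methods

This note records the models, statistics and design choices behind each
pipeline stage, what the synthetic-data generators do and do not emulate,
and the numerical conventions that make results reproducible.

## Identification filtering

Input rows carry a search-engine confidence in [0, 100]; the default cutoff
of 95 corresponds to the score band reported for a 5% local FDR in
ProteinPilot-style searches (per-replicate values 95.2–97 can be supplied
per dataset). The filter order is confidence → contaminant lists →
deduplication; a record failing several filters is attributed to the first.
Deduplication keeps the highest-confidence instance of each identity key,
ties broken by first occurrence, so output is deterministic. Identity keys
are either the bare sequence or sequence plus a canonical sorted
`pos:name` modification string. Rows with ambiguity codes (B, J, O, U, X,
Z) are rejected and reported, never recoded: every downstream statistic
assumes the 20-letter alphabet. HLA-protein exclusion lists may be given as
FASTA; peptides are removed when they occur as substrings of any entry.

The confidence filter is applied per record before replicate pooling
(whether the original workflow filtered before or after pooling is not
documented; per-record filtering is the order-invariant choice).

## Background frequencies and positional enrichment

The embedded background is the mean amino-acid composition of the reviewed
human Swiss-Prot proteome (Trp ≈ 1.2%, Phe ≈ 3.7%). A FASTA-derived
background is supported; its frequencies are floored at 1e−6 and
renormalised so absence in a small proteome cannot produce infinite fold
changes.

Enrichment of residue a at position p in an n-peptide set uses the binomial
z-score with the reference-proportion variance,

    z = (p_obs − p_ref) / sqrt(p_ref (1 − p_ref) / n),

two-sided at α = 0.05 (critical value 1.96). Cells with |z| above the
critical value are reported as FC = p_obs/p_ref when FC ≥ 1 or
FC_con = −1/FC when FC < 1; unobserved residues carry the sentinel −100.
The graphical tool originally used for this statistic does not publish its
formula; the binomial z above is the closest published description, and
matching third-party FC values is expected only to ≈ ±0.05 (background
version drift). Note that with the reference-proportion variance, swapping
observed and reference exactly inverts FC and flips the sign of z but not
its magnitude; a pooled variance would be needed for exact antisymmetry.
Calibration is verified by simulation: under the null (positions drawn
i.i.d. from the background, n = 1000 peptides, 200 repertoires) the
significant-cell fraction is 0.049–0.050.

Anchor positions are addressed C-terminally: PΩ = L, PΩ-2 = L − 2, so P7,
P8 and P9 of 9-, 10- and 11-mers are the same anchor.

## Positional covariation

Coupling from site i to site j is the count-weighted RMS log-ratio shift of
j's residue frequencies under conditioning on a residue x at i:

    D(i→j | x) = sqrt( Σ_a [ ln( f̃_j|x(a) / f̃_j(a) ) ]² ),
    coupling(i, j) = Σ_x (n_x / n) · D(i→j | x)   over subsets with n_x ≥ n_min.

Frequencies are regularised as a uniform mixture f̃ = (1 − w) f + w/20 with
w = 0.05. The mixture (rather than count pseudocounts) is deliberate: it
depends only on frequencies, so a site with a constant residue couples
exactly zero to every other site and duplicating the dataset leaves the
matrix unchanged — both properties fail with additive count pseudocounts.
n_min defaults to max(10, 5% of n); conditional frequencies from smaller
subsets are noise. The diagonal shows conservation, the same RMS divergence
of a position's frequencies from a background (the repertoire's own pooled
composition by default, a proteome background optionally). The matrix is
reported unsymmetrised (i→j and j→i differ in general) with a symmetrised
mean-of-transposes view for ranking and display.

The raw statistic's noise floor differs between pairs (it grows with the
number of mid-sized conditioning subsets), so detection uses a permutation
null: columns of the sequence matrix are shuffled independently, preserving
marginals while destroying coupling. Both a pooled off-diagonal null and
per-pair nulls are available; the per-pair comparison is the sharper test
and is what the analysis driver reports.

## Physicochemical PCA and clustering

Each peptide of length L becomes a 24·L-vector: per position, molecular
weight (free amino acid, Da), Kyte–Doolittle hydropathy, theoretical
maximum accessible surface area (Tien et al. 2013, Å²) and free-amino-acid
isoelectric point, plus 20 identity indicators. The property table is a
single replaceable DataFrame, since no particular scale set is canonical
for this analysis. Columns are standardised to zero mean/unit variance —
mandatory when mixing Da, Å² and indicators — and numerically constant
columns (sd below 1e−8 relative tolerance) are dropped and recorded. Each
peptide length is analysed independently.

PCA uses a full SVD; each component is oriented so its largest-|loading|
feature is positive, making signs reproducible. k-means (10 restarts,
seeded) runs on the first two PC scores for each candidate k (default 2–6);
k is chosen at the silhouette-coefficient peak, ties to the smaller k.
Cluster indices are relabelled by decreasing size (ties by centroid
coordinates) so labels are stable across reruns. Outputs include per-cluster
percentages, per-cluster motif summaries, a ranked loading report aggregated
by position and feature type, and an optional Gaussian-KDE density grid
(Scott's rule) on PC1/PC2.

## Repertoire overlap with rescue

Effective membership of dataset D among the datasets of one call is

    {p : conf_D(p) ≥ 95} ∪ {p : conf_D(p) > 20 and conf_other(p) ≥ 95 for some other},

i.e. a confident sighting in a compared dataset rescues sub-threshold
identifications of the same peptide. Rescue is evaluated only against the
datasets in the current call. Identity defaults to sequence-only here
(three-way overlap counts are conventionally reported by sequence alone);
modification-aware identity is available and both set sizes (core and
effective) are reported, since percentage denominators are otherwise
ambiguous. With rescue cutoff = primary cutoff the rule reduces exactly to
plain set intersection, which the tests exploit as a brute-force oracle.

## MRM validation and quantification

A peptide is monitored via 3–4 transitions. A (peptide, experiment) group
is a candidate when its transitions co-elute (RT spread ≤ 0.2 min — the
co-elution tolerance is an operational choice, exposed in config). A
candidate is `ms2_confirmed` when the instrument triggered an MS/MS scan in
that experiment; otherwise it is rescued iff its RT is within ±1.5 min
(inclusive) of the mean RT of that peptide's MS/MS-confirmed detections and
its spectral-library dot product is strictly > 0.7. The dot product is the
normalised inner product of square-root-transformed intensities over the
union of fragments (missing fragments contribute zero), requiring at least
two shared fragment ids; it is 1 iff the patterns are proportional and is
invariant to uniform scaling of either spectrum.

Validated detections are quantified as Σ(transition areas) / β2m area of
that experiment — β2m, the invariant light chain co-purified with HLA, is
the loading normaliser — and expressed as the proportion of the peptide's
maximum normalised area across all experiments of the call (assumed to span
all experiments jointly rather than per display panel). Proportions are
invariant to rescaling any single experiment's areas and β2m together. No
absolute quantification is attempted; ionisation-efficiency differences
make cross-peptide absolute comparison meaningless without labelled
standards.

## Thermal melts

Dye-based melt curves are truncated at their global fluorescence maximum
(the post-peak decay reflects aggregation, not unfolding) and fitted by
least squares to the Boltzmann sigmoid

    F(T) = B_l + (B_u − B_l) / (1 + exp((Tm − T)/s)),

with Tm initialised at the maximum of the derivative of a 5-point
centred-moving-average smooth, and bounds keeping Tm inside the fitted span.
A transition is accepted only when that derivative peak is interior and
exceeds twice the mean slope of a straight line through the truncated data;
flat or linear traces raise an explicit no-transition error, non-convergent
fits a fit error. Tm is reported to 0.1 °C. The fit is exactly equivariant
to temperature shifts and invariant to fluorescence rescaling. On the
synthetic suite (Tm 50–85 °C, 2% amplitude noise, 100 curves) recovery bias
is < 0.05 °C and RMSE < 0.2 °C.

Replicates are summarised by mean and sample (n−1) standard deviation. ΔTm
between a variant and reference complex is classified stabilising when
> +1 °C, destabilising when < −1 °C, else negligible. The published
melting-temperature table for the HLA-B57-family complexes is embedded as
fixed experimental input (`reference_tm.py`) for ΔTm arithmetic; raw
instrument curves are not redistributed, so those Tm values are inputs, not
fit targets.

## Synthetic data: what it emulates, and what it does not

`simulate_repertoire` draws peptides position-independently from per-length
profiles except at injected coupling pairs, where with probability equal to
the mixing weight the residue pair is drawn jointly; it appends ligand-like
confidence scores with a low-confidence tail, plus contaminant spikes drawn
from a pool at ligand-like confidences (so the list filter, not the
confidence filter, must catch them). The bundled three-spec cohort (n = 2000
per dataset, seed 1) mirrors the studied contrasts: shared P2 S/T/A/V bias,
aromatic PΩ with one Phe-major and two Trp-major datasets, PΩ-2 Arg
enrichment in exactly one, Glu enrichment in another, and a P2–PΩ joint
injection (weight 0.6) that pairs S/T with the major and A/V with the minor
aromatic while keeping the P2 marginals near the anchor profile — strong
enough for the coupling matrix to recover against its permutation null, as
the paired anchors are in real data.

`simulate_mrm` produces areas = truth × loading × fragment intensity ×
lognormal noise (sd 0.2 by default), jittered RTs, per-experiment β2m
factors (the loading factor is proportional to β2m, which normalisation
must cancel) and configurable MS/MS-trigger behaviour. `simulate_melt`
produces Boltzmann sigmoids with post-peak exponential decay and Gaussian
noise at 1 °C steps over 35–90 °C.

All generators are pure functions of (spec, seed); identical specs yield
byte-identical tables. What they do **not** emulate: real repertoires share
peptides across allotypes (the synthetic datasets are drawn independently,
so their overlap is essentially the contaminant spikes); confidence scores
are not generated from spectra; residue profiles are position-independent
apart from explicit injections, unlike the weaker higher-order structure of
real ligand sets; MRM chromatography and interference effects are reduced
to RT jitter and lognormal area noise. Passing tests therefore certify the
statistical machinery, not performance on any particular experimental
dataset.

## Problem sizes and determinism

Default analysis/test sizes — 2000-row cohort tables, 200 null repertoires
of 1000 peptides for calibration, 600-peptide coupling sets with 30
permutations, 1000-peptide PCA recovery sets, 100 melt curves — were chosen
so each stage's sampling error is far below the effects being measured
while the full suite runs in well under a minute. Every random draw goes
through a `numpy` Generator seeded from an explicit spec or CLI seed; no
global random state is used.

## Known limitations

The coupling statistic is a faithful implementation of the verbal
definition (perturbation response of positional frequencies), not a
re-derivation of any specific historical script; raw values are comparable
only against a permutation null, not across datasets of different size or
composition. The enrichment z-test is approximate for very rare residues at
small n. The silhouette criterion can prefer k > 2 when genuine substructure
exists; the chosen k and the full silhouette profile are always reported
rather than forcing k = 2. Peak integration, spectral searching and FDR
estimation are upstream of this package and out of scope.
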