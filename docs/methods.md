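# Methods

## Problem and model

The package predicts the equilibrium dissociation constant of the
IgG-Fc/FcRn interaction for mutated Fc domains, modeled as
log10 K_D (molar) at pH 7.0. The working hypothesis is that K_D
changes caused by interface mutations are captured by
structure-derived descriptors of the mutant complex model: per-residue
surface areas and solvation terms at the interface positions, plus
global interaction counts. A regression model maps the standardized
feature vector to log10 K_D.

The pipeline treats the complex model as rigid except for the mutated
side chains: variants are built on a fixed reference backbone, so all
feature changes come from side-chain replacement. This deliberately
ignores backbone relaxation, long-range electrostatics and
conformational dynamics (see Limitations).

## Structure handling

PDB text is parsed with gemmi behind the `structure_io` surface.
Hydrogens, waters and non-amino-acid heteroatoms are dropped, and
alternate locations resolve to the highest-occupancy conformer (ties
to the alphabetically first altloc). Chain roles — the FcRn-contacting
Fc chain, the FcRn α-chain, β2-microglobulin — are declared in a chain
map and never inferred; likewise EU-numbering offsets are explicit
per-role integers. This keeps a given input byte-identical across
runs and makes the Fc-position vocabulary (EU numbering) unambiguous.
Receptor chains keep author numbering, which is how receptor positions
(e.g. FcRn 129) are conventionally cited.

All geometry is heavy-atom only: crystal structures of these
complexes rarely resolve hydrogens, so the hydrogen-bond criterion is
a heavy-atom donor–acceptor distance. Van der Waals radii are a fixed
Bondi-like table (C 1.70, N 1.55, O 1.52, S 1.80, default 1.70 Å).

## Side-chain mutagenesis

Interactive mutagenesis tools are not reproducible components, so the
mutator is a deterministic template-graft procedure: the side chain
beyond Cβ is deleted and rebuilt from ideal internal coordinates
(z-matrix rows per residue type) on the N–CA–C(–CB) frame; a glycine
origin gets its Cβ from ideal tetrahedral geometry. χ1 and χ2 (where
present) are scanned on a 30° grid; χ3+ stay at template values. The
kept rotamer minimizes a soft-sphere clash score
Σ max(0, r_i + r_j − d)² against all heavy atoms outside the mutated
residue, with ties going to the first rotamer in scan order
(χ ascending from 0°). The 30° granularity is coarse but sufficient
because downstream features are 3.5–4.0 Å counts and surface areas,
not energies. Only the declared Fc chain is mutated.

## Features

The default catalog has 147 entries:

* 21 Fc positions (EU 251–257, 285, 286, 288, 307–311, 314, 428,
  433–436) × {ASA, BSA, solvation energy} = 63. These are the
  positions at which variants are modeled; substitutions elsewhere do
  not enter the features.
* 24 receptor-side positions × the same three terms = 72. The
  receptor list is a configurable reconstruction: interface residues
  of the FcRn α-chain and β2m ranked by buried area on the reference
  complex, truncated to 24, with FcRn 129 always pinned first when
  present.
* 12 complex-level metrics: interface residue count (BSA > 0.1 Å²),
  solvation gain on binding, a hydrophobicity surrogate, a
  binding-energy surrogate, permissive-cutoff hydrogen-bond and
  atom-pair salt-bridge counts, strict hydrogen bonds (≤ 3.5 Å), salt
  bridges (≤ 4.0 Å, one per residue pair), Cα–Cα contacts (≤ 4.0 Å),
  mean hydrogen-bond distance (0 when no bonds), paired hydrophilic
  residues, and the number of Fc∪β2m atoms in cross-chain contact.

Surface areas use Shrake–Rupley quadrature: 960 deterministic
golden-spiral points per atom on the probe-expanded sphere
(probe 1.4 Å), points discarded when inside any other expanded
sphere. BSA is isolated-chain ASA minus in-complex ASA, so it is
non-negative up to quadrature error by construction. Solvation energy
is Σ ASP(element) × atom SASA with Eisenberg–McLachlan-style constants
(C +0.016, N −0.006, O −0.006, S +0.021 kcal·mol⁻¹·Å⁻²).

Two catalog entries are documented surrogates rather than attempts to
reproduce any external interface-analysis software: the hydrophobicity
score is the fraction of interface BSA contributed by apolar (C, S)
atoms, and the binding-energy surrogate is −(solvation gain) +
0.5 × (hydrogen-bond count). Their absolute values are not comparable
with other tools; they exist to preserve the catalog shape and carry
qualitative signal. Similarly the "permissive" hydrogen-bond count
uses a 3.9 Å cutoff and the atom-pair salt-bridge count skips the
residue-pair deduplication.

Cutoffs not otherwise determined (paired-hydrophilic contacts, Fc–β2m
atom contacts) default to 4.0 Å heavy-atom distance, matching the
other contact criteria; every cutoff is a module constant. The
hydrophilic set is {S, T, N, Q, Y, H, K, R, D, E}; Cys and Trp are
borderline and excluded. The mean hydrogen-bond distance is the mean
donor–acceptor distance of counted pairs (not the spacing between
bond midpoints). The Cα–Cα contact criterion is implemented exactly
as stated at 4.0 Å even though that is a tight threshold for Cα
pairs; it is configurable via the module constant.

Numerical note: counts and distances are exactly invariant under
rigid motion of the complex. SASA-derived features are invariant
under translation exactly, but under rotation only to the quadrature
resolution, because the spiral point set is axis-fixed; with 960
points the total-area discrepancy is ~0.1%. The test suite asserts
counts exactly and areas at that tolerance.

## Curation

Measurements at pH 6.0 are mapped to the pH 7.0 scale by multiplying
K_D by an integer factor derived from the wild-type pair
(K_D = 1.3e-6 M at pH 6.0, 8.8e-5 M at pH 7.0 → factor 68), which is
justified to first order by the approximately log-linear pH dependence
between pH 6 and 7.4. The factor is recomputed from the configured
wild-type K_Ds and rounded, so other isotypes can supply their own
pair. Non-binders carry no usable K_D and are excluded with a logged
count.

Because only catalog positions enter the features, variants differing
only at off-catalog positions are indistinguishable ("effective
signature" equality) and would bias training; deduplication keeps the
first occurrence in input order (a geometric-mean-of-K_D policy is
available behind a flag). The FLS keeps pH 7.0 SPR records only; the
SLS appends the harmonized pH 6.0 records, listed after the FLS ones
so signature collisions resolve to SPR data.

## Learning

Estimator defaults (scikit-learn): random forest with 10 trees of
depth ≤ 10; RBF-kernel SVR with C = 1, ε = 0.1, γ = 1/n_features,
tol 1e-3; an MLP with hidden layers (20, 2), tanh activation, L-BFGS,
α = 20, max 4000 iterations, tol 1e-5; ordinary least squares with
intercept. The heavy L2 penalty on the MLP and the shallow forest are
overfitting guards appropriate to ~10³ samples and ≤ 147 features.

Evaluation is 10-fold shuffled cross-validation; the scaler (and
constant-column dropping) is refit on each training fold, so held-out
folds never leak into standardization. R² is the standard coefficient
of determination against the held-out mean and may be negative.

Feature selection: (1) iterative elimination — drop the
lowest-importance feature, accept while the mean CV R² stays within a
tolerance (default 0.01) of the initial model, stop at the first
rejected drop; (2) correlation pruning — among pairs with
|Pearson r| ≥ 0.9 (descending |r|, ties by feature id), drop the
lower-importance member. Importance is impurity-based for the forest,
|standardized coefficient| for MLR, and seeded permutation importance
(mean R² drop over 10 permutations, clipped at 0, normalized to sum 1)
for SVR/MLP, which have no native importances. Both thresholds are
arguments.

The shuffled-label control permutes responses with a seeded generator
and reruns the same CV; a model that learned real structure collapses
to mean R² ≈ 0 or below.

The end-to-end prediction path (`AffinityModel.predict`) reduces a
variant to its effective signature, mutates the reference, extracts
the catalog, applies the stored scaler and regressor. Everything is
deterministic given the stored model.

## Variant libraries

mut3/mut5 libraries draw the stated number of distinct positions
uniformly from the 21 modeled positions and a uniform non-wild-type
amino acid per position (optionally from an allowlist), rejecting
duplicate signatures until the requested size is reached (hard fail
after 100× attempts). Wild-type identities are read from the
reference model, never hard-coded. The mut8 library draws sizes
uniformly from {6, 7, 8} and restricts substitutions to those whose
single-mutation effect estimate is below +0.5 log10 K_D units — a
configurable operationalization of "not strongly destabilizing".
Position sampling is uniform (unweighted).

## Synthetic data: what it emulates and what it does not

Toy complexes plant each interaction type in its own slot: tip atoms
meet midway between chain baselines (16 Å apart) at the exact stated
distance while all other cross-chain pairs stay beyond cutoff
+ 0.5 Å. Known couplings are folded into the manifest (Ser–Ser
hydrogen-bond pairs and Lys–Asp bridges are also hydrophilic contact
pairs; bridges under 3.9 Å also hit the permissive hydrogen-bond
count; salt bridges are constrained to (3.5, 4.0] so they can never
double as strict hydrogen bonds). Planted residues carry only the
atoms the interaction needs.

The reference-like complex is three idealised chains carrying the
wild-type residues of the 21 Fc positions (plus decoy positions 235
and 239 for duplicate planting), an FcRn α-chain segment including
position 129, and a short β2m chain, facing each other across a
6.5 Å interface so that surface burial and contact counts respond to
mutations.

Affinity tables draw unique variants over the 21 positions (1–3
mutations each by default), featurize them with the real mutator and
featurizer, and set log10 K_D = −7.0 + w·z + N(0, σ) with sparse
default weights on two buried-area features, one accessible-area
feature and two contact counts (z = per-column z-scores of the
table). Defaults: n = 500, σ = 0.15 log units, 15% pH 6.0 ELISA
records stored as K_D/68 (so curation must invert them), five planted
duplicate pairs. These scales mirror the real study setting: a
~10³-variant table, a pH 6 minority around a sixth of the data, and
measurement scatter well under one log unit.

What passing tests therefore show: the geometric featurizer counts
exactly what is planted; curation inverts exactly the distortions the
generator applied; the learners recover a known sparse linear signal
through the full mutate→featurize→regress path. What they cannot
show: that real Fc/FcRn affinity is linear in these features, that
the rigid-backbone approximation holds for heavily mutated variants,
or how the pipeline behaves on assay noise that is not i.i.d.
Gaussian in log space.

## Problem sizes and determinism

The shipped study sizes — 500-variant tables with ~400 atoms per
complex model, 960 quadrature points, 10⁵ Monte-Carlo samples per atom
in the surface-area oracle, 150–200-variant libraries — were chosen so
a full verification run completes in minutes on a single core while
keeping every statistical margin comfortable (the planted-weight
recovery criterion has ~1.5σ of headroom at these sizes). All
randomness flows from explicit integer seeds; repeated runs are
byte-identical.

## Known limitations

* Rigid backbone and discrete rotamers: steric strain and induced fit
  are invisible; heavily packed mutations may get unrealistic models.
* The solvation and binding-energy terms are linear surface models,
  not physics; they are features, not energies.
* The receptor-side catalog is a reconstruction ranked by buried
  area, not a curated list; it is shipped as editable configuration.
* A single multiplicative pH-harmonization factor ignores
  histidine-specific pH effects, which can be much steeper.
* Only one Fc chain is mutated; homodimeric double mutation is not
  modeled.
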