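# Methods

`chromqsar` implements a grid-based 3D-QSAR workflow of the CoMSIA family
(Comparative Molecular Similarity Indices Analysis) for antibacterial
activity modelling of sulfonamide/chromene series, together with the data
curation, alignment and validation machinery around it. This note records
the model, the numerical choices, and what the synthetic benchmark does
and does not demonstrate.

## Activity scale

Minimum inhibitory concentrations (MIC, µg/mL) are converted to a
logarithmic potency, pMIC = −log10 of the molar MIC. Because MICs are
reported per mass, the conversion divides by the molecular weight first:
pMIC = −log10(MIC·10⁻³/MW). This molar basis is the default (standard
QSAR practice — it makes potencies comparable across molecular weights);
a `pmic_basis="mass"` switch takes −log10 of the µg/mL value directly for
reproduction attempts against sources whose basis is unstated. Censored
entries ("> 512") keep the bound and the censoring flag but are excluded
from all regression, as are rows without a MIC (dropped and counted in
the log).

## Per-atom parameterization

Each atom carries the five property weights the similarity fields consume:

| property | source | notes |
|---|---|---|
| partial charge (e) | Gasteiger iterative electronegativity equalization (RDKit) | deterministic; sums to the formal charge |
| vdW radius (Å) | packaged Bondi table (`data/vdw_radii.csv`) | error on missing element |
| hydrophobicity | Wildman–Crippen atomic logP increments (RDKit) | per-atom values sum to Crippen logP |
| donor flag | SMARTS: N or O bearing ≥1 H | |
| acceptor flag | SMARTS: any neutral O; N with an available lone pair, excluding amide/sulfonamide N, nitro N and pyrrole-type aromatic N | an atom may be both donor and acceptor |

Commercial force-field charge assignment (OPLS-class) is not reproducible
here; the Gasteiger scheme is deterministic and bit-stable, but absolute
electrostatic field values will differ from workflows that used other
charges. Protonation/tautomer enumeration is out of scope — structures
are taken as given.

## Pharmacophore alignment

Features use the conventional six-letter alphabet: A (acceptor) and D
(donor) at flagged heteroatoms; H (hydrophobe) at centroids of connected
apolar-carbon clusters of size ≥ 3 (carbon with no N/O neighbor); R at
aromatic ring centroids; N/P at centroids of connected formally charged
clusters. Detection order (kind, then lexicographic position) is
deterministic. Default matching tolerance: 1.0 Å.

Alignment is rigid-body only (no torsional flexibility): kind-consistent
maximal feature matchings are enumerated — each kind shared by molecule
and reference contributes min(count) pairs — capped at 5,000 candidates;
when the cap binds, candidates are ranked by a pose-invariant heuristic
(agreement of intra-set pairwise feature distances with the reference)
before exact least-squares superposition. Superposition is the Kabsch/SVD
solution constrained to proper rotations (det = +1), so mirror images are
never produced; collinear feature sets are rejected as degenerate. The
matching with minimal feature RMSD wins, ties broken by larger matching
and then lexicographic pair order, which makes the result invariant to
the molecule's initial pose.

The packaged reference hypothesis
(`data/reference_hypothesis_synthetic.txt`) is a synthetic stand-in with
the census one H-bond acceptor + three donors + three aromatic rings at
constructed coordinates; receptor-derived excluded volumes are not used.

## CoMSIA similarity fields

For field F and molecule j, the similarity index at grid point q is

    A_F(q) = − Σ_i  w_probe,F · w_i,F · exp(−α r_iq²)

with attenuation α = 0.3 Å⁻², grid spacing 2.0 Å, and an sp³-carbon probe
(radius 1.52 Å, charge +1, unit hydrophobic/donor/acceptor weights).
Atomic weights: vdW radius cubed (steric — the conventional CoMSIA
choice), partial charge (electrostatic), atomic logP increment
(hydrophobic), and 0/1 flags (donor/acceptor). The probe radius is
carried and reported but does not enter the index — the Gaussian form
needs no distance cutoff or singularity protection. The conventional
"30 kcal/mol energy cut-off" of grid-field workflows is honored as a
symmetric clamp of index magnitude at 30 (config-exposed); in practice it
only ever binds for pathological inputs.

The grid is the union bounding box of the training molecules plus a
4.0 Å margin per side. Only non-censored training compounds define the
grid; prediction-time molecules outside the box still get values from
the same formula and are flagged in the log, never rejected.

Descriptor assembly drops columns with standard deviation < 0.01
(config-exposed), mean-centers the rest, and divides each field block by
the square root of its total retained variance so each of the five blocks
contributes equal total variance — the analog of the usual block scaling
(CoMFA-std) for multi-field models. Column provenance (field, grid index)
is kept for contouring and contributions.

## PLS and validation

Single-response PLS is fitted by NIPALS. With one response the weight
vector has the closed form w ∝ X'y, so there is no inner iteration and no
random initialization; components are deterministic and score vectors
mutually orthogonal. Coefficients are reconstructed as B = W(P'W)⁻¹q, so
at full rank the solution equals OLS.

Component count is selected by leave-one-out cross-validation: for every
held-out sample the centering and block scaling are recomputed on the
remainder (the column filter stays fixed) and the model is refit; NIPALS
components are nested, so one maximal fit per held-out sample yields
PRESS for every count. Q²(c) = 1 − PRESS(c)/Σ(y−ȳ)²; the maximizing count
is selected, ties toward fewer components. Default maximum:
min(10, n − 2).

Reported statistics: training R² (coefficient of determination by
default; squared Pearson behind `r2_mode="pearson"`, since published
tables do not always say which was used), LOO Q², external-test
Q² = 1 − Σ(y_test − ŷ)²/Σ(y_test − ȳ_train)², and RMSE. Per-field
contributions are Σ_j |b_j|·sd_j over the field's columns, normalized to
sum to 1.

## Contours and SAR effects

The contoured quantity is STDEV×COEFF (column standard deviation times
PLS coefficient). Favorable/unfavorable regions are the columns at or
above the 80th / at or below the 20th percentile of each field's values
(percentile cutoffs are a declared display convention, config-exposed;
published maps give colors, not levels). Masks are disjoint by
construction and scale-free. Grids export to OpenDX with exact
origin/spacing/counts.

Per-compound SAR-effect labels formalize the qualitative
steric/hydrophobic/donor/acceptor effect tables of this kind of study:
score = (Σ|v| over favorable − Σ|v| over unfavorable)/Σ|v| per field,
labelled POSITIVE above +0.1, NEGATIVE below −0.1, else NEUTRAL.
Electrostatic contours are computed but not classified (the effect tables
carry no electrostatic column). Agreement with any published qualitative
table is illustrative, not a validation criterion.

## Synthetic benchmark

The generator emulates what a curated, aligned congeneric series looks
like to the downstream machinery, without chemical realism: molecules are
property-bearing point clouds sharing a rigid scaffold (10 atoms placed
uniformly in an 8 Å box) and differing only by which substituent fragment
(from a per-site library of 6, one empty, 1–3 atoms each, within 1 Å of
the site) occupies each of 4 attachment sites. Properties follow fixed
distributions: charges N(0, 0.2 e) with neutral fragments, hydrophobicity
N(0, 0.5), donor/acceptor flags Bernoulli(0.15), radii from the packaged
table. Everything is a pure function of the seed.

The discrete fragment structure is deliberate: it gives the descriptor
matrix the low intrinsic dimensionality real aligned series have, which
is what makes cross-validated prediction possible at all. An earlier
design with independently random atom clouds produces descriptor columns
with no correlation structure, and LOO Q² saturates near 0.5 regardless
of model — a useful reminder that PLS-QSAR depends on series coherence,
not just on a linear signal being present.

Activity is a stated sparse linear map: pMIC = 4.0 + Σ c_(F,k)·A_F(k) +
N(0, noise_sd), with the canonical benchmark (n = 60, noise SD 0.1 pMIC,
seed 42, 48/12 split) placing six causal columns on the three
continuous-valued fields (2 steric, 2 hydrophobic, 2 electrostatic),
chosen as each field's highest-variance columns subject to ≥2 grid cells
mutual separation ("distinct pharmacophoric regions"), with |c| = 1/sd so
each contributes about one pMIC unit of spread. Donor/acceptor fields are
left non-causal as negative controls for the contribution ranking; their
single columns are 0/1-flag-driven and too spiky to carry a recoverable
per-column signal at 15 % flag incidence. The intercept 4.0 sits in the
pMIC range implied by µg/mL-scale MICs.

What the benchmark does not emulate: assay heterogeneity and censoring
patterns of real MIC panels, conformational flexibility, chemistry-level
covariance between fields (e.g. donors are also charged), and alignment
error — on real series these inflate noise and depress Q² well below the
benchmark's ~0.99. Passing the benchmark demonstrates correctness of the
machinery, not attainable accuracy on laboratory data.

## Numerical notes

- Support recovery is assessed at grid resolution (a coefficient matches
  the true support if it lands on the same field within one grid cell):
  adjacent 2 Å columns of a Gaussian field are near-collinear, so exact
  single-column identification is not statistically meaningful — the same
  reason the field's display convention contours regions.
- Rank-exhausted NIPALS (‖X'y‖ ~ 0 or degenerate scores) raises rather
  than returning silent zeros; requesting components beyond rank is an
  error.
- Percentiles use linear interpolation (NumPy default); the favorable
  mask takes precedence at a shared threshold so masks stay disjoint.
- All randomness flows through `numpy.random.default_rng` seeded from the
  spec; independent streams are derived as `[seed, k]` so generation and
  noise injection never alias.
- Problem sizes throughout (n = 60 molecules, ~650-point grids, ≤ 10
  components) are chosen so the full analysis and its validation loops
  run in seconds while leaving every code path exercised.
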