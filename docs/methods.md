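# Methods

## Scope and data model

`pfaseval` evaluates predicted protein–PFAS complexes against experimental
(native) ones. Everything operates on a minimal in-memory model: a
`Complex` is one protein plus one ligand as ordered heavy-atom records with
coordinates in nanometres. Hydrogens, waters, monoatomic ions and hetero
groups other than the selected ligand are removed when a file is read;
structure files store Ångström, so coordinates are divided by 10 at the I/O
boundary and nowhere else. PDB and mmCIF are parsed and written through
gemmi (treated as equivalent carriers of the same coordinates), SDF through
RDKit, and PDBQT through a coordinate-only reader that ignores partial
charges and AutoDock atom types. All readers accept gzipped files. When a
residue has alternate locations, the highest-occupancy conformer is kept
(ties broken by altloc identifier, 'A' first). Atom serials are renumbered
sequentially on write; files beyond 99,999 atoms rely on gemmi's hybrid-36
encoding, which the reader also decodes.

## Pocket definition

The binding pocket is the set of protein *backbone* heavy atoms whose
distance to the unweighted centroid of the native ligand's heavy atoms is
at most the cutoff (default 1.0 nm). Two choices deserve note:

- the boundary is **inclusive** (a distance of exactly 1.0 nm is inside);
  at typical float coordinates the choice is immaterial, but it is fixed and
  tested;
- the pocket is anchored on the **native** complex and transferred to
  predictions through the atom correspondence, because the metric judges
  predictions against ground truth; side chains never enter any selection
  or fit.

An empty pocket (ligand far from the protein) produces a warning at
definition time and a hard error in any metric that would consume it.

## Atom correspondence

Predicted files are routinely renumbered and re-chained, so nothing assumes
shared numbering. Protein chains are matched greedily by pairwise alignment
score; residues are paired by global sequence alignment of one-letter codes
(identity scoring, gap open −10, extend −0.5 — conventional values; only
the pairing is consumed, never the score) and backbone atoms by (aligned
residue, atom name). Aligned identity below 90% raises an error, since that
almost always means the files do not describe the same protein. Residues
missing on either side are simply unpaired; pocket metrics report the
fraction of pocket atoms resolved (coverage), and records below 80%
coverage deserve suspicion.

Ligand atoms are paired by `name_order` (atom name when unique and
consistent, file order otherwise) by default. The opt-in `symmetry_min`
mode enumerates element-preserving automorphisms of the ligand bond graph
(from a supplied topology, or perceived from native coordinates by covalent
radii) and keeps the relabelling minimising the ligand-aligned RMSD, so
chemically indistinguishable atoms — the three CF3 fluorines of a
perfluoroalkyl chain, for instance — cannot inflate the metric. The
enumeration is capped (default 10,000 automorphisms) with a documented
fall-back to `name_order`. `name_order` is the default because it matches
what standard trajectory tooling does; `symmetry_min` is reported alongside
when equivalent-atom handling matters.

## Superposition and the four references

All fits are unweighted least squares over heavy atoms (Kabsch, via SVD),
restricted to proper rotations by flipping the smallest singular value when
the raw solution is a reflection. Fewer than three points, or a collinear
set, is a hard error (the rotation would not be unique). The implementation
is cross-checked in the test suite against an independent quaternion
eigenvalue oracle and against mdtraj.

The four references: backbone and pocket RMSDs superpose on the respective
selection and score the same atoms; ligand RMSD superposes ligand-on-ligand
(internal geometry only); and the pocket-aligned ligand RMSD applies the
*pocket* superposition to the predicted ligand and scores it directly,
with no further fitting. Consequences worth keeping in mind: a pure rigid
shift of the ligand reads exactly its magnitude in the pocket-aligned score
while the ligand-fit score stays zero, and for any rigid-ligand
perturbation the fit-free score dominates the fitted one. No mass
weighting anywhere; full precision is kept internally and rounding to
0.01 nm happens only in reporting layers.

Pose ranking is always taken from the producing engine's own order as
listed in the manifest; nothing is re-ranked. `best_of` breaks ties toward
the lower rank.

## PFAS classification

Three structural screens on the molecular graph (RDKit-backed):

- **OECD**: some saturated, non-aromatic carbon bears ≥ 2 fluorines and no
  hydrogen — covers −CF2− and −CF3. Attachment atoms are unrestricted, so a
  CF3 substituent on an aromatic ring counts.
- **EPA −CF2−CF<** (default, stricter reading): such a fully fluorinated
  CF2 carbon is bonded to another saturated carbon bearing ≥ 1 fluorine.
  Every EPA match is therefore an OECD match, and a molecule with a single
  fluorinated carbon (trifluoroacetic acid) matches OECD but not EPA. A
  looser −CF−CF− reading (≥ 1 fluorine on each carbon) is available behind
  `epa_loose=True`; note the EPA⇒OECD implication is only guaranteed under
  the default reading.
- **aromatic fluorine**: F bonded directly to an aromatic carbon.

Chain length is the number of carbons on the longest simple path through
C–C bonds (head carbon included), so the homologous perfluorocarboxylic
acids C7/C8/C9 label as expected and branched or cyclic skeletons are
handled by exhaustive path search (molecules here are small).

The charge category is a deliberate rule model of the pH 7.4 protonation
state, not a pKa predictor: carboxylic, sulfonic, sulfate and phosphonate
centres contribute −1 each; aliphatic amines (not amides, sulfonamides,
anilines) and quaternary ammonium +1 each; unknown groups contribute 0.
The sign of the sum gives {negative, neutral, positive} — the category, not
partial charges, is what downstream grouping consumes. The model refuses pH
values other than 7.4 rather than silently extrapolating. Component-code
resolution uses a small bundled table covering the perfluoroalkyl acids the
package ships examples for; codes whose structures could not be verified
are deliberately absent, and unknown codes raise.

## Curation and the date split

An entry is kept when it has exactly one protein chain, exactly one PFAS
ligand (strict mode), strictly more than 50 residues and no nonstandard
amino acids; every violated rule is reported. Entries flagged as having
failed in a docking engine are representable in the manifest but cannot be
re-derived here. The Before/After split compares the release date with the
2021-09-30 training cutoff; a date exactly on the cutoff counts as Before
(the boundary day is not populated in the bundled benchmark, so the worked
example is insensitive to this choice). Manifests use ISO-8601 dates;
US-style M/D/YYYY is accepted by the date parser for convenience when
transcribing printed tables.

## Statistics

Success = RMSD ≤ 0.2 nm (inclusive) under a stated reference; rates are
percentages. Confidence intervals are percentile bootstrap of the mean of
the 0/1 indicator, 10,000 resamples, 95% by default, fully seeded. For a
binary vector, resampling n observations with replacement and averaging is
*distributionally identical* to drawing Binomial(n, p̂)/n, and the
implementation uses that shortcut (the generic index-resampling path
remains for non-binary input); the test suite verifies 93–97% empirical
coverage for Bernoulli(0.7) at n = 200. Group comparisons use Welch's
unequal-variance t-test on the indicator vectors, with the conventional
star mapping (p < 0.05 / 0.01 / 0.001). Two zero-variance samples are a
degenerate error at the API level; the pipeline records such comparisons as
NaN instead of failing the run.

Top-N success takes, per entry, the minimum of the reference metric over
ranks 1..N (clamped to the available poses); hybrid success takes the
minimum over the union of each method's top-N candidates, excluding entries
that lack poses for any listed method, and the union is not deduplicated
(the minimum is idempotent, so duplicates cannot change the result).

Failure modes apply only to poses that failed the pocket-aligned criterion:
`ligand_structure` when the ligand-fit RMSD also exceeds the threshold,
`pocket_structure` when the pocket RMSD does, `both` when both do, and
`orientation` — residually — when neither does. The categories are
deliberately **non-exclusive** (shares may sum past 100%); orientation is
the only mutually exclusive one.

## Synthetic data: what it emulates and what it does not

The toy protein is a poly-alanine ideal α-helix (backbone atoms only,
0.15 nm rise, 100° turn) — metrics use backbone atoms exclusively, so
side-chain realism would buy nothing. The toy ligand is an all-anti
perfluoroalkyl chain with a carboxylate head: exact 0.154 nm C–C bonds,
exact tetrahedral fluorine placement (so symmetry tests have exact zero
cases), chain length k giving the perfluorocarboxylate composition
C_k F_{2k−1} O_2. The ligand is parked 0.5 nm off the helix axis at its
midpoint, guaranteeing a non-empty 1 nm pocket; the seed rotates only the
azimuthal placement, making every output a pure function of its arguments.

Perturbation modes and their tested contracts:

- `global_rigid` — whole-complex rigid motion; all four metrics ≤ 1e-9 nm.
- `ligand_rigid` — pure ligand translation of magnitude t; pocket-aligned
  score reads exactly t, ligand-fit score 0.
- `ligand_internal` — torsion kick of the stated angle about a random
  internal C–C bond (bond lengths and angles untouched); ligand RMSD > 0,
  protein metrics 0. `n_kicks` compounds kicks over distinct bonds.
- `pocket_noise` — iid Gaussian noise on pocket backbone atoms; pocket
  RMSD > 0 (≈ σ√3 for large pockets, since the 6-DOF fit absorbs
  vanishingly little), ligand-fit RMSD 0.

Two empirical facts shape the *failure cohort* generator. First, iid pocket
noise is unbiased, so the pocket superposition stays centred on the truth
and the unperturbed ligand still maps correctly — the pose usually
*succeeds* under the pocket-aligned reference despite a bad pocket metric;
a genuine pocket-structure failure therefore combines pocket noise with a
rigid ligand shift. Second, one torsion kick on a nearly linear
perfluoroalkyl chain cannot move its fitted ligand RMSD past 0.2 nm (the
kick axis almost coincides with the chain), so ligand-structure failures
compound five kicks on distinct bonds. Default failure magnitudes are
0.5 nm (shift), 150° × 5 kicks, and σ = 0.35 nm + 0.35 nm shift. Each
cohort member is guaranteed to realise its drawn mode (perturbation seeds
are redrawn within the mode in the rare borderline cases, which cannot
distort the mode mixture itself).

Synthetic evaluation tables draw each pose's success independently with the
split's probability; real predictors produce correlated poses within a
system, so synthetic Top-5 rates sit higher relative to Best-Pose rates
than real ones. Quantitative recovery tests therefore use Best-Pose rates;
monotonicity and dominance properties are unaffected. Passing tests on
synthetic data demonstrate the correctness of the metrics and statistics,
not the accuracy of any docking method on real complexes.

## Bundled benchmark example

The package ships an 18-complex table of experimentally solved
protein–PFAS systems carrying the EPA −CF2−CF− motif: entry and ligand
identifiers, release dates, and published per-complex RMSDs for two
prediction methods under the four references. It drives the worked
examples: splitting its release dates at the 2021-09-30 cutoff yields
13 Before / 5 After, and its pocket-aligned column gives a 66.7% (12/18)
success rate at 0.2 nm. `scripts/acceptance.py` recomputes these counts,
plus the C8 chain-length classification of perfluorooctanoic acid, from
scratch at every run.

## Problem sizes and numerical choices

Test simulations use 20-residue helices (125 for the σ√3 scaling check,
which needs a 500-atom selection), 300-member failure cohorts and
1000-per-split synthetic cohorts — sizes at which every statistical
check resolves its target comfortably while the whole suite runs in well
under a minute of compute-heavy time. Tolerances: rigid-motion identities
at 1e-9 nm (accumulated float error), oracle agreement at 1e-8, file round
trips at 1e-4 nm (PDB prints three decimals in Å). Bootstrap seeds default
to 20250826 and are recorded in every summary row and run log.

## Known limitations

- No structure repair, protonation or minimisation; inputs are taken as
  given (the cleaning step only removes, never builds).
- The charge model is a pH-7.4 rule table; molecules dominated by groups
  outside it (phenols, imidazoles, N-oxides…) will default to neutral.
- Bond perception for `symmetry_min` topology uses covalent radii on
  near-ideal geometry; heavily distorted ligands should supply an explicit
  topology.
- The PDBQT reader handles coordinates of the first MODEL only.
- Sequence-based correspondence assumes standard residue naming; exotic
  modified residues pair only when both sides name them identically.
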