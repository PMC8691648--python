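# Methods

`cadherlink` analyzes the extracellular machinery of intermicrovillar-link
cadherins (PCDH24/CDHR5-class protocadherins and their relatives): how
their ectodomains decompose into EC repeats, how much calcium each
inter-repeat linker can bind, how conserved each repeat is across species,
how large crystal-contact interfaces are, how long the resulting adhesive
links can be, how strongly the two partners bind, and how much their
ectodomain fragments aggregate beads. This note documents the models,
parameter choices and idealizations behind each stage.

## Sequence annotation

**Coordinate convention.** All sequences are *processed* proteins: residue
1 is the first mature residue after signal-peptide cleavage. The package
never predicts cleavage sites; callers strip signal peptides upstream.

**EC-repeat segmentation.** Cadherin EC repeats are ~100-residue β-sandwich
domains whose C-terminal ends carry the calcium-binding boundary motif of
the DXNDN class. Segmentation is a greedy N→C scan for boundary matches,
placing each repeat boundary on the last residue of the match — the same
convention used to truncate expression constructs "at DXNDN or similar
ends". Candidate repeats are accepted when their length falls in
[60, 130] residues (the typical range is 80–130; the wider floor tolerates
short engineered repeats). When the caller supplies an expected repeat
count and the strict scan disagrees, the scan retries once admitting
DXPDL-class boundary variants before raising `UnsegmentableSequence`.
The retry order (strict, then variant, then error) is fixed and
deterministic.

**Linker motif grammar.** The canonical inter-repeat linker motif is

    NTerm – XEX – DXD – D(R/Y)(D/E) – XDX – DXNDN – CTerm

with element patterns `x[DE]x`, `[DE]x[DE]`, `[DE][RY][DE]`, `x[DE]x`,
`[DE]xN[DE][NS]`, and the boundary variant DXPDL = `[DE]xP[DE]x`.
Aspartate/glutamate interchange is permitted throughout because both occur
at these positions in real linkers; strictness lives in the classification
logic, not the patterns. The ambiguity code `X` never satisfies an
acidic-required position.

Element matching selects an N→C ordered, non-overlapping chain of one
match per element by dynamic programming, maximizing the number of matched
elements. Ties are broken toward matching the more C-terminal elements
(the boundary motif is the most reliable anchor, and site 1 is the element
most often degenerate in nature), then toward earlier positions. A naive
first-occurrence scan was rejected because a decoy acidic triplet upstream
can consume an element slot and misclassify the window.

Classification and predicted calcium stoichiometry:

| class | condition | Ca²⁺ |
|---|---|---|
| canonical | all five elements, strict DXNDN | 3 |
| noncanonical | only site-1 (XEX/DXE) degenerate and/or DXNDN degraded to DXPDL (backbone-carbonyl site 3) | 2 |
| degenerate | two or more elements fail | 1 if ≥3 elements still match, else 0 |

The degenerate-count rule (≥3 surviving elements → 1 ion) is the package's
own choice for a case where only an upper bound (≤1) is established; it is
monotone under single-residue degradation, which the test suite checks as
a property. The classifier is sequence-only: a junction whose motif is
conserved but whose crystal shows an unoccupied site (as happens for the
mouse ortholog's tip site 0) is still reported by motif presence.

**Site 0.** The tip calcium site of Cr-2 protocadherin EC1 requires three
elements: N at position 1 exactly, a DXDXD (`[DE].[DE].[DE]`) match fully
inside residues 25–45, and a top XDX (`.[DE].`) inside residues 70–95.
The windows are centered on the published human positions (32–36, ~80)
with roughly ±10 residues of tolerance.

**Features.** N-glycosylation sequons are N-X-[S/T] with X ∉ {P, X};
disulfide candidates are cysteine pairs within one repeat separated by
40–90 residues (the A/F-strand spacing of the known EC1 bridges). Both are
heuristics over the processed sequence, not structure-aware predictions.

## Conservation

Pairwise alignment is global Needleman–Wunsch with affine gaps (Gotoh
recurrences) under BLOSUM62, gap open 10, gap extend 0.5 (a gap of length
L costs 10 + (L−1)·0.5). These are common defaults; the upstream tools the
field uses do not publish their parameters. Traceback ties break
diagonal > up > left, so every alignment is deterministic. The aligner is
profile-capable: a sequence is a one-row profile, and profile–profile
column scores are the mean substitution score over non-gap residue pairs.
Its optimal scores are verified in the tests against exhaustive path
enumeration (length ≤ 6) and against an independent aligner implementation.

Percent identity supports three normalizations, because published identity
figures rarely state theirs: `aligned_columns` (default; internal gap
columns count, terminal-overhang columns are excluded),
`shorter_sequence`, and `full_alignment`. Per-repeat profiles average all
species-pair identities at each repeat index and also report the grand
mean across repeats.

The MSA is progressive: a UPGMA guide tree on pairwise identity distances
(100 − %id; scipy average-linkage, sequences pre-sorted by id for
deterministic tie behavior), then profile–profile merges in tree order.
Conservation scores are per-column modal-residue fractions (denominator =
number of rows) at every non-gap reference column, binned linearly into
grades 1–9. This is an intentionally simple analog of Bayesian
evolutionary-rate grading: it captures column variability, not rate
heterogeneity, and the grade scale is equal-width bins over [0, 1].

## Structure analysis

**SASA.** Shrake–Rupley sampling with probe radius 1.4 Å and 960
quasi-uniform points per atom (golden-spiral construction; neighbor
culling via a k-d tree). Van der Waals radii are Bondi values shipped in
`VDW_RADII` (C 1.70, N 1.55, O 1.52, S 1.80, Ca²⁺ 2.31; default 1.80 Å for
unlisted elements); toy sphere atoms may override their radius per atom.
The sampler is validated against the closed-form two-overlapping-sphere
cap formulas (≤1% at 960 points) and against an independent Shrake–Rupley
implementation; doubling the point count moves toy-fixture areas by
<0.5%.

**Interfaces.** Buried area follows the PISA convention:
(SASA_A + SASA_B − SASA_AB)/2. Interfaces larger than the empirical
856 Å² threshold are flagged biologically relevant; residues losing >30%
of their isolated-chain SASA are interface residues. Waters, metal ions
and glycans are excluded from interface SASA by default (glycans are
discussed in this system as potential interference, not interface
contributors; a flag includes them). Because the original interface-area
tool and probe settings for the deposited structures are unpublished,
areas computed on them should be compared at ±5%.

**Symmetry expansion.** Space-group operators from the CRYST1 header
(via gemmi) combined with lattice translations in −1..1 on each axis;
mates are kept when any atom lies within 5 Å (configurable) of the input
model, the identity image is excluded, and duplicates are removed by
operator + translation identity.

**Superposition.** Kabsch least-squares rigid superposition (SVD with
determinant correction, so the rotation is always proper). Chains are
paired by residue number and atom name over main-chain atoms
(N, CA, C, O) by default, with a CA-only option, since published RMSDs do
not always state which convention they used.

**Metal sites and disulfides.** Calcium (or other metal) ions are reported
with all protein oxygen atoms within 3.0 Å; ions are attributed to an
inter-repeat linker by proximity (≤8 Å) to the junction's residue span.
Disulfides are SG–SG pairs within 2.3 Å.

**Orientation projections.** Domain axes are the leading eigenvectors of
the coordinate covariance. The reference domain's longest axis is rotated
to +z and the partner's longest axis is reported as its (x, y) projection;
because principal axes are direction-ambiguous, the partner axis sign is
fixed so its z-component is non-negative.

## Link geometry

The intermicrovillar link is modeled as two rigid tandem-domain ectodomains
joined tip-to-tip, 4.5 nm per domain (EC repeats plus the membrane-adjacent
domain counted as one more unit; mucin-like insertions excluded — the model
describes the shortest isoforms). Length = (n_a + n_b − overlap)·d, with
`overlap_for_length` the exact inverse (fractional overlaps permitted).
Unequal per-domain lengths are supported by removing the overlap at the
mean domain length — an extension beyond the uniform arithmetic, documented
here because the uniform case is the one with published anchors (90 nm for
a 10+10 homophilic link, 36 nm for 4+4, 63 nm for 10+4, ~48 nm observed
implying ~3 overlapping domains). Bending at linkers is not modeled; an
observed shortening is attributed entirely to overlap.

## Binding kinetics

1:1 Langmuir model with closed-form phases:
R(t) = R_eq(1 − e^{−(k_on C + k_off)t}) during association with
R_eq = R_max C/(C + K_D), and R(t′) = R₀e^{−k_off t′} during dissociation;
K_D = k_off/k_on. The closed forms are cross-checked against direct ODE
integration in the tests. Fitting is global nonlinear least squares over
all injections sharing (k_on, k_off, R_max), on log-parameters
(Levenberg–Marquardt). Initialization: k_off from a log-linear fit of the
highest-concentration dissociation tail; k_on from the slope of k_obs
versus C (k_obs estimated from plateau half-rise times); R_max from the
largest plateau scaled by its estimated fractional saturation.

Outlier injections — ones whose signal sits higher or lower than the
series predicts — are excluded and reported, never dropped silently: an
injection is flagged when its individually fitted plateau deviates from
the global prediction by >3× the robust (1.4826·MAD) cross-injection
deviation spread, centered on the median deviation because a genuine
outlier biases the global fit and shifts every deviation by a common
offset. Mass transport, bivalent analytes and heterogeneous surfaces are
not modeled. The default simulated design mirrors the published
experiment: seven injections spanning 2–23.5 μM against a surface with
K_D = 16 μM (k_on 10⁴ M⁻¹s⁻¹, k_off 0.16 s⁻¹), 120 s association, 180 s
dissociation, 1 Hz sampling.

## Bead quantification

Images are thresholded to exclude background (Otsu by default, or a fixed
value — published aggregation assays rarely report their exact threshold),
aggregates are 8-connected components, components under 4 px are
discarded, and areas are reported in pixels. Replicate statistics follow
the assay's reporting convention: per-biological-replicate mean aggregate
area, then mean of means, SD and SEM (= SD/√n) across replicates. A
single replicate reports SEM 0 with an explicit warning. No significance
testing is performed between calcium/EDTA conditions; the assay's own
reporting is descriptive.

## Synthetic data: what it emulates and what it does not

The family generator builds an ancestor whose junctions carry designed
25-residue motif cassettes (canonical `IEL…DAD…DRE…LDV…DVNDN`,
noncanonical `SYN…DAD…DRE…LDV…DMPDL`, degenerate all-inert), then mutates
descendants at a per-site substitution rate with uniform replacement.
Three idealizations make ground truth exact rather than probabilistic:

* unconstrained positions draw from a 15-letter alphabet excluding
  D, E, N, P and C, so no spurious boundary motifs, linker elements,
  sequons or cysteines can arise;
* cassettes, seeded sequons/disulfides/site-0 elements, and designated
  invariant sites are protected absolutely (rate 0);
* there are no insertions or deletions, so positional identity equals
  alignment identity.

Consequently, passing round-trip tests demonstrates correctness of the
segmentation/classification logic under the motif grammar — not robustness
to indels, compositional bias, or genuinely degenerate boundaries in real
ectodomains, where the expected-repeat retry and manual inspection matter.
The substitution model is non-phylogenetic (star topology from the
ancestor); identity levels, not tree structure, are the controlled
quantity. Toy structures are sphere-atom chains with closed-form
SASA/interface oracles; they validate the geometry code, not force-field
realism. Bead fields render non-overlapping disks by rejection sampling
with recorded pixel areas; real micrographs add uneven illumination and
touching aggregates, which the connectivity rule merges by design.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is reproducible bit-for-bit under a fixed seed.
* CSV outputs round floats to 6 significant digits so pipeline reruns are
  byte-identical; JSON keeps full precision.
* Alignment and chain-selection tie-breaks are fixed as described above;
  UPGMA input order is lexicographic in sequence ids.
* Degenerate inputs raise typed errors (`UnsegmentableSequence`,
  `WindowTooShort`, `NoAtoms`, `PairingMismatch`, `DegenerateGeometry`,
  `FitDivergence`, …) rather than returning sentinel values.
* Problem sizes in the test and acceptance workloads (3-repeat families,
  ≤6 species, 100-family segmentation sweeps, 960-point SASA on toy
  spheres, 20 seeded kinetic replicates) were chosen so the full suite
  completes in well under a minute of CPU while still exercising every
  code path at the study's stated experimental conditions.

## Known limitations

* The linker classifier cannot see structural occupancy; motif-conserved
  but empty sites are reported present.
* Conservation grades are modal fractions, not evolutionary rates; they
  will overstate conservation in families with few, closely related
  species.
* Interface areas on deposited crystal structures depend on radii/probe
  conventions that differ between tools by a few percent; comparisons
  should allow ±5%.
* The SPR fit reports a point estimate; the published ±0.05 μM is a
  fit-reported uncertainty whose convention is unknown and is not
  reproduced.
* The link-length model treats domains as rigid and collinear; bending at
  linkers shortens real links in a way this arithmetic attributes to
  overlap.
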