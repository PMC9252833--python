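# Methods

## Contact definition

Two residues are *in contact* when the Euclidean distance between their two
closest heavy atoms (any atoms that are not hydrogen or deuterium) is
strictly below a cutoff. A pair at exactly the cutoff is not a contact. The
default cutoff is 5.0 Å; 8.0 Å is a common choice for coarser
protein–nucleic-acid interface surveys, and any positive value can be set.
The distance map is the same residue-pair matrix with the continuous minimal
distances; the contact map is its boolean thresholding.

Intramolecular maps are square and symmetric; the diagonal is defined as
0 Å and is never a contact (a residue is not in contact with itself). The
sequence-separation filter takes an integer *n* and removes intramolecular
pairs whose chain ordinals differ by at most *n*. Ordinals follow file
order, not author numbering, so numbering gaps and insertion codes cannot
corrupt the filter; it is applied across chain breaks that share a chain id.
The filter never applies to intermolecular maps.

The vectorized implementation (all-atom `cdist` followed by a segmented
minimum over residue blocks) is pinned by tests to be bit-identical to the
exhaustive double loop on fixtures up to 50 residues, and distances are
rigid-motion invariant to 1e-9 Å.

## Structure model

PDB input is parsed (via gemmi) into an explicit model → chain → residue →
atom hierarchy. Hydrogens are retained and flagged non-heavy — they never
enter the contact definition but sharpen hydrogen-bond detection when
present. Waters are excluded by default; a flag includes them. Alternate
locations are resolved by policy, default `highest_occupancy` with ties
broken toward the earlier altloc letter; single-conformer maps are the norm.
Blank element columns are inferred from atom names. Chains are classified by
majority residue kind (protein / RNA / DNA), with `hybrid` when amino acids
and nucleotides each make up at least 20% of the chain.

Biological assemblies are rebuilt from the REMARK 350 BIOMT operators:
each operator produces rigid copies of its target chains with deterministic
derived ids (original id + operator ordinal); the identity operator keeps
the bare id. Copies that coincide with existing chains are kept — no
deduplication is attempted. Rigidity (intra-chain distances preserved to
1e-6 Å) is a tested invariant. Multi-model files are analysed per model; no
contact-probability averaging is offered.

## Interaction classification

Contacts are multivalent: each carries a *set* of labels, and a filter by
one label returns the subset whose set contains it.

**Hydropathy** (proteins only). The 20 standard amino acids partition into
hydrophobic Φ = {Gly, Ala, Leu, Ile, Val, Pro, Phe}, amphipathic
γ = {Trp, Tyr, Met, Lys}, and hydrophilic ζ = {Arg, Asn, Asp, Gln, Glu,
His, Ser, Thr, Cys} (a Kyte–Doolittle-derived three-class scheme).
Same-class pairs are labelled with the class; mixed pairs get
`mixed-hydropathy`, so the "hydrophobic" filter selects exactly the Φ–Φ
pairs (hydrophobic-core usage).

**Electrostatics.** Each residue hosts zero or more charge groups:
cations (Arg guanidinium, Lys NZ, His imidazole, protein N-terminal amine),
anions (Asp/Glu carboxylates, C-terminal carboxylate when OXT is present,
nucleotide phosphate P/OP1/OP2) and dipoles (uncharged polar side chains:
Ser OG, Thr OG1, Asn/Gln amides, Tyr OH, Cys SG, Trp NE1; nucleobase polar
N/O atoms as one group per base). The representative point is the centroid
of the member atoms present. Among group pairs within `max_group_dist`
(default 5.0 Å — salt bridges are often defined at ≤ 4 Å; we match the map
cutoff and report the distance), the highest-precedence label wins:
ion-ion > ion-dipole > dipole-dipole. Only attractive pairings are
labelled: like-charge proximity (cation–cation, anion–anion) gets no
electrostatic label, consistent with the filter's role of flagging
stabilizing interactions. His is treated as cationic for ion labels *and*
aromatic for π labels simultaneously (its protonation state is unknowable
without hydrogens); this deliberate double counting is consistent with
multivalent labels. Backbone carbonyl dipoles are not used — dipole groups
are side-chain/base only.

**π-electron interactions.** Ring centroids are atom means; normals are
best-fit plane normals (smallest singular vector of the centered ring
coordinates). Trp and the purines contribute two rings each. π–π requires
centroid distance ≤ `d_pipi` = 5.5 Å and normals parallel (≤ `a_par` = 30°)
or T-shaped (within `a_perp` = 30° of 90°). cation-π / anion-π / dipole-π
require a charge-group point within `d_x` = 6.0 Å of a ring centroid and
within `a_axial` = 45° of the ring normal axis — a group in the ring plane
never qualifies. All thresholds are config keys
(`molcontact.config.InteractionThresholds`); tests pin the defaults.

**Hydrogen bonds.** A geometric detector over per-residue donor/acceptor
heavy-atom tables (backbone N donor except Pro, backbone O acceptor; the
usual side-chain and nucleotide donors/acceptors including phosphate and
sugar oxygens). A pair qualifies at donor–acceptor distance ≤ 3.5 Å; when a
hydrogen attached to the donor (≤ 1.25 Å) exists, the D–H···A angle must
also be ≥ 120°. Intra-residue pairs are excluded. This is an in-house
geometric criterion, not a replication of any external H-bond program.

## Per-residue 1D tracks

All tracks align to chain ordinals after water removal.

- **Composition**: one-letter codes plus a chain-level frequency table.
- **Properties**: hydropathy class (Φ/γ/ζ); charge (+ for Arg/Lys/His,
  − for Asp/Glu, 0 otherwise); hydrophobic flag (Φ membership).
- **Secondary structure** (H/E/C): a deliberately simple backbone-pattern
  assignment. H where ≥ 4 consecutive residues satisfy the i→i+4 backbone
  O···N ≤ 3.5 Å pattern (the run plus its four capped partners is marked);
  E where a residue has ≥ 2 O···N pattern partners at separation > 4 or on
  another chain; C otherwise, including residues missing backbone atoms.
  It reproduces ideal geometries exactly and is *not* a DSSP/STRIDE
  replacement — on real structures with distorted or bifurcated hydrogen
  bonds it will under-assign relative to those programs.
- **Solvent accessibility**: Shrake–Rupley sphere sampling with a
  deterministic golden-spiral lattice, probe 1.4 Å, 960 points/atom,
  Bondi-style radii (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å; unknown
  elements 1.8 Å with a warning). Per-atom areas sum exactly to per-residue
  values. Relative accessibility divides by Gly-X-Gly theoretical maxima
  (Tien et al. 2013); both absolute and relative are exported. At 960
  points an isolated atom is within 1% of 4π(r+probe)².
- **Shannon entropy**: computed from the sequence itself as a sliding
  window (default 9, must be odd) of residue-type frequencies,
  −Σ p·log₂p, truncated at the termini. This is an explicit
  interpretation — no multiple-sequence alignment enters the workflow, so
  the track measures local sequence complexity, not evolutionary
  conservation.
- **Donor/acceptor counts**: per residue, hydrogen bonds donated and
  accepted; each bond contributes exactly once to each side.

## Chain interaction graph

Nodes are chains (with polymer type and length); an undirected edge weight
is the number of intermolecular residue pairs in contact at the cutoff
(the same default 5.0 Å as the maps), counting residue pairs once — not
atom pairs. Zero-weight pairs are omitted; intramolecular contacts never
form edges. The sum of edge weights equals the total intermolecular contact
count by construction, and tests cross-check it against the contact lists.

## Synthetic fixtures

The fixture generator emits small PDB texts whose advertised geometry is
exact to 1e-3 Å: a dipeptide at a chosen minimal distance, an Arg–Asp salt
bridge (NH1···OD1 = 2.80 Å, bidentate), parallel (3.8 Å) and T-shaped
(4.8 Å, 90°) Phe stacks, axial and in-plane Lys–Phe probes, an ideal
α-helix (φ = −57°, ψ = −47°, built from ideal internal coordinates by
natural-extension-of-reference-frame placement), a designed antiparallel
sheet pair (inter-strand O···N = 2.77 Å), a k-chain protein ring threaded
by an RNA strand (adjacent chains share 3 contacts, each chain touches one
RNA residue, non-adjacent chains are > 5 Å apart everywhere), a two-model
file related by a rigid shift, and a single chain with k-fold BIOMT
operators. These fixtures exercise the exact decision boundaries of the
classifiers; they do not emulate thermal noise, missing atoms, alternate
conformers in bulk, or the dense packing of real structures — passing tests
demonstrate correctness of the geometric criteria, not classifier accuracy
on crystallographic data.

## Numerical choices and degenerate inputs

Distance ties for the closest-atom pair break toward the lexicographically
smallest atom-name pair. Ring normals are defined up to sign; all angle
comparisons use the acute equivalent. Rotation matrices from headers are
validated orthonormal to 1e-4. Residues with no heavy atoms are an error
wherever a distance is requested; rings missing more than one atom are
skipped with a warning. Empty or garbled PDB input raises a parse error
naming the first offending line; models disagreeing on chain ids are
truncated to the common set with a recorded warning.

## Problem sizes

Tests and the acceptance script run on chains of 3–50 residues, 11-chain
assemblies, and 960-point SASA lattices — sizes at which the exhaustive
oracles (double-loop distances, hand pattern enumeration, closed-form
sphere areas) are exact and fast. The library itself has no size-dependent
switches; larger structures simply take proportionally longer.

## Known limitations

No structure repair, no mmCIF, no network fetching in the library, no
Cα-only map variants, no energetic scoring or pKa prediction, no
contact-probability averaging over models, and the secondary-structure and
entropy tracks are the simplified stand-ins described above.
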