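# molcontact

Heavy-atom contact maps and interaction analysis for biomolecular
structures — proteins, RNA and DNA, alone or in complex.

Structural biologists routinely ask which residues touch which: inside a
fold (secondary-structure packing, hydrophobic cores), across an interface
(protein–protein, protein–nucleic-acid), and *why* — is a contact a salt
bridge, a hydrogen bond, a π-stack? `molcontact` answers these questions
from a plain PDB file and writes machine-readable tables instead of
pictures, so the results can feed any downstream plot or statistic.

## The model

For residues *i*, *j* with heavy-atom sets $A_i$, $A_j$ (heavy = not
hydrogen), the inter-residue distance is

$$d(i,j) = \min_{a \in A_i,\; b \in A_j} \lVert x_a - x_b \rVert$$

and the contact map at cutoff $c$ is $\mathrm{CM}_{ij} = [\,d(i,j) < c\,]$
(strict inequality; default $c = 5.0$ Å). Intramolecular maps support a
sequence-separation filter that drops pairs with ordinal separation
$\le n$. Each contact then receives a *set* of physicochemical labels
(contacts are multivalent):

- **hydropathy** pairing over the three-class amino-acid partition
  Φ (hydrophobic: Gly, Ala, Leu, Ile, Val, Pro, Phe),
  γ (amphipathic: Trp, Tyr, Met, Lys),
  ζ (hydrophilic: Arg, Asn, Asp, Gln, Glu, His, Ser, Thr, Cys);
- **electrostatics**: ion-ion > ion-dipole > dipole-dipole between
  charge groups (guanidinium, ammonium, imidazole, carboxylates,
  phosphates, polar side chains, nucleobase polar atoms);
- **π interactions**: π–π (parallel or T-shaped ring stacks), cation-π,
  anion-π, dipole-π (group on the ring axis);
- **hydrogen bonds**: donor–acceptor distance ≤ 3.5 Å, plus a
  D–H···A angle ≥ 120° when hydrogens are present.

Per-residue 1D tracks (composition, charge, hydropathy, three-state
secondary structure, Shrake–Rupley solvent accessibility, sliding-window
Shannon entropy, H-bond donor/acceptor counts) annotate the map axes, and a
chain-level graph summarizes every interface: nodes are chains, edge
weights are intermolecular contact counts — the data behind a chord
diagram. Biological assemblies are rebuilt from REMARK 350 BIOMT operators.
See `docs/methods.md` for every threshold and its rationale.

## Worked example

The package ships a fixture generator, so the example needs no downloads.
Build an Arg–Asp salt bridge and analyse it:

```sh
molcontact fixture salt_bridge --out bridge.pdb
molcontact map bridge.pdb --filter electrostatics --out results
cat results/contacts.tsv
```

```
chain_a	resnum_a	icode_a	resname_a	chain_b	resnum_b	icode_b	resname_b	min_dist_A	atom_a	atom_b	labels
B	1	.	ASP	A	1	.	ARG	2.800	OD1	NH1	hbond;hydrophilic;ion-ion
```

One contact: Asp OD1 to Arg NH1 at 2.800 Å. The label set shows
multivalence — the pair is simultaneously a salt bridge (`ion-ion`:
carboxylate and guanidinium centroids within 5 Å), a hydrogen bond
(`hbond`: D–A 2.80 Å ≤ 3.5 Å) and a hydrophilic ζ–ζ pair. The same result
from Python:

```python
from molcontact import *

st = parse_pdb(make_fixture("salt_bridge"))
a, b = st.model()
contacts = label_contacts(contact_list(contact_map(distance_matrix(a, b), 5.0)), [a, b])
for c in contacts:
    print(c.res_a.label, c.res_b.label, f"{c.min_dist:.3f}", sorted(c.labels))
# B/ASP1 A/ARG1 2.800 ['hbond', 'hydrophilic', 'ion-ion']
```

A multi-chain example — an 11-chain protein ring threaded by an RNA strand
(the topology of a TRAP–RNA complex):

```sh
molcontact fixture ring_assembly --param k=11 --out ring.pdb
molcontact diagram ring.pdb
```

The JSON graph lists 11 protein nodes and one RNA node; every protein chain
carries two protein edges (its ring neighbours) and one RNA edge, so the
diagram renders as a closed ring with the RNA connected to all chains.

Other verbs: `molcontact features` writes per-residue track TSVs;
`molcontact fixture --help` lists all fixture kinds (helices, sheets,
π-stacks, multi-model files, BIOMT assemblies).

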