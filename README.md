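# ffinet

A force-field-inspired graph attention network for molecular property
prediction. Nodes aggregate messages from 1-, 2- and 3-hop neighbours along
the bonded graph; each path's attention score is computed from an embedding
basis extracted from the functional forms of the OPLS force-field energy
terms (bond: `{r, r²}`; angle: `{θ, θ²}`; torsion:
`{cos kφ, sin kφ, k=1..3}`; nonbonded: `{r⁻¹, r⁻¹², r⁻⁶}`), and axial
attention arbitrates between the three hop outputs per node. A
protein–ligand extension merges pocket and ligand graphs and adds typed
intermolecular nonbonded edges below a 5 Å cutoff.

The network is implemented on NumPy with
[`autograd`](https://github.com/HIPS/autograd) (custom differentiable
segment reductions) — no deep-learning framework required. RDKit handles
all chemistry and structure I/O.

## Layout

| module | role |
|---|---|
| `ffinet.molio` | SMILES tables, seeded ETKDG conformers, atom featurization, SDF/PDB/mol2 I/O |
| `ffinet.khop` | directed 1/2/3-hop simple-path indexes (+ independent enumeration oracle) |
| `ffinet.geometry` | distances / angles / signed dihedrals, basis expansion, standardisation |
| `ffinet.model` | embedding, positional encoding, k-hop + axial attention, readout, MLP head, interpretation (atom contributions, attention maps, node similarity) |
| `ffinet.complexes` | protein–ligand complex graphs, PDBBind-style directory reader |
| `ffinet.train` | 8:1:1 splits, Adam + early stopping, RMSE/MAE/R/SD/ROC-AUC metrics |
| `ffinet.synthdata` | synthetic molecules + geometry-dependent pseudo-energy targets |

## CLI

```bash
ffinet train --config cfg.yaml --checkpoint model.npz --metrics-out metrics.json
ffinet eval --checkpoint model.npz --data mols.csv --label-columns y
ffinet featurize --data mols.csv --output descriptors.tsv
ffinet explain --checkpoint model.npz --smiles "CCCO" --target-atom 1 --layer 0 --head 0
```

Example config:

```yaml
data:
  synthetic: {n_molecules: 200, seed: 0, noise_sd: 0.05}   # or path/smiles_column/label_columns
model: {hidden_dim: 64, n_heads: 4, n_layers: 2}
train: {batch_size: 128, learning_rate: 1.0e-3, max_epochs: 100, patience: 30, seed: 0}
```

Ablations are configuration switches: `use_hops: [1]` (1-hop only),
`use_hops: [1, 2]` (no 3-hop), `use_axial: false` (sum hop outputs instead
of axial attention).

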