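# sgatt

Molecular property prediction from two fused views of a molecule:

- a **knowledge-augmented molecular graph** — the RDKit graph extended with
  virtual nodes for discretised element properties (period, metallicity,
  group, radius group, weight group; one directed edge per property into
  each atom) and for matched functional-group substructures — encoded by a
  dual-channel attention message-passing network (GAT-style coefficients,
  GRU node updates, Set2Set readout);
- the **SMILES string itself**, segmented into frequent consecutive
  subsequences mined from the training corpus (BPE-style adjacent-pair
  merging that never splits an element symbol) and encoded by a
  transformer.

The two representations are combined by cross-attention (queries from the
token states, keys/values from the graph embedding) and decoded by a
three-layer feed-forward network into per-task predictions — multi-task
masked binary classification or regression (RMSE loss).

Everything runs on NumPy: the package ships a small reverse-mode autodiff
engine (`sgatt.autodiff`, `sgatt.nn`) with the transformer, GRU/LSTM cells,
Set2Set pooling and Adam implemented on top of it, so there is no deep
learning framework dependency.

## Package layout

| module           | role                                                        |
|------------------|-------------------------------------------------------------|
| `sgatt.molio`    | SMILES → molecular graphs; CSV dataset I/O                  |
| `sgatt.knowledge`| element-property triples, SMARTS groups, graph augmentation |
| `sgatt.fcs`      | subsequence vocabulary mining + greedy tokenization         |
| `sgatt.seqenc`   | transformer sequence encoder                                |
| `sgatt.ampnn`    | dual-channel attention MPNN + Set2Set readout               |
| `sgatt.fusion`   | cross-attention fusion, decoder, losses                     |
| `sgatt.model`    | full model assembly, featurisation, ablation wiring         |
| `sgatt.train`    | scaffold/random splits, training loop, metrics, embeddings  |
| `sgatt.fixtures` | synthetic labelled SMILES datasets for testing              |
| `sgatt.autodiff`, `sgatt.nn` | NumPy autodiff engine and layers                |

## CLI

```bash
# synthetic dataset (label = hydroxyl presence)
sgatt make-fixtures --out data.csv --n 200 --seed 0

# train (defaults in configs/default.yaml; ablations via `ablation: no_graph|no_sequence`)
sgatt train --config configs/default.yaml --data data.csv --out run/

# predict / embeddings / inspection
sgatt predict --checkpoint run/checkpoint --smiles-file in.txt
sgatt embed --checkpoint run/checkpoint --smiles-file in.txt --out emb.csv
sgatt augment --smiles "CCO"          # knowledge-augmented graph as JSON
sgatt tokenize --smiles "CCOc1ccccc1" # FCS segmentation
sgatt tune --data data.csv --trials 8 # random hyperparameter search
```

Training mines the token vocabulary on the training split, builds the
knowledge base from the bundled periodic-table CSV
(`src/sgatt/data/periodic_table.csv`) and functional-group SMARTS table
(`src/sgatt/data/functional_groups.tsv`), runs Adam with early stopping on
the validation metric, and aggregates test ROC-AUC (or RMSE/MAE) over the
configured seeds.

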