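# helixcontact

Inter-helical residue contact prediction for α-helical transmembrane
proteins from structure-derived geometric features.

Given an atomic structure (PDB format) and a transmembrane-helix annotation,
the package enumerates inter-helical candidate residue pairs
(|i−j| > 5, distinct helices), labels contacts by the strict 5.5 Å
minimum-heavy-atom-distance rule, and builds one of two feature
representations over the 3×3 sequence neighborhood of each pair
(center excluded):

* **SDF** (length 40): inter-helical tilt angle, mean / SD of all
  heavy-atom pair distances, Cα–Cα distance, and the angle between the
  residue-plane normals — five rigid-motion-invariant numbers per window
  position.
* **CF** (length 192): raw x, y, z of N, Cα, O, Cβ for both residues per
  window position — a deliberately frame-dependent baseline.

A six-hidden-layer leaky-ReLU network (Adam, binary cross-entropy,
Xavier-uniform init, gradients clipped to [−1, 1]; SDF inputs pass through a
frozen 40→192 linear projection) is trained on features from experimentally
determined structures and applied to features from predicted (noisy)
structures, improving on the contact maps implied directly by the predicted
coordinates. Evaluation is per sequence: trapezoidal AUC-ROC, average
precision (degenerating to precision×recall for binary annotations), and
top-L/L2/L5/L10 precision/recall, aggregated by sequence-level k-fold
cross-validation.

A synthetic generator produces idealized multi-helix bundles (full backbone
plus Cβ, known axes and annotations) and "predicted-structure" surrogates via
seeded coordinate perturbation, so the whole protocol is testable offline.

## CLI

```sh
# generate a 10-sequence synthetic paired benchmark
helixcontact simulate --n-sequences 10 --sigma 0.5 --seed 1 --out data/

# extract features + labels for both structure sources
helixcontact features --data data/ --feature-kind sdf --source both --out feats/

# train on experimental-source features, score the predicted source
helixcontact train --features-dir feats/ --feature-kind sdf --out model.npz
helixcontact predict --model model.npz --features-dir feats/ --source predicted --out scores/

# full protocol: CV of both feature kinds on both sources + annotation baseline
helixcontact evaluate --data data/ --k 5 --repeats 1 --epochs 200 --out report/
```

Flags can also be given through `--config file` (plain `key = value` lines;
flags override the file). Every run writes a `run.log` with the package
version, a config hash and all seeds.

## Layout

```
src/helixcontact/
  structure_io.py   PDB I/O, chain model, TM annotations, pair reconciliation
  contact_map.py    candidate pairs, contact labels, contact ratio
  features.py       geometric features, SDF/CF assembly, [-1,1] scaling
  model.py          frozen projection + MLP classifier (NumPy)
  evaluate.py       per-sequence metrics, CV orchestration, comparisons
  synthetic.py      ideal helix / bundle generator, noise surrogates
  pipeline.py       dataset assembly and the four-row protocol
  cli.py            simulate / features / train / predict / evaluate
```
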