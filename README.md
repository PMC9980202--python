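# allokit

Deep-learning and free-energy profiling of **dynamic allostery** in
boosted molecular-dynamics ensembles.

Many receptors — G-protein-coupled receptors above all — bind positive
and negative allosteric modulators (PAMs/NAMs) with almost no change in
their static structures, yet the modulators clearly reshape signaling.
The mechanism is dynamic: modulator binding redistributes the
conformational *ensemble*. `allokit` analyzes enhanced-sampling
(boost-potential) simulations of a receptor with and without a modulator
and answers two questions:

1. **Which residue contacts characterize the modulator-bound ensemble?**
   Per-frame residue contact maps (heavy-atom distance ≤ 4.5 Å) are
   encoded as images and a small 2D CNN is trained to classify frames by
   condition (e.g. `Agonist` vs `AgonistPAM`, 80/20 train/validation
   split, 15 epochs). Vanilla-gradient saliency on the contact map of
   the most populated conformational cluster ranks residue pairs; pairs
   with normalized gradient ≥ 0.7 whose **both** residues also change
   flexibility significantly (|mean ΔRMSF| ≥ replicate SD over three
   replicas) are the characteristic contacts.

2. **Does the modulator confine the conformational ensemble?** The
   selected contacts (and any configured Cα–Cα distances) serve as
   reaction coordinates. Because boosted simulations sample
   exp(−β[V+ΔV]), bin probabilities are reweighted by the second-order
   cumulant expansion ln⟨e^{βΔV}⟩_j ≈ βC1_j + β²C2_j/2 (the "Gaussian
   approximation", exact for near-Gaussian boost — checked by an
   anharmonicity diagnostic), giving free-energy profiles
   PMF = −kT ln p, min-shifted, with under-sampled bins masked. Counting
   local minima below 1 kcal/mol yields the confinement verdict, e.g.
   **"2 → 1 states"**: two low-energy conformations free, one bound.

Because production inputs are microseconds of membrane-protein MD, the
package includes a synthetic-ensemble generator with *analytic* ground
truth (exact target PMF, planted discriminative contacts, planted
stabilized residues) that the test suite and the acceptance script run
against. See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Generate the default synthetic system (3 replicas × 5,000 frames × 2
conditions; double-well free ensemble, single-well bound ensemble; four
planted discriminative contact pairs) and run the full workflow:

```bash
allokit generate --out demo/inputs --seed 1
allokit all --config demo/inputs/run.yaml --out demo/run
```

which prints

```
validation accuracy: 0.988
state counts: {'Agonist': 2, 'AgonistPAM': 1}
confinement: 2 -> 1 states
selected contacts: 4
```

and writes, among other tables, `demo/run/selected_contacts.csv`:

```
res_i,res_j,gradient,significant
10,13,1,True
22,25,0.99700511,True
46,49,0.99466637,True
34,37,0.93607089,True
```

Reading: the classifier separates bound from free frames with 98.8%
validation accuracy; the gradient ∩ flexibility selection recovers
exactly the four planted pairs (the generator plants (10,13), (22,25),
(34,37), (46,49)); and the reweighted free-energy profile of the
reporter coordinate shows two sub-kcal/mol states in the modulator-free
ensemble collapsing to one when bound — the confinement signature.
`pmf_*.txt` files hold the binned profiles (bin centers, PMF in
kcal/mol, frame counts, validity), `delta_rmsf.csv` the per-residue
flexibility statistics, and `report.json` the summary with seeds and the
config hash. Rerunning with the same config and seeds reproduces every
table byte-for-byte.

Stage subcommands (`allokit contacts|cluster|train|saliency|flex|reweight`)
run the pipeline up to that stage for debugging; `--seed`, `--bin-size`,
`--cutoff`, `--grad-threshold`, `--epochs` override the config.

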