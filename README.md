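# ghmotif

Signature-motif analysis for the **lysozyme superfamily** of glycoside
hydrolases — the structurally related families GH19 (plant chitinases),
GH22c/GH22i (C- and invertebrate-type lysozymes), GH23 (G-type), GH24v/GH24l
(viral and lambda-type) and GH46 (chitosanases). These enzymes share no
detectable sequence similarity, yet all carry a bilobal fold whose catalytic
cleft is flanked by two conserved structural elements: the central helix
bearing the general-acid glutamate, and a β-hairpin that turns out to be the
most sequence-conserved region of each family — the basis of a
family-specific *signature motif*.

`ghmotif` is a library (with a thin `ghmotif` command-line front end) for
the four stages of that analysis:

1. **Structure clustering** — pairwise structural-similarity Z-scores
   (e.g. Dali) are transformed to distances, D_ij = 100·(1 − 2·S_ij/(S_ii +
   S_jj)) by default, clustered by UPGMA, and each internal node is tested
   by a leave-one-structure-out jackknife: a node is *reliable* only if its
   clade reappears in every reduced tree. Within/between-family mean
   distances ⟨D_ij⟩ are tabulated.
2. **Conservation profiling** — per-column entropy conservation
   C = Σ_a f_a ln f_a over Henikoff-weighted frequencies, smoothed
   (window 3) and z-normalized, mapped onto the representative structure's
   author numbering; the signature motif is the most conserved window
   (length 8–18) containing the family β-hairpin.
3. **Signature search** — a position-specific log-odds profile (with
   pseudocounts and affine gap penalties) is built from the motif
   alignment, scored glocally against sequence databases by dynamic
   programming, and benchmarked as TPR/FPR against membership labels at a
   background-calibrated threshold.
4. **Active-site geometry** — backbone φ/ψ/ω torsions, left-handed
   conformation classes, β-turn typing (the conserved hairpin houses a
   type I turn in a 4:4 hairpin), and the catalytic-role distance table:
   minimum separations between the general acid (A), general base (B),
   catalytic-water-positioning Ser/Thr (C) and the accessory Gln (D),
   using side-chain oxygens (Cβ for Gln).

A first-class synthetic-data module generates every input the pipeline
consumes — clustered similarity matrices, planted-motif alignments, peptide
backbones built from prescribed dihedrals, labelled search databases — with
the ground truth needed to verify each stage end to end, offline.

## Worked example

```python
from ghmotif import (MsaSpec, generate_msa, compute_profile, extract_motif,
                     build_profile, calibrate_threshold,
                     generate_sequence_db, evaluate_search)

msa, truth = generate_msa(MsaSpec(seed=3))           # 40 seqs x 120 cols
profile = compute_profile(msa)                       # entropy conservation
region = extract_motif(profile, hairpin_columns=(43, 49))

block = msa.slice_columns(region.column_start, region.column_end + 1)
model = build_profile(block)
threshold = calibrate_threshold(model, seed=3)
db, db_truth = generate_sequence_db(truth.consensus, 50, 500, seed=4)
ev = evaluate_search(model, db, db_truth.labels, threshold)
print(region.column_start, region.column_end, ev.tpr, round(ev.fpr, 3))
```

prints

```
40 52 1.0 0.014
```

— the extracted motif window (columns 40–52) coincides exactly with the
planted conserved block, and the profile built from it recovers all 50
planted family members (TPR 1.0) at a 1.4% false-positive rate on 500
background sequences. The scripts in `examples/` walk through each stage
(clustering + jackknife, conservation profiling, signature search, hairpin
and active-site geometry) with commentary on the printed numbers.

The CLI exposes the same stages on files:

```sh
ghmotif simulate --seed 1 --out fixtures       # synthetic input set
ghmotif cluster  --matrix fixtures/similarity.phy --families fixtures/families.tsv --out results
ghmotif search   --motif-alignment fixtures/motif.fasta \
                 --database fixtures/database.fasta --labels fixtures/labels.tsv --out results
```

## Layout

```
src/ghmotif/      io.py (FASTA/PHYLIP/PDB/Newick/YAML), cluster.py,
                  conservation.py, signatures.py, geometry.py,
                  synthetic.py, cli.py
examples/         one narrative script per capability
docs/methods.md   models, conventions, defaults and their rationale
tests/            unit, property and acceptance tests (+ brute-force oracles)
```
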