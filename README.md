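# crfthread

Template-based protein structure prediction starts from a sequence–template
alignment: thread a query sequence onto a solved structure (the template) and
the alignment quality largely decides the quality of the final 3D model.
`crfthread` implements the alignment core of that pipeline for people working
on threading methods:

* a **5-state pairwise-alignment CRF** over the states `M` (aligned pair),
  `Ix` / `Iy` (insertions in template / query) and `Gh` / `Gt` (unpenalized
  head/tail gaps, giving local alignments), with exact Viterbi decoding,
  forward–backward posteriors and **maximum-expected-accuracy (MaxAcc)**
  decoding;
* **emission scorers** producing the per-pair scores θ<sub>ij</sub><sup>u</sup>:
  an affine baseline over nine sequential feature channels (residue identity,
  BLOSUM80/62/45, bidirectional PSFM·PSSM profile products, secondary-structure
  and solvent-accessibility agreement), and a deep scorer — two 1D residual
  convolutional networks whose outputs are lifted to the pairwise grid by
  outer concatenation and fed to a 2D residual network — trained by maximum
  likelihood of reference alignments (gradient: observed − expected emission
  counts, backpropagated through the network);
* **distance-potential threading**: a predicted query Cβ–Cβ distance
  distribution over 14 bins (<4 Å, 1 Å steps, >16 Å) is converted with a
  DFIRE reference state into a potential *u(j, l, bin)*, and an alignment is
  scored by

  &nbsp;&nbsp;&nbsp;&nbsp;S = w·S<sub>singleton</sub> + S<sub>pairwise</sub>,&nbsp;&nbsp;
  S<sub>pairwise</sub> = Σ<sub>{(i,j),(k,l)}</sub> −u(j, l, bin(d<sub>ik</sub>))

  over unordered aligned pairs with template distance under 16 Å.  The
  combinatorial maximization is attacked by **ADMM** (two alignment copies
  with a consensus constraint; each subproblem is exactly solvable by
  Viterbi), multi-start initialization, and a network refiner that re-scores
  the grid from the initial alignment, the emission scores and the summed
  pair potential;
* **template ranking** by
  SelectionScore = w₁·S<sub>singleton</sub> + S<sub>pairwise</sub> + w₂·S<sub>pairwise</sub>/n<sub>aligned</sub>
  (defaults w₁ = 1, w₂ = 5; `--easy` raises w and w₁ to 20), and
  reference-dependent **precision/recall** evaluation;
* a **synthetic-data generator** (toy folds, mutated/indelled queries with
  known reference alignments, noise-controlled "predicted" profiles and
  distance distributions) so the whole stack runs and is tested without any
  external databases or predictors.

Everything is plain scientific Python (numpy + numba dynamic programs,
hand-written backprop for the networks); file IO covers FASTA-style alignment
records, PDB templates (via Biopython), a documented text profile format and
HDF5 distance tensors.

## Worked example

```bash
crfthread simulate --out sim --n-pairs 4 --length-min 12 --length-max 16 \
                   --mutation 0.4 --indel 0.1 --seed 7
crfthread train    --data sim --out model.npz --epochs 25 --seed 0
crfthread align    --query sim/pair000/query.prof --template sim/pair000/template.pdb \
                   --meta sim/pair000/template.meta --model model.npz --out viterbi.aln
crfthread thread   --query sim/pair000/query.prof --template sim/pair000/template.pdb \
                   --meta sim/pair000/template.meta --model model.npz \
                   --dist sim/pair000/distpred.h5 --out threaded.aln
crfthread eval     --pred viterbi.aln  --ref sim/pair000/reference.aln
crfthread eval     --pred threaded.aln --ref sim/pair000/reference.aln
```

prints

```
simulated 4 pairs in sim
trained linear scorer on 4 pairs; mean loglik -19.0020 -> -1.3685
viterbi alignment: 17 columns, score 74.2936
threading objective 410.0667 (singleton 73.7891, pairwise 336.2776)
precision 0.9375 recall 0.9375 (15/16 pred, 16 ref pairs)
precision 1.0000 recall 1.0000 (16/16 pred, 16 ref pairs)
```

Training raises the mean log-likelihood of the reference alignments from
−19.0 to −1.4.  Decoding the trained emission scores alone misplaces one of
the 16 reference pairs (precision 0.94); adding the distance potential and
re-optimizing with ADMM recovers the full reference alignment (precision and
recall 1.0) — the pairwise term (336.3) rewards alignments whose implied
query geometry matches the predicted distance distribution.  The alignment
file itself holds the gapped template row, query row and the state string:

```
>fold1342382291 query1342382291-1469265225 w=1 total=410.066736 ...
DHFHDVYM-YMPPYWDI
RDDHDLYDNYQPPYCTI
MMMMMMMMYMMMMMMMM
```

`crfthread rank` scores a directory of candidate templates and writes a TSV
ranking; `crfthread align --decoder maxacc` switches to posterior decoding.

## Layout

```
src/crfthread/
  alignment.py   alignment representations, validation, evaluation, text IO
  features.py    query/template records, file formats, pairwise features
  crf.py         transition model, Viterbi, forward-backward, MaxAcc, loglik
  nn.py          numpy conv/norm layers with backprop, Adam
  drnf.py        linear + deep emission scorers, MLE training, refiner
  distance.py    14-bin discretization, DFIRE potential, threading objective
  threading.py   ADMM, multi-start, SelectionScore, template ranking
  fixtures.py    synthetic folds, pairs, datasets
  cli.py         the `crfthread` command
```

See `docs/methods.md` for the model details, parameter choices and
limitations.
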