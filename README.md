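# hicstruct

3D chromosome structure inference from Hi-C contact maps, built around a
graph convolutional coordinate regressor whose trained parameters can be
stored and re-applied to *different* maps of the same chromosome —
another resolution, restriction enzyme, cell population, or coverage
level — without retraining.

## Who this is for

Researchers working with chromosome conformation capture data who want
distance-restraint 3D reconstructions of single chromosomes from
cis-chromosomal contact maps, and in particular want to train once on
cheap low-resolution data and run inference on expensive high-resolution
data.

## The method

A Hi-C map of one chromosome is an N×N symmetric matrix of contact
frequencies `CF_ij`, read here as the adjacency matrix of an
edge-weighted graph over loci.  The pipeline is:

1. **Wish distances.**  Target distances come from the standard inverse
   power law `d(i,j) = (1/CF_ij)^γ`.  The conversion factor γ is
   unknown and grid-searched over {0.1, 0.2, …, 2.0}.
2. **Node features.**  Loci carry no features, so E-dimensional
   representations are trained on the raw-weight contact graph with the
   second-order LINE objective (edge-sampling SGD, weighted edges,
   degree^¾ negative sampling).
3. **Balancing.**  The map is normalized to a doubly stochastic matrix
   in [0, 1] with Knight–Ruiz balancing; these are the edge weights
   `e_ij` the graph convolution uses.
4. **Graph convolutional regression.**  One consolidate–update layer

       C(x_i) = Σ_{j∈N(i)} e_ij x_j / Σ_{j∈N(i)} e_ij
       x'_i   = W1 x_i + W2 C(x_i)

   followed by ReLU and a four-layer MLP (ReLU hidden layers, linear
   3-unit output) maps each node to xyz coordinates.  All parameters
   are shared across nodes, so the network is independent of N.
5. **Training.**  Full-batch Adam minimizes the MSE between the
   structure's pairwise distances and the wish distances over observed
   pairs, until the loss drops below a convergence threshold.  One
   model is fitted per γ; the structure with the highest distance
   Spearman correlation (dSCC) is kept.
6. **Generalization.**  A stored model runs on a new map after the new
   map's embeddings are aligned to the training embedding space by
   closed-form orthogonal Procrustes (SVD); across resolutions the
   lower-resolution embedding rows are first repeated k times so both
   matrices describe the same genomic regions row by row.

Evaluation uses dSCC (scale- and rigid-motion-invariant) and dRMSD; the
package also provides a linear-interpolation baseline, A/B compartment
calling from the principal eigenvector of the balanced map's Pearson
correlation matrix, and a synthetic-data module that generates planted
structures with maps derived through the same power law.

## Worked example

```python
from hicstruct import synthetic
from hicstruct.model import HiCStructureModel
from hicstruct.train import TrainConfig

# planted 60-locus helix; contacts follow CF = d^(-1/γ) with γ = 1
s = synthetic.make_structure(60, "helix", seed=0)
m = synthetic.structure_to_map(s, gamma=1.0)

model = HiCStructureModel(
    m,
    config=TrainConfig(seed=0, mlp_hidden=(32, 16, 8), max_epochs=2000),
    e_dim=64,
)
res = model.fit(gammas=[0.5, 1.0, 1.5])
print(res.summary())
```

prints

```
HiC structure reconstruction results
============================================
chromosome:            chr
loci (N):              60
bin size:              1000000
embedding size (E):    64
selected gamma:        1.5
dSCC at gamma*:        0.9979
final training MSE:    1.552e+01
epochs run:            2000  (epoch cap reached)

gamma     dSCC
----------------
 0.50    0.9676
 1.00    0.9978
 1.50    0.9979  *
```

The dSCC of 0.998 against the wish distances says the reconstructed
coordinates reproduce the planted distance ranks almost perfectly (a
perfect fit is 1.0; `res.structure.coords` holds the xyz coordinates).
The generating γ = 1.0 and the selected 1.5 are a near-tie (0.9978 vs
0.9979): on noise-free data every γ produces a monotone transform of
the same distances, so selection discriminates only through goodness
of fit and sharpens as training approaches the convergence threshold
(raise `max_epochs`; the short cap here keeps the example quick).

The same workflow is available from the shell:

```sh
hicstruct simulate --n 60 --kind helix --out-dir sim/
hicstruct train sim/map_matrix.txt --e-dim 64 --mlp-hidden 32,16,8 --out-dir run/
hicstruct generalize run/checkpoint.npz other_map.txt \
    --source-emb run/cache/emb_*.npz --out-dir gen/
```

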