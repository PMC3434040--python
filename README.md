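# embow

Spatial sparse bag-of-visual-words representations for standardized 2-D
gene-expression pattern images — with the complete multi-label annotation
and content-based retrieval protocols built on top of them, and a synthetic
embryo-image generator so the whole pipeline runs and is tested without any
external image collection.

## The problem

In situ hybridization images of *Drosophila*-style embryos record where a
gene is expressed. Curators annotate *groups* of such images with multiple
controlled-vocabulary (CV) terms naming the anatomical structures that show
expression, and search databases for images with similar patterns. Both
tasks need an image representation that (a) is robust to local distortions
and (b) keeps track of *where* in the embryo a pattern occurs, since CV
terms are spatially specific.

## The representation

Images are assumed pre-aligned and pre-scaled onto a common canvas.

1. **Patches.** Overlapping circles of radius 16 on a regular grid; each
   patch keeps its centre coordinates.
2. **Descriptors.** An upright SIFT descriptor per patch: y ∈ R^d, d = 128.
3. **Codebook.** k-means over a sample of descriptors yields a dictionary
   D ∈ R^{d×c} whose columns are "visual words" (c = 2000 by default;
   experiments here use c ≈ 50).
4. **Coding.** Either hard assignment to the nearest word,

       min_e ½‖De − y‖²   s.t. e_i ∈ {0,1}, Σ e_i = 1,

   or a sparse non-negative "visual sentence",

       min_x ½‖Dx − y‖² + λ‖x‖₁   s.t. x ≥ 0,   (λ = 0.01)

   solved by cyclic coordinate descent.
5. **Pooling.** Summing codes over all patches gives the global bag
   H = (h_1, …, h_J) with h_j = Σ_i e_ij; summing per cell of a 3×6 grid and
   concatenating gives the spatial bag M_n = (H_1, …, H_n), n = 18. Group
   vectors are L1-normalized sums of image vectors.

**Annotation** fits one-vs-rest linear SVMs (C = 1) per term over repeated
stratified 1:1 train/test partitions (30 by default) and reports AUC, macro
F1, sensitivity and specificity as mean ± SD, with optional random
over-sampling of positives. **Retrieval** ranks images by cosine similarity
of their representation vectors and returns the top 8, query removed.

## Worked example

`python examples/annotate_synthetic_terms.py` generates 60 labelled image
groups (four localized expression terms: three stripes, an anterior spot, a
posterior band, a dorsal band) and runs the annotation protocol in all four
representation modes:

```
mean AUC +- SD over 5 partitions:
      global-hard: 0.7659 +- 0.1035
    global-sparse: 0.7964 +- 0.0942
     spatial-hard: 0.8486 +- 0.0905
   spatial-sparse: 0.8934 +- 0.0577
```

Each number is the macro (unweighted over terms) AUC averaged over the five
random partitions. Adding spatial pooling helps most — the synthetic terms
are spatially localized — and sparse coding adds a further margin on top of
either pooling. `examples/retrieve_similar_patterns.py` does the same for
retrieval (mean precision@8 = 0.852 over 60 queries at its settings), and
`examples/sparse_vs_hard_codes.py` shows one patch's hard word versus its
sparse visual sentence.

The same pipeline is available as a CLI for on-disk image directories:

```bash
embow simulate --outdir data --groups 40 --seed 1
embow codebook --images data --out cb --size 50 --seed 1
embow annotate --images data --codebook cb --out metrics.csv --terms 4
embow retrieve --images data --codebook cb --query g00/0 --k 8
```

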