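# manifoldseg

Unsupervised manifold learning for **contrast-free detection of active
multiple-sclerosis lesions** on multiparametric brain MRI.

Active (enhancing) MS lesions are normally identified by injecting a
gadolinium-based contrast agent and looking for bright spots on
post-contrast T1-weighted images. Repeated gadolinium administration carries
retention concerns and cost, so there is real interest in finding the same
lesions from the *non-contrast* channels alone. `manifoldseg` implements an
unsupervised route: the four non-contrast channels — proton density (PD),
T2-weighted (T2W), FLAIR, and pre-contrast T1-weighted (T1pre) — are treated
as a feature vector per voxel and embedded into a **single scalar image**
with nonlinear dimensionality reduction:

- **Isomap** — classical multidimensional scaling (MDS) applied to
  graph-geodesic distances on a k-nearest-neighbour graph,
  `B = -1/2 J D² J`, embedding from the top eigenpairs of `B`;
- **LLE** (locally linear embedding) — barycentric reconstruction weights
  `min Σᵢ ‖xᵢ − Σⱼ wᵢⱼ xⱼ‖²` with `Σⱼ wᵢⱼ = 1`, embedding from the bottom
  eigenvectors of `(I−W)ᵀ(I−W)`;
- classical **MDS** is included as the linear baseline.

Thresholding the embedded image yields a binary active-lesion mask, which is
scored with the **Dice similarity** index, `DS = 2|A∩B| / (|A|+|B|)`,
against a ground truth obtained by thresholding the post-minus-pre contrast
subtraction image (the held-out T1post channel is used only there). Both
shortest-path backends (Floyd–Warshall and Dijkstra), the spectral solvers,
and the evaluation stack are implemented in this package; a synthetic
multiparametric brain-phantom generator and the Swiss-roll benchmark make
every stage testable without any data download.

## Worked example

```python
import manifoldseg as ms

phantom = ms.make_phantom(ms.PhantomSpec(seed=0))   # 256² slice + truth
for method in ("isomap", "lle"):
    res = ms.segment_volume(phantom, ms.RunConfig(method=method, seed=0))
    print(method, round(res.dice_result.dice, 3))
```

Running `python examples/phantom_segmentation.py` prints:

```
phantom: (256, 256) grid, 1684 lesion px, 892 active px

isomap: Dice = 0.926 (TP=778, FP=15, FN=110)
  codebook 1324 signatures, K_eff=100, backend=dijkstra, threshold=2.865

lle: Dice = 0.965 (TP=837, FP=9, FN=51)
  codebook 1324 signatures, K_eff=100, backend=n/a, threshold=1.108
```

The phantom has 10 white-matter lesions of which 5 are "active": only those
enhance on the held-out T1post channel, and — crucially — their signature on
the four input channels is a *joint* FLAIR+T1pre offset that no single
channel separates well (best single-channel balanced accuracy ≈ 0.67 by
construction). A Dice above 0.9 therefore means the embedding recovered
information that is only present in the joint feature space, i.e. the
non-contrast channels predicted where the contrast agent would enhance.

`python examples/swiss_roll_benchmark.py` reproduces the classic sanity
check (n = 1000, k = 12):

```
Spearman correlation with intrinsic (unrolled) distances:
  isomap: 0.9997
     lle: 0.8433
     mds: 0.3660
```

Other examples sweep the input resolution (`resolution_sensitivity.py`,
Dice degrades from 256² to 64² as lesion boundaries blur away), the
neighbourhood size (`k_sensitivity.py`, both methods are stable for
K ≥ 100 while Isomap is the steadier of the two), and a synthetic cohort
(`cohort_study.py`, median ± sd of per-subject Dice).

A thin CLI wraps the same pipeline for shell use:

```sh
manifoldseg phantom --grid 256 --seed 0 --out run/
manifoldseg segment run/manifest.yaml --method isomap --out run/isomap/
manifoldseg sweep run/manifest.yaml --axis k --values 50,100,200 --out run/sweep/
```

Every run writes a provenance JSON recording the data-dependent decisions
taken (codebook size, effective K, geodesic backend, thresholds, polarity).

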