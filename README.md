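# glandring

Ring-based **statistical proximity sampling** of glandular tissue for
automated tubule-formation grading.

Histological malignancy grading of breast and prostate cancer rests partly
on *tubularity*: whether glands still form ordered units — a lumen wrapped
by epithelium — or have lost that architecture. `glandring` quantifies this
directly from per-pixel tissue-class probability maps (lumen, epithelium,
nuclei, stroma), as produced by any stain-decomposition or pixel
classification front end. It is aimed at computational-pathology
researchers who have soft class maps and want architecture-aware features,
an image-level classifier, or an unsupervised cluster analysis of gland
neighborhoods.

## Method

For each 4-connected lumen region the package grows concentric,
shape-preserving annuli by sequential 3×3 dilation and records per ring
the class fractions

    f_{r,k} = Σ_{p∈ring r} P_k(p) / |ring r|,

stacked class-major into an R×K profile (default R = 10, K = 4 → 40
elements). An image is a **bag** of such per-lumen instances; bag
dissimilarity is the **linear assignment distance** (optimal one-to-one
matching of instances, mean matched Euclidean distance), and the resulting
dissimilarity matrix feeds standard classifiers — linear SVC, k-NN,
logistic regression, shrinkage LDA — under a 25% leave-one-out tuning +
5×10-fold cross-validation protocol. Four classical lumen-shape features
(size, bending energy Σκ², 4πA/P², solidity) serve as the baseline.
Gaussian-mixture clustering with BIC = −2 ln L + k ln n (and the AIC
analogue) selects a cluster count for unsupervised analysis.

A seeded synthetic-tissue generator provides labeled datasets: C1 images
with ordered lumen/epithelium/nuclei architecture, C0 images with the same
class composition but scrambled layering.

## Worked example

```python
from glandring.synthetic import TissueSimConfig, simulate_dataset
from glandring.eval import run_protocol
from glandring.mil import standardize_bags

ds = simulate_dataset(TissueSimConfig(seed=11), n_images_per_class=25)
report = run_protocol(ds.bags, seed=11)
print({k: round(v, 1) for k, v in report.accuracy_mean.items()})
# {'svc': 97.5, 'knn': 99.5, 'logistic': 95.5, 'ldc': 100.0}

baseline = run_protocol(standardize_bags(ds.shape_bags), seed=11)
print({k: round(v, 1) for k, v in baseline.accuracy_mean.items()})
# {'svc': 59.5, 'knn': 50.2, 'logistic': 54.2, 'ldc': 48.0}
```

The proximity features separate tubule-forming from tubule-absent images
almost perfectly (95–100% accuracy across classifier families), while the
four scalar shape features — computed from the *same* lumen regions —
stay near chance: the two synthetic classes share lumen geometry and
differ only in the spatial ordering of the surrounding tissue, which is
precisely what ring sampling encodes.

The same pipeline is scriptable from the shell:

```
glandring simulate --n-per-class 10 --seed 5 --out ds/
glandring extract --maps ds/C1_000.tif --rings 10 --no-order --with-shape --out features.csv
glandring distances --bags ds/bags.json --out D.csv
glandring classify --distances D.csv --labels ds/labels.csv --seed 7 --out report.json
glandring cluster --features features.wide.csv --kmax 10 --seed 7 --out scan.json
```

## Layout

| module | contents |
|---|---|
| `glandring.core_maps` | probability-map stacks, channel ordering, lumen binarization, 4-connected labeling |
| `glandring.proximity` | ring construction, ring proportions, R×K feature stacking |
| `glandring.shape` | chain-code boundary tracing, bending energy, 4πA/P², solidity |
| `glandring.mil` | bags, linear-assignment bag distance, dissimilarity matrices |
| `glandring.eval` | LOO tuning, repeated stratified 10-fold CV, classifier adapters |
| `glandring.cluster` | GMM fits, BIC/AIC scans, majority-vote bag labels |
| `glandring.synthetic` | seeded C0/C1 tissue generator |
| `glandring.io` / `glandring.cli` | TIFF/PNG/CSV/JSON readers-writers, `glandring` CLI |

See `docs/methods.md` for modeling assumptions, parameter defaults and
known limitations.
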