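# mventropy

Multivariate sample and fuzzy entropy for multichannel (RGB) images —
texture-irregularity features for biomedical and generic color image
classification.

Entropy-based texture descriptors measure how *irregular* an image is: low
values for repetitive, self-similar patterns, high values for disordered
ones.  Bi-dimensional sample entropy and fuzzy entropy do this for
grayscale images; `mventropy` implements their **multivariate** extension,
which embeds all color channels jointly, so cross-channel structure counts
toward a match instead of being averaged away.  The package is aimed at
image-analysis practitioners who want interpretable, training-free texture
features — e.g. to classify histology tissue textures with a standard SVM.

## The measures

For an image I ∈ ℝ^{H×W×q} and per-channel embedding sizes
M = [m₁, …, m_q] with n = max(M), composite delay vectors
X^m(i,j) ∈ ℝ^{Σm_k²} concatenate the per-channel m_k×m_k patches anchored
at (i,j), over the N_m = (H−n)(W−n) anchor grid.  With the Chebyshev
distance d and tolerance r,

* **MSampEnRGB(I, M, r) = −ln( B^{m+1}(r) / B^m(r) )**, where B^m and
  B^{m+1} are the mean frequencies of pairs with d ≤ r at the base and
  extended embedding dimension (extension = enlarging any one channel's
  patch to (m_k+1)×(m_k+1); q·N_m extended vectors; self-matches excluded);
* **MFuzEnRGB(I, M, r, s) = −ln( Φ^{m+1}/Φ^m )**, the fuzzy variant, which
  replaces hard counting by the graded similarity exp(−dˢ/r) and is
  therefore always defined.

Multiscale profiles evaluate either measure on block-mean coarse-grained
copies of the image (scale factors τ = 1..τ_max) and are the feature
vectors for classification.  MIX(p) generators provide synthetic images of
ground-truth irregularity (sine template corrupted by Uniform[−3,3] noise
with probability p) for validation.  See `docs/methods.md` for the full
conventions.

## Worked example

```python
import mventropy as mv

cfg = mv.EmbeddingConfig(M=(2, 2, 2), r=0.15, s=2.0)
for p in (0.1, 0.9):
    img = mv.normalize(mv.generate_mix2d(mv.MixParams(p=p, shape=(60, 60), q=3, seed=7)))
    samp = mv.msampen_rgb(img, cfg)
    fuz = mv.mfuzen_rgb(img, cfg)
    profile = mv.multiscale_profile(img, cfg, method="mfuzen", tau_max=3)
    print(f"MIX(p={p}):  MSampEnRGB={samp.value:.4f} (defined={samp.defined})  "
          f"MFuzEnRGB={fuz.value:.4f}")
    print(f"  mfuzen multiscale profile (tau=1..3): {profile.values.round(4)}")
```

prints

```
MIX(p=0.1):  MSampEnRGB=1.8596 (defined=True)  MFuzEnRGB=1.5892
  mfuzen multiscale profile (tau=1..3): [1.5892 1.2276 0.3551]
MIX(p=0.9):  MSampEnRGB=nan (defined=False)  MFuzEnRGB=3.6417
  mfuzen multiscale profile (tau=1..3): [3.6417 1.3533 0.7029]
```

Reading the numbers: the noisier image (p = 0.9) has the higher fuzzy
entropy (3.64 vs 1.59) — more irregular texture.  Its *sample* entropy is
undefined at this tight tolerance: no extended-dimension template pair
matches within r, the hard-threshold measure's known failure mode and the
reason the fuzzy variant exists.  Both multiscale profiles fall with τ, and
the noise-dominated image falls much faster — averaging τ×τ blocks destroys
uncorrelated fluctuation but preserves correlated structure.

## Command line

```bash
mventropy generate --mode 2d --p 0.5 --shape 100x100 --seed 1 --out mix.npy
mventropy compute --method mfuzen --m 2,2,2 --r 0.15 --s 2 mix.npy
mventropy multiscale --method msampen --m 2,2,2 --r 1 --tau-max 10 *.npy --out profiles.csv
mventropy classify --features features.csv --repeats 5 --kernel rbf
mventropy pipeline --config run.cfg --out-dir runs/
```

`pipeline` runs load/generate → crop → normalize → multiscale entropy →
SVM end to end, writing `features.csv` and a `report.json` that embeds the
exact configuration used.

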