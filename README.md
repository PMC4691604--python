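# stsal — structure-tensor saliency maps

`stsal` implements a bottom-up visual saliency model for predicting where
human attention lands in an image. It follows the classic Itti–Koch
architecture — per-feature activation maps, peak-promoting normalization,
linear fusion — but replaces the expensive Gabor orientation channel with
edge and corner features extracted by a **linear structure tensor**. The
result is a saliency map with sharp object boundaries, useful as a
preprocessing step for segmentation and detection, plus a
center-bias-corrected ROC evaluation against human eye fixations.

It is aimed at computational-neuroscience and computer-vision users who
want a fast, fully deterministic, dependency-light saliency baseline with
a testable synthetic-stimulus generator.

## The model

For an image with channels $I_i$, the structure tensor at scale $\sigma$ is

$$
J_\sigma=\begin{pmatrix}G&F\\F&H\end{pmatrix},\quad
G=K_\sigma * \sum_i \Big(\tfrac{\partial I_i}{\partial x}\Big)^2,\;
F=K_\sigma * \sum_i \tfrac{\partial I_i}{\partial x}\tfrac{\partial I_i}{\partial y},\;
H=K_\sigma * \sum_i \Big(\tfrac{\partial I_i}{\partial y}\Big)^2 ,
$$

with $K_\sigma$ a Gaussian kernel. $J_\sigma$ is positive semidefinite, so
its eigenvalues $\lambda_1\ge\lambda_2\ge 0$ summarize local structure:
$\lambda_1\gg\lambda_2$ marks an edge, both large a corner. The two feature
maps never need an eigendecomposition:

$$
A=\lambda_1-\lambda_2=\sqrt{(G-H)^2+4F^2}\ \text{(edge)},\qquad
B=\lambda_2=\tfrac{(G+H)-A}{2}\ \text{(corner)} .
$$

They combine into a contour activation map
$C_T=\tfrac12\big(N(A)+N(B)\big)$ with $N(\cdot)$ a min–max rescale, and
the final saliency map fuses contour with the Itti intensity and
opponent-color channels,

$$
S=\tfrac13\big(\oplus C_L+\oplus I+\oplus C_T\big),
$$

where $\oplus$ is the peak-promoting normalization (a map with one dominant
peak is kept, a map of many similar peaks is suppressed). Everything runs
at a 170×128 working resolution by default; evaluation uses the shuffled
ROC AUC (negatives drawn from other images' fixations) to correct for the
human tendency to fixate image centers.

## Worked example

```python
import numpy as np
from stsal import (STConfig, make_popout_image, make_fixations, st_saliency,
                   auc_basic, shuffled_auc)

# a red bar hidden in a field of green bars, with its ground-truth region
img, target = make_popout_image("color_popout", size=(170, 128), seed=3)
sal = st_saliency(img, STConfig())

row, col = np.unravel_index(np.argmax(sal.values), sal.shape)
mask = target.mask(*sal.shape)
print(f"argmax at (x={col}, y={row}); target {target}")
print(f"mean saliency: in-target {sal.values[mask].mean():.3f}, "
      f"background {sal.values[~mask].mean():.3f}")

fix = make_fixations(20, (170, 128), seed=11, region=target, image_id="demo")
neg = make_fixations(20, (170, 128), seed=12)
pool = [make_fixations(20, (170, 128), seed=s, center_sigma=30.0) for s in (13, 14)]
print(f"basic AUC    {auc_basic(sal, fix, neg):.3f}")
print(f"shuffled AUC {shuffled_auc(sal, fix, pool, n_shuffles=25, seed=0).auc:.3f}")
```

prints

```
argmax at (x=128, y=66); target Rect(x0=123, y0=56, x1=132, y1=72)
mean saliency: in-target 0.585, background 0.224
basic AUC    0.970
shuffled AUC 0.952
```

The most salient pixel falls on the red bar, the bar's region is about 2.6×
brighter than the background on average, and saliency separates simulated
target-driven fixations from random locations almost perfectly (AUC ≈ 0.97;
slightly lower, as expected, once the negatives share the fixations'
center bias).

## Command line

```bash
stsal run scene1.png scene2.png --out maps/ --sigma 2.0 --size 170x128
stsal eval --maps maps/ --fixations fix/ --shuffled --n-shuffles 100 \
           --seed 1 --out scores.csv
```

`run` writes per image a min–max-scaled 8-bit PNG, a lossless float text
sidecar, and a `config.json` snapshot. `eval` matches map and fixation
files by stem (fixation files are plain text, one `x y` pair per line,
`#` comments allowed) and emits a CSV of per-image AUC rows.

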