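# Methods

## Model overview and assumptions

The model is a purely bottom-up, feed-forward saliency pipeline. An input
image is bilinearly resized to a working resolution of 170×128 (width ×
height), three activation maps are computed — opponent color, intensity,
and a structure-tensor contour channel — and they are averaged with equal
weights after a peak-promoting normalization. Nothing is learned or
fitted; the same image and configuration always produce a bit-identical
map. The underlying assumptions are the standard ones of this model
family: saliency is driven by local feature contrast, channels contribute
independently and equally, and spatial competition can be approximated by
a single global normalization per map rather than a recurrent
winner-take-all network (dynamics such as inhibition of return are out of
scope).

## Structure-tensor contour channel

Per-channel image gradients are central differences in the interior and
one-sided differences at borders (unit pixel spacing). The gradient outer
products are summed over the image's channels and smoothed with a
Gaussian of standard deviation σ to form the tensor planes G, F, H. The
kernel is truncated at 4σ (radius `round(4σ)`) with mirror ("reflect
without edge repeat") border handling. We read the tensor's Gaussian
parameter as a standard deviation, the conventional meaning, and expose
it as `sigma`.

From the closed forms λ1−λ2 = √((G−H)² + 4F²) and λ1+λ2 = G+H, the edge
map is A = λ1−λ2 (anisotropy: exactly one dominant gradient direction)
and the corner map is B = λ2 = ((λ1+λ2) − (λ1−λ2))/2 (both eigenvalues
large). These are the canonical edge/corner measures recoverable from the
sum/difference pair without an eigendecomposition; B = λ1+λ2 (the tensor
trace, total gradient energy) is available as `corner_variant="trace"`
for ablation. The contour activation map is C_T = (N(A)+N(B))/2 with
N(·) a min–max rescale to [0,1]; no threshold or non-maximum suppression
is applied before normalization. The min–max reading of N(·) is a design
choice: the fusion stage uses a visibly different operator (⊕ below), and
using the simpler affine rescale here keeps the two distinct.
`contour_norm="itti"` swaps in ⊕ for ablation.

Tensor channels default to the raw R, G, B planes (`colorspace="rgb"`);
`colorspace="lab"` differentiates range-normalized CIELAB planes instead.

## Intensity and color channels

Both channels use a dyadic Gaussian pyramid (σ=1 blur, factor-2
decimation, stopping when a dimension would fall below 4; level sizes are
⌈n/2ᵏ⌉). Center–surround maps are |level_c − upsample(level_{c+d})| with
bilinear upsampling. At 170×128 the pyramid has six levels (0–5), so from
the default centers c ∈ {2,3} and offsets d ∈ {2,3} the pair (3,3) would
need a nonexistent level 6; channel computation skips any pair whose
surround level is missing and uses the remaining three. The intensity
plane is the channel mean (r+g+b)/3. Color uses the broadly tuned planes
R = r−(g+b)/2, G = g−(r+b)/2, B = b−(r+g)/2, Y = (r+g)/2−|r−g|/2−b (all
clipped at 0) and applies plain center–surround to the opponent planes
R−G and B−Y. This is a simplification of the classic chromatic double
opponency (which flips the opponent sign between center and surround);
for the stimuli modeled here the two behave equivalently, and the simple
form reuses one center–surround primitive. Grayscale inputs yield a zero
color map.

The normalization ⊕ rescales a map to [0,1], finds local maxima over a
7×7 neighborhood with a 0.05 detection threshold, and multiplies the map
by (1−m̄)², where m̄ is the mean of the local maxima excluding one
occurrence of the global maximum. A unique peak passes unchanged
((1−0)² = 1); a field of near-identical peaks is driven toward zero. The
neighborhood and threshold are unspecified in the source formulation and
are exposed as module constants.

## Fusion

S = (⊕C_L + ⊕I + ⊕C_T)/3. C_T is built with N(·) and *additionally*
passes through ⊕ at fusion — the two operators appear in two different
equations and both are applied. The final map is min–max rescaled to
[0,1] as an output convention; the model itself defines no output range.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `sigma` | 2.0 | px | tensor smoothing at working resolution; unstated in the source, chosen as a typical integration scale at 170×128 |
| `working_size` | (170, 128) | px | published evaluation size; exposed as config |
| `centers`, `surround_offsets` | (2,3), (2,3) | pyramid levels | see scale discussion above |
| `pyramid_blur_sigma` | 1.0 | px | per-octave blur |
| `n_shuffles` | 100 | — | shuffled-AUC draws; the protocol source states no value |

## Evaluation

AUC is the Mann–Whitney statistic of saliency sampled at fixated
(positive) versus control (negative) pixels, computed via midranks so
ties count ½ — a constant map scores exactly 0.5. Fixation coordinates
given in native image pixels are scaled to the map's resolution and
looked up at the nearest pixel. The shuffled variant draws, per shuffle,
as many negatives as positives from the pooled fixations of the other
images and averages over seeded draws; per-dataset scores are unweighted
means of per-image AUCs.

## Synthetic stimulus generator

`make_popout_image` produces four scene classes — blank, luminance step
edge, line crossing, color singleton — each returning the exact target
region by construction. Non-blank scenes carry seeded Gaussian luminance
noise (σ = 0.01, identical across color channels): real photographs carry
sensor noise, and a mathematically perfect ridge is a degenerate input to
⊕ (all its local maxima are exactly equal, so the suppression weight is
exactly zero). Design notes: the crossing uses full-span lines so the
crossing point is the only corner-rich locus; the color singleton's
distractor bars (5×12 px on a 16 px pitch) tile the entire field, since a
truncated array would make its own rim the most salient structure; its
target region is the red bar's bounding box plus a 2 px margin for the
smoothing-induced peak shift.

`make_fixations` simulates observers three ways: uniform, concentrated in
a target region, or Gaussian around the image center (a center-bias
model used to demonstrate the shuffled-AUC correction).

What the synthetic stimuli do not emulate: natural-image statistics
(1/f spectra, clutter, textures), photometric effects (shadows,
specularities), object-level and top-down influences, and real
eye-tracking artifacts (calibration error, saccade dynamics). Passing
tests therefore establish the pipeline's correctness and its qualitative
pop-out behavior, not its fixation-prediction accuracy on natural-image
benchmarks, which requires external eye-tracking datasets.

## Numerical choices and degenerate inputs

All arithmetic is float64; images are mapped to [0,1] at load. A constant
image yields exactly-zero tensors, features, activations, and saliency
(min–max normalization maps a constant plane to zeros rather than
dividing by zero). Diagonal tensor planes are clipped at 0 after
smoothing to absorb float dust, keeping the positive-semidefiniteness
invariant (F² ≤ G·H + 1e−9) exact. Argmax ties resolve to the first
flat-index occurrence (numpy convention). Problem sizes in the acceptance
script — 15 localization scenes, a 12-image simulated fixation dataset
with 20 fixations per image and 25 shuffles, a 20-image center-bias
control — were chosen so the whole report recomputes in a few seconds
while keeping the Monte-Carlo spread of the reported means small.

## Known limitations

- Single-scale contour channel (by design); fine and coarse edges compete
  within one σ.
- The skipped (3,3) center–surround pair slightly reduces multi-scale
  coverage at 170×128 relative to the full scheme on larger inputs.
- The plain opponent center–surround (vs true double opponency) can
  underweight isoluminant color contrast in natural images.
- ⊕'s global suppression weight is a coarse stand-in for local spatial
  competition; maps with one strong and several weak peaks keep the weak
  peaks partially suppressed.
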