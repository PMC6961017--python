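# Methods

## Model

An image is reduced to K superpixels (SLIC, requested segment count
round(H·W/A) for an expected average area A, compactness 10, connectivity
enforced). The graph has one node per superpixel with its mean intensity
in [0, 1] as the single input channel. Directed edges join every ordered
pair of superpixels whose hop distance on the 4-connectivity
region-adjacency graph is at most D, plus a loop at every node so a node
contributes to its own output. Each edge carries the pseudo-coordinate
u(s, t) = (Δcol, −Δrow)/c of the destination centroid relative to the
source; the row axis is negated so y points upward and angles follow the
counterclockwise convention.

A convolution layer owns an independent continuous filter per (input
channel n, output channel m) pair,

    φ(u) = Σ_j g_j exp(−½ (u−μ_j)ᵀ K_j⁻¹ (u−μ_j)),   j = 1..J,

with scalar weights g of either sign, 2-D means μ and diagonal
covariances K, and computes h_m(s) = Ψ(b_m + Σ_n Σ_{t∈N(s)} φ_{n,m}(u(s,t)) f_n(t)).
A network is a plain sequential composition of such layers — no
down/upsampling is needed because the superpixel representation is
already coarse. Activations are ReLU on hidden layers and identity on
the output layer.

Filter transforms act on the evaluation coordinate: every network
carries a 2×2 map Q (identity after construction) and evaluates filters
at Qu. Rotation by θ right-multiplies Q by R(−θ); mirroring by
diag(−1, 1). This is exact — no parameters are resampled, the
diagonal-covariance storage is untouched, rotations compose additively
and mirroring is an involution — and it yields the machine-precision
equivariance identity Φ_θ on R(θ)-rotated coordinates ≡ Φ on the
original graph. A rotation bank covers `count` nominal orientations
evenly spaced over [−π, π]; since −π and π coincide modulo 2π only the
−π endpoint is stored, so the default count of 11 keeps ten distinct
networks at spacing π/5 with θ = 0 always present.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| A | 256 px² | expected superpixel area; smaller A = finer graph and smaller visual field |
| D | 2 hops | neighbourhood radius; with L layers the visual field grows like L·D |
| W | 100 | target scale for mask-derived node labels; values ≫ 1 keep training away from the all-zero regression minimum |
| J | 4 | Gaussians per filter |
| coord_scale | D·√A px | pseudo-coordinate normaliser, puts 1-hop offsets at magnitude ≈ 1 so filter means live in [−1, 1]² |
| learning rate | 1e-3 (two-layer study), 1e-4 (four-layer study) | Adam step size; β = (0.9, 0.999), ε = 1e-8 |
| eval interval | 50 epochs | cadence of train/validation MSE records and model-selection snapshots |

Variances are stored as log-variances so optimisation is unconstrained
while positivity is structural. Initialisation: mixture weights g are
Glorot-uniform with fan_in = N·J and fan_out = M·J, means uniform on
[−1, 1]², variances 1, biases 0 — chosen so initial responses are O(1)
over the unit-scaled coordinate range. The bias is stored per filter
pair (the effective per-channel bias is the row sum), making the
enumerated trainable count per layer exactly MN(J(2d+1)+1): 420 scalars
for the two-layer verification network and 5775 for the four-layer main
network.

## Training

Loss is node-level mean squared error; the optimizer is Adam. One epoch
cycles once over the training graphs in a seeded random order taking one
Adam step per graph. Full-batch steps were rejected deliberately: with
learning rate 1e-4, N epochs of full-batch Adam bound the total
parameter displacement by roughly N·1e-4, which cannot reach the weight
magnitudes that W = 100 targets require; per-graph steps multiply the
step count by the training-set size while keeping the run deterministic
for a fixed seed. Every 50 epochs the mean train/validation MSE is
recorded and the parameters with the smallest validation MSE so far are
snapshotted; that snapshot is the returned model (selection by
validation MSE, not detection accuracy — the loss curves are the
quantity actually monitored). Gradients are hand-derived; the backward
kernel reuses the Gaussian exponentials cached by the forward pass, and
edges are accumulated in sorted (s, t) order so floating-point sums are
reproducible run to run. Correctness is pinned by a finite-difference
test over every parameter.

## Oriented-edge verification labels

For the verification study the node label at orientation θ is

    h_θ(s) = max( Σ_t ω² (f(t) − f(s)) / Σ_t ω², 0 ),  ω = sin(α(s,t) − θ),

summed over non-loop out-edges with ω > 0, where α is the edge angle.
Loops are excluded (α undefined) and a node with no positively weighted
neighbour gets 0 (the normaliser would be 0/0). Note the geometry: ω > 0
selects neighbours *above* s when θ = 0, so positive labels sit where
brighter content lies above — on and just below a bright blob's lower
boundary in image rows. Rotating the graph coordinates by δ and shifting
θ by δ leaves the labels unchanged, which is the property that makes the
study a clean test of filter rotation.

## Synthetic data

The generator stands in for a profile-image ear dataset with per-image
binary masks. A scene (default 96×128) is a textured background (flat,
linear gradient, or smoothed Gaussian noise), a large head-like bright
ellipse, and one connected ear-like target — a bright ellipse with a
darker internal notch — centred on the head boundary and rotated
in-plane about its own centre by the scene's rotation parameter.
Illumination multiplies the image before clipping to [0, 1]. Shapes are
rendered from analytic ellipse equations on rotated coordinates, so a
rotated scene equals the rigidly rotated upright scene up to pixel
discretisation. Subject appearance (head geometry and brightness, ear
size and resting angle) is a deterministic function of (seed,
subject_id) and is therefore constant across a subject's scenes, making
person-disjoint splits meaningful; splits follow 75 : 25 : 26
proportions by subject count. Blob masks for the verification study are
star-convex shapes (radius function with low-order harmonics), which
guarantees a single 4-connected component covering 10–40 % of the frame.

What the generator does *not* emulate: occlusion, motion blur, annotation
noise, cluttered multi-object backgrounds, and genuinely ear-shaped
texture. Passing tests therefore demonstrate that the pipeline learns
and that filter rotation transfers what was learned — not that the
default architecture would reach any particular accuracy on real
profile photographs.

## Experiments and problem sizes

*Verification study*: 100 generated blob masks at 96×128, graphs at
A = 400, D = 1, split 60/20/20; two-layer network (10 filter groups then
1 group of 10, J = 4), 2000 epochs at lr 1e-3. The trained network Φ0 is
evaluated against its analytic rotations Φ_θ on targets regenerated at
θ ∈ {3π/4, −π/2}; the rotated network must show the smaller MSE on every
split at every angle (six comparisons).

*Detection study*: 38 subjects × 4 upright scenes (152 scenes, 92/32/28
after the person-disjoint split), graphs at A = 256, D = 2, W = 100;
four-layer network (20/10/5/1 filter groups), 300 epochs at lr 1e-4.
These sizes are the package's desk-scale defaults, chosen so the full
study trains in minutes on one CPU core. Detection takes the argmax
node (ties to the lowest id) and scores a hit when its centroid falls
inside the ground-truth box enlarged by √A pixels per side (boundary
inclusive). Rotated evaluation generates fresh scenes for the unseen
test subjects with rotations uniform in [−π, π] and applies the
11-orientation bank under two rules: max (globally maximal node response
across the bank picks the detection; ties by smaller |θ|, then smaller
θ, then lower node id) and any (a hit if any bank member's argmax node
hits). By construction any-rule accuracy dominates both the max rule and
Φ0 alone; the max rule can fall below Φ0 because rotated filters may
introduce spurious maxima elsewhere in the image, and the synthetic
study reproduces exactly that qualitative pattern.

## Numerical choices and degenerate inputs

* Edge lists are duplicate-free, sorted, and always contain loops with
  u = (0, 0); pseudo-coordinates are exactly antisymmetric.
* SLIC may deliver fewer or more segments than requested; labels are
  re-indexed to a contiguous range. A = H·W degenerates to a single
  superpixel and is handled without calling SLIC.
* An all-zero mask produces all-zero targets; a constant feature field
  produces all-zero oriented labels; both are legal inputs.
* Detection on an empty output vector, non-binary masks, shape
  mismatches and channel mismatches raise ValueError.
* Checkpoints (JSON, shortest-round-trip float repr) and the plain-text
  graph tables (17 significant digits) round-trip exactly.

## Known limitations

* Single-channel (grayscale) features only; one target region per image.
* The max-rule/any-rule gap means the bank, as in the underlying method,
  needs an oracle-free angle-selection rule before it is usable when no
  ground truth is available; this package implements and measures the
  rules, it does not close that gap.
* The numba kernels are single-threaded by design (reproducibility
  first); large graphs (thousands of nodes) would need batching work
  that is out of scope here.
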