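# Methods

This note documents the estimator, the model choices behind each stage, the
parameters that matter, and what the synthetic fixtures do and do not
demonstrate about real data.

## Scene model

A scene is a scalar volume, a 1-D transfer function, a thin-lens camera and
a set of lights. The volume is a node-centered grid: voxel (i, j, k) sits
at `origin + (i, j, k)·spacing` (mm), the bounding box spans the outermost
nodes, and trilinear interpolation is used everywhere (it reproduces
tri-affine fields exactly, which the tests exploit). Intensity is
normalized to [0, 1] over the volume's stored min/max by default — transfer
functions are edited over the data's dynamic range, not the full 16-bit
range — with an explicit override for fixtures, which normalize over
(0, 65535) so a stored value maps to a predictable transfer-function
coordinate. Out-of-box samples clamp to the boundary value, which keeps
central differences defined on the faces.

Gradients are central differences of the normalized intensity with step one
voxel spacing per axis. The normalized gradient magnitude G_n divides by
the maximum gradient magnitude present in the volume, precomputed at load
from the node-wise gradient field; a constant volume uses 1 to keep the
quantity defined (it is zero anyway). This normalizer is a design choice:
any per-volume constant yields the same qualitative behaviour and only
rescales the hybrid sharpness parameter.

## Extinction and the transfer function

The opacity channel α(u) maps to extinction as σ_t = ρ·α(u) with a single
global density scale ρ (mm⁻¹, CLI flag). The majorant for Woodcock
tracking is σ̄ = ρ·max(α at the nodes), which bounds the piecewise-linear
curve everywhere and is independent of volume occupancy — conservative,
never wrong, at the cost of extra null collisions in sparse regions.
Specular roughness r maps to a Blinn exponent via e = 2/r² − 2 clamped to
[1, 10⁴], the standard roughness↔exponent bridge.

## Free paths and shadows

Woodcock tracking iterates t ← t − ln(1−ξ)/σ̄ from the box entry and
accepts a tentative collision with probability σ_t(x(t))/σ̄; exceeding the
exit parameter means no scattering. The estimator is unbiased for any
majorant dominating σ_t along the ray (verified against the analytic
heterogeneous free-path density by χ² in the tests). Shadow rays reuse the
same machinery as a *binary* query clipped to the light distance — blocked
or unblocked — so each direct-lighting estimate costs a constant number of
tracking operations and the indicator's expectation equals the
transmittance. Rays terminate at box exit; no Russian roulette.

## Hybrid scattering

At an accepted collision the renderer switches stochastically between
surface and volumetric scattering with

    P_brdf = 1 − exp(−s · g_f · G_n),   s = 8 by default.

The form satisfies the contract the switch needs: identically zero when the
gradient factor g_f or G_n is zero (flat regions always scatter
volumetrically), strictly increasing in both controls, bounded in [0, 1].
Opacity enters implicitly: collisions only occur where the medium is dense.
The sharpness s is a config knob; the mapping is isolated in
`brdf_probability` so an alternative can be swapped in without touching
callers. The mode draw is treated as sampling a *stochastic mixture*
scattering model: the chosen mode's full estimate is used as-is, whose
expectation is P·I_brdf + (1−P)·I_phase. (Dividing by the selection
probability instead would converge to the sum of both models and
double-count energy.)

Surface mode evaluates the Ashikhmin–Shirley Fresnel blend in a shading
frame whose normal is the normalized gradient, flipped toward the outgoing
direction (the data gives no preferred gradient sign). Diffuse term:
28ρ_d/(23π)·(1−F0)·(1−(1−cosθ_i/2)⁵)(1−(1−cosθ_o/2)⁵); glossy term: the
normalized Blinn lobe (e+1)/(8π)·(n·h)^e/((h·ω_i)·max(cosθ_i, cosθ_o))
times Schlick Fresnel F0 + (1−F0)(1−h·ω_i)⁵ and the specular colour, with
F0 = ((n_r−1)/(n_r+1))² from the index-of-reflection channel. The blend is
reciprocal by construction and energy conserving for physically plausible
materials (diffuse + specular ≤ 1 componentwise), which the furnace test
checks by quadrature. Importance sampling is an equal-weight mixture of
cosine-hemisphere and Blinn half-vector sampling; the pdf reported is the
mixture density (exact, including the half-vector sign recovery), and
below-horizon glossy samples carry zero BRDF value but a valid pdf.
Volumetric mode is the isotropic phase function, value = pdf = 1/(4π).

## Direct lighting and MIS

Per event one light is chosen uniformly (selection probability folded into
the light pdf). Two estimators for that light are combined with the power
heuristic (β = 2): sampling the light's area (pdf converted to solid angle
as d²/(A·|cosθ_l|)) and sampling the scattering function (intersecting the
chosen light; the background sphere is hit by any escaping ray at pdf
1/(4π)). Both strategies shadow-test with one binary Woodcock query.
Zero-pdf branches contribute zero, never NaN. The pdf reported by
`intersect_light` is exactly the density `sample_light` would have assigned
to that direction — the consistency MIS requires, asserted to 1e−6 in the
tests. Emission is deposited only at accepted collisions
(collision-based estimator), which for the single-scatter model converges
to (1 − e^(−σ_t·d))·E along a homogeneous ray — the closed form the
acceptance test uses.

Light shapes are textured rectangles plus an optional constant or
lat-long-textured background sphere; texture sampling is uniform (not
importance) — the simplest unbiased choice.

## Film pipeline

Per frame, in fixed order: Gaussian pre-filter (separable, σ = 0.66 px over
a 3×3 window — an anti-aliasing reconstruction filter; energy preserving on
interior pixels) → cumulative moving average (after N frames the HDR buffer
is exactly the mean of the N estimates) → exponential tone map
L′ = 1 − exp(−L/exposure) and gamma 1/γ → KNN denoise. The per-pixel
mean/M2 aggregates of the LDR image use Welford's single-pass update; their
pixel average (the mean running sample variance) drives the denoiser
through lerpC = exp(−k·variance) (k = 100), the weight of the *original*
image — so the filter is the identity at zero variance and maximal before
two frames exist, when the variance is undefined and treated as infinite.
The KNN weights combine a spatial Gaussian (σ = window/4 over a 7×7 window)
with colour similarity exp(−‖c_i−c_0‖²/h_eff²), where
h_eff² = h² + 8·variance (h = 0.2): while the estimate is noisy, colour
differences are expected and should not block smoothing; as it converges
the filter becomes strictly edge-preserving before fading out entirely.
All of these constants are keyword parameters on their functions.

The tone-map operator and every filter constant are this package's own
choices; they sit behind one function each so alternatives drop in.

NRMS — RMS difference divided by the reference's value range — is computed
on the HDR accumulation before tone mapping and denoising. A constant
reference has no range and is rejected rather than silently normalized.

## Reproducibility and problem sizes

Every run derives one RNG stream per frame from (seed, frame index); a
frame renders as one vectorized batch over all pixels, so results are
independent of pixel order and bit-reproducible from (config, seed). The
statistical tests run at the sizes their derivations call for: 10⁵ trials
for free-path/transmittance/mode-frequency laws (3σ binomial envelopes),
10³ direction pairs for reciprocity, product quadrature grids of ~2·10⁵
nodes for normalization (0.5 %) and furnace bounds, 40 independent runs for
the MIS variance comparison, 10⁴ frame estimates at 64² for the emissive
cube (1 % per-pixel envelope ≈ 7σ after the pre-filter), and N ∈ [16, 4096]
for the convergence slope. The emissive-cube reference is the
Gaussian-pre-filtered analytic image: the pre-filter is linear, so
filtering commutes with the expectation of the accumulated estimate.

The MIS variance comparison scene places a large quad light (half-extent
24 mm at 12 mm from the event) so that neither light sampling nor
scattering sampling dominates — the regime where combining them must win.
With a small distant light, light sampling alone is near-optimal and the
power heuristic can only tie it; the comparison would then measure noise.

## What the fixtures do and do not show

The procedural fixtures (constant cubes, axis-aligned slabs, Gaussian
shells, seeded noise) have exactly representable closed-form structure:
they make unbiasedness, interpolation exactness, and convergence-rate
claims *testable*. They do not exercise anisotropic voxel spacing beyond
metadata round-trips, partial-volume mixtures, scanner noise
characteristics, or the deep occlusion complexity of clinical CT — passing
tests show the estimator's laws hold, not that a particular clinical
transfer function will look right. Volumes are 32³–64³ where the paper-size
datasets are up to 512³; correctness of an unbiased estimator does not
depend on grid size, only performance does.

## Known limitations

Single scattering only — one scatter point and two auxiliary rays per
estimate; no multiple scattering or global illumination. No anisotropic
phase functions or microfacet anisotropy. No HDR-environment importance
sampling. No partitioned-majorant acceleration for Woodcock tracking; the
global majorant wastes null collisions in sparse volumes. The CLI is a
batch tool: interactivity is modelled as edit-and-restart (which is also
the renderer's actual semantics), not as a windowed GUI.
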