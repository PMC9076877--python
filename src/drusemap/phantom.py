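"""Paired-visit multispectral eye phantoms with ground truth.

The generator emulates the spectral structure the classification method
relies on, in abstract pixel units:

* **drusen** — bright on all three channels, rendered as non-overlapping
  discs with two concentric intensity zones (center brighter than edge), so
  clustering naturally resolves one to three adjacent drusen theme classes;
* **pigmentary abnormalities** — dark predominantly on the green (532 nm)
  channel, where melanin absorbs strongly;
* **vessels** — dark lines on all channels, also carrying the eight
  bifurcation-style registration landmarks;
* **vignetting** — radial background shading, plus per-channel Gaussian
  sensor noise;
* **misalignment** — each channel is emitted in its own slightly jittered
  affine frame together with exact landmark pairs, so registration is
  exercised, not bypassed.

Longitudinal change is applied by uniformly scaling the planted lesion
radii, with a 1-D search on the scale factor until the rendered mask-area
ratio hits the requested percent change to within 1%. All randomness flows
from a single seed through named streams, so adding a lesion type never
perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
from scipy import ndimage

from ._streams import stream
from .errors import NumericError, ValidationError
from .quantify import PROGRESSION, REGRESSION, STABLE
from .registration import LandmarkSet, SpatialTransform

__all__ = [
    "PhantomParams",
    "PhantomVisit",
    "PhantomPair",
    "CohortEye",
    "generate_visit",
    "generate_pair",
    "generate_cohort",
]

CHANNELS = ("faf", "ir", "green")


@dataclass(frozen=True)
class PhantomParams:
    """Generator configuration, amplitudes in [0,1] dynamic-range units."""

    image_size: tuple[int, int] = (192, 192)
    n_drusen: int = 4
    drusen_radius_range: tuple[float, float] = (10.0, 15.0)
    # per-channel added brightness (FAF, IR, green); the center zone is only
    # slightly brighter than the edge zone, as in soft drusen whose apex and
    # shoulder differ modestly in reflectance
    drusen_center_brightness: tuple[float, float, float] = (0.32, 0.29, 0.27)
    drusen_edge_brightness: tuple[float, float, float] = (0.27, 0.24, 0.22)
    center_zone_fraction: float = 0.6
    # lesions scatter over this fraction of image width around the center,
    # keeping the local lesion density low so background subtraction does
    # not carve deep halos around clustered lesions
    lesion_field_fraction: float = 0.34
    n_pigment: int = 2
    pigment_radius_range: tuple[float, float] = (7.0, 11.0)
    # pigment is dark predominantly on green
    pigment_darkness: tuple[float, float, float] = (0.06, 0.05, 0.30)
    n_vessels: int = 3
    vessel_darkness: float = 0.12
    vessel_half_width: float = 1.5
    vignetting_amplitude: float = 0.03
    # static background mottle (choroidal / RPE texture): a smooth random
    # field fixed per eye and shared by both visits, as real fundus texture
    # persists between appointments
    texture_amplitude: float = 0.02
    texture_n_blobs: int = 40
    texture_sigma_range: tuple[float, float] = (10.0, 22.0)
    texture_channel_gain: tuple[float, float, float] = (1.0, 0.9, 0.8)
    noise_sigma: float = 0.025
    target_percent_change: float = 0.0
    misalign_max_translation: float = 4.0
    misalign_max_rotation_deg: float = 2.0
    misalign_max_log_scale: float = 0.02
    # grader-noise morphology applied to the truth mask to form the expert
    # annotation: positive = dilation (generous outlining), negative =
    # erosion (conservative outlining of the unambiguous lesion extent)
    annotation_morphology: int = -1
    seed: int = 0

    def __post_init__(self) -> None:
        for amp in (
            *self.drusen_center_brightness,
            *self.drusen_edge_brightness,
            *self.pigment_darkness,
            self.vessel_darkness,
            self.vignetting_amplitude,
            self.noise_sigma,
        ):
            if not 0 <= amp <= 1:
                raise ValidationError("phantom amplitudes must lie in [0, 1]")
        if self.target_percent_change < -100:
            raise ValidationError("target_percent_change must be >= -100")
        if self.n_drusen < 0 or self.n_pigment < 0 or self.n_vessels < 0:
            raise ValidationError("lesion counts must be >= 0")


@dataclass
class PhantomVisit:
    """One visit: raw per-channel rasters in jittered frames, the reference
    CFP, exact landmark pairs, the expert-style annotation, and ground truth."""

    channels: dict  # name -> float raster in the channel's own frame
    cfp: np.ndarray  # (rows, cols, 3) reference-frame color image
    landmarks: dict  # name -> LandmarkSet (moving = channel frame, fixed = reference)
    annotation: np.ndarray  # bool, reference frame (truth + grader-noise dilation)
    truth_drusen: np.ndarray  # bool, reference frame
    truth_pigment: np.ndarray
    truth_vessels: np.ndarray
    drusen_area: int


@dataclass
class PhantomPair:
    visit1: PhantomVisit
    visit2: PhantomVisit
    true_percent_change: float
    target_percent_change: float
    params: PhantomParams


@dataclass
class CohortEye:
    eye_id: str
    label: str  # planted direction: progression / stable / regression
    params: PhantomParams
    pair: PhantomPair

    @property
    def true_percent_change(self) -> float:
        return self.pair.true_percent_change


# ---------------------------------------------------------------------------
# scene construction (deterministic given params.seed)


@dataclass(frozen=True)
class _Scene:
    drusen_centers: np.ndarray  # (n, 2) row/col
    drusen_radii: np.ndarray  # (n,)
    pigment_centers: np.ndarray
    pigment_radii: np.ndarray
    vessel_lines: np.ndarray  # (m, 3): angle, offset_row, offset_col
    landmarks_ref: np.ndarray  # (8, 2) fixed-frame landmark positions
    texture_centers: np.ndarray  # (K, 2) mottle blob centers
    texture_sigmas: np.ndarray  # (K,)
    texture_amps: np.ndarray  # (K,) signed amplitudes
    texture_norm: float = 1.0  # scale making the raw field unit-std on the grid


def _place_discs(
    rng: np.random.Generator,
    n: int,
    radius_range: tuple[float, float],
    shape: tuple[int, int],
    occupied: list[tuple[np.ndarray, float]],
    field_fraction: float,
    margin: float = 4.0,
    max_tries: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping disc centers inside the central
    lesion field (so grown visit-2 lesions stay within the macular mask)."""
    rows, cols = shape
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    reach = field_fraction * cols
    centers, radii = [], []
    for _ in range(n):
        for attempt in range(max_tries):
            r = float(rng.uniform(*radius_range))
            ang = rng.uniform(0, 2 * np.pi)
            rad = reach * np.sqrt(rng.uniform())
            c = center + rad * np.array([np.sin(ang), np.cos(ang)])
            ok = all(
                np.linalg.norm(c - oc) > r + orad + margin for oc, orad in occupied
            )
            if ok:
                centers.append(c)
                radii.append(r)
                occupied.append((c, r))
                break
        else:
            raise NumericError(
                "could not place non-overlapping lesions; packing infeasible"
            )
    return np.asarray(centers).reshape(-1, 2), np.asarray(radii)


def _build_scene(params: PhantomParams) -> _Scene:
    shape = params.image_size
    occupied: list[tuple[np.ndarray, float]] = []
    d_rng = stream(params.seed, "drusen-geometry")
    drusen_c, drusen_r = _place_discs(
        d_rng,
        params.n_drusen,
        params.drusen_radius_range,
        shape,
        occupied,
        params.lesion_field_fraction,
    )
    p_rng = stream(params.seed, "pigment-geometry")
    pig_c, pig_r = _place_discs(
        p_rng,
        params.n_pigment,
        params.pigment_radius_range,
        shape,
        occupied,
        params.lesion_field_fraction,
    )
    v_rng = stream(params.seed, "vessel-geometry")
    rows, cols = shape
    lines = []
    for _ in range(params.n_vessels):
        angle = v_rng.uniform(0, np.pi)
        off = v_rng.uniform(-0.25, 0.25) * cols
        lines.append((angle, off, 0.0))
    # eight bifurcation-style landmarks on a ring inside the macular region
    ring = 0.35 * cols
    angles = np.deg2rad(np.arange(0, 360, 45))
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    lms = center + ring * np.stack([np.sin(angles), np.cos(angles)], axis=1)
    t_rng = stream(params.seed, "background-texture")
    k = params.texture_n_blobs
    tex_c = t_rng.uniform([0, 0], [rows - 1, cols - 1], size=(k, 2))
    tex_s = t_rng.uniform(*params.texture_sigma_range, size=k)
    tex_a = t_rng.normal(0.0, 1.0, size=k)
    raw = _texture_field(_grid_coords(shape), tex_c, tex_s, tex_a)
    tex_norm = 1.0 / max(float(raw.std()), 1e-9)
    return _Scene(
        drusen_centers=drusen_c,
        drusen_radii=drusen_r,
        pigment_centers=pig_c,
        pigment_radii=pig_r,
        vessel_lines=np.asarray(lines).reshape(-1, 3),
        landmarks_ref=lms,
        texture_centers=tex_c,
        texture_sigmas=tex_s,
        texture_amps=tex_a,
        texture_norm=tex_norm,
    )


def _texture_field(
    coords: np.ndarray, centers: np.ndarray, sigmas: np.ndarray, amps: np.ndarray
) -> np.ndarray:
    field = np.zeros(coords.shape[0])
    for (tr, tc), ts, ta in zip(centers, sigmas, amps):
        td2 = (coords[:, 0] - tr) ** 2 + (coords[:, 1] - tc) ** 2
        field += ta * np.exp(-td2 / (2.0 * ts**2))
    return field


def _disc_union_mask(
    shape: tuple[int, int], centers: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    return _disc_union_at(coords, centers, radii).reshape(shape)


def _disc_union_at(coords: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    mask = np.zeros(coords.shape[0], dtype=bool)
    for (cr, ccol), r in zip(centers, radii):
        mask |= (coords[:, 0] - cr) ** 2 + (coords[:, 1] - ccol) ** 2 <= r**2
    return mask


def _vessel_at(
    coords: np.ndarray,
    lines: np.ndarray,
    half_width: float,
    center: np.ndarray,
) -> np.ndarray:
    mask = np.zeros(coords.shape[0], dtype=bool)
    for angle, off, _ in lines:
        # signed distance to a line through (center + off*normal) at `angle`
        nr, nc = np.cos(angle), -np.sin(angle)  # unit normal
        dist = (coords[:, 0] - center[0]) * nr + (coords[:, 1] - center[1]) * nc - off
        mask |= np.abs(dist) <= half_width
    return mask


def _scene_fields(
    params: PhantomParams, scene: _Scene, radii_scale: float, coords: np.ndarray
) -> dict:
    """Evaluate the analytic scene at continuous reference-frame coordinates.

    Rendering is analytic so each channel can be sampled directly on its own
    (jittered) pixel grid with no interpolation — the way a sensor samples
    the eye — keeping lesion boundaries crisp.
    """
    rows, cols = params.image_size
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    d2 = np.sum((coords - center) ** 2, axis=1)
    d2_corner = float(center[0] ** 2 + center[1] ** 2)
    radii = scene.drusen_radii * radii_scale
    if params.texture_amplitude > 0 and scene.texture_amps.size:
        texture = _texture_field(
            coords, scene.texture_centers, scene.texture_sigmas, scene.texture_amps
        )
        texture *= params.texture_amplitude * scene.texture_norm
    else:
        texture = np.zeros(coords.shape[0])
    return {
        "vignette": 1.0 - params.vignetting_amplitude * d2 / d2_corner,
        "texture": texture,
        "drusen": _disc_union_at(coords, scene.drusen_centers, radii),
        "drusen_core": _disc_union_at(
            coords, scene.drusen_centers, radii * params.center_zone_fraction
        ),
        "pigment": _disc_union_at(coords, scene.pigment_centers, scene.pigment_radii),
        "vessels": _vessel_at(
            coords, scene.vessel_lines, params.vessel_half_width, center
        ),
    }


def _compose_channel(params: PhantomParams, fields: dict, channel_index: int) -> np.ndarray:
    i = channel_index
    img = 0.5 * fields["vignette"]
    img = img + params.texture_channel_gain[i] * fields["texture"]
    img = img + params.drusen_edge_brightness[i] * (
        fields["drusen"] & ~fields["drusen_core"]
    )
    img = img + params.drusen_center_brightness[i] * fields["drusen_core"]
    img = img - params.pigment_darkness[i] * fields["pigment"]
    img = img - params.vessel_darkness * (fields["vessels"] & ~fields["drusen"])
    return np.clip(img, 0.0, 1.0)


def _grid_coords(shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)


def _render_scene(
    params: PhantomParams, scene: _Scene, radii_scale: float
) -> tuple[np.ndarray, dict]:
    """Render the reference-frame channel stack (rows, cols, 3) plus the
    truth masks for drusen/pigment/vessels."""
    shape = params.image_size
    fields = _scene_fields(params, scene, radii_scale, _grid_coords(shape))
    stack = np.stack(
        [_compose_channel(params, fields, i).reshape(shape) for i in range(3)], axis=-1
    )
    truth = {
        "drusen": fields["drusen"].reshape(shape),
        "pigment": fields["pigment"].reshape(shape),
        "vessels": fields["vessels"].reshape(shape),
    }
    return stack, truth


def _render_cfp(params: PhantomParams, scene: _Scene, radii_scale: float) -> np.ndarray:
    """A simple reference-frame color fundus rendering (visual anchor only)."""
    stack, truth = _render_scene(params, scene, radii_scale)
    base = np.stack(
        [0.85 * stack[..., 0], 0.55 * stack[..., 1], 0.30 * stack[..., 2]], axis=-1
    )
    base[truth["drusen"]] += np.array([0.08, 0.08, 0.0])
    return np.clip(base, 0.0, 1.0)


def _jitter_transform(params: PhantomParams, rng: np.random.Generator) -> SpatialTransform:
    """Small random similarity jitter (channel frame -> reference frame)."""
    rows, cols = params.image_size
    theta = np.deg2rad(rng.uniform(-1, 1) * params.misalign_max_rotation_deg)
    scale = float(np.exp(rng.uniform(-1, 1) * params.misalign_max_log_scale))
    t = rng.uniform(-1, 1, size=2) * params.misalign_max_translation
    c, s = np.cos(theta), np.sin(theta)
    A = scale * np.array([[c, -s], [s, c]])
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    trans = center - A @ center + t
    return SpatialTransform(model="similarity", matrix=np.hstack([A, trans[:, None]]))


def _scale_for_target(params: PhantomParams, scene: _Scene) -> tuple[float, float]:
    """Find the radius scale for visit 2 whose rendered drusen-mask area hits
    the target percent change within 1% (relative). Returns (scale, achieved
    percent change)."""
    target_ratio = 1.0 + params.target_percent_change / 100.0
    base = _disc_union_mask(params.image_size, scene.drusen_centers, scene.drusen_radii)
    base_area = int(base.sum())
    if base_area == 0:
        if target_ratio == 1.0:
            return 1.0, 0.0
        raise NumericError("cannot apply area change: no drusen planted")
    if target_ratio == 0.0:
        raise NumericError("a -100% change would erase all lesions")

    def area_ratio(s: float) -> float:
        m = _disc_union_mask(
            params.image_size, scene.drusen_centers, scene.drusen_radii * s
        )
        return m.sum() / base_area

    lo, hi = np.sqrt(target_ratio) * 0.7, np.sqrt(target_ratio) * 1.4
    if area_ratio(lo) > target_ratio or area_ratio(hi) < target_ratio:
        raise NumericError(
            f"target change {params.target_percent_change}% unreachable by scaling"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if area_ratio(mid) < target_ratio:
            lo = mid
        else:
            hi = mid
    scale = hi
    achieved = 100.0 * (area_ratio(scale) - 1.0)
    if abs(achieved - params.target_percent_change) > max(
        1.0, 0.01 * abs(params.target_percent_change)
    ):
        raise NumericError(
            f"could not match target change {params.target_percent_change}%: "
            f"achieved {achieved:.2f}%"
        )
    return scale, achieved


def generate_visit(params: PhantomParams, visit_index: int) -> PhantomVisit:
    """Generate one visit (0-based index; index 1 carries the area change).

    Deterministic given ``params.seed``: the underlying scene is shared by
    both visit indices, so calling with index 0 and 1 yields a registered
    longitudinal pair.
    """
    if visit_index not in (0, 1):
        raise ValidationError("visit_index must be 0 or 1")
    scene = _build_scene(params)
    scale = 1.0
    if visit_index == 1 and params.n_drusen > 0:
        scale, _ = _scale_for_target(params, scene)
    stack, truth = _render_scene(params, scene, scale)
    cfp = _render_cfp(params, scene, scale)

    channels: dict[str, np.ndarray] = {}
    landmarks: dict[str, LandmarkSet] = {}
    grid = _grid_coords(params.image_size)
    for i, name in enumerate(CHANNELS):
        rng = stream(params.seed, f"visit{visit_index}-{name}")
        jitter = _jitter_transform(params, rng)  # channel -> reference
        inv = jitter.inverse()
        # sample the analytic scene directly on the channel's own (jittered)
        # pixel grid — no interpolation in the synthetic raw image
        ref_coords = jitter.apply(grid)
        fields = _scene_fields(params, scene, scale, ref_coords)
        raw = _compose_channel(params, fields, i).reshape(params.image_size)
        if params.noise_sigma > 0:
            raw = raw + rng.normal(0.0, params.noise_sigma, size=raw.shape)
        channels[name] = np.clip(raw, 0.0, 1.0)
        landmarks[name] = LandmarkSet(
            moving=inv.apply(scene.landmarks_ref), fixed=scene.landmarks_ref
        )

    annotation = truth["drusen"]
    if params.annotation_morphology > 0:
        annotation = ndimage.binary_dilation(
            annotation, iterations=params.annotation_morphology
        )
    elif params.annotation_morphology < 0:
        annotation = ndimage.binary_erosion(
            annotation, iterations=-params.annotation_morphology
        )
    return PhantomVisit(
        channels=channels,
        cfp=cfp,
        landmarks=landmarks,
        annotation=annotation,
        truth_drusen=truth["drusen"],
        truth_pigment=truth["pigment"],
        truth_vessels=truth["vessels"],
        drusen_area=int(truth["drusen"].sum()),
    )


def generate_pair(params: PhantomParams) -> PhantomPair:
    """Generate both visits and record the achieved ground-truth change."""
    v1 = generate_visit(params, 0)
    v2 = generate_visit(params, 1)
    if v1.drusen_area > 0:
        true_pct = 100.0 * (v2.drusen_area / v1.drusen_area - 1.0)
    else:
        true_pct = 0.0
    return PhantomPair(
        visit1=v1,
        visit2=v2,
        true_percent_change=true_pct,
        target_percent_change=params.target_percent_change,
        params=params,
    )


_LABEL_RANGES = {
    PROGRESSION: (6.0, 40.0),
    STABLE: (-4.0, 4.0),
    REGRESSION: (-40.0, -6.0),
}


def generate_cohort(
    n_progression: int = 11,
    n_stable: int = 11,
    n_regression: int = 11,
    seed: int = 0,
    base_params: PhantomParams | None = None,
) -> list[CohortEye]:
    """Seeded phantom cohort with expert-style direction labels.

    Defaults mirror the balanced three-subgroup study design (11 eyes per
    direction). Per-eye target changes are drawn uniformly from the label's
    range: progression (+6, +40)%, stable (−4, +4)%, regression
    (−40, −6)%.
    """
    if min(n_progression, n_stable, n_regression) < 0:
        raise ValidationError("cohort counts must be >= 0")
    base = base_params or PhantomParams()
    labels = (
        [PROGRESSION] * n_progression + [STABLE] * n_stable + [REGRESSION] * n_regression
    )
    eyes: list[CohortEye] = []
    for i, label in enumerate(labels):
        eye_id = f"P{i + 1:03d}"
        rng = stream(seed, f"cohort-eye-{i}")
        target = float(rng.uniform(*_LABEL_RANGES[label]))
        eye_seed = int(rng.integers(2**31))
        n_drusen = int(rng.integers(3, 6))
        params = replace(
            base,
            seed=eye_seed,
            target_percent_change=target,
            n_drusen=n_drusen,
        )
        eyes.append(
            CohortEye(eye_id=eye_id, label=label, params=params, pair=generate_pair(params))
        )
    return eyes
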