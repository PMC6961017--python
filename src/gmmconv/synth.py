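"""Synthetic test data: blob masks and ear-detection scenes.

Nothing here is downloaded.  The scene generator emulates the structure
of profile-image ear-detection data: a grayscale image with a textured
background, one large head-like bright region, and a single connected
bright ear-like target (an ellipse with a darker internal notch) sitting
on the head boundary, rotated in-plane by a controllable angle about its
own centre; the matching binary mask marks the target exactly.  Subjects
keep their appearance parameters (head shape and brightness, ear size
and resting orientation) across all of their scenes so that a
person-disjoint train/validation/test split genuinely tests
generalisation to unseen subjects.

Shapes are rendered from analytic ellipse equations evaluated on rotated
coordinates, so a rotated scene equals the unrotated scene rigidly
rotated about the target centre, up to pixel discretisation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

BACKGROUND_TEXTURES = ("flat", "gradient", "noise")

#: split proportions by subject count (train : val : test), matching a
#: 126-person cohort split 75 / 25 / 26.
SPLIT_WEIGHTS = (75, 25, 26)


@dataclass
class SceneSpec:
    """Deterministic description of one scene; equal specs yield identical scenes."""

    seed: int = 0
    size: Tuple[int, int] = (96, 128)
    rotation: float = 0.0
    illumination: float = 1.0
    background_texture: str = "noise"
    subject_id: int = 0
    scene_id: int = 0  # varies only the background noise realisation

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError("scene must be at least 32x32 pixels")
        if self.background_texture not in BACKGROUND_TEXTURES:
            raise ValueError(f"unknown background texture {self.background_texture!r}")


@dataclass
class Scene:
    """A generated image, its binary target mask and bookkeeping."""

    image: np.ndarray
    mask: np.ndarray
    bbox: Tuple[int, int, int, int]  # (rmin, cmin, rmax, cmax), inclusive
    rotation: float
    subject_id: int


def _xy_grid(shape) -> Tuple[np.ndarray, np.ndarray]:
    rr, cc = np.indices(shape, dtype=np.float64)
    return cc, rr  # x = col, y = row (y handled with sign at use sites)


def _ellipse(shape, center_rc, axes, angle) -> np.ndarray:
    """Boolean ellipse with semi-axes ``axes`` rotated by ``angle`` (ccw, y up)."""
    x, yrow = _xy_grid(shape)
    dx = x - center_rc[1]
    dy = -(yrow - center_rc[0])  # y points upward
    c, s = np.cos(angle), np.sin(angle)
    xr = c * dx + s * dy
    yr = -s * dx + c * dy
    a, b = axes
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _tight_bbox(mask: np.ndarray) -> Tuple[int, int, int, int]:
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return int(rows[0]), int(cols[0]), int(rows[-1]), int(cols[-1])


def gen_blob_mask(seed: int, size: Tuple[int, int] = (96, 128)) -> np.ndarray:
    """One connected, smooth random blob covering 10-40% of the frame.

    The blob boundary is a star-convex radius function r(phi) with a few
    low-order harmonics, which guarantees 4-connectivity.
    """
    rng = np.random.default_rng(seed)
    h, w = size
    cy = h / 2 + rng.uniform(-h * 0.06, h * 0.06)
    cx = w / 2 + rng.uniform(-w * 0.06, w * 0.06)
    frac = rng.uniform(0.15, 0.33)
    r0 = np.sqrt(frac * h * w / np.pi)
    n_harm = 3
    amps = rng.uniform(0.0, 0.16, size=n_harm) * r0
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)
    x, yrow = _xy_grid((h, w))
    dx = x - cx
    dy = -(yrow - cy)
    phi = np.arctan2(dy, dx)
    r = np.hypot(dx, dy)
    radius = r0 * np.ones_like(phi)
    for k in range(n_harm):
        radius += amps[k] * np.cos((k + 2) * phi + phases[k])
    mask = (r <= radius).astype(np.int64)
    return mask


def _subject_params(seed: int, subject_id: int, size) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, subject_id)))
    h, w = size
    return {
        "bg_level": rng.uniform(0.15, 0.3),
        "head_level": rng.uniform(0.45, 0.55),
        "head_center": (h * rng.uniform(0.42, 0.58), w * rng.uniform(0.3, 0.4)),
        "head_axes": (w * rng.uniform(0.2, 0.26), h * rng.uniform(0.34, 0.42)),
        "ear_site_angle": rng.uniform(-0.35, 0.35),  # around horizontal-right
        "ear_axes": (rng.uniform(10.0, 13.0), rng.uniform(6.0, 8.0)),
        "ear_base_angle": rng.uniform(-0.3, 0.3) + np.pi / 2,
        "ear_level": rng.uniform(0.88, 0.98),
        "notch_level": rng.uniform(0.45, 0.6),
    }


def gen_scene(spec: SceneSpec, border_margin: float = 16.0) -> Scene:
    """Render one scene from its spec.

    ``border_margin`` keeps the target centre at least that many pixels
    from the frame border (pass 0 to allow border placement, a known
    failure mode worth probing).
    """
    h, w = spec.size
    p = _subject_params(spec.seed, spec.subject_id, spec.size)
    noise_rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(2, spec.subject_id, spec.scene_id)))

    if spec.background_texture == "flat":
        img = np.full((h, w), p["bg_level"])
    elif spec.background_texture == "gradient":
        ramp = np.linspace(-0.08, 0.08, w)[None, :]
        img = np.full((h, w), p["bg_level"]) + ramp
    else:
        noise = noise_rng.normal(0.0, 1.0, size=(h, w))
        noise = ndimage.gaussian_filter(noise, sigma=3.0)
        noise *= 0.05 / max(noise.std(), 1e-12)
        img = np.full((h, w), p["bg_level"]) + noise

    hc = p["head_center"]
    head = _ellipse((h, w), hc, p["head_axes"], 0.0)
    img[head] = p["head_level"]

    # ear centre on the head boundary, right-hand side (profile view)
    psi = p["ear_site_angle"]
    ec_col = hc[1] + p["head_axes"][0] * np.cos(psi)
    ec_row = hc[0] - p["head_axes"][1] * np.sin(psi)
    ec_row = float(np.clip(ec_row, border_margin, h - 1 - border_margin))
    ec_col = float(np.clip(ec_col, border_margin, w - 1 - border_margin))
    angle = p["ear_base_angle"] + spec.rotation

    outer = _ellipse((h, w), (ec_row, ec_col), p["ear_axes"], angle)
    # notch: a smaller darker ellipse offset along the ear's minor axis,
    # rotating rigidly with the ear about its centre
    off = np.array([p["ear_axes"][1] * 0.35, 0.0])
    c, s = np.cos(angle), np.sin(angle)
    off_x = c * off[0] - s * off[1]
    off_y = s * off[0] + c * off[1]
    notch_center = (ec_row - off_y, ec_col + off_x)
    notch = _ellipse((h, w), notch_center,
                     (p["ear_axes"][0] * 0.55, p["ear_axes"][1] * 0.45), angle)
    img[outer] = p["ear_level"]
    img[outer & notch] = p["notch_level"]

    img = np.clip(img * spec.illumination, 0.0, 1.0)
    mask = outer.astype(np.int64)
    if not mask.any():
        raise RuntimeError("degenerate scene: empty target mask")
    return Scene(image=img, mask=mask, bbox=_tight_bbox(mask),
                 rotation=spec.rotation, subject_id=spec.subject_id)


def split_subjects(n_subjects: int, seed: int) -> Dict[str, List[int]]:
    """Person-disjoint split with 75:25:26 proportions by subject count."""
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for a three-way split")
    total = sum(SPLIT_WEIGHTS)
    n_tr = max(1, int(round(n_subjects * SPLIT_WEIGHTS[0] / total)))
    n_va = max(1, int(round(n_subjects * SPLIT_WEIGHTS[1] / total)))
    n_te = n_subjects - n_tr - n_va
    if n_te < 1:
        n_te = 1
        n_tr = n_subjects - n_va - n_te
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    order = rng.permutation(n_subjects).tolist()
    return {
        "train": sorted(order[:n_tr]),
        "val": sorted(order[n_tr:n_tr + n_va]),
        "test": sorted(order[n_tr + n_va:]),
    }


def gen_dataset(
    n_subjects: int,
    scenes_per_subject: int,
    rotation_range: Tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    size: Tuple[int, int] = (96, 128),
) -> Tuple[List[Scene], Dict[str, List[int]]]:
    """Scenes for ``n_subjects`` people plus a person-disjoint split.

    Rotations are drawn uniformly from ``rotation_range`` per scene;
    illumination varies in [0.85, 1.15]; background texture cycles
    through the available kinds.  Returns ``(scenes, split)`` where
    ``split`` maps split names to subject ids and every scene records its
    ``subject_id``.
    """
    split = split_subjects(n_subjects, seed)
    scenes: List[Scene] = []
    for sid in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3, sid)))
        for i in range(scenes_per_subject):
            lo, hi = rotation_range
            rot = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            spec = SceneSpec(
                seed=seed, size=size, rotation=rot,
                illumination=float(rng.uniform(0.85, 1.15)),
                background_texture=BACKGROUND_TEXTURES[i % len(BACKGROUND_TEXTURES)],
                subject_id=sid, scene_id=i)
            scenes.append(gen_scene(spec))
    return scenes, split


def scenes_by_split(scenes: Sequence[Scene], split: Dict[str, List[int]]) -> Dict[str, List[Scene]]:
    """Group scenes by the split their subject belongs to."""
    member = {sid: name for name, ids in split.items() for sid in ids}
    out: Dict[str, List[Scene]] = {"train": [], "val": [], "test": []}
    for sc in scenes:
        out[member[sc.subject_id]].append(sc)
    return out
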