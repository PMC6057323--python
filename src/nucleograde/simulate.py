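"""Seeded synthetic H&E-like image cohorts with ground truth.

Emulates the acquisition structure of the clinical material the package
targets: two groups of 22 patients, 4-5 grayscale images per patient,
each a field of non-overlapping darkly-stained elliptical nuclei on a
lighter noisy background.  The two named presets plant the group
differences reported for advancing CIN grade: the ``high_like`` preset
has larger nuclei, more irregular boundaries, coarser intra-nuclear
texture and stronger intensity inhomogeneity than ``low_like``.

Nucleus shapes are star-convex radial-harmonic perturbations of an
ellipse (harmonics 3-6), so boundary irregularity is one controllable
scalar while masks stay single-component.  Intra-nuclear texture is a
Gaussian random field whose correlation length maps monotonically to
Tamura coarseness.  One seed stream is split hierarchically
(cohort -> patient -> image -> nucleus) so every sub-unit is
independently reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import write_image, write_table

MIN_BASE_RADIUS = 14.0  # keeps planted nuclei above the 500-px size filter
PLACEMENT_GAP = 4.0     # minimum clearance between nucleus envelopes, px
HARMONICS = (3, 4, 5, 6)


@dataclass
class NucleusSpec:
    """Planted parameters of one nucleus."""

    center: tuple[float, float]
    base_radius: float
    aspect: float = 1.0
    orientation: float = 0.0
    irregularity_amp: float = 0.0
    texture_corr_len: float = 3.0
    mean_intensity: float = 90.0
    intensity_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.base_radius < MIN_BASE_RADIUS:
            raise ValueError(f"base_radius must be >= {MIN_BASE_RADIUS}")
        if not (0.0 <= self.irregularity_amp <= 0.35):
            raise ValueError("irregularity_amp must lie in [0, 0.35]")
        if self.aspect < 1.0:
            raise ValueError("aspect is major/minor and must be >= 1")

    @property
    def max_radius(self) -> float:
        """Upper bound of the perturbed envelope radius."""
        return self.base_radius * np.sqrt(self.aspect) * (1.0 + self.irregularity_amp)


@dataclass
class GroupParams:
    """Sampling distributions (mean, sd) of the nucleus parameters for
    one patient group, plus per-image scene parameters.

    ``images_per_patient=None`` alternates 4 and 5 images per patient.
    """

    radius_mean: float = 18.0
    radius_sd: float = 1.6
    aspect_mean: float = 1.3
    aspect_sd: float = 0.15
    irregularity_mean: float = 0.08
    irregularity_sd: float = 0.03
    corr_len_mean: float = 3.0
    corr_len_sd: float = 0.5
    intensity_mean: float = 95.0
    intensity_between_sd: float = 8.0
    intensity_sd_mean: float = 10.0
    intensity_sd_sd: float = 2.0
    nuclei_per_image: int = 8
    images_per_patient: int | None = None  # None -> alternate 4 / 5
    background_intensity: float = 200.0
    background_noise_sd: float = 6.0

    def __post_init__(self) -> None:
        for name in ("radius_sd", "aspect_sd", "irregularity_sd", "corr_len_sd",
                     "intensity_between_sd", "intensity_sd_sd", "background_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nuclei_per_image < 0:
            raise ValueError("nuclei_per_image must be >= 0")

    @classmethod
    def preset(cls, name: str) -> "GroupParams":
        """Named presets: ``low_like`` and ``high_like``; the high-grade
        preset has strictly larger radius, irregularity, correlation
        length and intensity inhomogeneity."""
        if name == "low_like":
            return cls()
        if name == "high_like":
            return cls(radius_mean=22.0, radius_sd=2.2, aspect_mean=1.45, aspect_sd=0.2,
                       irregularity_mean=0.18, irregularity_sd=0.05,
                       corr_len_mean=6.0, corr_len_sd=1.0,
                       intensity_mean=85.0, intensity_between_sd=10.0,
                       intensity_sd_mean=18.0, intensity_sd_sd=3.0)
        raise ValueError(f"unknown preset {name!r}")

    def sample_spec(self, rng: np.random.Generator, center: tuple[float, float]) -> NucleusSpec:
        # radius and aspect are truncated at +-3 sd so every nucleus is
        # guaranteed to fit the placement envelope
        radius = float(np.clip(rng.normal(self.radius_mean, self.radius_sd),
                               max(MIN_BASE_RADIUS, self.radius_mean - 3 * self.radius_sd),
                               self.radius_mean + 3 * self.radius_sd))
        aspect = float(np.clip(rng.normal(self.aspect_mean, self.aspect_sd),
                               1.0, self.aspect_mean + 3 * self.aspect_sd))
        return NucleusSpec(
            center=center,
            base_radius=radius,
            aspect=aspect,
            orientation=rng.uniform(0, np.pi),
            irregularity_amp=float(np.clip(rng.normal(self.irregularity_mean, self.irregularity_sd), 0.0, 0.35)),
            texture_corr_len=max(0.5, rng.normal(self.corr_len_mean, self.corr_len_sd)),
            mean_intensity=float(np.clip(rng.normal(self.intensity_mean, self.intensity_between_sd), 30, 180)),
            intensity_sd=max(0.0, rng.normal(self.intensity_sd_mean, self.intensity_sd_sd)),
        )


@dataclass
class CohortSpec:
    """Full cohort description; identical spec + seed reproduce
    bit-identical outputs."""

    n_patients_per_group: int = 22
    seed: int = 0
    image_size: tuple[int, int] = (512, 512)
    low: GroupParams = field(default_factory=lambda: GroupParams.preset("low_like"))
    high: GroupParams = field(default_factory=lambda: GroupParams.preset("high_like"))

    def __post_init__(self) -> None:
        if self.n_patients_per_group < 1:
            raise ValueError("n_patients_per_group must be >= 1")


class PlacementError(RuntimeError):
    """Dart-throwing could not place the requested nuclei; use fewer
    nuclei per image or a larger frame."""


def make_nucleus_mask(spec: NucleusSpec, frame: tuple[int, int],
                      rng: np.random.Generator) -> np.ndarray:
    """Rasterize one star-convex nucleus mask in a full frame.

    The boundary radius is ``r(theta) = ellipse(theta) * (1 +
    amp * sum_h a_h cos(h theta + phi_h))`` over harmonics 3-6, with the
    harmonic weights (normalized to sum 1) and phases drawn from ``rng``.
    """
    H, W = frame
    r0, c0 = spec.center
    if not (spec.max_radius + 2 <= r0 <= H - 1 - spec.max_radius - 2 and
            spec.max_radius + 2 <= c0 <= W - 1 - spec.max_radius - 2):
        raise ValueError("nucleus does not fit inside the frame with a 2-px margin")
    weights = rng.uniform(0.2, 1.0, size=len(HARMONICS))
    weights /= weights.sum()
    phases = rng.uniform(0, 2 * np.pi, size=len(HARMONICS))

    ext = int(np.ceil(spec.max_radius)) + 2
    rr, cc = np.mgrid[-ext:ext + 1, -ext:ext + 1].astype(float)
    rho = np.hypot(rr, cc)
    theta = np.arctan2(rr, cc)
    # ellipse radius with preserved area: semi-axes r*sqrt(aspect), r/sqrt(aspect)
    a = spec.base_radius * np.sqrt(spec.aspect)
    b = spec.base_radius / np.sqrt(spec.aspect)
    phi = theta - spec.orientation
    r_ell = (a * b) / np.hypot(b * np.cos(phi), a * np.sin(phi))
    pert = np.zeros_like(theta)
    for h, w_h, ph in zip(HARMONICS, weights, phases):
        pert += w_h * np.cos(h * theta + ph)
    r_bound = r_ell * (1.0 + spec.irregularity_amp * pert)
    local = rho <= r_bound

    mask = np.zeros(frame, dtype=bool)
    ri, ci = int(round(r0)), int(round(c0))
    mask[ri - ext:ri + ext + 1, ci - ext:ci + ext + 1] = local
    # guard: keep the largest component should extreme perturbations pinch
    labels, n = ndi.label(mask, structure=np.ones((3, 3), bool))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (1 + int(np.argmax(counts)))
    return mask


def _place_centers(rng: np.random.Generator, group: GroupParams,
                   frame: tuple[int, int], n: int, max_tries: int = 400):
    """Dart-throwing placement guaranteeing non-overlap with clearance."""
    H, W = frame
    # conservative envelope bound used both for margins and spacing
    r_env = (group.radius_mean + 3 * group.radius_sd) * np.sqrt(group.aspect_mean + 3 * group.aspect_sd) * 1.35
    margin = r_env + PLACEMENT_GAP
    if H - 2 * margin <= 0 or W - 2 * margin <= 0:
        raise PlacementError("frame too small for the nucleus size distribution")
    # whole-configuration restarts: an unlucky early dart can make the
    # remaining placements infeasible even when a valid layout exists
    for _restart in range(40):
        centers: list[tuple[float, float]] = []
        for _ in range(n):
            for _try in range(max_tries):
                cand = (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))
                if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) >= 2 * r_env + PLACEMENT_GAP
                       for c in centers):
                    centers.append(cand)
                    break
            else:
                break
        if len(centers) == n:
            return centers
    raise PlacementError(f"could not place {n} nuclei in a {H}x{W} frame; use fewer nuclei")


def _gaussian_field(rng: np.random.Generator, shape: tuple[int, int],
                    corr_len: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length
    ``corr_len`` (Gaussian-kernel smoothing of white noise)."""
    white = rng.normal(size=shape)
    f = ndi.gaussian_filter(white, sigma=corr_len, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else np.zeros(shape)


def render_image(specs: list[NucleusSpec], group: GroupParams,
                 frame: tuple[int, int], seed) -> tuple[np.ndarray, np.ndarray]:
    """Render one grayscale scene and its ground-truth label mask.

    Background is ``background_intensity`` plus white noise; each
    nucleus is filled with its mean intensity plus a Gaussian random
    field scaled to its intensity SD, blended over a ~2-px smoothed
    boundary transition.  Fully determined by ``specs`` and ``seed``.
    """
    rng = np.random.default_rng(seed)
    H, W = frame
    img = group.background_intensity + rng.normal(0, group.background_noise_sd, size=frame)
    labels = np.zeros(frame, dtype=np.uint16)
    for idx, spec in enumerate(specs, start=1):
        nuc_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
        mask = make_nucleus_mask(spec, frame, nuc_rng)
        rr, cc = np.nonzero(mask)
        r0, r1 = rr.min() - 3, rr.max() + 4
        c0, c1 = cc.min() - 3, cc.max() + 4
        sub = mask[r0:r1, c0:c1]
        tex = spec.mean_intensity + spec.intensity_sd * _gaussian_field(
            nuc_rng, sub.shape, spec.texture_corr_len)
        w = ndi.gaussian_filter(sub.astype(float), 1.0, mode="constant")
        img[r0:r1, c0:c1] = img[r0:r1, c0:c1] * (1 - w) + tex * w
        labels[mask] = idx
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), labels


def sample_image(rng: np.random.Generator, group: GroupParams,
                 frame: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, list[NucleusSpec]]:
    """Sample nucleus specs for one scene and render it."""
    centers = _place_centers(rng, group, frame, group.nuclei_per_image)
    specs = [group.sample_spec(rng, c) for c in centers]
    gray, labels = render_image(specs, group, frame, rng.integers(0, 2 ** 31))
    return gray, labels, specs


def iter_cohort(spec: CohortSpec):
    """Yield ``(patient_id, group_name, images)`` where ``images`` is a
    list of ``(gray, labels, nucleus_specs)`` tuples; deterministic in
    ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    for g_idx, (g_name, params) in enumerate((("low", spec.low), ("high", spec.high))):
        group_seq = root.spawn(2)[g_idx]
        patient_seqs = group_seq.spawn(spec.n_patients_per_group)
        for p_idx in range(spec.n_patients_per_group):
            rng = np.random.default_rng(patient_seqs[p_idx])
            n_images = params.images_per_patient or (4 + p_idx % 2)
            pid = f"{g_name}_{p_idx + 1:03d}"
            images = [sample_image(rng, params, spec.image_size) for _ in range(n_images)]
            yield pid, g_name, images


def generate_cohort(spec: CohortSpec, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write a full synthetic cohort to disk.

    Produces ``images/*.png`` (8-bit grayscale), ``masks/*.png`` (16-bit
    ground-truth labels), ``manifest.csv`` (patient_id, image_path,
    group) and ``ground_truth.csv`` (per-nucleus planted parameters).
    Returns the manifest.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "masks"), exist_ok=True)
    manifest_rows, truth_rows = [], []
    for pid, g_name, images in iter_cohort(spec):
        for i_idx, (gray, labels, specs) in enumerate(images, start=1):
            rel = os.path.join("images", f"{pid}_img{i_idx}.png")
            write_image(os.path.join(out_dir, rel), gray)
            write_image(os.path.join(out_dir, "masks", f"{pid}_img{i_idx}.png"), labels)
            manifest_rows.append({"patient_id": pid, "image_path": rel, "group": g_name})
            for n_idx, s in enumerate(specs, start=1):
                truth_rows.append({
                    "patient_id": pid, "image_path": rel, "nucleus_label": n_idx,
                    "center_row": s.center[0], "center_col": s.center[1],
                    "base_radius": s.base_radius, "aspect": s.aspect,
                    "orientation": s.orientation, "irregularity_amp": s.irregularity_amp,
                    "texture_corr_len": s.texture_corr_len,
                    "mean_intensity": s.mean_intensity, "intensity_sd": s.intensity_sd,
                })
    manifest = pd.DataFrame(manifest_rows)
    write_table(manifest, os.path.join(out_dir, "manifest.csv"))
    write_table(pd.DataFrame(truth_rows), os.path.join(out_dir, "ground_truth.csv"))
    return manifest
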