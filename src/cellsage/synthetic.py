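"""Two-class synthetic histology-like patch generator.

Benign patches place roughly circular nuclei by a homogeneous Poisson
process; malignant patches use a clustered parent-offspring (Thomas-type)
process with denser, larger, more eccentric nuclei. Patients carry their own
density/size/stain offsets so patient-wise partitioning is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import color as skcolor
from skimage.draw import ellipse

from .data import (BENIGN_SUBTYPES, MAGNIFICATIONS, MALIGNANT_SUBTYPES,
                   DatasetIndex, SampleRecord, write_manifest)

STROMA_RGB = np.array([230.0, 180.0, 200.0])
NUCLEUS_RGB = np.array([90.0, 60.0, 130.0])


@dataclass
class SyntheticConfig:
    patch_size: int = 96
    n_patients_per_class: int = 14
    images_per_patient: int = 10
    benign_density: float = 0.8        # nuclei per kilo-pixel
    malignant_density: float = 4.5
    benign_radius: tuple[float, float] = (3.5, 0.4)     # mean, sd (pixels)
    malignant_radius: tuple[float, float] = (5.0, 1.4)
    malignant_eccentricity: float = 2.5  # max major/minor axis ratio
    cluster_spread: float = 7.0          # offspring sd around cluster parents
    mean_cluster_size: float = 5.0
    stain_jitter_sd: float = 0.05
    patient_density_sd: float = 0.15     # relative, log-normal
    patient_radius_sd: float = 0.25      # pixels, additive
    patient_stain_sd: float = 2.0        # CIELAB offset sd
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.patch_size < 64:
            raise ValueError(f"patch_size must be >= 64, got {self.patch_size}")
        if self.malignant_density <= self.benign_density:
            raise ValueError("malignant_density must exceed benign_density")
        for sd in (self.benign_radius[1], self.malignant_radius[1],
                   self.stain_jitter_sd, self.patient_density_sd,
                   self.patient_radius_sd, self.patient_stain_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")


@dataclass
class SyntheticPatient:
    patient_id: str
    class_label: str
    subtype: str
    density_factor: float = 1.0
    radius_offset: float = 0.0
    stain_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))


def make_patients(config: SyntheticConfig) -> list[SyntheticPatient]:
    """Draw per-patient effects once, deterministically from config.seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    patients = []
    for label, prefix, subtypes in (("benign", "B", BENIGN_SUBTYPES),
                                    ("malignant", "M", MALIGNANT_SUBTYPES)):
        for i in range(config.n_patients_per_class):
            patients.append(SyntheticPatient(
                patient_id=f"{prefix}{i + 1:03d}",
                class_label=label,
                subtype=subtypes[i % len(subtypes)],
                density_factor=float(np.exp(rng.normal(0.0, config.patient_density_sd))),
                radius_offset=float(rng.normal(0.0, config.patient_radius_sd)),
                stain_offset=rng.normal(0.0, config.patient_stain_sd, size=3),
            ))
    return patients


def _nucleus_positions(rng, config, label, expected):
    size = config.patch_size
    if label == "benign":
        n = rng.poisson(expected)
        return rng.uniform(0, size, size=(n, 2))
    # Thomas process: Poisson parents, Gaussian offspring around each parent
    n_parents = rng.poisson(max(expected / config.mean_cluster_size, 0.1))
    pts = []
    for _ in range(n_parents):
        parent = rng.uniform(0, size, size=2)
        n_off = rng.poisson(config.mean_cluster_size)
        pts.append(parent + rng.normal(0.0, config.cluster_spread, size=(n_off, 2)))
    if not pts:
        return np.empty((0, 2))
    all_pts = np.concatenate(pts)
    inside = np.all((all_pts >= 0) & (all_pts < size), axis=1)
    return all_pts[inside]


def render_patch(patient: SyntheticPatient, config: SyntheticConfig,
                 draw_seed: int, return_meta: bool = False):
    """Render one patch; optionally return the placement log for oracles."""
    rng = np.random.default_rng(draw_seed)
    size = config.patch_size
    benign = patient.class_label == "benign"
    density = (config.benign_density if benign else config.malignant_density)
    expected = density * patient.density_factor * size * size / 1000.0
    positions = _nucleus_positions(rng, config, patient.class_label, expected)

    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = STROMA_RGB
    # low-frequency stromal texture + pixel noise
    coarse = rng.normal(0.0, 12.0, size=(size // 8 + 1, size // 8 + 1, 3))
    texture = np.kron(coarse, np.ones((8, 8, 1)))[:size, :size]
    img += texture + rng.normal(0.0, config.noise_sd, size=img.shape)

    mean_r, sd_r = config.benign_radius if benign else config.malignant_radius
    for (cy, cx) in positions:
        r_major = max(rng.normal(mean_r + patient.radius_offset, sd_r), 1.2)
        ratio = rng.uniform(1.0, 1.3 if benign else config.malignant_eccentricity)
        r_minor = max(r_major / ratio, 1.0)
        theta = rng.uniform(0.0, np.pi)
        rr, cc = ellipse(cy, cx, r_major, r_minor, shape=(size, size), rotation=theta)
        shade = NUCLEUS_RGB + rng.normal(0.0, 8.0, size=3)
        img[rr, cc] = shade + rng.normal(0.0, 4.0, size=(rr.size, 3))

    # per-patient stain shift in CIELAB
    if np.any(patient.stain_offset):
        lab = skcolor.rgb2lab(np.clip(img / 255.0, 0.0, 1.0))
        lab += patient.stain_offset
        img = np.clip(skcolor.lab2rgb(lab), 0.0, 1.0) * 255.0
    patch = np.clip(img, 0.0, 255.0).astype(np.uint8)
    if return_meta:
        return patch, {"nucleus_count": len(positions),
                       "positions": positions, "expected": expected}
    return patch


def stain_perturb(image: np.ndarray, stain_jitter_sd: float,
                  draw_seed: int) -> np.ndarray:
    """Random per-channel affine perturbation in CIELAB; identity at sd = 0."""
    arr = np.asarray(image)
    if stain_jitter_sd == 0.0:
        return arr.copy()
    rng = np.random.default_rng(draw_seed)
    scale = rng.normal(1.0, stain_jitter_sd, size=3)
    offset = rng.normal(0.0, stain_jitter_sd * 25.0, size=3)
    lab = skcolor.rgb2lab(np.clip(arr.astype(np.float64) / 255.0, 0.0, 1.0))
    lab = lab * scale + offset
    out = np.clip(skcolor.lab2rgb(lab), 0.0, 1.0) * 255.0
    return out.astype(arr.dtype if arr.dtype == np.uint8 else np.float64)


def reference_patch(config: SyntheticConfig | None = None) -> np.ndarray:
    """Canonical benign patch used as the default stain-profile reference."""
    config = config or SyntheticConfig()
    patient = SyntheticPatient("REF", "benign", BENIGN_SUBTYPES[0])
    return render_patch(patient, config, draw_seed=20_000)


def generate_dataset(config: SyntheticConfig, out_dir: str | Path):
    """Write PNG patches + manifest.csv; returns (manifest path, index)."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    patients = make_patients(config)
    records = []
    counter = 0
    for patient in patients:
        for j in range(config.images_per_patient):
            ss = np.random.SeedSequence([config.seed, 7, counter])
            draw_seed, jitter_seed = [int(s) for s in ss.generate_state(2)]
            patch = render_patch(patient, config, draw_seed)
            patch = stain_perturb(patch, config.stain_jitter_sd, jitter_seed)
            fname = f"{patient.patient_id}_{j:03d}.png"
            Image.fromarray(patch, mode="RGB").save(img_dir / fname)
            records.append(SampleRecord(
                image_path=str(img_dir / fname),
                patient_id=patient.patient_id,
                class_label=patient.class_label,
                subtype=patient.subtype,
                magnification=MAGNIFICATIONS[j % len(MAGNIFICATIONS)],
            ))
            counter += 1
    manifest = out_dir / "manifest.csv"
    write_manifest(records, manifest)
    return manifest, DatasetIndex(records)
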