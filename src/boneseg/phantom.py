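"""Synthetic patella-like phantom with cartilage layer and ground-truth masks.

The bone body is a superellipsoid (exponent 2.5), which has a flatter
articular facet than an ellipsoid; a cartilage layer of uniform thickness
(measured along +x, the articular axis) covers the central portion of the
+x face.  Volumes are rasterized at modality-specific voxel spacings with
modality-specific nominal tissue intensities plus additive Gaussian noise.
Ground-truth bone/cartilage masks and the cartilage-adjacent bone-surface
region are rasterized from the same analytic geometry, so every validation
experiment has an exact reference.

Two imaging "arms" are emulated: a high bone–cartilage-contrast T1-VIBE-like
MRI (contrast 0.95), a DESS-like MRI (contrast 0.72), and a CT arm with
bright bone.  "Scan/re-scan" is emulated as two noise realizations of the
same anatomy plus a small rigid pose perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .registration import RigidTransform
from .volume_io import ImageVolume, Modality

TISSUES = ("background", "bone", "cartilage")

#: label codes used in exported truth volumes
LABEL_BACKGROUND, LABEL_BONE, LABEL_CARTILAGE = 0, 1, 2


@dataclass
class PhantomSpec:
    """Full parameterization of the synthetic phantom.

    Attributes
    ----------
    bone_semiaxes : (a, b, c) mm
        Superellipsoid semiaxes along (x, y, z).
    cartilage_thickness : mm
        Thickness of the cartilage shell on the +x articular face,
        measured along x.
    facet_fraction : float in (0, 1)
        Fraction of the +x face silhouette covered by cartilage; keeps the
        layer off the bone's equatorial rim, as articular cartilage is.
    exponent : float
        Superellipsoid exponent (2 = ellipsoid; 2.5 gives a flatter facet).
    spacing : modality -> (ds, dr, dc) mm
    intensities : modality -> tissue -> nominal intensity
    noise_sd : modality -> additive Gaussian noise SD
    pose : RigidTransform
        Rigid motion applied to the anatomy before rasterization.
    margin_mm : mm of empty background around the bone's bounding box.
    seed : RNG seed for the noise.
    """

    bone_semiaxes: tuple[float, float, float] = (22.0, 18.0, 14.0)
    cartilage_thickness: float = 3.0
    facet_fraction: float = 0.8
    exponent: float = 2.5
    spacing: dict = field(default_factory=dict)
    intensities: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=dict)
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    margin_mm: float = 6.0
    seed: int = 42

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.bone_semiaxes) or self.cartilage_thickness <= 0:
            raise ValueError("semiaxes and cartilage_thickness must be strictly positive")
        if not 0 < self.facet_fraction < 1:
            raise ValueError("facet_fraction must lie in (0, 1)")
        for m, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{m}] must be >= 0")
        for m, tissue_map in self.intensities.items():
            if tissue_map["bone"] == tissue_map["cartilage"]:
                raise ValueError(f"bone and cartilage intensities coincide for {m} "
                                 "(zero contrast)")


@dataclass
class GroundTruth:
    """Analytic tissue masks aligned to a generated volume."""

    bone_mask: np.ndarray
    cartilage_mask: np.ndarray
    cartilage_adjacent_bone: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.bone_mask & self.cartilage_mask):
            raise ValueError("bone and cartilage masks overlap")
        if np.any(self.cartilage_adjacent_bone & ~self.bone_mask):
            raise ValueError("cartilage_adjacent_bone must be a subset of bone_mask")

    def label_volume(self) -> np.ndarray:
        lab = np.zeros(self.bone_mask.shape, dtype=np.uint8)
        lab[self.bone_mask] = LABEL_BONE
        lab[self.cartilage_mask] = LABEL_CARTILAGE
        return lab


def default_spec() -> PhantomSpec:
    """The repository's canonical phantom.

    Patella-scale superellipsoid bone, 3 mm cartilage on the +x face.
    Nominal intensities are chosen so the bone/cartilage contrast
    ``|I_bone - I_cart| / I_cart`` is 0.95 for the T1-VIBE-like arm and
    0.72 for the DESS-like arm, the values typical of those sequences; CT
    bone is bright (1000) on a dark background.
    """
    return PhantomSpec(
        bone_semiaxes=(22.0, 18.0, 14.0),
        cartilage_thickness=3.0,
        spacing={
            Modality.MRI_T1VIBE: (0.7, 0.4, 0.4),
            Modality.MRI_DESS: (1.0, 0.3, 0.3),
            Modality.CT: (0.6, 0.3, 0.3),
        },
        intensities={
            Modality.MRI_T1VIBE: {"bone": 5.0, "cartilage": 100.0, "background": 40.0},
            Modality.MRI_DESS: {"bone": 28.0, "cartilage": 100.0, "background": 40.0},
            Modality.CT: {"bone": 1000.0, "cartilage": 100.0, "background": 0.0},
        },
        noise_sd={
            Modality.MRI_T1VIBE: 2.0,
            Modality.MRI_DESS: 2.0,
            Modality.CT: 10.0,
        },
        seed=42,
    )


def _grid_mm(spec: PhantomSpec, modality: Modality):
    """Grid shape, origin and voxel-centre mm coordinates for a modality."""
    a, b, c = spec.bone_semiaxes
    ds, dr, dc = spec.spacing[modality]
    half = (a + spec.cartilage_thickness + spec.margin_mm,
            b + spec.margin_mm,
            c + spec.margin_mm)
    n_rows = int(np.ceil(2 * half[0] / dr))
    n_cols = int(np.ceil(2 * half[1] / dc))
    n_slices = int(np.ceil(2 * half[2] / ds))
    origin = (-half[0], -half[1], -half[2])
    return (n_slices, n_rows, n_cols), origin


def _tissue_labels(spec: PhantomSpec, modality: Modality) -> np.ndarray:
    """Rasterize the analytic geometry into a tissue-label grid."""
    shape, origin = _grid_mm(spec, modality)
    ds, dr, dc = spec.spacing[modality]
    x0, y0, z0 = origin
    sl, rw, cl = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             np.arange(shape[2]), indexing="ij")
    pts = np.stack([x0 + rw.ravel() * dr,
                    y0 + cl.ravel() * dc,
                    z0 + sl.ravel() * ds], axis=1)
    q = spec.pose.inverse().apply(pts) if not spec.pose.is_identity() else pts

    a, b, c = spec.bone_semiaxes
    e = spec.exponent
    yz = np.abs(q[:, 1] / b) ** e + np.abs(q[:, 2] / c) ** e
    F = np.abs(q[:, 0] / a) ** e + yz
    bone = F <= 1.0

    # cartilage: within the facet silhouette, above the +x surface, within
    # `thickness` of it along x
    facet = yz <= spec.facet_fraction ** e
    with np.errstate(invalid="ignore"):
        surf_x = a * np.clip(1.0 - yz, 0.0, None) ** (1.0 / e)
    cart = (~bone) & facet & (q[:, 0] > 0) & (q[:, 0] <= surf_x + spec.cartilage_thickness)

    labels = np.zeros(len(pts), dtype=np.uint8)
    labels[bone] = LABEL_BONE
    labels[cart] = LABEL_CARTILAGE
    return labels.reshape(shape)


def generate(spec: PhantomSpec, modality: Modality | str) -> tuple[ImageVolume, GroundTruth]:
    """Rasterize the phantom for one imaging arm.

    Voxel intensities are the nominal intensity of the tissue occupying each
    voxel centre plus seeded Gaussian noise; masks come from the same
    analytic geometry and are therefore independent of the noise.
    Deterministic given ``(spec, modality)``.
    """
    modality = Modality(modality)
    if modality not in spec.spacing or modality not in spec.intensities:
        raise ValueError(f"spec has no parameters for modality {modality}")
    labels = _tissue_labels(spec, modality)
    shape, origin = _grid_mm(spec, modality)

    inten = spec.intensities[modality]
    vox = np.full(labels.shape, float(inten["background"]))
    vox[labels == LABEL_BONE] = float(inten["bone"])
    vox[labels == LABEL_CARTILAGE] = float(inten["cartilage"])

    sd = float(spec.noise_sd.get(modality, 0.0))
    if sd > 0:
        rng = np.random.default_rng([spec.seed, list(Modality).index(modality)])
        vox = vox + rng.normal(0.0, sd, size=vox.shape)

    bone = labels == LABEL_BONE
    cart = labels == LABEL_CARTILAGE
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    adjacent = bone & ndimage.binary_dilation(cart, structure=struct)
    truth = GroundTruth(bone_mask=bone, cartilage_mask=cart,
                        cartilage_adjacent_bone=adjacent)
    volume = ImageVolume(vox, spec.spacing[modality], modality, origin)
    return volume, truth


def misalign(points: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Apply a rigid motion to an ``(N, 3)`` point cloud (registration test
    cases).  ``RigidTransform`` construction already rejects reflections and
    non-orthonormal matrices."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("point cloud must be (N, 3)")
    return transform.apply(pts)


def rescan_spec(spec: PhantomSpec, seed: int,
                pose_perturbation: RigidTransform | None = None) -> PhantomSpec:
    """Derive the second acquisition of a scan/re-scan pair: a new noise
    seed plus a small rigid pose perturbation composed with the base pose."""
    pose = spec.pose if pose_perturbation is None else pose_perturbation.compose(spec.pose)
    return replace(spec, seed=seed, pose=pose)
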