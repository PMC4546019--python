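"""Atlas-guided filling of enclosed signal voids (workflow step 2).

A population atlas is built from artifact-free subjects: the voxelwise mean
Dixon-water image, the stable oral-cavity air core (air in at least ``q`` of
subjects inside a dental bounding region), and a *dental fill template* — the
region around the oral cavity where air is assumed to be of metallic origin.
The template is the air core dilated by a margin, minus anything that is air
in a substantial fraction of the population (anatomical air: the cavity
itself, sinuses), so that a patient's own anatomical air maps to ~zero
template overlap and is left alone.

A patient is aligned to the atlas by a 12-dof affine registration of the
water images; the template is then warped into patient space and every
detected void component is filled with soft tissue (0.1 cm^-1) where it
overlaps the template.  The completion/reversal policy is applied per
component: components filled more than 80% are filled completely (this also
completes artifact voids extending outside the template), components filled
less than 10% are considered registration errors and reversed.  The high
completion threshold is what keeps connected sinuses from being filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .detect import AIR_THRESHOLD, VoidComponents, detect_voids
from .grids import SOFT_TISSUE_MU, MuMap, VoxelGrid3D
from .levelset import ContourResult, LevelSetParams, close_and_fill, evolve_contour

__all__ = [
    "Atlas",
    "FillPolicy",
    "FillReport",
    "ComponentFill",
    "RegistrationError",
    "build_atlas",
    "register_to_atlas",
    "warp_mask_to_patient",
    "fill_masked_voids",
    "inpaint",
    "InpaintResult",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Atlas:
    """Population-mean water image with oral-cavity air core and fill template.

    ``anatomical_air_mask`` marks where a substantial fraction of the
    artifact-free population shows internal air (oral cavity, sinuses); a
    detected component that mostly coincides with it is anatomy, not
    artifact, and is never filled.
    """

    mean_water: VoxelGrid3D
    oral_cavity_mask: VoxelGrid3D  # stable air core (air in >= q of subjects)
    fill_mask: VoxelGrid3D  # dental template used for filling
    n_subjects: int
    anatomical_air_mask: VoxelGrid3D | None = None

    def __post_init__(self) -> None:
        if not np.any(self.oral_cavity_mask.values):
            raise ValueError("atlas oral-cavity mask is empty")


@dataclass(frozen=True)
class FillPolicy:
    """Soft-tissue fill value and the strict 80%/10% completion/reversal rules."""

    fill_value: float = SOFT_TISSUE_MU
    complete_threshold: float = 0.80
    reverse_threshold: float = 0.10

    def __post_init__(self) -> None:
        if not (0 <= self.reverse_threshold < self.complete_threshold <= 1):
            raise ValueError("need 0 <= reverse < complete <= 1")

    def action(self, fraction: float) -> str:
        if fraction > self.complete_threshold:
            return "completed"
        if fraction < self.reverse_threshold:
            return "reversed"
        return "kept_partial"


@dataclass(frozen=True)
class ComponentFill:
    component_id: int
    fraction: float
    action: str  # {"completed", "kept_partial", "reversed"}
    voxels_changed: int


@dataclass(frozen=True)
class FillReport:
    fills: tuple[ComponentFill, ...] = ()

    def by_action(self, action: str) -> tuple[ComponentFill, ...]:
        return tuple(f for f in self.fills if f.action == action)

    def table(self) -> list[dict]:
        return [
            {
                "component_id": f.component_id,
                "fraction": f.fraction,
                "action": f.action,
                "voxels_changed": f.voxels_changed,
            }
            for f in self.fills
        ]


class RegistrationError(RuntimeError):
    """Atlas registration failed; diagnostics in the message."""


# ---------------------------------------------------------------------------
# atlas construction
# ---------------------------------------------------------------------------

# dental bounding region as FOV fractions ((x0,x1),(y0,y1),(z0,z1))
_DEFAULT_DENTAL_BOX = ((0.15, 0.85), (0.55, 0.95), (0.15, 0.50))


def _dental_box_mask(grid: VoxelGrid3D, box_frac) -> np.ndarray:
    mask = np.ones(grid.shape, dtype=bool)
    for ax, (f0, f1) in enumerate(box_frac):
        n = grid.shape[ax]
        idx = np.arange(n)
        sel = (idx >= f0 * n) & (idx <= f1 * n)
        shape = [1, 1, 1]
        shape[ax] = n
        mask &= sel.reshape(shape)
    return mask


def _water_air(water: np.ndarray) -> np.ndarray:
    """Internal air of one subject: low water signal inside the body envelope."""
    hi = np.percentile(water, 99)
    if hi <= 0:
        return np.zeros_like(water, dtype=bool)
    air = water < 0.2 * hi
    body = ndimage.binary_fill_holes(~air)
    return air & body


def build_atlas(
    waters: list[VoxelGrid3D],
    q: float = 0.9,
    exclude_q: float = 0.3,
    anat_q: float = 0.1,
    dental_margin_mm: float = 28.0,
    dental_box=_DEFAULT_DENTAL_BOX,
) -> Atlas:
    """Voxelwise-mean atlas with oral-cavity core and dental fill template.

    ``q`` is the population air quantile defining the stable oral-cavity
    core; ``exclude_q`` the (lower) quantile marking anatomical air that the
    fill template must never include; ``anat_q`` the (permissive) quantile
    for the anatomical-air map used to recognize cavity/sinus components —
    lower than ``exclude_q`` because it must cover individual anatomical
    variation, not just the stable core; ``dental_margin_mm`` how far around
    the cavity the template reaches.
    """
    if not waters:
        raise ValueError("need at least one water image")
    ref = waters[0]
    for wtr in waters[1:]:
        ref.require_compatible(wtr)
    stack_mean = np.zeros(ref.shape)
    air_freq = np.zeros(ref.shape)
    for wtr in waters:
        stack_mean += wtr.values
        air_freq += _water_air(wtr.values)
    stack_mean /= len(waters)
    air_freq /= len(waters)

    box = _dental_box_mask(ref, dental_box)
    core = ndimage.binary_dilation(
        (air_freq >= min(q, 1.0 - 1e-9)) & box,
        ndimage.generate_binary_structure(3, 3),
    )
    if not core.any():
        raise ValueError("no stable oral-cavity air found in the dental region")

    dist = ndimage.distance_transform_edt(~core, sampling=ref.spacing)
    anat_air = ndimage.binary_dilation(
        air_freq >= exclude_q, ndimage.generate_binary_structure(3, 3)
    )
    # the template marks likely *dental* artifact areas: confined to the
    # dental bounding region so it can never reach the sinuses, and clear of
    # anatomical air (plus a one-voxel guard for anatomical jitter)
    fill_mask = (dist <= dental_margin_mm) & box & ~anat_air
    return Atlas(
        mean_water=ref.with_values(stack_mean),
        oral_cavity_mask=ref.with_values(core),
        fill_mask=ref.with_values(fill_mask),
        n_subjects=len(waters),
        anatomical_air_mask=ref.with_values(air_freq >= anat_q),
    )


# ---------------------------------------------------------------------------
# registration (SimpleITK affine)
# ---------------------------------------------------------------------------

def _to_sitk(grid: VoxelGrid3D) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    return img


def _norm01(v: np.ndarray) -> np.ndarray:
    hi = np.percentile(v, 99)
    return np.clip(v / hi, 0, 1) if hi > 0 else v


def register_to_atlas(
    patient_water: VoxelGrid3D,
    atlas: Atlas,
    exclude_sub_threshold: bool = True,
) -> sitk.Transform:
    """Affine (12-dof) alignment of the patient onto the atlas.

    Mean-squares metric on percentile-normalized, lightly smoothed images,
    multi-resolution, deterministic (dense sampling, geometric initializer).
    Sub-threshold (air/artifact) voxels of the patient are excluded from the
    metric so large signal voids do not drag the alignment.  The returned
    transform maps patient-space points to atlas-space points.
    """
    fixed_arr = _norm01(patient_water.values)
    moving_arr = _norm01(atlas.mean_water.values)
    fixed = sitk.SmoothingRecursiveGaussian(_to_sitk(patient_water.with_values(fixed_arr)), 2.0)
    moving = sitk.SmoothingRecursiveGaussian(_to_sitk(atlas.mean_water.with_values(moving_arr)), 2.0)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    if exclude_sub_threshold:
        mask = sitk.Cast(_to_sitk(patient_water.with_values(fixed_arr > 0.05)), sitk.sitkUInt8)
        reg.SetMetricFixedMask(mask)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=150,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetInitialTransform(
        sitk.CenteredTransformInitializer(
            fixed, moving, sitk.AffineTransform(3),
            sitk.CenteredTransformInitializerFilter.GEOMETRY,
        ),
        inPlace=False,
    )
    try:
        # fixed = patient, moving = atlas: the result maps patient-space
        # points to atlas-space points, which is exactly what resampling the
        # atlas template onto the patient grid needs.
        return reg.Execute(fixed, moving)
    except RuntimeError as err:  # pragma: no cover - optimizer failure path
        raise RegistrationError(f"atlas registration failed: {err}") from err


def warp_mask_to_patient(
    mask: VoxelGrid3D,
    transform: sitk.Transform | None,
    patient_ref: VoxelGrid3D,
) -> VoxelGrid3D:
    """Warp an atlas-space mask into patient space (nearest neighbor)."""
    if transform is None:
        transform = sitk.Transform(3, sitk.sitkIdentity)
    mask_img = sitk.Cast(_to_sitk(mask.with_values(mask.values.astype(np.uint8))), sitk.sitkUInt8)
    ref_img = _to_sitk(patient_ref)
    warped = sitk.Resample(mask_img, ref_img, transform, sitk.sitkNearestNeighbor, 0)
    arr = sitk.GetArrayFromImage(warped).T.astype(bool)
    return patient_ref.with_values(arr)


# ---------------------------------------------------------------------------
# filling
# ---------------------------------------------------------------------------

def fill_masked_voids(
    mu: MuMap,
    voids: VoidComponents,
    atlas: Atlas,
    transform: sitk.Transform | None,
    policy: FillPolicy = FillPolicy(),
) -> tuple[MuMap, FillReport]:
    """Fill void components overlapping the warped dental template.

    Components that mostly coincide with the atlas's anatomical-air map
    (oral cavity, sinuses) are reversed outright.  For the rest, the overlap
    fraction with the template decides the action: strictly above the
    completion threshold the whole component is filled, strictly below the
    reversal threshold nothing is changed, in between only the overlapping
    voxels are filled.
    """
    template = warp_mask_to_patient(atlas.fill_mask, transform, mu.grid).values
    anatomical = None
    if atlas.anatomical_air_mask is not None:
        anatomical = warp_mask_to_patient(
            atlas.anatomical_air_mask, transform, mu.grid
        ).values
    out = mu.values.copy()
    fills = []
    for comp in voids.components:
        comp_mask = voids.mask(comp.id)
        overlap = comp_mask & template
        fraction = float(overlap.sum() / comp.voxel_count)
        action = policy.action(fraction)
        if anatomical is not None:
            anat_fraction = float((comp_mask & anatomical).sum() / comp.voxel_count)
            if anat_fraction > 0.5:
                action = "reversed"
        if action == "completed":
            changed = comp_mask
        elif action == "reversed":
            changed = np.zeros_like(comp_mask)
        else:
            changed = overlap
        out[changed] = policy.fill_value
        fills.append(
            ComponentFill(
                component_id=comp.id,
                fraction=fraction,
                action=action,
                voxels_changed=int(changed.sum()),
            )
        )
    return (
        MuMap(mu.grid.with_values(out), mu.body_mask, mu.provenance),
        FillReport(tuple(fills)),
    )


# ---------------------------------------------------------------------------
# end-to-end inpainting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InpaintResult:
    mu_inpainted: MuMap
    fill_report: FillReport
    voids: VoidComponents
    contour: ContourResult | None
    changed_mask: VoxelGrid3D  # all voxels modified by the correction

    @property
    def n_changed(self) -> int:
        return int(self.changed_mask.values.sum())


def inpaint(
    mu_dixon: MuMap,
    nac_pet: VoxelGrid3D,
    patient_water: VoxelGrid3D,
    atlas: Atlas,
    policy: FillPolicy = FillPolicy(),
    levelset_params: LevelSetParams | None = None,
) -> InpaintResult:
    """Full correction: detect -> (outer only) contour closing -> atlas fill.

    Returns the corrected map (provenance ``inpainted``) together with the
    fill report, the detected components and QC masks.  An artifact-free
    input passes through unchanged.
    """
    stage = "detect"
    try:
        voids = detect_voids(mu_dixon)
        contour = None
        mu_work = mu_dixon
        if any(c.artifact_class == "outer" for c in voids.components):
            stage = "contour"
            contour = evolve_contour(mu_dixon, nac_pet, levelset_params, voids)
            mu_work = close_and_fill(mu_dixon, contour)
            stage = "re-detect"
            voids = detect_voids(mu_work)
        stage = "register"
        transform = register_to_atlas(patient_water, atlas)
        stage = "fill"
        mu_filled, report = fill_masked_voids(mu_work, voids, atlas, transform, policy)
    except Exception as err:
        raise RuntimeError(f"inpainting failed at stage {stage!r}: {err}") from err

    changed = mu_filled.values != mu_dixon.values
    return InpaintResult(
        mu_inpainted=MuMap(mu_filled.grid, mu_dixon.body_mask, provenance="inpainted"),
        fill_report=report,
        voids=voids,
        contour=contour,
        changed_mask=mu_dixon.grid.with_values(changed),
    )
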