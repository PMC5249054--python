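"""Per-object 3D morphometry: volume, surface area, surface derivative, SMI.

The structure model index (SMI) of Hildebrand & Ruegsegger summarizes the
shape of a 3D object as

    SMI = 6 * S' * V / S**2

where ``V`` is the object volume, ``S`` its surface area and ``S'`` the rate
of change of surface area under an infinitesimal uniform dilation.  Ideal
plates give 0, cylinders 3 and spheres 4; values in between indicate mixed
structure.  Digitized objects can fall slightly outside [0, 4].

Surface area is measured as the area of a marching-cubes isosurface at level
0.5 of the Gaussian-smoothed (sigma = 1 voxel) binary mask; smoothing the
staircase surface is required for the mesh area to converge to the true area
(the raw binary mesh overestimates a sphere's surface by ~8.5%).  The default
surface-derivative estimator displaces the mesh vertices outward along their
gradient normals by a sub-voxel step and takes the forward difference of the
mesh area, which is the classic surface-dilation construction of the SMI; a
voxel-dilation variant (one-voxel Euclidean ball, forward difference) is kept
as ``method="voxel"`` but is anisotropy-biased and not the default.

Objects thinner than a few voxels in any direction would be destroyed by the
smoothing, so masks with a bounding-box dimension below 4 voxels are first
upsampled by nearest-neighbour replication (shape-preserving, deterministic).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .segmentation import LabeledVolume

logger = logging.getLogger(__name__)

#: Gaussian pre-smoothing of the binary mask before meshing, in voxels.
MESH_SIGMA = 1.0
#: Outward vertex displacement used for the surface derivative, in voxels.
MESH_EPS = 0.25
#: Bounding-box dimensions below this are upsampled before meshing.
_MIN_THICKNESS = 4
#: SMI values outside this band are logged as suspicious digitization.
_SMI_PLAUSIBLE = (-0.5, 4.5)


@dataclass
class ObjectMorphometry:
    """Morphometric record of a single calcification object.

    Units: V in um^3, S in um^2, S_prime in um (um^2 per um of dilation),
    diameters in um; SMI is dimensionless.
    """

    object_id: int
    voxel_count: int
    V: float
    S: float
    S_prime: float
    SMI: float
    d_sphere: float
    d_cube: float


@dataclass
class SampleMorphometry:
    """Per-biopsy aggregate over that sample's objects.

    ``sd_SMI`` uses the n-1 denominator and is defined as 0 for a single
    object.  Samples with exactly one object are flagged ``excluded`` (a
    single calcification is considered non-representative of the lesion).
    """

    sample_id: object
    n_objects: int
    mean_V: float
    mean_SMI: float
    sd_SMI: float
    mean_d_cube: float
    max_d_sphere: float
    excluded: bool


def object_volume(voxel_count: int, spacing: float) -> float:
    """Exact voxel volume ``count * spacing**3`` in um^3."""
    if voxel_count < 1:
        raise ValueError("object must contain at least one voxel")
    return float(voxel_count) * float(spacing) ** 3


def equivalent_diameters(V: float) -> tuple[float, float]:
    """Sphere-equivalent diameter and cube-equivalent edge for volume ``V``.

    Returns ``(d_sphere, d_cube)`` with ``d_sphere = (6V/pi)**(1/3)`` and
    ``d_cube = V**(1/3)``, both in um.
    """
    if not V > 0:
        raise ValueError("V must be positive")
    return (6.0 * V / math.pi) ** (1.0 / 3.0), V ** (1.0 / 3.0)


def smi(V: float, S: float, S_prime: float) -> float:
    """Structure model index ``6 * S' * V / S**2`` (unclamped)."""
    if not S > 0:
        raise ValueError("surface area must be positive")
    value = 6.0 * S_prime * V / S**2
    if not _SMI_PLAUSIBLE[0] <= value <= _SMI_PLAUSIBLE[1]:
        logger.warning("SMI %.3f outside plausible band %s", value, _SMI_PLAUSIBLE)
    return value


def _check_padding(mask: np.ndarray, margin: int = 2) -> None:
    """Reject objects whose surface would be truncated by the volume border."""
    for axis in range(3):
        edge = [slice(None)] * 3
        for sl in (slice(0, margin), slice(-margin, None)):
            edge[axis] = sl
            if mask[tuple(edge)].any():
                raise ValueError(
                    "object lies within 2 voxels of the volume border; "
                    "pad the volume (e.g. numpy.pad) before measuring"
                )


def _prepare_mask(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Upsample thin masks so smoothing cannot erase them.

    Returns the (possibly replicated) mask and the integer upsampling factor.
    """
    coords = np.nonzero(mask)
    extents = [c.max() - c.min() + 1 for c in coords]
    thinnest = min(extents)
    if thinnest >= _MIN_THICKNESS:
        return mask, 1
    factor = math.ceil(_MIN_THICKNESS / thinnest)
    up = mask
    for axis in range(3):
        up = np.repeat(up, factor, axis=axis)
    return up, factor


def _smoothed_field(mask: np.ndarray, sigma: float) -> np.ndarray:
    f = mask.astype(np.float64)
    if sigma > 0:
        f = ndimage.gaussian_filter(f, sigma, mode="constant", cval=0.0)
    return f


def _mesh(mask: np.ndarray, sigma: float):
    field = _smoothed_field(np.pad(mask, 4), sigma)
    verts, faces, normals, _ = marching_cubes(field, level=0.5)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return verts, faces, normals / norms


def _surface_measures(
    mask: np.ndarray,
    spacing: float,
    sigma: float = MESH_SIGMA,
    eps: float = MESH_EPS,
    method: str = "mesh",
) -> tuple[float, float]:
    """Surface area S (um^2) and derivative S' (um) of a binary object mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("object mask is empty")
    up, factor = _prepare_mask(mask)
    h = spacing / factor  # effective voxel edge, um
    verts, faces, unit_normals = _mesh(up, sigma)
    S = mesh_surface_area(verts, faces) * h**2
    if method == "mesh":
        # skimage normals follow the data gradient and point into the object;
        # outward displacement is verts + eps * n (pinned by a unit test).
        S_dilated = mesh_surface_area(verts + eps * unit_normals, faces) * h**2
        S_prime = (S_dilated - S) / (eps * h)
    elif method == "voxel":
        ball = ndimage.generate_binary_structure(3, 1)  # Euclidean ball, r=1
        dilated = ndimage.binary_dilation(np.pad(up, 4), structure=ball)[
            4:-4, 4:-4, 4:-4
        ]
        dverts, dfaces, _ = _mesh(dilated, sigma)
        S_dilated = mesh_surface_area(dverts, dfaces) * h**2
        S_prime = (S_dilated - S) / h
    else:
        raise ValueError(f"unknown surface-derivative method {method!r}")
    return float(S), float(S_prime)


def surface_area(mask: np.ndarray, spacing: float, sigma: float = MESH_SIGMA) -> float:
    """Isosurface-mesh area of a binary object mask, in um^2."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("object mask is empty")
    _check_padding(mask)
    S, _ = _surface_measures(mask, spacing, sigma=sigma)
    return S


def surface_derivative(
    mask: np.ndarray,
    spacing: float,
    sigma: float = MESH_SIGMA,
    eps: float = MESH_EPS,
    method: str = "mesh",
) -> float:
    """Change of surface area per um of uniform dilation, in um."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("object mask is empty")
    _check_padding(mask)
    _, S_prime = _surface_measures(mask, spacing, sigma=sigma, eps=eps, method=method)
    return S_prime


def measure_object(
    mask: np.ndarray,
    spacing: float,
    object_id: int = 1,
    method: str = "mesh",
) -> ObjectMorphometry:
    """Full morphometric record for a single binary object mask."""
    mask = np.asarray(mask, dtype=bool)
    count = int(mask.sum())
    V = object_volume(count, spacing)
    S, S_prime = _surface_measures(mask, spacing, method=method)
    d_sphere, d_cube = equivalent_diameters(V)
    return ObjectMorphometry(
        object_id=object_id,
        voxel_count=count,
        V=V,
        S=S,
        S_prime=S_prime,
        SMI=smi(V, S, S_prime),
        d_sphere=d_sphere,
        d_cube=d_cube,
    )


def measure_objects(
    labeled: LabeledVolume, method: str = "mesh"
) -> list[ObjectMorphometry]:
    """Measure every labelled object on its own zero-padded sub-volume."""
    records: list[ObjectMorphometry] = []
    slices = ndimage.find_objects(labeled.labels)
    for k, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sub = labeled.labels[sl] == k
        records.append(
            measure_object(np.pad(sub, 4), labeled.spacing, object_id=k, method=method)
        )
    return records


def aggregate_sample(
    objects: list[ObjectMorphometry], sample_id: object
) -> SampleMorphometry:
    """Aggregate a sample's objects into per-biopsy summary statistics."""
    n = len(objects)
    if n == 0:
        return SampleMorphometry(
            sample_id=sample_id,
            n_objects=0,
            mean_V=math.nan,
            mean_SMI=math.nan,
            sd_SMI=math.nan,
            mean_d_cube=math.nan,
            max_d_sphere=math.nan,
            excluded=False,
        )
    smis = np.array([o.SMI for o in objects])
    return SampleMorphometry(
        sample_id=sample_id,
        n_objects=n,
        mean_V=float(np.mean([o.V for o in objects])),
        mean_SMI=float(smis.mean()),
        sd_SMI=float(smis.std(ddof=1)) if n > 1 else 0.0,
        mean_d_cube=float(np.mean([o.d_cube for o in objects])),
        max_d_sphere=float(np.max([o.d_sphere for o in objects])),
        excluded=n == 1,
    )


def objects_to_dataframe(objects: list[ObjectMorphometry]):
    """Per-object table; V in um^3 plus a compatibility column in 1e5 um^3."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "object_id": o.object_id,
                "voxel_count": o.voxel_count,
                "V_um3": o.V,
                "S_um2": o.S,
                "S_prime_um": o.S_prime,
                "SMI": o.SMI,
                "d_sphere_um": o.d_sphere,
                "d_cube_um": o.d_cube,
            }
            for o in objects
        ],
        columns=[
            "object_id",
            "voxel_count",
            "V_um3",
            "S_um2",
            "S_prime_um",
            "SMI",
            "d_sphere_um",
            "d_cube_um",
        ],
    )
    df["V_1e5_um3"] = df["V_um3"] / 1e5
    return df


def samples_to_dataframe(samples: list[SampleMorphometry]):
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "n_objects": s.n_objects,
                "mean_V_um3": s.mean_V,
                "mean_SMI": s.mean_SMI,
                "sd_SMI": s.sd_SMI,
                "mean_d_cube_um": s.mean_d_cube,
                "max_d_sphere_um": s.max_d_sphere,
                "excluded": s.excluded,
            }
            for s in samples
        ]
    )
    if len(df):
        df["mean_V_1e5_um3"] = df["mean_V_um3"] / 1e5
    return df
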