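"""Synthetic phantoms and cohorts, plus the bundled reference cohort.

Two generators make every pipeline stage testable without any external data:

* :func:`make_phantom` voxelizes canonical solids (sphere, cylinder, plate,
  ellipsoid, cluster) with known analytic volume, surface and SMI limits,
  optionally embedded in Gaussian background noise — the ground truth for
  the morphometry estimators.
* :func:`make_cohort` simulates per-biopsy cohorts whose microcalcification
  count, volume and SMI distributions are moment-matched to the group-level
  summaries of the bundled reference cohort (counts and volumes log-normal —
  both are strongly right-skewed, with SDs exceeding means — SMI normal).
  Optionally each simulated object is rendered as a phantom so the full
  image pipeline can run end to end against known planted values.

:func:`load_reference_cohort` returns the packaged 29-sample summary table
(B-classification, group, counts, mean volumes, SMI statistics, recorded
morphology flags).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .categorization import CohortRecord, MorphologyFlags
from .morphometry import (
    ObjectMorphometry,
    SampleMorphometry,
    aggregate_sample,
    equivalent_diameters,
)
from .volume_io import VoxelVolume

# ---------------------------------------------------------------------------
# phantoms


@dataclass
class PhantomSpec:
    """Geometric description of one phantom, all sizes in micrometres.

    ``shape`` is one of sphere / cylinder / plate / ellipsoid / cluster.
    Cylinders extend along z, plates lie normal to z.  ``members`` holds the
    sub-specs of a cluster (their centers are offsets from the cluster
    center).  ``center_um`` defaults to the grid center.
    """

    shape: str
    radius_um: float | None = None
    length_um: float | None = None
    lateral_um: float | None = None
    thickness_um: float | None = None
    semi_axes_um: tuple[float, float, float] | None = None
    center_um: tuple[float, float, float] | None = None
    intensity: float = 1000.0
    members: list["PhantomSpec"] = field(default_factory=list)

    def analytic_truth(self) -> dict:
        """Analytic V, S and the ideal SMI limit, where closed forms exist."""
        if self.shape == "sphere":
            r = self.radius_um
            return {"V": 4 / 3 * math.pi * r**3, "S": 4 * math.pi * r**2, "SMI": 4.0}
        if self.shape == "cylinder":
            r, L = self.radius_um, self.length_um
            return {
                "V": math.pi * r**2 * L,
                "S": 2 * math.pi * r * L + 2 * math.pi * r**2,
                "SMI": 3.0,
            }
        if self.shape == "plate":
            a, t = self.lateral_um, self.thickness_um
            return {"V": a * a * t, "S": 2 * a * a + 4 * a * t, "SMI": 0.0}
        if self.shape == "ellipsoid":
            a, b, c = self.semi_axes_um
            return {"V": 4 / 3 * math.pi * a * b * c, "S": None, "SMI": None}
        return {"V": None, "S": None, "SMI": None}


def _rasterize(
    spec: PhantomSpec, grid_shape: tuple[int, int, int], spacing: float
) -> np.ndarray:
    """Voxel mask of the continuous shape sampled at voxel centers."""
    center = (
        np.array(spec.center_um, dtype=float) / spacing
        if spec.center_um is not None
        else (np.asarray(grid_shape, dtype=float) - 1) / 2
    )
    z, y, x = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    dz, dy, dx = z - center[0], y - center[1], x - center[2]
    if spec.shape == "sphere":
        r = spec.radius_um / spacing
        return dz**2 + dy**2 + dx**2 <= r**2
    if spec.shape == "cylinder":
        r, half = spec.radius_um / spacing, spec.length_um / (2 * spacing)
        return (np.abs(dz) <= half) & (dy**2 + dx**2 <= r**2)
    if spec.shape == "plate":
        half_a = spec.lateral_um / (2 * spacing)
        half_t = spec.thickness_um / (2 * spacing)
        return (np.abs(dz) <= half_t) & (np.abs(dy) <= half_a) & (np.abs(dx) <= half_a)
    if spec.shape == "ellipsoid":
        a, b, c = (np.array(spec.semi_axes_um) / spacing).tolist()
        return (dz / a) ** 2 + (dy / b) ** 2 + (dx / c) ** 2 <= 1.0
    if spec.shape == "cluster":
        base_um = (
            np.array(spec.center_um, dtype=float)
            if spec.center_um is not None
            else ((np.asarray(grid_shape, dtype=float) - 1) / 2) * spacing
        )
        mask = np.zeros(grid_shape, dtype=bool)
        for member in spec.members:
            offset = np.array(member.center_um or (0, 0, 0), dtype=float)
            shifted = PhantomSpec(
                **{
                    **member.__dict__,
                    "center_um": tuple(base_um + offset),
                    "members": member.members,
                }
            )
            mask |= _rasterize(shifted, grid_shape, spacing)
        return mask
    raise ValueError(f"unknown phantom shape {spec.shape!r}")


def make_phantom(
    spec: PhantomSpec,
    grid_shape: tuple[int, int, int],
    spacing: float,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    background: float = 0.0,
) -> tuple[VoxelVolume, dict]:
    """Render one phantom into a noisy grayscale volume with ground truth.

    Raises if the shape comes within 3 voxels of the grid border (its
    surface would be clipped).  The truth record carries the exact voxel
    count and the analytic V/S/SMI where closed forms exist.
    """
    mask = _rasterize(spec, grid_shape, spacing)
    if not mask.any():
        raise ValueError("phantom does not cover any voxel; enlarge it or the grid")
    margin = 3
    edges = [
        mask[:margin].any(), mask[-margin:].any(),
        mask[:, :margin].any(), mask[:, -margin:].any(),
        mask[:, :, :margin].any(), mask[:, :, -margin:].any(),
    ]
    if any(edges):
        raise ValueError(
            "phantom clipped by the grid (needs >= 3 voxels margin on every side)"
        )
    data = np.full(grid_shape, background, dtype=np.float64)
    data[mask] = spec.intensity
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sigma, size=grid_shape)
    truth = {"voxel_count": int(mask.sum()), **spec.analytic_truth()}
    truth["V_voxel"] = truth["voxel_count"] * spacing**3
    return VoxelVolume(data=data, spacing=spacing), truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class GroupSpec:
    """Sampling distributions of one histologic group.

    Counts and sample-level mean volumes are log-normal (moment-matched to
    ``*_mean``/``*_sd``); per-sample mean SMI is normal.  ``smi_within_sd``
    is the within-sample SD of object SMIs and ``volume_within_cv`` the
    within-sample coefficient of variation of object volumes (neither is
    identified by the published summaries; see the methods note).
    """

    n_samples: int
    count_mean: float
    count_sd: float
    volume_mean_um3: float
    volume_sd_um3: float
    smi_mean: float
    smi_sd: float
    smi_within_sd: float = 0.32
    volume_within_cv: float = 1.0
    b_class: str = "B2"


@dataclass
class CohortSpec:
    groups: dict[str, GroupSpec]
    age_mean: float = 60.5
    age_sd: float = 8.8
    seed: int = 0


def default_cohort_spec(n_per_group: int | None = None, seed: int = 0) -> CohortSpec:
    """Cohort matching the reference study's group-level summaries.

    Group sizes default to the study's (13 / 7 / 7 evaluable samples); count,
    volume and SMI moments are the published group means and SDs (volumes in
    1e5 um^3: 106/88/56 means, 207/169/50 SDs).
    """
    sizes = {"A": 13, "B": 7, "C": 7}
    params = {
        "A": dict(count_mean=23.2, count_sd=32.6, volume_mean_um3=106e5,
                  volume_sd_um3=207e5, smi_mean=2.97, smi_sd=0.31, b_class="B2"),
        "B": dict(count_mean=41.4, count_sd=52.7, volume_mean_um3=88e5,
                  volume_sd_um3=169e5, smi_mean=2.90, smi_sd=0.28, b_class="B3"),
        "C": dict(count_mean=33.6, count_sd=12.8, volume_mean_um3=56e5,
                  volume_sd_um3=50e5, smi_mean=3.03, smi_sd=0.10, b_class="B5"),
    }
    return CohortSpec(
        groups={
            g: GroupSpec(n_samples=n_per_group or sizes[g], **params[g])
            for g in ("A", "B", "C")
        },
        seed=seed,
    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("log-normal mean must be positive")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2, math.sqrt(sigma2)


def _nominal_surface(V: float, target_smi: float) -> tuple[float, float]:
    """Bookkeeping S and S' consistent with a drawn (V, SMI) pair.

    Synthetic cohort objects are defined by volume and SMI alone; the
    sphere-equivalent surface provides a consistent S, and S' is whatever
    makes 6 S' V / S^2 equal the drawn SMI.
    """
    S = (36 * math.pi * V**2) ** (1 / 3)
    return S, target_smi * S**2 / (6 * V)


def make_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, list[CohortRecord]]:
    """Simulate a cohort; returns the per-object table and cohort records.

    Deterministic given ``spec.seed``.  Aggregates are computed through
    :func:`mcmorph.morphometry.aggregate_sample`, the same code path real
    measurements take.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    records: list[CohortRecord] = []
    sample_counter = 0
    for group in sorted(spec.groups):
        g = spec.groups[group]
        c_mu, c_sigma = _lognormal_params(g.count_mean, g.count_sd)
        v_mu, v_sigma = _lognormal_params(g.volume_mean_um3, g.volume_sd_um3)
        for _ in range(g.n_samples):
            sample_counter += 1
            sid = f"S{sample_counter:03d}"
            count = max(1, int(round(rng.lognormal(c_mu, c_sigma))))
            sample_mean_v = rng.lognormal(v_mu, v_sigma)
            sample_mean_smi = rng.normal(g.smi_mean, g.smi_sd)
            ov_mu, ov_sigma = _lognormal_params(
                sample_mean_v, g.volume_within_cv * sample_mean_v
            )
            volumes = rng.lognormal(ov_mu, ov_sigma, size=count)
            smis = rng.normal(sample_mean_smi, g.smi_within_sd, size=count)
            objects = []
            for i, (V, s) in enumerate(zip(volumes, smis), start=1):
                S, S_prime = _nominal_surface(V, s)
                d_sphere, d_cube = equivalent_diameters(V)
                objects.append(
                    ObjectMorphometry(
                        object_id=i,
                        voxel_count=0,
                        V=float(V),
                        S=S,
                        S_prime=S_prime,
                        SMI=float(s),
                        d_sphere=d_sphere,
                        d_cube=d_cube,
                    )
                )
                rows.append(
                    {"sample_id": sid, "group": group, "object_id": i,
                     "V_um3": float(V), "SMI": float(s)}
                )
            agg = aggregate_sample(objects, sid)
            records.append(
                CohortRecord(
                    sample_id=sid,
                    b_class=g.b_class,
                    birads=4,
                    age=float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 35, 95)),
                    morphometry=agg,
                )
            )
    return pd.DataFrame(rows), records


# --- rendering simulated objects into volumes ------------------------------

#: SMI-to-shape map used when rendering simulated objects as phantoms: this
#: is a stand-in for visual variety, not a claim about real calcifications.
#: Aspect ratios are chosen so the *finite* solid's SMI sits near its class
#: ideal: a finite rod's SMI exceeds 3 by ~8/aspect from its end caps, and a
#: finite plate's SMI exceeds 0 by ~6*pi/aspect from its rim.
_ROD_ASPECT = 12.0  # length / diameter of rendered rods
_PLATE_ASPECT = 60.0  # lateral / thickness of rendered plates


def shape_for_smi(target_smi: float) -> str:
    if target_smi <= 1.5:
        return "plate"
    if target_smi <= 3.5:
        return "cylinder"
    return "sphere"


def _spec_for_object(V: float, target_smi: float, center_um) -> PhantomSpec:
    shape = shape_for_smi(target_smi)
    if shape == "sphere":
        r = (3 * V / (4 * math.pi)) ** (1 / 3)
        return PhantomSpec("sphere", radius_um=r, center_um=center_um)
    if shape == "cylinder":
        # V = pi r^2 L with L = aspect * 2r
        r = (V / (2 * math.pi * _ROD_ASPECT)) ** (1 / 3)
        return PhantomSpec(
            "cylinder", radius_um=r, length_um=2 * r * _ROD_ASPECT, center_um=center_um
        )
    t = (V / _PLATE_ASPECT**2) ** (1 / 3)
    return PhantomSpec(
        "plate", lateral_um=t * _PLATE_ASPECT, thickness_um=t, center_um=center_um
    )


def render_sample(
    object_table: pd.DataFrame,
    spacing: float = 9.0,
    noise_sigma: float = 0.0,
    intensity: float = 1000.0,
    seed: int | None = None,
) -> tuple[VoxelVolume, pd.DataFrame]:
    """Render one sample's simulated objects into a single noisy volume.

    Objects are laid out on a cubic cell grid with generous separation so
    segmentation recovers exactly one component per planted object.  Returns
    the volume and a truth table (planted volume, target SMI, shape class).
    """
    objs = object_table.reset_index(drop=True)
    n = len(objs)
    if n == 0:
        raise ValueError("no objects to render")
    extents = []
    for _, row in objs.iterrows():
        spec = _spec_for_object(row.V_um3, row.SMI, None)
        if spec.shape == "sphere":
            ext = 2 * spec.radius_um
        elif spec.shape == "cylinder":
            ext = spec.length_um
        else:
            ext = spec.lateral_um
        extents.append(ext)
    cell_um = max(extents) + 12 * spacing
    per_axis = math.ceil(n ** (1 / 3))
    dims = tuple([int(round(per_axis * cell_um / spacing)) + 8] * 3)
    data = np.zeros(dims, dtype=np.float64)
    truth_rows = []
    for i, (_, row) in enumerate(objs.iterrows()):
        iz, rem = divmod(i, per_axis * per_axis)
        iy, ix = divmod(rem, per_axis)
        center = tuple(
            (idx + 0.5) * cell_um + 4 * spacing for idx in (iz, iy, ix)
        )
        spec = _spec_for_object(row.V_um3, row.SMI, center)
        spec.intensity = intensity
        mask = _rasterize(spec, dims, spacing)
        data[mask] = intensity
        truth_rows.append(
            {
                "object_id": row.object_id,
                "planted_V_um3": row.V_um3,
                "target_SMI": row.SMI,
                "shape": spec.shape,
                "voxel_count": int(mask.sum()),
            }
        )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sigma, size=dims)
    return VoxelVolume(data=data, spacing=spacing), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# bundled reference cohort


def _data_path(name: str) -> Path:
    return Path(resources.files("mcmorph").joinpath("data", name))


def reference_cohort_dataframe() -> pd.DataFrame:
    """The packaged 29-sample summary table as printed (volumes in 1e5 um^3)."""
    return pd.read_csv(_data_path("reference_cohort.csv"), comment="#")


def load_classification_expectations() -> pd.DataFrame:
    """Documented discordances of the rule scheme on the reference cohort."""
    return pd.read_csv(_data_path("classification_expectations.csv"), comment="#")


def load_reference_cohort() -> list[CohortRecord]:
    """Cohort records for all 29 reference samples.

    Sample aggregates are reconstructed from the printed summaries: mean
    volume is converted from 1e5 um^3, and since per-object sizes are not
    published, ``mean_d_cube`` and ``max_d_sphere`` are the equivalent
    diameters of the printed mean volume (a documented proxy).  Samples with
    a single calcification carry ``excluded=True``; recorded morphology
    flags are attached as-printed.
    """
    df = reference_cohort_dataframe()
    records = []
    for _, row in df.iterrows():
        mean_v = float(row.mean_V_1e5_um3) * 1e5
        d_sphere, d_cube = equivalent_diameters(mean_v)
        morph = SampleMorphometry(
            sample_id=int(row.sample_id),
            n_objects=int(row.n_objects),
            mean_V=mean_v,
            mean_SMI=float(row.smi_mean),
            sd_SMI=float(row.smi_sd),
            mean_d_cube=d_cube,
            max_d_sphere=d_sphere,
            excluded=int(row.n_objects) == 1,
        )
        flags = MorphologyFlags(
            fl=bool(row.fl), fp=bool(row.fp), ch=bool(row.ch)
        )
        if flags.ns != bool(row.ns):
            raise ValueError(
                f"inconsistent flags in reference cohort row {row.sample_id}"
            )
        records.append(
            CohortRecord(
                sample_id=int(row.sample_id),
                b_class=str(row.b_class),
                birads=int(row.birads),
                age=float(row.age),
                group=str(row.group),
                morphometry=morph,
                flags=flags,
            )
        )
    return records
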