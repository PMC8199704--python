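"""Synthetic study inputs: CT phantom, analytic dose, plans, demography.

No patient data ships with this package, so every pipeline stage is
exercised against fully synthetic, seed-deterministic inputs:

- a cylindrical CT phantom with sphere/box organs of known HU, standing
  in for a patient CT series and structure set;
- an analytic photon-beam dose field — exponentially attenuated along
  the beam axis, laterally Gaussian, plus a small uniform floor that
  emulates the scatter and leakage radiation present outside the field
  (the physical effect a Monte Carlo recalculation captures and a TPS
  underestimates);
- a Weibull life table and constant/exponential baseline incidence
  curves standing in for national statistics.

Organ shapes are restricted to spheres and boxes so voxel membership
has a closed-form oracle, and the dose field is closed-form so DVH and
risk results can be hand-checked end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import yaml
from pydicom.dataset import Dataset

from .errors import InvalidInputError
from .plan_export import VMATBeam
from .risk import BaselineRates, LifeTable
from .rt_io import (
    CTVolume,
    DoseGrid,
    GridGeometry,
    PlanarContour,
    StructureSet,
    write_ct_series,
    write_rtdose,
    write_rtstruct,
)

# ---------------------------------------------------------------------------
# Phantom


@dataclass(frozen=True)
class OrganSpec:
    """One organ: a sphere (size = radius) or box (size = (lx, ly, lz)), mm."""

    name: str
    shape: str  # "sphere" | "box"
    center: tuple[float, float, float]
    size: float | tuple[float, float, float]
    hu: float

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "box"):
            raise InvalidInputError(f"organ shape must be sphere/box, got {self.shape!r}")

    def half_extent(self) -> np.ndarray:
        if self.shape == "sphere":
            return np.full(3, float(self.size))
        return np.asarray(self.size, dtype=float) / 2.0

    def membership(self, X, Y, Z) -> np.ndarray:
        """Analytic voxel-centre membership (boundary-inclusive)."""
        cx, cy, cz = self.center
        if self.shape == "sphere":
            return (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= float(self.size) ** 2
        hx, hy, hz = self.half_extent()
        return (
            (np.abs(X - cx) <= hx) & (np.abs(Y - cy) <= hy) & (np.abs(Z - cz) <= hz)
        )


@dataclass(frozen=True)
class PhantomSpec:
    geometry: GridGeometry
    body_center: tuple[float, float] = (0.0, 0.0)
    body_radius: float = 100.0
    body_hu: float = 8.0
    outside_hu: float = -1000.0
    organs: tuple[OrganSpec, ...] = ()
    ngon: int = 64  # contour polygon resolution for spheres
    seed: int = 0


def _contours_for_organ(organ: OrganSpec, geometry: GridGeometry, ngon: int):
    _, _, zs = geometry.axis_coords()
    cx, cy, cz = organ.center
    contours = []
    if organ.shape == "box":
        hx, hy, hz = organ.half_extent()
        rect = np.array(
            [[cx - hx, cy - hy], [cx + hx, cy - hy], [cx + hx, cy + hy], [cx - hx, cy + hy]]
        )
        for z in zs:
            if abs(z - cz) <= hz:
                contours.append(PlanarContour(z=float(z), vertices=rect.copy()))
    else:
        r = float(organ.size)
        theta = np.linspace(0.0, 2 * np.pi, ngon, endpoint=False)
        for z in zs:
            h2 = r**2 - (z - cz) ** 2
            if h2 <= 0:
                continue
            rho = np.sqrt(h2)
            verts = np.column_stack([cx + rho * np.cos(theta), cy + rho * np.sin(theta)])
            contours.append(PlanarContour(z=float(z), vertices=verts))
    return contours


def make_phantom(spec: PhantomSpec) -> tuple[CTVolume, StructureSet]:
    """Build the phantom CT volume and its per-slice contour set.

    Deterministic for a given spec (the seed is reserved for future
    noise models; the default phantom is noise-free).  Organs must be
    disjoint and inside the body cylinder, else an error is raised.
    """
    xs, ys, zs = spec.geometry.axis_coords()
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    hu = np.full(spec.geometry.shape, spec.outside_hu, dtype=float)
    bx, by = spec.body_center
    body = (X - bx) ** 2 + (Y - by) ** 2 <= spec.body_radius**2
    hu[body] = spec.body_hu

    masks = []
    for organ in spec.organs:
        c = np.asarray(organ.center)
        h = organ.half_extent()
        corners = c[:2] + np.array([[sx * h[0], sy * h[1]] for sx in (-1, 1) for sy in (-1, 1)])
        if np.any(np.hypot(*(corners - np.array([bx, by])).T) > spec.body_radius):
            raise InvalidInputError(f"organ {organ.name!r} extends outside the body")
        m = organ.membership(X, Y, Z)
        masks.append(m)
        hu[m] = organ.hu
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if np.any(masks[i] & masks[j]):
                raise InvalidInputError(
                    f"organs {spec.organs[i].name!r} and {spec.organs[j].name!r} overlap"
                )

    structures = StructureSet(
        rois={
            organ.name: _contours_for_organ(organ, spec.geometry, spec.ngon)
            for organ in spec.organs
        }
    )
    return CTVolume(spec.geometry, hu), structures


# ---------------------------------------------------------------------------
# Analytic dose


@dataclass(frozen=True)
class AnalyticBeamSpec:
    """Closed-form beam: D0 e^(-mu depth) e^(-r^2 / 2 sigma^2) + eps D0.

    ``depth`` is distance along the axis past the entry point (clamped
    at 0 upstream), ``r`` the lateral distance from the axis, and the
    ``leakage_fraction`` eps a uniform out-of-field floor emulating
    scatter and leakage radiation.
    """

    d0: float = 50.0
    sigma_mm: float = 8.0
    mu_per_mm: float = 0.005
    leakage_fraction: float = 0.02
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    entry: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise InvalidInputError("d0 must be > 0")
        if not (0.0 <= self.leakage_fraction <= 0.1):
            raise InvalidInputError("leakage_fraction must be in [0, 0.1]")

    def dose_at(self, X, Y, Z) -> np.ndarray:
        axis = np.asarray(self.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        ex, ey, ez = self.entry
        px, py, pz = X - ex, Y - ey, Z - ez
        depth = np.maximum(px * axis[0] + py * axis[1] + pz * axis[2], 0.0)
        r2 = px**2 + py**2 + pz**2 - depth**2
        r2 = np.maximum(r2, 0.0)
        primary = self.d0 * np.exp(-self.mu_per_mm * depth) * np.exp(
            -r2 / (2.0 * self.sigma_mm**2)
        )
        return primary + self.leakage_fraction * self.d0


def make_analytic_dose(geometry: GridGeometry, spec: AnalyticBeamSpec) -> DoseGrid:
    """Evaluate the analytic beam on a grid (stands in for the MC engine)."""
    xs, ys, zs = geometry.axis_coords()
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    return DoseGrid(geometry, spec.dose_at(X, Y, Z))


# ---------------------------------------------------------------------------
# Demography


def make_life_table(shape_k: float, scale_b: float, a_max: int = 90) -> LifeTable:
    """Weibull survival S(a) = exp(-(a/b)^k) over ages 0..a_max."""
    if shape_k <= 0 or scale_b <= 0:
        raise InvalidInputError("Weibull shape and scale must be > 0")
    ages = np.arange(a_max + 1, dtype=float)
    return LifeTable(np.exp(-((ages / scale_b) ** shape_k)))


def make_baseline_rates(
    form: str,
    rate: float,
    growth: float = 0.0,
    a_max: int = 90,
    site: str = "",
    sex: str = "",
) -> BaselineRates:
    """Constant (lambda = rate) or exponential (rate * e^(growth a)) incidence."""
    if rate < 0:
        raise InvalidInputError("baseline rate must be >= 0")
    ages = np.arange(a_max + 1, dtype=float)
    if form == "constant":
        rates = np.full(a_max + 1, float(rate))
    elif form == "exponential":
        rates = rate * np.exp(growth * ages)
    else:
        raise InvalidInputError(f"unknown baseline form {form!r}")
    return BaselineRates(rates, site=site, sex=sex)


# ---------------------------------------------------------------------------
# Demo VMAT plan


def make_vmat_plan(
    weights=(0.0, 0.4, 1.0),
    gantry=(181.0, 270.0, 179.0),
    total_mu: float = 200.0,
    n_leaf_pairs: int = 10,
    omit_mlc_after_first: bool = False,
) -> Dataset:
    """Build a minimal single-arc RTPLAN dataset for tests and demos."""
    ds = Dataset()
    ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.481.5"  # RT Plan Storage
    ds.SOPInstanceUID = pydicom.uid.generate_uid()
    meta = pydicom.dataset.FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = "SYNTH-ARC"

    fg = Dataset()
    rb = Dataset()
    rb.ReferencedBeamNumber = 1
    rb.BeamMeterset = float(total_mu)
    fg.ReferencedBeamSequence = [rb]
    ds.FractionGroupSequence = [fg]

    beam = Dataset()
    beam.BeamNumber = 1
    beam.BeamName = "Arc1"
    beam.FinalCumulativeMetersetWeight = 1.0
    beam.ControlPointSequence = []
    rng = np.random.default_rng(7)
    for i, (w, g) in enumerate(zip(weights, gantry)):
        cp = Dataset()
        cp.ControlPointIndex = i
        cp.CumulativeMetersetWeight = float(w)
        cp.GantryAngle = float(g)
        if i == 0:
            cp.NominalBeamEnergy = 6.0
        if not (omit_mlc_after_first and i > 0):
            bank = np.round(rng.uniform(-50, 50, n_leaf_pairs), 1)
            bld = Dataset()
            bld.RTBeamLimitingDeviceType = "MLCX"
            bld.LeafJawPositions = [float(v) for v in np.concatenate([bank - 60, bank + 60])]
            jx = Dataset()
            jx.RTBeamLimitingDeviceType = "ASYMX"
            jx.LeafJawPositions = [-100.0, 100.0]
            jy = Dataset()
            jy.RTBeamLimitingDeviceType = "ASYMY"
            jy.LeafJawPositions = [-80.0, 80.0]
            cp.BeamLimitingDevicePositionSequence = [bld, jx, jy]
        beam.ControlPointSequence.append(cp)
    ds.BeamSequence = [beam]
    return ds


# ---------------------------------------------------------------------------
# Bundled default phantom study


def default_phantom_spec(seed: int = 0) -> tuple[PhantomSpec, AnalyticBeamSpec]:
    """The bundled demo study: a body cylinder with two organs.

    ``target_ball`` sits on the beam axis in the high-dose region;
    ``far_organ`` is a box deep in the leakage floor where the lateral
    Gaussian has decayed to numerical noise, so its dose is uniform at
    eps * D0 and its DVH occupies a single bin — the configuration with
    a closed-form LAR.
    """
    geometry = GridGeometry(origin=(-63.0, -63.0, 0.0), spacing=(2.0, 2.0, 2.0), dims=(64, 64, 24))
    phantom = PhantomSpec(
        geometry=geometry,
        body_center=(0.0, 0.0),
        body_radius=55.0,
        body_hu=8.0,
        outside_hu=-1000.0,
        organs=(
            OrganSpec("target_ball", "sphere", (-30.0, 0.0, 23.0), 10.0, 80.0),
            OrganSpec("far_organ", "box", (35.0, 0.0, 23.0), (20.0, 20.0, 10.0), 120.0),
        ),
        seed=seed,
    )
    beam = AnalyticBeamSpec(
        d0=50.0,
        sigma_mm=8.0,
        mu_per_mm=0.005,
        leakage_fraction=0.02,
        axis=(0.0, 0.0, 1.0),
        entry=(-30.0, 0.0, 0.0),
    )
    return phantom, beam


def write_study_bundle(out_dir: str | Path, seed: int = 0) -> Path:
    """Write the demo study to disk: DICOM CT/RTSTRUCT/RTDOSE, CSV life
    table and baseline rates, RTPLAN, and a ready-to-run pipeline config.

    Returns the path of the written config YAML.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phantom_spec, beam_spec = default_phantom_spec(seed)
    ct, structures = make_phantom(phantom_spec)
    dose = make_analytic_dose(phantom_spec.geometry, beam_spec)

    ct_dir = out_dir / "ct"
    write_ct_series(ct, ct_dir)
    write_rtstruct(structures, out_dir / "structures.dcm")
    write_rtdose(dose, out_dir / "dose.dcm")
    make_life_table(5.0, 80.0, 90).to_csv(out_dir / "life_table.csv")
    make_baseline_rates("exponential", 5.0, 0.05, 90).to_csv(out_dir / "baseline.csv")
    make_vmat_plan().save_as(out_dir / "plan.dcm", enforce_file_format=True)

    config = {
        "rtdose": "dose.dcm",
        "rtstruct": "structures.dcm",
        "ct_dir": "ct",
        "sex": "male",
        "exposure_ages": [30, 40, 50, 60, 70, 80],
        "bin_width": 0.1,
        "target_spacing_mm": 2.0,
        "life_table": "life_table.csv",
        "baseline_rates": "baseline.csv",
        "organs": [
            {"name": "target_ball", "site": "colon", "model": "plateau", "delta": 0.09},
            {"name": "far_organ", "site": "colon", "model": "plateau", "delta": 0.09},
        ],
    }
    config_path = out_dir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
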