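"""Stoichiometric HU calibration: CT number -> tissue composition and density.

Monte Carlo dose engines transport particles through materials, not CT
numbers, so every voxel's Hounsfield unit (HU) must be mapped to an
elemental weight-fraction vector and a mass density before simulation.
The mapping used here is the stoichiometric calibration of Schneider
et al.: the HU axis is divided into a small number of reference tissues
(air, lung, adipose, soft tissues, a graded bone series, implant metals)
and compositions are interpolated linearly between neighbouring nodes.

The bundled 27-node table spans CT numbers from -1050 to 3095 and is
replaceable by any CSV with the same column schema (``hu`` followed by
the 17 element symbols).  Mass density is a separate piecewise-linear
curve over HU, also user-replaceable; the bundled curve follows the
values typical of the Schneider calibration literature and should be
swapped for a scanner-specific fit in production use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError

#: Element symbols of the calibration table, in column order.
ELEMENTS = (
    "H", "C", "N", "O", "Na", "Mg", "P", "S", "Cl",
    "Ar", "K", "Ca", "Ti", "Cu", "Zn", "Ag", "Sn",
)

#: Element names in the dialect of the GATE material database.
_GATE_ELEMENT_NAMES = {
    "H": "Hydrogen", "C": "Carbon", "N": "Nitrogen", "O": "Oxygen",
    "Na": "Sodium", "Mg": "Magnesium", "P": "Phosphor", "S": "Sulfur",
    "Cl": "Chlorine", "Ar": "Argon", "K": "Potassium", "Ca": "Calcium",
    "Ti": "Titanium", "Cu": "Copper", "Zn": "Zinc", "Ag": "Silver",
    "Sn": "Tin",
}

_FRACTION_SUM_TOL = 0.2  # printed rows sum to 100 up to rounding


@dataclass(frozen=True)
class ElementFractions:
    """Weight percent per element (17 elements, summing to ~100)."""

    values: np.ndarray  # shape (17,), percent

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(ELEMENTS),):
            raise InvalidInputError(
                f"expected {len(ELEMENTS)} element fractions, got shape {v.shape}"
            )
        if np.any(v < 0):
            raise InvalidInputError("element fractions must be nonnegative")
        total = float(v.sum())
        if not (100.0 - _FRACTION_SUM_TOL <= total <= 100.0 + _FRACTION_SUM_TOL):
            raise InvalidInputError(
                f"element fractions sum to {total:.4f}, expected 100 +/- {_FRACTION_SUM_TOL}"
            )
        object.__setattr__(self, "values", v)

    def __getitem__(self, symbol: str) -> float:
        return float(self.values[ELEMENTS.index(symbol)])

    def as_dict(self) -> dict[str, float]:
        return {el: float(f) for el, f in zip(ELEMENTS, self.values)}


@dataclass(frozen=True)
class CalibrationNode:
    """One reference tissue: a CT number and its composition."""

    hu: int
    fractions: ElementFractions

    def __post_init__(self) -> None:
        if not (-1050 <= self.hu <= 4000):
            raise InvalidInputError(f"node HU {self.hu} outside [-1050, 4000]")


class CompositionTable:
    """Ordered HU calibration nodes with per-element interpolation.

    Parameters
    ----------
    nodes
        Calibration nodes with strictly increasing HU.
    """

    def __init__(self, nodes: Sequence[CalibrationNode]):
        if not nodes:
            raise InvalidInputError("composition table must have at least one node")
        hu = np.array([n.hu for n in nodes], dtype=float)
        if np.any(np.diff(hu) <= 0):
            raise InvalidInputError("node HU values must be strictly increasing")
        self.nodes = list(nodes)
        self._hu = hu
        self._matrix = np.vstack([n.fractions.values for n in nodes])

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def hu_range(self) -> tuple[float, float]:
        return float(self._hu[0]), float(self._hu[-1])

    def node_at(self, hu: int) -> CalibrationNode:
        """Return the node with exactly this HU, or raise KeyError."""
        for n in self.nodes:
            if n.hu == hu:
                return n
        raise KeyError(f"no calibration node at HU {hu}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompositionTable":
        df = pd.read_csv(path)
        missing = {"hu", *ELEMENTS} - set(df.columns)
        if missing:
            raise SchemaError(f"calibration CSV missing columns: {sorted(missing)}")
        nodes = [
            CalibrationNode(
                hu=int(row["hu"]),
                fractions=ElementFractions(row[list(ELEMENTS)].to_numpy(dtype=float)),
            )
            for _, row in df.iterrows()
        ]
        return cls(nodes)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self._matrix, columns=list(ELEMENTS))
        df.insert(0, "hu", self._hu.astype(int))
        df.to_csv(path, index=False)


def load_default_calibration() -> CompositionTable:
    """Load the bundled 27-tissue HU->composition table."""
    with resources.as_file(
        resources.files("secr.data") / "hu_composition.csv"
    ) as p:
        return CompositionTable.from_csv(p)


def composition_at(table: CompositionTable, hu: float) -> ElementFractions:
    """Interpolate the elemental composition at an arbitrary CT number.

    Linear interpolation per element between the bracketing nodes,
    renormalized so the fractions sum to exactly 100.  HU outside the
    table range is clamped to the nearest end node (with a warning):
    clinical scanners floor at -1024 and metal artifacts can exceed the
    table, so rejection would be unusable in practice.
    """
    if not math.isfinite(hu):
        raise InvalidInputError(f"HU must be finite, got {hu}")
    lo, hi = table.hu_range
    if hu < lo or hu > hi:
        warnings.warn(
            f"HU {hu} outside calibration range [{lo:g}, {hi:g}]; clamping",
            stacklevel=2,
        )
        hu = min(max(hu, lo), hi)
    exact = np.flatnonzero(table._hu == hu)
    if exact.size:  # node query: return the stored row verbatim
        return table.nodes[int(exact[0])].fractions
    raw = np.array(
        [np.interp(hu, table._hu, table._matrix[:, j]) for j in range(len(ELEMENTS))]
    )
    total = raw.sum()
    return ElementFractions(raw * (100.0 / total))


class DensityModel:
    """Piecewise-linear HU -> mass density (g/cm3) curve."""

    def __init__(self, hu: Sequence[float], density: Sequence[float]):
        hu = np.asarray(hu, dtype=float)
        density = np.asarray(density, dtype=float)
        if hu.size == 0:
            raise InvalidInputError("density model must have at least one breakpoint")
        if np.any(np.diff(hu) <= 0):
            raise InvalidInputError("density breakpoints must be strictly increasing in HU")
        if np.any(density <= 0):
            raise InvalidInputError("densities must be strictly positive")
        self.hu = hu
        self.density = density

    @classmethod
    def from_csv(cls, path: str | Path) -> "DensityModel":
        df = pd.read_csv(path)
        missing = {"hu", "density_g_cm3"} - set(df.columns)
        if missing:
            raise SchemaError(f"density CSV missing columns: {sorted(missing)}")
        return cls(df["hu"].to_numpy(), df["density_g_cm3"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"hu": self.hu, "density_g_cm3": self.density}).to_csv(
            path, index=False
        )


def load_default_density_model() -> DensityModel:
    """Load the bundled Schneider-style density curve."""
    with resources.as_file(resources.files("secr.data") / "hu_density.csv") as p:
        return DensityModel.from_csv(p)


def density_at(model: DensityModel, hu: float) -> float:
    """Evaluate mass density at a CT number (g/cm3), clamped at the ends."""
    if not math.isfinite(hu):
        raise InvalidInputError(f"HU must be finite, got {hu}")
    return float(np.interp(hu, model.hu, model.density))


def material_name(lo: int, hi: int) -> str:
    """Deterministic material name for the half-open HU interval [lo, hi)."""
    def fmt(v: int) -> str:
        return f"m{-v}" if v < 0 else str(v)

    return f"HU_{fmt(lo)}_{fmt(hi)}"


def export_material_database(
    table: CompositionTable,
    model: DensityModel,
    hu_bin_width: int,
    out_dir: str | Path,
    materials_filename: str = "patient_materials.db",
    map_filename: str = "patient_hu2mat.txt",
) -> tuple[Path, Path]:
    """Emit a binned material database in the GATE text dialect.

    The table's HU range is partitioned into ``ceil(range / width)``
    contiguous half-open bins; each bin becomes one material whose
    composition and density are evaluated at the bin center (clamped to
    the table range for the possibly-overhanging last bin).

    Returns the (materials file, HU map file) paths.
    """
    if len(table) == 0:  # defensive; constructor forbids empty
        raise InvalidInputError("empty composition table")
    if hu_bin_width < 1:
        raise InvalidInputError(f"hu_bin_width must be >= 1, got {hu_bin_width}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo, hi = table.hu_range
    n_bins = math.ceil((hi - lo) / hu_bin_width)

    mat_lines = ["[Materials]"]
    map_lines = ["# HU_start HU_end material"]
    for k in range(n_bins):
        b_lo = int(lo) + k * hu_bin_width
        b_hi = b_lo + hu_bin_width
        center = min(max((b_lo + b_hi) / 2.0, lo), hi)
        frac = composition_at(table, center)
        rho = density_at(model, center)
        name = material_name(b_lo, b_hi)
        nz = [(el, f) for el, f in zip(ELEMENTS, frac.values) if f > 0]
        mat_lines.append(f"{name}: d={rho:.6g} g/cm3 ; n={len(nz)}")
        total = sum(f for _, f in nz)
        for el, f in nz:
            mat_lines.append(f"        +el: name={_GATE_ELEMENT_NAMES[el]} ; f={f / total:.6f}")
        map_lines.append(f"{b_lo} {b_hi} {name}")

    mat_path = out_dir / materials_filename
    map_path = out_dir / map_filename
    mat_path.write_text("\n".join(mat_lines) + "\n")
    map_path.write_text("\n".join(map_lines) + "\n")
    return mat_path, map_path
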