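"""Differential dose-volume histograms (DVH).

Every risk quantity in this package is computed from the differential
DVH of an organ: the volume :math:`V_i` (cm^3) receiving dose in bin
:math:`i`, with bin-centre dose :math:`D_i` (Gy) and total organ volume
:math:`V = \\sum_i V_i`.  Bins are uniform and half-open,
``[k*w, (k+1)*w)``, except that the last bin is closed above so the
maximum voxel dose is always counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryMismatchError, InvalidInputError
from .rt_io import DoseGrid, OrganMask


@dataclass
class DVH:
    """Differential dose-volume histogram for one organ.

    Attributes
    ----------
    organ : str
        Organ name.
    bin_width : float
        Uniform bin width in Gy.
    edges : numpy.ndarray
        Bin edges (Gy), length ``nbins + 1``, strictly increasing,
        starting at 0.
    volumes : numpy.ndarray
        Volume per bin (cm^3), length ``nbins``.
    """

    organ: str
    bin_width: float
    edges: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.bin_width <= 0:
            raise InvalidInputError("bin width must be positive")
        if self.edges.ndim != 1 or np.any(np.diff(self.edges) <= 0):
            raise InvalidInputError("bin edges must be strictly increasing")
        if self.volumes.shape != (self.edges.size - 1,):
            raise InvalidInputError("need one volume per bin")
        if np.any(self.volumes < 0):
            raise InvalidInputError("bin volumes must be nonnegative")

    @property
    def centers(self) -> np.ndarray:
        """Bin-centre doses D_i (Gy)."""
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total_volume(self) -> float:
        """Total organ volume V (cm^3)."""
        return float(self.volumes.sum())

    # -- serialization ------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "dose_bin_lo": self.edges[:-1],
                "dose_bin_hi": self.edges[1:],
                "volume_cm3": self.volumes,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, organ: str | None = None) -> "DVH":
        df = pd.read_csv(path)
        lo = df["dose_bin_lo"].to_numpy(dtype=float)
        hi = df["dose_bin_hi"].to_numpy(dtype=float)
        edges = np.append(lo, hi[-1])
        return cls(
            organ=organ or Path(path).stem,
            bin_width=float(hi[0] - lo[0]),
            edges=edges,
            volumes=df["volume_cm3"].to_numpy(dtype=float),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "organ": self.organ,
                    "bin_width": self.bin_width,
                    "edges": self.edges.tolist(),
                    "volumes": self.volumes.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DVH":
        d = json.loads(Path(path).read_text())
        return cls(
            organ=d["organ"],
            bin_width=d["bin_width"],
            edges=np.asarray(d["edges"]),
            volumes=np.asarray(d["volumes"]),
        )


def compute_dvh(dose: DoseGrid, mask: OrganMask, bin_width: float = 0.1) -> DVH:
    """Histogram the member-voxel doses of an organ.

    Parameters
    ----------
    dose, mask
        Must share an identical grid geometry; resample the dose first
        if they do not.
    bin_width : float
        Uniform bin width in Gy (default 0.1).

    Returns
    -------
    DVH
        Differential DVH with ``V = member count x voxel volume``.
    """
    if bin_width <= 0:
        raise InvalidInputError("bin_width must be > 0")
    if not dose.geometry.approx_equal(mask.geometry):
        raise GeometryMismatchError(
            "dose and mask geometries differ; resample the dose onto the mask "
            "grid (secr.rt_io.resample_to) before computing a DVH"
        )
    doses = dose.values[mask.membership]
    if doses.size == 0:
        raise InvalidInputError(f"organ {mask.name!r}: empty mask")
    vmax = float(doses.max())
    nbins = int(np.floor(vmax / bin_width)) + 1
    edges = np.arange(nbins + 1, dtype=float) * bin_width
    counts, _ = np.histogram(doses, bins=edges)  # last bin closed above
    return DVH(
        organ=mask.name,
        bin_width=bin_width,
        edges=edges,
        volumes=counts * mask.voxel_volume_cm3,
    )


class CumulativeDVH:
    """Cumulative curve: volume receiving at least a given dose.

    The curve starts at the total volume V for dose 0, is nonincreasing,
    and steps (right-continuously) at bin edges.
    """

    def __init__(self, dvh: DVH):
        self.organ = dvh.organ
        self.edges = dvh.edges
        self._csum = np.concatenate([[0.0], np.cumsum(dvh.volumes)])
        self.total_volume = float(self._csum[-1])

    def __call__(self, dose):
        """Volume (cm^3) receiving >= ``dose`` Gy."""
        d = np.asarray(dose, dtype=float)
        n_below = np.searchsorted(self.edges[1:], d, side="right")
        out = self.total_volume - self._csum[n_below]
        return float(out) if np.isscalar(dose) else out


def cumulative(dvh: DVH) -> CumulativeDVH:
    """Build the cumulative (volume >= dose) curve from a differential DVH."""
    return CumulativeDVH(dvh)


def mean_dose(dvh: DVH) -> float:
    """Volume-weighted mean dose, sum(V_i * D_i) / V, in Gy."""
    V = dvh.total_volume
    if V <= 0:
        raise InvalidInputError("mean dose undefined for zero total volume")
    return float(np.sum(dvh.volumes * dvh.centers) / V)
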