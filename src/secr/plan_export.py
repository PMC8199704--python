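"""VMAT plan parsing and macro export for an external Monte Carlo engine.

A VMAT arc is delivered as a sequence of control points, each carrying a
gantry angle, a cumulative meterset weight in [0, 1], and the MLC leaf
and jaw positions.  The Monte Carlo engine consumes one *segment* per
consecutive control-point pair: gantry start/stop angle, the monitor
units delivered over the segment (total MU x weight increment), and the
machine aperture at the segment start.  The emitted macro file is a
tab-separated UTF-8 table, one segment per line, with columns::

    beam  segment  energy  gantry_start_deg  gantry_stop_deg  mu
    jaw_x1  jaw_x2  jaw_y1  jaw_y2  mlc_a  mlc_b

``mlc_a``/``mlc_b`` are comma-joined leaf positions (mm) for the two
banks.  Floats are written with ``repr`` so a parse-back reproduces the
segment table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom

from .errors import DicomFormatError, DicomModalityError, InvalidInputError


@dataclass
class ControlPoint:
    gantry_deg: float
    cumulative_weight: float
    mlc_a: np.ndarray | None = None
    mlc_b: np.ndarray | None = None
    jaws: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)


@dataclass
class VMATBeam:
    name: str
    energy: str
    total_mu: float
    control_points: list[ControlPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.control_points) < 2:
            raise InvalidInputError(
                f"beam {self.name!r}: needs >= 2 control points"
            )
        if self.total_mu <= 0:
            raise InvalidInputError(f"beam {self.name!r}: total MU must be > 0")
        w = [cp.cumulative_weight for cp in self.control_points]
        if any(b < a - 1e-12 for a, b in zip(w, w[1:])):
            raise InvalidInputError(
                f"beam {self.name!r}: cumulative weights must be nondecreasing"
            )
        if abs(w[0]) > 1e-9 or abs(w[-1] - 1.0) > 1e-9:
            raise InvalidInputError(
                f"beam {self.name!r}: cumulative weights must run from 0 to 1"
            )


@dataclass
class Segment:
    """One delivery segment between consecutive control points."""

    beam: str
    index: int
    energy: str
    gantry_start_deg: float
    gantry_stop_deg: float
    mu: float
    jaws: tuple[float, float, float, float]
    mlc_a: np.ndarray
    mlc_b: np.ndarray


def _normalize_angle(deg: float) -> float:
    return float(deg) % 360.0


def read_rtplan(path: str | Path) -> list[VMATBeam]:
    """Read the VMAT beams of a DICOM RTPLAN.

    MLC positions omitted at a control point inherit the previous
    control point's positions (DICOM convention).  Cumulative meterset
    weights are normalized by the beam's final cumulative weight.
    """
    ds = pydicom.dcmread(path)
    modality = getattr(ds, "Modality", None)
    if modality != "RTPLAN":
        raise DicomModalityError(f"{path}: expected RTPLAN, got {modality!r}")
    # total MU per beam from the fraction group
    mu_by_beam: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(rb, "BeamMeterset"):
                mu_by_beam[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)
    beams = []
    for beam in getattr(ds, "BeamSequence", []):
        number = int(beam.BeamNumber)
        if number not in mu_by_beam:
            raise DicomFormatError(f"beam {number}: missing BeamMeterset")
        cps_raw = list(getattr(beam, "ControlPointSequence", []))
        if len(cps_raw) < 2:
            raise InvalidInputError(f"beam {number}: fewer than 2 control points")
        final_w = float(getattr(beam, "FinalCumulativeMetersetWeight", 1.0)) or 1.0
        energy = ""
        gantry = 0.0
        mlc_a = mlc_b = None
        jaws = (0.0, 0.0, 0.0, 0.0)
        cps = []
        for cp in cps_raw:
            if hasattr(cp, "NominalBeamEnergy"):
                energy = f"{float(cp.NominalBeamEnergy):g}MV"
            if hasattr(cp, "GantryAngle"):
                gantry = _normalize_angle(float(cp.GantryAngle))
            for bld in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                kind = bld.RTBeamLimitingDeviceType
                pos = np.asarray(bld.LeafJawPositions, dtype=float)
                if kind in ("MLCX", "MLCY"):
                    half = pos.size // 2
                    mlc_a, mlc_b = pos[:half].copy(), pos[half:].copy()
                elif kind in ("X", "ASYMX"):
                    jaws = (float(pos[0]), float(pos[1]), jaws[2], jaws[3])
                elif kind in ("Y", "ASYMY"):
                    jaws = (jaws[0], jaws[1], float(pos[0]), float(pos[1]))
            cps.append(
                ControlPoint(
                    gantry_deg=gantry,
                    cumulative_weight=float(cp.CumulativeMetersetWeight) / final_w,
                    mlc_a=None if mlc_a is None else mlc_a.copy(),
                    mlc_b=None if mlc_b is None else mlc_b.copy(),
                    jaws=jaws,
                )
            )
        beams.append(
            VMATBeam(
                name=str(getattr(beam, "BeamName", f"Beam{number}")),
                energy=energy,
                total_mu=mu_by_beam[number],
                control_points=cps,
            )
        )
    if not beams:
        raise DicomFormatError(f"{path}: no beams with control points")
    return beams


def segment_table(beams: list[VMATBeam], midpoint_mlc: bool = False) -> list[Segment]:
    """Build the per-segment delivery table (N control points -> N-1 rows).

    Leaf positions are taken at the segment start by default;
    ``midpoint_mlc=True`` averages start and end positions instead.
    """
    if not beams:
        raise InvalidInputError("no beams to export")
    segments = []
    for beam in beams:
        cps = beam.control_points
        for i, (a, b) in enumerate(zip(cps, cps[1:])):
            mlc_a = a.mlc_a if a.mlc_a is not None else np.array([])
            mlc_b = a.mlc_b if a.mlc_b is not None else np.array([])
            if midpoint_mlc and b.mlc_a is not None and mlc_a.size:
                mlc_a = 0.5 * (mlc_a + b.mlc_a)
                mlc_b = 0.5 * (mlc_b + b.mlc_b)
            segments.append(
                Segment(
                    beam=beam.name,
                    index=i,
                    energy=beam.energy,
                    gantry_start_deg=a.gantry_deg,
                    gantry_stop_deg=b.gantry_deg,
                    mu=beam.total_mu * (b.cumulative_weight - a.cumulative_weight),
                    jaws=a.jaws,
                    mlc_a=np.asarray(mlc_a, dtype=float),
                    mlc_b=np.asarray(mlc_b, dtype=float),
                )
            )
    return segments


_COLUMNS = (
    "beam", "segment", "energy", "gantry_start_deg", "gantry_stop_deg",
    "mu", "jaw_x1", "jaw_x2", "jaw_y1", "jaw_y2", "mlc_a", "mlc_b",
)


def export_macro(
    beams: list[VMATBeam], path: str | Path, midpoint_mlc: bool = False
) -> list[Segment]:
    """Write the segment table as a tab-separated macro file."""
    segments = segment_table(beams, midpoint_mlc=midpoint_mlc)
    lines = ["\t".join(_COLUMNS)]
    for s in segments:
        lines.append(
            "\t".join(
                [
                    s.beam,
                    str(s.index),
                    s.energy,
                    repr(s.gantry_start_deg),
                    repr(s.gantry_stop_deg),
                    repr(s.mu),
                    *[repr(float(j)) for j in s.jaws],
                    ",".join(repr(float(v)) for v in s.mlc_a),
                    ",".join(repr(float(v)) for v in s.mlc_b),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return segments


def parse_macro(path: str | Path) -> list[Segment]:
    """Parse a macro file back into the segment table (exact round-trip)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != _COLUMNS:
        raise InvalidInputError(f"{path}: not a secr macro file")

    def floats(cell: str) -> np.ndarray:
        return np.array([float(v) for v in cell.split(",") if v], dtype=float)

    segments = []
    for line in lines[1:]:
        f = line.split("\t")
        segments.append(
            Segment(
                beam=f[0],
                index=int(f[1]),
                energy=f[2],
                gantry_start_deg=float(f[3]),
                gantry_stop_deg=float(f[4]),
                mu=float(f[5]),
                jaws=tuple(float(v) for v in f[6:10]),
                mlc_a=floats(f[10]),
                mlc_b=floats(f[11]) if len(f) > 11 else np.array([]),
            )
        )
    return segments
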