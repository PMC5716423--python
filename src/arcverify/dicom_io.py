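"""Optional DICOM RT Plan ingestion (requires ``pydicom``).

The CSV plan dialect is the normative input format; this module is a
convenience for loading a real VMAT arc beam.  Cumulative meterset weights
are rescaled to MU using the referenced beam meterset, MLCX leaf positions
map to banks A/B in listed order, and attributes omitted from later control
points (DICOM's delta encoding) are carried forward.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import UnsupportedContentError
from .records_io import ArcPlan, ControlPoint
from .records_io import read_plan as _read_plan  # noqa: F401  (re-export convenience)

__all__ = ["read_dicom_plan"]


def _require_pydicom():
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise UnsupportedContentError(
            "reading DICOM RT Plans requires the optional dependency pydicom"
        ) from exc
    return pydicom


def read_dicom_plan(path: str | Path, beam_index: int = 0) -> ArcPlan:
    """Read one arc beam of a DICOM RT Plan into an :class:`ArcPlan`.

    Raises :class:`UnsupportedContentError` if the file has no MLC arc beam
    with at least two control points.
    """
    pydicom = _require_pydicom()
    ds = pydicom.dcmread(str(path), force=True)
    beams = getattr(ds, "BeamSequence", None)
    if not beams:
        raise UnsupportedContentError(f"{path}: no BeamSequence")
    mlc_beams = [b for b in beams if _has_mlc(b)]
    if not mlc_beams:
        raise UnsupportedContentError(f"{path}: no beam with an MLCX device")
    beam = mlc_beams[beam_index]
    cps_in = getattr(beam, "ControlPointSequence", None)
    if cps_in is None or len(cps_in) < 2:
        raise UnsupportedContentError(
            f"{path}: beam has fewer than 2 control points (static beam?)"
        )

    meterset = _beam_meterset(ds, beam)
    final_weight = float(getattr(beam, "FinalCumulativeMetersetWeight", 1.0))
    if final_weight <= 0:
        raise UnsupportedContentError(f"{path}: non-positive final meterset weight")

    gantry = None
    mlc = None
    jaws = {"X": None, "Y": None}
    sense = None
    cps: list[ControlPoint] = []
    for i, cp in enumerate(cps_in):
        if hasattr(cp, "GantryAngle"):
            gantry = float(cp.GantryAngle) % 360.0
        direction = getattr(cp, "GantryRotationDirection", None)
        if direction == "CW":
            sense = 1
        elif direction == "CC":
            sense = -1
        for dev in getattr(cp, "BeamLimitingDevicePositionSequence", []):
            kind = dev.RTBeamLimitingDeviceType
            values = np.asarray([float(v) for v in dev.LeafJawPositions])
            if kind == "MLCX":
                mlc = values
            elif kind in ("X", "ASYMX"):
                jaws["X"] = values
            elif kind in ("Y", "ASYMY"):
                jaws["Y"] = values
        if gantry is None or mlc is None:
            raise UnsupportedContentError(
                f"{path}: control point {i} lacks gantry angle or MLCX positions"
            )
        if mlc.size % 2 != 0:
            raise UnsupportedContentError(f"{path}: odd MLCX position count")
        n_pairs = mlc.size // 2
        jx = jaws["X"] if jaws["X"] is not None else np.array([-200.0, 200.0])
        jy = jaws["Y"] if jaws["Y"] is not None else np.array([-200.0, 200.0])
        weight = float(cp.CumulativeMetersetWeight)
        cps.append(
            ControlPoint(
                index=i,
                cumulative_mu=meterset * weight / final_weight,
                gantry_deg=gantry,
                bank_a=mlc[:n_pairs],
                bank_b=mlc[n_pairs:],
                jaws=np.array([jx[0], jx[1], jy[0], jy[1]]),
            )
        )

    if sense is None:
        from .records_io import _infer_sense

        sense = _infer_sense([cp.gantry_deg for cp in cps])
    plan = ArcPlan(
        patient_id=str(getattr(ds, "PatientID", "")),
        field_id=str(getattr(beam, "BeamName", getattr(beam, "BeamNumber", ""))),
        control_points=cps,
        rotation_sense=sense,
    )
    plan.validate()
    return plan


def _has_mlc(beam) -> bool:
    for dev in getattr(beam, "BeamLimitingDeviceSequence", []):
        if dev.RTBeamLimitingDeviceType == "MLCX":
            return True
    # some plans only declare MLCX inside control points
    for cp in getattr(beam, "ControlPointSequence", []):
        for dev in getattr(cp, "BeamLimitingDevicePositionSequence", []):
            if dev.RTBeamLimitingDeviceType == "MLCX":
                return True
    return False


def _beam_meterset(ds, beam) -> float:
    beam_number = getattr(beam, "BeamNumber", None)
    for fg in getattr(ds, "FractionGroupSequence", []):
        for ref in getattr(fg, "ReferencedBeamSequence", []):
            if getattr(ref, "ReferencedBeamNumber", None) == beam_number:
                return float(ref.BeamMeterset)
    raise UnsupportedContentError("no referenced beam meterset for the arc beam")
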