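"""Morphometric diagnostic criteria for coarctation of the aorta.

Three published rules classify a subject from the minimum internal
diameters (mm) of five aortic sites -- ascending aorta (AOA), proximal
arch (D1), distal arch (D2), isthmus (D3) and descending aorta (DA) --
plus body weight:

* CHD-database rule: coarctation if D1 < 0.6*AOA, or D2 < 0.5*AOA, or
  D3 < 0.4*AOA (meeting any one condition suffices).
* Karl's rule: coarctation if the narrowest transverse-arch diameter,
  min(D1, D2), is below a weight-bracketed threshold; for small infants
  the threshold is weight (kg) + 1 mm.
* Langley's rule: coarctation if min(D1, D2) < 0.5*DA.

All comparisons are strict; boundary values classify as no coarctation.
The transverse arch spans the proximal and distal arch only -- the isthmus
has its own role in the CHD rule and is not part of min(D1, D2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SiteMeasurements",
    "DiagnosisResult",
    "CRITERIA",
    "CHD_FRACTIONS",
    "LANGLEY_FRACTION",
    "transverse_arch_min",
    "karl_threshold",
    "diagnose_chd",
    "diagnose_karl",
    "diagnose_langley",
    "diagnose",
]

CRITERIA = ("chd", "karl", "langley")

#: Fractions of the ascending-aorta diameter below which D1/D2/D3 indicate CoA.
CHD_FRACTIONS = {"D1": 0.6, "D2": 0.5, "D3": 0.4}
LANGLEY_FRACTION = 0.5


@dataclass(frozen=True)
class SiteMeasurements:
    """Per-subject minimum diameters (mm) at the five sites, plus weight.

    Any field may be None when not measured; each criterion validates the
    fields it needs.
    """

    aoa: float | None = None
    d1: float | None = None
    d2: float | None = None
    d3: float | None = None
    da: float | None = None
    weight_kg: float | None = None

    def require(self, *fields: str) -> None:
        for name in fields:
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"measurement {name!r} is required but missing")
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"measurement {name!r} must be positive and finite, got {v}")


@dataclass(frozen=True)
class DiagnosisResult:
    criterion: str
    is_coa: bool
    triggered: tuple[str, ...]

    @property
    def label(self) -> str:
        return "coa" if self.is_coa else "control"


def transverse_arch_min(m: SiteMeasurements) -> float:
    """Narrowest transverse-arch diameter, min(D1, D2)."""
    m.require("d1", "d2")
    return min(m.d1, m.d2)


def karl_threshold(weight_kg: float) -> float:
    """Weight-bracketed transverse-arch threshold (mm) for Karl's rule.

    Brackets: w < 6 kg -> w + 1; 6 <= w < 20 -> w; 20 <= w < 30 -> w/2;
    30 <= w < 40 -> w/2.5; w >= 40 -> w/3.  The published bracket list
    leaves 10-20 kg unstated; it is filled by extending threshold = w, the
    continuation of the 6-10 kg bracket (see docs/methods.md).
    """
    if not (weight_kg > 0 and math.isfinite(weight_kg)):
        raise ValueError(f"weight must be positive and finite, got {weight_kg}")
    if weight_kg < 6:
        return weight_kg + 1.0
    if weight_kg < 20:
        return float(weight_kg)
    if weight_kg < 30:
        return weight_kg / 2.0
    if weight_kg < 40:
        return weight_kg / 2.5
    return weight_kg / 3.0


def diagnose_chd(m: SiteMeasurements) -> DiagnosisResult:
    """CHD-database rule: any arch segment below its AOA fraction."""
    m.require("aoa", "d1", "d2", "d3")
    triggered = tuple(
        f"{site} < {frac}*AOA"
        for site, frac in CHD_FRACTIONS.items()
        if getattr(m, site.lower()) < frac * m.aoa
    )
    return DiagnosisResult("chd", bool(triggered), triggered)


def diagnose_karl(m: SiteMeasurements) -> DiagnosisResult:
    """Karl's rule: narrowest transverse arch below the weight threshold."""
    m.require("d1", "d2", "weight_kg")
    arch = transverse_arch_min(m)
    thr = karl_threshold(m.weight_kg)
    hit = arch < thr
    triggered = (f"min(D1,D2) < {thr:g} mm",) if hit else ()
    return DiagnosisResult("karl", hit, triggered)


def diagnose_langley(m: SiteMeasurements) -> DiagnosisResult:
    """Langley's rule: narrowest transverse arch below half the DA diameter."""
    m.require("d1", "d2", "da")
    arch = transverse_arch_min(m)
    hit = arch < LANGLEY_FRACTION * m.da
    triggered = ("min(D1,D2) < 0.5*DA",) if hit else ()
    return DiagnosisResult("langley", hit, triggered)


_DISPATCH = {"chd": diagnose_chd, "karl": diagnose_karl, "langley": diagnose_langley}


def diagnose(m: SiteMeasurements, criterion: str) -> DiagnosisResult:
    """Apply one of the named criteria ('chd', 'karl', 'langley')."""
    try:
        fn = _DISPATCH[criterion]
    except KeyError:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}") from None
    return fn(m)
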