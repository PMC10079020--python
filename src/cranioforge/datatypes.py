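"""Core domain types for the craniodental ecomorphology pipeline.

The pipeline studies five specimen groups from a pine-squirrel hybrid zone:
allopatric and hybrid-zone Douglas squirrels, genetic hybrids, and hybrid-zone
and allopatric red squirrels.  Specimens carry caliper incisor measurements,
traced cranial-suture polylines, and 2-D mandible landmark configurations
(15 fixed anatomical landmarks plus 45 sliding semilandmarks on curves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np


class Group(Enum):
    """Genotype/geography class of a specimen.

    Ordered from pure Douglas squirrel to pure red squirrel: allopatric
    Douglas, hybrid-zone Douglas, hybrid, hybrid-zone red, allopatric red.
    """

    ALLO_DOUG = "ALLO_DOUG"
    HZ_DOUG = "HZ_DOUG"
    HYBRID = "HYBRID"
    HZ_RED = "HZ_RED"
    ALLO_RED = "ALLO_RED"

    @classmethod
    def parse(cls, text: str) -> "Group":
        key = str(text).strip().upper().replace(" ", "_").replace("-", "_")
        aliases = {
            "ALLO_DOUG": cls.ALLO_DOUG,
            "ALLO_DOUGLAS": cls.ALLO_DOUG,
            "ALLOPATRIC_DOUGLAS": cls.ALLO_DOUG,
            "HZ_DOUG": cls.HZ_DOUG,
            "HZ_DOUGLAS": cls.HZ_DOUG,
            "HYBRID": cls.HYBRID,
            "HYBRIDS": cls.HYBRID,
            "HZ_RED": cls.HZ_RED,
            "ALLO_RED": cls.ALLO_RED,
            "ALLOPATRIC_RED": cls.ALLO_RED,
        }
        if key not in aliases:
            raise ValueError(f"unknown group label: {text!r}")
        return aliases[key]


#: canonical group order used throughout tables and reports
GROUP_ORDER: tuple[Group, ...] = (
    Group.ALLO_DOUG,
    Group.HZ_DOUG,
    Group.HYBRID,
    Group.HZ_RED,
    Group.ALLO_RED,
)


class Sex(Enum):
    F = "F"
    M = "M"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def parse(cls, text: str) -> "Sex":
        key = str(text).strip().upper()
        if key in ("F", "FEMALE"):
            return cls.F
        if key in ("M", "MALE"):
            return cls.M
        if key in ("", "U", "UNKNOWN", "NA", "NAN", "NONE"):
            return cls.UNKNOWN
        raise ValueError(f"unknown sex label: {text!r}")


class SutureName(Enum):
    NASOFRONTAL = "NASOFRONTAL"
    PREMAXILLOFRONTAL = "PREMAXILLOFRONTAL"
    MAXILLOFRONTAL = "MAXILLOFRONTAL"
    CORONAL = "CORONAL"
    SAGITTAL = "SAGITTAL"

    @classmethod
    def parse(cls, text: str) -> "SutureName":
        key = str(text).strip().upper()
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown suture name: {text!r}") from None


#: canonical suture order used in LR tables
SUTURE_ORDER: tuple[SutureName, ...] = (
    SutureName.NASOFRONTAL,
    SutureName.PREMAXILLOFRONTAL,
    SutureName.MAXILLOFRONTAL,
    SutureName.CORONAL,
    SutureName.SAGITTAL,
)


class AdmixtureClass(Enum):
    PURE_RED = "PURE_RED"
    PURE_DOUGLAS = "PURE_DOUGLAS"
    HYBRID = "HYBRID"


class ValidationError(ValueError):
    """Raised when input data violate a domain-type invariant."""


@dataclass
class SpecimenRecord:
    """One museum specimen: identity, genotype class, sex, mass, admixture.

    ``admixture_q`` is the fraction of the genome assigned to the red-squirrel
    parental population; it is required for specimens in the HYBRID group.
    """

    specimen_id: str
    group: Group
    sex: Sex = Sex.UNKNOWN
    body_mass: Optional[float] = None  # grams
    admixture_q: Optional[float] = None  # in [0, 1]

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValidationError("specimen_id must be non-empty")
        if self.body_mass is not None:
            if not math.isfinite(self.body_mass) or self.body_mass <= 0:
                raise ValidationError(
                    f"{self.specimen_id}: body_mass must be positive, got {self.body_mass}"
                )
        if self.admixture_q is not None:
            if not (0.0 <= self.admixture_q <= 1.0):
                raise ValidationError(
                    f"{self.specimen_id}: admixture_q must lie in [0, 1], got {self.admixture_q}"
                )
        if self.group is Group.HYBRID and self.admixture_q is None:
            raise ValidationError(
                f"{self.specimen_id}: HYBRID specimens require an admixture_q value"
            )


@dataclass
class IncisorMeasurement:
    """Lower-incisor caliper dimensions in millimetres."""

    specimen_id: str
    ap_length: float  # antero-posterior length, mm
    ml_width: float  # medio-lateral width, mm

    def __post_init__(self) -> None:
        for name, v in (("ap_length", self.ap_length), ("ml_width", self.ml_width)):
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"{self.specimen_id}: incisor {name} must be positive and finite, got {v}"
                )


@dataclass
class SutureTrace:
    """Ordered planar polyline tracing one named cranial suture.

    Units are arbitrary but must be consistent within a trace; the length
    ratio statistic is scale-invariant.
    """

    specimen_id: str
    suture: SutureName
    vertices: np.ndarray  # (k, 2)
    side: Optional[str] = None  # optional left/right bookkeeping, not used in LR

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValidationError(
                f"{self.specimen_id}/{self.suture.value}: need >= 2 planar vertices"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError(
                f"{self.specimen_id}/{self.suture.value}: non-finite vertex coordinates"
            )
        if np.allclose(v, v[0]):
            raise ValidationError(
                f"{self.specimen_id}/{self.suture.value}: all vertices identical"
            )
        if np.array_equal(v[0], v[-1]):
            raise ValidationError(
                f"{self.specimen_id}/{self.suture.value}: first and last vertex coincide"
            )
        self.vertices = v


@dataclass
class LandmarkConfiguration:
    """A 2-D landmark configuration for one specimen.

    ``points`` holds fixed landmarks first, then semilandmarks in curve order.
    ``roles`` flags each point ``'fixed'`` or ``'semi'``; ``curves`` partitions
    the semilandmark indices (into ``points``) into ordered digitization
    curves.  The conforming scheme has 15 fixed and 45 semilandmarks; other
    counts are allowed but flagged non-conforming.
    """

    specimen_id: str
    points: np.ndarray  # (n, 2), mm
    roles: Sequence[str] = field(default_factory=list)
    curves: Sequence[Sequence[int]] = field(default_factory=list)
    scale: Optional[float] = None  # units per pixel if digitized from an image

    N_FIXED_CONFORMING = 15
    N_SEMI_CONFORMING = 45

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(f"{self.specimen_id}: points must be (n, 2)")
        if not np.all(np.isfinite(pts)):
            raise ValidationError(f"{self.specimen_id}: non-finite landmark coordinates")
        self.points = pts
        if not self.roles:
            self.roles = ["fixed"] * pts.shape[0]
        self.roles = list(self.roles)
        if len(self.roles) != pts.shape[0]:
            raise ValidationError(f"{self.specimen_id}: roles length != point count")
        if any(r not in ("fixed", "semi") for r in self.roles):
            raise ValidationError(f"{self.specimen_id}: roles must be 'fixed' or 'semi'")
        semi_idx = {i for i, r in enumerate(self.roles) if r == "semi"}
        in_curves: list[int] = [i for c in self.curves for i in c]
        if len(set(in_curves)) != len(in_curves):
            raise ValidationError(f"{self.specimen_id}: a point appears in two curves")
        if set(in_curves) != semi_idx:
            raise ValidationError(
                f"{self.specimen_id}: curves must partition exactly the semilandmarks"
            )

    @property
    def n_fixed(self) -> int:
        return sum(1 for r in self.roles if r == "fixed")

    @property
    def n_semi(self) -> int:
        return sum(1 for r in self.roles if r == "semi")

    @property
    def conforming(self) -> bool:
        """True when the configuration matches the 15 + 45 digitization scheme."""
        return (
            self.n_fixed == self.N_FIXED_CONFORMING
            and self.n_semi == self.N_SEMI_CONFORMING
        )


@dataclass
class CalibrationParams:
    """Rodent calibration of log10 bite force (N) on log10 incisor strength index."""

    zi_slope: float = 0.566
    zi_intercept: float = 1.432  # log10 Newtons


#: published reference fit of log10 bite force on log10 body mass for the
#: original 70-specimen squirrel sample (documentation only; the pipeline
#: always refits this regression on the analyzed sample).
REFERENCE_BFQ_REGRESSION = {"slope": 0.3849, "intercept": 0.6970, "r2": 0.419}
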