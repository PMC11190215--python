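"""Audiogram inclusion/exclusion screening.

Before any diagnostic use, each record is screened against validity rules of
the kind used for automated audiogram interpretation:

1. completeness — mandatory octave frequencies present in both conductions;
2. air-conduction thresholds within instrument limits (−10..110 dB HL, with a
   stricter 90 dB ceiling at low frequencies, where audiometer output is
   limited);
3. no implausible jump between adjacent air-conduction octaves (|Δ| ≤ 30 dB);
4. bone-conduction thresholds within instrument limits (−10..60 dB HL,
   40 dB ceiling at 250 Hz);
5. bone threshold consistent with air at the same frequency (the signed
   air−bone difference must lie in −10..50 dB: a larger gap exceeds what
   middle-ear pathology can produce, and bone more than 10 dB *worse* than
   air is physically inconsistent beyond test–retest error).

Two of the published rule statements are ambiguous as written and are
therefore configurable here: whether the stricter air/bone ceiling applies at
or below 250 Hz (default) or above it, and whether the octave-step rule is
one-sided (only rises checked) or symmetric (default — a strictly one-sided
reading would reject every rising audiogram and hence essentially all
conductive losses).

All checks are pure: they report reasons and never mutate or repair records.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .core import (
    AIR_FREQS,
    BONE_FREQS,
    REQUIRED_AIR_FREQS,
    REQUIRED_BONE_FREQS,
    Audiogram,
    AudiogramSet,
)

__all__ = [
    "ReasonCode",
    "RejectionReason",
    "QcConfig",
    "QcReport",
    "check_completeness",
    "check_air_range",
    "check_air_steps",
    "check_bone_range",
    "check_air_bone_relation",
    "run_checks",
    "apply_qc",
]


class ReasonCode(enum.Enum):
    MISSING_FREQUENCY = "missing_frequency"
    AIR_OUT_OF_RANGE = "air_out_of_range"
    AIR_STEP_VIOLATION = "air_step_violation"
    BONE_OUT_OF_RANGE = "bone_out_of_range"
    AIR_BONE_RELATION = "air_bone_relation"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class RejectionReason:
    """One concrete rule violation, naming the frequency and value(s)."""

    code: ReasonCode
    conduction: str | None  # air | bone | None (relation involves both)
    frequency: int
    detail: str


@dataclass(frozen=True)
class QcConfig:
    """Tunable bounds of the screening rules (dB HL unless noted)."""

    air_min: float = -10.0
    air_max: float = 110.0
    air_max_low_freq: float = 90.0
    bone_min: float = -10.0
    bone_max: float = 60.0
    bone_max_low_freq: float = 40.0
    #: boundary frequency of the stricter low-frequency ceilings
    low_freq_cutoff: int = 250
    #: if True (default) the stricter ceiling applies at f <= low_freq_cutoff;
    #: if False it applies at f > low_freq_cutoff (the alternative reading).
    low_freq_limit_at_or_below: bool = True
    #: inclusive bounds on the signed step AC(f) − AC(f_lower) between
    #: adjacent measured air octaves.
    step_bounds: tuple[float, float] = (-30.0, 30.0)
    #: inclusive bounds on the signed air−bone difference AC(f) − BC(f).
    air_bone_bounds: tuple[float, float] = (-10.0, 50.0)


DEFAULT_QC = QcConfig()


def check_completeness(a: Audiogram, cfg: QcConfig = DEFAULT_QC) -> list[RejectionReason]:
    """Mandatory frequencies: air 250–8000 Hz, bone 500–4000 Hz.

    125 Hz air and 250 Hz bone are optional and never flagged.
    """
    reasons = []
    for f in REQUIRED_AIR_FREQS:
        if f not in a.ac:
            reasons.append(RejectionReason(
                ReasonCode.MISSING_FREQUENCY, "air", f, f"air threshold absent at {f} Hz"))
    for f in REQUIRED_BONE_FREQS:
        if f not in a.bc:
            reasons.append(RejectionReason(
                ReasonCode.MISSING_FREQUENCY, "bone", f, f"bone threshold absent at {f} Hz"))
    return reasons


def _ceiling(freq: int, hi: float, hi_low: float, cfg: QcConfig) -> float:
    low = freq <= cfg.low_freq_cutoff if cfg.low_freq_limit_at_or_below \
        else freq > cfg.low_freq_cutoff
    return hi_low if low else hi


def check_air_range(a: Audiogram, cfg: QcConfig = DEFAULT_QC) -> list[RejectionReason]:
    """Air thresholds within −10..110 dB HL (ceiling 90 dB at low frequencies)."""
    reasons = []
    for f in AIR_FREQS:
        if f not in a.ac:
            continue
        v = a.ac[f]
        hi = _ceiling(f, cfg.air_max, cfg.air_max_low_freq, cfg)
        if v < cfg.air_min or v > hi:
            reasons.append(RejectionReason(
                ReasonCode.AIR_OUT_OF_RANGE, "air", f,
                f"air {v:g} dB at {f} Hz outside [{cfg.air_min:g}, {hi:g}]"))
    return reasons


def check_air_steps(a: Audiogram, cfg: QcConfig = DEFAULT_QC) -> list[RejectionReason]:
    """Adjacent-octave air step within bounds (default |Δ| ≤ 30 dB, inclusive).

    Applied to consecutive grid frequencies at which air was measured.
    """
    lo, hi = cfg.step_bounds
    present = [f for f in AIR_FREQS if f in a.ac]
    reasons = []
    for f_lower, f in zip(present, present[1:]):
        delta = a.ac[f] - a.ac[f_lower]
        if delta < lo or delta > hi:
            reasons.append(RejectionReason(
                ReasonCode.AIR_STEP_VIOLATION, "air", f,
                f"air step {delta:+g} dB from {f_lower} to {f} Hz outside [{lo:g}, {hi:g}]"))
    return reasons


def check_bone_range(a: Audiogram, cfg: QcConfig = DEFAULT_QC) -> list[RejectionReason]:
    """Bone thresholds within −10..60 dB HL (ceiling 40 dB at 250 Hz)."""
    reasons = []
    for f in BONE_FREQS:
        if f not in a.bc:
            continue
        v = a.bc[f]
        hi = _ceiling(f, cfg.bone_max, cfg.bone_max_low_freq, cfg)
        if v < cfg.bone_min or v > hi:
            reasons.append(RejectionReason(
                ReasonCode.BONE_OUT_OF_RANGE, "bone", f,
                f"bone {v:g} dB at {f} Hz outside [{cfg.bone_min:g}, {hi:g}]"))
    return reasons


def check_air_bone_relation(a: Audiogram, cfg: QcConfig = DEFAULT_QC) -> list[RejectionReason]:
    """Signed air−bone difference within −10..50 dB wherever both measured."""
    lo, hi = cfg.air_bone_bounds
    reasons = []
    for f in BONE_FREQS:
        if f not in a.bc or f not in a.ac:
            continue
        gap = a.ac[f] - a.bc[f]
        if gap < lo or gap > hi:
            reasons.append(RejectionReason(
                ReasonCode.AIR_BONE_RELATION, None, f,
                f"air−bone difference {gap:+g} dB at {f} Hz outside [{lo:g}, {hi:g}]"))
    return reasons


_CHECKS = (
    check_completeness,
    check_air_range,
    check_air_steps,
    check_bone_range,
    check_air_bone_relation,
)


def run_checks(a: Audiogram, cfg: QcConfig = DEFAULT_QC) -> list[RejectionReason]:
    """All five screening checks on one record; empty list means valid."""
    reasons: list[RejectionReason] = []
    for check in _CHECKS:
        reasons.extend(check(a, cfg))
    return reasons


@dataclass
class QcReport:
    """Outcome of screening a set: kept records, rejections with reasons,
    and per-reason-code counts."""

    kept: AudiogramSet
    rejected: list[tuple[Audiogram, list[RejectionReason]]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": len(self.kept),
            "n_rejected": len(self.rejected),
            "reason_counts": dict(self.counts),
            "rejections": [
                {
                    "subject_id": a.subject_id,
                    "ear": a.ear,
                    "reasons": [
                        {"code": str(r.code), "frequency": r.frequency, "detail": r.detail}
                        for r in reasons
                    ],
                }
                for a, reasons in self.rejected
            ],
        }


def apply_qc(aset: AudiogramSet, cfg: QcConfig = DEFAULT_QC) -> QcReport:
    """Screen every record; keep those passing all five checks, in input order."""
    kept_idx: list[int] = []
    rejected: list[tuple[Audiogram, list[RejectionReason]]] = []
    counts: dict[str, int] = {str(code): 0 for code in ReasonCode}
    for i, a in enumerate(aset.records):
        reasons = run_checks(a, cfg)
        if reasons:
            rejected.append((a, reasons))
            for r in reasons:
                counts[str(r.code)] += 1
        else:
            kept_idx.append(i)
    return QcReport(kept=aset.subset(kept_idx), rejected=rejected, counts=counts)
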