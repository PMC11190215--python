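"""Deterministic rule engine for hearing-loss type diagnosis.

The clinical decision rules operate on three summaries of one ear's
audiogram:

* **PTA4** — the pure-tone average over 500/1000/2000/4000 Hz, per
  conduction.  Following the WHO criterion, a mean below 20 dB HL counts as
  normal for that conduction.
* **High-frequency averages** — air over 4000/8000 Hz and bone over the grid
  octaves within 4–6 kHz (only 4000 Hz is ever measured by bone), used to
  confirm sensorineural loss extends into the upper range.
* **Air–bone gap presence** — the gap AC−BC is computed per frequency at
  500–4000 Hz; a gap is *present* when it reaches 10 dB at three or more of
  the four frequencies, or 15 dB at any single one (bounds inclusive).

The four diagnostic classes are then:

=============== =============== =============== ===========
class           air PTA4        bone PTA4       air–bone gap
=============== =============== =============== ===========
normal          < 20            < 20            absent
conductive      ≥ 20            < 20            present
sensorineural   ≥ 20 (and HF)   ≥ 20 (and HF)   absent
mixed           ≥ 20            ≥ 20            present
=============== =============== =============== ===========

Any threshold combination matching none of the rows (e.g. normal PTA with a
large gap, or air loss with normal bone but no gap) is labelled
``INDETERMINATE`` rather than forced into a class.  All means are compared
unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    AIR_HF_FREQS,
    BONE_HF_FREQS,
    PTA_FREQS,
    Audiogram,
    HearingLossLabel,
)

__all__ = ["RuleConfig", "GapProfile", "mean_threshold", "air_bone_gaps", "classify"]


@dataclass(frozen=True)
class RuleConfig:
    """Cut-offs of the diagnostic rules (dB HL)."""

    pta_cutoff: float = 20.0
    gap_multi_threshold: float = 10.0
    gap_multi_min_count: int = 3
    gap_single_threshold: float = 15.0
    gap_freqs: tuple[int, ...] = PTA_FREQS
    air_hf_freqs: tuple[int, ...] = AIR_HF_FREQS
    bone_hf_freqs: tuple[int, ...] = BONE_HF_FREQS

    def __post_init__(self) -> None:
        if not (self.gap_single_threshold >= self.gap_multi_threshold > 0):
            raise ValueError("need gap_single_threshold >= gap_multi_threshold > 0")
        if self.gap_multi_min_count > len(self.gap_freqs):
            raise ValueError("gap_multi_min_count exceeds number of gap frequencies")


DEFAULT_RULES = RuleConfig()


def mean_threshold(a: Audiogram, conduction: str, freqs) -> float:
    """Unrounded arithmetic mean of thresholds at *freqs* for one conduction.

    Raises ``ValueError`` naming the first absent frequency.
    """
    table = a.ac if conduction == "air" else a.bc
    values = []
    for f in freqs:
        if f not in table:
            raise ValueError(
                f"cannot average {conduction} thresholds: {f} Hz not measured "
                f"(subject {a.subject_id}, {a.ear})")
        values.append(table[f])
    return sum(values) / len(values)


@dataclass(frozen=True)
class GapProfile:
    """Per-frequency air−bone gaps at 500–4000 Hz and the derived presence flag.

    Negative gaps (bone worse than air, within QC tolerance) are carried but
    never count toward presence.
    """

    gaps: dict[int, float]
    present: bool


def air_bone_gaps(a: Audiogram, cfg: RuleConfig = DEFAULT_RULES) -> GapProfile:
    """Compute AC−BC per gap frequency and decide gap presence.

    Present iff at least ``gap_multi_min_count`` gaps reach
    ``gap_multi_threshold`` dB, or any single gap reaches
    ``gap_single_threshold`` dB (both inclusive).
    """
    gaps: dict[int, float] = {}
    for f in cfg.gap_freqs:
        if f not in a.ac or f not in a.bc:
            raise ValueError(
                f"air-bone gap needs both conductions at {f} Hz "
                f"(subject {a.subject_id}, {a.ear})")
        gaps[f] = a.ac[f] - a.bc[f]
    n_multi = sum(1 for g in gaps.values() if g >= cfg.gap_multi_threshold)
    present = n_multi >= cfg.gap_multi_min_count or \
        max(gaps.values()) >= cfg.gap_single_threshold
    return GapProfile(gaps=gaps, present=present)


def classify(a: Audiogram, cfg: RuleConfig = DEFAULT_RULES) -> HearingLossLabel:
    """Apply the diagnostic rule table to one complete audiogram.

    Requires the record to be complete (QC completeness); raises
    ``ValueError`` otherwise.
    """
    if not a.is_complete():
        raise ValueError(
            f"classify requires a complete audiogram (subject {a.subject_id}, {a.ear})")
    cut = cfg.pta_cutoff
    air_pta = mean_threshold(a, "air", cfg.gap_freqs)
    bone_pta = mean_threshold(a, "bone", cfg.gap_freqs)
    gap = air_bone_gaps(a, cfg).present

    if air_pta < cut and bone_pta < cut and not gap:
        return HearingLossLabel.NORMAL
    if air_pta >= cut and bone_pta < cut and gap:
        return HearingLossLabel.CONDUCTIVE
    if air_pta >= cut and bone_pta >= cut and gap:
        return HearingLossLabel.MIXED
    if air_pta >= cut and bone_pta >= cut and not gap:
        air_hf = mean_threshold(a, "air", cfg.air_hf_freqs)
        bone_hf = mean_threshold(a, "bone", cfg.bone_hf_freqs)
        if air_hf >= cut and bone_hf >= cut:
            return HearingLossLabel.SENSORINEURAL
    return HearingLossLabel.INDETERMINATE
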