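"""Seeded generator of labelled synthetic audiograms.

Clinical audiometry datasets are confidential, so experiments here run on
synthetic records drawn from a simple parametric family: a per-ear bone-level
curve (base level + slope per octave + per-frequency jitter) plus a
class-specific air–bone gap curve, both quantised to the 5-dB steps used in
clinical practice.  Class priors:

* **normal** — bone base ∈ [−5, 12] dB HL, gaps within 0–9 dB;
* **sensorineural** — bone base ∈ [25, 58] dB HL with a positive slope bias
  (losses typically worsen toward high frequencies), gaps within 0–9 dB;
* **conductive** — bone base ∈ [−5, 12] dB HL (normal cochlea), gaps 15–40 dB;
* **mixed** — bone base ∈ [25, 50] dB HL, gaps 15–40 dB.

The prior only shapes the curves; correctness is enforced by rejection
sampling against the diagnostic rule engine and the QC screen: every emitted
audiogram passes all five validity checks and is classified exactly as its
intended label.  Class membership of each record is drawn from configurable
proportions whose default matches a large clinical population (normal 17.17%,
conductive 4.37%, mixed 26.71%, sensorineural 51.69%).

A single owned random generator per call, seeded from the config, makes
generation fully reproducible; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AIR_FREQS,
    BONE_FREQS,
    CLINICAL_LABELS,
    Audiogram,
    AudiogramSet,
    HearingLossLabel,
)
from .qc import DEFAULT_QC, QcConfig, run_checks
from .rules import DEFAULT_RULES, RuleConfig, classify

__all__ = ["GeneratorConfig", "GenerationError", "sample_audiogram", "generate_dataset"]

#: Default class proportions (normal, conductive, mixed, sensorineural),
#: the exact class fractions of a 15,046-ear clinical population
#: (2584 / 657 / 4028 / 7777 ears ≈ 17.17 / 4.37 / 26.77 / 51.69 %).
DEFAULT_PROPORTIONS: tuple[float, float, float, float] = (
    2584 / 15046, 657 / 15046, 4028 / 15046, 7777 / 15046)


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot hit the target class."""


@dataclass(frozen=True)
class ClassPrior:
    """Curve prior for one diagnostic class (all dB HL / dB per octave)."""

    bone_base: tuple[float, float]
    slope: tuple[float, float]
    gap: tuple[float, float]


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 1000
    class_proportions: tuple[float, float, float, float] = DEFAULT_PROPORTIONS
    seed: int = 0
    #: per-frequency jitter of the bone-level curve (dB, Gaussian sd)
    jitter_sd: float = 2.5
    #: per-frequency jitter of the gap curve (dB, Gaussian sd)
    gap_jitter_sd: float = 2.0
    quantize_step: float = 5.0
    #: probability that the optional frequencies are measured
    p_air_125: float = 0.8
    p_bone_250: float = 0.5
    max_attempts: int = 1000
    priors: dict[HearingLossLabel, ClassPrior] = field(default_factory=lambda: {
        HearingLossLabel.NORMAL: ClassPrior(bone_base=(-5.0, 12.0), slope=(-1.0, 2.0), gap=(0.0, 7.0)),
        HearingLossLabel.SENSORINEURAL: ClassPrior(bone_base=(25.0, 58.0), slope=(0.0, 5.0), gap=(0.0, 7.0)),
        HearingLossLabel.CONDUCTIVE: ClassPrior(bone_base=(-5.0, 12.0), slope=(-1.0, 2.0), gap=(15.0, 40.0)),
        HearingLossLabel.MIXED: ClassPrior(bone_base=(25.0, 50.0), slope=(-1.0, 4.0), gap=(15.0, 40.0)),
    })

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (4,) or (p < 0).any():
            raise ValueError("class_proportions must be 4 nonnegative numbers")
        if abs(float(p.sum()) - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {p.sum()!r}")
        if self.n < 0:
            raise ValueError("n must be nonnegative")


_N_OCT = len(AIR_FREQS)
_CENTER_OCTAVE = AIR_FREQS.index(1000)
_BONE_IDX = [AIR_FREQS.index(f) for f in BONE_FREQS]


def _quantize(x: np.ndarray, step: float) -> np.ndarray:
    return np.round(x / step) * step


def _air_ceiling(cfg_qc: QcConfig) -> np.ndarray:
    return np.array([
        cfg_qc.air_max_low_freq if (f <= cfg_qc.low_freq_cutoff) == cfg_qc.low_freq_limit_at_or_below
        else cfg_qc.air_max
        for f in AIR_FREQS
    ])


def _bone_ceiling(cfg_qc: QcConfig) -> np.ndarray:
    return np.array([
        cfg_qc.bone_max_low_freq if (f <= cfg_qc.low_freq_cutoff) == cfg_qc.low_freq_limit_at_or_below
        else cfg_qc.bone_max
        for f in BONE_FREQS
    ])


def sample_audiogram(
    target: HearingLossLabel,
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
    subject_id: str = "syn",
    qc_cfg: QcConfig = DEFAULT_QC,
    rule_cfg: RuleConfig = DEFAULT_RULES,
) -> Audiogram:
    """Draw one QC-valid audiogram that the rule engine labels *target*.

    Rejection sampling: draw from the class prior, quantise, clip to the
    instrument limits, then verify against the QC checks and the classifier;
    retry up to ``cfg.max_attempts`` times.
    """
    if target not in CLINICAL_LABELS:
        raise ValueError(f"target must be one of the four clinical classes, got {target}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    prior = cfg.priors[target]
    step = cfg.quantize_step
    air_hi = _air_ceiling(qc_cfg)
    bone_hi = _bone_ceiling(qc_cfg)
    octaves = np.arange(_N_OCT) - _CENTER_OCTAVE

    for _ in range(cfg.max_attempts):
        base = rng.uniform(*prior.bone_base)
        slope = rng.uniform(*prior.slope)
        bone_curve = base + slope * octaves + rng.normal(0.0, cfg.jitter_sd, _N_OCT)
        gap_curve = rng.uniform(*prior.gap) + rng.normal(0.0, cfg.gap_jitter_sd, _N_OCT)
        gap_curve = np.clip(gap_curve, 0.0, qc_cfg.air_bone_bounds[1] - step)

        ac = np.clip(_quantize(bone_curve + gap_curve, step), qc_cfg.air_min, air_hi)
        bc = np.clip(_quantize(bone_curve[_BONE_IDX], step), qc_cfg.bone_min,
                     bone_hi)
        # keep the recorded gap inside the air-bone relation bounds
        bc = np.clip(bc, ac[_BONE_IDX] - qc_cfg.air_bone_bounds[1],
                     ac[_BONE_IDX] - qc_cfg.air_bone_bounds[0])

        ear = "left" if rng.random() < 0.5 else "right"
        ac_map = {f: float(ac[i]) for i, f in enumerate(AIR_FREQS)}
        if rng.random() >= cfg.p_air_125:
            del ac_map[125]
        bc_map = {f: float(bc[j]) for j, f in enumerate(BONE_FREQS)}
        if rng.random() >= cfg.p_bone_250:
            del bc_map[250]
        candidate = Audiogram(subject_id=subject_id, ear=ear, ac=ac_map, bc=bc_map)

        if run_checks(candidate, qc_cfg):
            continue
        if classify(candidate, rule_cfg) is target:
            return candidate
    raise GenerationError(
        f"could not generate a {target.value} audiogram within "
        f"{cfg.max_attempts} attempts (config: {cfg})")


def generate_dataset(
    cfg: GeneratorConfig,
    qc_cfg: QcConfig = DEFAULT_QC,
    rule_cfg: RuleConfig = DEFAULT_RULES,
) -> AudiogramSet:
    """Generate ``cfg.n`` labelled audiograms, classes drawn from
    ``cfg.class_proportions`` (multinomial, seeded).

    Every record passes QC and its attached label equals the rule engine's
    classification; the whole set is reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    class_idx = rng.choice(4, size=cfg.n, p=np.asarray(cfg.class_proportions, dtype=float))
    records: list[Audiogram] = []
    labels: list[HearingLossLabel] = []
    for i, c in enumerate(class_idx):
        target = CLINICAL_LABELS[int(c)]
        records.append(sample_audiogram(
            target, cfg, rng, subject_id=f"syn-{i:06d}",
            qc_cfg=qc_cfg, rule_cfg=rule_cfg))
        labels.append(target)
    return AudiogramSet(records, labels)
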