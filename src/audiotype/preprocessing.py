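"""Feature-sequence encoding, feature scaling, and class-imbalance weights.

An audiogram becomes a 7-step sequence ordered by the air-conduction octave
grid (125 → 8000 Hz); each step carries two features — the air and bone
thresholds at that frequency — plus a bone-presence flag.  Bone is never
measured at 125 and 8000 Hz and optionally at 250 Hz, so those steps carry an
absent bone value; the numeric fill (0, the channel centre after z-scoring)
is applied only *after* normalisation, so absent values never contaminate the
fitted statistics.

Four scaling methods are provided, all fitted on training data only and per
channel by default:

* ``zscore``   — (x − μ) / σ with population (ddof=0) σ;
* ``minmax``   — (x − min) / (max − min), the linear/max–min scaler;
* ``robust``   — (x − median) / IQR, quartiles by linear interpolation;
* ``maxabs``   — x / max|x|.

Class weights for imbalance correction use the balanced heuristic
w_c = N / (K·n_c): misclassifying a minority class is penalised in inverse
proportion to its frequency, and Σ_c n_c·w_c = N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AIR_FREQS, CLINICAL_LABELS, Audiogram, HearingLossLabel

__all__ = [
    "FeatureSequence",
    "NormalizerParams",
    "ClassWeights",
    "encode_sequence",
    "encode_set",
    "fit_normalizer",
    "apply_normalizer",
    "compute_class_weights",
    "NORMALIZATION_METHODS",
]

NORMALIZATION_METHODS = ("zscore", "minmax", "robust", "maxabs")


@dataclass(frozen=True)
class FeatureSequence:
    """7-step × 2-channel encoding of one audiogram.

    ``air``/``bone`` are float arrays of length 7 in air-grid order;
    ``bone_present`` marks which bone entries were measured (entries with a
    False flag hold NaN until filled by :func:`apply_normalizer`).
    """

    air: np.ndarray
    bone: np.ndarray
    bone_present: np.ndarray

    def __post_init__(self) -> None:
        for name in ("air", "bone", "bone_present"):
            if getattr(self, name).shape != (7,):
                raise ValueError(f"{name} must have shape (7,)")


def encode_sequence(a: Audiogram) -> FeatureSequence:
    """Encode a complete audiogram; absent bone steps get NaN + False flag."""
    if not a.is_complete():
        raise ValueError(
            f"encode_sequence requires a complete audiogram "
            f"(subject {a.subject_id}, {a.ear})")
    air = np.array([a.ac.get(f, np.nan) for f in AIR_FREQS], dtype=float)
    # optional 125 Hz air: fall back to the adjacent octave so the air channel
    # is always fully numeric (only bone carries an absence flag)
    if np.isnan(air[0]):
        air[0] = air[1]
    bone = np.full(7, np.nan)
    present = np.zeros(7, dtype=bool)
    for i, f in enumerate(AIR_FREQS):
        if f in a.bc:
            bone[i] = a.bc[f]
            present[i] = True
    return FeatureSequence(air=air, bone=bone, bone_present=present)


def encode_set(records) -> list[FeatureSequence]:
    return [encode_sequence(a) for a in records]


@dataclass(frozen=True)
class NormalizerParams:
    """Fitted per-channel location/scale for one scaling method.

    ``center``/``scale`` have one entry per channel (air, bone), or a single
    shared entry when fitted pooled.
    """

    method: str
    center: np.ndarray
    scale: np.ndarray
    pooled: bool = False


def _center_scale(values: np.ndarray, method: str) -> tuple[float, float]:
    if method == "zscore":
        return float(values.mean()), float(values.std(ddof=0))
    if method == "minmax":
        lo, hi = float(values.min()), float(values.max())
        return lo, hi - lo
    if method == "robust":
        q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
        return float(med), float(q3 - q1)
    if method == "maxabs":
        return 0.0, float(np.abs(values).max())
    raise ValueError(f"unknown normalization method {method!r}")


def fit_normalizer(
    train: list[FeatureSequence],
    method: str = "zscore",
    pooled: bool = False,
    on_zero_scale: str = "error",
) -> NormalizerParams:
    """Fit scaling statistics on training sequences only.

    Statistics use observed values only: the full air channel and the
    flagged-present bone entries.  ``on_zero_scale`` controls degenerate
    (constant) channels: ``"error"`` raises, ``"unit"`` substitutes scale 1.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training sequences to fit a normalizer")
    air_vals = np.concatenate([s.air for s in train])
    bone_vals = np.concatenate([s.bone[s.bone_present] for s in train])
    if bone_vals.size == 0:
        raise ValueError("no observed bone values in training data")
    if pooled:
        c, s = _center_scale(np.concatenate([air_vals, bone_vals]), method)
        centers, scales = [c], [s]
    else:
        ca, sa = _center_scale(air_vals, method)
        cb, sb = _center_scale(bone_vals, method)
        centers, scales = [ca, cb], [sa, sb]
    for i, s in enumerate(scales):
        if s == 0.0:
            if on_zero_scale == "unit":
                scales[i] = 1.0
            else:
                raise ValueError(
                    f"degenerate (constant) channel {i} under {method!r}: scale is 0")
    return NormalizerParams(method=method, center=np.asarray(centers, dtype=float),
                            scale=np.asarray(scales, dtype=float), pooled=pooled)


def apply_normalizer(params: NormalizerParams, seq: FeatureSequence) -> FeatureSequence:
    """Transform one sequence; absent bone entries become 0 after scaling
    (the channel centre under z-scoring).  Flags are preserved."""
    ia, ib = (0, 0) if params.pooled else (0, 1)
    air = (seq.air - params.center[ia]) / params.scale[ia]
    bone = np.where(
        seq.bone_present,
        (np.where(seq.bone_present, seq.bone, 0.0) - params.center[ib]) / params.scale[ib],
        0.0,
    )
    return FeatureSequence(air=air, bone=bone, bone_present=seq.bone_present.copy())


def sequences_to_array(
    seqs: list[FeatureSequence], with_mask: bool = False
) -> np.ndarray:
    """Stack sequences into an (n, 7, 2) array — (n, 7, 3) with the
    bone-presence mask as a third channel."""
    n = len(seqs)
    k = 3 if with_mask else 2
    out = np.empty((n, 7, k))
    for i, s in enumerate(seqs):
        out[i, :, 0] = s.air
        out[i, :, 1] = s.bone
        if with_mask:
            out[i, :, 2] = s.bone_present.astype(float)
    return out


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights, keyed in the fixed clinical class order."""

    weights: dict[HearingLossLabel, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.weights[c] for c in CLINICAL_LABELS])


def compute_class_weights(
    labels, n_classes: int | None = None
) -> ClassWeights:
    """Balanced weights w_c = N / (K·n_c) over the clinical classes present
    in *labels*.  Raises if any of the K classes is unrepresented."""
    labels = list(labels)
    classes = CLINICAL_LABELS[:n_classes] if n_classes else CLINICAL_LABELS
    counts = {c: 0 for c in classes}
    for lab in labels:
        if lab not in counts:
            raise ValueError(f"label {lab} outside the clinical classes {classes}")
        counts[lab] += 1
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"cannot weight empty class(es): {[str(c) for c in empty]}")
    n_total = len(labels)
    k = len(classes)
    return ClassWeights({c: n_total / (k * n) for c, n in counts.items()})
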