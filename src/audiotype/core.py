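"""Domain types and file IO for pure-tone audiometry records.

A pure-tone audiometry test measures, for one ear, the softest audible level
(in dB HL) of pure tones at octave frequencies, separately for air conduction
(AC, via headphones, through the whole auditory pathway) and bone conduction
(BC, via a skull vibrator, bypassing the outer/middle ear).  The AC grid spans
125–8000 Hz (seven octaves); BC is not measured at the two extreme
frequencies, so its grid spans 250–4000 Hz (five octaves).

Records are exchanged as flat CSV (one row per ear), JSON-lines (one object
per record), or a minimal XML dialect of per-point tonal records::

    <audiometry>
      <ear subject_id="p001" side="left">
        <tonal_point conduction="air" frequency="1000" level="20" masked="false"/>
        ...
      </ear>
    </audiometry>

All readers preserve thresholds exactly and never substitute values for
missing optional frequencies.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.etree import ElementTree

import pandas as pd

__all__ = [
    "AIR_FREQS",
    "BONE_FREQS",
    "PTA_FREQS",
    "AIR_HF_FREQS",
    "BONE_HF_FREQS",
    "REQUIRED_AIR_FREQS",
    "REQUIRED_BONE_FREQS",
    "FrequencyGrid",
    "HearingLossLabel",
    "CLINICAL_LABELS",
    "Audiogram",
    "AudiogramSet",
    "AudiometryParseError",
    "read_audiograms",
    "write_audiograms",
]

#: Octave frequencies (Hz) tested by air conduction, in measurement order.
AIR_FREQS: tuple[int, ...] = (125, 250, 500, 1000, 2000, 4000, 8000)
#: Octave frequencies (Hz) tested by bone conduction (extremes not measured).
BONE_FREQS: tuple[int, ...] = (250, 500, 1000, 2000, 4000)
#: Frequencies entering the four-frequency pure-tone average (PTA4).
PTA_FREQS: tuple[int, ...] = (500, 1000, 2000, 4000)
#: High-frequency air average frequencies (grid octaves within 4–8 kHz).
AIR_HF_FREQS: tuple[int, ...] = (4000, 8000)
#: High-frequency bone average frequencies (grid octaves within 4–6 kHz).
BONE_HF_FREQS: tuple[int, ...] = (4000,)

#: Air frequencies whose presence is mandatory for a complete record
#: (125 Hz is optional).
REQUIRED_AIR_FREQS: tuple[int, ...] = (250, 500, 1000, 2000, 4000, 8000)
#: Bone frequencies whose presence is mandatory (250 Hz is optional).
REQUIRED_BONE_FREQS: tuple[int, ...] = (500, 1000, 2000, 4000)


@dataclass(frozen=True)
class FrequencyGrid:
    """The frequency grids of the measurement protocol.

    Exposed as a type so alternative protocols can be described, but all
    shipped operations default to the standard octave grids above.
    """

    air_freqs: tuple[int, ...] = AIR_FREQS
    bone_freqs: tuple[int, ...] = BONE_FREQS
    pta_freqs: tuple[int, ...] = PTA_FREQS
    air_hf_freqs: tuple[int, ...] = AIR_HF_FREQS
    bone_hf_freqs: tuple[int, ...] = BONE_HF_FREQS

    def __post_init__(self) -> None:
        for name in ("air_freqs", "bone_freqs", "pta_freqs"):
            seq = getattr(self, name)
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError(f"{name} must be strictly increasing: {seq}")
        if len(self.air_freqs) != 7:
            raise ValueError("air grid must have exactly 7 octave frequencies")
        if len(self.bone_freqs) != 5:
            raise ValueError("bone grid must have exactly 5 octave frequencies")
        common = set(self.air_freqs) & set(self.bone_freqs)
        if not set(self.pta_freqs) <= common:
            raise ValueError("pta_freqs must lie on both conduction grids")


DEFAULT_GRID = FrequencyGrid()


class HearingLossLabel(enum.Enum):
    """Diagnostic class of one ear's audiometry result.

    ``INDETERMINATE`` marks threshold combinations matched by none of the four
    clinical rule rows; it never enters training sets.
    """

    NORMAL = "normal"
    CONDUCTIVE = "conductive"
    MIXED = "mixed"
    SENSORINEURAL = "sensorineural"
    INDETERMINATE = "indeterminate"

    def __str__(self) -> str:  # serialization-friendly
        return self.value


#: Fixed class order used everywhere (confusion matrices, model outputs,
#: tie-breaking): normal, conductive, mixed, sensorineural.
CLINICAL_LABELS: tuple[HearingLossLabel, ...] = (
    HearingLossLabel.NORMAL,
    HearingLossLabel.CONDUCTIVE,
    HearingLossLabel.MIXED,
    HearingLossLabel.SENSORINEURAL,
)


class AudiometryParseError(ValueError):
    """Raised when an input file does not conform to its documented schema."""


_ABSENT = object()


@dataclass
class Audiogram:
    """One ear's air/bone threshold maps over the octave grids.

    Thresholds are stored exactly as read (plain numbers, typically multiples
    of 5 dB); frequencies that were not measured are simply absent from the
    maps — never filled with a default.
    """

    subject_id: str
    ear: str  # "left" | "right"
    ac: dict[int, float] = field(default_factory=dict)
    bc: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ear not in ("left", "right"):
            raise ValueError(f"ear must be 'left' or 'right', got {self.ear!r}")
        bad_air = set(self.ac) - set(AIR_FREQS)
        bad_bone = set(self.bc) - set(BONE_FREQS)
        if bad_air:
            raise ValueError(f"air thresholds at off-grid frequencies: {sorted(bad_air)}")
        if bad_bone:
            raise ValueError(f"bone thresholds at off-grid frequencies: {sorted(bad_bone)}")
        for freq, level in list(self.ac.items()) + list(self.bc.items()):
            if not math.isfinite(level):
                raise ValueError(f"non-finite threshold {level!r} at {freq} Hz")

    # -- accessors ---------------------------------------------------------

    def get_threshold(self, conduction: str, freq: int, default=_ABSENT):
        """Stored threshold for (conduction, freq), or *default* if unmeasured.

        Raises ``KeyError`` for a frequency that is not on the requested
        conduction's grid (e.g. bone at 8000 Hz, which is never measured),
        and — when no *default* is given — for an on-grid frequency that this
        record lacks.
        """
        if conduction == "air":
            grid, table = AIR_FREQS, self.ac
        elif conduction == "bone":
            grid, table = BONE_FREQS, self.bc
        else:
            raise ValueError(f"conduction must be 'air' or 'bone', got {conduction!r}")
        if freq not in grid:
            raise KeyError(f"{freq} Hz is not on the {conduction}-conduction grid")
        if freq in table:
            return table[freq]
        if default is _ABSENT:
            raise KeyError(f"{conduction} threshold at {freq} Hz not measured for this record")
        return default

    def has(self, conduction: str, freq: int) -> bool:
        table = self.ac if conduction == "air" else self.bc
        return freq in table

    def is_complete(self) -> bool:
        """True when all mandatory frequencies are present (optional ones may
        be missing: 125 Hz air, 250 Hz bone)."""
        return set(REQUIRED_AIR_FREQS) <= set(self.ac) and set(REQUIRED_BONE_FREQS) <= set(self.bc)


def get_threshold(a: Audiogram, conduction: str, freq: int, default=_ABSENT):
    """Functional alias for :meth:`Audiogram.get_threshold`."""
    return a.get_threshold(conduction, freq, default)


@dataclass
class AudiogramSet:
    """An ordered collection of audiograms with optional parallel labels."""

    records: list[Audiogram] = field(default_factory=list)
    labels: list[HearingLossLabel] | None = None

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.records):
            raise ValueError(
                f"labels length {len(self.labels)} != records length {len(self.records)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, indices: Sequence[int]) -> "AudiogramSet":
        recs = [self.records[i] for i in indices]
        labs = [self.labels[i] for i in indices] if self.labels is not None else None
        return AudiogramSet(recs, labs)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_CSV_AIR_COLS = [f"ac_{f}" for f in AIR_FREQS]
_CSV_BONE_COLS = [f"bc_{f}" for f in BONE_FREQS]
_CSV_COLS = ["subject_id", "ear", *_CSV_AIR_COLS, *_CSV_BONE_COLS]


def _format_level(x: float) -> str:
    # plain decimal; integers without trailing ".0"
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _record_to_row(a: Audiogram) -> dict[str, object]:
    row: dict[str, object] = {"subject_id": a.subject_id, "ear": a.ear}
    for f in AIR_FREQS:
        row[f"ac_{f}"] = a.ac.get(f)
    for f in BONE_FREQS:
        row[f"bc_{f}"] = a.bc.get(f)
    return row


def write_audiograms(aset: AudiogramSet, path: str | Path, format: str = "csv") -> None:
    """Write an :class:`AudiogramSet` to *path* as ``csv``, ``jsonl`` or ``xml``.

    The written file round-trips losslessly through :func:`read_audiograms`
    (thresholds, ids, ears and labels all preserved exactly).
    """
    if len(aset) == 0:
        raise ValueError("refusing to write an empty AudiogramSet")
    path = Path(path)
    if format == "csv":
        rows = []
        for i, a in enumerate(aset.records):
            row = _record_to_row(a)
            if aset.labels is not None:
                row["label"] = str(aset.labels[i])
            rows.append(row)
        cols = _CSV_COLS + (["label"] if aset.labels is not None else [])
        df = pd.DataFrame(rows, columns=cols)
        df.to_csv(path, index=False)
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for i, a in enumerate(aset.records):
                obj: dict[str, object] = {
                    "subject_id": a.subject_id,
                    "ear": a.ear,
                    "ac": {str(f): a.ac[f] for f in AIR_FREQS if f in a.ac},
                    "bc": {str(f): a.bc[f] for f in BONE_FREQS if f in a.bc},
                }
                if aset.labels is not None:
                    obj["label"] = str(aset.labels[i])
                fh.write(json.dumps(obj) + "\n")
    elif format == "xml":
        root = ElementTree.Element("audiometry")
        for i, a in enumerate(aset.records):
            ear = ElementTree.SubElement(root, "ear", subject_id=a.subject_id, side=a.ear)
            if aset.labels is not None:
                ear.set("label", str(aset.labels[i]))
            for f in AIR_FREQS:
                if f in a.ac:
                    ElementTree.SubElement(
                        ear, "tonal_point", conduction="air",
                        frequency=str(f), level=_format_level(a.ac[f]), masked="false",
                    )
            for f in BONE_FREQS:
                if f in a.bc:
                    ElementTree.SubElement(
                        ear, "tonal_point", conduction="bone",
                        frequency=str(f), level=_format_level(a.bc[f]), masked="true",
                    )
        tree = ElementTree.ElementTree(root)
        ElementTree.indent(tree)
        tree.write(path, encoding="unicode", xml_declaration=True)
    else:
        raise ValueError(f"unknown format {format!r} (expected csv, jsonl or xml)")


def _parse_label(text: object) -> HearingLossLabel:
    try:
        return HearingLossLabel(str(text))
    except ValueError as exc:
        raise AudiometryParseError(f"unknown label {text!r}") from exc


def _read_csv(path: Path) -> AudiogramSet:
    try:
        df = pd.read_csv(path, dtype={"subject_id": str, "ear": str})
    except pd.errors.EmptyDataError as exc:
        raise AudiometryParseError(f"{path}: empty file") from exc
    missing = [c for c in ("subject_id", "ear") if c not in df.columns]
    if missing:
        raise AudiometryParseError(f"{path}: missing required columns {missing}")
    records: list[Audiogram] = []
    labels: list[HearingLossLabel] = []
    has_label = "label" in df.columns
    for idx, row in df.iterrows():
        ac = {}
        for f in AIR_FREQS:
            col = f"ac_{f}"
            if col in df.columns and pd.notna(row[col]):
                ac[f] = float(row[col])
        bc = {}
        for f in BONE_FREQS:
            col = f"bc_{f}"
            if col in df.columns and pd.notna(row[col]):
                bc[f] = float(row[col])
        try:
            records.append(Audiogram(str(row["subject_id"]), str(row["ear"]), ac, bc))
        except ValueError as exc:
            raise AudiometryParseError(f"{path}: row {idx}: {exc}") from exc
        if has_label:
            labels.append(_parse_label(row["label"]))
    return AudiogramSet(records, labels if has_label else None)


def _read_jsonl(path: Path) -> AudiogramSet:
    records: list[Audiogram] = []
    labels: list[HearingLossLabel] = []
    saw_label = False
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise AudiometryParseError(f"{path}: empty file")
    for lineno, line in enumerate(lines, start=1):
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise AudiometryParseError(f"{path}: line {lineno}: invalid JSON: {exc}") from exc
        try:
            ac = {int(k): float(v) for k, v in obj.get("ac", {}).items()}
            bc = {int(k): float(v) for k, v in obj.get("bc", {}).items()}
            records.append(Audiogram(str(obj["subject_id"]), str(obj["ear"]), ac, bc))
        except (KeyError, ValueError, TypeError) as exc:
            raise AudiometryParseError(f"{path}: line {lineno}: {exc}") from exc
        if "label" in obj:
            saw_label = True
            labels.append(_parse_label(obj["label"]))
        elif saw_label:
            raise AudiometryParseError(f"{path}: line {lineno}: label present on some records only")
    return AudiogramSet(records, labels if saw_label else None)


def _read_xml(path: Path) -> AudiogramSet:
    try:
        tree = ElementTree.parse(path)
    except ElementTree.ParseError as exc:
        raise AudiometryParseError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "audiometry":
        raise AudiometryParseError(f"{path}: root element must be <audiometry>, got <{root.tag}>")
    records: list[Audiogram] = []
    labels: list[HearingLossLabel] = []
    saw_label = False
    for ear_el in root.findall("ear"):
        sid = ear_el.get("subject_id")
        side = ear_el.get("side")
        if sid is None or side is None:
            raise AudiometryParseError(f"{path}: <ear> missing subject_id/side attributes")
        # (masked, unmasked) candidates per (conduction, frequency)
        points: dict[tuple[str, int], dict[bool, float]] = {}
        for pt in ear_el.findall("tonal_point"):
            try:
                conduction = pt.attrib["conduction"]
                freq = int(pt.attrib["frequency"])
                level = float(pt.attrib["level"])
            except (KeyError, ValueError) as exc:
                raise AudiometryParseError(
                    f"{path}: subject {sid} {side}: bad <tonal_point> {pt.attrib}: {exc}"
                ) from exc
            if conduction not in ("air", "bone"):
                raise AudiometryParseError(
                    f"{path}: subject {sid} {side}: conduction must be air|bone, got {conduction!r}"
                )
            masked = pt.get("masked", "false").lower() == "true"
            slot = points.setdefault((conduction, freq), {})
            if masked in slot:
                raise AudiometryParseError(
                    f"{path}: subject {sid} {side}: duplicate "
                    f"{'masked' if masked else 'unmasked'} {conduction} point at {freq} Hz"
                )
            slot[masked] = level
        ac: dict[int, float] = {}
        bc: dict[int, float] = {}
        for (conduction, freq), slot in points.items():
            # masking precedence: a masked bone threshold supersedes an
            # unmasked one at the same frequency (the masked value reflects
            # the test ear alone); for air the unmasked point is kept.
            if len(slot) == 2:
                level = slot[True] if conduction == "bone" else slot[False]
            else:
                level = next(iter(slot.values()))
            (ac if conduction == "air" else bc)[freq] = level
        try:
            records.append(Audiogram(str(sid), str(side), ac, bc))
        except ValueError as exc:
            raise AudiometryParseError(f"{path}: subject {sid} {side}: {exc}") from exc
        if ear_el.get("label") is not None:
            saw_label = True
            labels.append(_parse_label(ear_el.get("label")))
        elif saw_label:
            raise AudiometryParseError(f"{path}: label present on some <ear> elements only")
    if not records:
        raise AudiometryParseError(f"{path}: no <ear> records found")
    return AudiogramSet(records, labels if saw_label else None)


def read_audiograms(path: str | Path, format: str | None = None) -> AudiogramSet:
    """Read audiograms from *path* (``csv``, ``jsonl`` or ``xml``).

    When *format* is None it is inferred from the file suffix.  Raises
    :class:`AudiometryParseError` on malformed input, naming the offending
    line or element.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".jsonl": "jsonl", ".xml": "xml"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path}")
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise AudiometryParseError(f"{path}: empty file")
    if format == "csv":
        return _read_csv(path)
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "xml":
        return _read_xml(path)
    raise ValueError(f"unknown format {format!r} (expected csv, jsonl or xml)")
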