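"""Acquisition descriptors for the relaxometry protocol.

A :class:`SequenceParams` records everything a signal model needs to know
about one pulse sequence: repetition time, echo time(s), effective inversion
time, nominal flip angle and — for inversion-prepared gradient-echo readouts —
the pulse-train geometry (echo spacing, train length, and which pulse in the
train acquires the centre of k-space).

All times are stored in seconds.  Dictionaries / YAML configs may give any
time field in milliseconds by suffixing the key with ``_ms``
(e.g. ``tr_ms: 1190``).

The module ships the 3-T protocol presets used throughout the package
(:data:`PROTOCOL_PRESETS`): two IR-sGRE scans, three variable-flip-angle sGRE
scans, an 8-echo ME-sGRE scan for R2*, and the single-slice IRSE
gold-standard series used for phantom validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "SequenceKind",
    "SequenceParams",
    "PROTOCOL_PRESETS",
    "load_presets",
    "get_preset",
]


class SequenceKind(str, Enum):
    """Pulse-sequence families supported by the signal models."""

    SGRE = "sGRE"
    IR_SGRE = "IR-sGRE"
    ME_SGRE = "ME-sGRE"
    IR_SE = "IR-SE"


@dataclass(frozen=True)
class SequenceParams:
    """Parameters of one acquisition.

    Parameters
    ----------
    kind:
        Sequence family (spoiled gradient echo, inversion-prepared spoiled
        gradient echo, multi-echo spoiled gradient echo or inversion-recovery
        spin echo).
    tr:
        Repetition time in seconds.  For IR-prepared sequences this is the
        time between successive inversion pulses.
    te_list:
        Echo time(s) in seconds; a single entry for sGRE / IR-sGRE / IR-SE.
    ti_eff:
        Effective inversion time in seconds: time from the inversion pulse to
        the excitation acquiring the central k-space line (IR sequences only).
    flip_deg:
        Nominal excitation flip angle β in degrees.
    echo_spacing:
        Spacing τ between readout-train pulses in seconds (IR-sGRE only).
    train_length:
        Number N of excitation pulses per readout train (IR-sGRE only).
    readout_index:
        1-based index of the pulse acquiring the k-space centre.  Defaults to
        the train midpoint ``ceil(N/2)``, matching linear slice-direction
        ordering with the centre line in the middle of the train.
    name:
        Optional label (used by presets and provenance records).
    """

    kind: SequenceKind
    tr: float
    te_list: tuple[float, ...] = (0.0,)
    ti_eff: float | None = None
    flip_deg: float = 90.0
    echo_spacing: float | None = None
    train_length: int | None = None
    readout_index: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", SequenceKind(self.kind))
        object.__setattr__(self, "te_list", tuple(float(t) for t in self.te_list))
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if len(self.te_list) < 1:
            raise ValueError("te_list must contain at least one echo time")
        if any(te < 0 or te >= self.tr for te in self.te_list):
            raise ValueError("echo times must satisfy 0 <= te < tr")
        if self.kind in (SequenceKind.IR_SGRE, SequenceKind.IR_SE):
            if self.ti_eff is None:
                raise ValueError(f"{self.kind.value} requires ti_eff")
            if not 0 < self.ti_eff < self.tr:
                raise ValueError("ti_eff must satisfy 0 < ti_eff < tr")
        if self.kind is SequenceKind.IR_SGRE:
            if self.echo_spacing is None or self.train_length is None:
                raise ValueError("IR-sGRE requires echo_spacing and train_length")
            if self.echo_spacing <= 0:
                raise ValueError("echo_spacing must be positive")
            if self.train_length < 1:
                raise ValueError("train_length must be >= 1")
            if self.readout_index is None:
                object.__setattr__(
                    self, "readout_index", math.ceil(self.train_length / 2)
                )
            if not 1 <= self.readout_index <= self.train_length:
                raise ValueError("readout_index must lie in [1, train_length]")

    # -- derived timing ---------------------------------------------------
    @property
    def te(self) -> float:
        """First (or only) echo time in seconds."""
        return self.te_list[0]

    @property
    def flip_rad(self) -> float:
        return math.radians(self.flip_deg)

    @property
    def inversion_to_train(self) -> float:
        """Delay from the inversion pulse to the first train pulse (seconds).

        Derived from ``ti_eff`` and the readout index: the centre-line pulse
        fires ``(readout_index - 1) * echo_spacing`` after the train starts.
        """
        if self.kind is not SequenceKind.IR_SGRE:
            raise ValueError("inversion_to_train is defined for IR-sGRE only")
        t1 = self.ti_eff - (self.readout_index - 1) * self.echo_spacing
        if t1 <= 0:
            raise ValueError(
                "ti_eff is too short for the given train geometry "
                f"(inversion-to-train delay = {t1:.4g} s)"
            )
        return t1

    @property
    def post_train_delay(self) -> float:
        """Free-relaxation time from the last train pulse to the next inversion."""
        td = self.tr - self.inversion_to_train - (self.train_length - 1) * self.echo_spacing
        if td < 0:
            raise ValueError(
                f"train does not fit within tr (post-train delay = {td:.4g} s)"
            )
        return td

    # -- construction helpers ---------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "SequenceParams":
        """Build from a plain dict; ``*_ms`` keys are converted to seconds."""
        out: dict = {}
        for key, val in d.items():
            if key.endswith("_ms"):
                base = key[:-3]
                if base == "te_list":
                    out[base] = tuple(v / 1000.0 for v in val)
                else:
                    out[base] = val / 1000.0
            else:
                out[key] = tuple(val) if key == "te_list" else val
        return cls(**out)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind.value,
            "tr": self.tr,
            "te_list": list(self.te_list),
            "flip_deg": self.flip_deg,
            "name": self.name,
        }
        if self.ti_eff is not None:
            d["ti_eff"] = self.ti_eff
        if self.kind is SequenceKind.IR_SGRE:
            d["echo_spacing"] = self.echo_spacing
            d["train_length"] = self.train_length
            d["readout_index"] = self.readout_index
        return d

    def with_ti(self, ti_eff: float) -> "SequenceParams":
        return replace(self, ti_eff=ti_eff)


# Train length for the 3D IR-sGRE readout: 72 slice encodes with 11.1% slice
# oversampling, 72 * 1.111 -> 80 pulses per train.
_IR_TRAIN_LENGTH = 80
_IR_ECHO_SPACING = 4.5e-3

PROTOCOL_PRESETS: dict[str, SequenceParams] = {
    "ir_sgre_a": SequenceParams(
        kind=SequenceKind.IR_SGRE, tr=1.190, te_list=(2.3e-3,), ti_eff=1.000,
        flip_deg=5.0, echo_spacing=_IR_ECHO_SPACING, train_length=_IR_TRAIN_LENGTH,
        name="ir_sgre_a",
    ),
    "ir_sgre_b": SequenceParams(
        kind=SequenceKind.IR_SGRE, tr=0.632, te_list=(2.3e-3,), ti_eff=0.450,
        flip_deg=5.0, echo_spacing=_IR_ECHO_SPACING, train_length=_IR_TRAIN_LENGTH,
        name="ir_sgre_b",
    ),
    "sgre_fa12": SequenceParams(
        kind=SequenceKind.SGRE, tr=5.7e-3, te_list=(2.5e-3,), flip_deg=12.0,
        name="sgre_fa12",
    ),
    "sgre_fa5": SequenceParams(
        kind=SequenceKind.SGRE, tr=5.7e-3, te_list=(2.5e-3,), flip_deg=5.0,
        name="sgre_fa5",
    ),
    "sgre_fa3": SequenceParams(
        kind=SequenceKind.SGRE, tr=5.7e-3, te_list=(2.5e-3,), flip_deg=3.0,
        name="sgre_fa3",
    ),
    "me_sgre": SequenceParams(
        kind=SequenceKind.ME_SGRE, tr=50e-3,
        te_list=(4.6e-3, 8.5e-3, 14.0e-3, 19.5e-3, 25.0e-3, 30.5e-3, 36.0e-3, 41.5e-3),
        flip_deg=15.0, name="me_sgre",
    ),
    "irse": SequenceParams(
        kind=SequenceKind.IR_SE, tr=1.550, te_list=(11e-3,), ti_eff=0.030,
        flip_deg=90.0, name="irse",
    ),
}

# Inversion times of the gold-standard IRSE series (seconds).
IRSE_TI_LIST: tuple[float, ...] = (0.030, 0.330, 0.730, 1.130, 1.530)

#: Sequence names forming the DESPOT1-HIFI protocol (3 sGRE + 2 IR-sGRE).
HIFI_PROTOCOL: tuple[str, ...] = (
    "sgre_fa12", "sgre_fa5", "sgre_fa3", "ir_sgre_a", "ir_sgre_b",
)


def irse_series(ti_list: Sequence[float] = IRSE_TI_LIST) -> list[SequenceParams]:
    """The IRSE gold-standard acquisitions, one per inversion time."""
    return [PROTOCOL_PRESETS["irse"].with_ti(ti) for ti in ti_list]


def hifi_protocol() -> list[SequenceParams]:
    """The five DESPOT1-HIFI acquisitions in protocol order."""
    return [PROTOCOL_PRESETS[n] for n in HIFI_PROTOCOL]


def get_preset(name: str) -> SequenceParams:
    try:
        return PROTOCOL_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown sequence preset {name!r}; available: {sorted(PROTOCOL_PRESETS)}"
        ) from None


def load_presets(path: str | Path) -> dict[str, SequenceParams]:
    """Read sequence presets from a YAML mapping of name -> parameter dict."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        name: SequenceParams.from_dict({"name": name, **d}) for name, d in raw.items()
    }


def dump_presets(presets: dict[str, SequenceParams], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({n: p.to_dict() for n, p in presets.items()}, fh)
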