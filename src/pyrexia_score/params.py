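"""Algorithm parameters for pyrexia-score versions 1.0–5.0.

The defaults are the published version-5.0 variable values on the
normalized scale (100 = reference mean).  Field naming follows the
algorithm's variable names so that a serialized parameter file reads the
same as the published table:

* ``F1..F4`` / ``T1..T4`` — minimum-change ratio factors and absolute
  gates for the current sampling date t0 (order LEU, THR, LDH, CRP);
  ``F5..F8`` / ``T5..T8`` — the same for the preceding interval (t-1 vs
  t-2).
* ``FS1..FS8`` — weights of the eight binary change indicators (v ≥ 3).
* ``OA1..OA6`` — simultaneity multipliers for pairs of t0 indicators
  (LEU↓&THR↓, LEU↓&LDH↑, LEU↓&CRP↑, THR↓&LDH↑, THR↓&CRP↑, LDH↑&CRP↑),
  v ≥ 4.
* ``CT`` / ``GC`` — CRP gate: when CRP at t0 is below CT the score is
  multiplied by GC (v = 5).
* ``IC1..IC4`` / ``IM1..IM4`` — infection signature: minimum-rise factors
  and minimum absolute values, printed order LEU, CRP, THR, LDH; a
  positive signature multiplies the score by ``IS`` (v = 5).  ``IS``
  itself is not part of the published table; the default 0.1 matches the
  magnitude of GC (both are documented only as "much smaller than 1") and
  is configurable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class ParameterSet:
    # t0 block: change factors and absolute gates (LEU, THR, LDH, CRP)
    F1: float = 1.05
    T1: float = 100.0
    F2: float = 1.02
    T2: float = 90.0
    F3: float = 0.80
    T3: float = 80.0
    F4: float = 0.70
    T4: float = 800.0
    # t-1 block
    F5: float = 1.10
    T5: float = 120.0
    F6: float = 1.10
    T6: float = 90.0
    F7: float = 0.80
    T7: float = 80.0
    F8: float = 0.70
    T8: float = 500.0
    # indicator weights
    FS1: float = 1.69
    FS2: float = 3.24
    FS3: float = 2.25
    FS4: float = 2.25
    FS5: float = 1.44
    FS6: float = 4.84
    FS7: float = 2.25
    FS8: float = 1.44
    # simultaneity multipliers
    OA1: float = 2.0
    OA2: float = 1.4
    OA3: float = 1.2
    OA4: float = 1.4
    OA5: float = 1.0
    OA6: float = 1.1
    # CRP gate
    CT: float = 300.0
    GC: float = 0.1
    # infection signature (order LEU, CRP, THR, LDH)
    IC1: float = 0.90
    IM1: float = 100.0
    IC2: float = 0.90
    IM2: float = 200.0
    IC3: float = 0.90
    IM3: float = 100.0
    IC4: float = 0.90
    IM4: float = 120.0
    IS: float = 0.1
    version: int = 5
    #: which of the four rise conditions (LEU, CRP, THR, LDH) must hold for
    #: a positive infection signature; by default only the leukocyte and
    #: CRP rises are required, the thrombocyte/LDH conditions are
    #: evaluated and exposed but not part of the conjunction.
    infection_mask: tuple[bool, bool, bool, bool] = (True, True, False, False)

    def __post_init__(self) -> None:
        self.infection_mask = tuple(bool(b) for b in self.infection_mask)
        self.validate()

    def validate(self) -> None:
        if self.version not in (1, 2, 3, 4, 5):
            raise ValueError(f"version must be 1..5, got {self.version}")
        for name in _FAMILIES["F"] + _FAMILIES["IC"]:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in _FAMILIES["T"] + _FAMILIES["IM"] + _FAMILIES["FS"] + \
                _FAMILIES["OA"] + ("CT",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("GC", "IS"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if len(self.infection_mask) != 4:
            raise ValueError("infection_mask must have four entries")

    # -- grouped views -----------------------------------------------------
    @property
    def f_t0(self) -> tuple[float, ...]:
        return (self.F1, self.F2, self.F3, self.F4)

    @property
    def t_t0(self) -> tuple[float, ...]:
        return (self.T1, self.T2, self.T3, self.T4)

    @property
    def f_t1(self) -> tuple[float, ...]:
        return (self.F5, self.F6, self.F7, self.F8)

    @property
    def t_t1(self) -> tuple[float, ...]:
        return (self.T5, self.T6, self.T7, self.T8)

    @property
    def weights(self) -> tuple[float, ...]:
        return (self.FS1, self.FS2, self.FS3, self.FS4,
                self.FS5, self.FS6, self.FS7, self.FS8)

    @property
    def oa(self) -> tuple[float, ...]:
        return (self.OA1, self.OA2, self.OA3, self.OA4, self.OA5, self.OA6)

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["infection_mask"] = list(self.infection_mask)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


_FAMILIES: dict[str, tuple[str, ...]] = {
    "F": tuple(f"F{i}" for i in range(1, 9)),
    "T": tuple(f"T{i}" for i in range(1, 9)),
    "FS": tuple(f"FS{i}" for i in range(1, 9)),
    "OA": tuple(f"OA{i}" for i in range(1, 7)),
    "IC": tuple(f"IC{i}" for i in range(1, 5)),
    "IM": tuple(f"IM{i}" for i in range(1, 5)),
}

#: every tunable scalar, grouped by family (used by the optimizer).
PARAMETER_FAMILIES = {**_FAMILIES, "GC": ("GC",), "IS": ("IS",), "CT": ("CT",)}


def parameter_family(name: str) -> str:
    for family, names in PARAMETER_FAMILIES.items():
        if name in names:
            return family
    raise KeyError(f"unknown parameter: {name}")
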