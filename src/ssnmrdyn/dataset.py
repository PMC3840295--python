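"""Per-residue observation containers shared by the fitting modules."""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import FieldContext

#: Observable kinds understood by the back-calculator and the fitters.
KINDS = ("R1", "R2", "eta", "S2dip")


@dataclass(frozen=True)
class Observation:
    """A single tagged observable: kind, field context (None for S2dip), value, sigma."""

    kind: str
    field: FieldContext | None
    value: float
    sigma: float

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown observable kind {self.kind!r}")
        if self.kind == "S2dip":
            if self.field is not None:
                raise ValueError("S2dip is field-independent; field must be None")
        elif self.field is None:
            raise ValueError(f"{self.kind} requires a field context")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class ResidueDataset:
    """One residue's observables, as consumed by the model-free fitter."""

    residue: str
    observations: list = field(default_factory=list)

    def __post_init__(self):
        keys = []
        n_dip = 0
        for obs in self.observations:
            if obs.kind == "S2dip":
                n_dip += 1
            else:
                keys.append((obs.kind, round(obs.field.b0, 6)))
        if n_dip > 1:
            raise ValueError(f"residue {self.residue}: at most one S2dip observation")
        if len(keys) != len(set(keys)):
            raise ValueError(f"residue {self.residue}: duplicated (kind, field) observation")

    @property
    def s2dip(self) -> Observation | None:
        for obs in self.observations:
            if obs.kind == "S2dip":
                return obs
        return None

    def without_s2dip(self) -> "ResidueDataset":
        return ResidueDataset(self.residue,
                              [o for o in self.observations if o.kind != "S2dip"])

    def __len__(self) -> int:
        return len(self.observations)
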