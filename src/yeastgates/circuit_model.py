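"""Two-input logic gates, strain naming, and growth-condition parameters.

The circuits under study implement the six common two-input Boolean
functions (AND, OR, NAND, NOR, XOR, XNOR) in yeast, with one strain per
gate x input-state combination (e.g. ``OR01`` is the OR gate presented
with inputs (0, 1)).  Two control strains accompany every run: ``WT``,
the non-fluorescent wild type (negative control, expected low), and
``NOR00``, a NOR gate with both inputs off (positive control, expected
high).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

Bit = int
InputPair = tuple[Bit, Bit]

_GATE_FUNCS = {
    "AND": lambda a, b: a & b,
    "OR": lambda a, b: a | b,
    "NAND": lambda a, b: 1 - (a & b),
    "NOR": lambda a, b: 1 - (a | b),
    "XOR": lambda a, b: a ^ b,
    "XNOR": lambda a, b: 1 - (a ^ b),
}

GATE_NAMES: tuple[str, ...] = tuple(_GATE_FUNCS)
INPUT_PAIRS: tuple[InputPair, ...] = ((0, 0), (0, 1), (1, 0), (1, 1))


class GateError(ValueError):
    """Unknown gate name or malformed strain label."""


@dataclass(frozen=True)
class GateType:
    """A two-input Boolean gate with its full truth table."""

    name: str
    truth_table: Mapping[InputPair, Bit]

    def __post_init__(self) -> None:
        if set(self.truth_table) != set(INPUT_PAIRS):
            raise GateError(
                f"truth table of {self.name} must cover exactly the 4 input pairs"
            )

    def __call__(self, inputs: InputPair) -> Bit:
        return self.truth_table[inputs]


GATES: dict[str, GateType] = {
    name: GateType(name, {pair: fn(*pair) for pair in INPUT_PAIRS})
    for name, fn in _GATE_FUNCS.items()
}


def expected_output(gate: GateType | str, inputs: InputPair) -> Bit:
    """Boolean output of ``gate`` for the given input pair.

    Raises :class:`GateError` for an unknown gate name and ``ValueError``
    for inputs outside {0, 1}.
    """
    if isinstance(gate, str):
        try:
            gate = GATES[gate.upper()]
        except KeyError:
            raise GateError(f"unknown gate {gate!r}") from None
    a, b = inputs
    if a not in (0, 1) or b not in (0, 1):
        raise ValueError(f"inputs must be bits, got {inputs!r}")
    return gate.truth_table[(a, b)]


@dataclass(frozen=True)
class StrainSpec:
    """One experimental or control strain.

    ``grnas`` lists the gRNA part names (coding sequences and promoter
    target sites share the same DNA sequence in these circuits) that the
    strain's design is expected to carry; it is consumed by the DNAseq
    verification stage and may be empty elsewhere.
    """

    label: str
    gate: GateType | None  # None for WT
    inputs: InputPair | None  # None for WT
    expected_output: Bit
    is_control: bool = False
    grnas: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.gate is not None and self.inputs is not None:
            want = self.gate.truth_table[self.inputs]
            if self.expected_output != want:
                raise GateError(
                    f"{self.label}: expected_output {self.expected_output} "
                    f"contradicts {self.gate.name}{self.inputs}"
                )

    def with_grnas(self, grnas) -> "StrainSpec":
        return StrainSpec(
            self.label, self.gate, self.inputs, self.expected_output,
            self.is_control, frozenset(grnas),
        )


_LABEL_RE = re.compile(r"^(AND|OR|NAND|NOR|XOR|XNOR)([01])([01])$")


def parse_strain_label(label: str) -> StrainSpec:
    """Parse a strain label like ``"OR01"``, ``"WT"`` or ``"NOR00"``.

    The first digit after the gate name is input 1, the second input 2.
    ``WT`` is the negative control (expected low); ``NOR00`` is the
    positive control (expected high) and is flagged as a control while
    retaining its gate semantics.
    """
    name = label.strip().upper()
    if name == "WT":
        return StrainSpec("WT", None, None, 0, is_control=True)
    m = _LABEL_RE.match(name)
    if m is None:
        raise GateError(f"unparseable strain label {label!r}")
    gate = GATES[m.group(1)]
    inputs: InputPair = (int(m.group(2)), int(m.group(3)))
    return StrainSpec(
        name, gate, inputs, gate.truth_table[inputs],
        is_control=(name == "NOR00"),
    )


def experimental_strains() -> list[StrainSpec]:
    """The 24 experimental strains: 6 gates x 4 input states."""
    return [
        parse_strain_label(f"{g}{a}{b}") for g in GATE_NAMES for a, b in INPUT_PAIRS
    ]


def control_strains() -> list[StrainSpec]:
    """Positive (NOR00) and negative (WT) fluorescence controls."""
    return [parse_strain_label("NOR00"), parse_strain_label("WT")]


_MEDIA = ("SC", "rich", "slow", "high_osmolarity")


@dataclass(frozen=True)
class GrowthCondition:
    """Protocol growth parameters.

    ``temperature_C`` (T): incubation temperature, 30 or 37 C.
    ``overnight_hours`` (H): overnight incubation, 8-18 h (default 16).
    ``medium`` (M): SC (default), rich, slow, or high-osmolarity medium.
    ``target_od`` (D): intended post-dilution starting OD of the growth
    phase, in OD units (nominally 3e-4 in the study).
    """

    temperature_C: float = 30.0
    overnight_hours: float = 16.0
    medium: str = "SC"
    target_od: float = 3e-4

    def __post_init__(self) -> None:
        if self.temperature_C not in (30, 37):
            raise ValueError("temperature must be 30 or 37 C")
        if not 8 <= self.overnight_hours <= 18:
            raise ValueError("overnight incubation must be 8-18 h")
        if self.medium not in _MEDIA:
            raise ValueError(f"medium must be one of {_MEDIA}")
        if self.target_od <= 0:
            raise ValueError("target OD must be positive")

    @property
    def is_standard(self) -> bool:
        """Standard growth conditions: T=30, H=16, M=SC (any target OD)."""
        return (
            self.temperature_C == 30
            and self.overnight_hours == 16
            and self.medium == "SC"
        )


STANDARD_CONDITION = GrowthCondition()


def load_strain_specs(path: str | Path) -> list[StrainSpec]:
    """Load strain/circuit specs from YAML or JSON.

    Each entry needs a ``label``; ``grnas`` is an optional list of part
    names attached to the parsed spec.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    specs = []
    for entry in data:
        spec = parse_strain_label(entry["label"])
        specs.append(spec.with_grnas(entry.get("grnas", ())))
    return specs
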