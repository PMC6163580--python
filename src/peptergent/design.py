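"""Sequence-level design checks for beta-amphipathic peptergents.

A peptergent candidate alternates hydrophobic residues with hydrophilic
ones (amphipathy drives the two-faced strand), is about twelve residues
long (matching the hydrophobic belt width of membrane beta barrels),
places positive charges in the N-terminal half and negative charges in
the C-terminal half (favouring antiparallel pairing) and stays globally
neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.IUPACData import protein_letters_1to3

from .model import ClassTable, HydropathyClass

_ONE_TO_THREE = {k: v.upper() for k, v in protein_letters_1to3.items()}


@dataclass(frozen=True)
class SequencePattern:
    """Per-residue hydropathy classes of a peptide sequence."""

    classes: tuple[HydropathyClass, ...]
    sequence: str
    tokens: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def net_charge(self) -> int:
        return sum(c.charge for c in self.classes)


def tokenize(sequence: str) -> list[str]:
    """Split a sequence string into residue tokens.

    Whitespace- or dash-separated multi-letter tokens (``VAL-ARG-ADA``)
    are used as-is; a contiguous string is read one letter at a time
    with standard one- to three-letter translation.
    """
    sequence = sequence.strip()
    if not sequence:
        return []
    for sep in (None, "-"):
        parts = sequence.split(sep) if sep else sequence.split()
        if len(parts) > 1:
            return [p.upper() for p in parts if p]
    return [
        _ONE_TO_THREE.get(ch.upper(), ch.upper()) for ch in sequence
    ]


def classify_sequence(
    sequence: str, class_table: ClassTable | None = None
) -> SequencePattern:
    """Map a sequence to its residue hydropathy pattern.

    Raises ValueError naming the first token absent from the table
    (tokens that fall through one-letter translation unchanged).
    """
    class_table = class_table or ClassTable.default()
    tokens = tokenize(sequence)
    classes = []
    for tok in tokens:
        if tok not in class_table:
            raise ValueError(f"unknown residue token {tok!r}")
        classes.append(class_table.lookup(tok).hydropathy)
    return SequencePattern(tuple(classes), sequence, tuple(tokens))


def alternation_score(pattern: SequencePattern) -> float:
    """Fraction of adjacent residue pairs whose hydrophobic vs
    hydrophilic status differs; 1.0 is perfect alternation.  Charged
    residues count as hydrophilic."""
    if len(pattern) < 2:
        raise ValueError("alternation needs at least 2 residues")

    def hydrophobic(c: HydropathyClass) -> bool:
        return c is HydropathyClass.HYDROPHOBIC

    flips = sum(
        hydrophobic(a) != hydrophobic(b)
        for a, b in zip(pattern.classes[:-1], pattern.classes[1:])
    )
    return flips / (len(pattern) - 1)


@dataclass(frozen=True)
class DesignRules:
    """Peptergent design heuristics (all tunable)."""

    target_length: int = 12
    min_alternation: float = 0.8
    require_terminal_charge_complementarity: bool = True
    require_net_neutrality: bool = True


@dataclass
class DesignReport:
    """Per-rule pass/fail with the counts behind each verdict."""

    length_ok: bool
    alternation_ok: bool
    terminal_charge_ok: bool
    neutrality_ok: bool
    length: int = 0
    alternation: float = 0.0
    net_charge: int = 0
    n_half_charge: int = 0
    c_half_charge: int = 0
    rules: DesignRules = field(default_factory=DesignRules)

    @property
    def all_ok(self) -> bool:
        return (
            self.length_ok
            and self.alternation_ok
            and self.terminal_charge_ok
            and self.neutrality_ok
        )


def design_check(
    pattern: SequencePattern, rules: DesignRules | None = None
) -> DesignReport:
    """Evaluate a pattern against the peptergent design heuristics.

    The N-terminal part is the first ceil(n/2) residues and the
    C-terminal part the remaining floor(n/2).
    """
    rules = rules or DesignRules()
    n = len(pattern)
    split = (n + 1) // 2
    n_half = sum(c.charge for c in pattern.classes[:split])
    c_half = sum(c.charge for c in pattern.classes[split:])
    net = pattern.net_charge
    alternation = alternation_score(pattern) if n >= 2 else 0.0
    return DesignReport(
        length_ok=(n == rules.target_length),
        alternation_ok=(alternation >= rules.min_alternation),
        terminal_charge_ok=(
            (n_half > 0 and c_half < 0)
            if rules.require_terminal_charge_complementarity
            else True
        ),
        neutrality_ok=(net == 0) if rules.require_net_neutrality else True,
        length=n,
        alternation=alternation,
        net_charge=net,
        n_half_charge=n_half,
        c_half_charge=c_half,
        rules=rules,
    )
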