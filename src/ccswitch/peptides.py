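"""Coiled-coil peptide bookkeeping: heptad registers, kinase-motif grafting,
helical wheels, hydrophobic moments, masses and extinction coefficients.

A parallel dimeric coiled coil is specified by a seven-residue (heptad)
repeat *abcdefg* in which *a* and *d* residues form the hydrophobic
helix-helix interface and *e*/*g* flank it.  Everything in this module is
pure sequence arithmetic on that register; no structure prediction.
"""

from __future__ import annotations

import cmath
import math
import re
from dataclasses import dataclass, field, replace

HEPTAD = "abcdefg"

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")

#: residues that can carry a phosphoryl group
PHOSPHO_ACCEPTORS = set("STY")

# Elemental composition of amino-acid *residues* (amino acid minus water).
_RESIDUE_FORMULA = {
    "A": dict(C=3, H=5, N=1, O=1),
    "R": dict(C=6, H=12, N=4, O=1),
    "N": dict(C=4, H=6, N=2, O=2),
    "D": dict(C=4, H=5, N=1, O=3),
    "C": dict(C=3, H=5, N=1, O=1, S=1),
    "E": dict(C=5, H=7, N=1, O=3),
    "Q": dict(C=5, H=8, N=2, O=2),
    "G": dict(C=2, H=3, N=1, O=1),
    "H": dict(C=6, H=7, N=3, O=1),
    "I": dict(C=6, H=11, N=1, O=1),
    "L": dict(C=6, H=11, N=1, O=1),
    "K": dict(C=6, H=12, N=2, O=1),
    "M": dict(C=5, H=9, N=1, O=1, S=1),
    "F": dict(C=9, H=9, N=1, O=1),
    "P": dict(C=5, H=7, N=1, O=1),
    "S": dict(C=3, H=5, N=1, O=2),
    "T": dict(C=4, H=7, N=1, O=2),
    "W": dict(C=11, H=10, N=2, O=1),
    "Y": dict(C=9, H=9, N=1, O=2),
    "V": dict(C=5, H=9, N=1, O=1),
}

# IUPAC 2021 standard atomic weights (average) and monoisotopic masses.
_AVG_WEIGHT = dict(H=1.008, C=12.011, N=14.007, O=15.999, S=32.06, P=30.974)
_MONO_WEIGHT = dict(
    H=1.00782503, C=12.0, N=14.00307401, O=15.99491462, S=31.97207117,
    P=30.97376200,
)


def _formula_mass(formula: dict, weights: dict) -> float:
    return sum(n * weights[el] for el, n in formula.items())


def residue_mass(res: str, convention: str = "average") -> float:
    """Mass of one amino-acid residue (amino acid minus water), Da."""
    weights = _AVG_WEIGHT if convention == "average" else _MONO_WEIGHT
    try:
        return _formula_mass(_RESIDUE_FORMULA[res], weights)
    except KeyError:
        raise ValueError(f"non-canonical residue {res!r}") from None


def _water(convention: str) -> float:
    w = _AVG_WEIGHT if convention == "average" else _MONO_WEIGHT
    return 2 * w["H"] + w["O"]


def _mod_delta(mod: str, convention: str) -> float:
    w = _AVG_WEIGHT if convention == "average" else _MONO_WEIGHT
    if mod == "acetyl":          # N-terminal H -> COCH3
        return 2 * w["C"] + 2 * w["H"] + w["O"]
    if mod == "amide":           # C-terminal OH -> NH2
        return w["N"] + w["H"] - w["O"]
    if mod == "phospho":         # side chain + HPO3
        return w["H"] + w["P"] + 3 * w["O"]
    raise ValueError(f"unknown modification {mod!r}")


def validate_sequence(sequence: str) -> None:
    """Raise ValueError naming the first offending index if any residue is
    not one of the 20 canonical one-letter codes."""
    if not sequence:
        raise ValueError("empty sequence")
    for i, res in enumerate(sequence, start=1):
        if res not in CANONICAL:
            raise ValueError(f"non-canonical residue {res!r} at position {i}")


@dataclass(frozen=True)
class RegisteredPeptide:
    """A peptide with a heptad register assignment.

    ``register_offset`` maps residue 1 *of the heptad core* to a register
    position: offset 0 puts it at *a*, offset 4 at *e*, and so on.
    ``n_flank``/``c_flank`` are non-heptad caps or linkers (register '-'),
    excluded from wheel and pairing logic but included in mass and
    extinction-coefficient calculations.  ``sidechain_mods`` holds
    (1-based full-sequence index, modification) pairs.
    """

    name: str
    sequence: str
    register_offset: int = 0
    n_term_mod: str = "free"
    c_term_mod: str = "free"
    sidechain_mods: tuple = ()
    n_flank: str = ""
    c_flank: str = ""

    def __post_init__(self):
        validate_sequence(self.sequence)
        if not 0 <= self.register_offset <= 6:
            raise ValueError("register_offset must be in 0..6")
        if self.n_term_mod not in ("free", "acetyl"):
            raise ValueError(f"unknown N-terminal mod {self.n_term_mod!r}")
        if self.c_term_mod not in ("free", "amide"):
            raise ValueError(f"unknown C-terminal mod {self.c_term_mod!r}")
        if not self.sequence.startswith(self.n_flank) or not self.sequence.endswith(
            self.c_flank
        ):
            raise ValueError("flanks must be prefixes/suffixes of sequence")
        for idx, mod in self.sidechain_mods:
            if not 1 <= idx <= len(self.sequence):
                raise ValueError(f"sidechain mod index {idx} out of range")
            if mod == "phospho" and self.sequence[idx - 1] not in PHOSPHO_ACCEPTORS:
                raise ValueError(
                    f"phospho at index {idx}: residue "
                    f"{self.sequence[idx - 1]!r} is not S/T/Y"
                )

    # -- register bookkeeping -------------------------------------------------

    @property
    def core(self) -> str:
        end = len(self.sequence) - len(self.c_flank)
        return self.sequence[len(self.n_flank):end]

    @property
    def core_start(self) -> int:
        """1-based full-sequence index of the first core residue."""
        return len(self.n_flank) + 1

    @property
    def registers(self) -> str:
        """Per-residue register string over the full sequence ('-' flanks)."""
        core_regs = assign_register(self.core, self.register_offset)
        return "-" * len(self.n_flank) + "".join(core_regs) + "-" * len(self.c_flank)

    def index_of(self, register: str, heptad_index: int) -> int:
        """1-based full-sequence index of register position ``register`` in
        heptad ``heptad_index`` (1-based) of the core."""
        if register not in HEPTAD:
            raise ValueError(f"unknown register {register!r}")
        if heptad_index < 1:
            raise ValueError("heptad_index is 1-based")
        # core position p (1-based) has register HEPTAD[(offset+p-1) % 7]
        want = HEPTAD.index(register)
        first = (want - self.register_offset) % 7 + 1   # first core pos at register
        pos = first + 7 * (heptad_index - 1)
        if pos > len(self.core):
            raise ValueError(
                f"register {register}{heptad_index} is outside the core "
                f"(length {len(self.core)})"
            )
        return pos + len(self.n_flank)

    def residue_at(self, register: str, heptad_index: int) -> str:
        return self.sequence[self.index_of(register, heptad_index) - 1]


def assign_register(sequence: str, register_offset: int) -> list:
    """Register positions per residue: residue i (1-based) sits at
    ``HEPTAD[(register_offset + i - 1) % 7]``."""
    validate_sequence(sequence)
    if not 0 <= register_offset <= 6:
        raise ValueError("register_offset must be in 0..6")
    return [HEPTAD[(register_offset + i) % 7] for i in range(len(sequence))]


def insert_kinase_motif(
    parent: RegisteredPeptide,
    motif: str,
    anchor_register: str,
    heptad_index: int,
) -> RegisteredPeptide:
    """Graft a kinase-recognition motif (e.g. ``"RRxS"``) onto ``parent``.

    The motif's phospho-acceptor (its last S/T) is placed at
    ``anchor_register`` of heptad ``heptad_index``; 'x' positions keep the
    parent residue.  For the basophilic RRXS consensus anchored at *a* of
    heptad k, the two Arg land at *e* and *f* of heptad k-1, away from the
    hydrophobic interface.
    """
    motif = motif.strip()
    if not re.fullmatch(r"[A-Zx]+", motif):
        raise ValueError(f"bad motif {motif!r}: use one-letter codes and 'x'")
    acceptors = [i for i, m in enumerate(motif) if m in ("S", "T")]
    if acceptors:
        acc = acceptors[-1]
    elif all(m == "x" for m in motif):
        acc = len(motif) - 1      # pure placeholder motif: anchor its last slot
    else:
        raise ValueError(f"motif {motif!r} has no S/T phospho-acceptor")
    anchor_idx = parent.index_of(anchor_register, heptad_index)   # 1-based
    start = anchor_idx - acc
    end = start + len(motif) - 1
    if start < 1 or end > len(parent.sequence):
        clipped = [p for p in range(start, end + 1)
                   if p < 1 or p > len(parent.sequence)]
        raise ValueError(
            f"motif {motif!r} anchored at {anchor_register}{heptad_index} "
            f"overruns the terminus at positions {clipped}"
        )
    seq = list(parent.sequence)
    for j, m in enumerate(motif):
        if m != "x":
            seq[start - 1 + j] = m
    return replace(parent, sequence="".join(seq))


def substitute_at_register(
    parent: RegisteredPeptide,
    register: str,
    heptad_index: int,
    new_residue: str,
) -> RegisteredPeptide:
    """Point substitution addressed by (register, heptad); annotation kept."""
    if new_residue not in CANONICAL:
        raise ValueError(f"non-canonical residue {new_residue!r}")
    idx = parent.index_of(register, heptad_index)
    seq = list(parent.sequence)
    seq[idx - 1] = new_residue
    return replace(parent, sequence="".join(seq))


@dataclass(frozen=True)
class WheelLayout:
    """Single-turn helical-wheel placement of the heptad core."""

    residues: tuple       # (core position 1-based, register, residue, angle deg)
    degrees_per_residue: float

    def angles_by_register(self) -> dict:
        out = {}
        for _, reg, _, ang in self.residues:
            out.setdefault(reg, ang)
        return out


# 3.5 residues/turn: register positions of successive heptads superimpose.
COILED_COIL_DEGREES = 720.0 / 7.0


def helical_wheel(
    peptide: RegisteredPeptide, degrees_per_residue: float = COILED_COIL_DEGREES
) -> WheelLayout:
    """Project the heptad core onto an idealized helical wheel.

    The default 102.857 deg/residue (3.5 residues/turn) is the coiled-coil
    supercoil-corrected periodicity, so residues seven apart share an angle
    exactly and the seven register positions occupy seven distinct sectors.
    """
    core = peptide.core
    if len(core) < 7:
        raise ValueError("need at least one full heptad (7 core residues)")
    regs = assign_register(core, peptide.register_offset)
    rows = []
    for i, (res, reg) in enumerate(zip(core, regs)):
        ang = (i * degrees_per_residue) % 360.0
        rows.append((i + 1, reg, res, ang))
    return WheelLayout(residues=tuple(rows), degrees_per_residue=degrees_per_residue)


#: Eisenberg consensus hydrophobicity scale.
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}


def hydrophobic_moment(
    peptide: RegisteredPeptide,
    scale: dict = None,
    degrees_per_residue: float = COILED_COIL_DEGREES,
):
    """First-moment amphipathicity of the heptad core.

    mu_H = | sum_i h_i exp(i * delta * n_i) | with delta the wheel step;
    returns (magnitude, direction in degrees).  With the default 3.5
    residues/turn step the moment of any homopolymer vanishes over whole
    heptads and the magnitude is invariant to rotation by full turns.
    """
    scale = EISENBERG if scale is None else scale
    core = peptide.core
    if len(core) < 7:
        raise ValueError("need at least 7 core residues")
    missing = sorted({r for r in core if r not in scale})
    if missing:
        raise ValueError(f"residues missing from scale: {missing}")
    step = math.radians(degrees_per_residue)
    vec = sum(scale[r] * cmath.exp(1j * step * n) for n, r in enumerate(core))
    return abs(vec), math.degrees(cmath.phase(vec)) % 360.0


def molecular_mass(entity, convention: str = "average") -> float:
    """Average (default) or monoisotopic mass in Da.

    Accepts a plain sequence string (free termini, no modifications) or a
    :class:`RegisteredPeptide` (termini and side-chain modifications
    honoured).  Free termini contribute one water; acetyl adds +C2H2O,
    C-terminal amide swaps OH for NH2, phospho adds +HPO3.
    """
    if convention not in ("average", "monoisotopic"):
        raise ValueError(f"unknown mass convention {convention!r}")
    if isinstance(entity, RegisteredPeptide):
        seq = entity.sequence
        mods = [m for _, m in entity.sidechain_mods]
        if entity.n_term_mod == "acetyl":
            mods.append("acetyl")
        if entity.c_term_mod == "amide":
            mods.append("amide")
    else:
        seq = entity
        validate_sequence(seq)
        mods = []
    mass = sum(residue_mass(r, convention) for r in seq) + _water(convention)
    mass += sum(_mod_delta(m, convention) for m in mods)
    return mass


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients at 280 nm (M^-1 cm^-1)."""

    eps280_trp: float = 5690.0
    eps280_tyr: float = 1280.0

    def __post_init__(self):
        if self.eps280_trp <= 0 or self.eps280_tyr <= 0:
            raise ValueError("extinction coefficients must be positive")


def epsilon280(sequence: str, table: ExtinctionTable = ExtinctionTable()) -> float:
    """epsilon_280 = 5690 * nTrp + 1280 * nTyr (default table)."""
    validate_sequence(sequence)
    return table.eps280_trp * sequence.count("W") + table.eps280_tyr * sequence.count("Y")
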