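"""Dimer stability: a-a' pairing preferences and the two-state thermal model.

Partner choice in the heterodimer family is ranked by a relative coupling
free energy for the residue pair at facing *a* positions (Ile-Ile most
stabilizing; Ser-Ile the least destabilizing substitution; Ser prefers the
homotypic Ser-Ser among polar partners).  The shipped table is
order-calibrated only: the ordinal relations are contractual, the absolute
kcal/mol values are placeholders a user can replace via CSV.

Thermal denaturation is modelled as a two-state heterodimer equilibrium
A + B <=> AB with a van 't Hoff temperature dependence of the dissociation
constant anchored at the melting temperature:

    Kd(T) = Kd(Tm) * exp(-dH/R * (1/T - 1/Tm)),   Kd(Tm) = Ctot/4,

so that the fraction folded is exactly 0.5 at Tm for equimolar strands at
total peptide concentration Ctot.  The CD observable is the mean residue
ellipticity at 222 nm interpolated between folded/unfolded baselines.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

R_KCAL = 1.98720425e-3  # kcal mol^-1 K^-1


class PairingTable:
    """Symmetric (residue, residue') -> relative coupling energy map."""

    def __init__(self, energies: dict, source: str = "user"):
        self.source = source
        self._e = {}
        for (a, b), v in energies.items():
            self._e[(a, b)] = float(v)
            if (b, a) in energies and not math.isclose(
                energies[(b, a)], v, rel_tol=0, abs_tol=1e-12
            ):
                raise ValueError(f"asymmetric entries for pair {a}-{b}")
            self._e[(b, a)] = float(v)

    @property
    def residues(self):
        return sorted({a for a, _ in self._e})

    def score(self, res_a: str, res_aprime: str) -> float:
        try:
            return self._e[(res_a, res_aprime)]
        except KeyError:
            raise KeyError(
                f"pair {res_a}-{res_aprime} not tabulated; available residues: "
                f"{self.residues}"
            ) from None

    @classmethod
    def from_csv(cls, path, source=None) -> "PairingTable":
        energies = {}
        with open(path) as fh:
            for row in csv.DictReader(fh):
                energies[(row["res_a"], row["res_aprime"])] = float(row["energy"])
        return cls(energies, source=source or str(path))

    @classmethod
    def default(cls) -> "PairingTable":
        ref = resources.files("ccswitch.data").joinpath("pairing_table.csv")
        with resources.as_file(ref) as path:
            table = cls.from_csv(path, source="ccswitch default (order-calibrated)")
        return table


def score_pairing(res_a: str, res_aprime: str, table: PairingTable = None) -> float:
    """Relative a-a' coupling energy (kcal/mol; more negative = more stable)."""
    table = table or PairingTable.default()
    return table.score(res_a, res_aprime)


def rank_partner_variants(b_peptide, register: str, heptad_index: int,
                          candidate_a_residues, table: PairingTable = None):
    """Rank candidate a'-residues for the partner strand against the residue
    ``b_peptide`` presents at (register, heptad).  Returns (residue, score)
    pairs, most stabilizing first; ties break alphabetically."""
    table = table or PairingTable.default()
    b_res = b_peptide.residue_at(register, heptad_index)
    scored = [(cand, table.score(b_res, cand)) for cand in candidate_a_residues]
    return sorted(scored, key=lambda rs: (rs[1], rs[0]))


@dataclass(frozen=True)
class MeltParams:
    """Two-state heterodimer melt parameters.

    ``total_concentration`` is the *total* peptide concentration in uM
    (equimolar strands, i.e. Ctot/2 each); ``dH`` is the van 't Hoff
    dissociation enthalpy in kcal/mol; baselines are MRE222 values in
    deg cm^2 dmol^-1, optionally with linear temperature slopes.
    """

    tm_celsius: float
    dh_kcal: float = 40.0
    total_concentration: float = 100.0
    folded_baseline: float = -33000.0
    unfolded_baseline: float = -3000.0
    folded_slope: float = 0.0
    unfolded_slope: float = 0.0

    def __post_init__(self):
        if self.dh_kcal <= 0:
            raise ValueError("van 't Hoff dH must be positive")
        if self.total_concentration <= 0:
            raise ValueError("total_concentration must be positive")


def dissociation_kd(T_celsius, params: MeltParams):
    """Kd(T) in uM from the van 't Hoff anchor at Tm (Kd(Tm) = Ctot/4)."""
    T = np.asarray(T_celsius, dtype=float) + 273.15
    tm = params.tm_celsius + 273.15
    kd_tm = params.total_concentration / 4.0
    return kd_tm * np.exp(-params.dh_kcal / R_KCAL * (1.0 / T - 1.0 / tm))


def fraction_folded(T_celsius, params: MeltParams):
    """Fraction of strands in the dimer at temperature(s) T.

    Solves the equimolar heterodimer mass balance P f^2 - (2P+Kd) f + P = 0
    (P = Ctot/2 per strand) for the physical root; exactly 0.5 at Tm,
    monotone non-increasing in T.
    """
    kd = dissociation_kd(T_celsius, params)
    P = params.total_concentration / 2.0
    b = 2.0 * P + kd
    f = (b - np.sqrt(b * b - 4.0 * P * P)) / (2.0 * P)
    return np.clip(f, 0.0, 1.0)


@dataclass(frozen=True)
class MeltCurve:
    """MRE222 versus temperature."""

    temperature_c: np.ndarray
    mre222: np.ndarray

    def __post_init__(self):
        if len(self.temperature_c) != len(self.mre222):
            raise ValueError("temperature and MRE arrays differ in length")


def melt_curve(params: MeltParams, temperature_grid) -> MeltCurve:
    """Forward CD melt: baseline-interpolated two-state unfolding curve."""
    T = np.asarray(temperature_grid, dtype=float)
    if T.size == 0:
        raise ValueError("empty temperature grid")
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperature grid must be strictly ascending")
    f = fraction_folded(T, params)
    folded = params.folded_baseline + params.folded_slope * T
    unfolded = params.unfolded_baseline + params.unfolded_slope * T
    return MeltCurve(temperature_c=T, mre222=folded + (unfolded - folded) * (1.0 - f))
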