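"""Dissociation-gated phosphorylation kinetics of the coiled-coil switch.

Core scheme (solution mode)::

            koff            kp
    AB  <========>  A + B  ---->  A + B'
            kon

The kinase-recognition Ser is buried in the dimer interface, so only the
*free* monomeric B is phosphorylated (and only free B' is dephosphorylated
when a phosphatase is present).  Phosphorylation drains the monomer pool
and pulls the dimer equilibrium apart; the observed rate is therefore set
jointly by kp and by the free-monomer fraction, which depends on the dimer
stability (Keq = kon/koff) and on total peptide concentration.

Two membrane extensions reuse the same interaction module:

* tether mode - a permanently membrane-attached anchor (the acidic strand
  fused to a His-tagged fluorescent protein) binds a soluble cargo
  (the switch strand); phosphorylation of the free cargo empties the
  membrane complex.
* avidity mode - both strands carry a weak amphipathic membrane-targeting
  sequence; monomers exchange rapidly with the membrane (k1on/k1off) while
  the dimer, presenting two MTSs, detaches ``avidity_factor`` times slower,
  so only the heterodimer accumulates at the membrane.

All concentrations are uM (surface quantities in uM-equivalent units of
the well-mixed proxy), times in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

RTOL = 1e-8
ATOL = 1e-12


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the switch scheme (uM, min units)."""

    kon: float = 120.0          # uM^-1 min^-1, A + B association
    koff: float = 10.0          # min^-1, A-B dissociation
    kp: float = 0.20            # min^-1, phosphorylation of free B at 1x kinase
    kinase_scale: float = 1.0
    kdp: float = 0.0            # min^-1, dephosphorylation of free B' at 1x
    phosphatase_scale: float = 1.0
    # tether mode: cargo <-> membrane anchor binding (same CC interaction,
    # optionally distinct context)
    kon_t: float = None
    koff_t: float = None
    # avidity mode: single-MTS membrane exchange and dimer avidity
    k1on: float = 0.0           # min^-1 per monomer
    k1off: float = 0.0          # min^-1 per monomer
    avidity_factor: float = 1.0  # dimer detaches at k1off/avidity_factor
    kon_mem: float = None       # on-membrane dimerization rate (default kon)
    # optional weakened partial complex of A with phosphorylated B
    enable_partial_complex: bool = False
    kon_p: float = 0.0
    koff_p: float = 0.0
    allow_membrane_phospho: bool = False

    def __post_init__(self):
        for name in ("kon", "koff", "kp", "kinase_scale", "kdp",
                     "phosphatase_scale", "k1on", "k1off", "kon_p", "koff_p"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.avidity_factor < 1:
            raise ValueError("avidity_factor must be >= 1")

    @property
    def keq(self) -> float:
        """Association constant kon/koff (uM^-1)."""
        return self.kon / self.koff

    def tether_rates(self):
        kon_t = self.kon if self.kon_t is None else self.kon_t
        koff_t = self.koff if self.koff_t is None else self.koff_t
        return kon_t, koff_t


@dataclass(frozen=True)
class SystemState:
    """Species concentrations (uM) / surface quantities (uM-equivalent)."""

    A: float = 0.0
    B: float = 0.0
    AB: float = 0.0
    Bp: float = 0.0
    ABp: float = 0.0
    anchor_total: float = 0.0
    anchor_cargo: float = 0.0
    A_mem: float = 0.0
    B_mem: float = 0.0
    AB_mem: float = 0.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"negative initial {name}")
        if self.anchor_cargo > self.anchor_total and self.anchor_total:
            raise ValueError("anchor_cargo exceeds anchor_total")


@dataclass(frozen=True)
class Event:
    """Set enzyme activity multipliers at a given time (integration restart)."""

    time: float
    kinase: float = None        # new kinase_scale, None = unchanged
    phosphatase: float = None   # new phosphatase_scale, None = unchanged

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("event before t=0")


@dataclass
class TimeCourse:
    """Sampled trajectories of species and/or instrument observables."""

    times: np.ndarray
    series: dict
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, y in self.series.items():
            y = np.asarray(y, dtype=float)
            if y.shape != self.times.shape:
                raise ValueError(f"series {name!r} length mismatch")
            self.series[name] = y

    def __getitem__(self, name):
        return self.series[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, **self.series})


def _check_times(times):
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a sorted 1-D grid with >= 2 points")
    if t[0] < 0:
        raise ValueError("times must be non-negative")
    return t


def _integrate(rhs, y0, times, params, events):
    """Piecewise stiff integration with enzyme-activity switching at events."""
    t = _check_times(times)
    events = sorted(events or (), key=lambda e: e.time)
    ks, ps = params.kinase_scale, params.phosphatase_scale
    # apply events at or before t0, collect strictly interior break times
    interior = []
    for e in events:
        if e.time <= t[0]:
            ks = e.kinase if e.kinase is not None else ks
            ps = e.phosphatase if e.phosphatase is not None else ps
        elif e.time < t[-1]:
            interior.append(e)
    breaks = [t[0]] + sorted({e.time for e in interior}) + [t[-1]]
    out = np.empty((len(y0), t.size))
    y = np.asarray(y0, dtype=float)
    for a, b in zip(breaks[:-1], breaks[1:]):
        mask = (t >= a) & (t <= b)
        t_eval = np.unique(np.concatenate([t[mask], [a, b]]))
        sol = solve_ivp(
            rhs, (a, b), y, t_eval=t_eval, args=(ks, ps),
            method="LSODA", rtol=RTOL, atol=ATOL,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed on [{a}, {b}] (rtol={RTOL}, atol={ATOL}): "
                f"{sol.message}"
            )
        pos = np.searchsorted(t_eval, t[mask])
        out[:, mask] = sol.y[:, pos]
        y = sol.y[:, -1]
        for e in interior:
            if e.time == b:
                ks = e.kinase if e.kinase is not None else ks
                ps = e.phosphatase if e.phosphatase is not None else ps
    return t, out


# -- solution mode ------------------------------------------------------------

def simulate_solution(params: KineticParameters, init: SystemState, times,
                      events=()) -> TimeCourse:
    """Integrate the dissociation-gated scheme in bulk solution.

    Conservation (A-total and B-family totals) holds to the solver
    tolerance and is recorded in ``meta['conservation_error']``.
    """
    p = params

    def rhs(t, y, ks, ps):
        A, B, AB, Bp, ABp = y
        bind = p.kon * A * B - p.koff * AB
        phos = p.kp * ks * B
        dephos = p.kdp * ps * Bp
        bind_p = (p.kon_p * A * Bp - p.koff_p * ABp) if p.enable_partial_complex else 0.0
        return [
            -bind - bind_p,
            -bind - phos + dephos,
            bind,
            phos - dephos - bind_p,
            bind_p,
        ]

    y0 = [init.A, init.B, init.AB, init.Bp, init.ABp]
    t, y = _integrate(rhs, y0, times, p, events)
    series = dict(zip(("A", "B", "AB", "Bp", "ABp"), y))
    a_tot = series["A"] + series["AB"] + series["ABp"]
    b_tot = series["B"] + series["Bp"] + series["AB"] + series["ABp"]
    err = _conservation_error((a_tot, b_tot))
    return TimeCourse(t, series, meta=dict(
        mode="solution", params=p, conservation_error=err))


def _conservation_error(totals):
    err = 0.0
    for tot in totals:
        ref = max(abs(tot[0]), 1e-30)
        err = max(err, float(np.max(np.abs(tot - tot[0])) / ref))
    return err


def equilibrium_dimer(a_total: float, b_total: float, kd: float) -> float:
    """Closed-form [AB] at binding equilibrium (quadratic mass balance)."""
    b = a_total + b_total + kd
    return (b - np.sqrt(b * b - 4.0 * a_total * b_total)) / 2.0


# -- tether mode --------------------------------------------------------------

def simulate_tether(params: KineticParameters, init: SystemState, times,
                    events=()) -> TimeCourse:
    """Membrane anchor/cargo tether: anchor density fixed, cargo exchanges
    between solution and the anchor-cargo membrane complex; phosphorylation
    and dephosphorylation act on the free solution pools only."""
    if init.anchor_total <= 0:
        raise ValueError("tether mode requires a positive anchor density")
    kon_t, koff_t = params.tether_rates()
    p = params

    def rhs(t, y, ks, ps):
        B, Bp, C = y
        free_anchor = init.anchor_total - C
        bind = kon_t * B * free_anchor - koff_t * C
        phos = p.kp * ks * B
        dephos = p.kdp * ps * Bp
        return [-bind - phos + dephos, phos - dephos, bind]

    y0 = [init.B, init.Bp, init.anchor_cargo]
    t, y = _integrate(rhs, y0, times, p, events)
    B, Bp, C = y
    series = dict(
        B=B, Bp=Bp, anchor_cargo=C,
        anchor_total=np.full_like(t, init.anchor_total),
        cargo_membrane=C,
    )
    b_tot = B + Bp + C
    err = _conservation_error((b_tot, series["anchor_total"]))
    return TimeCourse(t, series, meta=dict(
        mode="tether", params=p, conservation_error=err))


# -- avidity mode -------------------------------------------------------------

def simulate_avidity(params: KineticParameters, init: SystemState, times,
                     events=()) -> TimeCourse:
    """MinD-style avidity switch: both strands carry a weak MTS; monomers
    and the dimer attach to the membrane at k1on, but the dimer, holding on
    with two MTSs, detaches avidity_factor-fold slower.  Dimerization is
    allowed in both compartments.  By default phosphorylation is routed
    through the solution pool; ``allow_membrane_phospho`` additionally lets
    membrane-bound monomeric B be processed (released as solution B')."""
    p = params
    kon_m = p.kon if p.kon_mem is None else p.kon_mem

    def rhs(t, y, ks, ps):
        A, B, AB, Bp, Am, Bm, ABm = y
        bind_s = p.kon * A * B - p.koff * AB
        bind_m = kon_m * Am * Bm - p.koff * ABm
        phos = p.kp * ks * B
        phos_m = p.kp * ks * Bm if p.allow_membrane_phospho else 0.0
        dephos = p.kdp * ps * Bp
        exA = p.k1on * A - p.k1off * Am
        exB = p.k1on * B - p.k1off * Bm
        exAB = p.k1on * AB - (p.k1off / p.avidity_factor) * ABm
        return [
            -bind_s - exA,
            -bind_s - exB - phos + dephos,
            bind_s - exAB,
            phos + phos_m - dephos,
            exA - bind_m,
            exB - bind_m - phos_m,
            exAB + bind_m,
        ]

    y0 = [init.A, init.B, init.AB, init.Bp, init.A_mem, init.B_mem, init.AB_mem]
    t, y = _integrate(rhs, y0, times, p, events)
    A, B, AB, Bp, Am, Bm, ABm = y
    series = dict(
        A=A, B=B, AB=AB, Bp=Bp, A_mem=Am, B_mem=Bm, AB_mem=ABm,
        A_membrane_total=Am + ABm,
        B_membrane_total=Bm + ABm,
    )
    a_tot = A + AB + Am + ABm
    b_tot = B + Bp + AB + Bm + ABm
    err = _conservation_error((a_tot, b_tot))
    return TimeCourse(t, series, meta=dict(
        mode="avidity", params=p, conservation_error=err))


# -- effective rate and observables -------------------------------------------

_PRODUCT_SERIES = dict(solution="Bp", tether="cargo_membrane",
                       avidity="B_membrane_total")
_SIMULATORS = dict(solution=simulate_solution, tether=simulate_tether,
                   avidity=simulate_avidity)


def _auto_times(params: KineticParameters, init: SystemState, mode: str):
    """Time grid spanning ~5 apparent lifetimes of the phosphorylation step."""
    a_tot = init.A + init.AB
    b_tot = init.B + init.AB
    if mode == "solution" and a_tot > 0 and b_tot > 0:
        kd = params.koff / params.kon if params.kon > 0 else np.inf
        ab = equilibrium_dimer(a_tot, b_tot, kd) if np.isfinite(kd) else 0.0
        f_free = max((b_tot - ab) / b_tot, 1e-4)
    else:
        f_free = 1.0
    k0 = max(params.kp * params.kinase_scale * f_free, 1e-6)
    t_end = 5.0 / k0
    return np.linspace(0.0, t_end, 400)


def effective_rate(params: KineticParameters, init: SystemState,
                   mode: str = "solution", times=None, events=()):
    """Simulate the chosen mode and fit the observed product (or membrane
    release) trajectory with the single-exponential rise-to-plateau model;
    returns the fitted rate constant in min^-1.

    Decreases with dimer stability (Keq) at fixed totals, increases as the
    totals are diluted at fixed Keq, and approaches kp * (free-B fraction)
    in the fast-exchange limit kon, koff >> kp.
    """
    from .fitting import fit_rise

    if params.kp * params.kinase_scale <= 0 and mode != "tether":
        raise ValueError("effective_rate requires kp * kinase_scale > 0")
    if times is None:
        times = _auto_times(params, init, mode)
    tc = _SIMULATORS[mode](params, init, times, events=events)
    y = tc[_PRODUCT_SERIES[mode]]
    res = fit_rise(tc.times, y)
    if not res.converged:
        raise RuntimeError("effective-rate fit did not converge")
    return res.k


def observables(tc: TimeCourse, mapping: dict) -> TimeCourse:
    """Map species trajectories to instrument signals.

    ``mapping['kind']``:

    * ``'cd'`` - MRE222(t) interpolated between ``mre_folded`` and
      ``mre_unfolded`` by the folded fraction AB(t)/ab_ref (ab_ref defaults
      to the trajectory maximum).
    * ``'hplc'`` - reversed-phase peak areas; the acidic column denatures
      the complex, so substrate area tracks B + AB and product area tracks
      B' (+ partial complex), scaled by ``area_per_uM``.
    * ``'slb'`` - per-channel intensities as linear combinations of species:
      ``channels={name: {species: coefficient}}``.
    """
    kind = mapping.get("kind")
    if kind == "cd":
        ab = tc["AB"] + (tc.series.get("ABp", 0.0) * mapping.get("w_partial", 0.0))
        ab_ref = mapping.get("ab_ref") or float(np.max(ab))
        if ab_ref <= 0:
            frac = np.zeros_like(tc.times)
        else:
            frac = ab / ab_ref
        mre_f = mapping.get("mre_folded", -33000.0)
        mre_u = mapping.get("mre_unfolded", -3000.0)
        series = dict(mre222=mre_u + (mre_f - mre_u) * frac)
    elif kind == "hplc":
        s = mapping.get("area_per_uM", 1.0)
        abp = tc.series.get("ABp", np.zeros_like(tc.times))
        series = dict(
            substrate_area=s * (tc["B"] + tc["AB"]),
            product_area=s * (tc["Bp"] + abp),
        )
    elif kind == "slb":
        series = {}
        for name, combo in mapping["channels"].items():
            y = np.zeros_like(tc.times)
            for sp, coef in combo.items():
                if sp not in tc.series:
                    raise KeyError(f"unknown species {sp!r} in channel {name!r}")
                y = y + coef * tc[sp]
            series[name] = y
    else:
        raise KeyError(f"unknown observable kind {kind!r}")
    return TimeCourse(tc.times, series, meta={**tc.meta, "observables": kind})
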