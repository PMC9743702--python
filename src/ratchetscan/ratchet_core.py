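"""Brownian-ratchet random walk model of preinitiation-complex (PIC) scanning.

The 43S preinitiation complex is modelled as a walker on the discrete
positions of a linear mRNA.  Each step it moves 1 nt in the 5'-3' or 3'-5'
direction with equal probability, except that a "pawl" (a 5' block,
stochastically deposited behind the walker) and the eIF4E-bound cap rectify
the oscillation into net 5'-3' progress.  The P-site of the complex sits at
the 13th-15th nt of the bound mRNA fragment; whenever an AUG occupies the
P-site the complex recognises it with probability ``1 - p_leakage``.
Recognition of an out-of-frame start (or runoff past the 3' end of the
modelled window) can trigger nonsense-mediated decay (NMD) of the mRNA with
probability ``p_nmd``.

Two equivalent engines are provided: a stochastic trajectory simulator
(:func:`simulate_scan` / :func:`simulate_ensemble`) and an exact
absorbing-Markov-chain solver (:func:`exact_recognition_probabilities`)
used as an independent oracle and as a fast deterministic backend for
parameter fitting.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "RUNOFF",
    "P_SITE_OFFSET",
    "ScanParameters",
    "StartSite",
    "MrnaLayout",
    "ScanOutcome",
    "EnsembleSummary",
    "ExactScanResult",
    "solo_layout",
    "duo_layout",
    "fitting_layouts",
    "simulate_scan",
    "simulate_ensemble",
    "expression_level",
    "net_leakage",
    "scans_per_triplet",
    "exact_recognition_probabilities",
    "layouts_to_json",
    "layouts_from_json",
]

#: Sentinel for a trajectory that ran off the 3' end without initiating.
RUNOFF = -1

#: The P-site covers the 13th-15th nt of the PIC-bound fragment, i.e. it
#: trails the 5' edge of the footprint by 12 nt.
P_SITE_OFFSET = 12


def _check_prob(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and 0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a finite probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ScanParameters:
    """The three probabilities of the ratchet-and-pawl scanning model.

    Parameters
    ----------
    p_pawl
        Per-step probability that a pawl is deposited immediately 5' of the
        PIC's trailing edge.
    p_leakage
        Probability that a single P-site inspection of an AUG fails
        (leaky scanning); may be overridden per site for context-specific
        AUGs.
    p_nmd
        Probability that recognition of a nonfunctional (out-of-frame)
        start, or 3' runoff, triggers decay of the mRNA.
    """

    p_pawl: float
    p_leakage: float
    p_nmd: float

    def __post_init__(self) -> None:
        _check_prob("p_pawl", self.p_pawl)
        _check_prob("p_leakage", self.p_leakage)
        _check_prob("p_nmd", self.p_nmd)

    def replace(self, **kwargs: float) -> "ScanParameters":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {"p_pawl": self.p_pawl, "p_leakage": self.p_leakage, "p_nmd": self.p_nmd}


@dataclass(frozen=True)
class StartSite:
    """One AUG triplet on the mRNA.

    ``position`` is the 1-based coordinate of the A.  ``outcome_class`` is
    ``"functional"`` (initiation yields protein, never NMD) or
    ``"nonfunctional"`` (out-of-frame; initiation may trigger NMD).
    """

    position: int
    outcome_class: str = "functional"
    leakage_override: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("site position must be >= 1")
        if self.outcome_class not in ("functional", "nonfunctional"):
            raise ValueError(f"unknown outcome_class {self.outcome_class!r}")
        if self.leakage_override is not None:
            _check_prob("leakage_override", self.leakage_override)

    @property
    def functional(self) -> bool:
        return self.outcome_class == "functional"


@dataclass(frozen=True)
class MrnaLayout:
    """1-D geometry of a reporter mRNA with classified start sites.

    Coordinates are 1-based from the 5' end; the cap sits at position 0 and
    acts as a permanent pawl.  The annotated start (aATG) has its A at
    ``upstream_len + 1`` and exactly one site must occupy that position.
    """

    upstream_len: int = 50
    downstream_len: int = 50
    sites: tuple[StartSite, ...] = ()
    runoff_nmd: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        if self.upstream_len < 0 or self.downstream_len < 0:
            raise ValueError("window lengths must be non-negative")
        positions = [s.position for s in self.sites]
        if len(set(positions)) != len(positions):
            raise ValueError("no two sites may share a position")
        if sum(p == self.aatg_position for p in positions) != 1:
            raise ValueError(
                f"layout must contain exactly one site at the aATG position {self.aatg_position}"
            )
        if any(p < 1 or p > self.length for p in positions):
            raise ValueError("site positions must fit within the mRNA window")

    @property
    def length(self) -> int:
        return self.upstream_len + 3 + self.downstream_len

    @property
    def aatg_position(self) -> int:
        return self.upstream_len + 1

    @property
    def aatg_index(self) -> int:
        for i, s in enumerate(self.sites):
            if s.position == self.aatg_position:
                return i
        raise ValueError("layout has no aATG site")  # unreachable after validation

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def functional_mask(self) -> np.ndarray:
        return np.array([s.functional for s in self.sites], dtype=bool)

    def site_leakages(self, params: ScanParameters) -> np.ndarray:
        return np.array(
            [s.leakage_override if s.leakage_override is not None else params.p_leakage
             for s in self.sites],
            dtype=float,
        )


@dataclass
class ScanOutcome:
    """Result of a single PIC trajectory."""

    initiated_at: int  # site index into layout.sites, or RUNOFF
    nmd_activated: bool
    n_steps: int
    visits: np.ndarray  # per-site count of P-site inspections
    trajectory: list[tuple[int, int]] | None = None  # (trailing_edge, pawl_frontier)


@dataclass
class EnsembleSummary:
    """Aggregate of many independent scanning trajectories on one layout.

    ``expression`` is the predicted protein level: the fraction of
    trajectories that initiated at a functional site times the fraction of
    mRNA surviving NMD.  ``mrna`` is ``1 - fraction_nmd``.  ``net_leakage``
    is ``1 - fraction_init[aATG]`` (the fraction of PICs that never
    initiate at the annotated start; meaningful for Solo layouts).
    """

    n_reps: int
    fraction_init: np.ndarray
    fraction_runoff: float
    fraction_nmd: float
    expression: float
    mrna: float
    net_leakage: float
    mean_visits: np.ndarray
    label: str = ""

    def as_dict(self) -> dict:
        d = {
            "label": self.label,
            "n_reps": self.n_reps,
            "fraction_runoff": self.fraction_runoff,
            "fraction_nmd": self.fraction_nmd,
            "expression": self.expression,
            "mrna": self.mrna,
            "net_leakage": self.net_leakage,
        }
        for i, (f, v) in enumerate(zip(self.fraction_init, self.mean_visits)):
            d[f"fraction_init_{i}"] = f
            d[f"mean_visits_{i}"] = v
        return d


# ---------------------------------------------------------------------------
# layout constructors


def solo_layout(
    upstream_len: int = 50,
    downstream_len: int = 50,
    leakage_override: float | None = None,
    runoff_nmd: bool = True,
    label: str = "Solo",
) -> MrnaLayout:
    """Reporter with only the annotated start codon."""
    site = StartSite(upstream_len + 1, "functional", leakage_override)
    return MrnaLayout(upstream_len, downstream_len, (site,), runoff_nmd, label)


def duo_layout(
    datg_position: int,
    upstream_len: int = 50,
    downstream_len: int = 50,
    functional: bool | None = None,
    datg_leakage_override: float | None = None,
    aatg_leakage_override: float | None = None,
    runoff_nmd: bool = True,
    label: str = "",
) -> MrnaLayout:
    """Reporter with the aATG plus one downstream ATG.

    ``datg_position`` is relative to the aATG's A = +1, so +7 places the
    dATG 6 nt downstream.  When ``functional`` is None the outcome class is
    derived from the reading frame: in-frame (``(pos - 1) % 3 == 0``)
    dATGs yield functional protein, out-of-frame ones do not.
    """

    if datg_position < 4:
        raise ValueError("dATG must not overlap the aATG (position >= +4)")
    if functional is None:
        functional = (datg_position - 1) % 3 == 0
    aatg = StartSite(upstream_len + 1, "functional", aatg_leakage_override)
    datg = StartSite(
        upstream_len + datg_position,
        "functional" if functional else "nonfunctional",
        datg_leakage_override,
    )
    if not label:
        frame = (datg_position - 1) % 3
        label = f"Duo(+{datg_position}, frame +{frame})"
    return MrnaLayout(upstream_len, downstream_len, (aatg, datg), runoff_nmd, label)


def fitting_layouts(
    positions: Sequence[int] = range(7, 32),
    upstream_len: int = 50,
    downstream_len: int = 50,
) -> tuple[MrnaLayout, list[MrnaLayout]]:
    """The Solo reporter plus the Duo set used for parameter fitting.

    By default the 25 dATG positions +7..+31 (aATG-dATG distance 6-30 nt).
    """

    solo = solo_layout(upstream_len, downstream_len)
    duos = [duo_layout(p, upstream_len, downstream_len) for p in positions]
    return solo, duos


# ---------------------------------------------------------------------------
# stochastic simulation


def _site_tables(layout: MrnaLayout, params: ScanParameters) -> tuple[int, np.ndarray, np.ndarray]:
    """Map trailing-edge positions to the site (if any) inspected there.

    Returns ``(t_max, site_of_t, leak_of_t)`` where ``t_max`` is the last
    trailing-edge position before runoff.  A site at position ``p`` aligns
    with the P-site when the trailing edge sits at ``p - P_SITE_OFFSET``;
    sites closer than 13 nt to the 5' end are never inspected (the P-site
    cannot reach them, mirroring the cap-proximal blind spot of the PIC).
    """

    t_max = layout.length - P_SITE_OFFSET
    if t_max < 1:
        raise ValueError("mRNA window shorter than the PIC footprint")
    site_of_t = np.full(t_max + 2, -1, dtype=np.int64)
    leak_of_t = np.ones(t_max + 2, dtype=float)
    leaks = layout.site_leakages(params)
    for i, site in enumerate(layout.sites):
        t = site.position - P_SITE_OFFSET
        if 1 <= t <= t_max:
            site_of_t[t] = i
            leak_of_t[t] = leaks[i]
    return t_max, site_of_t, leak_of_t


def simulate_scan(
    layout: MrnaLayout,
    params: ScanParameters,
    rng: np.random.Generator,
    record_trajectory: bool = False,
) -> ScanOutcome:
    """Simulate one PIC trajectory.

    Per step: (1) pawl lottery at the position immediately 5' of the
    trailing edge, (2) direction draw, forced 5'-3' if a 3'-5' move would
    cross the pawl frontier or cap, (3) move 1 nt, (4) P-site inspection if
    an AUG is exactly aligned.  The trajectory ends on recognition or when
    the P-site's leading position passes the 3' end of the window.
    """

    t_max, site_of_t, leak_of_t = _site_tables(layout, params)
    t = 1  # trailing edge; cap (permanent pawl) at 0
    frontier = 0
    visits = np.zeros(layout.n_sites, dtype=np.int64)
    traj = [(t, frontier)] if record_trajectory else None
    n_steps = 0
    while True:
        n_steps += 1
        if rng.random() < params.p_pawl:
            frontier = t - 1
        if t - 1 <= frontier or rng.random() < 0.5:
            t += 1
        else:
            t -= 1
        if traj is not None:
            traj.append((t, frontier))
        if t > t_max:
            nmd = layout.runoff_nmd and rng.random() < params.p_nmd
            return ScanOutcome(RUNOFF, nmd, n_steps, visits, traj)
        site = site_of_t[t]
        if site >= 0:
            visits[site] += 1
            if rng.random() >= leak_of_t[t]:
                if layout.sites[site].functional:
                    return ScanOutcome(site, False, n_steps, visits, traj)
                nmd = rng.random() < params.p_nmd
                return ScanOutcome(site, nmd, n_steps, visits, traj)


def simulate_ensemble(
    layout: MrnaLayout,
    params: ScanParameters,
    n_reps: int,
    rng: np.random.Generator,
) -> EnsembleSummary:
    """Aggregate ``n_reps`` independent trajectories (vectorised).

    All replicates advance in lock-step; the per-step update rule is
    identical to :func:`simulate_scan` and the two are cross-checked
    against the exact Markov-chain solver in the test suite.
    """

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    t_max, site_of_t, leak_of_t = _site_tables(layout, params)
    n_sites = layout.n_sites
    functional = layout.functional_mask()

    t = np.ones(n_reps, dtype=np.int64)
    g = np.ones(n_reps, dtype=np.int64)  # gap to pawl frontier (t - frontier)
    alive = np.arange(n_reps)
    result = np.full(n_reps, -9, dtype=np.int64)
    visits = np.zeros((n_reps, n_sites), dtype=np.int64)

    while alive.size:
        m = alive.size
        u = rng.random((3, m))
        g[u[0] < params.p_pawl] = 1
        fwd = (g == 1) | (u[1] < 0.5)
        step = np.where(fwd, 1, -1)
        t += step
        g += step
        runoff = t > t_max
        tc = np.minimum(t, t_max + 1)
        sidx = site_of_t[tc]
        aligned = (sidx >= 0) & ~runoff
        done = runoff.copy()
        if aligned.any():
            aw = np.flatnonzero(aligned)
            visits[alive[aw], sidx[aw]] += 1
            recognised = u[2][aw] >= leak_of_t[tc[aw]]
            done[aw[recognised]] = True
        if done.any():
            di = alive[done]
            result[di] = np.where(runoff[done], RUNOFF, sidx[done])
            keep = ~done
            alive, t, g = alive[keep], t[keep], g[keep]

    fraction_init = np.array([(result == i).mean() for i in range(n_sites)])
    fraction_runoff = float((result == RUNOFF).mean())
    nmd_eligible = np.zeros(n_reps, dtype=bool)
    if layout.runoff_nmd:
        nmd_eligible |= result == RUNOFF
    for i in range(n_sites):
        if not functional[i]:
            nmd_eligible |= result == i
    nmd = nmd_eligible & (rng.random(n_reps) < params.p_nmd)
    fraction_nmd = float(nmd.mean())

    expression = float(fraction_init[functional].sum()) * (1.0 - fraction_nmd)
    return EnsembleSummary(
        n_reps=n_reps,
        fraction_init=fraction_init,
        fraction_runoff=fraction_runoff,
        fraction_nmd=fraction_nmd,
        expression=expression,
        mrna=1.0 - fraction_nmd,
        net_leakage=1.0 - float(fraction_init[layout.aatg_index]),
        mean_visits=visits.mean(axis=0),
        label=layout.label,
    )


def expression_level(summary: EnsembleSummary, solo_summary: EnsembleSummary) -> float:
    """Protein level of a variant normalised by the Solo reporter."""
    if solo_summary.expression <= 0:
        raise ZeroDivisionError(
            "Solo expression is zero; parameters are degenerate (no initiation at the aATG)"
        )
    return summary.expression / solo_summary.expression


def net_leakage(
    layout: MrnaLayout,
    params: ScanParameters,
    n_reps: int,
    rng: np.random.Generator,
) -> float:
    """Fraction of PICs that never initiate at the aATG of a Solo reporter."""
    if layout.n_sites != 1:
        raise ValueError("net leakage is defined for a single-site (Solo) layout")
    return simulate_ensemble(layout, params, n_reps, rng).net_leakage


def scans_per_triplet(net_leakage_rate: float, single_scan_leakage: float) -> float:
    """Number of P-site inspections per triplet implied by the two rates.

    From ``net = single ** n_scans``:  ``n = log(net) / log(single)``.
    """

    for name, v in (("net_leakage_rate", net_leakage_rate), ("single_scan_leakage", single_scan_leakage)):
        if not (isinstance(v, (int, float)) and math.isfinite(v) and 0.0 < v < 1.0):
            raise ValueError(f"{name} must lie strictly in (0, 1), got {v!r}")
    return math.log(net_leakage_rate) / math.log(single_scan_leakage)


# ---------------------------------------------------------------------------
# exact absorbing-Markov-chain oracle


@dataclass
class ExactScanResult:
    """Exact absorption probabilities of the scanning chain on one layout."""

    layout: MrnaLayout
    params: ScanParameters
    p_init: np.ndarray  # per-site recognition probability
    p_runoff: float
    expected_inspections: np.ndarray  # per-site mean number of P-site inspections

    @property
    def fraction_nmd(self) -> float:
        p = float(self.p_init[~self.layout.functional_mask()].sum())
        if self.layout.runoff_nmd:
            p += self.p_runoff
        return self.params.p_nmd * p

    @property
    def mrna(self) -> float:
        return 1.0 - self.fraction_nmd

    @property
    def expression(self) -> float:
        return float(self.p_init[self.layout.functional_mask()].sum()) * self.mrna

    @property
    def net_leakage(self) -> float:
        return 1.0 - float(self.p_init[self.layout.aatg_index])


@functools.lru_cache(maxsize=100_000)
def _exact_absorption(
    layout: MrnaLayout,
    p_pawl: float,
    leakages: tuple[float, ...],
    state_cap: int,
) -> tuple[tuple[float, ...], float, tuple[float, ...]]:
    """Solve the absorbing chain over (trailing edge, pawl gap) states.

    State ``(t, g)``: trailing edge ``t`` in 1..t_max and gap
    ``g = t - frontier`` in 1..t.  Absorption occurs at each recognition
    event and at runoff.  Independent of ``p_nmd`` (the decay lottery acts
    after absorption), which lets fits cache solves across p_nmd values.
    """

    t_max = layout.length - P_SITE_OFFSET
    if t_max < 1:
        raise ValueError("mRNA window shorter than the PIC footprint")
    n = t_max * (t_max + 1) // 2
    if n > state_cap:
        raise ValueError(f"state space of {n} states exceeds cap {state_cap}")

    site_of_t = np.full(t_max + 2, -1, dtype=np.int64)
    leak_of_t = np.ones(t_max + 2, dtype=float)
    for i, site in enumerate(layout.sites):
        ts = site.position - P_SITE_OFFSET
        if 1 <= ts <= t_max:
            site_of_t[ts] = i
            leak_of_t[ts] = leakages[i]

    ts_arr = np.concatenate([np.full(t, t, dtype=np.int64) for t in range(1, t_max + 1)])
    gs_arr = np.concatenate([np.arange(1, t + 1, dtype=np.int64) for t in range(1, t_max + 1)])

    def index(t: np.ndarray, g: np.ndarray) -> np.ndarray:
        return t * (t - 1) // 2 + g - 1

    n_sites = layout.n_sites
    runoff_col = n_sites
    rows, cols, vals = [], [], []
    arows, acols, avals = [], [], []

    def add(src_t, src_g, dst_t, dst_g, prob):
        i = index(src_t, src_g)
        runoff = dst_t > t_max
        if runoff.any():
            arows.append(i[runoff])
            acols.append(np.full(int(runoff.sum()), runoff_col))
            avals.append(prob[runoff])
        m = ~runoff
        if m.any():
            dt, dg, pi, ii = dst_t[m], dst_g[m], prob[m], i[m]
            sidx = site_of_t[dt]
            leak = leak_of_t[dt]
            rows.append(ii)
            cols.append(index(dt, dg))
            vals.append(pi * leak)
            hit = sidx >= 0
            if hit.any():
                arows.append(ii[hit])
                acols.append(sidx[hit])
                avals.append(pi[hit] * (1.0 - leak[hit]))

    q = p_pawl
    ones2 = np.full(n, 2, dtype=np.int64)
    add(ts_arr, gs_arr, ts_arr + 1, ones2, np.full(n, q))  # pawl placed, forced 5'-3'
    g1 = gs_arr == 1
    add(ts_arr[g1], gs_arr[g1], ts_arr[g1] + 1, gs_arr[g1] + 1, np.full(int(g1.sum()), 1 - q))
    g2 = ~g1
    half = np.full(int(g2.sum()), (1 - q) / 2)
    add(ts_arr[g2], gs_arr[g2], ts_arr[g2] + 1, gs_arr[g2] + 1, half)
    add(ts_arr[g2], gs_arr[g2], ts_arr[g2] - 1, gs_arr[g2] - 1, half)

    Q = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    R = sp.csc_matrix(
        (np.concatenate(avals), (np.concatenate(arows), np.concatenate(acols))),
        shape=(n, n_sites + 1),
    )
    e = np.zeros(n)
    e[0] = 1.0  # start state (t=1, g=1): trailing edge at position 1, cap at 0
    y = spla.spsolve((sp.eye(n, format="csc") - Q.T).tocsc(), e)

    absorbed = R.T @ y
    p_init = absorbed[:n_sites]
    p_runoff = float(absorbed[runoff_col])

    # Expected inspections: each entry into an aligned state is one
    # inspection; surviving entries equal the expected visits of that state.
    inspections = np.zeros(n_sites)
    for i, site in enumerate(layout.sites):
        tsite = site.position - P_SITE_OFFSET
        if not (1 <= tsite <= t_max):
            continue
        leak = leakages[i]
        if leak > 0:
            state_ids = index(np.full(tsite, tsite), np.arange(1, tsite + 1))
            inspections[i] = y[state_ids].sum() / leak
        else:
            inspections[i] = p_init[i]
    return tuple(p_init), p_runoff, tuple(inspections)


def exact_recognition_probabilities(
    layout: MrnaLayout,
    params: ScanParameters,
    state_cap: int = 200_000,
) -> ExactScanResult:
    """Exact per-site recognition and runoff probabilities by linear solve.

    Treats the scanning process as an absorbing Markov chain over
    (trailing edge, pawl frontier) states; intended for windows up to a
    few hundred nt (the state count grows quadratically with window
    length, capped by ``state_cap``).
    """

    leaks = tuple(layout.site_leakages(params))
    p_init, p_runoff, inspections = _exact_absorption(layout, params.p_pawl, leaks, state_cap)
    return ExactScanResult(
        layout=layout,
        params=params,
        p_init=np.array(p_init),
        p_runoff=p_runoff,
        expected_inspections=np.array(inspections),
    )


# ---------------------------------------------------------------------------
# layout (de)serialisation


def layout_to_dict(layout: MrnaLayout) -> dict:
    return {
        "upstream_len": layout.upstream_len,
        "downstream_len": layout.downstream_len,
        "runoff_nmd": layout.runoff_nmd,
        "label": layout.label,
        "sites": [
            {
                "position": s.position,
                "outcome_class": s.outcome_class,
                "leakage_override": s.leakage_override,
            }
            for s in layout.sites
        ],
    }


def layout_from_dict(d: dict) -> MrnaLayout:
    sites = tuple(
        StartSite(s["position"], s.get("outcome_class", "functional"), s.get("leakage_override"))
        for s in d["sites"]
    )
    return MrnaLayout(
        upstream_len=d.get("upstream_len", 50),
        downstream_len=d.get("downstream_len", 50),
        sites=sites,
        runoff_nmd=d.get("runoff_nmd", True),
        label=d.get("label", ""),
    )


def layouts_to_json(layouts: Sequence[MrnaLayout], path: str | Path) -> None:
    Path(path).write_text(json.dumps([layout_to_dict(l) for l in layouts], indent=1))


def layouts_from_json(path: str | Path) -> list[MrnaLayout]:
    return [layout_from_dict(d) for d in json.loads(Path(path).read_text())]
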