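"""Eight-state, seven-reaction equilibrium model of a transporter-like sensor.

States A..H are four conformations with or without bound ligand, connected
by seven reversible reactions that form a spanning tree::

    A + L_out <-> B <-> C <-> D          (K1 [1/uM], K2, K3)
    A <-> E <-> F <-> G                  (K4, K5, K6)
    G + L_in  <-> H                      (K7 [1/uM])

There is deliberately no D<->H edge (the ligand-bound inward transition of
a transporter is structurally absent here), so state weights are simple
path products from A and no cycle constraint arises.  States D and F are
the signaling states; the signaling fraction is f_D + f_F (optionally
efficacy-weighted).

Only equilibria are modeled; no kinetics.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

STATES = ("A", "B", "C", "D", "E", "F", "G", "H")

#: Illustrative low-basal default regime (the source analysis proposes the
#: topology and directions, not numeric constants).  K-values chosen so
#: ligand-free weights are dominated by state A; results that depend on
#: them are regime-dependent.
DEFAULT_PARAMS = dict(K1=0.1, K2=3.0, K3=5.0, K4=0.002, K5=10.0, K6=5.0, K7=0.05)

#: Named multiplicative perturbation presets mirroring the mutant classes:
#: pushing the extracellular-gate equilibria (K2, K4) up mimics the
#: wedge-type gain-of-function substitutions; pushing them down mimics the
#: ligand-pocket-adjacent hypo-responsive substitution.
PRESETS = {
    "extracellular-gate": {"K2": 5.0, "K4": 5.0},
    "TM1-loop-block": {"K2": 0.01, "K4": 0.01},
}


@dataclass(frozen=True)
class StateParams:
    K1: float  # 1/uM, A + L_out <-> B
    K2: float  # B <-> C
    K3: float  # C <-> D
    K4: float  # A <-> E
    K5: float  # E <-> F
    K6: float  # F <-> G
    K7: float  # 1/uM, G + L_in <-> H
    L_out: float = 0.0  # uM
    L_in: float = 0.0  # uM

    def __post_init__(self) -> None:
        for name in ("K1", "K2", "K3", "K4", "K5", "K6", "K7", "L_out", "L_in"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @classmethod
    def defaults(cls, L_out: float = 0.0, L_in: float = 0.0, **overrides) -> "StateParams":
        kw = dict(DEFAULT_PARAMS)
        kw.update(overrides)
        return cls(L_out=L_out, L_in=L_in, **kw)


@dataclass(frozen=True)
class StateDistribution:
    fractions: dict  # state letter -> fraction
    signal_weights: tuple[float, float] = (1.0, 1.0)  # efficacy of D, F

    @property
    def signaling_fraction(self) -> float:
        wd, wf = self.signal_weights
        return wd * self.fractions["D"] + wf * self.fractions["F"]


@dataclass(frozen=True)
class DoseResponse:
    grid: tuple[float, ...]
    signaling: tuple[float, ...]
    basal: float
    plateau: float
    ec50: Optional[float]


@dataclass(frozen=True)
class PerturbationReport:
    factors: dict
    before: DoseResponse
    after: DoseResponse
    constitutive: bool  # basal increased
    hyper_responsive: bool  # EC50 decreased
    hypo_responsive: bool  # EC50 increased


def state_weights(p: StateParams) -> dict:
    """Unnormalized state weights (path products from A; w_A = 1)."""
    w = {"A": 1.0}
    w["B"] = p.K1 * p.L_out
    w["C"] = w["B"] * p.K2
    w["D"] = w["C"] * p.K3
    w["E"] = p.K4
    w["F"] = w["E"] * p.K5
    w["G"] = w["F"] * p.K6
    w["H"] = w["G"] * p.K7 * p.L_in
    return w


def solve_equilibrium(
    p: StateParams, signal_weights: tuple[float, float] = (1.0, 1.0)
) -> StateDistribution:
    """Normalize the state weights into fractions."""
    w = state_weights(p)
    total = sum(w.values())
    return StateDistribution(
        fractions={s: w[s] / total for s in STATES},
        signal_weights=signal_weights,
    )


def _hyperbola_coefficients(p: StateParams) -> tuple[float, float, float, float]:
    """Signaling fraction as (a*L + b) / (c*L + d) in L = L_out."""
    a = p.K1 * p.K2 * p.K3
    b = p.K4 * p.K5
    c = p.K1 * (1.0 + p.K2 + p.K2 * p.K3)
    d = 1.0 + p.K4 * (1.0 + p.K5 + p.K5 * p.K6 + p.K5 * p.K6 * p.K7 * p.L_in)
    return a, b, c, d


def basal_signaling(p: StateParams) -> float:
    """Signaling fraction at zero extracellular ligand."""
    return solve_equilibrium(replace(p, L_out=0.0)).signaling_fraction


def plateau_signaling(p: StateParams) -> float:
    """Limit of the signaling fraction as L_out -> infinity."""
    a, _b, c, _d = _hyperbola_coefficients(p)
    if c == 0.0:
        return basal_signaling(p)
    return a / c


def ec50_closed_form(p: StateParams) -> Optional[float]:
    """EC50 of the dose-response hyperbola: the midpoint of
    (a*L + b)/(c*L + d) between L=0 and L=inf lies at L = d/c.

    Returns None when the curve is flat (plateau == basal)."""
    a, b, c, d = _hyperbola_coefficients(p)
    if c == 0.0 or a * d == b * c:  # degenerate or flat curve
        return None
    return d / c


def _signaling_at(p: StateParams, L_out: float) -> float:
    return solve_equilibrium(replace(p, L_out=L_out)).signaling_fraction


def dose_response(
    p: StateParams, grid: Sequence[float], rel_tol: float = 1e-9
) -> DoseResponse:
    """Signaling fraction over an L_out grid, with basal, plateau and a
    numerically bisected EC50 (midpoint crossing between basal and plateau)."""
    if any(g < 0 for g in grid):
        raise ValueError("grid values must be non-negative")
    signaling = tuple(_signaling_at(p, g) for g in grid)
    basal = basal_signaling(p)
    plateau = plateau_signaling(p)
    ec50 = None
    if not math.isclose(basal, plateau, rel_tol=1e-12, abs_tol=1e-15):
        target = 0.5 * (basal + plateau)
        # bracket the crossing; the curve is monotone in L_out
        lo, hi = 0.0, 1.0
        rising = plateau > basal
        for _ in range(200):
            v = _signaling_at(p, hi)
            if (v > target) == rising and v != target:
                break
            hi *= 2.0
        else:
            raise ArithmeticError("failed to bracket EC50")
        for _ in range(400):
            mid = 0.5 * (lo + hi)
            v = _signaling_at(p, mid)
            if (v > target) == rising:
                hi = mid
            else:
                lo = mid
            if hi - lo <= rel_tol * max(hi, 1e-300):
                break
        ec50 = 0.5 * (lo + hi)
    return DoseResponse(tuple(grid), signaling, basal, plateau, ec50)


def perturb_and_compare(
    p: StateParams,
    factors: Optional[dict] = None,
    preset: Optional[str] = None,
    grid: Sequence[float] = (0.0, 0.1, 1.0, 10.0, 100.0, 1000.0),
) -> PerturbationReport:
    """Apply multiplicative factors to selected equilibrium constants and
    compare basal / plateau / EC50 before and after."""
    if preset is not None:
        if preset not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}")
        factors = dict(PRESETS[preset], **(factors or {}))
    if not factors:
        factors = {}
    for k, f in factors.items():
        if k not in ("K1", "K2", "K3", "K4", "K5", "K6", "K7"):
            raise ValueError(f"unknown equilibrium constant {k!r}")
        if f <= 0:
            raise ValueError("perturbation factors must be > 0")
    p2 = replace(p, **{k: getattr(p, k) * f for k, f in factors.items()})
    before = dose_response(p, grid)
    after = dose_response(p2, grid)
    eps = 1e-12
    constitutive = after.basal > before.basal * (1 + eps)
    hyper = (
        before.ec50 is not None
        and after.ec50 is not None
        and after.ec50 < before.ec50 * (1 - eps)
    )
    hypo = (
        before.ec50 is not None
        and after.ec50 is not None
        and after.ec50 > before.ec50 * (1 + eps)
    )
    return PerturbationReport(dict(factors), before, after, constitutive, hyper, hypo)


# ---------------------------------------------------------------------------
# parameter-file / export helpers


def read_params(path) -> StateParams:
    """Read ``key=value`` parameter text (K1..K7, L_out, L_in)."""
    kw = {}
    from pathlib import Path

    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        kw[key.strip()] = float(value)
    return StateParams(**kw)


def distribution_to_json(dist: StateDistribution) -> str:
    return json.dumps(
        {
            "fractions": {s: dist.fractions[s] for s in STATES},
            "signaling_fraction": dist.signaling_fraction,
        },
        indent=2,
    )


def dose_response_to_tsv(dr: DoseResponse) -> str:
    buf = io.StringIO()
    buf.write("L_out\tsignaling_fraction\n")
    for L, s in zip(dr.grid, dr.signaling):
        buf.write(f"{L:.6g}\t{s:.10g}\n")
    buf.write(f"# basal\t{dr.basal:.10g}\n")
    buf.write(f"# plateau\t{dr.plateau:.10g}\n")
    buf.write(f"# EC50\t{dr.ec50 if dr.ec50 is not None else 'NA'}\n")
    return buf.getvalue()
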