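"""Deterministic mass-action model of the Ras activation cycle.

The model couples three nodes — activation, deactivation, effector
binding — in seven reaction channels over eight species::

    (1) RasD + GEF  ⇌  RasD·GEF            (kon_GEF, koff_GEF)
    (2) RasD·GEF    →  RasT + GEF          (k_GEF, GEF-catalysed exchange)
    (3) RasT + GAP  ⇌  RasT·GAP            (kon_GAP, koff_GAP)
    (4) RasT·GAP    →  RasD + GAP          (k_GAP, GAP-catalysed hydrolysis)
    (5) RasD        →  RasT                (k_GDP_exch_intr)
    (6) RasT        →  RasD                (k_GTP_hydr_intr)
    (7) RasT + EFF  ⇌  RasT·EFF            (kon_EFF, koff_EFF)

RasD/RasT are GDP- and GTP-loaded Ras (nucleotide pools are not modelled:
free nucleotide is assumed saturating, as for ATP in kinase models).  The
readout is the steady-state abundance of the active-Ras–effector complex,
RasT·EFF.  The cycle is driven (no detailed balance), so "equilibrium"
means the long-time fixed point of the rate equations: trajectories are
integrated until derivatives vanish and the fixed point is then polished
by a root-finder on the conservation-reduced system.

State is in molecule numbers; bimolecular on-rates are given in M⁻¹s⁻¹
and converted to per-molecule units via 1/(N_A·V) for the configured
reaction volume.  Mutants are parameterised by dimensionless fold
changes of the five measured quantities (GEF- and GAP-catalysed rates,
the two intrinsic rates, and the effector K_D) relative to wild type.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.constants import Avogadro
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .catalog import ValidationError

__all__ = [
    "SPECIES",
    "RasModelParams",
    "FoldChangeSet",
    "ReactionSystem",
    "SteadyStateResult",
    "build_reactions",
    "steady_state",
    "apply_fold_changes",
    "compare_variants",
    "simulate_variants",
    "load_params",
    "format_reactions",
]

SPECIES = ("RasD", "RasT", "RasD_GEF", "RasT_GAP", "RasT_EFF", "GEF", "GAP", "EFF")

_RATE_FIELDS = (
    "k_gef",
    "k_gap",
    "k_gdp_exch_intr",
    "k_gtp_hydr_intr",
    "kon_gef",
    "koff_gef",
    "kon_gap",
    "koff_gap",
    "kon_eff",
    "koff_eff",
)


@dataclass(frozen=True)
class RasModelParams:
    """Abundances, reaction volume and rate constants for one Ras variant.

    Abundances are molecule numbers in a reaction volume of ``volume``
    litres.  Unimolecular rates are s⁻¹; ``kon_*`` are M⁻¹s⁻¹.
    """

    ras_total: float
    gef_total: float
    gap_total: float
    eff_total: float
    volume: float
    k_gef: float
    k_gap: float
    k_gdp_exch_intr: float
    k_gtp_hydr_intr: float
    kon_gef: float
    koff_gef: float
    kon_gap: float
    koff_gap: float
    kon_eff: float
    koff_eff: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValidationError(f"reaction volume must be > 0, got {self.volume}")
        for name in ("ras_total", "gef_total", "gap_total", "eff_total"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"rate {name} must be finite and >= 0, got {value}")

    @property
    def kd_eff(self) -> float:
        """Effector dissociation constant K_D = koff/kon, in M."""
        return self.koff_eff / self.kon_eff


@dataclass(frozen=True)
class FoldChangeSet:
    """Dimensionless mutant-over-wild-type fold changes (> 0) for the five
    measured quantities; the wild type is the all-ones set."""

    name: str
    gef: float = 1.0
    gap: float = 1.0
    intrinsic_exchange: float = 1.0
    intrinsic_hydrolysis: float = 1.0
    kd_eff: float = 1.0

    def __post_init__(self) -> None:
        for field_name in ("gef", "gap", "intrinsic_exchange", "intrinsic_hydrolysis", "kd_eff"):
            value = getattr(self, field_name)
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"{self.name}: fold change {field_name} must be finite and > 0, got {value}"
                )

    @property
    def is_wild_type(self) -> bool:
        return all(
            getattr(self, f) == 1.0
            for f in ("gef", "gap", "intrinsic_exchange", "intrinsic_hydrolysis", "kd_eff")
        )


@dataclass(frozen=True)
class ReactionSystem:
    """Mass-action reaction network in per-molecule units."""

    params: RasModelParams
    stoichiometry: np.ndarray  # (8 species, 7 channels)
    kon_gef_pm: float  # per-molecule bimolecular rates, s⁻¹·molecule⁻¹
    kon_gap_pm: float
    kon_eff_pm: float

    def fluxes(self, y: np.ndarray) -> np.ndarray:
        """Net flux through each of the seven channels (molecules/s)."""
        p = self.params
        ras_d, ras_t, ras_d_gef, ras_t_gap, ras_t_eff, gef, gap, eff = y
        return np.array(
            [
                self.kon_gef_pm * ras_d * gef - p.koff_gef * ras_d_gef,
                p.k_gef * ras_d_gef,
                self.kon_gap_pm * ras_t * gap - p.koff_gap * ras_t_gap,
                p.k_gap * ras_t_gap,
                p.k_gdp_exch_intr * ras_d,
                p.k_gtp_hydr_intr * ras_t,
                self.kon_eff_pm * ras_t * eff - p.koff_eff * ras_t_eff,
            ]
        )

    def rhs(self, y: np.ndarray) -> np.ndarray:
        """Time derivative dy/dt of all eight species."""
        return self.stoichiometry @ self.fluxes(y)

    def initial_state(self, ras_gtp_fraction: float = 0.0) -> np.ndarray:
        """All enzymes/effector free; Ras split between GDP and GTP forms
        (default: fully GDP-loaded)."""
        if not 0.0 <= ras_gtp_fraction <= 1.0:
            raise ValidationError("ras_gtp_fraction must be in [0, 1]")
        p = self.params
        y0 = np.zeros(len(SPECIES))
        y0[0] = p.ras_total * (1.0 - ras_gtp_fraction)
        y0[1] = p.ras_total * ras_gtp_fraction
        y0[5] = p.gef_total
        y0[6] = p.gap_total
        y0[7] = p.eff_total
        return y0

    def conservation_errors(self, y: np.ndarray) -> dict[str, float]:
        """Absolute deviation of each conserved total."""
        p = self.params
        return {
            "ras": abs(y[0] + y[1] + y[2] + y[3] + y[4] - p.ras_total),
            "gef": abs(y[2] + y[5] - p.gef_total),
            "gap": abs(y[3] + y[6] - p.gap_total),
            "eff": abs(y[4] + y[7] - p.eff_total),
        }


@dataclass(frozen=True)
class SteadyStateResult:
    """Steady-state abundances (molecules) of the eight species."""

    abundances: dict[str, float]
    converged: bool
    residual: float  # max |dy/dt| at the reported state, molecules/s

    @property
    def ras_t_eff(self) -> float:
        """The model readout: abundance of the active-Ras–effector complex."""
        return self.abundances["RasT_EFF"]


# Stoichiometry: rows = species in SPECIES order, columns = channels 1-7.
_STOICHIOMETRY = np.array(
    [
        # 1    2    3    4    5    6    7
        [-1,   0,   0,   1,  -1,   1,   0],  # RasD
        [ 0,   1,  -1,   0,   1,  -1,  -1],  # RasT
        [ 1,  -1,   0,   0,   0,   0,   0],  # RasD_GEF
        [ 0,   0,   1,  -1,   0,   0,   0],  # RasT_GAP
        [ 0,   0,   0,   0,   0,   0,   1],  # RasT_EFF
        [-1,   1,   0,   0,   0,   0,   0],  # GEF
        [ 0,   0,  -1,   1,   0,   0,   0],  # GAP
        [ 0,   0,   0,   0,   0,   0,  -1],  # EFF
    ],
    dtype=float,
)


def build_reactions(params: RasModelParams) -> ReactionSystem:
    """Assemble the seven-channel reaction system in per-molecule units.

    Bimolecular rates (M⁻¹s⁻¹) are divided by N_A·V so that fluxes are in
    molecules per second for molecule-number state variables.
    """
    scale = 1.0 / (Avogadro * params.volume)
    return ReactionSystem(
        params=params,
        stoichiometry=_STOICHIOMETRY.copy(),
        kon_gef_pm=params.kon_gef * scale,
        kon_gap_pm=params.kon_gap * scale,
        kon_eff_pm=params.kon_eff * scale,
    )


def _reduced_residual(x: np.ndarray, system: ReactionSystem) -> np.ndarray:
    """Fixed-point residual in the 4 free coordinates
    (RasD, RasD·GEF, RasT·GAP, RasT·EFF); the other species follow from
    the four conservation laws."""
    p = system.params
    ras_d, ras_d_gef, ras_t_gap, ras_t_eff = x
    y = np.array(
        [
            ras_d,
            p.ras_total - ras_d - ras_d_gef - ras_t_gap - ras_t_eff,
            ras_d_gef,
            ras_t_gap,
            ras_t_eff,
            p.gef_total - ras_d_gef,
            p.gap_total - ras_t_gap,
            p.eff_total - ras_t_eff,
        ]
    )
    dy = system.rhs(y)
    return dy[[0, 2, 3, 4]]


def _full_state(x: np.ndarray, p: RasModelParams) -> np.ndarray:
    ras_d, ras_d_gef, ras_t_gap, ras_t_eff = x
    return np.array(
        [
            ras_d,
            p.ras_total - ras_d - ras_d_gef - ras_t_gap - ras_t_eff,
            ras_d_gef,
            ras_t_gap,
            ras_t_eff,
            p.gef_total - ras_d_gef,
            p.gap_total - ras_t_gap,
            p.eff_total - ras_t_eff,
        ]
    )


def steady_state(
    system: ReactionSystem,
    initial: Optional[np.ndarray] = None,
    tol: float = 1e-9,
    t_max: float = 1e12,
) -> SteadyStateResult:
    """Find the long-time fixed point of the rate equations.

    The trajectory is integrated (LSODA) over geometrically growing time
    windows until the max-norm of the derivative falls below ``tol``
    (molecules/s) or ``t_max`` seconds of model time are exhausted; the
    endpoint is then polished with a root-finder on the
    conservation-reduced four-variable system, which enforces the
    conservation laws exactly.  ``converged`` is False (with the residual
    reported) if neither stage reaches ``tol``.
    """
    p = system.params
    y = system.initial_state() if initial is None else np.asarray(initial, dtype=float)
    if y.shape != (len(SPECIES),):
        raise ValidationError(f"initial state must have {len(SPECIES)} species")
    scale = max(p.ras_total, p.gef_total, p.gap_total, p.eff_total, 1.0)

    t_end = 1e2
    while True:
        sol = solve_ivp(
            lambda _t, yy: system.rhs(yy),
            (0.0, t_end),
            y,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12 * scale,
        )
        y = sol.y[:, -1]
        if np.max(np.abs(system.rhs(y))) < tol or t_end >= t_max:
            break
        t_end *= 100.0

    # Root polish on the reduced system, from the integrated endpoint.
    x0 = y[[0, 2, 3, 4]]
    polished = root(_reduced_residual, x0, args=(system,), method="hybr", tol=1e-14)
    candidate = _full_state(polished.x, p)
    use_polished = polished.success and candidate.min() > -1e-9 * scale
    if use_polished:
        y = np.clip(candidate, 0.0, None)
    residual = float(np.max(np.abs(system.rhs(y))))
    converged = residual < tol
    return SteadyStateResult(
        abundances=dict(zip(SPECIES, (float(v) for v in y))),
        converged=converged,
        residual=residual,
    )


def apply_fold_changes(wt: RasModelParams, fc: FoldChangeSet) -> RasModelParams:
    """Parameterise a mutant by scaling wild-type rates with fold changes.

    The four catalytic/intrinsic rates are multiplied directly.  The
    effector K_D fold change is applied to the off-rate (kon unchanged):
    measured effector-binding perturbations of Ras interface mutants are
    dominated by faster dissociation.  Enzyme binding rates and all
    abundances stay at wild-type values.
    """
    return replace(
        wt,
        k_gef=wt.k_gef * fc.gef,
        k_gap=wt.k_gap * fc.gap,
        k_gdp_exch_intr=wt.k_gdp_exch_intr * fc.intrinsic_exchange,
        k_gtp_hydr_intr=wt.k_gtp_hydr_intr * fc.intrinsic_hydrolysis,
        koff_eff=wt.koff_eff * fc.kd_eff,
    )


def compare_variants(
    wt_result: SteadyStateResult,
    reference_result: SteadyStateResult,
    variant_results: Mapping[str, SteadyStateResult],
    rel_tol: float = 1e-9,
) -> pd.DataFrame:
    """Report, per variant, whether its RasT·EFF readout lies in the closed
    interval bounded by the wild-type and reference (oncogenic) values.

    Returns a DataFrame (index = variant name) with columns ``ras_t_eff``
    and ``intermediate``; the number of outliers is
    ``(~df.intermediate).sum()``.  Endpoints count as intermediate; a
    small relative tolerance absorbs solver round-off at the interval
    edges.
    """
    for name, res in (("wild-type", wt_result), ("reference", reference_result)):
        if not res.converged:
            raise ValidationError(f"{name} steady state did not converge")
    lo, hi = sorted((wt_result.ras_t_eff, reference_result.ras_t_eff))
    slack = rel_tol * max(abs(lo), abs(hi), 1.0)
    rows = {}
    for name, res in variant_results.items():
        if not res.converged:
            raise ValidationError(f"variant {name!r} steady state did not converge")
        value = res.ras_t_eff
        rows[name] = {
            "ras_t_eff": value,
            "intermediate": bool(lo - slack <= value <= hi + slack),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def simulate_variants(
    wt: RasModelParams,
    fold_change_sets: Sequence[FoldChangeSet],
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Steady-state RasT·EFF for each fold-change set (plus wild type).

    Returns a DataFrame indexed by variant name with columns ``ras_t_eff``,
    ``converged`` and ``residual``; the wild type appears as ``WT``.
    """
    rows = {}
    wt_res = steady_state(build_reactions(wt), tol=tol)
    rows["WT"] = {
        "ras_t_eff": wt_res.ras_t_eff,
        "converged": wt_res.converged,
        "residual": wt_res.residual,
    }
    for fc in fold_change_sets:
        res = steady_state(build_reactions(apply_fold_changes(wt, fc)), tol=tol)
        rows[fc.name] = {
            "ras_t_eff": res.ras_t_eff,
            "converged": res.converged,
            "residual": res.residual,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Parameter configuration


def _params_from_dict(cfg: dict) -> tuple[RasModelParams, dict[str, FoldChangeSet]]:
    abundances = cfg["abundances"]
    rates = cfg["rates"]
    params = RasModelParams(
        ras_total=float(abundances["ras_total"]),
        gef_total=float(abundances["gef_total"]),
        gap_total=float(abundances["gap_total"]),
        eff_total=float(abundances["eff_total"]),
        volume=float(cfg["volume_litres"]),
        **{name: float(rates[name]) for name in _RATE_FIELDS},
    )
    variants = {
        name: FoldChangeSet(name=name, **{k: float(v) for k, v in spec.items()})
        for name, spec in (cfg.get("variants") or {}).items()
    }
    return params, variants


def load_params(path: str | Path | None = None) -> tuple[RasModelParams, dict[str, FoldChangeSet]]:
    """Load wild-type parameters and variant fold-change sets from YAML.

    Without a path, the packaged default configuration is used
    (representative placeholder values; substitute measured ones by
    passing your own file).
    """
    if path is None:
        text = resources.files("rastriage.data").joinpath("ras_wt_params.yaml").read_text()
    else:
        text = Path(path).read_text()
    return _params_from_dict(yaml.safe_load(text))


def format_reactions(system: ReactionSystem) -> str:
    """Human-readable reaction list with per-molecule rate constants."""
    p = system.params
    lines = [
        f"# volume = {p.volume:g} L; bimolecular rates converted by 1/(N_A*V)",
        f"RasD + GEF <-> RasD_GEF    kon={system.kon_gef_pm:.6g}/molecule/s  koff={p.koff_gef:g}/s",
        f"RasD_GEF -> RasT + GEF     k={p.k_gef:g}/s",
        f"RasT + GAP <-> RasT_GAP    kon={system.kon_gap_pm:.6g}/molecule/s  koff={p.koff_gap:g}/s",
        f"RasT_GAP -> RasD + GAP     k={p.k_gap:g}/s",
        f"RasD -> RasT               k={p.k_gdp_exch_intr:g}/s",
        f"RasT -> RasD               k={p.k_gtp_hydr_intr:g}/s",
        f"RasT + EFF <-> RasT_EFF    kon={system.kon_eff_pm:.6g}/molecule/s  koff={p.koff_eff:g}/s",
    ]
    return "\n".join(lines) + "\n"
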