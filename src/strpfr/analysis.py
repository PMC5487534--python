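"""Closed-form analyses around the simulator.

Growth-rate splitting between the compartments, translation-quota
derivation from turnover ratios, half-life conversions, and the
steady-state protein level as a function of the protein degradation
constant, ``c = r_translation / k_deg``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coupling import PopulationExpressionTrace
from .single_cell import SingleCellTrace

__all__ = [
    "TurnoverInput",
    "SteadyStateResult",
    "split_growth_rates",
    "translations_per_mrna",
    "k_from_halflife",
    "translation_rates",
    "steady_state_protein",
    "dilution_only_plateau",
]


def split_growth_rates(
    dilution_rate: float, tau_str: float, tau_pfr: float, mu_pfr: float = 0.0
) -> float:
    """STR growth rate required to sustain the system dilution rate.

    The residence-time-weighted average of the compartment growth rates
    must equal the chemostat dilution rate:
    ``(mu_str*tau_str + mu_pfr*tau_pfr) / (tau_str + tau_pfr) = D``.
    With no growth in the starvation loop (``mu_pfr = 0``) the stirred
    tank must overshoot ``D`` to compensate.

    Parameters are ``D`` and ``mu_pfr`` in h^-1 and the residence times
    in seconds (any common time unit works); returns ``mu_str`` in the
    units of ``D``.
    """
    if tau_str <= 0:
        raise ValueError("tau_str must be > 0")
    return (dilution_rate * (tau_str + tau_pfr) - mu_pfr * tau_pfr) / tau_str


@dataclass(frozen=True)
class TurnoverInput:
    """Protein and mRNA levels with their first-order loss constants."""

    c_protein: float       # copies per cell
    c_mrna: float          # copies per cell
    k_deg_protein: float   # h^-1 (growth dilution: k = mu)
    k_deg_mrna: float      # h^-1

    def __post_init__(self) -> None:
        for name in ("c_protein", "c_mrna", "k_deg_protein", "k_deg_mrna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def translations_per_mrna(inp: TurnoverInput) -> int:
    """Translation quota as the protein/mRNA turnover ratio.

    ``N = (c_protein * k_deg_protein) / (c_mrna * k_deg_mrna)``, rounded
    to the nearest integer: at steady state each degraded transcript
    must have produced this many proteins to sustain the protein pool.
    """
    denom = inp.c_mrna * inp.k_deg_mrna
    if denom <= 0:
        raise ValueError("c_mrna * k_deg_mrna must be > 0")
    return round(inp.c_protein * inp.k_deg_protein / denom)


def k_from_halflife(t_half_min: float) -> float:
    """First-order rate constant (h^-1) from a half-life in minutes."""
    if t_half_min <= 0:
        raise ValueError("half-life must be > 0 min")
    return math.log(2.0) * 60.0 / t_half_min


def translation_rates(
    trace: SingleCellTrace, cycle_time: float | None = None
) -> dict[str, float]:
    """Per-gene translation rates in proteins per cell per minute.

    Each PFR-STR cycle delivers one episode's worth of protein; the
    rate is the episode's final protein count divided by the cycle
    time (default: the episode length itself, ~497 s with the standard
    parameters).
    """
    cycle = trace.episode_length if cycle_time is None else cycle_time
    if cycle <= 0:
        raise ValueError("cycle time must be > 0 s")
    return {
        gene: count / (cycle / 60.0)
        for gene, count in trace.final_protein.items()
    }


@dataclass
class SteadyStateResult:
    """Steady-state protein levels over a grid of degradation constants."""

    gene_names: tuple[str, ...]
    r_translation: dict[str, float]   # proteins cell^-1 h^-1
    k_deg_grid: np.ndarray            # h^-1, all > 0
    c_protein_ss: np.ndarray          # (n_genes, n_k)

    def to_frame(self) -> pd.DataFrame:
        n_genes, n_k = self.c_protein_ss.shape
        return pd.DataFrame(
            {
                "k_deg_per_h": np.tile(self.k_deg_grid, n_genes),
                "gene": np.repeat(self.gene_names, n_k),
                "c_protein_ss": self.c_protein_ss.ravel(),
            }
        )

    def to_tsv(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def crossover_k_deg(self, reference: dict[str, float]) -> dict[str, float]:
        """Degradation constant at which the simulated steady state
        falls below a user-supplied reference level, per gene:
        ``k* = r_translation / c_reference`` (h^-1)."""
        out = {}
        for gene, ref_level in reference.items():
            if ref_level <= 0:
                raise ValueError(f"{gene}: reference level must be > 0")
            out[gene] = self.r_translation[gene] / ref_level
        return out


def steady_state_protein(
    r_translation: dict[str, float],
    k_deg_grid,
) -> SteadyStateResult:
    """Steady-state protein levels ``c = r / k_deg`` per gene.

    ``r_translation`` is in proteins per cell per hour (use
    ``translation_rates(trace)[g] * 60``).  The analytic branch needs
    ``k_deg > 0``; the dilution-only case (``k_deg = 0`` in the sweep
    figure sense) is not a fixed point of this balance — read it from
    the coupled long-run simulation via :func:`dilution_only_plateau`.
    """
    k = np.asarray(list(k_deg_grid), dtype=float)
    if np.any(k <= 0):
        raise ValueError("k_deg grid must be strictly positive")
    names = tuple(r_translation)
    rates = np.array([r_translation[g] for g in names])
    return SteadyStateResult(
        gene_names=names,
        r_translation=dict(r_translation),
        k_deg_grid=k,
        c_protein_ss=rates[:, None] / k[None, :],
    )


def dilution_only_plateau(
    expr: PopulationExpressionTrace, tail_fraction: float = 0.2
) -> dict[str, float]:
    """Per-capita protein plateau of a long coupled run (k_deg = 0 case).

    With no active degradation, protein is lost only through cell drain
    (washout plus flagless daughters); the plateau of the per-capita
    level over the trailing ``tail_fraction`` of the run estimates the
    new steady state.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    start = int(expr.times.size * (1 - tail_fraction))
    tail = expr.protein_per_cell[:, start:]
    return {
        gene: float(tail[gi].mean()) for gi, gene in enumerate(expr.gene_names)
    }
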