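"""Deterministic 1D-lattice model of one induction episode.

A cell entering the starvation zone (PFR) derepresses the operon for a
fixed induction window ``t_ind`` (default 30-125 s after entry).  RNA
polymerases initiate at the promoter whenever the window is open and the
previous polymerase has cleared the minimum spacing ``delta_x``; each
committed polymerase runs to the terminator at ``operon.length`` even
after the window closes.  The growing transcript is translated gene by
gene: ribosomes load at each gene's first coding nucleotide once it is
transcribed (with a ``delta_y`` look-ahead), keep ``delta_y`` spacing,
and detach past the stop codon, incrementing the protein count.  Each
gene on each transcript receives at most ``n_tl_max`` ribosome loadings;
once that quota is met the 5'->3' degradation machinery may proceed
through the gene.  A single RNase per transcript starts at the 5' end,
trails the hindmost obstacle ahead of it (ribosome, or the synthesis
front while the polymerase is attached) by ``delta_z``, and erases the
strand; a gene stops counting toward the mRNA level once the RNase
passes its first coding nucleotide.

The model is deliberately free of randomness: identical inputs give
bit-identical traces.  Time advances in fixed steps of ``params.dt``
(default one nucleotide per elongation step), and within each step the
update order is RNases, ribosomes, polymerases, then promoter
initiation, with the most-downstream agent of each species moving first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import OperonDefinition, SimulationParameters

__all__ = [
    "LatticeState",
    "SingleCellTrace",
    "try_initiate_rnap",
    "step_rnaps",
    "step_ribosomes",
    "step_rnases",
    "count_levels",
    "simulate_episode",
]

_EPS = 1e-9


class _Strand:
    """One transcript with its polymerase, ribosomes and RNase."""

    __slots__ = (
        "x", "attached", "ribosomes", "ribo_genes", "z",
        "tl_counts", "counted", "present", "alive",
    )

    def __init__(self, n_genes: int):
        self.x = 1              # RNAP position; first elongation step done
        self.attached = True    # RNAP still on the DNA
        self.ribosomes: list[int] = []   # positions, descending (leader first)
        self.ribo_genes: list[int] = []  # gene index per ribosome, same order
        self.z = 0              # last degraded nucleotide (0 = none)
        self.tl_counts = [0] * n_genes
        self.counted = [False] * n_genes  # currently counted toward mRNA level
        self.present = [False] * n_genes  # gene region partially present
        self.alive = True

    @property
    def length(self) -> int:
        """Synthesized transcript length; equals the RNAP position."""
        return self.x


class LatticeState:
    """Mutable lattice state shared by the per-species step functions."""

    def __init__(self, params: SimulationParameters, operon: OperonDefinition):
        self.params = params
        self.operon = operon
        self.c_start = [g.c_start for g in operon.genes]
        self.c_end = [g.c_end for g in operon.genes]
        self.quota = [g.n_tl_max for g in operon.genes]
        self.n_genes = len(operon.genes)
        # gene index per nucleotide, -1 in untranslated/intergenic regions
        gene_of_pos = np.full(operon.length + 2, -1, dtype=np.int16)
        for gi, g in enumerate(operon.genes):
            gene_of_pos[g.c_start: g.c_end + 1] = gi
        self.gene_of_pos = gene_of_pos
        self.strands: list[_Strand] = []
        self.mrna = [0] * self.n_genes
        self.mrna_partial = [0] * self.n_genes
        self.protein = [0] * self.n_genes
        self.n_initiated = 0
        self.degraded_nt = 0
        # fractional-step accumulators; one whole unit = one nucleotide pass
        self.acc_rnap = 0.0
        self.acc_ribosome = 0.0
        self.acc_rnase = 0.0

    # -- helpers -------------------------------------------------------

    def trailing_rnap_x(self) -> int | None:
        """Position of the hindmost polymerase still on the DNA."""
        for strand in reversed(self.strands):
            if strand.attached:
                return strand.x
        return None

    def any_alive(self) -> bool:
        return any(s.alive for s in self.strands)


# ---------------------------------------------------------------------------
# per-species moves (one nucleotide per pass)
# ---------------------------------------------------------------------------

def _rnase_pass(state: LatticeState) -> None:
    delta_z = state.params.delta_z
    for strand in state.strands:
        if not strand.alive:
            continue
        target = strand.z + 1
        if strand.attached:
            if target > strand.x - 1:
                continue  # cannot overtake the synthesis front
        elif target > strand.x:
            continue
        # steric gap to the hindmost obstacle ahead: the hindmost
        # ribosome, or the synthesis front while the RNAP is attached
        if strand.ribosomes:
            if strand.ribosomes[-1] - strand.z <= delta_z:
                continue
        elif strand.attached and strand.x - strand.z <= delta_z:
            continue
        # translation gate: degradation may not enter gene g before its
        # translation quota is exhausted
        gi = state.gene_of_pos[target]
        if gi >= 0 and strand.tl_counts[gi] < state.quota[gi]:
            continue
        strand.z = target
        state.degraded_nt += 1
        if gi >= 0:
            if target == state.c_start[gi] and strand.counted[gi]:
                state.mrna[gi] -= 1
                strand.counted[gi] = False
            if target == state.c_end[gi] and strand.present[gi]:
                state.mrna_partial[gi] -= 1
                strand.present[gi] = False
        if not strand.attached and strand.z >= strand.x:
            strand.alive = False


def _ribosome_pass(state: LatticeState) -> None:
    delta_y = state.params.delta_y
    c_end = state.c_end
    for strand in state.strands:
        if not strand.alive:
            continue
        positions = strand.ribosomes
        genes = strand.ribo_genes
        j = 0
        while j < len(positions):
            y = positions[j]
            if j > 0 and positions[j - 1] - y < delta_y:
                j += 1
                continue
            if strand.attached and strand.x - y <= delta_y:
                j += 1
                continue
            gi = genes[j]
            if y + 1 > c_end[gi]:
                # past the stop codon: one finished protein
                state.protein[gi] += 1
                del positions[j]
                del genes[j]
                continue
            positions[j] = y + 1
            j += 1


def _ribosome_initiations(state: LatticeState) -> None:
    delta_y = state.params.delta_y
    for strand in state.strands:
        if not strand.alive:
            continue
        for gi in range(state.n_genes):
            if strand.tl_counts[gi] >= state.quota[gi]:
                continue
            start = state.c_start[gi]
            if strand.z >= start:
                continue  # binding site already degraded
            if strand.attached and strand.x - start <= delta_y:
                continue  # not enough transcript synthesized yet
            if not strand.attached and strand.x <= start:
                continue
            # nearest ribosome at/ahead of the start must have cleared delta_y
            blocked = False
            for y in reversed(strand.ribosomes):
                if y >= start:
                    blocked = y - start < delta_y
                    break
            if blocked:
                continue
            idx = 0
            while idx < len(strand.ribosomes) and strand.ribosomes[idx] > start:
                idx += 1
            strand.ribosomes.insert(idx, start)
            strand.ribo_genes.insert(idx, gi)
            strand.tl_counts[gi] += 1


def _rnap_pass(state: LatticeState) -> None:
    delta_x = state.params.delta_x
    length = state.operon.length
    prev_x: int | None = None
    for strand in state.strands:
        if not strand.attached:
            continue
        if prev_x is not None and prev_x - strand.x < delta_x:
            prev_x = strand.x
            continue
        strand.x += 1
        gi = state.gene_of_pos[strand.x]
        if gi >= 0 and strand.x == state.c_start[gi]:
            state.mrna_partial[gi] += 1
            strand.present[gi] = True
        # a gene counts toward the strict mRNA level once fully transcribed
        gi_done = state.gene_of_pos[strand.x]
        if (
            gi_done >= 0
            and strand.x == state.c_end[gi_done]
            and strand.z < state.c_start[gi_done]
        ):
            state.mrna[gi_done] += 1
            strand.counted[gi_done] = True
        if strand.x >= length:
            strand.attached = False  # termination: RNAP leaves the template
        prev_x = strand.x if strand.attached else prev_x


# ---------------------------------------------------------------------------
# public step operations
# ---------------------------------------------------------------------------

def try_initiate_rnap(
    state: LatticeState, t: float, trailing_x: int | None = None
) -> LatticeState:
    """Attempt one promoter initiation at time ``t`` (s after PFR entry).

    The first elongation step is the initiation step: it occurs only
    while ``t`` lies inside the induction window and the trailing
    polymerase (evaluated at the start of the step, ``trailing_x``) has
    cleared ``delta_x`` nucleotides.  Mutates and returns ``state``.
    """
    start, end = state.params.t_ind
    if t < start - _EPS or t > end + _EPS:
        return state
    if trailing_x is None:
        trailing_x = state.trailing_rnap_x()
    if trailing_x is not None and trailing_x < state.params.delta_x:
        return state
    strand = _Strand(state.n_genes)
    state.strands.append(strand)
    state.n_initiated += 1
    # degenerate single-nucleotide "operon": immediate termination
    if strand.x >= state.operon.length:
        strand.attached = False
    return state


def _species_passes(acc: float, velocity: float, dt: float) -> tuple[int, float]:
    acc += velocity * dt
    n = int(acc + _EPS)
    return n, acc - n


def step_rnases(state: LatticeState, dt: float | None = None) -> LatticeState:
    """Advance all RNases by ``velo_rnase * dt`` nucleotides."""
    dt = state.params.dt if dt is None else dt
    n, state.acc_rnase = _species_passes(state.acc_rnase, state.params.velo_rnase, dt)
    for _ in range(n):
        _rnase_pass(state)
    return state


def step_ribosomes(state: LatticeState, dt: float | None = None) -> LatticeState:
    """Advance all ribosomes and perform pending quota-limited loadings."""
    dt = state.params.dt if dt is None else dt
    n, state.acc_ribosome = _species_passes(
        state.acc_ribosome, state.params.velo_ribosome, dt
    )
    for _ in range(n):
        _ribosome_pass(state)
    _ribosome_initiations(state)
    return state


def step_rnaps(state: LatticeState, dt: float | None = None) -> LatticeState:
    """Advance all polymerases by ``velo_rnap * dt`` nucleotides."""
    dt = state.params.dt if dt is None else dt
    n, state.acc_rnap = _species_passes(state.acc_rnap, state.params.velo_rnap, dt)
    for _ in range(n):
        _rnap_pass(state)
    return state


def count_levels(state: LatticeState) -> tuple[list[int], list[int]]:
    """Recompute per-gene (mRNA, protein) counts from agent positions.

    A strand counts toward gene ``g`` while the gene is fully
    transcribed (``L >= c_end``) and its first coding nucleotide has
    not been degraded (``z < c_start``); contributions are clamped at
    zero, so a region degraded before the gene completed never counts.
    Independent of the incremental bookkeeping kept during stepping;
    used as an internal cross-check.
    """
    mrna = [0] * state.n_genes
    for strand in state.strands:
        if not strand.alive:
            continue
        for gi in range(state.n_genes):
            if strand.x >= state.c_end[gi] and strand.z < state.c_start[gi]:
                mrna[gi] += 1
    return mrna, list(state.protein)


# ---------------------------------------------------------------------------
# episode driver and trace
# ---------------------------------------------------------------------------

@dataclass
class SingleCellTrace:
    """Per-gene mRNA/protein time courses of one induction episode.

    The trace is the shared look-up table: every cell flagged at
    ``t_flag`` contributes ``mrna[g, round((t - t_flag)/dt)]`` transcripts
    while ``t - t_flag <= episode_length``, and holds its final protein
    gain ``protein[g, -1]`` forever after.
    """

    gene_names: tuple[str, ...]
    times: np.ndarray          # s since PFR entry, step dt
    mrna: np.ndarray           # (n_genes, n_times) int32, intact-gene readout
    mrna_partial: np.ndarray   # (n_genes, n_times) int32, presence readout
    protein: np.ndarray        # (n_genes, n_times) int32
    initiations: np.ndarray    # cumulative promoter initiations, int32
    dt: float
    episode_length: float      # s; last mRNA nucleotide degraded
    n_strands: int             # transcripts initiated
    truncated: bool = False

    def gene_index(self, gene: int | str) -> int:
        if isinstance(gene, str):
            return self.gene_names.index(gene)
        return gene

    def mrna_at(
        self, gene: int | str, elapsed: float, readout: str = "intact"
    ) -> int:
        """Episode mRNA level ``elapsed`` seconds after PFR entry.

        ``readout="intact"`` counts transcripts whose gene region is
        fully synthesized and untouched by the RNase (the level entering
        the population superposition); ``"presence"`` counts transcripts
        with any part of the region remaining, which is what a
        hybridization measurement sees.
        """
        if elapsed < 0 or elapsed > self.episode_length:
            return 0
        idx = min(int(round(elapsed / self.dt)), self.times.size - 1)
        table = self.mrna if readout == "intact" else self.mrna_partial
        return int(table[self.gene_index(gene), idx])

    def protein_at(self, gene: int | str, elapsed: float) -> int:
        """Episode protein gain; holds the terminal value past the episode."""
        gi = self.gene_index(gene)
        if elapsed < 0:
            return 0
        idx = min(int(round(elapsed / self.dt)), self.times.size - 1)
        return int(self.protein[gi, idx])

    @property
    def final_protein(self) -> dict[str, int]:
        return {
            name: int(self.protein[gi, -1])
            for gi, name in enumerate(self.gene_names)
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time_s, gene, mrna_count, protein_count."""
        n_genes, n_times = self.mrna.shape
        return pd.DataFrame(
            {
                "time_s": np.tile(self.times, n_genes),
                "gene": np.repeat(self.gene_names, n_times),
                "mrna_count": self.mrna.ravel(),
                "mrna_present_count": self.mrna_partial.ravel(),
                "protein_count": self.protein.ravel(),
            }
        )

    def to_tsv(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_episode(
    params: SimulationParameters,
    operon: OperonDefinition,
    horizon: float = 1200.0,
    check_invariants: bool = False,
) -> SingleCellTrace:
    """Run one full induction episode and return its look-up table.

    The episode starts at PFR entry (t = 0) and ends when the last
    transcript nucleotide has been degraded.  ``horizon`` bounds the
    simulated time; if it is reached with transcripts still present the
    trace is flagged ``truncated`` and a warning is emitted.

    With ``check_invariants`` the incremental per-gene counters are
    compared against :func:`count_levels` and agent spacings are
    asserted every step (slow; meant for tests).
    """
    state = LatticeState(params, operon)
    dt = params.dt
    _, t_end = params.t_ind
    n_genes = state.n_genes

    times: list[float] = []
    mrna_rows: list[list[int]] = []
    partial_rows: list[list[int]] = []
    protein_rows: list[list[int]] = []
    inits: list[int] = []
    episode_length = 0.0
    truncated = False

    max_ticks = int(np.ceil(horizon / dt)) + 1
    for tick in range(max_ticks):
        t = tick * dt
        if tick > 0:
            trailing = state.trailing_rnap_x()
            step_rnases(state, dt)
            step_ribosomes(state, dt)
            step_rnaps(state, dt)
            try_initiate_rnap(state, t, trailing_x=trailing)
        elif 0.0 >= params.t_ind[0] - _EPS:
            try_initiate_rnap(state, 0.0)

        times.append(t)
        mrna_rows.append(list(state.mrna))
        partial_rows.append(list(state.mrna_partial))
        protein_rows.append(list(state.protein))
        inits.append(state.n_initiated)

        if check_invariants:
            _assert_invariants(state)

        if t > t_end + _EPS and not state.any_alive():
            episode_length = t
            break
    else:
        truncated = state.any_alive()
        episode_length = times[-1]
        if truncated:
            warnings.warn(
                "episode horizon reached with undegraded transcripts; "
                "trace is truncated",
                stacklevel=2,
            )

    return SingleCellTrace(
        gene_names=operon.names,
        times=np.asarray(times),
        mrna=np.asarray(mrna_rows, dtype=np.int32).T.copy(),
        mrna_partial=np.asarray(partial_rows, dtype=np.int32).T.copy(),
        protein=np.asarray(protein_rows, dtype=np.int32).T.copy(),
        initiations=np.asarray(inits, dtype=np.int32),
        dt=dt,
        episode_length=episode_length,
        n_strands=state.n_initiated,
        truncated=truncated,
    )


def _assert_invariants(state: LatticeState) -> None:
    mrna, protein = count_levels(state)
    assert mrna == state.mrna, "incremental mRNA counters drifted"
    assert protein == state.protein
    min_gap_x = state.params.delta_x - 1
    prev = None
    for strand in state.strands:
        if strand.attached:
            if prev is not None:
                assert prev - strand.x >= min_gap_x, "RNAP spacing violated"
            prev = strand.x
        ys = strand.ribosomes
        for a, b in zip(ys, ys[1:]):
            assert a - b >= state.params.delta_y - 1, "ribosome spacing violated"
        if strand.alive and ys:
            # ribosomes may load right next to a gated RNase, but the
            # RNase itself never advances past (or onto) a ribosome
            assert ys[-1] > strand.z
        if strand.alive:
            assert 0 <= strand.z <= strand.x
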