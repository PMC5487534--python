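"""Superposition of the episode over the population and the census."""

from __future__ import annotations

import math

import numpy as np
import pytest

from strpfr.config import ReactorConfig
from strpfr.coupling import (
    cell_mrna,
    cell_protein,
    induction_census,
    mean_induction_census,
    pfr_port_profile,
    population_trajectory,
)
from strpfr.population import CellRecord, run_population


def _cell(flags, born=0.0, removed=math.inf, cid=0) -> CellRecord:
    return CellRecord(id=cid, born_at=born, flags=list(flags), removed_at=removed)


class TestPerCellLookups:
    def test_flagless_cell_is_silent(self, episode):
        cell = _cell([])
        assert cell_mrna(cell, episode, "trpA", 1000.0) == 0
        assert cell_protein(cell, episode, "trpA", 1000.0) == 0

    def test_single_flag_is_a_shifted_lookup(self, episode):
        cell = _cell([100.0])
        t = 100.0 + 450.0
        assert cell_mrna(cell, episode, "trpA", t) == episode.mrna_at("trpA", 450.0)
        assert (
            cell_protein(cell, episode, "trpE", t)
            == episode.protein_at("trpE", 450.0)
        )

    def test_two_active_flags_add(self, episode):
        cell = _cell([0.0, 200.0])
        t = 430.0
        expected = episode.mrna_at("trpA", 430.0) + episode.mrna_at("trpA", 230.0)
        assert cell_mrna(cell, episode, "trpA", t) == expected

    def test_finished_episode_holds_terminal_protein(self, episode):
        delta_t = episode.episode_length
        cell = _cell([0.0])
        assert (
            cell_protein(cell, episode, "trpB", 2 * delta_t)
            == episode.final_protein["trpB"]
        )

    def test_k_finished_flags_give_k_terminal_values(self, episode):
        delta_t = episode.episode_length
        flags = [0.0, 600.0, 1200.0]
        cell = _cell(flags)
        t = 1200.0 + delta_t + 10.0
        assert (
            cell_protein(cell, episode, "trpC", t)
            == len(flags) * episode.final_protein["trpC"]
        )

    def test_future_flags_do_not_contribute(self, episode):
        cell = _cell([500.0])
        assert cell_mrna(cell, episode, "trpL", 100.0) == 0
        assert cell_protein(cell, episode, "trpL", 100.0) == 0


class TestSuperpositionOracle:
    def test_population_totals_equal_brute_force_sum(self, smallpop, episode):
        """Linearity: the vectorized trajectory equals the per-cell sum."""
        grid = np.array([0.0, 200.0, 600.0, 1000.0, 1500.0, 1799.0])
        expr = population_trajectory(smallpop, episode, grid)
        for ti, t in enumerate(grid):
            live = [c for c in smallpop.cells if c.born_at <= t < c.removed_at]
            assert expr.n_live[ti] == len(live)
            for gene in episode.gene_names:
                gi = expr.gene_index(gene)
                brute_m = sum(cell_mrna(c, episode, gene, t) for c in live)
                brute_p = sum(cell_protein(c, episode, gene, t) for c in live)
                assert expr.mrna_total[gi, ti] == brute_m
                assert expr.protein_total[gi, ti] == brute_p

    def test_flagless_population_is_identically_zero(self, episode):
        reactor = ReactorConfig(n0=50, q_pfr=0.0)
        pop = run_population(reactor, 1200.0, seed=2)
        expr = population_trajectory(pop, episode, np.arange(0.0, 1200.0, 100.0))
        assert expr.mrna_total.sum() == 0
        assert expr.protein_total.sum() == 0


class TestPortProfile:
    def test_downstream_genes_absent_at_all_ports(self, episode):
        """Within the PFR only the leader and trpE can have appeared."""
        profile = pfr_port_profile(episode, ports=(31.0, 70.0, 110.0))
        downstream = profile[profile.gene.isin(["trpD", "trpC", "trpB", "trpA"])]
        assert (downstream.mrna_intact == 0).all()
        assert (downstream.mrna_present == 0).all()

    def test_port_zero_precedes_the_induction_delay(self, episode):
        profile = pfr_port_profile(episode, ports=(0.0,))
        assert (profile.mrna_intact == 0).all()
        assert (profile.mrna_present == 0).all()

    def test_nascent_trpE_visible_late_in_the_loop(self, episode):
        profile = pfr_port_profile(episode, ports=(110.0,))
        trpE = profile[profile.gene == "trpE"]
        assert int(trpE.mrna_present.iloc[0]) > 0

    def test_port_beyond_residence_time_rejected(self, episode):
        with pytest.raises(ValueError):
            pfr_port_profile(episode, ports=(130.0,), tau_pfr=125.0)


class TestInductionCensus:
    def test_initial_population_fully_naive(self, pop2h, episode):
        census = induction_census(pop2h, episode, 0.0)
        assert census.frac_not_induced == 1.0

    def test_fractions_sum_to_one(self, pop2h, episode):
        for t in (600.0, 1800.0, 5400.0):
            census = induction_census(pop2h, episode, t)
            assert (
                census.frac_not_induced + census.frac_once + census.frac_multiple
                == pytest.approx(1.0, abs=1e-12)
            )

    def test_census_invariant_to_cell_relabeling(self, smallpop, episode):
        t = 1500.0
        ref = induction_census(smallpop, episode, t)
        relabeled = type(smallpop)(
            reactor=smallpop.reactor,
            seed=smallpop.seed,
            duration=smallpop.duration,
            times=smallpop.times,
            n_str=smallpop.n_str,
            n_pfr=smallpop.n_pfr,
            cells=list(reversed([
                CellRecord(
                    id=len(smallpop.cells) - 1 - c.id,
                    born_at=c.born_at,
                    flags=list(c.flags),
                    removed_at=c.removed_at,
                )
                for c in smallpop.cells
            ])),
            event_log=[
                (tt, kind, len(smallpop.cells) - 1 - cid)
                for tt, kind, cid in smallpop.event_log
            ],
        )
        out = induction_census(relabeled, episode, t)
        assert out.as_tuple() == ref.as_tuple()

    def test_tiny_pfr_flow_leaves_population_uninduced(self, episode):
        reactor = ReactorConfig(n0=400, q_pfr=0.05)
        pop = run_population(reactor, 3600.0, seed=6)
        census = mean_induction_census(pop, episode, 1800.0, 3600.0, 300.0)
        assert census.frac_not_induced > 0.95


class TestTimescales:
    def test_mrna_settles_within_two_episode_lengths(self, pop2h, episode):
        grid = np.arange(0.0, 7200.0 + 1, 30.0)
        expr = population_trajectory(pop2h, episode, grid)
        total = expr.mrna_per_cell.sum(axis=0)
        plateau = total[grid >= 1800.0].mean()
        window = total[(grid >= episode.episode_length) & (grid <= 2 * episode.episode_length)]
        assert abs(window.mean() - plateau) / plateau < 0.05
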