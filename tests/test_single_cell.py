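"""The deterministic lattice engine: motion rules, counting, episodes."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest

from strpfr.config import GeneRegion, OperonDefinition, SimulationParameters
from strpfr.single_cell import (
    LatticeState,
    count_levels,
    simulate_episode,
    step_rnaps,
    try_initiate_rnap,
)


def _tiny_operon() -> OperonDefinition:
    return OperonDefinition(
        length=400,
        genes=(GeneRegion("leader", 10, 40, 0), GeneRegion("gene1", 60, 380, 2)),
    )


def _state_with_rnaps(positions, operon=None, **param_kw) -> LatticeState:
    """Lattice with polymerases planted at given descending positions."""
    state = LatticeState(
        SimulationParameters(**param_kw), operon or _tiny_operon()
    )
    for x in positions:
        try_initiate_rnap(state, t=state.params.t_ind[0])
        state.strands[-1].x = x
    return state


class TestRnapMotion:
    def test_lone_polymerase_advances_at_elongation_rate(self):
        state = _state_with_rnaps([500], operon=OperonDefinition(
            length=6726, genes=(GeneRegion("g", 10, 6726, 0),)))
        step_rnaps(state, dt=1.0)
        assert state.strands[0].x == 521  # 21 nt per second

    def test_follower_halts_inside_minimum_spacing(self):
        state = _state_with_rnaps([380, 300])
        dt = state.params.dt
        step_rnaps(state, dt=dt)  # one single-nucleotide pass
        assert state.strands[0].x == 381
        assert state.strands[1].x == 300  # gap 80 < delta_x

    def test_termination_detaches_polymerase(self):
        operon = _tiny_operon()
        state = _state_with_rnaps([operon.length - 1], operon=operon)
        step_rnaps(state, dt=state.params.dt)
        assert state.strands[0].x == operon.length
        assert not state.strands[0].attached


class TestInitiation:
    def test_no_initiation_before_induction_delay(self):
        state = LatticeState(SimulationParameters(), _tiny_operon())
        try_initiate_rnap(state, t=20.0)
        assert state.n_initiated == 0

    def test_no_initiation_after_window_closes(self):
        state = LatticeState(SimulationParameters(), _tiny_operon())
        try_initiate_rnap(state, t=126.0)
        assert state.n_initiated == 0

    def test_blocked_by_trailing_polymerase_inside_spacing(self):
        state = _state_with_rnaps([50])
        try_initiate_rnap(state, t=40.0)
        assert state.n_initiated == 1  # 50 < delta_x blocks the promoter

    def test_initiates_once_spacing_cleared(self):
        state = _state_with_rnaps([100])
        try_initiate_rnap(state, t=40.0)
        assert state.n_initiated == 2
        assert state.strands[-1].x == 1  # initiation is the first step


class TestCountLevels:
    def test_empty_lattice_all_zero(self, params, operon):
        state = LatticeState(params, operon)
        mrna, protein = count_levels(state)
        assert mrna == [0] * 6 and protein == [0] * 6

    def test_complete_undegraded_strand_counts_every_gene(self, params, operon):
        state = _state_with_rnaps([operon.length], operon=operon)
        state.strands[0].attached = False
        mrna, _ = count_levels(state)
        assert mrna == [1] * 6

    def test_rnase_past_leader_start_uncounts_leader_only(self, params, operon):
        state = _state_with_rnaps([operon.length], operon=operon)
        state.strands[0].attached = False
        state.strands[0].z = operon["trpL"].c_start
        mrna, _ = count_levels(state)
        assert mrna == [0, 1, 1, 1, 1, 1]


class TestDefaultEpisode:
    """One PFR-triggered induction with the standard parameter set."""

    def test_twenty_full_operon_transcripts(self, episode):
        assert episode.n_strands == 20
        assert not episode.truncated

    def test_final_protein_counts_follow_quota(self, episode):
        assert episode.final_protein == {
            "trpL": 0, "trpE": 80, "trpD": 80, "trpC": 100, "trpB": 200,
            "trpA": 200,
        }

    def test_episode_spans_one_reactor_cycle(self, episode):
        # all transcripts degraded shortly before the ~497 s cycle closes
        assert 480.0 <= episode.episode_length <= 500.0

    def test_protein_traces_monotone_no_decay(self, episode):
        assert (np.diff(episode.protein, axis=1) >= 0).all()

    def test_mrna_nonnegative_and_gone_at_end(self, episode):
        assert (episode.mrna >= 0).all()
        assert (episode.mrna[:, -1] == 0).all()
        assert (episode.mrna_partial >= 0).all()
        assert (episode.mrna_partial[:, -1] == 0).all()

    def test_only_trpA_retains_intact_transcripts_late(self, episode):
        """Gene length vs quota*spacing makes trpA the lone late residual."""
        late = episode.times >= 400.0
        assert episode.mrna[episode.gene_index("trpA"), late].max() > 0
        for gene in ("trpE", "trpD", "trpC", "trpB"):
            assert episode.mrna[episode.gene_index(gene)].max() == 0

    def test_determinism_bit_identical(self, params, operon, episode):
        again = simulate_episode(params, operon)
        assert np.array_equal(again.mrna, episode.mrna)
        assert np.array_equal(again.protein, episode.protein)
        assert again.episode_length == episode.episode_length

    def test_invariants_hold_throughout(self, params, operon):
        """Spacings, counter consistency and ordering, asserted per step."""
        trace = simulate_episode(params, operon, check_invariants=True)
        assert trace.n_strands == 20


class TestClosedFormInitiation:
    @pytest.mark.parametrize(
        "window, velocity, spacing",
        [((30.0, 125.0), 21, 100), ((10.0, 60.0), 30, 120), ((0.0, 45.0), 14, 70)],
    )
    def test_unblocked_train_matches_closed_form(self, window, velocity, spacing):
        params = SimulationParameters(
            velo_rnap=velocity, velo_ribosome=velocity, velo_rnase=velocity,
            delta_x=spacing, delta_y=spacing, delta_z=spacing, t_ind=window,
        )
        operon = OperonDefinition(
            length=3000, genes=(GeneRegion("g", 10, 3000, 0),)
        )
        trace = simulate_episode(params, operon, horizon=window[1] + 3000 / velocity + 60)
        expected = 1 + math.floor((window[1] - window[0]) * velocity / spacing)
        assert trace.n_strands == expected


class TestSmallWindows:
    def test_zero_width_window_single_transcript(self, operon):
        params = SimulationParameters(t_ind=(30.0, 30.0))
        trace = simulate_episode(params, operon)
        assert trace.n_strands == 1
        assert trace.final_protein == {
            g.name: g.n_tl_max for g in operon
        }

    def test_short_horizon_flags_truncation(self, params, operon):
        with pytest.warns(UserWarning, match="truncated"):
            trace = simulate_episode(params, operon, horizon=50.0)
        assert trace.truncated


class TestRandomOperons:
    def test_every_strand_delivers_its_full_quota(self):
        """Degradation is gated on quota completion, so final protein
        is exactly (strand count) x (per-gene quota) for any operon."""
        rng = random.Random(42)
        for _ in range(6):
            genes, cursor = [], 1
            for gi in range(rng.randint(2, 4)):
                start = cursor + rng.randint(5, 40)
                end = start + rng.randint(120, 400)
                genes.append(
                    GeneRegion(f"g{gi}", start, end, rng.randint(0, 5))
                )
                cursor = end
            operon = OperonDefinition(length=cursor + rng.randint(0, 50),
                                      genes=tuple(genes))
            params = SimulationParameters(t_ind=(10.0, 40.0))
            trace = simulate_episode(params, operon, horizon=900.0)
            assert not trace.truncated
            assert trace.final_protein == {
                g.name: trace.n_strands * g.n_tl_max for g in operon
            }
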