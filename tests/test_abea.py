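import math

import numpy as np
import pytest

import squigalign as sq
from squigalign.abea import NEG_INF, BandState, Direction, Trace
from squigalign.event_detection import Event

from conftest import make_instance


class TestCountBands:
    @pytest.mark.parametrize(
        "n_events,n_kmers,expected", [(13, 6, 18), (1, 1, 1), (5, 3, 7)]
    )
    def test_formula(self, n_events, n_kmers, expected):
        assert sq.count_bands(n_events, n_kmers) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sq.count_bands(0, 5)
        with pytest.raises(ValueError):
            sq.count_bands(5, -1)


class TestDefaultTransitions:
    def test_balanced_read_stays_half(self):
        t = sq.default_transitions(100, 100)
        assert t.lp_stay == pytest.approx(math.log(0.5))

    def test_two_events_per_kmer(self):
        t = sq.default_transitions(200, 100)
        assert math.exp(t.lp_stay) == pytest.approx(2 / 3)

    def test_move_probabilities_sum_to_one(self):
        t = sq.default_transitions(137, 55)
        total = math.exp(t.lp_step) + math.exp(t.lp_stay) + math.exp(t.lp_skip)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sq.TransitionParams(
                lp_step=math.log(0.9), lp_stay=math.log(0.9),
                lp_skip=math.log(0.1), lp_trim=math.log(0.01),
            )


class TestBandMove:
    def _band(self, ll_score, ur_score, W=4):
        b = BandState.blank(W, (0, 0))
        b.scores[0] = ll_score
        b.scores[W - 1] = ur_score
        return b

    def test_upper_right_better_moves_right(self):
        assert sq.band_move(self._band(-3.0, -1.0), 4) == Direction.RIGHT

    def test_lower_left_better_moves_down(self):
        assert sq.band_move(self._band(-1.0, -3.0), 4) == Direction.DOWN

    def test_tie_moves_down(self):
        assert sq.band_move(self._band(-1.0, -1.0), 4) == Direction.DOWN

    @pytest.mark.parametrize("idx,expected", [(5, Direction.RIGHT), (4, Direction.DOWN)])
    def test_both_ends_outside_alternates_by_parity(self, idx, expected):
        assert sq.band_move(self._band(NEG_INF, NEG_INF), idx) == expected


class TestAlignment:
    def test_single_cell_perfect_match(self, m2):
        # one event at the scaled model level: the only path is
        # origin -> (0,0) via DIAG, scoring lp_step + emission-at-mean
        seq = "AC"
        rank = sq.kmer_rank("AC")
        ev = [Event(0, 10, m2.mean(rank), 0.0)]
        trans = sq.default_transitions(1, 1)
        a = sq.abea_align(ev, seq, m2, sq.ScalingParams(), W=8, trans=trans)
        assert a.pairs == [(0, 0)]
        lp = sq.log_prob_emission(ev[0].mean, rank, m2, sq.ScalingParams())
        assert a.score == pytest.approx(trans.lp_step + lp)

    def test_fig2_geometry_band_count(self, m2):
        # 13 events x 6 k-mers: bands b0..b17 over the table proper plus
        # the two seed bands and the band past the corner
        rng = np.random.default_rng(0)
        seq = sq.random_sequence(7, seed=1)
        ev = [Event(i * 10, 10, float(x), 0.0) for i, x in enumerate(rng.uniform(70, 120, 13))]
        a, bands = sq.abea_align(ev, seq, m2, sq.ScalingParams(), W=30, return_bands=True)
        assert len(bands) == 13 + 6 + 2
        table_proper = [
            b for b in bands if 0 <= sum(b.lower_left) <= 13 + 6 - 2
        ]
        assert len(table_proper) == sq.count_bands(13, 6) == 18

    def test_band_chain_single_steps(self, m2):
        events, seq, trans = make_instance(2, m2)
        _, bands = sq.abea_align(
            events, seq, m2, sq.ScalingParams(), W=16, trans=trans, return_bands=True
        )
        for prev, curr in zip(bands, bands[1:]):
            de = curr.lower_left[0] - prev.lower_left[0]
            dk = curr.lower_left[1] - prev.lower_left[1]
            assert (de, dk) in [(1, 0), (0, 1)]  # one DOWN or one RIGHT

    def test_monotone_pairs(self, m2):
        for seed in range(6):
            events, seq, trans = make_instance(seed, m2)
            a = sq.abea_align(events, seq, m2, sq.ScalingParams(), trans=trans)
            for (e0, q0), (e1, q1) in zip(a.pairs, a.pairs[1:]):
                assert (e1 - e0, q1 - q0) in [(1, 1), (1, 0), (0, 1)]
            assert len(set(a.pairs)) == len(a.pairs)

    def test_determinism(self, m2):
        events, seq, trans = make_instance(4, m2)
        a = sq.abea_align(events, seq, m2, sq.ScalingParams(), trans=trans)
        b = sq.abea_align(events, seq, m2, sq.ScalingParams(), trans=trans)
        assert a.score == b.score and a.pairs == b.pairs and a.moves == b.moves

    def test_fill_band_matches_oracle_cells(self, m2):
        # every in-band cell of a wide-band run must hold the value of the
        # unbanded recurrence (checked via the full-table oracle scores)
        rng = np.random.default_rng(7)
        seq = sq.random_sequence(6, seed=7)  # 5 k-mers
        ev = [Event(i * 10, 10, float(x), 0.0) for i, x in enumerate(rng.uniform(70, 120, 8))]
        trans = sq.default_transitions(8, 5)
        _, bands = sq.abea_align(
            ev, seq, m2, sq.ScalingParams(), W=30, trans=trans, return_bands=True
        )
        # walk every banded cell that lies in the table
        for band in bands:
            ll_e, ll_k = band.lower_left
            for o in range(band.width):
                e, q = ll_e - o, ll_k + o
                if 0 <= e < 8 and 0 <= q < 5 and band.scores[o] > NEG_INF:
                    cell = _oracle_cell(ev, seq, m2, trans, e, q)
                    assert band.scores[o] == pytest.approx(cell, abs=1e-9)

    def test_unreachable_last_column_yields_failed_alignment(self, m2):
        # with skips forbidden, a single event can never cross three
        # k-mers, so no finite score reaches the last column
        seq = sq.random_sequence(4, seed=9)  # 3 k-mers
        ev = [Event(0, 10, 95.0, 0.0)]
        trans = sq.TransitionParams(
            lp_step=math.log(0.5),
            lp_stay=math.log(0.5 - 1e-12),
            lp_skip=float("-inf"),
            lp_trim=math.log(0.01),
        )
        a = sq.abea_align(ev, seq, m2, sq.ScalingParams(), W=16, trans=trans)
        assert a.pairs == [] and not a.qc_pass and a.score == NEG_INF

    def test_qc_requires_full_kmer_span(self, m2):
        events, seq, trans = make_instance(6, m2)
        a = sq.abea_align(events, seq, m2, sq.ScalingParams(), trans=trans)
        ok, avg = sq.qc_check(a, trans)
        assert ok == a.qc_pass and avg == pytest.approx(a.avg_log_emission)
        # an alignment that never reaches k-mer 0 must fail QC
        clipped = sq.EventAlignment(
            pairs=[(e, q) for e, q in a.pairs if q > 0],
            score=a.score,
            moves=[m for (e, q), m in zip(a.pairs, a.moves) if q > 0],
            emissions=[x for (e, q), x in zip(a.pairs, a.emissions) if q > 0],
            n_kmers=a.n_kmers,
        )
        if clipped.pairs:
            assert not sq.qc_check(clipped, trans)[0]

    def test_wrong_sequence_fails_qc(self, m6):
        # events simulated from one sequence, aligned against an unrelated
        # one: the average emission collapses below the QC floor
        seq_true = sq.random_sequence(300, seed=21)
        seq_wrong = sq.random_sequence(300, seed=22)
        ev, _ = sq.simulate_events(
            seq_true, m6, sq.ScalingParams(), sq.SimParams(seed=21)
        )
        a = sq.abea_align(ev, seq_wrong, m6, sq.ScalingParams(), W=100)
        assert a.avg_log_emission < -5.0
        assert not a.qc_pass


def _oracle_cell(events, seq, model, trans, e_target, q_target):
    """Unbanded recurrence value of one cell, by independent full table."""
    ranks = [int(r) for r in sq.seq_to_kmer_ranks(seq, model.k)]
    n_e, n_k = len(events), len(ranks)
    S = np.full((n_e + 1, n_k + 1), NEG_INF)
    S[0, 0] = 0.0
    for e in range(n_e):
        S[e + 1, 0] = (e + 1) * trans.lp_trim
    for e in range(n_e):
        for q in range(n_k):
            mu = model.mean(ranks[q])
            sd = model.stdv(ranks[q])
            lp = -0.5 * math.log(2 * math.pi) - math.log(sd) - 0.5 * ((events[e].mean - mu) / sd) ** 2
            S[e + 1, q + 1] = max(
                S[e, q] + trans.lp_step + lp,
                S[e, q + 1] + trans.lp_stay + lp,
                S[e + 1, q] + trans.lp_skip,
            )
    return S[e_target + 1, q_target + 1]
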