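"""Lifting-gate fluid semantics: mixing, splitting, conservation."""

import numpy as np
import pytest

import liftgate as lg
from liftgate.chip import (
    ChipState,
    FluidParcel,
    FluidicsError,
    VirtualChip,
    close_valve,
    load_inlet,
    open_valve,
    run_protocol,
    topology_from_dict,
)


def three_valve_chain():
    """Tiny rig: inlet well -> v1 - v2 - v3, detection channel after v3."""
    return topology_from_dict(
        {
            "name": "chain3",
            "n_valves": 3,
            "valve_capacity_nl": 10.0,
            "detection_node": "det",
            "reservoirs": {"IN": "INLET", "OUT": "OUTLET"},
            "edges": [["IN", "v1"], ["v1", "v2"], ["v2", "v3"], ["v3", "det"], ["det", "OUT"]],
        }
    )


@pytest.fixture()
def chain_state():
    return ChipState(topology=three_valve_chain())


class TestTopology:
    def test_default_chip_dimensions(self, topology):
        assert topology.n_valves == 15
        assert len(topology.reservoirs) == 6
        assert sum(r == "INLET" for r in topology.reservoirs.values()) == 3

    def test_default_chip_graph_is_sound(self, topology):
        topology.validate()  # connected, symmetric, detection reachable

    def test_asymmetric_edge_rejected(self):
        with pytest.raises(FluidicsError, match="symmetric"):
            lg.ChipTopology(
                n_valves=1, reservoirs={"IN": "INLET"},
                adjacency={"IN": frozenset({"v1"}), "v1": frozenset()},
                detection_node="v1",
            ).validate()


class TestLoadInlet:
    def test_load_credits_the_well(self, chain_state):
        load_inlet(chain_state, "IN", "ecoli_pbs", 2000.0)
        assert chain_state.parcel_at("IN").volume_nl == 2000.0
        assert chain_state.reservoir_loaded["IN"] == {"ecoli_pbs": 2000.0}

    def test_sequential_loads_accumulate(self, chain_state):
        load_inlet(chain_state, "IN", "pbs", 1000.0)
        load_inlet(chain_state, "IN", "pbs", 500.0)
        assert chain_state.reservoir_loaded["IN"] == {"pbs": 1500.0}
        assert chain_state.parcel_at("IN").volume_nl == 1500.0

    def test_zero_volume_rejected(self, chain_state):
        with pytest.raises(FluidicsError):
            load_inlet(chain_state, "IN", "pbs", 0.0)

    def test_outlet_cannot_be_loaded(self, chain_state):
        with pytest.raises(FluidicsError, match="OUTLET"):
            load_inlet(chain_state, "OUT", "pbs", 10.0)


class TestOpenClose:
    def test_open_draws_up_to_capacity_from_inlet_well(self, chain_state):
        load_inlet(chain_state, "IN", "dye", 2000.0)
        open_valve(chain_state, 1)
        assert chain_state.parcel_at("v1").volume_nl == pytest.approx(10.0)
        assert chain_state.parcel_at("IN").volume_nl == pytest.approx(1990.0)

    def test_open_on_open_is_a_noop(self, chain_state):
        load_inlet(chain_state, "IN", "dye", 2000.0)
        open_valve(chain_state, 1)
        before = chain_state.parcel_at("v1").volume_nl
        open_valve(chain_state, 1)
        assert chain_state.parcel_at("v1").volume_nl == before

    def test_merge_is_volume_weighted(self):
        a = FluidParcel(10.0, {"A": 1.0})
        b = FluidParcel(10.0, {"B": 1.0})
        m = a.merge(b)
        assert m.volume_nl == 20.0
        assert m.composition == {"A": 0.5, "B": 0.5}

    def test_close_splits_equally_between_open_neighbours(self):
        # star: v1 holds 10 nL, v2 and v3 open on either side
        topo = topology_from_dict(
            {
                "name": "star", "n_valves": 3, "detection_node": "det",
                "reservoirs": {"IN": "INLET"},
                "edges": [["IN", "v1"], ["v2", "v1"], ["v1", "v3"],
                          ["v3", "det"], ["v2", "det"]],
            }
        )
        state = ChipState(topology=topo)
        load_inlet(state, "IN", "dye", 10.0)
        open_valve(state, 1)        # draws all 10 nL
        open_valve(state, 2)
        open_valve(state, 3)
        close_valve(state, 1)       # IN well is empty; v2, v3 open; IN still open end
        # neighbours: IN (reservoir, open end), v2, v3 -> three-way split
        for node in ("IN", "v2", "v3"):
            assert state.parcel_at(node).volume_nl == pytest.approx(10.0 / 3)
            assert state.parcel_at(node).composition == {"dye": 1.0}

    def test_close_empty_valve_moves_nothing(self, chain_state):
        close_valve(chain_state, 2)
        assert chain_state.parcel_at("v2").is_empty()
        assert chain_state.warnings == []

    def test_close_with_no_open_neighbour_traps_with_warning(self, chain_state):
        load_inlet(chain_state, "IN", "dye", 5.0)
        open_valve(chain_state, 2)  # nothing to draw mid-chain
        # move fluid to v2 via v1, then seal both sides of v2
        open_valve(chain_state, 1)
        close_valve(chain_state, 1)     # splits between IN and v2 -> v2 gets 2.5
        held = chain_state.parcel_at("v2").volume_nl
        assert held == pytest.approx(2.5)
        close_valve(chain_state, 2)     # v1 and v3 closed: nowhere to go
        assert chain_state.trapped["v2"].volume_nl == pytest.approx(held)
        assert any("trapped" in w for w in chain_state.warnings)
        # reopening reclaims the audit parcel
        open_valve(chain_state, 2)
        assert "v2" not in chain_state.trapped
        assert chain_state.parcel_at("v2").volume_nl == pytest.approx(held)

    def test_relocation_matches_hand_ledger_on_three_valve_chain(self, chain_state):
        """Close toward one neighbour, reopen, close toward the other; the
        full parcel ends where the hand-computed ledger says."""
        load_inlet(chain_state, "IN", "dye", 10.0)
        open_valve(chain_state, 1)                   # v1: 10
        open_valve(chain_state, 2)
        close_valve(chain_state, 1)                  # split IN/v2 -> v2: 5, IN: 5
        assert chain_state.parcel_at("v2").volume_nl == pytest.approx(5.0)
        open_valve(chain_state, 3)
        close_valve(chain_state, 2)                  # v1 closed, v3 open -> v3: 5
        assert chain_state.parcel_at("v3").volume_nl == pytest.approx(5.0)
        close_valve(chain_state, 3)                  # only det open -> delivered
        assert chain_state.parcel_at("det").volume_nl == pytest.approx(5.0)
        assert chain_state.parcel_at("det").composition == {"dye": 1.0}

    def test_unknown_valve_rejected(self, chain_state):
        with pytest.raises(FluidicsError):
            open_valve(chain_state, 9)


class TestConservation:
    def test_random_actuations_conserve_each_reagent(self, topology, rng):
        """Arbitrary open/close storms keep per-reagent volume balanced
        against an independent sum over wells, valves and audit fields."""
        for _ in range(30):
            state = ChipState(topology=topology)
            load_inlet(state, "R1", "ecoli_pbs", 2000.0)
            load_inlet(state, "R2", "sybr_gold", 2000.0)
            load_inlet(state, "R3", "pbs", 5000.0)
            for _ in range(200):
                vid = int(rng.integers(1, 16))
                if rng.random() < 0.5:
                    open_valve(state, vid)
                else:
                    close_valve(state, vid)
            # independent brute-force ledger over every container
            held = {}
            for parcel in list(state.contents.values()) + list(state.trapped.values()):
                for reagent, vol in parcel.reagent_volumes().items():
                    held[reagent] = held.get(reagent, 0.0) + vol
            assert held["ecoli_pbs"] == pytest.approx(2000.0, rel=1e-9)
            assert held["sybr_gold"] == pytest.approx(2000.0, rel=1e-9)
            assert held["pbs"] == pytest.approx(5000.0, rel=1e-9)

    def test_compositions_stay_normalised(self, topology, rng):
        state = ChipState(topology=topology)
        load_inlet(state, "R1", "a", 100.0)
        load_inlet(state, "R2", "b", 100.0)
        load_inlet(state, "R3", "c", 100.0)
        for _ in range(300):
            vid = int(rng.integers(1, 16))
            (open_valve if rng.random() < 0.5 else close_valve)(state, vid)
            for parcel in state.contents.values():
                if not parcel.is_empty():
                    assert all(0.0 <= f <= 1.0 + 1e-12 for f in parcel.composition.values())
                    assert sum(parcel.composition.values()) == pytest.approx(1.0, rel=1e-9)


class TestRunProtocol:
    def test_reference_staining_delivers_a_mixed_parcel(self, staining_script):
        state, trace, delivered = run_protocol(staining_script)
        assert delivered.volume_nl > 0
        assert delivered.composition["ecoli_pbs"] > 0
        assert delivered.composition["sybr_gold"] > 0
        assert trace.total_duration_ms >= 20 * 60 * 1000

    def test_script_that_never_feeds_the_detector_delivers_nothing(self):
        s = lg.parse_script("main:\n o 1\n w 100\n c 1\nend\n")
        _, _, delivered = run_protocol(s)
        assert delivered.volume_nl == 0.0

    def test_protocol_conserves_everything_loaded(self, staining_script):
        state, _, _ = run_protocol(staining_script)
        assert state.conservation_error() < 1e-9

    def test_invalid_script_is_refused(self):
        s = lg.parse_script("main:\n o 16\nend\n")
        with pytest.raises(FluidicsError, match="validation"):
            run_protocol(s)

    def test_state_snapshot_is_json(self, staining_script):
        import json

        state, _, _ = run_protocol(staining_script)
        snapshot = json.loads(state.to_json())
        assert snapshot["contents"]["detect"]["volume_nl"] > 0


class TestVirtualChipBackend:
    def test_satisfies_the_device_backend_contract(self):
        chip = VirtualChip()
        assert isinstance(chip, lg.DeviceBackend)
        assert chip.n_valves == 15

    def test_wait_advances_only_the_clock(self):
        chip = VirtualChip()
        chip.set_valve(1, True)
        before = chip.state.to_json()
        chip.advance_time(1200000)
        assert chip.state.to_json() == before
        assert chip.elapsed_ms == 1200000
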