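"""Calpha model parsing, site mapping and proximity search."""

import numpy as np
import pytest

from conftest import pdb_atom, toy_pdb
from gba1pd.structure import (
    MapStatus,
    ProximityConfig,
    ca_distance,
    find_proximal_pathogenic,
    load_ca_model,
    map_site,
)
from gba1pd.variants import parse_hgvs_p, to_mature_numbering


class TestLoadCaModel:
    def test_toy_model_roundtrip(self, toy_model_text):
        model = load_ca_model(toy_model_text, chain="A")
        assert len(model) == 4
        assert model.residue_name(1) == "ALA"
        np.testing.assert_allclose(model.coord(2), [3.0, 4.0, 0.0])

    def test_residue_without_ca_becomes_gap(self):
        text = "\n".join([
            pdb_atom(1, "CA", "ALA", 1, 0, 0, 0),
            pdb_atom(2, "N", "GLY", 2, 1, 1, 1),
            pdb_atom(3, "CA", "SER", 3, 2, 0, 0),
            "END",
        ])
        model = load_ca_model(text, chain="A")
        assert len(model) == 2
        assert model.gaps == (2,)

    def test_altloc_resolved_by_occupancy(self):
        text = "\n".join([
            pdb_atom(1, "CA", "LEU", 1, 1.0, 0, 0, occ=0.4, altloc="A"),
            pdb_atom(2, "CA", "LEU", 1, 2.0, 0, 0, occ=0.6, altloc="B"),
            "END",
        ])
        model = load_ca_model(text, chain="A")
        assert model.coord(1)[0] == 2.0

    def test_missing_chain_is_an_error(self, toy_model_text):
        with pytest.raises(ValueError, match="chain"):
            load_ca_model(toy_model_text, chain="B")


class TestMapSite:
    def test_offset_and_statuses(self, toy_model_text):
        model = load_ca_model(toy_model_text)
        assert map_site(483).mature_position == 444
        assert map_site(40, model).status is MapStatus.MAPPED
        assert map_site(40, model).mature_position == 1
        assert map_site(13, model).status is MapStatus.UNMAPPED_SIGNAL_PEPTIDE
        assert map_site(139, model).status is MapStatus.MISSING_DENSITY


class TestCaDistance:
    def test_pythagorean_triangle(self, toy_model_text):
        model = load_ca_model(toy_model_text)
        assert ca_distance(model, 1, 2) == pytest.approx(5.0)
        assert ca_distance(model, 1, 1) == 0.0
        assert ca_distance(model, 1, 3) == ca_distance(model, 3, 1)

    def test_unmapped_residue_is_an_error(self, toy_model_text):
        model = load_ca_model(toy_model_text)
        with pytest.raises(KeyError):
            ca_distance(model, 1, 99)


class TestProximity:
    def test_adjacent_known_severe_variant_hits(self):
        # p.Y61H sits one position from the known severe p.C62W
        hits = find_proximal_pathogenic("p.Y61H", ["p.C62W"])
        assert len(hits) == 1
        assert hits[0].seq_distance == 1 and hits[0].evidence == "sequence"
        hits = find_proximal_pathogenic("p.R434C", ["p.V433L", "p.W432R", "p.N435T"])
        assert {h.neighbor_hgvs_p for h in hits} == {"p.V433L", "p.W432R", "p.N435T"}

    def test_isolated_vus_has_no_hits(self, toy_model_text):
        model = load_ca_model(toy_model_text)
        assert find_proximal_pathogenic("p.A100G", ["p.L483P"], model) == []

    def test_spatial_cutoff_is_strict(self):
        # mature residues 1 and 2 are exactly 5 A apart (3-4-5 triangle)
        text = toy_pdb([(1, "ALA", (0.0, 0.0, 0.0)), (2, "GLY", (3.0, 4.0, 0.0))])
        model = load_ca_model(text)
        vus, known = "p.A40G", ["p.G41W"]
        strict = find_proximal_pathogenic(vus, known, model,
                                          ProximityConfig(seq_window=2, ca_cutoff=5.0))
        assert strict[0].evidence == "sequence"  # 1 apart in sequence, 5.0 A away
        wider = find_proximal_pathogenic(vus, known, model,
                                         ProximityConfig(seq_window=2, ca_cutoff=5.01))
        assert wider[0].evidence == "both"

    def test_signal_peptide_pairs_use_sequence_rule_only(self):
        hits = find_proximal_pathogenic("p.K13R", ["p.L14P"])
        assert hits and hits[0].evidence == "sequence"


def _random_structure(rng, n):
    return [(i + 1, "ALA", tuple(rng.uniform(0, 30, 3))) for i in range(n)]


def _brute_force_pairs(vus, known, model, config):
    """Independent oracle: exhaustive all-pairs evaluation from first principles."""
    expected = set()
    vpos = parse_hgvs_p(vus).position
    for neighbor in known:
        npos = parse_hgvs_p(neighbor).position
        hit = abs(vpos - npos) <= config.seq_window
        vm, nm = to_mature_numbering(vpos), to_mature_numbering(npos)
        if not hit and vm is not None and nm is not None:
            if model.has_mature(vm) and model.has_mature(nm):
                d = float(np.linalg.norm(model.coord(vm) - model.coord(nm)))
                hit = d < config.ca_cutoff
        if hit:
            expected.add(neighbor)
    return expected


def test_matches_brute_force_oracle_on_random_toys(rng):
    for trial in range(10):
        n = int(rng.integers(10, 50))
        model = load_ca_model(toy_pdb(_random_structure(rng, n)))
        known = [f"p.A{int(p)}G" for p in rng.integers(1, n + 45, size=8)]
        vus = f"p.L{int(rng.integers(1, n + 45))}P"
        known = [k for k in known if k != vus]
        config = ProximityConfig(seq_window=2, ca_cutoff=8.0)
        hits = {h.neighbor_hgvs_p for h in find_proximal_pathogenic(vus, known, model, config)}
        assert hits == _brute_force_pairs(vus, set(known), model, config)


def test_enlarging_thresholds_never_removes_hits(rng):
    model = load_ca_model(toy_pdb(_random_structure(rng, 40)))
    known = [f"p.A{p}G" for p in range(41, 85, 4)]
    vus = "p.L60P"
    base = {h.neighbor_hgvs_p
            for h in find_proximal_pathogenic(vus, known, model, ProximityConfig(2, 5.0))}
    for window, cutoff in [(3, 5.0), (2, 10.0), (5, 15.0)]:
        bigger = {h.neighbor_hgvs_p
                  for h in find_proximal_pathogenic(vus, known, model,
                                                    ProximityConfig(window, cutoff))}
        assert base <= bigger


def test_proximity_is_symmetric(rng):
    model = load_ca_model(toy_pdb(_random_structure(rng, 30)))
    config = ProximityConfig(2, 8.0)
    a, b = "p.A50G", "p.L52P"
    ab = find_proximal_pathogenic(a, [b], model, config)
    ba = find_proximal_pathogenic(b, [a], model, config)
    assert bool(ab) == bool(ba)
    if ab:
        assert ab[0].seq_distance == ba[0].seq_distance
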