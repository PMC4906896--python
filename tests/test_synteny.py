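import numpy as np
import pandas as pd
import pytest

from ptxmap import synteny
from ptxmap.simulate import SimConfig, simulate_anchoring_fixture, simulate_cross
from tests.conftest import true_map_table


def _map(rows):
    return pd.DataFrame(rows, columns=["marker_id", "lg", "position",
                                       "bin_id", "configuration"])


class TestAnchoring:
    def test_median_position(self):
        mt = _map([("m1", 2, 5.0, 1, "ABxAA"), ("m2", 2, 6.0, 2, "ABxAA"),
                   ("m3", 2, 7.0, 3, "ABxAA")])
        lookup = pd.DataFrame({"marker_id": ["m1", "m2", "m3"],
                               "scaffold_id": ["s1"] * 3})
        anch = synteny.anchor_scaffolds(mt, lookup)
        row = anch.table.iloc[0]
        assert row["lg"] == 2 and row["position"] == pytest.approx(6.0)

    def test_tied_vote_is_conflicted(self):
        mt = _map([("m1", 1, 5.0, 1, "ABxAA"), ("m2", 2, 6.0, 1, "ABxAA")])
        lookup = pd.DataFrame({"marker_id": ["m1", "m2"],
                               "scaffold_id": ["s1", "s1"]})
        anch = synteny.anchor_scaffolds(mt, lookup)
        assert len(anch.table) == 0
        assert anch.conflicted["scaffold_id"].tolist() == ["s1"]

    def test_fixture_scaffolds_anchor_to_true_lg(self, small_cross,
                                                 small_true_map):
        fx = simulate_anchoring_fixture(small_true_map, seed=5)
        anch = synteny.anchor_scaffolds(small_true_map, fx.marker_lookup,
                                        fx.scaffolds)
        assert len(anch.conflicted) == 0
        # every scaffold was built from consecutive markers of one LG
        truth_lg = (fx.marker_lookup
                    .merge(small_true_map, on="marker_id")
                    .groupby("scaffold_id")["lg"].first())
        placed = anch.table.set_index("scaffold_id")["lg"]
        assert (placed == truth_lg.loc[placed.index]).all()

    def test_anchored_bp_is_sum_of_lengths(self, small_true_map):
        fx = simulate_anchoring_fixture(small_true_map, seed=6)
        anch = synteny.anchor_scaffolds(small_true_map, fx.marker_lookup,
                                        fx.scaffolds)
        assert anch.anchored_bp == fx.scaffolds.set_index("scaffold_id") \
            .loc[anch.table["scaffold_id"], "length_bp"].sum()


class TestPseudomolecules:
    def test_two_scaffolds_spacer_arithmetic(self):
        mt = _map([("m1", 1, 0.0, 1, "ABxAA"), ("m2", 1, 5.0, 2, "ABxAA")])
        lookup = pd.DataFrame({"marker_id": ["m1", "m2"],
                               "scaffold_id": ["s1", "s2"]})
        anch = synteny.anchor_scaffolds(mt, lookup)
        seqs = {"s1": "A" * 1000, "s2": "G" * 1000}
        records, coords = synteny.build_pseudomolecules(anch, seqs)
        assert len(records) == 1
        name, seq = records[0]
        assert len(seq) == 2100
        assert coords["start"].tolist() == [1, 1101]
        assert coords["end"].tolist() == [1000, 2100]

    def test_coordinates_slice_back_to_input(self, small_true_map):
        fx = simulate_anchoring_fixture(small_true_map, seed=7,
                                        with_sequences=True)
        anch = synteny.anchor_scaffolds(small_true_map, fx.marker_lookup,
                                        fx.scaffolds)
        records, coords = synteny.build_pseudomolecules(anch, fx.sequences)
        by_lg = dict(records)
        rng = np.random.default_rng(0)
        for _, row in coords.sample(25, random_state=1).iterrows():
            seq = by_lg[f"pseudomolecule_LG{row['lg']}"]
            assert seq[row["start"] - 1:row["end"]] == \
                fx.sequences[row["scaffold_id"]]

    def test_missing_sequence_skipped_with_warning(self):
        mt = _map([("m1", 1, 0.0, 1, "ABxAA"), ("m2", 1, 5.0, 2, "ABxAA")])
        lookup = pd.DataFrame({"marker_id": ["m1", "m2"],
                               "scaffold_id": ["s1", "s2"]})
        anch = synteny.anchor_scaffolds(mt, lookup)
        with pytest.warns(UserWarning, match="s2"):
            records, coords = synteny.build_pseudomolecules(
                anch, {"s1": "A" * 100})
        assert len(coords) == 1


class TestHitFilter:
    @pytest.mark.parametrize("e,score,length,kept", [
        (1e-12, 85.0, 60, True),
        (1e-9, 200.0, 500, False),     # e-value fails
        (1e-10, 80.0, 50, False),      # boundary: e passes, score strict >
        (1e-10, 80.5, 50, True),
        (1e-30, 200.0, 49, False),     # length fails
    ])
    def test_boundary_semantics(self, e, score, length, kept):
        hits = pd.DataFrame([{
            "query_id": "q", "subject_id": "chr1", "percent_identity": 90.0,
            "alignment_length": length, "mismatches": 0, "gap_opens": 0,
            "query_start": 1, "query_end": length, "subject_start": 1,
            "subject_end": length, "e_value": e, "bit_score": score,
        }])
        assert (len(synteny.filter_hits(hits)) == 1) is kept


def _hit(q, chrom, start, e=1e-30, score=200.0):
    return {
        "query_id": q, "subject_id": chrom, "percent_identity": 95.0,
        "alignment_length": 300, "mismatches": 5, "gap_opens": 0,
        "query_start": 1, "query_end": 300, "subject_start": start,
        "subject_end": start + 299, "e_value": e, "bit_score": score,
    }


class TestMicrosynteny:
    def test_close_pair_detected(self):
        pos = pd.DataFrame({"cds_id": ["c1", "c2"], "scaffold_id": "s",
                            "lg": 1, "position": [3.0, 6.0]})
        hits = pd.DataFrame([_hit("c1", "chr1", 1_000_000),
                             _hit("c2", "chr1", 3_000_000)])
        blocks, pairs, _ = synteny.detect_microsynteny(pos, hits)
        assert len(pairs) == 1
        assert len(blocks) == 0  # a single pair does not make a block

    def test_distant_cds_no_pair(self):
        pos = pd.DataFrame({"cds_id": ["c1", "c2"], "scaffold_id": "s",
                            "lg": 1, "position": [0.0, 12.0]})
        hits = pd.DataFrame([_hit("c1", "chr1", 1_000_000),
                             _hit("c2", "chr1", 2_000_000)])
        _, pairs, _ = synteny.detect_microsynteny(pos, hits)
        assert len(pairs) == 0

    def test_distant_reference_positions_no_pair(self):
        pos = pd.DataFrame({"cds_id": ["c1", "c2"], "scaffold_id": "s",
                            "lg": 1, "position": [0.0, 2.0]})
        hits = pd.DataFrame([_hit("c1", "chr1", 1_000_000),
                             _hit("c2", "chr1", 40_000_000)])
        _, pairs, _ = synteny.detect_microsynteny(pos, hits)
        assert len(pairs) == 0

    def test_planted_blocks_recovered(self, small_true_map):
        """Zero-noise fixture: exactly the planted collinear blocks are
        recovered, and every block re-validates both distance rules."""
        fx = simulate_anchoring_fixture(small_true_map, seed=8, n_blocks=3,
                                        n_noise_hits=0)
        anch = synteny.anchor_scaffolds(small_true_map, fx.marker_lookup,
                                        fx.scaffolds)
        pos = synteny.cds_map_positions(anch, fx.cds)
        kept = synteny.filter_hits(fx.hits)
        blocks, _, _ = synteny.detect_microsynteny(pos, kept)
        assert len(blocks) == 3
        found = {(b["lg"], b["chrom"]) for _, b in blocks.iterrows()}
        planted = {(t["lg"], t["chrom"]) for t in fx.truth_blocks}
        assert found == planted
        assert synteny.validate_blocks(blocks, pos, kept)

    def test_planted_blocks_survive_noise(self, small_true_map):
        fx = simulate_anchoring_fixture(small_true_map, seed=9, n_blocks=3,
                                        n_noise_hits=60)
        anch = synteny.anchor_scaffolds(small_true_map, fx.marker_lookup,
                                        fx.scaffolds)
        pos = synteny.cds_map_positions(anch, fx.cds)
        blocks, _, _ = synteny.detect_microsynteny(
            pos, synteny.filter_hits(fx.hits))
        found = {(b["lg"], b["chrom"]) for _, b in blocks.iterrows()}
        assert {(t["lg"], t["chrom"]) for t in fx.truth_blocks} <= found

    def test_noise_only_rarely_makes_false_blocks(self, small_true_map):
        """Scattered best hits alone should almost never chain into a
        two-pair block (20 seeds, expected false-block rate < 0.05/run)."""
        false_blocks = 0
        for seed in range(20):
            fx = simulate_anchoring_fixture(small_true_map, seed=100 + seed,
                                            n_blocks=0, n_noise_hits=80)
            anch = synteny.anchor_scaffolds(small_true_map, fx.marker_lookup,
                                            fx.scaffolds)
            pos = synteny.cds_map_positions(anch, fx.cds)
            blocks, _, _ = synteny.detect_microsynteny(
                pos, synteny.filter_hits(fx.hits))
            false_blocks += len(blocks)
        assert false_blocks <= 2

    def test_zero_cds_empty_hit_table(self, small_true_map):
        fx = simulate_anchoring_fixture(small_true_map, seed=10, n_blocks=0,
                                        mean_cds_per_scaffold=0.0)
        assert len(fx.cds) == 0
        assert len(fx.hits) == 0
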