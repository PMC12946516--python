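"""Iterative RBH pairing: filters, tie rules, oracle equivalence, regions."""

import numpy as np
import pandas as pd
import pytest

from homeobias.io import GenomicInterval, SRARegionSet
from homeobias.pairing import (
    assign_dyads_to_regions,
    assign_genes_to_regions,
    best_hits,
    filter_hits,
    iterative_rbh,
    merge_collinear_blocks,
    reciprocal_best,
)

from conftest import hits_frame, make_hit


# ---------------------------------------------------------------------------
# brute-force oracle, independent of the implementation
# ---------------------------------------------------------------------------


def oracle_filter(rows, cov=0.90, ident=90.0, ev=1e-5):
    return [
        r for r in rows
        if r["aln_length"] / r["subject_length"] >= cov
        and r["pct_identity"] >= ident
        and r["e_value"] <= ev
    ]


def oracle_best(rows):
    """Best hit per query by (bit desc, e asc, identity desc, subject asc)."""
    best = {}
    for r in rows:
        key = (-r["bit_score"], r["e_value"], -r["pct_identity"], r["subject_id"])
        q = r["query_id"]
        if q not in best or key < best[q][0]:
            best[q] = (key, r["subject_id"])
    return {q: s for q, (_, s) in best.items()}


def oracle_rbh_round(mu_rows, um_rows):
    bm, bu = oracle_best(oracle_filter(mu_rows)), oracle_best(oracle_filter(um_rows))
    return {(m, u) for m, u in bm.items() if bu.get(u) == m}


def random_hit_rows(rng, n_genes=50, n_hits=150):
    rows = []
    for _ in range(n_hits):
        q = f"m{rng.integers(n_genes)}"
        s = f"u{rng.integers(n_genes)}"
        slen = int(rng.integers(500, 2000))
        rows.append(make_hit(
            q, s,
            identity=float(np.round(rng.uniform(85, 100), 1)),
            aln=int(rng.integers(int(0.7 * slen), slen + 1)),
            e=float(10.0 ** -rng.integers(3, 60)),
            bit=float(rng.choice([500, 750, 1000, 1500])),  # ties on purpose
            slen=slen,
        ))
    return rows


# ---------------------------------------------------------------------------


class TestFilterHits:
    def test_boundary_values_retained_inclusive(self):
        h = hits_frame([make_hit("m", "u", identity=90.0, aln=900, e=1e-5, slen=1000)])
        assert len(filter_hits(h)) == 1

    def test_identity_below_threshold_dropped(self):
        h = hits_frame([make_hit("m", "u", identity=89.9)])
        assert len(filter_hits(h)) == 0

    def test_coverage_strictly_below_dropped(self):
        h = hits_frame([make_hit("m", "u", aln=899, slen=1000)])
        assert len(filter_hits(h)) == 0

    def test_zero_subject_length_errors(self):
        h = hits_frame([make_hit("m", "u", slen=0)])
        with pytest.raises(ValueError):
            filter_hits(h)

    def test_relaxing_thresholds_never_shrinks_result(self, rng):
        h = hits_frame(random_hit_rows(rng))
        n = len(filter_hits(h))
        assert len(filter_hits(h, min_identity=85.0)) >= n
        assert len(filter_hits(h, min_target_coverage=0.5)) >= n
        assert len(filter_hits(h, max_evalue=1e-3)) >= n


class TestBestHits:
    def test_highest_bit_score_wins(self):
        h = hits_frame([
            make_hit("m1", "uA", bit=500), make_hit("m1", "uB", bit=450),
        ])
        assert best_hits(h)["m1"] == "uA"

    def test_bit_tie_broken_by_evalue(self):
        h = hits_frame([
            make_hit("m1", "uA", bit=500, e=1e-40), make_hit("m1", "uB", bit=500, e=1e-50),
        ])
        assert best_hits(h)["m1"] == "uB"

    def test_full_tie_broken_lexicographically(self):
        h = hits_frame([make_hit("m1", "uC"), make_hit("m1", "uA"), make_hit("m1", "uB")])
        assert best_hits(h)["m1"] == "uA"


class TestReciprocalBest:
    def test_mutual_pair_kept(self):
        assert reciprocal_best(pd.Series({"A": "B"}), pd.Series({"B": "A"})) == [("A", "B")]

    def test_one_sided_pair_dropped(self):
        assert reciprocal_best(pd.Series({"A": "B"}), pd.Series({"B": "C"})) == []

    def test_empty_maps(self):
        assert reciprocal_best(pd.Series(dtype=object), pd.Series(dtype=object)) == []


class TestIterativeRbh:
    def test_second_round_rescues_masked_pair(self):
        # A2's best is B1, masked in round 1 by the stronger A1-B1 pair
        mu = hits_frame([
            make_hit("A1", "B1", bit=1000),
            make_hit("A2", "B1", bit=900),
            make_hit("A2", "B2", bit=800),
        ])
        um = hits_frame([
            make_hit("B1", "A1", bit=1000),
            make_hit("B2", "A2", bit=800),
        ])
        res = iterative_rbh(mu, um)
        assert list(map(tuple, res.dyads.to_numpy())) == [("A1", "B1", 1), ("A2", "B2", 2)]
        assert res.n_rounds == 3  # the third round finds nothing

    def test_empty_reverse_table_pairs_nothing(self):
        mu = hits_frame([make_hit("A1", "B1")])
        res = iterative_rbh(mu, hits_frame([]))
        assert len(res.dyads) == 0
        assert res.unique_m == {"A1"} and res.unique_u == {"B1"}

    def test_round1_matches_bruteforce_oracle_on_random_tables(self, rng):
        for _ in range(50):
            mu_rows = random_hit_rows(rng, n_genes=rng.integers(10, 100))
            um_rows = random_hit_rows(rng, n_genes=rng.integers(10, 100))
            res = iterative_rbh(hits_frame(mu_rows), hits_frame(um_rows))
            round1 = set(
                map(tuple, res.dyads.loc[res.dyads["round"] == 1, ["m_gene", "u_gene"]].to_numpy())
            )
            assert round1 == oracle_rbh_round(mu_rows, um_rows)
            # no gene paired twice across rounds
            assert res.dyads["m_gene"].is_unique and res.dyads["u_gene"].is_unique

    def test_recovers_planted_dyads_without_noise(self, small_dataset):
        d = small_dataset
        res = iterative_rbh(d.hits_mu, d.hits_um)
        truth = set(zip(d.truth.dyads.m_gene, d.truth.dyads.u_gene))
        found = set(zip(res.dyads.m_gene, res.dyads.u_gene))
        tp = len(truth & found)
        assert tp / len(found) > 0.95 and tp / len(truth) > 0.95


class TestBlockMerging:
    def test_gap_within_threshold_merges(self):
        out = merge_collinear_blocks([("c", 0, 100), ("c", 150, 300)], max_gap_bp=100)
        assert [(iv.start, iv.end) for iv, _ in out] == [(0, 300)]

    def test_gap_beyond_threshold_stays_split(self):
        out = merge_collinear_blocks([("c", 0, 100), ("c", 201, 300)], max_gap_bp=100)
        assert len(out) == 2

    def test_single_block_unchanged(self):
        out = merge_collinear_blocks([("c", 10, 90)], max_gap_bp=1000)
        assert [(iv.chrom, iv.start, iv.end) for iv, _ in out] == [("c", 10, 90)]

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_collinear_blocks([("c", 0, 10)], max_gap_bp=-1)


class TestRegionAssignment:
    @pytest.fixture()
    def regions(self):
        r = SRARegionSet()
        r.add(GenomicInterval("1U", 0, 1000), "SRA01")
        return r

    def test_midpoint_inside_region(self, regions):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["1U"], "start": [100], "end": [200]})
        assert assign_genes_to_regions(genes, regions)["label"].iloc[0] == "rearranged"

    def test_midpoint_at_region_end_is_outside(self, regions):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["1U"], "start": [900], "end": [1100]})
        assert assign_genes_to_regions(genes, regions)["label"].iloc[0] == "non_rearranged"

    def test_unknown_chromosome_is_control(self, regions):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["9Z"], "start": [0], "end": [10]})
        assert assign_genes_to_regions(genes, regions)["label"].iloc[0] == "non_rearranged"

    def test_dyad_rearranged_if_either_member_is(self, regions):
        genes = pd.DataFrame({
            "gene_id": ["m1", "u1"], "chrom": ["1M", "1U"],
            "start": [0, 100], "end": [10, 200],
        })
        labels = assign_genes_to_regions(genes, regions)
        dyads = pd.DataFrame({"dyad_id": ["d1"], "m_gene": ["m1"], "u_gene": ["u1"]})
        out = assign_dyads_to_regions(dyads, labels)
        assert out["label"].iloc[0] == "rearranged"
        assert out["region_id"].iloc[0] == "SRA01"
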