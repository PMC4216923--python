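"""Methylated-site calling, DMP/DMR detection, retention and clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from maepi import (MethylationCallPolicy, call_dmps, call_dmrs,
                   call_methylated_sites, cluster_samples,
                   estimate_conversion_rate, pairwise_fisher,
                   remove_parental_dmps, retention_analysis, site_universe)
from conftest import make_records

POLICY = MethylationCallPolicy()


class TestConversionRate:
    def test_direct_fraction(self):
        spike = pd.DataFrame({"s:meth": [10], "s:unmeth": [990]})
        assert estimate_conversion_rate(spike) == pytest.approx(0.99)

    def test_fully_converted(self):
        spike = pd.DataFrame({"s:meth": [0], "s:unmeth": [1000]})
        assert estimate_conversion_rate(spike) == 1.0

    def test_zero_coverage_errors(self):
        spike = pd.DataFrame({"s:meth": [0], "s:unmeth": [0]})
        with pytest.raises(ValueError, match="coverage"):
            estimate_conversion_rate(spike)

    def test_synthetic_nonconversion_recovered(self):
        rng = np.random.default_rng(0)
        depth = rng.poisson(75, 2000)
        meth = rng.binomial(depth, 0.004)
        spike = pd.DataFrame({"s:meth": meth, "s:unmeth": depth - meth})
        assert 0.995 <= estimate_conversion_rate(spike) <= 0.997


class TestSiteCalling:
    def test_status_thresholds(self):
        rec = make_records({"s": [(1, 1), (3, 0), (2, 98), (150, 100), (0, 50)]})
        status = call_methylated_sites(rec, POLICY)["s"]
        assert list(status) == ["not_evaluable", "methylated", "unmethylated",
                               "not_evaluable", "unmethylated"]

    def test_universe_gates(self):
        rec = make_records({
            "p1": [(5, 5), (0, 60), (0, 250), (0, 1)],
            "p2": [(5, 5), (0, 60), (0, 60), (0, 60)],
            "d1": [(5, 5), (0, 60), (0, 60), (0, 60)],
        })
        evaluable, analyzable = site_universe(rec, ["p1", "p2"], ["d1"], POLICY)
        assert list(evaluable) == [True, True, False, False]
        # site 2 is evaluable everywhere but methylated nowhere
        assert list(analyzable) == [True, False, False, False]

    def test_universe_needs_two_parents(self):
        rec = make_records({"p1": [(5, 5)], "d1": [(5, 5)]})
        with pytest.raises(ValueError):
            site_universe(rec, ["p1"], ["d1"], POLICY)

    def test_missing_sample_errors(self):
        rec = make_records({"p1": [(5, 5)], "p2": [(5, 5)]})
        with pytest.raises(ValueError, match="ghost"):
            site_universe(rec, ["p1", "p2"], ["ghost"], POLICY)


class TestPairwiseFisher:
    def test_exact_hypergeometric_value(self):
        # [[10,0],[0,10]]: the two extreme tables out of C(20,10)
        assert pairwise_fisher((10, 0), (0, 10)) == \
            pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_identical_rows_p_one(self):
        assert pairwise_fisher((7, 3), (7, 3)) == 1.0

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            pairwise_fisher((0, 0), (5, 5))

    def test_matches_scipy_on_random_tables(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(1)
        for _ in range(300):
            d1, d2 = rng.integers(1, 120, 2)
            a = rng.binomial(d1, rng.random())
            c = rng.binomial(d2, rng.random())
            mine = pairwise_fisher((a, d1 - a), (c, d2 - c))
            ref = fisher_exact([[a, d1 - a], [c, d2 - c]])[1]
            assert mine == pytest.approx(ref, rel=1e-9)


def _null_records(n, samples, depth=70, seed=0, strong=()):
    """n CG sites with background methylation; ``strong`` marks sites where
    derived samples switch to near-full methylation."""
    rng = np.random.default_rng(seed)
    counts = {}
    for s in samples:
        d = rng.poisson(depth, n)
        p = np.full(n, 0.004)
        if not s.startswith("p") and len(strong):
            p[np.asarray(strong)] = 0.97
        m = rng.binomial(d, p)
        counts[s] = list(zip(m, d - m))
    return make_records(counts)


class TestParentalRemoval:
    def test_identical_parents_nothing_removed(self):
        rec = make_records({"p1": [(40, 0)] * 5, "p2": [(40, 0)] * 5})
        keep, removed = remove_parental_dmps(rec, ["p1", "p2"], POLICY)
        assert removed == 0 and keep.all()

    def test_divergent_site_removed_among_nulls(self):
        rec = _null_records(1000, ["p1", "p2"], seed=3)
        rec.loc[0, "p1:meth"], rec.loc[0, "p1:unmeth"] = 50, 0
        rec.loc[0, "p2:meth"], rec.loc[0, "p2:unmeth"] = 0, 50
        keep, removed = remove_parental_dmps(rec, ["p1", "p2"], POLICY)
        assert removed == 1
        assert not keep[0]

    def test_empty_analyzable_set(self):
        rec = make_records({"p1": [(5, 5)], "p2": [(5, 5)]})
        keep, removed = remove_parental_dmps(
            rec, ["p1", "p2"], POLICY, analyzable=np.zeros(1, dtype=bool))
        assert removed == 0 and not keep.any()

    def test_exactly_two_parents_required(self):
        rec = make_records({"p1": [(5, 5)]})
        with pytest.raises(ValueError):
            remove_parental_dmps(rec, ["p1"], POLICY)


class TestDMPCalling:
    def test_no_difference_no_dmps(self):
        rec = make_records({s: [(30, 40)] * 20 for s in ["p1", "p2", "d1"]})
        dmps = call_dmps(rec, ["p1", "p2"], ["d1"], POLICY)
        assert dmps.empty

    def test_strong_gain_called_among_nulls(self):
        rec = _null_records(1000, ["p1", "p2", "d1"], seed=4, strong=[10])
        dmps = call_dmps(rec, ["p1", "p2"], ["d1"], POLICY)
        assert len(dmps) == 1
        assert dmps.loc[0, "direction"] == "gain"
        assert dmps.loc[0, "site_idx"] == 10

    def test_direction_requires_both_parents(self):
        # derived sits between the parents: significant vs one side only
        rec = make_records({"p1": [(70, 0)], "p2": [(0, 70)],
                            "d1": [(35, 35)]})
        dmps = call_dmps(rec, ["p1", "p2"], ["d1"], POLICY)
        assert dmps.empty

    def test_lower_fdr_never_increases_calls(self):
        rec = _null_records(500, ["p1", "p2", "d1", "d2"], seed=5,
                            strong=[3, 17, 44])
        loose = call_dmps(rec, ["p1", "p2"], ["d1", "d2"], POLICY)
        strict_policy = MethylationCallPolicy(dmp_fdr=0.01)
        strict = call_dmps(rec, ["p1", "p2"], ["d1", "d2"], strict_policy)
        assert len(strict) <= len(loose)


def _toy_dmps(positions, sample="d1"):
    return pd.DataFrame({
        "chrom": "chr1", "pos": positions, "strand": "+", "context": "CG",
        "sample": sample, "direction": "gain", "p_bonf": 1e-12, "q": 1e-10,
        "site_idx": range(len(positions)),
    })


def _region_records(n, carrier_meth=True):
    """Records where d1 is fully methylated and parents unmethylated."""
    base = [(0, 70)] * n
    hot = [(68, 2)] * n if carrier_meth else base
    return make_records({"p1": base, "p2": base, "d1": hot})


class TestDMRCalling:
    def test_five_close_dmps_one_region(self):
        dmps = _toy_dmps([100, 120, 140, 160, 180])
        rec = _region_records(5)
        rec["pos"] = [100, 120, 140, 160, 180]
        dmrs = call_dmrs(dmps, rec, ["p1", "p2"], ["d1"], POLICY)
        assert len(dmrs) == 1
        r = dmrs.iloc[0]
        assert (r["start"], r["end"], r["n_dmps"]) == (100, 180, 5)

    def test_four_dmps_no_region(self):
        dmps = _toy_dmps([100, 120, 140, 160])
        rec = _region_records(4)
        rec["pos"] = [100, 120, 140, 160]
        assert call_dmrs(dmps, rec, ["p1", "p2"], ["d1"], POLICY).empty

    def test_fifty_bp_gap_breaks_chain(self):
        # 60 bp gap between two blocks of 4 and 1: neither side survives
        pos = [100, 110, 120, 130, 190]
        dmps = _toy_dmps(pos)
        rec = _region_records(5)
        rec["pos"] = pos
        assert call_dmrs(dmps, rec, ["p1", "p2"], ["d1"], POLICY).empty

    def test_gap_of_49_chains_gap_of_50_breaks(self):
        pos = [100, 149, 198, 247, 296]  # gaps of 49 chain together
        dmps = _toy_dmps(pos)
        rec = _region_records(5)
        rec["pos"] = pos
        assert len(call_dmrs(dmps, rec, ["p1", "p2"], ["d1"], POLICY)) == 1
        pos = [100, 150, 200, 250, 300]  # gaps of exactly 50 break
        dmps = _toy_dmps(pos)
        rec = _region_records(5)
        rec["pos"] = pos
        assert call_dmrs(dmps, rec, ["p1", "p2"], ["d1"], POLICY).empty

    def test_chaining_invariant_to_input_order(self):
        pos = [100, 120, 140, 160, 180]
        dmps = _toy_dmps(pos).sample(frac=1.0, random_state=2)
        rec = _region_records(5)
        rec["pos"] = pos
        shuffled = call_dmrs(dmps, rec, ["p1", "p2"], ["d1"], POLICY)
        ordered = call_dmrs(_toy_dmps(pos), rec, ["p1", "p2"], ["d1"], POLICY)
        assert shuffled.equals(ordered)

    def test_narrow_span_ignored(self):
        pos = [100, 101, 102, 103, 104]  # 5 DMPs but span 5 < 10
        dmps = _toy_dmps(pos)
        rec = _region_records(5)
        rec["pos"] = pos
        assert call_dmrs(dmps, rec, ["p1", "p2"], ["d1"], POLICY).empty


class TestRetention:
    def _setup(self):
        rec = _null_records(300, ["p1", "p2", "d1"], seed=6,
                            strong=list(range(30)))
        return rec, call_dmps(rec, ["p1", "p2"], ["d1"], POLICY)

    def test_offspring_identical_to_carrier_full_retention(self):
        rec, dmps = self._setup()
        rec["g11:meth"] = rec["d1:meth"]
        rec["g11:unmeth"] = rec["d1:unmeth"]
        kept, lost, frac = retention_analysis(dmps, rec, ["p1", "p2"],
                                              "d1", "g11", POLICY)
        assert frac == 1.0 and lost == 0

    def test_offspring_identical_to_parents_zero_retention(self):
        rec, dmps = self._setup()
        rec["g11:meth"] = rec["p1:meth"]
        rec["g11:unmeth"] = rec["p1:unmeth"]
        kept, lost, frac = retention_analysis(dmps, rec, ["p1", "p2"],
                                              "d1", "g11", POLICY)
        assert frac == 0.0 and kept == 0

    def test_missing_offspring_errors(self):
        rec, dmps = self._setup()
        with pytest.raises(ValueError, match="offspring"):
            retention_analysis(dmps, rec, ["p1", "p2"], "d1", "nope", POLICY)


class TestTreatmentContrast:
    def test_saline_cg_dmp_excess_tracks_multiplier(self, dmp_study):
        """Pooled over simulations, the saline/control CG-DMP position
        ratio brackets the configured 1.45x CG multiplier."""
        totals = {"control": 0, "saline": 0}
        for run in dmp_study:
            cg = run["dmps"][run["dmps"]["context"] == "CG"]
            for arm in totals:
                samples = [s for s in run["derived"]
                           if run["treatments"][s] == arm]
                sub = cg[cg["sample"].isin(samples)]
                totals[arm] += len(sub[["chrom", "pos", "strand"]]
                                   .drop_duplicates())
        assert totals["control"] > 100  # enough events for a ratio
        ratio = totals["saline"] / totals["control"]
        assert 1.15 <= ratio <= 1.75, totals


class TestClustering:
    def test_identical_pair_merges_first(self):
        rec = make_records({
            "a": [(60, 10)] * 30, "b": [(60, 10)] * 30, "c": [(5, 65)] * 30,
        })
        Z, labels, newick = cluster_samples(rec, range(30), ["a", "b", "c"],
                                            n_sites=30, seed=0)
        first = sorted(labels[int(i)] for i in Z[0, :2])
        assert first == ["a", "b"]
        assert newick.count("(") == 2 and newick.endswith(";")

    def test_deterministic_for_fixed_seed(self):
        rec = _null_records(200, ["a", "b", "c", "d"], seed=7, strong=[1, 5])
        z1 = cluster_samples(rec, range(200), list("abcd"), 50, seed=3)
        z2 = cluster_samples(rec, range(200), list("abcd"), 50, seed=3)
        assert np.array_equal(z1[0], z2[0]) and z1[2] == z2[2]

    def test_two_samples_required(self):
        rec = make_records({"a": [(5, 5)]})
        with pytest.raises(ValueError):
            cluster_samples(rec, [0], ["a"])
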