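"""Mutation filtering, spectrum classification and rate estimation."""

import numpy as np
import pandas as pd
import pytest

from maepi import (FilterPolicy, SimulationConfig, UndefinedTiTvError,
                   accumulation_model, classify_substitution, compare_rates,
                   filter_variants, fixation_probability, mutation_rate,
                   simulate_pedigree, simulate_variant_counts,
                   substitution_class, titv_ratio)
from maepi.pedigree import PedigreeSample
from maepi.variants import SUBSTITUTION_CLASSES

PEDIGREE = [
    PedigreeSample("G0", "progenitor", 0, "control", "progenitor"),
    PedigreeSample("A1", "L1", 10, "control", "derived"),
    PedigreeSample("A2", "L1", 10, "control", "derived"),
    PedigreeSample("B1", "L2", 10, "saline", "derived"),
]


def candidate(vclass="SBS", **counts):
    """One candidate row; counts maps sample -> (alt, dp)."""
    row = {"chrom": "chr1", "pos": 100, "ref": "C", "alt": "T",
           "vclass": vclass}
    for s in ("G0", "A1", "A2", "B1"):
        alt, dp = counts.get(s, (0, 20))
        row[f"{s}:alt"] = alt
        row[f"{s}:dp"] = dp
    return pd.DataFrame([row])


class TestClassification:
    @pytest.mark.parametrize("ref,alt,titv,pair", [
        ("C", "T", "transition", "G:C"),
        ("G", "A", "transition", "G:C"),
        ("A", "G", "transition", "A:T"),
        ("T", "C", "transition", "A:T"),
        ("C", "A", "transversion", "G:C"),
        ("C", "G", "transversion", "G:C"),
        ("A", "T", "transversion", "A:T"),
        ("T", "G", "transversion", "A:T"),
    ])
    def test_titv_and_pair(self, ref, alt, titv, pair):
        assert classify_substitution(ref, alt) == (titv, pair)

    @pytest.mark.parametrize("ref,alt,cls", [
        ("C", "T", "GC>AT"), ("G", "A", "GC>AT"),
        ("A", "G", "AT>GC"), ("T", "C", "AT>GC"),
        ("C", "A", "GC>TA"), ("G", "T", "GC>TA"),
        ("C", "G", "GC>CG"), ("G", "C", "GC>CG"),
        ("A", "T", "AT>TA"), ("T", "A", "AT>TA"),
        ("A", "C", "AT>CG"), ("T", "G", "AT>CG"),
    ])
    def test_strand_symmetric_collapse(self, ref, alt, cls):
        assert substitution_class(ref, alt) == cls

    @pytest.mark.parametrize("ref,alt", [("C", "C"), ("N", "A"), ("A", "x")])
    def test_invalid_bases_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            classify_substitution(ref, alt)


class TestFilter:
    def test_depth_below_sbs_minimum_rejected(self):
        out = filter_variants(candidate(A1=(7, 7)), PEDIGREE)
        assert out.empty

    def test_clean_homozygote_accepted(self):
        out = filter_variants(candidate(A1=(20, 20)), PEDIGREE)
        assert len(out) == 1
        assert out.loc[0, "lineage"] == "L1"
        assert out.loc[0, "zygosity"] == "homozygous"
        assert out.loc[0, "titv"] == "transition"

    def test_heterozygous_pattern_rejected(self):
        out = filter_variants(candidate(A1=(10, 20)), PEDIGREE)
        assert out.empty

    def test_cross_lineage_sharing_rejected(self):
        out = filter_variants(candidate(A1=(20, 20), B1=(20, 20)), PEDIGREE)
        assert out.empty

    def test_within_lineage_sharing_counted_once(self):
        out = filter_variants(candidate(A1=(20, 20), A2=(19, 19)), PEDIGREE)
        assert len(out) == 1
        assert out.loc[0, "carrier"] == "A1,A2"

    def test_progenitor_presence_rejected(self):
        out = filter_variants(candidate(G0=(18, 20), A1=(20, 20)), PEDIGREE)
        assert out.empty

    def test_insufficient_progenitor_coverage_rejected(self):
        out = filter_variants(candidate(G0=(0, 5), A1=(20, 20)), PEDIGREE)
        assert out.empty

    def test_sbs_depth_above_maximum_rejected(self):
        out = filter_variants(candidate(A1=(80, 80)), PEDIGREE)
        assert out.empty

    def test_indel_depth_five_accepted(self):
        cand = candidate(vclass="deletion", A1=(6, 6))
        cand["ref"] = "CTT"
        cand["alt"] = "C"
        out = filter_variants(cand, PEDIGREE)
        assert len(out) == 1
        assert out.loc[0, "titv"] == "NA"

    def test_missing_progenitor_errors(self):
        with pytest.raises(ValueError, match="progenitor"):
            filter_variants(candidate(), PEDIGREE[1:])

    def test_missing_sample_column_errors(self):
        cand = candidate().drop(columns=["B1:alt", "B1:dp"])
        with pytest.raises(ValueError, match="B1"):
            filter_variants(cand, PEDIGREE)

    def test_idempotent(self):
        cand = pd.concat([candidate(A1=(20, 20)), candidate(A1=(10, 20))],
                         ignore_index=True)
        once = filter_variants(cand, PEDIGREE)
        twice = filter_variants(once, PEDIGREE)
        assert twice[once.columns[:5]].equals(once[once.columns[:5]])

    def test_recovery_on_clean_synthetic_data(self):
        """With no sequencing error every homozygous lineage-unique event
        with in-bounds depths is recovered and every het is excluded."""
        cfg = SimulationConfig(seed=9, chromosome_lengths=(50_000, 50_000),
                               transition_rate=2e-6, transversion_rate=1e-6,
                               insertion_rate=3e-7, deletion_rate=3e-7,
                               het_fraction=0.6, seq_error_rate=0.0,
                               false_candidate_rate=0.0)
        truth, samples = simulate_pedigree(cfg, methylomes=False)
        cand = simulate_variant_counts(truth, cfg)
        policy = FilterPolicy()
        called = filter_variants(cand, truth.genomic_samples, policy)
        called_keys = set(zip(called["chrom"], called["pos"], called["alt"]))

        zyg = truth.genotypes.pivot_table(
            index="mut_id", columns="sample_id", values="zygosity",
            aggfunc="first")
        counts = cand.set_index(["chrom", "pos", "alt"])
        expected = set()
        for m in truth.mutations.itertuples(index=False):
            key = (m.chrom, m.pos, m.alt)
            row = counts.loc[key]
            z = zyg.loc[m.mut_id].dropna()
            if (z == "heterozygous").any():
                assert key not in called_keys  # het pattern must be excluded
                continue
            carriers = z[z == "homozygous"].index
            dmin = policy.min_depth(m.vclass)
            dmax = policy.max_depth(m.vclass)
            ok = [s for s in carriers
                  if dmin <= row[f"{s}:dp"] <= dmax]
            if ok and row["G0:dp"] >= dmin:
                expected.add(key)
        assert expected, "degenerate simulation: no recoverable events"
        assert called_keys == expected


class TestTiTv:
    def _muts(self, classes):
        rev = {"GC>AT": ("C", "T"), "AT>GC": ("A", "G"), "GC>TA": ("C", "A"),
               "GC>CG": ("C", "G"), "AT>TA": ("A", "T"), "AT>CG": ("A", "C")}
        rows = []
        for cls in classes:
            ref, alt = rev[cls]
            titv = "transition" if cls in ("GC>AT", "AT>GC") else "transversion"
            rows.append({"vclass": "SBS", "ref": ref, "alt": alt,
                         "titv": titv, "sub_class": cls})
        return pd.DataFrame(rows)

    def test_equal_classes_gc_half_gives_half(self):
        muts = self._muts(SUBSTITUTION_CLASSES)
        assert titv_ratio(muts, 1000, 0.5, normalized=True) == pytest.approx(0.5)

    def test_raw_ratio_printed_counts(self):
        muts = self._muts(["GC>AT"] * 30 + ["GC>TA"] * 14)
        assert titv_ratio(muts) == pytest.approx(30 / 14)

    def test_no_transversions_is_undefined(self):
        with pytest.raises(UndefinedTiTvError):
            titv_ratio(self._muts(["GC>AT", "AT>GC"]))

    def test_uniform_spectrum_raw_ratio_half(self):
        rng = np.random.default_rng(0)
        classes = rng.choice(SUBSTITUTION_CLASSES, size=6000)
        r = titv_ratio(self._muts(classes))
        assert abs(r - 0.5) < 0.03

    def test_normalization_weights_by_base_content(self):
        # same counts, GC-poor genome: GC-source classes get larger rates
        muts = self._muts(["GC>AT"] * 10 + ["AT>TA"] * 10)
        low_gc = titv_ratio(muts, 10_000, 0.2, normalized=True)
        high_gc = titv_ratio(muts, 10_000, 0.8, normalized=True)
        assert low_gc > high_gc


class TestRates:
    def test_worked_example(self):
        assert mutation_rate(42, 9, 10) == pytest.approx(0.467, abs=5e-4)

    def test_zero_mutations(self):
        assert mutation_rate(0, 3, 10) == 0.0

    def test_control_total(self):
        assert mutation_rate(52, 9, 10) == pytest.approx(0.5778, abs=5e-5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mutation_rate(5, 0, 10)
        with pytest.raises(ValueError):
            mutation_rate(5, 3, 0)


class TestAccumulationModel:
    def test_all_heterozygous_twenty_percent_underestimate(self):
        res = accumulation_model(mu=0.0, tau=0.3, g=10)
        assert res.expected_identified / res.expected_accumulated == \
            pytest.approx(8 / 10)
        assert res.underestimation_fraction == pytest.approx(0.20)

    def test_all_homozygous_fully_observed(self):
        res = accumulation_model(mu=0.7, tau=0.0, g=10)
        assert res.underestimation_fraction == 0.0

    def test_matches_markov_chain_oracle_at_g10(self):
        # oracle: sum the fixation probability over birth generations
        oracle = sum(fixation_probability(10 - k) for k in range(1, 11))
        assert oracle == pytest.approx(4.000977, abs=1e-6)
        closed = accumulation_model(0.0, 1.0, 10).expected_identified
        assert abs(closed - oracle) / oracle < 3e-4

    @pytest.mark.parametrize("g", range(10, 51, 5))
    def test_closed_form_tracks_oracle_for_long_designs(self, g):
        oracle = sum(fixation_probability(g - k) for k in range(1, g + 1))
        closed = accumulation_model(0.0, 1.0, g).expected_identified
        assert abs(closed - oracle) / oracle < 1e-3

    def test_short_design_rejected(self):
        with pytest.raises(ValueError):
            accumulation_model(0.1, 0.1, 1)


class TestCompareRates:
    def test_identical_groups(self):
        cmp = compare_rates([0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
        assert cmp.ratio == pytest.approx(1.0)
        assert cmp.p_value == 1.0

    def test_ratio_of_means(self):
        cmp = compare_rates([0.1, 0.1, 0.1], [0.2, 0.2, 0.2])
        assert cmp.ratio == pytest.approx(2.0)

    def test_single_lineage_rejected(self):
        with pytest.raises(ValueError):
            compare_rates([0.1], [0.2, 0.3])

    def test_simulated_twofold_multiplier_recovered(self):
        """Pooled over seeds, the realized rate ratio brackets the 2x truth."""
        total = {"control": 0.0, "saline": 0.0}
        for seed in range(8):
            cfg = SimulationConfig(seed=seed,
                                   chromosome_lengths=(100_000, 100_000),
                                   transition_rate=2e-6, transversion_rate=1e-6,
                                   insertion_rate=3e-7, deletion_rate=3e-7)
            truth, _ = simulate_pedigree(cfg, methylomes=False)
            by_arm = truth.mutations["lineage"].str[0].value_counts()
            total["control"] += by_arm.get("C", 0)
            total["saline"] += by_arm.get("S", 0)
        assert 1.5 <= total["saline"] / total["control"] <= 2.5
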