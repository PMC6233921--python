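"""Genotype parsing, QC, haplotype construction and count tallying."""

import numpy as np
import pandas as pd
import pytest

import normsel as ns
from normsel import haplotypes as hap


def calls_df(rows):
    return pd.DataFrame(rows, columns=hap.GENOTYPE_COLUMNS)


def simple_calls(pop="sudden_1", gen=10, inds=("i1",), chroms=("I", "II"), n_snp=3,
                 call="REF"):
    rows = []
    for ind in inds:
        for chrom in chroms:
            for s in range(n_snp):
                rows.append(
                    (pop, gen, ind, hap.CHROMOSOME_REGION[chrom], chrom,
                     f"{chrom}_s{s}", 1000 * (s + 1), call)
                )
    return calls_df(rows)


class TestReadGenotypeTable:
    def test_round_trips_well_formed_file(self, tmp_path):
        df = simple_calls(inds=("i1", "i2"))
        path = tmp_path / "g.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = hap.read_genotype_table(path)
        pd.testing.assert_frame_equal(back, df)

    def test_unknown_call_code_rejected_with_row(self, tmp_path):
        df = simple_calls()
        df.loc[2, "call"] = "X"
        path = tmp_path / "g.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match=r"row 2.*'X'"):
            hap.read_genotype_table(path)

    def test_chromosome_region_mismatch_rejected(self, tmp_path):
        df = simple_calls()
        df.loc[0, "region"] = 3
        path = tmp_path / "g.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="inconsistent with"):
            hap.read_genotype_table(path)

    def test_missing_column_rejected(self, tmp_path):
        df = simple_calls().drop(columns=["position"])
        path = tmp_path / "g.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="position"):
            hap.read_genotype_table(path)

    def test_individual_in_two_regions_rejected(self, tmp_path):
        df = pd.concat(
            [simple_calls(chroms=("I", "II")), simple_calls(chroms=("V", "X"))]
        )
        path = tmp_path / "g.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="more than one region"):
            hap.read_genotype_table(path)


class TestQc:
    def test_clean_data_unchanged(self):
        df = simple_calls(inds=("i1", "i2", "i3"))
        kept, report = hap.apply_qc(df)
        assert len(kept) == len(df)
        assert report.dropped_snps == [] and report.dropped_individuals == []

    def test_high_missing_snp_dropped(self):
        # one SNP missing in 2/5 individuals (40% > 30% threshold)
        df = simple_calls(inds=tuple(f"i{k}" for k in range(5)))
        mask = (df["snp_id"] == "I_s0") & df["individual"].isin(["i0", "i1"])
        df.loc[mask, "call"] = "MISSING"
        kept, report = hap.apply_qc(df)
        assert report.dropped_snps == ["I_s0"]
        assert "I_s0" not in set(kept["snp_id"])

    def test_high_het_snp_dropped(self):
        df = simple_calls(inds=tuple(f"i{k}" for k in range(5)))
        mask = (df["snp_id"] == "II_s1") & df["individual"].isin(["i0", "i1"])
        df.loc[mask, "call"] = "HET"
        kept, report = hap.apply_qc(df, het_threshold=0.30)
        assert report.dropped_snps == ["II_s1"]

    def test_failing_individual_dropped(self):
        df = simple_calls(inds=tuple(f"i{k}" for k in range(10)), n_snp=4)
        df.loc[(df["individual"] == "i0") & (df["chromosome"] == "I"), "call"] = "MISSING"
        # i0 now missing 4/8 = 50% of its SNPs; SNP-level missingness is 10%
        kept, report = hap.apply_qc(df)
        assert report.dropped_snps == []
        assert report.dropped_individuals == [("sudden_1", 10, "i0")]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = simple_calls(inds=tuple(f"i{k}" for k in range(12)), n_snp=6)
        noisy = rng.random(len(df)) < 0.15
        df.loc[noisy, "call"] = "MISSING"
        once, _ = hap.apply_qc(df)
        twice, report2 = hap.apply_qc(once)
        pd.testing.assert_frame_equal(once, twice)
        assert report2.dropped_snps == [] and report2.dropped_individuals == []

    def test_all_removed_is_an_error(self):
        df = simple_calls(call="MISSING")
        with pytest.raises(ValueError):
            hap.apply_qc(df)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError, match="snp_fail_threshold"):
            hap.apply_qc(simple_calls(), snp_fail_threshold=0.0)


class TestHaplotypeConstruction:
    def test_all_ref_gives_zero_string(self):
        cwhs = hap.calls_to_cwh(simple_calls())
        assert set(cwhs["allele_string"]) == {"000"}
        assert len(cwhs) == 2  # one row per chromosome

    def test_identical_calls_identical_ids(self):
        cwhs = hap.calls_to_cwh(simple_calls(inds=("i1", "i2")))
        per_ind = cwhs.groupby("individual")["allele_string"].apply(tuple)
        assert per_ind["i1"] == per_ind["i2"]

    def test_het_individual_excluded_with_warning(self):
        df = simple_calls(inds=("i1", "i2"))
        df.loc[(df["individual"] == "i1") & (df.index % 7 == 0), "call"] = "HET"
        with pytest.warns(UserWarning, match="excluded"):
            cwhs = hap.calls_to_cwh(df)
        assert set(cwhs["individual"]) == {"i2"}

    def test_single_missing_imputed_to_sample_major(self):
        df = simple_calls(inds=("i1", "i2", "i3"), n_snp=3)
        df.loc[(df["individual"] != "i1") & (df["snp_id"] == "I_s0"), "call"] = "ALT"
        df.loc[(df["individual"] == "i1") & (df["snp_id"] == "I_s0"), "call"] = "MISSING"
        cwhs = hap.calls_to_cwh(df)
        s = cwhs[(cwhs["individual"] == "i1") & (cwhs["chromosome"] == "I")]["allele_string"]
        assert s.iloc[0] == "100"

    def test_excess_missing_excluded(self):
        df = simple_calls(inds=("i1", "i2"))
        df.loc[(df["individual"] == "i1") & (df["chromosome"] == "I"), "call"] = "MISSING"
        with pytest.warns(UserWarning):
            cwhs = hap.calls_to_cwh(df)
        assert set(cwhs["individual"]) == {"i2"}

    def test_rwh_concatenates_both_chromosomes(self):
        df = simple_calls(inds=("i1",))
        df.loc[(df["chromosome"] == "II") & (df["snp_id"] == "II_s2"), "call"] = "ALT"
        rwhs = hap.cwh_to_rwh(hap.calls_to_cwh(df))
        assert rwhs["rwh_id"].iloc[0] == "R1:000001"

    def test_single_chromosome_individual_excluded(self):
        df = simple_calls(inds=("i1",), chroms=("I",))
        with pytest.warns(UserWarning, match="one chromosome"):
            rwhs = hap.cwh_to_rwh(hap.calls_to_cwh(df))
        assert rwhs.empty

    def test_distinct_rwh_bounds(self):
        # 2 CWHs on chrom I x 1 CWH on chrom II in full linkage -> 2 RWHs
        df = simple_calls(inds=("i1", "i2", "i3", "i4"))
        df.loc[(df["individual"].isin(["i1", "i2"])) & (df["chromosome"] == "I"), "call"] = "ALT"
        rwhs = hap.cwh_to_rwh(hap.calls_to_cwh(df))
        assert rwhs["rwh_id"].nunique() == 2
        counts = hap.tally_rwh(rwhs)
        assert counts["count"].sum() == 4


class TestGrouping:
    def make_counts(self, freq_by_rwh, n=100):
        rows = []
        for gen in (10, 35):
            for rwh, f in freq_by_rwh.items():
                rows.append(("sudden", "1", gen, 1, rwh, int(round(f * n))))
        return pd.DataFrame(
            rows, columns=["regime", "replicate", "generation", "region", "rwh_id", "count"]
        )

    def test_top_k_hand_tally(self):
        counts = self.make_counts({"a": 0.5, "b": 0.3, "c": 0.1, "d": 0.06, "e": 0.04})
        grouped = ns.group_minor(counts, top_k=3)
        assert grouped.primary[("sudden", "1", 1)] == ("a", "b", "c")
        bg = grouped.table[grouped.table["rwh_id"] == "H0A"]
        assert (bg["count"] == 10).all()  # 6 + 4 per epoch

    def test_fewer_than_top_k_all_primary(self):
        counts = self.make_counts({"a": 0.6, "b": 0.4})
        grouped = ns.group_minor(counts, top_k=3)
        assert set(grouped.primary[("sudden", "1", 1)]) == {"a", "b"}
        assert not (grouped.table["designation"] == "background").any()

    def test_counts_conserved(self):
        counts = self.make_counts({"a": 0.5, "b": 0.3, "c": 0.1, "d": 0.06, "e": 0.04})
        grouped = ns.group_minor(counts, top_k=2)
        for gen in (10, 35):
            assert (
                grouped.table[grouped.table["generation"] == gen]["count"].sum()
                == counts[counts["generation"] == gen]["count"].sum()
            )

    def test_pooling_sums_replicates(self):
        rows = [
            ("sudden", "1", 10, 1, "a", 3),
            ("sudden", "2", 10, 1, "a", 5),
            ("sudden", "1", 10, 1, "b", 13),
            ("sudden", "2", 10, 1, "b", 11),
        ]
        counts = pd.DataFrame(
            rows, columns=["regime", "replicate", "generation", "region", "rwh_id", "count"]
        )
        obs = ns.pool_to_regime(ns.group_minor(counts))
        assert obs.counts_at("sudden", 10) == {"a": 8, "b": 24}

    def test_primary_in_one_replicate_stays_primary_regime_wide(self):
        # rwh "c" is minor in replicate 1 (grouped to background) but primary in
        # replicate 2; regime-wide it must stay primary with its full count
        rows = []
        for rwh, c in (("a", 60), ("b", 30), ("d", 8), ("c", 2)):
            rows.append(("sudden", "1", 10, 1, rwh, c))
        for rwh, c in (("c", 70), ("a", 30)):
            rows.append(("sudden", "2", 10, 1, rwh, c))
        counts = pd.DataFrame(
            rows, columns=["regime", "replicate", "generation", "region", "rwh_id", "count"]
        )
        grouped = ns.group_minor(counts, top_k=3)
        assert "c" not in grouped.primary[("sudden", "1", 1)]
        obs = ns.pool_to_regime(grouped)
        assert obs.primary[("sudden", 1)] == ("a", "b", "c", "d")
        assert obs.counts_at("sudden", 10)["c"] == 72


class TestPipelineClosure:
    def test_tally_reproduces_generator_draws(self, experiment):
        """qc -> cwh -> rwh -> tally reproduces the recorded multinomial draws."""
        kept, report = hap.apply_qc(experiment.genotypes)
        assert report.dropped_snps == [] and report.dropped_individuals == []
        counts = hap.tally_rwh(hap.cwh_to_rwh(hap.calls_to_cwh(kept)))
        id_map = experiment.truth.rwh_pipeline_ids
        for (pop, gen, region), drawn in experiment.truth.genotype_draws.items():
            regime, _, rep = pop.rpartition("_")
            sub = counts[
                (counts["regime"] == regime)
                & (counts["replicate"] == rep)
                & (counts["generation"] == gen)
                & (counts["region"] == region)
            ]
            got = dict(zip(sub["rwh_id"], sub["count"]))
            assert got == {id_map[r]: c for r, c in drawn.items()}

    def test_written_files_round_trip(self, small_spec, norms, tmp_path):
        exp = ns.simulate_experiment(small_spec, norms, seed=5, out_dir=tmp_path)
        back = hap.read_genotype_table(tmp_path / "genotypes.tsv")
        pd.testing.assert_frame_equal(back, exp.genotypes)
        counts = hap.read_rwh_counts(tmp_path / "rwh_counts.tsv")
        assert counts["count"].sum() == exp.rwh_counts["count"].sum()

    def test_distinct_rwh_count_within_fig_bounds(self, experiment):
        kept, _ = hap.apply_qc(experiment.genotypes)
        cwhs = hap.calls_to_cwh(kept)
        rwhs = hap.cwh_to_rwh(cwhs)
        merged = rwhs.merge(
            cwhs.pivot_table(
                index=["population", "generation", "individual"],
                columns="chromosome",
                values="allele_string",
                aggfunc="first",
            ),
            on=["population", "generation", "individual"],
        )
        for region, grp in merged.groupby("region"):
            chroms = hap.REGION_CHROMOSOMES[region]
            n_a = grp[chroms[0]].nunique()
            n_b = grp[chroms[1]].nunique()
            n_rwh = grp["rwh_id"].nunique()
            assert max(n_a, n_b) <= n_rwh <= n_a * n_b
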