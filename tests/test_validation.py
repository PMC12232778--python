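import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdmr.intervals import GenomicInterval
from methdmr.synthetic import simulate_clone_bisulfite, \
    simulate_haplotype_records
from methdmr.validation import (CloneCallTable, clone_methylation_percent,
                                conversion_qc, filter_haplotype_records,
                                ont_percpg_tests, ont_region_test,
                                read_clone_table)


def _meta(n_case, n_ctrl, case_group="TDP-A", seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_case + n_ctrl):
        rows.append({"sample_id": f"s{i:03d}",
                     "group": case_group if i < n_case else "CTRL",
                     "sex": "F" if rng.random() < 0.5 else "M",
                     "age_at_death": float(rng.integers(60, 90)),
                     "tissue": "FCX"})
    return pd.DataFrame(rows)


class TestClonePercent:
    def test_formula_arithmetic(self):
        calls = pd.DataFrame(np.zeros((6, 45)),
                             index=[f"c{i}" for i in range(6)])
        calls.iloc[:3, :] = 1.0   # 135 of 270 calls methylated
        pct, _ = clone_methylation_percent(CloneCallTable("s", calls))
        assert pct == pytest.approx(50.0)

    def test_invariant_to_clone_and_position_order(self, rng):
        calls = pd.DataFrame(rng.integers(0, 2, size=(6, 45)).astype(float),
                             index=[f"c{i}" for i in range(6)])
        calls[calls.sample(frac=0.1, axis=1, random_state=1).columns] = np.nan
        table = CloneCallTable("s", calls)
        pct, _ = clone_methylation_percent(table)
        shuffled = calls.sample(frac=1, axis=0, random_state=2) \
                        .sample(frac=1, axis=1, random_state=3)
        pct2, _ = clone_methylation_percent(CloneCallTable("s", shuffled))
        assert pct == pytest.approx(pct2)

    def test_counting_oracle_with_missing(self, rng):
        vals = rng.integers(0, 2, size=(6, 45)).astype(float)
        mask = rng.random((6, 45)) < 0.1
        vals[mask] = np.nan
        calls = pd.DataFrame(vals, index=[f"c{i}" for i in range(6)])
        pct, _ = clone_methylation_percent(CloneCallTable("s", calls))
        meth = scored = 0
        for i in range(6):
            for j in range(45):
                if not np.isnan(vals[i, j]):
                    scored += 1
                    meth += int(vals[i, j])
        assert pct == pytest.approx(100.0 * meth / scored)

    def test_all_missing_is_nan(self):
        calls = pd.DataFrame(np.full((2, 3), np.nan))
        pct, _ = clone_methylation_percent(CloneCallTable("s", calls))
        assert np.isnan(pct)


class TestConversionQC:
    def test_perfect_conversion_passes(self):
        table = simulate_clone_bisulfite(3, 5, 0.5, conversion_error=0.0,
                                         seed=0)
        out = conversion_qc(table)
        assert (out["rate"] == 1.0).all()
        assert (out["status"] == "pass").all()

    def test_threshold_boundary(self):
        conv = pd.DataFrame({"clone": ["c1"], "converted": [90],
                             "unconverted": [10]})
        table = CloneCallTable("s", pd.DataFrame(np.zeros((1, 2))), conv)
        out = conversion_qc(table, threshold=0.95)
        assert out.loc[0, "status"] == "fail"
        assert out.loc[0, "rate"] == pytest.approx(0.90)

    def test_no_noncpg_cytosines_undetermined(self):
        conv = pd.DataFrame({"clone": ["c1"], "converted": [0],
                             "unconverted": [0]})
        table = CloneCallTable("s", pd.DataFrame(np.zeros((1, 2))), conv)
        assert conversion_qc(table).loc[0, "status"] == "undetermined"


class TestCloneTableIO:
    def test_round_trip_from_tsv(self, tmp_path):
        rows = []
        for clone in ("c1", "c2"):
            for pos, call in ((100, 1), (110, 0), (120, 1)):
                rows.append({"sample": "s1", "clone": clone,
                             "position": pos, "call": call,
                             "context": "cpg"})
            rows.append({"sample": "s1", "clone": clone, "position": 999,
                         "call": 0, "context": "non_cpg"})
        pd.DataFrame(rows).to_csv(tmp_path / "t.tsv", sep="\t", index=False)
        (table,) = read_clone_table(tmp_path / "t.tsv")
        pct, _ = clone_methylation_percent(table)
        assert pct == pytest.approx(100 * 4 / 6)
        qc = conversion_qc(table)
        assert (qc["status"] == "pass").all()


REGION = GenomicInterval("chr1", 7574506, 7574692)


class TestHaplotypeFilter:
    def test_coverage_floor_enforced(self):
        meta = _meta(4, 4)
        recs = simulate_haplotype_records(meta, REGION, coverage_mean=8,
                                          seed=2)
        out = filter_haplotype_records(recs, min_coverage=5)
        assert (out["n_total"] >= 5).all()

    def test_invalid_counts_rejected(self):
        bad = pd.DataFrame([{"sample_id": "s", "haplotype": 1,
                             "chrom": "chr1", "pos": 10, "n_mod": 6,
                             "n_total": 5}])
        with pytest.raises(ValueError):
            filter_haplotype_records(bad)


class TestPerCpGTests:
    def test_identical_groups_near_one(self):
        meta = _meta(6, 6)
        recs = simulate_haplotype_records(meta, REGION, delta=0.0, seed=3)
        out = ont_percpg_tests(recs, meta, REGION, ("TDP-A",))
        ok = out[out["skipped"] == ""]
        assert (ok["p_value"] > 0.05).mean() > 0.8

    def test_statistic_matches_rank_sum_enumeration(self):
        meta = _meta(6, 6)
        recs = simulate_haplotype_records(meta, REGION, n_cpgs=1,
                                          delta=1.0, seed=4)
        out = ont_percpg_tests(recs, meta, REGION, ("TDP-A",))
        row = out.iloc[0]
        sub = recs[recs["pos"] == row["pos"]]
        groups = meta.set_index("sample_id").loc[sub["sample_id"], "group"]
        frac = (sub["n_mod"] / sub["n_total"]).to_numpy()
        case = frac[(groups == "TDP-A").to_numpy()]
        ctrl = frac[(groups == "CTRL").to_numpy()]
        # brute-force U statistic: count case-over-control wins
        u = sum((a > b) + 0.5 * (a == b) for a in case for b in ctrl)
        assert row["statistic"] == pytest.approx(u)

    def test_planted_shift_detected_in_most_cpgs(self):
        meta = _meta(25, 25)
        recs = simulate_haplotype_records(meta, REGION, n_cpgs=10,
                                          baseline=0.6, delta=-1.4,
                                          coverage_mean=20, seed=5)
        out = ont_percpg_tests(recs, meta, REGION, ("TDP-A",))
        assert (out["p_value"] < 0.05).mean() > 0.5

    def test_one_sided_coverage_skipped(self):
        meta = _meta(1, 6)   # one case sample = 2 haplotype units < 3
        recs = simulate_haplotype_records(meta, REGION, seed=6)
        out = ont_percpg_tests(recs, meta, REGION, ("TDP-A",))
        assert (out["skipped"] != "").all()


class TestRegionTest:
    def test_identical_groups_null(self):
        meta = _meta(10, 10)
        recs = simulate_haplotype_records(meta, REGION, delta=0.0, phi=0.0,
                                          seed=7)
        fit = ont_region_test(recs, meta, REGION, ("TDP-A",), phi=0.0,
                              covariates=())
        assert fit.p_value > 0.01

    def test_planted_hypomethylation_recovered(self):
        meta = _meta(25, 25)
        recs = simulate_haplotype_records(meta, REGION, n_cpgs=10,
                                          baseline=0.6, delta=-1.0,
                                          coverage_mean=30, seed=8)
        fit = ont_region_test(recs, meta, REGION, ("TDP-A",), phi=0.02)
        est = fit.logFC * np.log(2)
        assert est < 0
        assert abs(est - (-1.0)) / 1.0 < 0.15
        assert fit.p_value < 1e-4

    def test_single_cpg_region_equals_percpg_model(self):
        meta = _meta(10, 10)
        recs = simulate_haplotype_records(meta, REGION, n_cpgs=1,
                                          delta=0.8, phi=0.0, seed=9)
        fit = ont_region_test(recs, meta, REGION, ("TDP-A",), phi=0.0,
                              covariates=())
        from methdmr.diffmeth import fit_locus
        kept = filter_haplotype_records(recs, min_coverage=5)
        pooled = kept.groupby("sample_id")[["n_mod", "n_total"]].sum()
        m = meta.set_index("sample_id").loc[pooled.index]
        direct = fit_locus(pooled["n_mod"].to_numpy(),
                           pooled["n_total"].to_numpy(),
                           pd.DataFrame(index=pooled.index),
                           (m["group"] == "TDP-A").to_numpy(), phi=0.0)
        assert fit.p_value == pytest.approx(direct.p_value, abs=1e-10)
        assert fit.logFC == pytest.approx(direct.logFC, abs=1e-10)
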