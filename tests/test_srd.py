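"""Stop Rate Difference: tabulation, testing, replicate integration, exon score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from ejcmap.io import assign_reads
from ejcmap.simulate import SimConfig, build_toy_genome, simulate_eclip
from ejcmap.annotation import exon_table
from ejcmap.srd import (
    arrest_test,
    chi2_pvalues,
    exon_srd,
    pool_position_stats,
    position_stats,
    secondary_window_overlap,
    srd_pipeline,
    srd_table,
)

from conftest import bed, make_exon


def brute_force_position_stats(reads_rel: list[tuple[int, int]]) -> dict[int, tuple[int, int]]:
    """Loop over (read, position) pairs: arrests and throughs per position."""
    out: dict[int, list[int]] = {}
    for rel5, rel3 in reads_rel:
        out.setdefault(rel5, [0, 0])[0] += 1
        for p in range(rel5 + 1, rel3 + 1):
            out.setdefault(p, [0, 0])[1] += 1
    return {p: tuple(v) for p, v in out.items()}


def brute_force_chi2_p(a_s, t_s, a_c, t_c) -> float:
    """Hand-rolled expected-count chi-square, 1 df, no correction."""
    from scipy.stats import chi2 as chi2_dist
    obs = np.array([[a_s, t_s], [a_c, t_c]], dtype=float)
    if obs.sum(axis=0).min() == 0 or obs.sum(axis=1).min() == 0:
        return 1.0
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2_dist.sf(stat, 1))


def _stats(rows: list[tuple[str, int, int, int]]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["exon_id", "position", "n_arrest", "n_through"])
    df["stop_rate"] = df["n_arrest"] / (df["n_arrest"] + df["n_through"])
    return df


class TestPositionStats:
    def test_counting_example(self):
        # + strand exon [0,40); reads (5',3') = (10,29),(10,29),(12,31)
        exon = make_exon(0, 40, "+", "g:1")
        reads = bed([(10, 30, "+"), (10, 30, "+"), (12, 32, "+")])
        stats = position_stats(assign_reads(reads, [exon])).set_index("position")
        r10, r12 = 10 - 40, 12 - 40
        assert stats.loc[r10, "n_arrest"] == 2 and stats.loc[r10, "n_through"] == 0
        assert stats.loc[r10, "stop_rate"] == 1.0
        assert stats.loc[r12, "n_arrest"] == 1 and stats.loc[r12, "n_through"] == 2
        assert stats.loc[r12, "stop_rate"] == pytest.approx(1 / 3)

    def test_single_read(self):
        exon = make_exon(0, 40, "+", "g:1")
        stats = position_stats(assign_reads(bed([(20, 35, "+")]), [exon]))
        by_pos = stats.set_index("position")["stop_rate"]
        assert by_pos[20 - 40] == 1.0
        assert (by_pos.drop(20 - 40) == 0.0).all()

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(8)
        exon = make_exon(0, 120, "+", "g:1")
        rows = []
        for _ in range(400):
            s = int(rng.integers(0, 110))
            rows.append((s, min(s + int(rng.integers(1, 35)), 120), "+"))
        assigned = assign_reads(bed(rows), [exon])
        got = position_stats(assigned).set_index("position")
        expected = brute_force_position_stats(
            list(zip(assigned["rel5"], assigned["rel3"]))
        )
        assert set(got.index) == set(expected)
        for p, (na, nt) in expected.items():
            assert (got.loc[p, "n_arrest"], got.loc[p, "n_through"]) == (na, nt)

    def test_minus_strand_orientation(self):
        exon = make_exon(0, 40, "-", "g:1")
        # minus read genomic [10, 30): 5' end at 29 -> rel5 = 0-29-1 = -30
        stats = position_stats(assign_reads(bed([(10, 30, "-")]), [exon]))
        assert stats.loc[stats["n_arrest"] == 1, "position"].item() == -30
        # covers genomically down to 10 -> rel3 = 0-10-1 = -11
        assert stats["position"].min() == -30 and stats["position"].max() == -11

    def test_pooling_sums_counts(self):
        a = _stats([("e", -5, 3, 7)])
        b = _stats([("e", -5, 1, 9), ("e", -4, 2, 0)])
        pooled = pool_position_stats([a, b]).set_index("position")
        assert pooled.loc[-5, "n_arrest"] == 4 and pooled.loc[-5, "n_through"] == 16
        assert pooled.loc[-5, "stop_rate"] == pytest.approx(0.2)


class TestArrestTest:
    def test_worked_example(self):
        # [[10,90],[2,98]]: expected counts 6/94, chi2 = 32/6 + 32/94 = 5.6738
        p = arrest_test(10, 90, 2, 98)
        assert p == pytest.approx(brute_force_chi2_p(10, 90, 2, 98), abs=1e-12)
        assert p == pytest.approx(0.01722, abs=5e-5)

    def test_identical_rates_p_one(self):
        assert arrest_test(5, 95, 5, 95) == 1.0

    def test_degenerate_marginal_p_one(self):
        assert arrest_test(0, 0, 2, 98) == 1.0
        assert arrest_test(0, 100, 0, 50) == 1.0

    def test_vector_matches_scipy(self):
        rng = np.random.default_rng(3)
        tbl = rng.integers(1, 200, size=(200, 4))
        ours = chi2_pvalues(*tbl.T)
        for row, p in zip(tbl, ours):
            ref = chi2_contingency(row.reshape(2, 2), correction=False).pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(a=st.integers(1, 500), t=st.integers(1, 500),
           ac=st.integers(0, 500), tc=st.integers(1, 500), bump=st.integers(1, 100))
    def test_monotone_in_sample_arrests(self, a, t, ac, tc, bump):
        """More arrests (all else fixed) never weakens an enriched signal."""
        rate_s, rate_c = a / (a + t), ac / (ac + tc)
        if rate_s <= rate_c:
            return
        assert arrest_test(a + bump, t, ac, tc) <= arrest_test(a, t, ac, tc) + 1e-12


class TestSrdTable:
    def test_replicate_integration_arithmetic(self):
        # three replicates at one position, rates .3/.4/.5 vs control .1
        reps = [_stats([("e", -27, r, 100 - r)]) for r in (30, 40, 50)]
        ctrl = _stats([("e", -27, 10, 90)])
        out = srd_table(reps, ctrl)
        row = out.iloc[0]
        assert row["srd"] == pytest.approx(0.4 - 0.1)
        assert row["n_significant_replicates"] == 3
        assert bool(row["significant"])

    def test_one_sided_gate(self):
        # sample rates below control: never significant regardless of p
        reps = [_stats([("e", -27, r, 100 - r)]) for r in (30, 40, 50)]
        ctrl = _stats([("e", -27, 50, 50)])
        out = srd_table(reps, ctrl)
        assert out.iloc[0]["srd"] == pytest.approx(0.4 - 0.5)
        assert not out.iloc[0]["significant"]

    def test_missing_replicate_averaged_over_present(self):
        reps = [_stats([("e", -27, 30, 70)]), _stats([("e", -27, 50, 50)]),
                _stats([("e", -26, 1, 1)])]
        ctrl = _stats([("e", -27, 10, 90), ("e", -26, 1, 1)])
        out = srd_table(reps, ctrl).set_index("position")
        assert out.loc[-27, "srd"] == pytest.approx((0.3 + 0.5) / 2 - 0.1)

    def test_missing_control_flagged_rate_zero(self):
        reps = [_stats([("e", -27, 30, 70)]), _stats([("e", -27, 40, 60)])]
        ctrl = _stats([("e", -40, 1, 9)])
        out = srd_table(reps, ctrl)
        row = out[out["position"] == -27].iloc[0]
        assert bool(row["control_missing"])
        assert row["srd"] == pytest.approx(0.35)


class TestExonSrd:
    def _positions(self, sig: dict[int, float]) -> pd.DataFrame:
        return pd.DataFrame(
            {"exon_id": "g:2", "position": list(sig), "srd": list(sig.values()),
             "significant": True}
        )

    def _exons(self):
        return [make_exon(1000, 1200, "+", "g:2")]

    def test_mean_over_window_positions(self):
        out = exon_srd(self._positions({-27: 0.4, -25: 0.2}), self._exons())
        row = out.iloc[0]
        assert row["srd_score"] == pytest.approx(0.3)
        assert bool(row["detected"]) and row["n_significant_positions"] == 2

    def test_outside_window_not_detected(self):
        out = exon_srd(self._positions({-22: 0.4}), self._exons())
        assert not out.iloc[0]["detected"]
        assert np.isnan(out.iloc[0]["srd_score"])

    def test_negative_members_included_in_mean(self):
        out = exon_srd(self._positions({-27: 0.4, -24: -0.1}), self._exons())
        assert out.iloc[0]["srd_score"] == pytest.approx(0.15)
        assert bool(out.iloc[0]["detected"])

    def test_short_exon_flagged(self):
        short = [make_exon(0, 28, "+", "g:2")]
        out = exon_srd(self._positions({-27: 0.4}), short)
        assert bool(out.iloc[0]["window_truncated"])


class TestSecondaryWindow:
    def test_subset(self):
        assert secondary_window_overlap({"e1", "e2"}, {"e1", "e2", "e3"}) == 1.0

    def test_disjoint(self):
        assert secondary_window_overlap({"e1"}, {"e2"}) == 0.0

    def test_empty_undefined(self):
        assert secondary_window_overlap(set(), {"e1"}) is None


class TestOnSyntheticData:
    def test_significant_positions_concentrate_at_known_crosslink(self):
        """All crosslinks at -27: significant positions stay in [-32,-23].

        Concentration is tallied over the junction-proximal range the
        meta-exon analysis operates in ([-100,-1], the standard peak
        search interval); a raw p<0.05 position test unavoidably sprinkles
        ~0.1% isolated false positives over the rest of each exon body,
        which is background, not deposition geometry.
        """
        cfg = SimConfig(seed=19, n_genes=200, crosslink_sd=0.05,
                        eclip_depth=50_000, sminput_depth=50_000)
        genome, models, truth = build_toy_genome(cfg)
        libs = simulate_eclip(cfg, genome, truth)
        exons = exon_table(models)
        pos, _ = srd_pipeline(
            [libs[f"eclip_{i}"] for i in (1, 2, 3)],
            [libs[f"sminput_{j}"] for j in (1, 2)], exons,
        )
        sig = pos[pos["significant"] & pos["position"].between(-100, -1)]
        in_window = sig["position"].between(-32, -23).mean()
        assert in_window >= 0.9

    def test_secondary_window_nearly_empty_at_default_noise(self, default_sim,
                                                            default_exons, default_srd):
        cfg, _, _, _, libs = default_sim
        # all-replicate detections in the secondary window [-22,-13]
        reps = [libs[f"eclip_{i}"] for i in (1, 2, 3)]
        ctrls = [libs[f"sminput_{j}"] for j in (1, 2)]
        _, ex18 = srd_pipeline(reps, ctrls, default_exons, min_reps=3,
                               window=(-22, -13))
        assert ex18["detected"].mean() <= 0.01

    def test_specificity_on_last_exons(self, default_srd, default_sim):
        _, _, _, truth, _ = default_sim
        _, ex = default_srd
        last = ex[ex["cls"] == "last"]
        assert last["detected"].mean() <= 0.05
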