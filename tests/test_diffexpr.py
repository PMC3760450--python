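"""ANCOVA differential expression, BH FDR, the filter cascade and recovery."""

import numpy as np
import pandas as pd
import pytest

import chronostage as cs
from chronostage.config import AnalysisConfig
from chronostage.datatypes import META_COLUMNS, select_samples
from chronostage.diffexpr import (
    ancova_de,
    ancova_samples,
    bh_fdr,
    de_cascade,
    delay_resistant_genes,
    early_response,
    lenient_significant,
    range_guard,
    recovery_analysis,
)


# ---------------------------------------------------------------------------
# BH FDR


def brute_force_bh(p):
    """Literal step-up definition: q_i = min_{rank(j) >= rank(i)} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos_i, i in enumerate(order):
        q[i] = min(p[order[pos]] * m / (pos + 1) for pos in range(pos_i, m))
    return np.minimum(q, 1.0)


class TestBHFDR:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            q = bh_fdr(p)
            np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_q_at_least_p_and_rank_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# ANCOVA


def _ancova_fixture(shift=1.0, noise=0.05, seed=0, n_probes=3):
    """Controls at harvests 14 and 20, exposed at 20, PA = harvest time."""
    rows = []
    for h in (14.0, 20.0):
        for r in range(1, 5):
            rows.append((f"c{h:g}r{r}", 0.0, "continuous", h, r))
    for r in range(1, 5):
        rows.append((f"e20r{r}", 15.0, "continuous", 20.0, r))
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    rng = np.random.default_rng(seed)
    t = meta["harvest_h"].to_numpy(dtype=float)
    exposed = (meta["concentration_uM"] > 0).to_numpy(dtype=float)
    values = np.vstack(
        [
            5.0 + 0.1 * t + shift * exposed + rng.normal(0, noise, len(meta))
            for _ in range(n_probes)
        ]
    )
    matrix = pd.DataFrame(
        values, index=[f"p{i}" for i in range(n_probes)], columns=meta["sample_id"]
    )
    pa = pd.DataFrame(
        {"pa_h": t, "harvest_h": meta["harvest_h"]},
        index=pd.Index(meta["sample_id"], name="sample_id"),
    )
    return matrix, meta, pa


class TestAncova:
    def test_shift_recovered_and_matches_statsmodels(self):
        import statsmodels.api as sm

        matrix, meta, pa = _ancova_fixture(shift=1.0)
        res = ancova_de(matrix, meta, pa, 20.0)
        assert res["log2fc"].to_numpy() == pytest.approx(1.0, abs=0.1)
        assert (res["p"] < 1e-4).all()
        # oracle: per-probe OLS through statsmodels
        exp, ctl = ancova_samples(meta, 20.0)
        samples = ctl + exp
        X = sm.add_constant(
            np.column_stack(
                [
                    pa.loc[samples, "pa_h"],
                    [0.0] * len(ctl) + [1.0] * len(exp),
                ]
            )
        )
        for probe in matrix.index:
            fit = sm.OLS(matrix.loc[probe, samples].to_numpy(), X).fit()
            assert res.loc[probe, "log2fc"] == pytest.approx(fit.params[2], abs=1e-10)
            assert res.loc[probe, "p"] == pytest.approx(fit.pvalues[2], abs=1e-10)

    def test_identical_groups_give_zero_fold(self):
        matrix, meta, pa = _ancova_fixture(shift=0.0, noise=0.0)
        res = ancova_de(matrix, meta, pa, 20.0)
        assert res["log2fc"].to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_delay_absorbed_by_pa_covariate(self):
        """Exposed samples drawn from the delayed trajectory, PA correctly
        supplied: the exposure contrast is null."""
        cfg = cs.SimConfig(effect_scale=0.0, delay_max=6.0, n_probes=500, seed=17)
        matrix, meta, _, truth = cs.generate(cfg)
        pa = pd.DataFrame(
            {
                "pa_h": truth.sample_age,
                "harvest_h": meta.set_index("sample_id")["harvest_h"],
            }
        )
        res = ancova_de(matrix, meta, pa, 20.0)
        dev = truth.probes.index[truth.probes["class"] == "developmental"]
        assert res.loc[dev, "log2fc"].abs().mean() < 0.1
        assert (res.loc[dev, "p"] < 1e-4).sum() <= 2

    def test_rank_deficient_design_errors(self):
        matrix, meta, pa = _ancova_fixture()
        pa["pa_h"] = 20.0  # constant covariate -> collinear with the intercept
        with pytest.raises(ValueError, match="rank-deficient"):
            ancova_de(matrix, meta, pa, 20.0)

    def test_missing_pa_errors(self):
        matrix, meta, pa = _ancova_fixture()
        with pytest.raises(ValueError, match="Predicted Age"):
            ancova_de(matrix, meta, pa.iloc[:3], 20.0)


class TestRangeGuard:
    def _matrix(self, exposed_log2, control_log2):
        cols = [f"e{i}" for i in range(len(exposed_log2))] + [
            f"c{i}" for i in range(len(control_log2))
        ]
        values = np.array([list(exposed_log2) + list(control_log2)])
        m = pd.DataFrame(values, index=["p"], columns=cols)
        return m, [c for c in cols if c.startswith("e")], [
            c for c in cols if c.startswith("c")
        ]

    def test_exposed_equal_to_control_max_fails(self):
        m, e, c = self._matrix([np.log2(200.0)] * 2, [np.log2(100.0), np.log2(200.0)])
        assert not range_guard(m, e, c).loc["p"]

    def test_above_envelope_passes(self):
        # controls span [100, 200]; exposed mean 250 >= 1.2 * 200 = 240
        m, e, c = self._matrix([np.log2(250.0)] * 2, [np.log2(100.0), np.log2(200.0)])
        assert range_guard(m, e, c).loc["p"]

    def test_below_envelope_passes(self):
        # exposed mean 80 <= 100 / 1.2 = 83.3
        m, e, c = self._matrix([np.log2(80.0)] * 2, [np.log2(100.0), np.log2(200.0)])
        assert range_guard(m, e, c).loc["p"]

    def test_inside_envelope_fails(self):
        m, e, c = self._matrix([np.log2(150.0)] * 2, [np.log2(100.0), np.log2(200.0)])
        assert not range_guard(m, e, c).loc["p"]


# ---------------------------------------------------------------------------
# the eight-probe cascade toy


JITTER = np.array([-0.03, -0.01, 0.01, 0.03])


def _toy_cascade():
    """Eight probes exercising each rule of the strict cascade.

    Controls at harvests 14 and 20 (4 replicates each), exposed at 20; PA is
    the harvest time.  Survivors: up_clean, down_clean, up_mid (see the
    per-probe comments).
    """
    rows = []
    for h in (14.0, 20.0):
        for r in range(1, 5):
            rows.append((f"c{h:g}r{r}", 0.0, "continuous", h, r))
    for r in range(1, 5):
        rows.append((f"e20r{r}", 15.0, "continuous", 20.0, r))
    meta = pd.DataFrame(rows, columns=META_COLUMNS)

    def probe(c14, c20, e20, spread=None):
        e_jit = JITTER if spread is None else spread
        return np.concatenate([c14 + JITTER, c20 + JITTER, e20 + e_jit])

    data = {
        # +2.0 contrast, far above the envelope -> survives all three rules
        "up_clean": probe(5.0, 5.3, 7.3),
        # -2.0 contrast, far below the envelope -> survives
        "down_clean": probe(6.0, 6.3, 4.3),
        # +1.7 contrast (> log2(1.8) = 0.848) -> survives
        "up_mid": probe(8.0, 8.2, 9.9),
        # +0.5 contrast: tiny p but below the 1.8-fold cutoff
        "small_fold": probe(5.0, 5.2, 5.7),
        # no contrast at all
        "null_a": probe(5.0, 5.0, 5.0),
        # +1.9 contrast but the exposed level sits inside the control
        # min-max envelope (the delayed-trajectory artifact) -> range guard
        "range_fail": probe(7.0, 5.0, 6.9),
        # large contrast, huge exposed spread -> p above 1e-4
        "noisy": probe(5.0, 5.1, 6.1, spread=np.array([-1.5, -0.5, 0.5, 1.5])),
        "null_b": probe(6.0, 6.0, 6.0),
    }
    matrix = pd.DataFrame(data, index=meta["sample_id"]).T
    pa = pd.DataFrame(
        {
            "pa_h": meta["harvest_h"].astype(float).to_numpy(),
            "harvest_h": meta["harvest_h"],
        },
        index=pd.Index(meta["sample_id"], name="sample_id"),
    )
    return matrix, meta, pa


def test_cascade_toy_enumerated_by_independent_rules():
    """The cascade's survivors equal a hand enumeration of p/fold/range."""
    import statsmodels.api as sm

    matrix, meta, pa = _toy_cascade()
    cfg = AnalysisConfig()
    exp, ctl = ancova_samples(meta, 20.0)
    samples = ctl + exp
    X = sm.add_constant(
        np.column_stack(
            [pa.loc[samples, "pa_h"], [0.0] * len(ctl) + [1.0] * len(exp)]
        )
    )
    expected = []
    for probe in matrix.index:
        fit = sm.OLS(matrix.loc[probe, samples].to_numpy(), X).fit()
        p_ok = fit.pvalues[2] < cfg.p_de
        fold_ok = abs(fit.params[2]) >= np.log2(cfg.fc_de)
        linear = 2.0 ** matrix.loc[probe]
        exp_mean = linear[exp].mean()
        cmin, cmax = linear[ctl].min(), linear[ctl].max()
        range_ok = exp_mean >= cfg.range_guard * cmax or exp_mean <= cmin / cfg.range_guard
        if p_ok and fold_ok and range_ok:
            expected.append(probe)
    assert expected == ["up_clean", "down_clean", "up_mid"]

    summary = de_cascade(matrix, meta, pa)
    assert summary.harvests == [20.0]
    assert summary.significant[20.0] == expected
    # each distractor fails for its designed reason
    res = summary.results[20.0]
    assert res.loc["small_fold", "p"] < cfg.p_de
    assert abs(res.loc["small_fold", "log2fc"]) < np.log2(cfg.fc_de)
    assert res.loc["noisy", "p"] > cfg.p_de
    assert abs(res.loc["range_fail", "log2fc"]) >= np.log2(cfg.fc_de)
    assert res.loc["range_fail", "p"] < cfg.p_de
    assert not res.loc["range_fail", "range_pass"]


# ---------------------------------------------------------------------------
# cascade on synthetic data


class TestCascade:
    def test_counts_grow_with_harvest(self, default_run):
        summary = de_cascade(
            default_run.present, default_run.metadata, default_run.pa_table
        )
        counts = [len(summary.significant[h]) for h in summary.harvests]
        assert counts == sorted(counts)
        assert counts[-1] > counts[0] > 0

    def test_detected_probes_are_toxicant_responsive(self, default_run):
        summary = de_cascade(
            default_run.present, default_run.metadata, default_run.pa_table
        )
        classes = default_run.truth.probes["class"]
        assert all(classes[p] in ("toxicant", "both") for p in summary.union)

    def test_venn_partition_conserved(self, default_run):
        summary = de_cascade(
            default_run.present, default_run.metadata, default_run.pa_table
        )
        assert sum(summary.venn.values()) == len(summary.union)
        # regions are disjoint: every union member has exactly one signature
        assert len(set(summary.union)) == len(summary.union)

    def test_null_data_yield_almost_no_hits(self, delay_only_run):
        summary = de_cascade(
            delay_only_run.present, delay_only_run.metadata, delay_only_run.pa_table
        )
        n_tests = sum(len(r) for r in summary.results.values())
        # expected strict false positives: well under n_tests * 1e-4 after the
        # fold and range rules
        assert sum(len(v) for v in summary.significant.values()) <= max(
            3, 5 * n_tests * 1e-4
        )


class TestRecovery:
    def test_washout_unique_probes_are_the_recovery_specific_class(self, default_run):
        rec = recovery_analysis(
            default_run.present, default_run.metadata, default_run.pa_table
        )
        truth = default_run.truth.probes
        triggered = set(truth.index[truth.washout_triggered])
        assert set(rec.washout_unique) == triggered & set(rec.strict.union)
        assert len(rec.washout_unique) > 0

    def test_lenient_continuous_hit_is_not_unique(self, default_run):
        rec = recovery_analysis(
            default_run.present, default_run.metadata, default_run.pa_table
        )
        lenient = set(rec.continuous_lenient)
        assert all(p not in lenient for p in rec.washout_unique)
        # strict washout hits that do respond during exposure are not unique
        overlapping = [p for p in rec.strict.union if p in lenient]
        assert all(p not in rec.washout_unique for p in overlapping)

    def test_missing_continuous_arm_errors(self, default_run):
        meta = default_run.metadata
        washout_only = meta[meta["regime"].isin(["washout8", "sham8"])]
        sub = default_run.present[list(washout_only["sample_id"])]
        with pytest.raises(ValueError, match="continuous"):
            recovery_analysis(sub, washout_only, default_run.pa_table)


class TestDelayResistant:
    def _design(self):
        rows = []
        for h in (0.0, 2.0, 8.0, 14.0, 20.0, 26.0):
            for conc in (0.0, 15.0):
                if h == 0.0 and conc > 0:
                    continue
                for r in range(1, 5):
                    rows.append((f"{'e' if conc else 'c'}{h:g}r{r}", conc, "continuous", h, r))
        return pd.DataFrame(rows, columns=META_COLUMNS)

    def test_hand_cases(self):
        meta = self._design()
        t = meta["harvest_h"].to_numpy(dtype=float)
        exposed = (meta["concentration_uM"] > 0).to_numpy()
        # tracker: ramps 1 log2 per interval in both arms -> passes both rules
        tracker = t / 6.0
        # delayed: exposed arm differs 1.5-fold (0.585 log2) from 14 h onward
        delayed = t / 6.0 - np.where(exposed & (t >= 14.0), np.log2(1.5), 0.0)
        # flat: no consecutive 1.8-fold step
        flat = np.full(len(meta), 3.0)
        matrix = pd.DataFrame(
            [tracker, delayed, flat],
            index=["tracker", "delayed", "flat"],
            columns=meta["sample_id"],
        )
        out = delay_resistant_genes(["tracker", "delayed", "flat"], matrix, meta)
        assert out == ["tracker"]

    def test_generator_immune_class_recovered(self):
        cfg = cs.SimConfig(
            n_probes=600,
            delay_immune_fraction=0.3,
            slope_range=(0.15, 0.3),
            saturating_fraction=0.0,
            seed=23,
        )
        matrix, meta, calls, truth = cs.generate(cfg)
        dev = list(
            truth.probes.index[truth.probes["class"].isin(["developmental", "both"])]
        )
        out = set(delay_resistant_genes(dev, matrix, meta))
        immune = set(truth.probes.index[truth.probes.delay_immune])
        # only immune probes can satisfy the <=1.2-fold rule under a 6 h delay
        assert out <= immune
        # steep immune probes (consecutive step s*6 >= log2(1.8)) are found
        steep = {
            p
            for p in immune
            if abs(truth.probes.loc[p, "slope"]) * 6.0 >= np.log2(1.8)
            and truth.probes.loc[p, "class"] == "developmental"
        }
        assert len(out & steep) / max(len(steep), 1) > 0.5


class TestEarlyResponse:
    def test_empty_harvest_two_set(self):
        from chronostage.diffexpr import DESetSummary

        summary = DESetSummary(arm="continuous", harvests=[2.0], significant={2.0: []})
        assert early_response(summary) == []

    def test_early_onset_probes_recovered(self, default_run):
        summary = de_cascade(
            default_run.present, default_run.metadata, default_run.pa_table
        )
        early = set(early_response(summary))
        truth = default_run.truth.probes
        early_truth = set(
            truth.index[
                truth["class"].isin(["toxicant", "both"])
                & (truth.onset_h == 0.0)
                & (~truth.washout_triggered)
            ]
        )
        late_truth = set(
            truth.index[truth["class"].isin(["toxicant", "both"]) & (truth.onset_h >= 8.0)]
        )
        assert len(early & early_truth) / len(early_truth) > 0.9
        assert not early & late_truth

    def test_gene_mapping_applied(self, default_run):
        summary = de_cascade(
            default_run.present, default_run.metadata, default_run.pa_table
        )
        probes = summary.significant[2.0]
        mapping = {p: [f"gene_{p}"] for p in probes}
        genes = early_response(summary, mapping)
        assert genes == [f"gene_{p}" for p in probes]
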