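"""Variant calling, sample positivity, fingerprints and panel selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, chi2

from ctmon.detection import (MonitoredVariant, call_variants, calls_to_frame,
                             check_fingerprint, classify_sample,
                             genotype_from_af, max_homopolymer_run,
                             read_panel_vcf, residual_tumour_p, select_panel,
                             summarize_sample, write_panel_vcf)
from ctmon.errormodel import ErrorModelParams, ErrorModel, bb_tail_pvalues, fit_background
from ctmon.simdata import simulate_site_observations


def make_model(mean=2e-4, strength=5000.0):
    """A uniform background model across all strata."""
    params = []
    for r in "ACGT":
        for a in "ACGT":
            if r == a:
                continue
            for level in (2, 3, 4):
                params.append(ErrorModelParams(
                    f"{r}>{a}", level, mean / 3 * strength,
                    (1 - mean / 3) * strength, 100, "moments"))
    return ErrorModel(params)


def make_pileup(rows):
    """rows: (pos, level, depth, ref, alt, alt_count)."""
    recs = []
    for pos, level, depth, ref, alt, alt_count in rows:
        counts = {b: 0 for b in "ACGT"}
        counts[alt] = alt_count
        counts[ref] = depth - alt_count
        recs.append({"chrom": "sim1", "pos": pos, "level": level,
                     "depth": depth, "nA": counts["A"], "nC": counts["C"],
                     "nG": counts["G"], "nT": counts["T"]})
    return pd.DataFrame(recs)


def hand_bh(ps):
    """Step-up Benjamini-Hochberg computed by the textbook procedure."""
    m = len(ps)
    order = np.argsort(ps)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, ps[idx] * m / rank)
        q[idx] = prev
    return q


class TestCallVariants:
    panel = [MonitoredVariant("sim1", 10, "C", "T"),
             MonitoredVariant("sim1", 11, "C", "T"),
             MonitoredVariant("sim1", 12, "C", "T")]

    def test_zero_alt_everywhere_is_undetected_with_p_one(self):
        pileup = make_pileup([(10, l, 1000, "C", "T", 0) for l in (2, 3, 4)])
        calls = call_variants(pileup, self.panel[:1], make_model())
        c = calls[0]
        assert c.p == 1.0 and c.maf == 0.0 and not c.detected and c.assessable

    def test_small_p_is_detected_at_stated_threshold(self):
        pileup = make_pileup([(10, 2, 2000, "C", "T", 8)])
        calls = call_variants(pileup, self.panel[:1], make_model())
        assert calls[0].p < 0.05 and calls[0].detected

    def test_fdr_matches_hand_step_up(self):
        pileup = make_pileup(
            [(10, 2, 2000, "C", "T", 4), (11, 2, 2000, "C", "T", 6),
             (12, 2, 2000, "C", "T", 2)])
        calls = call_variants(pileup, self.panel, make_model())
        ps = np.array([c.p for c in calls])
        expected = hand_bh(ps)
        assert np.allclose([c.fdr for c in calls], expected, rtol=1e-12)
        # BH q-values dominate their p-values and respect p-ordering
        assert all(c.fdr >= c.p for c in calls)

    def test_position_absent_from_pileup_not_assessable(self):
        pileup = make_pileup([(10, 2, 2000, "C", "T", 0)])
        calls = call_variants(pileup, self.panel, make_model())
        assert calls[0].assessable
        assert not calls[1].assessable and "coverage" in calls[1].reason
        assert not calls[1].detected

    def test_indels_carried_but_not_scored(self):
        panel = [MonitoredVariant("sim1", 10, "C", "T", variant_class="indel")]
        calls = call_variants(make_pileup([(10, 2, 2000, "C", "T", 5)]),
                              panel, make_model())
        assert not calls[0].assessable and "indel" in calls[0].reason

    def test_fingerprint_variants_never_enter_burden_statistics(self):
        panel = self.panel[:1] + [
            MonitoredVariant("sim1", 11, "C", "T", role="fingerprint")]
        pileup = make_pileup([(10, 2, 2000, "C", "T", 0),
                              (11, 2, 2000, "C", "T", 1000)])
        calls = call_variants(pileup, panel, make_model())
        assert len(calls) == 1 and calls[0].variant.pos == 10


class TestResidualTumourP:
    def _call(self, p):
        c = call_variants(make_pileup([(10, 2, 1000, "C", "T", 0)]),
                          [MonitoredVariant("sim1", 10, "C", "T")],
                          make_model())[0]
        c.p = p
        return c

    def test_single_variant_identity(self):
        assert residual_tumour_p([self._call(0.04)]) == pytest.approx(0.04)

    def test_all_null_variants_give_one(self):
        calls = [self._call(1.0) for _ in range(30)]
        assert residual_tumour_p(calls) == pytest.approx(1.0)

    def test_three_variant_chi2_oracle(self):
        calls = [self._call(p) for p in (0.01, 0.5, 0.5)]
        stat = 2 * (math.log(100) + math.log(2) + math.log(2))
        expected = float(chi2.sf(stat, df=6))
        assert residual_tumour_p(calls) == pytest.approx(expected, rel=1e-12)

    def test_no_assessable_variants_is_an_error(self):
        c = self._call(0.5)
        c.assessable = False
        with pytest.raises(ValueError, match="assessable"):
            residual_tumour_p([c])

    def test_alternative_combiners_available(self):
        calls = [self._call(p) for p in (0.01, 0.2)]
        assert 0 < residual_tumour_p(calls, method="stouffer") < 1
        assert residual_tumour_p(calls, method="bonferroni") == pytest.approx(0.02)


class TestClassifySample:
    def _calls(self, n_detected, n_total=5):
        calls = []
        for i in range(n_total):
            c = call_variants(make_pileup([(10, 2, 1000, "C", "T", 0)]),
                              [MonitoredVariant("sim1", 10, "C", "T")],
                              make_model())[0]
            c.detected = i < n_detected
            c.p = 0.01 if c.detected else 0.9
            calls.append(c)
        return calls

    def test_adjuvant_three_detected_is_positive(self):
        assert classify_sample(self._calls(3), "adjuvant") is True

    def test_adjuvant_two_detected_is_negative(self):
        assert classify_sample(self._calls(2), "adjuvant") is False

    def test_palliative_threshold_rule(self):
        assert classify_sample(self._calls(0), "palliative", residual_p=0.2) is False
        assert classify_sample(self._calls(0), "palliative", residual_p=0.04) is True

    def test_unknown_cohort_rejected(self):
        with pytest.raises(ValueError, match="cohort"):
            classify_sample(self._calls(0), "neoadjuvant")

    def test_pure_function_of_inputs(self):
        calls = self._calls(3)
        assert all(classify_sample(calls, "adjuvant") for _ in range(5))

    def test_null_sample_specificity_bounded_by_binomial(self):
        """Adjuvant >= 3-variant rule on variant-free samples: the sample
        false-positive rate stays below the binomial bound implied by the
        empirical per-variant false-positive rate."""
        rng = np.random.default_rng(5150)
        train = simulate_site_observations(8000, depth=5000, error_mean=2e-4,
                                           error_rho=1e-4, level=2, rng=rng)
        model = fit_background(train)
        n_samples, n_variants, depth = 400, 20, 5000
        # brute-force resampling oracle of the per-variant and sample rates
        params = model.get("C>T", 2)
        m = (1 - 1e-4) / 1e-4
        p_true = rng.beta((2e-4 / 3) * m, (1 - 2e-4 / 3) * m,
                          size=(n_samples, n_variants))
        alts = rng.binomial(depth, p_true)
        ps = bb_tail_pvalues(alts.ravel(), depth, params).reshape(alts.shape)
        detected = ps < 0.05
        per_variant_fpr = detected.mean()
        sample_positive = (detected.sum(axis=1) >= 3).mean()
        bound = float(binom.sf(2, n_variants, per_variant_fpr))
        se = math.sqrt(max(bound, 1e-4) * (1 - bound) / n_samples)
        assert sample_positive <= bound + 3 * se

    def test_power_at_one_percent_af(self):
        """Spiked variant at AF 1%, depth 5000, background 2e-4: detection
        in >= 99% of 200 simulations."""
        rng = np.random.default_rng(808)
        train = simulate_site_observations(8000, depth=5000, error_mean=2e-4,
                                           error_rho=1e-4, level=2, rng=rng)
        model = fit_background(train)
        params = model.get("C>T", 2)
        depth, af = 5000, 0.01
        alts = rng.binomial(depth, af, size=200)
        ps = bb_tail_pvalues(alts, depth, params)
        assert (ps < 0.05).mean() >= 0.99


class TestFingerprint:
    def plasma(self, afs, depth=500):
        return pd.DataFrame({"snv": [f"s{i}" for i in range(len(afs))],
                             "af": afs, "depth": depth})

    def test_identical_genotypes_full_concordance(self):
        res = check_fingerprint(self.plasma([0.5] * 20),
                                {f"s{i}": "0/1" for i in range(20)})
        assert res.concordance == 1.0 and res.passed

    def test_fully_discordant_fails(self):
        res = check_fingerprint(self.plasma([0.0] * 20),
                                {f"s{i}": "1/1" for i in range(20)})
        assert res.concordance == 0.0 and not res.passed and res.assessable

    def test_boundary_ninety_percent_passes_inclusive(self):
        afs = [0.5] * 18 + [0.0, 1.0]  # exactly 18/20 concordant het calls
        res = check_fingerprint(self.plasma(afs),
                                {f"s{i}": "0/1" for i in range(20)})
        assert res.concordance == pytest.approx(0.9) and res.passed

    def test_too_few_covered_snvs_not_assessable(self):
        res = check_fingerprint(self.plasma([0.5] * 8),
                                {f"s{i}": "0/1" for i in range(8)})
        assert not res.assessable
        low_depth = self.plasma([0.5] * 20, depth=50)
        res = check_fingerprint(low_depth, {f"s{i}": "0/1" for i in range(20)})
        assert not res.assessable

    @pytest.mark.parametrize("af, gt", [(0.05, "0/0"), (0.1, "0/1"),
                                        (0.5, "0/1"), (0.9, "0/1"),
                                        (0.95, "1/1")])
    def test_genotype_bins(self, af, gt):
        assert genotype_from_af(af) == gt


class TestSelectPanel:
    def candidates(self, n=50, **overrides):
        base = {"ref": "C", "alt": "T", "driver": False, "population_af": 0.0,
                "context": "ACGTACGTACG", "on_target": True}
        rows = []
        for i in range(n):
            row = dict(base, chrom="1", pos=i + 1, tumour_af=0.1 + 0.002 * i)
            rows.append(row)
        df = pd.DataFrame(rows)
        for col, val in overrides.items():
            df.loc[0, col] = val
        return df

    def test_fifty_eligible_yield_exactly_thirty(self):
        panel, warnings = select_panel(self.candidates(50))
        assert len(panel) == 30 and not warnings

    def test_common_population_variant_removed(self):
        df = self.candidates(5, population_af=0.05)
        panel, _ = select_panel(df)
        assert all(v.pos != 1 for v in panel)

    def test_homopolymer_context_removed(self):
        df = self.candidates(5, context="TCAAAAAAAAGT")  # 8-base A run
        panel, _ = select_panel(df)
        assert all(v.pos != 1 for v in panel)
        assert max_homopolymer_run("TCAAAAAAAAGT") == 8

    def test_off_target_removed_and_warning_when_few_survive(self):
        df = self.candidates(2)
        df["on_target"] = [True, False]
        panel, warnings = select_panel(df)
        assert len(panel) == 1
        assert warnings and "sensitivity" in warnings[0]

    def test_drivers_rank_before_higher_af_passengers(self):
        df = self.candidates(40)
        df.loc[3, "driver"] = True  # low tumour AF but a driver
        panel, _ = select_panel(df, max_variants=10)
        assert panel[0].pos == 4 and panel[0].driver

    def test_fingerprints_appended_after_monitored(self):
        fp = [MonitoredVariant("1", 999, "G", "A", role="fingerprint")]
        panel, _ = select_panel(self.candidates(5), fingerprints=fp)
        assert panel[-1].role == "fingerprint"


class TestPanelIOAndSummary:
    def test_vcf_round_trip(self, tmp_path):
        panel = [
            MonitoredVariant("chr7", 140453136, "A", "T", tumour_af=0.31,
                             driver=True),
            MonitoredVariant("chr5", 1295228, "G", "A",
                             variant_class="promoter-SNV"),
            MonitoredVariant("chr1", 1000, "G", "A", role="fingerprint",
                             germline_genotype="0/1"),
        ]
        path = tmp_path / "panel.vcf"
        write_panel_vcf(panel, path)
        back = read_panel_vcf(path)
        assert {(v.chrom, v.pos, v.ref, v.alt, v.role, v.variant_class)
                for v in back} == {
            (v.chrom, v.pos, v.ref, v.alt, v.role, v.variant_class)
            for v in panel}

    def test_summary_counts_and_frame_layout(self):
        panel = [MonitoredVariant("sim1", 10, "C", "T"),
                 MonitoredVariant("sim1", 11, "C", "T")]
        pileup = make_pileup([(10, 2, 2000, "C", "T", 10),
                              (11, 2, 2000, "C", "T", 0)])
        calls = call_variants(pileup, panel, make_model())
        result = summarize_sample("s1", calls, "adjuvant")
        assert result.n_assessable == 2 and result.n_detected == 1
        assert result.n_detected <= result.n_assessable <= len(panel)
        assert not result.ctdna_positive
        frame = calls_to_frame("s1", calls)
        assert list(frame["sample"].unique()) == ["s1"]
        assert frame.loc[0, "level2_altC"] == 10
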