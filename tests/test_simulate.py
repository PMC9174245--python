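import dataclasses

import numpy as np
import pandas as pd
import pytest

from btcmeth.differential import differential_cgi
from btcmeth.simulate import (
    CohortSpec,
    degrade_ffpe,
    generate_cohort,
    generate_droplets,
    generate_multidataset,
    generate_on_universe,
)

SMALL_NULL = CohortSpec(
    n_tumour=10, n_normal=10, n_cgis=30, probes_per_cgi=(3, 5),
    n_hyper=0, n_hypo=0, kappa=50.0, seed=0,
)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        a = generate_cohort(CohortSpec(n_cgis=40, seed=7))
        b = generate_cohort(CohortSpec(n_cgis=40, seed=7))
        pd.testing.assert_frame_equal(a.beta, b.beta)
        pd.testing.assert_frame_equal(a.sheet, b.sheet)
        assert a.truth.cgi_labels.equals(b.truth.cgi_labels)
        c = generate_cohort(CohortSpec(n_cgis=40, seed=8))
        assert not a.beta.equals(c.beta)

    def test_null_spec_yields_no_discoveries_across_seeds(self):
        """With nothing planted, the Δβ>0.2 & p<0.05 criterion should
        find nothing in at least 95% of replicate seeds."""
        clean = 0
        for seed in range(100):
            c = generate_cohort(dataclasses.replace(SMALL_NULL, seed=seed))
            rec = differential_cgi(c.beta, c.probes, c.sheet)
            clean += int((rec["direction"] != "none").sum() == 0)
        assert clean >= 95

    def test_strong_effect_exceeds_delta_threshold(self, strong_cohort):
        """delta=0.4, purity=1, kappa=100: every planted hyper CGI shows
        an observed Δβ above 0.2."""
        rec = differential_cgi(
            strong_cohort.beta, strong_cohort.probes, strong_cohort.sheet
        )
        deltas = rec.loc[list(strong_cohort.truth.hyper_cgis), "delta_beta"]
        assert (deltas > 0.2).all()
        # and within the plausible band around the planted effect
        assert deltas.between(0.3, 0.5).all()

    def test_purity_dilutes_observed_effect(self):
        base = CohortSpec(
            n_tumour=15, n_normal=10, n_cgis=40, n_hyper=6, n_hypo=0,
            delta=0.4, kappa=100.0, seed=5,
        )
        pure = generate_cohort(dataclasses.replace(
            base, purity_range=(1.0, 1.0)))
        dilute = generate_cohort(dataclasses.replace(
            base, purity_range=(0.4, 0.4)))
        rec_p = differential_cgi(pure.beta, pure.probes, pure.sheet)
        rec_d = differential_cgi(dilute.beta, dilute.probes, dilute.sheet)
        dp = rec_p.loc[list(pure.truth.hyper_cgis), "delta_beta"].mean()
        dd = rec_d.loc[list(dilute.truth.hyper_cgis), "delta_beta"].mean()
        assert dd == pytest.approx(0.4 * dp, rel=0.25)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_cgis=5, n_hyper=4, n_hypo=2).validate()
        with pytest.raises(ValueError):
            CohortSpec(delta=1.5).validate()
        with pytest.raises(ValueError):
            CohortSpec(purity_range=(0.0, 1.0)).validate()

    def test_recovery_monotone_in_delta_and_sample_size(self):
        """Planted-CGI recovery is non-decreasing along a delta grid and
        a sample-size grid (averaged over seeds)."""

        def recovery(delta, n_tumour):
            frac = []
            for seed in range(5):
                spec = CohortSpec(
                    n_tumour=n_tumour, n_normal=10, n_cgis=40,
                    probes_per_cgi=(3, 6), n_hyper=8, n_hypo=0,
                    delta=delta, kappa=80.0, purity_range=(1.0, 1.0),
                    seed=seed,
                )
                c = generate_cohort(spec)
                rec = differential_cgi(c.beta, c.probes, c.sheet)
                found = set(rec.index[rec["direction"] == "hyper"])
                truth = set(c.truth.hyper_cgis)
                frac.append(len(found & truth) / len(truth))
            return np.mean(frac)

        by_delta = [recovery(d, 10) for d in (0.1, 0.25, 0.4)]
        assert by_delta == sorted(by_delta)
        by_n = [recovery(0.25, n) for n in (4, 10, 20)]
        assert by_n == sorted(by_n)


class TestDegradeFfpe:
    def test_severity_bounds(self, strong_cohort):
        with pytest.raises(ValueError):
            degrade_ffpe(strong_cohort.beta, ["sim_T01"], severity=0.0,
                         seed=1)
        with pytest.raises(KeyError):
            degrade_ffpe(strong_cohort.beta, ["nope"], severity=0.5, seed=1)

    def test_intermediate_fraction_increases(self, strong_cohort):
        beta = strong_cohort.beta
        sid = beta.columns[0]
        out = degrade_ffpe(beta, [sid], severity=1.0, seed=2)

        def inter(v):
            return float(np.mean((v > 0.3) & (v < 0.7)))

        assert inter(out[sid].to_numpy()) > inter(beta[sid].to_numpy())
        # untouched samples identical
        others = [c for c in beta.columns if c != sid]
        pd.testing.assert_frame_equal(out[others], beta[others])

    def test_monotone_in_severity(self, strong_cohort):
        beta = strong_cohort.beta
        sid = beta.columns[1]

        def inter_at(sev):
            out = degrade_ffpe(beta, [sid], severity=sev, seed=3)
            v = out[sid].to_numpy()
            return float(np.mean((v > 0.3) & (v < 0.7)))

        fractions = [inter_at(s) for s in (0.2, 0.5, 0.9)]
        assert fractions == sorted(fractions)


class TestMultidataset:
    spec = CohortSpec(
        n_tumour=12, n_normal=8, n_cgis=50, probes_per_cgi=(3, 5),
        n_hyper=10, n_hypo=0, delta=0.4, kappa=80.0,
        purity_range=(0.9, 1.0),
    )
    other = dataclasses.replace(spec, n_hyper=4)

    def test_truth_partition_sizes(self):
        md = generate_multidataset(
            self.spec, {"COAD": self.other}, overlap=0.5, seed=9
        )
        assert len(md.shared) == 5  # round(0.5 * 10)
        assert len(md.btc_specific) == 5
        assert set(md.btc_specific) | set(md.shared) == set(
            md.btc.truth.hyper_cgis
        )
        coad_hyper = set(md.others["COAD"].truth.hyper_cgis)
        assert set(md.shared) <= coad_hyper
        assert len(coad_hyper) == 5 + 4  # shared + private

    def test_overlap_one_leaves_nothing_specific(self):
        md = generate_multidataset(
            self.spec, {"COAD": self.other}, overlap=1.0, seed=9
        )
        assert md.btc_specific == ()

    def test_mismatched_universe_rejected(self):
        bad = dataclasses.replace(self.other, n_cgis=60)
        with pytest.raises(ValueError, match="universe"):
            generate_multidataset(self.spec, {"COAD": bad}, overlap=0.5,
                                  seed=1)

    def test_replication_cohort_shares_layout_and_truth(self):
        md = generate_multidataset(self.spec, {}, overlap=0.0, seed=3)
        rep = generate_on_universe(
            md.btc, md.btc.truth.cgi_labels, self.spec, seed=4, cohort="VAL"
        )
        pd.testing.assert_frame_equal(rep.probes, md.btc.probes)
        assert rep.truth.cgi_labels.equals(md.btc.truth.cgi_labels)
        assert not rep.beta.equals(md.btc.beta)


class TestGenerateDroplets:
    def test_zero_lambda_class_all_negative(self):
        counts, truth = generate_droplets(
            5, 5, accepted=2000, lam_positive=0.5, lam_negative=0.0, seed=1
        )
        target = counts[counts["channel"] == "target"].set_index("sample_id")
        negatives = truth.index[truth == 0]
        assert (target.loc[negatives, "positive_droplets"] == 0).all()

    def test_high_lambda_saturates_positive_fraction(self):
        counts, truth = generate_droplets(
            200, 0, accepted=5000, lam_positive=5.0, seed=2
        )
        target = counts[counts["channel"] == "target"]
        frac = target["positive_droplets"] / target["accepted_droplets"]
        # 1 - exp(-5) ~ 0.9933
        assert frac.mean() == pytest.approx(1 - np.exp(-5), abs=0.005)

    def test_control_channel_positive_rich(self):
        counts, _ = generate_droplets(3, 3, accepted=2000, lam_control=1.0,
                                      seed=3)
        control = counts[counts["channel"] == "control"]
        assert (control["positive_droplets"] > 0).all()

    def test_seed_reproducibility(self):
        a, _ = generate_droplets(4, 4, seed=11)
        b, _ = generate_droplets(4, 4, seed=11)
        pd.testing.assert_frame_equal(a, b)
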