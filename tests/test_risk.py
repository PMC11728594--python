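import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from gwrisk.exposure import vf_indoor, vf_outdoor
from gwrisk.risk import (
    SampleTable,
    UndefinedShareError,
    apply_boiling,
    compound_shares,
    pathway_risks,
    pathway_shares,
    standardized_risks,
    summarize,
    survey_stats,
    total_metric,
)
from gwrisk.synthetic import generate_site, table1_site_config


def oracle_totals(cw, chem, p, s, metric):
    """Independent straight-line total over the four pathways."""
    vfi, vfo = vf_indoor(chem, s), vf_outdoor(chem, s)
    if metric == "cr":
        if chem.sf_oral is None:
            parts = []
        else:
            parts = [
                oracle.ingestion_cr(cw, p.gwcr, p.ef, p.ed, p.bw, p.at_c, chem.sf_oral),
                oracle.dermal_cr(cw, chem.kp, p.t_event, p.ev, p.sa, p.ef, p.ed,
                                 p.bw, p.at_c, chem.sf_oral, chem.abs_gi),
            ]
        if chem.iur is not None:
            parts += [
                oracle.inhalation_cr(cw, vfi, p.et_in, p.ef, p.ed, p.at_c, chem.iur),
                oracle.inhalation_cr(cw, vfo, p.et_out, p.ef, p.ed, p.at_c, chem.iur),
            ]
    else:
        parts = [
            oracle.ingestion_hq(cw, p.gwcr, p.ef, p.ed, p.bw, p.at_nc, chem.rfd_oral),
            oracle.dermal_hq(cw, chem.kp, p.t_event, p.ev, p.sa, p.ef, p.ed,
                             p.bw, p.at_nc, chem.rfd_oral, chem.abs_gi),
        ]
        if chem.rfc is not None:
            parts += [
                oracle.inhalation_hq(cw, vfi, p.et_in, p.ef, p.ed, p.at_nc, chem.rfc),
                oracle.inhalation_hq(cw, vfo, p.et_out, p.ef, p.ed, p.at_nc, chem.rfc),
            ]
    return sum(parts) if parts else None


class TestBoiling:
    def test_default_sixty_percent_reduction(self, exposure):
        assert apply_boiling(1.0, exposure) == pytest.approx(0.4, rel=1e-12)

    def test_no_reduction_is_identity(self, exposure):
        p = exposure.model_copy(update={"boil_reduction": 0.0})
        assert apply_boiling(0.73, p) == 0.73

    def test_zero_stays_zero(self, exposure):
        assert apply_boiling(0.0, exposure) == 0.0

    def test_boiling_scales_ingestion_only(self, chems, exposure, site):
        chem = chems["trichloroethylene"]
        raw = {r.pathway: r for r in pathway_risks(1.0, chem, exposure, site)}
        boiled = {
            r.pathway: r for r in pathway_risks(1.0, chem, exposure, site, boiled=True)
        }
        assert boiled["ingestion"].cr == pytest.approx(0.4 * raw["ingestion"].cr, rel=1e-12)
        assert boiled["ingestion"].hq == pytest.approx(0.4 * raw["ingestion"].hq, rel=1e-12)
        for pathway in ("dermal", "inhalation_indoor", "inhalation_outdoor"):
            assert boiled[pathway].cr == raw[pathway].cr
            assert boiled[pathway].hq == raw[pathway].hq


class TestPathwayRisks:
    def test_zero_concentration_zero_metrics(self, chems, exposure, site):
        for r in pathway_risks(0.0, chems["trichloroethylene"], exposure, site):
            assert r.cr == 0.0 and r.hq == 0.0

    def test_missing_iur_yields_absent_not_zero(self, chems, exposure, site):
        results = {
            r.pathway: r
            for r in pathway_risks(1.0, chems["1,2-dichloroethylene"], exposure, site)
        }
        assert results["inhalation_indoor"].cr is None
        assert results["ingestion"].cr is None  # no oral slope factor either
        assert results["ingestion"].hq > 0

    def test_vinyl_chloride_ingestion_dominates(self, chems, exposure, site):
        results = pathway_risks(0.5, chems["vinyl chloride"], exposure, site)
        crs = {r.pathway: r.cr for r in results if r.cr is not None}
        assert max(crs, key=crs.get) == "ingestion"

    def test_matches_independent_oracle_on_random_draws(self, chems, exposure, site):
        rng = np.random.default_rng(20)
        names = chems.names
        for _ in range(250):
            chem = chems[names[rng.integers(len(names))]]
            cw = float(rng.lognormal(-1, 2))
            p = exposure.model_copy(
                update={
                    "gwcr": float(rng.uniform(0.5, 5)),
                    "ed": float(rng.uniform(1, 40)),
                    "bw": float(rng.uniform(40, 100)),
                }
            )
            results = pathway_risks(cw, chem, p, site)
            for metric in ("cr", "hq"):
                expected = oracle_totals(cw, chem, p, site, metric)
                got = total_metric(results, metric)
                if expected is None:
                    assert got is None
                else:
                    assert got == pytest.approx(expected, rel=1e-12)


class TestShares:
    def test_scale_invariance(self, chems, exposure, site):
        chem = chems["trichloroethylene"]
        a = pathway_shares(pathway_risks(1.0, chem, exposure, site), "cr")
        b = pathway_shares(pathway_risks(7.3, chem, exposure, site), "cr")
        for pathway in a:
            assert a[pathway] == pytest.approx(b[pathway], rel=1e-12)

    def test_shares_sum_to_one(self, chems, exposure, site):
        for chem in chems:
            for metric in ("cr", "hq"):
                results = pathway_risks(1.0, chem, exposure, site)
                if total_metric(results, metric) is None:
                    continue
                shares = pathway_shares(results, metric)
                assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_dermal_share_below_two_permille(self, chems, exposure, site):
        for chem in chems:
            for metric in ("cr", "hq"):
                results = pathway_risks(1.0, chem, exposure, site)
                if total_metric(results, metric) is None:
                    continue
                assert pathway_shares(results, metric)["dermal"] < 0.002, chem.name

    def test_all_zero_is_undefined(self, chems, exposure, site):
        results = pathway_risks(0.0, chems["trichloroethylene"], exposure, site)
        with pytest.raises(UndefinedShareError):
            pathway_shares(results, "cr")

    def test_single_compound_share_is_one(self, chems, exposure, site):
        shares = compound_shares({"vinyl chloride": 0.5}, chems, exposure, site)
        assert shares == {"vinyl chloride": pytest.approx(1.0)}

    def test_empty_table_rejected(self, chems, exposure, site):
        with pytest.raises(ValueError):
            compound_shares({}, chems, exposure, site)

    def test_standardized_equals_arbitrary_concentration_shares(
        self, chems, exposure, site
    ):
        std = standardized_risks(chems, exposure, site)
        chem = chems["trichloromethane"]
        direct = pathway_shares(pathway_risks(4.2, chem, exposure, site), "cr")
        for pathway, share in std.pathway_shares["cr"][chem.name].items():
            assert share == pytest.approx(direct[pathway], rel=1e-12)

    def test_standardized_ingestion_dominates_everywhere(self, chems, exposure, site):
        std = standardized_risks(chems, exposure, site)
        for compound, shares in std.pathway_shares["cr"].items():
            assert shares["ingestion"] > 0.89, compound


class TestSummarize:
    def test_additivity_and_flags(self, chems, exposure, site):
        summary = summarize({"vinyl chloride": 0.15}, chems, exposure, site)
        results = summary.results
        total = results.loc[results["cr"].notna(), "cr"].sum()
        assert summary.total_cr["vinyl chloride"] == pytest.approx(total, rel=1e-12)
        assert not summary.acceptable_cr["vinyl chloride"]  # far above 1e-6

    def test_compound_shares_sum_to_one(self, chems, exposure, site):
        conc = {name: 0.5 for name in chems.names}
        summary = summarize(conc, chems, exposure, site)
        for metric in ("cr", "hq"):
            assert sum(summary.compound_shares[metric].values()) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_acceptability_threshold_boundary(self, chems, exposure, site):
        chem = chems["vinyl chloride"]
        unit_cr = total_metric(pathway_risks(1.0, chem, exposure, site), "cr")
        at_threshold = 1e-6 / unit_cr
        summary = summarize({chem.name: at_threshold}, chems, exposure, site)
        assert not summary.acceptable_cr[chem.name]
        summary = summarize({chem.name: at_threshold * 0.99}, chems, exposure, site)
        assert summary.acceptable_cr[chem.name]


class TestSurveyStats:
    def make_table(self, rows):
        return SampleTable(
            pd.DataFrame(rows, columns=["well", "compound", "conc_mg_L", "censored"])
        )

    def test_all_censored(self, chems):
        table = self.make_table(
            [(f"W{i}", "trichloroethylene", 0.0003, True) for i in range(5)]
        )
        stats = survey_stats(table, chems)
        assert stats.loc["trichloroethylene", "detection_rate"] == 0.0
        assert stats.loc["trichloroethylene", "exceedance_rate"] == 0.0
        assert stats.loc["trichloroethylene", "mean"] == 0.0

    def test_single_exceedance(self, chems):
        table = self.make_table([("W1", "trichloroethylene", 5.0, False)])
        stats = survey_stats(table, chems)
        assert stats.loc["trichloroethylene", "detection_rate"] == 1.0
        assert stats.loc["trichloroethylene", "exceedance_rate"] == 1.0

    def test_substitution_strategies(self, chems):
        dl = chems["trichloroethylene"].detection_limit
        table = self.make_table(
            [("W1", "trichloroethylene", dl, True), ("W2", "trichloroethylene", 1.0, False)]
        )
        means = {
            mode: survey_stats(table, chems, substitution=mode).loc[
                "trichloroethylene", "mean"
            ]
            for mode in ("zero", "half", "dl")
        }
        assert means["zero"] == pytest.approx(0.5)
        assert means["half"] == pytest.approx((1.0 + dl / 2) / 2)
        assert means["dl"] == pytest.approx((1.0 + dl) / 2)

    def test_unknown_compound_rejected(self, chems):
        table = self.make_table([("W1", "benzene", 1.0, False)])
        with pytest.raises(KeyError, match="benzene"):
            survey_stats(table, chems)

    def test_table1_like_site_reproduces_detection_rates(self, chems):
        cfg = table1_site_config(n_wells=76, chems=chems, seed=11)
        stats = survey_stats(generate_site(cfg), chems)
        # 3-sigma binomial bounds around the configured detection probabilities
        for name, target in (("trichloroethylene", 0.821), ("vinyl chloride", 0.627)):
            se = np.sqrt(target * (1 - target) / 76)
            got = stats.loc[name, "detection_rate"]
            assert abs(got - target) < 3 * se + 1 / 76, name
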