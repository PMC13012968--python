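"""Generator contracts: determinism, calibration, duplicate bookkeeping."""

import numpy as np
import pytest
from scipy.stats import weibull_min

from pvsignals.config import SimulationConfig
from pvsignals.errors import ConfigurationError
from pvsignals.simulate import generate_dataset


def test_identical_seed_gives_identical_dataset():
    config = SimulationConfig(
        group_sizes={"COMBO": 50, "BEV_MONO": 50, "TMZ_MONO": 50, "BACKGROUND": 100},
        seed=11,
    )
    t1, tr1 = generate_dataset(config)
    t2, tr2 = generate_dataset(config)
    assert t1.reports.equals(t2.reports)
    assert t1.drugs.equals(t2.drugs)
    assert t1.events.equals(t2.events)
    assert tr1.duplicated_case_ids == tr2.duplicated_case_ids


def test_all_zero_group_sizes_gives_empty_tables():
    config = SimulationConfig(group_sizes={g: 0 for g in ("COMBO", "BEV_MONO", "TMZ_MONO", "BACKGROUND")})
    tables, truth = generate_dataset(config)
    assert tables.n_reports == 0
    assert len(tables.drugs) == 0 and len(tables.events) == 0
    assert truth.n_duplicates == 0


@pytest.mark.parametrize(
    "override, key",
    [
        ({"duplicate_rate": 1.5}, "duplicate_rate"),
        ({"group_sizes": {"COMBO": -1}}, "group_sizes.COMBO"),
        ({"event_catalog": {"X": 2.0}}, "event_catalog.X"),
        ({"signal_multipliers": {"COMBO": {"Diarrhoea": -0.1}}}, "signal_multipliers.COMBO.Diarrhoea"),
        ({"tto_models": {"COMBO": {"Diarrhoea": (0.0, 10.0)}}}, "tto_models.COMBO.Diarrhoea"),
        ({"demographics": {"sex": {"male": 0.5, "female": 0.6}}}, "demographics.sex"),
    ],
)
def test_invalid_config_names_offending_key(override, key):
    with pytest.raises(ConfigurationError) as err:
        SimulationConfig(**override)
    assert err.value.key == key


def test_marginal_reporting_rates_calibrated():
    """Observed per-(group, term) reporting fractions stay within 4 binomial
    standard errors of baseline x multiplier."""
    config = SimulationConfig(
        group_sizes={"COMBO": 2000, "BEV_MONO": 2000, "TMZ_MONO": 2000, "BACKGROUND": 2000},
        signal_multipliers={"TMZ_MONO": {"Thrombocytopenia": 4.0}},
        duplicate_rate=0.0,
        seed=5,
    )
    tables, truth = generate_dataset(config)
    assert len(config.event_catalog) >= 20
    groups = truth.group_of_report
    ev = tables.events.drop_duplicates(subset=["report_id", "event_term"])
    base_ids = [rid for rid in tables.reports["report_id"] if rid in groups]
    for group in ("COMBO", "TMZ_MONO", "BACKGROUND"):
        n = 2000
        members = {rid for rid, g in groups.items() if g == group}
        counts = ev[ev["report_id"].isin(members)]["event_term"].value_counts()
        for term, p0 in config.event_catalog.items():
            p = min(1.0, p0 * config.effective_multiplier(group, term))
            se = np.sqrt(p * (1 - p) / n)
            observed = counts.get(term, 0) / n
            assert abs(observed - p) <= 4 * se + 1e-12, (group, term, observed, p)


def test_onset_intervals_follow_configured_weibull():
    """KS distance between generated onset intervals and the configured
    Weibull CDF stays below 0.1 at n = 500."""
    config = SimulationConfig(
        group_sizes={"COMBO": 0, "BEV_MONO": 0, "TMZ_MONO": 500, "BACKGROUND": 0},
        event_catalog={"Thrombocytopenia": 1.0},
        tto_models={"TMZ_MONO": {"Thrombocytopenia": (1.5, 40.0)}},
        missingness={"start_date": 0.0, "onset_date": 0.0},
        duplicate_rate=0.0,
        seed=3,
    )
    tables, _ = generate_dataset(config)
    starts = tables.drugs.set_index("report_id")["therapy_start_date"]
    import datetime as dt

    tto = []
    for row in tables.events.itertuples(index=False):
        d0 = dt.date.fromisoformat(starts[row.report_id])
        d1 = dt.date.fromisoformat(row.onset_date)
        tto.append((d1 - d0).days)
    tto = np.sort(np.array(tto, dtype=float))
    assert len(tto) == 500
    cdf = weibull_min.cdf(tto, 1.5, scale=40.0)
    ecdf_hi = np.arange(1, len(tto) + 1) / len(tto)
    ecdf_lo = np.arange(0, len(tto)) / len(tto)
    ks = max(np.max(np.abs(cdf - ecdf_hi)), np.max(np.abs(cdf - ecdf_lo)))
    assert ks < 0.1


def test_duplicate_bookkeeping_matches_truth(small_dataset):
    config, tables, truth = small_dataset
    n_versions = (tables.reports["case_version"] == 2).sum()
    assert n_versions == truth.n_duplicates
    assert set(tables.reports.loc[tables.reports["case_version"] == 2, "case_id"]) == set(
        truth.duplicated_case_ids
    )


def test_combo_roles_consistent_with_group(small_dataset):
    config, tables, truth = small_dataset
    combo_ids = [r for r, g in truth.group_of_report.items() if g == "COMBO"]
    drugs = tables.drugs[tables.drugs["report_id"].isin(combo_ids)]
    by_report = drugs.groupby("report_id")
    ps_counts = {"BEVACIZUMAB": 0, "TEMOZOLOMIDE": 0}
    for rid, grp in by_report:
        roles = dict(zip(grp["drug_name"], grp["role"]))
        assert set(roles) == {"BEVACIZUMAB", "TEMOZOLOMIDE"}
        assert sorted(roles.values()) == ["C", "PS"]
        ps = [d for d, r in roles.items() if r == "PS"][0]
        assert truth.combo_ps_drug[rid] == ps
        ps_counts[ps] += 1
    # PS randomised between the two drugs: both assignments exercised
    assert min(ps_counts.values()) > 0


def test_partial_date_mode_emits_year_month():
    config = SimulationConfig(
        group_sizes={"COMBO": 0, "BEV_MONO": 200, "TMZ_MONO": 0, "BACKGROUND": 0},
        missingness={"start_date": 0.0},
        partial_date_rate=0.5,
        duplicate_rate=0.0,
        seed=9,
    )
    tables, _ = generate_dataset(config)
    starts = tables.drugs["therapy_start_date"]
    partial = starts.str.len() == 7
    full = starts.str.len() == 10
    assert partial.sum() > 0 and full.sum() > 0
    assert (partial | full).all()
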