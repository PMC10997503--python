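import numpy as np
import pytest

from allrisk.cohort import PatientRecord
from allrisk.cutpoints import (
    ClinicalRules,
    CutpointSet,
    assign_risk_group,
    assign_risk_groups,
    classify_cog_clinical,
    cpe,
    crosstab_riskgroups,
    default_cutpoints,
    find_cutpoints,
    load_default_rules,
)
from allrisk.errors import ConfigError, UnclassifiedError
from allrisk.survival import km_estimate

from conftest import make_outcomes


def cpe_bruteforce(scores, include_ties=False):
    """Independent O(n^2) enumeration of the pairwise concordance kernel."""
    n = len(scores)
    numer = denom = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = abs(scores[i] - scores[j])
            if d == 0:
                if include_ties:
                    numer += 0.5
                    denom += 1
                continue
            numer += 1.0 / (1.0 + np.exp(-d))
            denom += 1
    return 0.5 if denom == 0 else numer / denom


class TestCPE:
    def test_two_scores_closed_form(self):
        assert cpe([0.0, 1.0]) == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)
        assert cpe([0.0, 1.0]) == pytest.approx(0.7311, abs=5e-5)

    def test_all_tied_convention(self):
        assert cpe([2.0, 2.0, 2.0]) == 0.5

    def test_large_separation_limit(self):
        assert cpe([0.0, 100.0]) == pytest.approx(1.0, abs=1e-12)

    def test_too_few(self):
        with pytest.raises(ValueError):
            cpe([1.0])

    @pytest.mark.parametrize("seed,include_ties", [(0, False), (1, False), (2, True)])
    def test_matches_bruteforce_oracle(self, seed, include_ties):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=400), 1)  # rounded -> tied pairs
        assert cpe(scores, include_ties=include_ties) == pytest.approx(
            cpe_bruteforce(scores, include_ties=include_ties), abs=1e-10
        )

    def test_at_least_half_and_location_invariant(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=200)
        v = cpe(scores)
        assert v >= 0.5
        assert cpe(scores + 17.3) == pytest.approx(v, abs=1e-12)


class TestAssign:
    @pytest.fixture(scope="class")
    def cuts(self):
        return default_cutpoints()

    def test_printed_cutpoints_shipped(self, cuts):
        assert cuts.cutpoints == [-1.377, -0.589, 0.093]
        assert cuts.labels == ("Low", "Standard", "Intermediate", "High")

    @pytest.mark.parametrize(
        "score,label",
        [
            (-2.1002, "Low"),
            (0.0, "Intermediate"),  # -0.589 < 0 <= 0.093
            (-1.377, "Low"),  # boundary falls in the lower group
            (-0.5, "Intermediate"),
            (0.094, "High"),
        ],
    )
    def test_assignment(self, cuts, score, label):
        assert assign_risk_group(score, cuts) == label

    def test_monotone_labels(self, cuts):
        scores = np.linspace(-4, 3, 300)
        groups = assign_risk_groups(scores, cuts)
        rank = {lab: i for i, lab in enumerate(cuts.labels)}
        ranks = np.array([rank[g] for g in groups])
        assert np.all(np.diff(ranks) >= 0)

    def test_invalid_cutpoint_set(self):
        with pytest.raises(ValueError):
            CutpointSet(cutpoints=[0.0, 0.0], labels=("a", "b", "c"))
        with pytest.raises(ValueError):
            CutpointSet(cutpoints=[0.0], labels=("a", "b", "c"))


def clustered_scores_and_outcomes(rng, centers, n_per, hazard_scale=1.0):
    scores, times, events = [], [], []
    for c in centers:
        s = rng.normal(c, 0.05, size=n_per)
        t = rng.exponential(np.exp(-hazard_scale * s))
        cens = rng.exponential(np.exp(-hazard_scale * np.mean(centers)) * 1.5, size=n_per)
        scores.append(s)
        times.append(np.minimum(t, cens))
        events.append((t <= cens).astype(int))
    return (np.concatenate(scores), make_outcomes(np.concatenate(times),
                                                  np.concatenate(events)))


class TestFindCutpoints:
    def test_two_cluster_gap(self):
        rng = np.random.default_rng(3)
        scores, outcomes = clustered_scores_and_outcomes(rng, [-1.0, 1.0], 150)
        cuts, achieved = find_cutpoints(scores, outcomes, k_groups=2,
                                        grid_quantile_step=0.05)
        assert -0.8 < cuts.cutpoints[0] < 0.8
        assert achieved > 0.5

    def test_four_cluster_gaps(self):
        rng = np.random.default_rng(4)
        centers = [-2.0, -0.7, 0.7, 2.0]
        scores, outcomes = clustered_scores_and_outcomes(rng, centers, 120)
        cuts, _ = find_cutpoints(scores, outcomes, k_groups=4, grid_quantile_step=0.05)
        gaps = [(-1.8, -0.9), (-0.5, 0.5), (0.9, 1.8)]
        for cut, (lo, hi) in zip(cuts.cutpoints, gaps):
            assert lo < cut < hi

    def test_infeasible_min_group_frac(self):
        rng = np.random.default_rng(5)
        scores, outcomes = clustered_scores_and_outcomes(rng, [-1.0, 1.0], 50)
        with pytest.raises(ConfigError):
            find_cutpoints(scores, outcomes, k_groups=4, min_group_frac=0.6)

    def test_assignment_invariance_under_affine_transform(self):
        rng = np.random.default_rng(6)
        scores, outcomes = clustered_scores_and_outcomes(rng, [-1.0, 0.0, 1.0], 100)
        cuts1, v1 = find_cutpoints(scores, outcomes, k_groups=3, grid_quantile_step=0.1)
        cuts2, v2 = find_cutpoints(2.0 * scores + 5.0, outcomes, k_groups=3,
                                   grid_quantile_step=0.1)
        g1 = assign_risk_groups(scores, cuts1)
        g2 = assign_risk_groups(2.0 * scores + 5.0, cuts2)
        assert (g1 == g2).all()
        assert v1 == pytest.approx(v2, abs=1e-9)

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        scores, outcomes = clustered_scores_and_outcomes(rng, [-1.0, 1.0], 100)
        a = find_cutpoints(scores, outcomes, k_groups=2, grid_quantile_step=0.05)
        b = find_cutpoints(scores, outcomes, k_groups=2, grid_quantile_step=0.05)
        assert a[0].cutpoints == b[0].cutpoints and a[1] == b[1]


def make_record(**overrides):
    base = dict(
        id="p", age_years=5.0, wbc=10.0, d8_mrd=1e-3, d29_mrd=1e-5, frg=False,
        urg=False, cns="CNS1", nci_risk="SR", event_type="none",
        time_from_eoi_years=5.0,
    )
    base.update(overrides)
    return PatientRecord(**base)


class TestClinicalRules:
    def test_first_match_and_default(self):
        rules = ClinicalRules(
            rules=[{"label": "VHR", "all": [{"field": "urg", "op": "eq", "value": True}]}],
            default="HR",
        )
        assert classify_cog_clinical(make_record(urg=True), rules) == "VHR"
        assert classify_cog_clinical(make_record(urg=False), rules) == "HR"

    def test_missing_field_signals(self):
        rules = ClinicalRules(
            rules=[{"label": "X", "all": [{"field": "d29_mrd", "op": "ge", "value": 0.01}]}],
            default="Y",
        )
        with pytest.raises(UnclassifiedError) as err:
            classify_cog_clinical(make_record(d29_mrd=None), rules)
        assert err.value.field == "d29_mrd"

    def test_no_match_no_default(self):
        rules = ClinicalRules(
            rules=[{"label": "X", "all": [{"field": "urg", "op": "eq", "value": True}]}]
        )
        with pytest.raises(UnclassifiedError):
            classify_cog_clinical(make_record(urg=False), rules)

    def test_shipped_default_rules(self):
        rules = load_default_rules()
        assert classify_cog_clinical(make_record(urg=True), rules) == "VHR"
        assert classify_cog_clinical(make_record(d29_mrd=0.02), rules) == "VHR"
        fav = make_record(frg=True, d8_mrd=1e-3, d29_mrd=1e-5)
        assert classify_cog_clinical(fav, rules) == "SR-Fav"
        assert classify_cog_clinical(make_record(d29_mrd=5e-4), rules) == "SR-High"
        hr_fav = make_record(nci_risk="HR", frg=True, d29_mrd=1e-5)
        assert classify_cog_clinical(hr_fav, rules) == "HR-Fav"

    def test_bad_operator_rejected(self):
        with pytest.raises(ConfigError):
            ClinicalRules(rules=[{"label": "X", "all": [{"field": "urg", "op": "??"}]}])


class TestCrosstab:
    def test_known_counts_and_totals(self):
        labels_a = ["r1"] * 30 + ["r2"] * 30
        labels_b = (["c1"] * 26 + ["c2"] * 4) + (["c1"] * 10 + ["c2"] * 20)
        outcomes = make_outcomes(np.linspace(1, 6, 60), [1, 0] * 30)
        tab = crosstab_riskgroups(labels_a, labels_b, outcomes, horizon=5.0)
        assert tab.counts.loc["r1", "c1"] == 26
        assert tab.counts.loc["r2", "c2"] == 20
        assert tab.counts.loc["Total", "Total"] == 60
        assert tab.counts.loc["r1", "Total"] == 30

    def test_small_cells_suppressed(self):
        labels_a = ["r1"] * 24 + ["r2"] * 26
        labels_b = ["c1"] * 50
        outcomes = make_outcomes(np.linspace(1, 6, 50), [1] * 50)
        tab = crosstab_riskgroups(labels_a, labels_b, outcomes, horizon=3.0)
        assert np.isnan(tab.km.loc["r1", "c1"])  # 24 < 25 -> suppressed
        assert not np.isnan(tab.km.loc["r2", "c1"])

    def test_cell_km_matches_direct_estimate(self):
        rng = np.random.default_rng(10)
        n = 80
        labels_a = np.where(rng.random(n) < 0.5, "a1", "a2")
        labels_b = ["b1"] * n
        times = rng.exponential(4, n)
        events = rng.integers(0, 2, n)
        outcomes = make_outcomes(times, events)
        tab = crosstab_riskgroups(labels_a, labels_b, outcomes, horizon=2.0, min_n=1)
        cell = [o for o, la in zip(outcomes, labels_a) if la == "a1"]
        assert tab.km.loc["a1", "b1"] == pytest.approx(km_estimate(cell).at(2.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            crosstab_riskgroups(["a"], ["b", "c"], make_outcomes([1, 2], [1, 1]), 1.0)
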