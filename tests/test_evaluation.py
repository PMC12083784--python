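"""Gold-standard assignment, pair confusion, agreement metrics, matching."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_records
from oatnet import (
    ClinicConnectionRule,
    CommunityPartition,
    PairConfusion,
    assign_clinics,
    community_match,
    concordance_metrics,
    gwet_ac1,
    gwet_ac1_ci,
    pair_confusion,
    summarize_structures,
)


def records_with_loads(loads_by_clinic, phys="p1"):
    """One physician with the given distinct-client counts per clinic."""
    rows = []
    i = 0
    for clinic, n in loads_by_clinic.items():
        for _ in range(n):
            rows.append((f"c{i}", phys, clinic, "methadone", "2020-01-01"))
            i += 1
    return make_records(rows)


@pytest.mark.parametrize(
    "rule,expected",
    [
        (ClinicConnectionRule("percent", 15), {"A", "B", "C"}),
        (ClinicConnectionRule("percent", 30), {"A"}),
        (ClinicConnectionRule("majority"), {"A"}),
        (ClinicConnectionRule("any"), {"A", "B", "C"}),
    ],
)
def test_connection_rules_on_60_25_15_split(rule, expected):
    records = records_with_loads({"A": 60, "B": 25, "C": 15})
    gold = assign_clinics(records, rule)
    assert set(gold.clinics_of["p1"]) == expected


def test_strict_percent_rule_uses_strictly_greater():
    records = records_with_loads({"A": 85, "C": 15})
    loose = assign_clinics(records, ClinicConnectionRule("percent", 15))
    strict = assign_clinics(records, ClinicConnectionRule("percent", 15, strict=True))
    assert set(loose.clinics_of["p1"]) == {"A", "C"}
    assert set(strict.clinics_of["p1"]) == {"A"}


def test_single_clinic_physician_same_under_every_rule():
    records = records_with_loads({"Z": 12})
    for rule in (
        ClinicConnectionRule("any"),
        ClinicConnectionRule("majority"),
        ClinicConnectionRule("percent", 45),
    ):
        assert set(assign_clinics(records, rule).clinics_of["p1"]) == {"Z"}


def test_same_clinic_pair_labels():
    rows = [
        ("c1", "p1", "A", "methadone", "2020-01-01"),
        ("c2", "p2", "A", "methadone", "2020-01-02"),
        ("c3", "p3", "B", "methadone", "2020-01-03"),
    ]
    gold = assign_clinics(make_records(rows), ClinicConnectionRule("any"))
    assert gold.same_clinic("p1", "p2")
    assert not gold.same_clinic("p1", "p3")


# ---------------------------------------------------------------------------
# pair confusion
# ---------------------------------------------------------------------------


def make_partition(mapping):
    return CommunityPartition(assignment=dict(mapping), algorithm="test")


def gold_from(clinics_of):
    from oatnet.evaluation import GoldStandardAssignment

    return GoldStandardAssignment(
        clinics_of={p: frozenset(cs) for p, cs in clinics_of.items()},
        rule=ClinicConnectionRule("any"),
    )


def test_all_same_clinic_same_community():
    gold = gold_from({p: {"X"} for p in "pqr"})
    part = make_partition({p: "one" for p in "pqr"})
    conf = pair_confusion(part, gold, list("pqr"))
    assert (conf.a, conf.b, conf.c, conf.d) == (3, 0, 0, 0)


def test_perfect_two_by_two_split():
    gold = gold_from({"p": {"X"}, "q": {"X"}, "r": {"Y"}, "s": {"Y"}})
    part = make_partition({"p": "1", "q": "1", "r": "2", "s": "2"})
    conf = pair_confusion(part, gold, "pqrs")
    assert (conf.a, conf.b, conf.c, conf.d) == (2, 0, 0, 4)
    assert conf.n == 6


def test_confusion_matches_double_loop_enumeration():
    rng = np.random.default_rng(8)
    phys = [f"p{i}" for i in range(12)]
    clinics_of = {p: {f"k{rng.integers(0, 4)}"} | ({f"k{rng.integers(0, 4)}"} if rng.random() < 0.3 else set()) for p in phys}
    labels = {p: f"g{rng.integers(0, 4)}" for p in phys}
    conf = pair_confusion(make_partition(labels), gold_from(clinics_of), phys)
    a = b = c = d = 0
    for i, j in itertools.combinations(phys, 2):
        sc = bool(clinics_of[i] & clinics_of[j])
        sm = labels[i] == labels[j]
        a += sc and sm
        b += (not sc) and sm
        c += sc and not sm
        d += (not sc) and (not sm)
    assert (conf.a, conf.b, conf.c, conf.d) == (a, b, c, d)
    assert conf.n == len(phys) * (len(phys) - 1) // 2


def test_coverage_mismatch_reports_missing_physicians():
    gold = gold_from({"p": {"X"}})
    part = make_partition({"p": "1"})
    with pytest.raises(ValueError, match="q"):
        pair_confusion(part, gold, ["p", "q"])


# ---------------------------------------------------------------------------
# concordance metrics
# ---------------------------------------------------------------------------


from conftest import exact_pair_metrics as exact_metrics


def test_metric_suite_on_worked_table():
    rep = concordance_metrics(PairConfusion(40, 10, 20, 130))
    assert rep.overall == pytest.approx(0.85)
    assert rep.positive_agreement == pytest.approx(0.7273, abs=1e-4)
    assert rep.negative_agreement == pytest.approx(0.8966, abs=1e-4)
    assert rep.sensitivity == pytest.approx(2 / 3, abs=1e-4)
    assert rep.specificity == pytest.approx(0.9286, abs=1e-4)
    assert rep.ppv == pytest.approx(0.80)
    assert rep.npv == pytest.approx(0.8667, abs=1e-4)
    assert rep.ac1 == pytest.approx(0.7505, abs=1e-4)


def test_perfect_agreement_table():
    rep = concordance_metrics(PairConfusion(5, 0, 0, 20))
    assert rep.overall == 1.0
    assert rep.positive_agreement == 1.0
    assert rep.negative_agreement == 1.0
    assert rep.ac1 == pytest.approx(1.0)
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0
    assert rep.ppv == 1.0 and rep.npv == 1.0


def test_symmetric_table_gives_zero_ac1():
    rep = concordance_metrics(PairConfusion(25, 25, 25, 25))
    assert rep.overall == pytest.approx(0.5)
    assert rep.ac1 == pytest.approx(0.0, abs=1e-12)


def test_zero_denominators_are_nan_not_zero():
    rep = concordance_metrics(PairConfusion(0, 0, 0, 10))
    assert math.isnan(rep.sensitivity)  # no gold-positive pairs
    assert math.isnan(rep.ppv)  # no predicted-positive pairs
    assert rep.specificity == 1.0
    assert "sensitivity_undefined" in rep.flags


@given(
    a=st.integers(0, 200), b=st.integers(0, 200), c=st.integers(0, 200), d=st.integers(0, 200)
)
def test_metrics_match_rational_oracle(a, b, c, d):
    if a + b + c + d == 0:
        return
    rep = concordance_metrics(PairConfusion(a, b, c, d))
    exact = exact_metrics(a, b, c, d)
    for name in ("overall", "positive_agreement", "negative_agreement",
                 "sensitivity", "specificity", "ppv", "npv", "ac1"):
        got = getattr(rep, name)
        want = exact[name]
        if want is None:
            assert math.isnan(got)
        else:
            assert got == pytest.approx(float(want), abs=1e-12)
            assert -1.0 - 1e-12 <= got <= 1.0 + 1e-12


def test_ac1_stable_on_low_prevalence_tables():
    # kappa's denominator degenerates here; AC1 stays finite and bounded
    rep = concordance_metrics(PairConfusion(1, 2, 1, 996))
    assert abs(rep.ac1) <= 1.0
    assert rep.ac1 > 0.9


# ---------------------------------------------------------------------------
# AC1 confidence intervals
# ---------------------------------------------------------------------------


def ac1_variance_oracle(a, b, c, d):
    """Independent per-pair linearized variance (array expansion)."""
    n = a + b + c + d
    r1 = np.repeat([1, 0, 1, 0], [a, b, c, d]).astype(float)
    r2 = np.repeat([1, 1, 0, 0], [a, b, c, d]).astype(float)
    pa_i = (r1 == r2).astype(float)
    pi_i = (r1 + r2) / 2.0
    pi = pi_i.mean()
    pe = 2 * pi * (1 - pi)
    ac1 = (pa_i.mean() - pe) / (1 - pe)
    pe_i = pi_i * (1 - pi) + (1 - pi_i) * pi
    ac1_i = (pa_i - pe) / (1 - pe)
    star = ac1_i - 2 * (1 - ac1) * (pe_i - pe) / (1 - pe)
    return ((star - ac1) ** 2).sum() / (n * (n - 1))


def test_perfect_agreement_ci_collapses_to_point():
    ci = gwet_ac1_ci(PairConfusion(5, 0, 0, 15))
    assert ci.lo == pytest.approx(1.0) and ci.hi == pytest.approx(1.0)


def test_delta_ci_brackets_point_and_is_symmetric():
    conf = PairConfusion(40, 10, 20, 130)
    ac1 = gwet_ac1(conf)
    ci = gwet_ac1_ci(conf, method="delta")
    assert ci.lo < ac1 < ci.hi
    assert (ac1 - ci.lo) == pytest.approx(ci.hi - ac1, abs=1e-12)
    # variance agrees with the independent array-expansion estimator
    from oatnet.evaluation import _ac1_delta_variance

    assert _ac1_delta_variance(conf) == pytest.approx(
        ac1_variance_oracle(40, 10, 20, 130), rel=1e-12
    )


def test_bootstrap_and_delta_cis_agree():
    conf = PairConfusion(40, 10, 20, 130)
    delta = gwet_ac1_ci(conf, method="delta")
    boot = gwet_ac1_ci(conf, method="bootstrap", n_boot=4000, seed=0)
    half_delta = (delta.hi - delta.lo) / 2
    half_boot = (boot.hi - boot.lo) / 2
    assert abs(half_delta - half_boot) < 0.02


# ---------------------------------------------------------------------------
# community-to-clinic matching
# ---------------------------------------------------------------------------


def test_community_match_hand_example():
    # community {A,B,C}; clinic X = {A,B,D,E}, clinic Y = {C}
    gold = gold_from({"A": {"X"}, "B": {"X"}, "C": {"Y"}, "D": {"X"}, "E": {"X"}})
    part = make_partition({"A": "g", "B": "g", "C": "g", "D": "d", "E": "e"})
    report = community_match(part, gold)
    row = report.detail.set_index("community").loc["g"]
    assert row["matched_clinic"] == "X"
    assert row["recall"] == pytest.approx(0.5)
    assert row["one_minus_purity"] == pytest.approx(1 / 3)
    assert row["f"] == pytest.approx(4 / 7, abs=1e-4)


def test_exact_community_gets_perfect_scores():
    gold = gold_from({"A": {"X"}, "B": {"X"}, "C": {"Y"}})
    part = make_partition({"A": "g", "B": "g", "C": "h"})
    detail = community_match(part, gold).detail.set_index("community")
    assert detail.loc["g", "recall"] == 1.0
    assert detail.loc["g", "one_minus_purity"] == 0.0
    assert detail.loc["g", "f"] == 1.0


def test_singleton_community_in_larger_clinic():
    gold = gold_from({p: {"Z"} for p in "ABCD"})
    part = make_partition({"A": "a", "B": "b", "C": "c", "D": "d"})
    detail = community_match(part, gold).detail
    assert (detail["recall"] == 0.25).all()
    assert (detail["one_minus_purity"] == 0.0).all()
    assert np.allclose(detail["f"], 0.4)


def test_match_tie_breaks_to_larger_clinic_then_id():
    # overlap 1 with both X (2 attached) and Y (1 attached): prefer X
    gold = gold_from({"A": {"X"}, "B": {"Y"}, "C": {"X"}})
    part = make_partition({"A": "g", "B": "g", "C": "c"})
    detail = community_match(part, gold).detail.set_index("community")
    assert detail.loc["g", "matched_clinic"] == "X"


def test_summary_quartiles_follow_linear_interpolation():
    gold = gold_from({p: {p} for p in "ABCD"})
    part = make_partition({p: p for p in "ABCD"})
    report = community_match(part, gold)
    assert report.summary["recall"]["median"] == 1.0
    assert report.summary["f"]["q1"] == 1.0


# ---------------------------------------------------------------------------
# structure summaries
# ---------------------------------------------------------------------------


def test_summarize_structures_counts():
    rows = []
    for c in range(10):
        rows.append((f"c{c}", "p1", "K", "methadone", "2020-01-01"))
        rows.append((f"c{c}", "p2", "K", "methadone", "2020-01-02"))
    records = make_records(rows)
    table = summarize_structures({"K": {"p1", "p2"}}, records)
    assert table.loc["n_physicians", "median"] == 2
    assert table.loc["n_clients", "median"] == 10
    assert table.loc["client_load", "median"] == 10
    assert table.loc["n_ties", "median"] == 10  # one tie of weight 10


def test_summarize_quartiles_hand_check():
    rows = []
    sizes = {"K1": 1, "K2": 2, "K3": 3, "K4": 4}
    groups = {}
    i = 0
    for clinic, n_phys in sizes.items():
        groups[clinic] = set()
        for p in range(n_phys):
            pid = f"{clinic}p{p}"
            groups[clinic].add(pid)
            rows.append((f"c{i}", pid, clinic, "methadone", "2020-01-01"))
            i += 1
    table = summarize_structures(groups, make_records(rows))
    # physician counts {1,2,3,4}: numpy linear-interpolation quartiles
    assert table.loc["n_physicians", "median"] == pytest.approx(2.5)
    assert table.loc["n_physicians", "q1"] == pytest.approx(1.75)
    assert table.loc["n_physicians", "q3"] == pytest.approx(3.25)
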