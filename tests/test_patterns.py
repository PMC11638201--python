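"""Cardiometabolic-pattern analytics: flags, combinations, shares."""

import itertools

import numpy as np
import pytest

from mmpatterns._utils import ValidationError
from mmpatterns.diagnosis import (ACC_AHA_2017, CHL_2018,
                                  build_disease_matrix)
from mmpatterns.patterns import (CARDIOMETABOLIC, PatternDefinition,
                                 combination_frequencies,
                                 component_disease_shares, pattern_flags,
                                 pattern_share_by_disease)
from mmpatterns.prevalence import multimorbid_flags

from conftest import make_cohort, make_row


def test_pattern_flags_small_cases():
    cohort = make_cohort([
        make_row("A", 150, 95, diseases=("diabetes",)),   # htn + diabetes
        make_row("B", 150, 95),                            # htn only
        make_row("C", 110, 70, diseases=("copd", "asthma")),  # off-pattern
        make_row("D", 110, 70, diseases=("diabetes", "angina")),
    ])
    m = build_disease_matrix(cohort, CHL_2018)
    np.testing.assert_array_equal(
        pattern_flags(m, CARDIOMETABOLIC), [1, 0, 0, 1])


def test_pattern_flags_member_not_in_registry(random_disease_matrix):
    bad = PatternDefinition("bad", ("hypertension", "gout"))
    with pytest.raises(ValidationError, match="gout"):
        pattern_flags(random_disease_matrix, bad)


def test_pattern_flags_equal_brute_force(random_disease_matrix):
    flags = pattern_flags(random_disease_matrix, CARDIOMETABOLIC)
    idx = [random_disease_matrix.registry.index(c)
           for c in sorted(CARDIOMETABOLIC.members)]
    brute = np.array([int(row[idx].sum() >= 2)
                      for row in random_disease_matrix.values])
    np.testing.assert_array_equal(flags, brute)


def test_pattern_flags_bounded_by_multimorbidity(random_disease_matrix):
    assert (pattern_flags(random_disease_matrix, CARDIOMETABOLIC)
            <= multimorbid_flags(random_disease_matrix)).all()


def test_pattern_flags_dominance_across_criteria(small_cohort):
    f_chl = pattern_flags(build_disease_matrix(small_cohort, CHL_2018),
                          CARDIOMETABOLIC)
    f_acc = pattern_flags(build_disease_matrix(small_cohort, ACC_AHA_2017),
                          CARDIOMETABOLIC)
    assert (f_acc >= f_chl).all()


def test_component_shares_recount_and_empty_denominator(
        random_disease_matrix):
    shares = component_disease_shares(random_disease_matrix, CARDIOMETABOLIC,
                                      exclude="hypertension")
    flags = pattern_flags(random_disease_matrix, CARDIOMETABOLIC).astype(bool)
    for row in shares.itertuples(index=False):
        col = random_disease_matrix.column(row.code).astype(bool)
        assert row.n == int((col & flags).sum())
    assert set(shares["code"]) == CARDIOMETABOLIC.members - {"hypertension"}

    zeros = type(random_disease_matrix)(
        values=np.zeros((4, 26), dtype=np.int8),
        row_ids=np.array(list("ABCD")),
        criterion=random_disease_matrix.criterion,
        registry=random_disease_matrix.registry)
    with pytest.raises(ValidationError, match="denominator"):
        component_disease_shares(zeros, CARDIOMETABOLIC, "hypertension")
    with pytest.raises(ValidationError, match="member"):
        component_disease_shares(random_disease_matrix, CARDIOMETABOLIC,
                                 exclude="copd")


def test_component_share_rank_order_stable_across_criteria(default_cohort):
    """Switching to the intensive criterion grows the flagged group but must
    not reorder the component-disease mix."""
    ranks = {}
    for crit in (CHL_2018, ACC_AHA_2017):
        m = build_disease_matrix(default_cohort, crit)
        shares = component_disease_shares(m, CARDIOMETABOLIC, "hypertension")
        ranks[crit.name] = list(shares["code"])
    assert ranks["CHL2018"] == ranks["ACCAHA2017"]


def test_combination_frequencies_exact_enumeration_oracle(rng,
                                                          random_disease_matrix):
    table = combination_frequencies(random_disease_matrix, CARDIOMETABOLIC)
    codes = [c for c in random_disease_matrix.registry.codes
             if c in CARDIOMETABOLIC.members]
    cols = {c: random_disease_matrix.column(c) for c in codes}
    # brute-force: per participant, their exact member profile
    profiles = {}
    for i in range(random_disease_matrix.n):
        profile = frozenset(c for c in codes if cols[c][i])
        if len(profile) >= 2:
            profiles[profile] = profiles.get(profile, 0) + 1
    got = {frozenset(r.combination.split("+")): r.n
           for r in table.table.itertuples(index=False)}
    assert got == profiles
    # exact-profile counts partition the flagged participants
    n_flagged = int(pattern_flags(random_disease_matrix,
                                  CARDIOMETABOLIC).sum())
    assert table.table["n"].sum() == n_flagged


def test_combination_frequencies_at_least_dominates_exact(
        random_disease_matrix):
    exact = combination_frequencies(random_disease_matrix, CARDIOMETABOLIC,
                                    convention="exact")
    atleast = combination_frequencies(random_disease_matrix, CARDIOMETABOLIC,
                                      convention="at_least")
    ge = dict(zip(atleast.table["combination"], atleast.table["n"]))
    for row in exact.table.itertuples(index=False):
        assert ge[row.combination] >= row.n
    # superset-inclusive pair counts equal the brute-force carrier recount
    codes = [c for c in random_disease_matrix.registry.codes
             if c in CARDIOMETABOLIC.members]
    for ci, cj in itertools.combinations(codes, 2):
        n = int((random_disease_matrix.column(ci).astype(bool)
                 & random_disease_matrix.column(cj).astype(bool)).sum())
        if n:
            assert ge[f"{ci}+{cj}"] == n


def test_combination_frequencies_all_zero_matrix_is_empty(
        random_disease_matrix):
    zeros = type(random_disease_matrix)(
        values=np.zeros((4, 26), dtype=np.int8),
        row_ids=np.array(list("ABCD")),
        criterion=random_disease_matrix.criterion,
        registry=random_disease_matrix.registry)
    assert combination_frequencies(zeros, CARDIOMETABOLIC).table.empty


def test_combination_pct_uses_full_cohort_base():
    rows = [make_row(f"P{i}", 150, 95,
                     diseases=("diabetes",) if i < 2 else ())
            for i in range(8)]
    m = build_disease_matrix(make_cohort(rows), CHL_2018)
    table = combination_frequencies(m, CARDIOMETABOLIC).table
    assert len(table) == 1
    assert table.loc[0, "combination"] == "hypertension+diabetes"
    assert table.loc[0, "n"] == 2
    assert table.loc[0, "pct"] == 25.0  # 2/8 of the full cohort


def test_pattern_share_by_disease_recount(random_disease_matrix):
    shares = pattern_share_by_disease(random_disease_matrix, CARDIOMETABOLIC)
    flags = pattern_flags(random_disease_matrix, CARDIOMETABOLIC).astype(bool)
    assert len(shares) == 26
    for row in shares.itertuples(index=False):
        col = random_disease_matrix.column(row.code).astype(bool)
        assert row.n_carriers == int(col.sum())
        assert row.n_pattern == int((col & flags).sum())


def test_pattern_share_missing_for_zero_carriers():
    cohort = make_cohort([make_row("A", 150, 95, diseases=("diabetes",)),
                          make_row("B", 110, 70, diseases=("copd",))])
    m = build_disease_matrix(cohort, CHL_2018)
    shares = pattern_share_by_disease(m, CARDIOMETABOLIC)
    cancer = shares[shares["code"] == "cancer"].iloc[0]
    assert cancer["n_carriers"] == 0 and np.isnan(cancer["pct"])
    htn = shares[shares["code"] == "hypertension"].iloc[0]
    assert htn["pct"] == 100.0  # the only carrier is pattern-flagged
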