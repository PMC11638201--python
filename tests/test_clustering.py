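"""Yule's Q, Ward/Lance-Williams clustering, dendrogram cut, Newick export.

The Ward implementation is checked three independent ways: a closed-form
cluster-distance oracle (treating the supplied dissimilarities as squared
Euclidean, the identity the Lance-Williams Ward recurrence preserves),
R's hclust(method="ward.D") via Rscript, and SciPy's ward linkage for the
squared dialect.
"""

import itertools
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from mmpatterns._utils import ValidationError
from mmpatterns.clustering import (ContingencyTable2x2, DissimilarityMatrix,
                                   adjusted_rand_index, agglomerate_ward,
                                   association_matrix, contingency, cut,
                                   export_newick, name_clusters,
                                   to_dissimilarity, yule_q)
from mmpatterns.diagnosis import CHL_2018, DiseaseMatrix, build_disease_matrix
from mmpatterns.registry import DEFAULT_REGISTRY

from conftest import make_cohort, make_row


def random_dissimilarity(rng, n):
    d = rng.uniform(0.02, 2.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d=d, codes=tuple(f"L{i}" for i in range(n)))


def naive_ward_rescan(d):
    """O(n^3) oracle: closed-form Ward distance recomputed from the original
    matrix at every step (no Lance-Williams updates)."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    for step in range(n - 1):
        def dist(A, B):
            SA = d[np.ix_(A, A)].sum()
            SB = d[np.ix_(B, B)].sum()
            SAB = d[np.ix_(A, B)].sum()
            a, b = len(A), len(B)
            return (2 * a * b / (a + b)
                    * (SAB / (a * b) - SA / (2 * a * a) - SB / (2 * b * b)))

        h, i, j = min((dist(clusters[i], clusters[j]), i, j)
                      for i, j in itertools.combinations(sorted(clusters), 2))
        clusters[n + step] = clusters.pop(i) + clusters.pop(j)
        merges.append((i, j, h, len(clusters[n + step])))
    return merges


# -- contingency and Yule's Q ---------------------------------------------

def two_column_matrix(x, y):
    values = np.zeros((len(x), 26), dtype=np.int8)
    values[:, 1] = x  # diabetes
    values[:, 2] = y  # acute_mi
    return DiseaseMatrix(values=values,
                         row_ids=np.array([f"P{i}" for i in range(len(x))]),
                         criterion=CHL_2018, registry=DEFAULT_REGISTRY)


def test_contingency_enumerated_by_hand():
    m = two_column_matrix([1, 1, 0, 0], [1, 0, 1, 0])
    t = contingency(m, "diabetes", "acute_mi")
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
    with pytest.raises(ValidationError):
        contingency(m, "diabetes", "diabetes")


def test_contingency_identical_columns():
    m = two_column_matrix([1, 0, 1], [1, 0, 1])
    t = contingency(m, "diabetes", "acute_mi")
    assert t.b == t.c == 0 and t.a == 2 and t.d == 1


def test_contingency_matches_brute_force_row_loop(random_disease_matrix):
    t = contingency(random_disease_matrix, "copd", "asthma")
    a = b = c = d = 0
    for row in random_disease_matrix.values:
        x, y = row[DEFAULT_REGISTRY.index("copd")], row[
            DEFAULT_REGISTRY.index("asthma")]
        a += x and y
        b += x and not y
        c += (not x) and y
        d += (not x) and (not y)
    assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
    assert t.n == random_disease_matrix.n


@pytest.mark.parametrize("table,expected", [
    (ContingencyTable2x2(25, 25, 25, 25), 0.0),          # exact independence
    (ContingencyTable2x2(10, 0, 0, 40), 1.0),             # perfect positive
    (ContingencyTable2x2(0, 10, 40, 0), -1.0),            # perfect negative
    (ContingencyTable2x2(30, 10, 20, 40), 1000.0 / 1400.0),
])
def test_yule_q_direct_formula(table, expected):
    assert yule_q(table) == pytest.approx(expected)


def test_yule_q_degenerate_table_corrected_and_logged(caplog):
    with caplog.at_level("INFO", logger="mmpatterns"):
        q = yule_q(ContingencyTable2x2(5, 0, 0, 0))
    assert "continuity correction" in caplog.text
    assert -1 < q < 1
    with pytest.raises(ValidationError):
        yule_q(ContingencyTable2x2(0, 0, 0, 0))


@given(a=st.integers(0, 200), b=st.integers(0, 200),
       c=st.integers(0, 200), d=st.integers(0, 200))
def test_yule_q_symmetry_properties(a, b, c, d):
    """Q is invariant under (a<->d, b<->c) and flips sign when one
    variable's coding is reversed (a<->b, c<->d)."""
    if a + b + c + d == 0:
        return
    q = yule_q(ContingencyTable2x2(a, b, c, d))
    assert -1.0 <= q <= 1.0
    assert yule_q(ContingencyTable2x2(d, c, b, a)) == pytest.approx(q)
    if a * d + b * c > 0 and b * a + d * c > 0:  # neither table degenerate
        q_recoded = yule_q(ContingencyTable2x2(b, a, d, c))
        assert q_recoded == pytest.approx(-q)


def test_association_matrix_independent_columns_near_zero(rng):
    n = 10_000
    values = (rng.random((n, 26)) < 0.2).astype(np.int8)
    m = DiseaseMatrix(values=values,
                      row_ids=np.array([f"P{i}" for i in range(n)]),
                      criterion=CHL_2018, registry=DEFAULT_REGISTRY)
    assoc = association_matrix(m)
    off = assoc.q[~np.eye(26, dtype=bool)]
    assert np.abs(off).max() < 0.1


def test_association_matrix_duplicated_column_gives_q_one(rng):
    values = (rng.random((500, 26)) < 0.3).astype(np.int8)
    values[:, 2] = values[:, 1]
    values[0, :] = 1
    values[1, :] = 0
    m = DiseaseMatrix(values=values,
                      row_ids=np.array([f"P{i}" for i in range(500)]),
                      criterion=CHL_2018, registry=DEFAULT_REGISTRY)
    assoc = association_matrix(m)
    assert assoc.q[1, 2] == 1.0
    assert np.allclose(assoc.q, assoc.q.T)
    assert np.allclose(np.diag(assoc.q), 1.0)


def test_association_matrix_names_constant_column():
    cohort = make_cohort([make_row("A", 150, 95, diseases=("diabetes",)),
                          make_row("B", 110, 70)])
    m = build_disease_matrix(cohort, CHL_2018)
    with pytest.raises(ValidationError, match="asthma"):
        association_matrix(m)


def test_to_dissimilarity_is_one_minus_q(rng, small_cohort):
    assoc = association_matrix(build_disease_matrix(small_cohort, CHL_2018))
    dis = to_dissimilarity(assoc)
    off = ~np.eye(26, dtype=bool)
    np.testing.assert_allclose(dis.d[off], (1.0 - assoc.q)[off])
    assert (np.diag(dis.d) == 0).all()
    assert dis.d.min() >= 0 and dis.d.max() <= 2


# -- Ward clustering -------------------------------------------------------

def test_two_leaves_single_merge():
    d = np.array([[0.0, 0.7], [0.7, 0.0]])
    dend = agglomerate_ward(DissimilarityMatrix(d=d, codes=("A", "B")))
    assert len(dend.merges) == 1
    m = dend.merges[0]
    assert (m.left, m.right, m.size) == (0, 1, 2)
    assert m.height == pytest.approx(0.7)


def test_well_separated_pairs_merge_first():
    d = np.full((4, 4), 1.9)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.1
    d[2, 3] = d[3, 2] = 0.1
    dend = agglomerate_ward(
        DissimilarityMatrix(d=d, codes=("A", "B", "C", "D")))
    assert {(dend.merges[0].left, dend.merges[0].right),
            (dend.merges[1].left, dend.merges[1].right)} == {(0, 1), (2, 3)}


def test_ward_matches_naive_rescan_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(3, 11))
        dm = random_dissimilarity(rng, n)
        ours = [(m.left, m.right, m.height, m.size)
                for m in agglomerate_ward(dm).merges]
        oracle = naive_ward_rescan(dm.d)
        for got, want in zip(ours, oracle):
            assert got[:2] == want[:2] and got[3] == want[3]
            assert got[2] == pytest.approx(want[2], abs=1e-9)


def test_ward_heights_non_decreasing(rng):
    for _ in range(10):
        dm = random_dissimilarity(rng, 12)
        h = agglomerate_ward(dm).heights
        assert (np.diff(h) >= -1e-9).all()


def test_ward_d2_dialect_matches_scipy(rng):
    for _ in range(5):
        dm = random_dissimilarity(rng, 9)
        dend = agglomerate_ward(dm, square_dissimilarity=True)
        ours = cophenet(dend.to_linkage())
        ref = cophenet(linkage(squareform(dm.d), method="ward"))
        np.testing.assert_allclose(ours, ref)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
def test_ward_d_dialect_matches_r_hclust(rng, tmp_path):
    for trial in range(3):
        dm = random_dissimilarity(rng, 8)
        path = tmp_path / f"d{trial}.csv"
        np.savetxt(path, dm.d, delimiter=",")
        out = subprocess.run(
            ["Rscript", "-e",
             f'd<-as.matrix(read.csv("{path}",header=FALSE));'
             'h<-hclust(as.dist(d),method="ward.D");'
             'cat(sprintf("%.15g",as.vector(as.dist(cophenetic(h)))),'
             'sep=",")'],
            capture_output=True, text=True, check=True)
        ref = np.array([float(x) for x in out.stdout.split(",")])
        ours = cophenet(agglomerate_ward(dm).to_linkage())
        np.testing.assert_allclose(ours, ref, rtol=1e-8)


def test_ward_rejects_bad_input():
    with pytest.raises(ValidationError):
        DissimilarityMatrix(d=np.array([[0.0, 0.5], [0.4, 0.0]]),
                            codes=("A", "B"))
    with pytest.raises(ValidationError):
        DissimilarityMatrix(d=np.array([[0.0, -0.2], [-0.2, 0.0]]),
                            codes=("A", "B"))


def test_ward_is_deterministic(rng):
    dm = random_dissimilarity(rng, 10)
    a = agglomerate_ward(dm).to_merge_table()
    b = agglomerate_ward(dm).to_merge_table()
    assert a.equals(b)


# -- cut, naming, newick ----------------------------------------------------

def test_cut_extremes(rng):
    dm = random_dissimilarity(rng, 6)
    dend = agglomerate_ward(dm)
    singletons = cut(dend, 6)
    assert sorted(singletons.mapping.values()) == [1, 2, 3, 4, 5, 6]
    one = cut(dend, 1)
    assert set(one.mapping.values()) == {1}
    with pytest.raises(ValidationError):
        cut(dend, 0)
    with pytest.raises(ValidationError):
        cut(dend, 7)


def test_cut_recovers_planted_blocks():
    # two well-separated pairs -> k=2 must recover them exactly
    d = np.full((4, 4), 1.9)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.1
    d[2, 3] = d[3, 2] = 0.1
    dend = agglomerate_ward(
        DissimilarityMatrix(d=d, codes=("A", "B", "C", "D")))
    asg = cut(dend, 2)
    assert asg.mapping["A"] == asg.mapping["B"]
    assert asg.mapping["C"] == asg.mapping["D"]
    assert asg.mapping["A"] != asg.mapping["C"]


def test_name_clusters_attaches_pattern_names(default_cohort):
    assoc = association_matrix(build_disease_matrix(default_cohort, CHL_2018))
    dend = agglomerate_ward(to_dissimilarity(assoc))
    named = name_clusters(cut(dend, 4))
    assert set(named.names.values()) == {
        "cardiometabolic", "respiratory", "digestive-bone-kidney",
        "mental-cancer"}
    cardio = [cid for cid, nm in named.names.items()
              if nm == "cardiometabolic"][0]
    assert {"hypertension", "diabetes", "acute_mi", "angina",
            "stroke_tia"} <= set(named.members(cardio))


def test_newick_two_leaf_shape():
    d = np.array([[0.0, 0.8], [0.8, 0.0]])
    dend = agglomerate_ward(DissimilarityMatrix(d=d, codes=("A", "B")))
    assert export_newick(dend) == "(A:0.8,B:0.8);"


def test_newick_round_trip_recovers_topology(rng):
    import dendropy

    dm = random_dissimilarity(rng, 7)
    dend = agglomerate_ward(dm)
    tree = dendropy.Tree.get(data=export_newick(dend), schema="newick")
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    assert leaves == set(dm.codes)
    # clades of the parsed tree match the merge history's clusters
    clades = {frozenset(lf.taxon.label for lf in nd.leaf_iter())
              for nd in tree.preorder_node_iter() if not nd.is_leaf()}
    members = {i: frozenset([dm.codes[i]]) for i in range(7)}
    expected = set()
    for step, m in enumerate(dend.merges):
        members[7 + step] = members[m.left] | members[m.right]
        expected.add(members[7 + step])
    assert clades == expected


def test_newick_26_leaves(default_cohort):
    assoc = association_matrix(build_disease_matrix(default_cohort, CHL_2018))
    dend = agglomerate_ward(to_dissimilarity(assoc))
    nwk = export_newick(dend)
    for code in DEFAULT_REGISTRY.codes:
        assert code in nwk
    assert nwk.endswith(";")


# -- adjusted Rand index ----------------------------------------------------

def test_ari_against_sklearn(rng):
    from sklearn.metrics import adjusted_rand_score

    for _ in range(20):
        a = rng.integers(0, 4, size=30)
        b = rng.integers(0, 3, size=30)
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_score(a, b))
    x = rng.integers(0, 4, size=30)
    assert adjusted_rand_index(x, x) == 1.0
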