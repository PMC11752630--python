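"""Node/edge scores, SFFL scoring with the miRNA drop rule, and the
random-triple permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apamirnet.datatypes import PipelineConfig, ValidationError
from apamirnet.ffl import SFFL
from apamirnet.scoring import (
    ClusterContext,
    annotate_apa_loss,
    edge_score,
    node_score,
    sffl_permutation_test,
    sffl_score,
)

# ---------------------------------------------------------------------------
# node scores


def test_node_score_closed_forms():
    assert node_score(0.5) == pytest.approx(0.0, abs=1e-12)
    assert node_score(0.05) == pytest.approx(1.6449, abs=1e-4)
    # p = 1 hits the clip floor: the standard-normal quantile at 1e-12
    assert node_score(1.0) == pytest.approx(-7.034, abs=1e-3)
    with pytest.raises(ValidationError):
        node_score(1.2)


@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
@settings(derandomize=True, max_examples=50)
def test_node_score_strictly_decreasing(p1, p2):
    lo, hi = sorted((p1, p2))
    if hi - lo > 1e-9:
        assert node_score(lo) >= node_score(hi)


# ---------------------------------------------------------------------------
# edge scores


def _vectors_with_correlation(r, n=28, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    x -= x.mean()
    e -= e.mean()
    e -= (e @ x) / (x @ x) * x
    x /= np.linalg.norm(x)
    e /= np.linalg.norm(e)
    y = r * x + np.sqrt(1 - r * r) * e
    return x, y


def test_edge_score_closed_forms():
    x, y = _vectors_with_correlation(0.0)
    assert edge_score(x, y) == pytest.approx(0.0, abs=1e-10)
    x, y = _vectors_with_correlation(0.5)
    # atanh(0.5) * sqrt(25) = 0.5493 * 5
    assert edge_score(x, y) == pytest.approx(2.7465, abs=1e-4)


def test_edge_score_perfect_correlation_clips_and_scales():
    x = np.random.default_rng(1).normal(size=30)
    s1 = edge_score(x, x)
    s2 = edge_score(x, 7.0 * x + 3.0)
    assert np.isfinite(s1) and s1 == pytest.approx(s2)


def test_edge_score_affine_invariance_and_sign():
    x, y = _vectors_with_correlation(0.6, seed=2)
    assert edge_score(x, y) == pytest.approx(edge_score(2 * x + 1, -3 * y + 5))
    assert edge_score(x, -y, signed=True) == pytest.approx(
        -edge_score(x, y, signed=True))


def test_edge_score_degenerate_inputs():
    with pytest.raises(ValidationError):
        edge_score([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])  # n < 4
    with pytest.warns(UserWarning, match="zero-variance"):
        assert edge_score(np.ones(10), np.arange(10.0)) == 0.0


# ---------------------------------------------------------------------------
# SFFL scoring


def _context_with_exact_scores(n=28):
    """Context whose three rows m, t, g have pairwise Fisher-z edge scores
    exactly 1, 2 and 3 (for n = 28, sqrt(n-3) = 5)."""
    C = np.eye(3)
    C[0, 1] = C[1, 0] = np.tanh(1 / 5)   # m–t
    C[0, 2] = C[2, 0] = np.tanh(2 / 5)   # m–g
    C[1, 2] = C[2, 1] = np.tanh(3 / 5)   # t–g
    L = np.linalg.cholesky(C)
    rng = np.random.default_rng(0)
    E = rng.normal(size=(3, n))
    E -= E.mean(axis=1, keepdims=True)
    # orthonormalize the centered rows
    q, _ = np.linalg.qr(E.T)
    Z = L @ q.T[:3]
    return ClusterContext(
        cluster="A", n_cells=n, Z=Z,
        row_index={"m": 0, "t": 1, "g": 2},
        node_scores={"m": 1.0, "t": 2.0, "g": 3.0},
    )


def test_sffl_score_mean_of_six_entries():
    """Node scores {1,2,3} and edge scores {1,2,3} average to S = 2.0 for a
    feedback loop (three nodes, m–g, t–g and both m–t cross-edges... the two
    cross-edges share one correlation), here checked on the miRNA-centric
    pattern with its three distinct edges."""
    ctx = _context_with_exact_scores()
    s = sffl_score(SFFL("m", "t", "g", "mirna_centric"), ctx)
    assert s == pytest.approx(2.0, abs=1e-9)


def test_sffl_score_mirna_drop_rule():
    """Without a miRNA expression row only {2, 3} node scores and the t–g
    edge score {3} remain: S = 8/3."""
    ctx = _context_with_exact_scores()
    ctx.row_index = {"t": 1, "g": 2}
    del ctx.node_scores["m"]
    s = sffl_score(SFFL("m", "t", "g", "mirna_centric"), ctx)
    assert s == pytest.approx(8.0 / 3.0, abs=1e-9)


def test_sffl_score_feedback_counts_cross_edge_twice():
    ctx = _context_with_exact_scores()
    s = sffl_score(SFFL("m", "t", "g", "feedback"), ctx)
    # entries: nodes {1,2,3}, edges {m-g: 2, t-g: 3, m-t: 1 twice}
    assert s == pytest.approx((1 + 2 + 3 + 2 + 3 + 1 + 1) / 7.0, abs=1e-9)


def test_sffl_unscorable_without_tf_or_gene():
    ctx = _context_with_exact_scores()
    ctx.row_index = {"t": 1}
    assert np.isnan(sffl_score(SFFL("m", "t", "g", "mirna_centric"), ctx))


def test_drop_rule_matches_tf_gene_substructure():
    """Scoring with the miRNA blanked equals scoring the TF–gene pair
    directly from its node scores and edge score."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(2, 40))
    Xc = X - X.mean(axis=1, keepdims=True)
    Z = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
    ctx = ClusterContext(cluster="A", n_cells=40, Z=Z,
                         row_index={"t": 0, "g": 1},
                         node_scores={"t": 1.3, "g": -0.2})
    s = sffl_score(SFFL("absent_mir", "t", "g", "feedback"), ctx)
    expected = (1.3 - 0.2 + edge_score(X[0], X[1])) / 3.0
    assert s == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# permutation test


def _random_context(nodes, n=30, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(len(nodes), n))
    Xc = X - X.mean(axis=1, keepdims=True)
    Z = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
    return ClusterContext(
        cluster="A", n_cells=n, Z=Z,
        row_index={nd: i for i, nd in enumerate(nodes)},
        node_scores={nd: float(rng.normal()) for nd in nodes},
    )


def test_constant_expression_uniform_de_gives_p_one():
    nodes = ["m1", "t1", "g1", "g2"]
    ctx = ClusterContext(cluster="A", n_cells=20,
                         Z=np.zeros((4, 20)),
                         row_index={nd: i for i, nd in enumerate(nodes)},
                         node_scores={nd: 0.0 for nd in nodes})
    config = PipelineConfig(n_permutations=200, seed=0)
    out = sffl_permutation_test(
        [SFFL("m1", "t1", "g1", "mirna_centric")], ctx,
        {"miRNA": ["m1"], "TF": ["t1"], "gene": ["g1", "g2"]},
        config, np.random.default_rng(0))
    assert out[0].p == pytest.approx(1.0)


def test_permutation_p_matches_exhaustive_triple_enumeration():
    """With pools of size (2,2,2) the null has 8 equally likely triples; the
    Monte-Carlo p must sit within 3 binomial sd of the enumeration value."""
    nodes = ["m1", "m2", "t1", "t2", "g1", "g2"]
    ctx = _random_context(nodes, seed=4)
    pools = {"miRNA": ["m1", "m2"], "TF": ["t1", "t2"], "gene": ["g1", "g2"]}
    B = 4000
    config = PipelineConfig(n_permutations=B, seed=0)
    sffl = SFFL("m1", "t1", "g1", "mirna_centric")
    out = sffl_permutation_test([sffl], ctx, pools, config,
                                np.random.default_rng(11))
    obs = out[0].score
    scores = []
    for m in pools["miRNA"]:
        for t in pools["TF"]:
            for g in pools["gene"]:
                scores.append(sffl_score(SFFL(m, t, g, "mirna_centric"), ctx))
    q = np.mean([s >= obs - 1e-12 for s in scores])
    sd = np.sqrt(q * (1 - q) / B)
    assert abs(out[0].p - q) <= 3 * sd + 2.0 / (B + 1)


def test_permutation_deterministic_and_order_independent():
    nodes = ["m1", "m2", "t1", "t2", "g1", "g2", "g3"]
    ctx = _random_context(nodes, seed=5)
    pools = {"miRNA": ["m1", "m2"], "TF": ["t1", "t2"],
             "gene": ["g1", "g2", "g3"]}
    config = PipelineConfig(n_permutations=300, seed=0)
    cands = [SFFL("m1", "t1", "g1", "mirna_centric"),
             SFFL("m2", "t2", "g2", "tf_centric")]
    a = sffl_permutation_test(cands, ctx, pools, config,
                              np.random.default_rng(7))
    b = sffl_permutation_test(cands, ctx, pools, config,
                              np.random.default_rng(7))
    assert [(s.p, s.p_adj) for s in a] == [(s.p, s.p_adj) for s in b]


def test_empty_pool_rejected():
    ctx = _random_context(["t1", "g1"], seed=6)
    config = PipelineConfig(n_permutations=10, seed=0)
    with pytest.raises(ValidationError, match="empty candidate pool"):
        sffl_permutation_test([], ctx, {"miRNA": [], "TF": ["t1"],
                                        "gene": ["g1"]}, config,
                              np.random.default_rng(0))


# ---------------------------------------------------------------------------
# APA-loss annotation


def _avoidance(rows):
    return pd.DataFrame(rows, columns=["cluster", "family_id", "p_adj"])


def test_annotate_flags_by_cluster_and_family():
    av = _avoidance([("OPC", "MIR214", 0.01), ("Other", "MIR214", 0.9)])
    sffls = [SFFL("MIR214", "JUN", "PTX3", "mirna_centric", cluster="OPC"),
             SFFL("MIR214", "JUN", "PTX3", "mirna_centric", cluster="Other")]
    out, _ = annotate_apa_loss(sffls, [], av, alpha=0.05)
    assert out[0].apa_loss_flag is True
    assert out[1].apa_loss_flag is False


def test_annotate_without_avoidance_warns_all_false():
    sffls = [SFFL("m", "t", "g", "mirna_centric", cluster="A")]
    with pytest.warns(UserWarning, match="no avoidance"):
        out, _ = annotate_apa_loss(sffls, [], _avoidance([]), alpha=0.05)
    assert out[0].apa_loss_flag is False


def test_annotate_cluster_mismatch_is_error():
    av = _avoidance([("OPC", "MIR214", 0.01)])
    sffls = [SFFL("m", "t", "g", "mirna_centric", cluster="Elsewhere")]
    with pytest.raises(ValidationError, match="Elsewhere"):
        annotate_apa_loss(sffls, [], av, alpha=0.05)
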