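"""Binding-site fate, lost/retained totals, and the label-shuffle test."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from apamirnet.avoidance import (
    avoidance_permutation_test,
    avoidance_statistic,
    family_lost_retained,
    gene_loss_overlap,
    site_fate,
    substream,
)
from apamirnet.datatypes import (
    ApaMatrix,
    ClusterAssignment,
    PipelineConfig,
    ValidationError,
)


@pytest.mark.parametrize("site,cleavage,fate", [
    ((150, 157), 100, "lost"),
    ((150, 157), 157, "retained"),   # boundary: site ends exactly at cleavage
    ((150, 157), 156, "lost"),       # one truncated base loses the site
])
def test_site_fate_rule(site, cleavage, fate):
    assert site_fate(site, cleavage) == fate


def test_avoidance_statistic_values():
    assert avoidance_statistic(30, 10) == pytest.approx(0.75)
    assert avoidance_statistic(0, 5) == 0.0
    with pytest.raises(ValidationError):
        avoidance_statistic(0, 0)


def test_lost_fraction_orders_like_ratio():
    rng = np.random.default_rng(0)
    L, R = rng.random(1000) * 10, rng.random(1000) * 10 + 1e-6
    frac = L / (L + R)
    ratio = L / R
    order_f = np.argsort(frac, kind="stable")
    assert np.all(np.diff(ratio[order_f]) >= -1e-12)


def test_family_lost_retained_toy(toy_apa, toy_sites):
    """Cleavages {100, 300}, one site (150,157): lost on the proximal
    isoform, retained on the distal. Cluster sums 30 / 10 → (L,R)=(30,10)."""
    out = family_lost_retained(toy_apa, toy_sites, {"c1", "c2"})
    row = out.iloc[0]
    assert (row["lost"], row["retained"]) == (30.0, 10.0)
    assert avoidance_statistic(row["lost"], row["retained"]) == 0.75
    assert row["contributing_genes"] == ["G1"]


def test_site_upstream_of_all_cleavages_only_retained(toy_apa):
    sites = pd.DataFrame({"family_id": ["F1"], "gene_id": ["G1"],
                          "start": [50], "end": [57]})
    out = family_lost_retained(toy_apa, sites, {"c1", "c2"})
    assert out.iloc[0]["lost"] == 0.0
    assert out.iloc[0]["retained"] == 40.0


def _random_case(rng, n_genes=3, n_fams=2, n_cells=5):
    meta_rows, values = [], []
    for gi in range(n_genes):
        k = int(rng.integers(2, 4))
        pos = sorted(rng.choice(np.arange(10, 200), size=k, replace=False))
        for j, p in enumerate(pos):
            meta_rows.append({"gene_id": f"G{gi}", "site_id": f"G{gi}:PA{j}",
                              "cleavage_pos": int(p)})
            values.append(rng.integers(0, 6, size=n_cells))
    apa = ApaMatrix(np.array(values, dtype=float), pd.DataFrame(meta_rows),
                    [f"c{i}" for i in range(n_cells)])
    site_rows = []
    for f in range(n_fams):
        for _ in range(int(rng.integers(1, 5))):
            g = f"G{int(rng.integers(0, n_genes))}"
            start = int(rng.integers(0, 190))
            site_rows.append({"family_id": f"F{f}", "gene_id": g,
                              "start": start, "end": start + 7})
    sites = pd.DataFrame(site_rows).drop_duplicates().reset_index(drop=True)
    return apa, sites


def test_lost_retained_matches_quadruple_loop_oracle():
    """Weighted (L,R) equals an exhaustive loop over
    (gene, isoform, site, cell)."""
    rng = np.random.default_rng(11)
    for _ in range(10):
        apa, sites = _random_case(rng)
        cells = set(apa.cell_ids[:3])
        out = family_lost_retained(apa, sites, cells).set_index("family_id")
        eligible = apa.genes_with_multiple_sites()
        oracle = {f: [0.0, 0.0] for f in sites["family_id"].unique()}
        for _, iso in apa.site_meta.iterrows():
            if iso["gene_id"] not in eligible:
                continue
            i = apa.site_meta[(apa.site_meta["gene_id"] == iso["gene_id"]) &
                              (apa.site_meta["site_id"] == iso["site_id"])].index[0]
            for _, s in sites[sites["gene_id"] == iso["gene_id"]].iterrows():
                for ci, c in enumerate(apa.cell_ids):
                    if c not in cells:
                        continue
                    fate = site_fate((s["start"], s["end"]), iso["cleavage_pos"])
                    oracle[s["family_id"]][0 if fate == "lost" else 1] += \
                        apa.values[i, ci]
        for f, (L, R) in oracle.items():
            assert out.loc[f, "lost"] == pytest.approx(L)
            assert out.loc[f, "retained"] == pytest.approx(R)


def test_lost_retained_invariant_to_cell_order(toy_apa, toy_sites):
    perm = [3, 0, 2, 1]
    apa2 = ApaMatrix(toy_apa.values[:, perm], toy_apa.site_meta,
                     [toy_apa.cell_ids[i] for i in perm])
    a = family_lost_retained(toy_apa, toy_sites, {"c1", "c2"})
    b = family_lost_retained(apa2, toy_sites, {"c1", "c2"})
    pd.testing.assert_frame_equal(a, b)


def test_lost_retained_linear_in_values(toy_apa, toy_sites):
    """The weighted totals are linear in the matrix, so re-aggregating split
    expression mass leaves (L, R) unchanged."""
    half = ApaMatrix(toy_apa.values / 2, toy_apa.site_meta, toy_apa.cell_ids)
    a = family_lost_retained(toy_apa, toy_sites, {"c1", "c2"})
    b = family_lost_retained(half, toy_sites, {"c1", "c2"})
    assert np.allclose(a["lost"], 2 * b["lost"])
    assert np.allclose(a["retained"], 2 * b["retained"])


def test_binary_mode_counts_used_isoforms(toy_apa, toy_sites):
    out = family_lost_retained(toy_apa, toy_sites, set(toy_apa.cell_ids),
                               mode="binary")
    # both isoforms nonzero in >= 5% of 4 cells → one lost + one retained copy
    assert (out.iloc[0]["lost"], out.iloc[0]["retained"]) == (1.0, 1.0)


# ---------------------------------------------------------------------------
# permutation test


def test_identical_cells_give_p_one(toy_sites, toy_clusters):
    meta = pd.DataFrame({"gene_id": ["G1", "G1"], "site_id": ["a", "b"],
                         "cleavage_pos": [100, 300]})
    vals = np.tile(np.array([[3.0], [1.0]]), (1, 4))
    apa = ApaMatrix(vals, meta, ["c1", "c2", "c3", "c4"])
    config = PipelineConfig(n_permutations=200, seed=0)
    res = avoidance_permutation_test(apa, toy_sites, toy_clusters, "A", config)
    assert np.allclose(res["p"].dropna(), 1.0)


def test_permutation_p_matches_exact_enumeration(toy_apa, toy_sites, toy_clusters):
    """Monte-Carlo p (B = 10,000) is within 3 binomial sd of the exact p from
    enumerating all C(4,2) = 6 focal-cell subsets."""
    B = 10_000
    config = PipelineConfig(n_permutations=B, seed=123)
    res = avoidance_permutation_test(toy_apa, toy_sites, toy_clusters, "A",
                                     config)
    p_mc = res["p"].iloc[0]

    def stat(cells):
        out = family_lost_retained(toy_apa, toy_sites, set(cells))
        return avoidance_statistic(out.iloc[0]["lost"], out.iloc[0]["retained"])

    obs = stat(["c1", "c2"])
    subsets = list(combinations(toy_apa.cell_ids, 2))
    q = np.mean([stat(s) >= obs - 1e-12 for s in subsets])
    sd = np.sqrt(q * (1 - q) / B)
    assert abs(p_mc - q) <= 3 * sd + 2.0 / (B + 1)


def test_paper_exact_flag_strictly_greater(toy_apa, toy_sites, toy_clusters):
    config = PipelineConfig(n_permutations=500, seed=5,
                            smooth_permutation_p=False)
    res = avoidance_permutation_test(toy_apa, toy_sites, toy_clusters, "A",
                                     config)
    p = res["p"].iloc[0]
    assert 0.0 <= p <= 1.0
    assert p * 500 == int(round(p * 500))  # literal count / B


def test_fixed_seed_reproducible(toy_apa, toy_sites, toy_clusters):
    config = PipelineConfig(n_permutations=300, seed=77)
    a = avoidance_permutation_test(toy_apa, toy_sites, toy_clusters, "A", config)
    b = avoidance_permutation_test(toy_apa, toy_sites, toy_clusters, "A", config)
    pd.testing.assert_frame_equal(a, b)


def test_cluster_relabeling_permutes_results(toy_apa, toy_sites, toy_clusters):
    """A bijective renaming of cluster labels leaves the numbers unchanged
    when the same RNG stream is supplied."""
    config = PipelineConfig(n_permutations=300, seed=9)
    renamed = ClusterAssignment(toy_clusters.labels.map({"A": "X", "B": "Y"}))
    a = avoidance_permutation_test(toy_apa, toy_sites, toy_clusters, "A",
                                   config, rng=substream(9, "t"))
    b = avoidance_permutation_test(toy_apa, toy_sites, renamed, "X",
                                   config, rng=substream(9, "t"))
    for col in ("lost", "retained", "statistic", "p", "p_adj"):
        assert np.allclose(a[col], b[col], equal_nan=True)


def test_untestable_family_excluded_from_bh(toy_apa, toy_clusters):
    sites = pd.DataFrame({
        "family_id": ["F1", "F2"], "gene_id": ["G1", "ABSENT"],
        "start": [150, 10], "end": [157, 17]})
    config = PipelineConfig(n_permutations=100, seed=1)
    res = avoidance_permutation_test(toy_apa, sites, toy_clusters, "A", config)
    f2 = res[res["family_id"] == "F2"].iloc[0]
    assert np.isnan(f2["statistic"]) and np.isnan(f2["p"])
    assert res[res["family_id"] == "F1"]["p"].notna().all()


# ---------------------------------------------------------------------------
# overlap


def test_gene_loss_overlap_examples():
    out = gene_loss_overlap({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
    d = dict(zip(out["clusters"], out["exclusive_count"]))
    assert d == {"A": 1, "B": 1, "A&B": 1}

    same = gene_loss_overlap({"A": {"g1"}, "B": {"g1"}})
    d = dict(zip(same["clusters"], same["exclusive_count"]))
    assert d == {"A": 0, "B": 0, "A&B": 1}


def test_gene_loss_overlap_matches_membership_oracle():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(20)]
    sets = {c: set(rng.choice(genes, size=rng.integers(0, 15), replace=False))
            for c in ("A", "B", "C")}
    out = gene_loss_overlap(sets)
    d = dict(zip(out["clusters"], out["exclusive_count"]))
    for g in genes:
        member = frozenset(c for c in sets if g in sets[c])
        if member:
            key = "&".join(sorted(member))
            d[key] -= 1
    assert all(v == 0 for v in d.values())
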