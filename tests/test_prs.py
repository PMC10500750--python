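import numpy as np
import pandas as pd
import pytest

from prsoverlap.formats import GenotypePanel
from prsoverlap.prs import SNPSelection, clump, filter_sumstats, score, select_top

from conftest import random_panel


def _stats(rows):
    return pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 "beta", "se", "p", "n", "maf"],
    )


@pytest.fixture
def stats3():
    return _stats(
        [
            ["rs1", "1", 100, "A", "G", 0.5, 0.1, 1e-6, 1000, 0.2],
            ["rs2", "1", 5000, "C", "T", 0.2, 0.1, 0.01, 1000, 0.005],
            ["rs3", "19", 45_000_000, "G", "A", 0.1, 0.1, 0.4, 1000, 0.3],
        ]
    )


def test_filter_removes_rare_snps(stats3):
    out = filter_sumstats(stats3, maf_min=0.01, p_max=0.5)
    assert "rs2" not in out["variant_id"].tolist()
    assert out.attrs["filter_counts"]["maf"] == 1


def test_filter_p_threshold(stats3):
    out = filter_sumstats(stats3, maf_min=0.0, p_max=0.1)
    assert out["variant_id"].tolist() == ["rs1", "rs2"]


def test_filter_region_boundary_inclusive(stats3):
    # pos == end must be excluded (1-based inclusive on both ends)
    out = filter_sumstats(
        stats3, maf_min=0.0, p_max=1.0, exclude_regions=[("19", 44_000_000, 45_000_000)]
    )
    assert "rs3" not in out["variant_id"].tolist()
    assert out.attrs["filter_counts"]["region"] == 1


def test_filter_bad_region_errors(stats3):
    with pytest.raises(ValueError, match="start > end"):
        filter_sumstats(stats3, exclude_regions=[("1", 200, 100)])


def test_filter_empty_exclusion_list(stats3):
    out = filter_sumstats(stats3, maf_min=0.0, p_max=1.0, exclude_regions=[])
    assert len(out) == 3


# ---------------------------------------------------------------------------
# clumping


def brute_force_clump(stats, panel, window_bp, r2_max):
    """Oracle: re-scan the remaining list after every index selection."""
    col = {v: j for j, v in enumerate(panel.variants["variant_id"])}
    G = panel.dosage - panel.dosage.mean(axis=0)
    remaining = stats.sort_values(
        ["p", "chrom", "pos", "variant_id"], kind="stable"
    ).to_dict("records")
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index["variant_id"])
        survivors = []
        gi = G[:, col[index["variant_id"]]]
        for row in remaining:
            if row["chrom"] == index["chrom"] and abs(row["pos"] - index["pos"]) <= window_bp:
                gj = G[:, col[row["variant_id"]]]
                denom = np.sqrt((gi @ gi) * (gj @ gj))
                r2 = (gi @ gj) ** 2 / denom**2 if denom > 0 else 0.0
                if r2 >= r2_max:
                    continue
            survivors.append(row)
        remaining = survivors
    return set(kept)


def test_clump_single_snp_retained(rng):
    panel = random_panel(rng, n=50, m=1)
    stats = _stats([["v0", "1", 1000, "A", "G", 0.5, 0.1, 0.01, 50, 0.3]])
    sel = clump(stats, panel)
    assert sel.table["variant_id"].tolist() == ["v0"]


def test_clump_keeps_lowest_p_of_a_correlated_pair(rng):
    # two SNPs 1 kb apart in near-perfect LD: only the 1e-8 one survives
    d = rng.binomial(2, 0.3, size=500).astype(float)
    noise = d.copy()
    flip = rng.random(500) < 0.005
    noise[flip] = 2 - noise[flip]
    variants = pd.DataFrame(
        {
            "variant_id": ["a", "b"],
            "chrom": "1",
            "pos": [10_000, 11_000],
            "allele_counted": "A",
            "allele_other": "G",
        }
    )
    panel = GenotypePanel(variants, [f"s{i}" for i in range(500)], np.column_stack([d, noise]))
    stats = _stats(
        [
            ["a", "1", 10_000, "A", "G", 0.5, 0.1, 1e-8, 500, 0.3],
            ["b", "1", 11_000, "A", "G", 0.4, 0.1, 1e-4, 500, 0.3],
        ]
    )
    sel = clump(stats, panel, window_bp=1_000_000, r2_max=0.1)
    assert sel.table["variant_id"].tolist() == ["a"]


@pytest.mark.parametrize("seed", range(5))
def test_clump_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    panel = random_panel(rng, n=120, m=100, spacing=400)
    stats = _stats(
        [
            [f"v{j}", "1", (j + 1) * 400, "A", "G", rng.normal(), 0.1,
             float(rng.random()), 120, 0.3]
            for j in range(100)
        ]
    )
    sel = clump(stats, panel, window_bp=5_000, r2_max=0.2)
    oracle = brute_force_clump(stats, panel, 5_000, 0.2)
    assert set(sel.table["variant_id"]) == oracle


def test_clump_retained_pairs_below_r2_threshold(rng):
    """Post-hoc invariant: every retained same-chromosome pair within the
    window has r^2 < r2_max."""
    panel = random_panel(rng, n=100, m=60, spacing=300)
    stats = _stats(
        [
            [f"v{j}", "1", (j + 1) * 300, "A", "G", 0.1, 0.1, float(rng.random()), 100, 0.3]
            for j in range(60)
        ]
    )
    r2_max, window = 0.15, 4_000
    sel = clump(stats, panel, window_bp=window, r2_max=r2_max)
    kept = sel.table
    col = {v: j for j, v in enumerate(panel.variants["variant_id"])}
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            a, b = kept.iloc[i], kept.iloc[j]
            if abs(a["pos"] - b["pos"]) <= window:
                r = np.corrcoef(
                    panel.dosage[:, col[a["variant_id"]]],
                    panel.dosage[:, col[b["variant_id"]]],
                )[0, 1]
                assert r * r < r2_max


def test_clump_empty_stats_gives_empty_selection(rng):
    panel = random_panel(rng, n=20, m=5)
    sel = clump(_stats([]), panel)
    assert len(sel) == 0


def test_select_top():
    table = _stats(
        [
            ["a", "1", 100, "A", "G", 0.1, 0.1, 0.3, 10, 0.3],
            ["b", "1", 200, "A", "G", 0.2, 0.1, 0.001, 10, 0.3],
            ["c", "1", 300, "A", "G", 0.3, 0.1, 0.02, 10, 0.3],
        ]
    )
    sel = SNPSelection(table)
    assert select_top(sel, 0).table.empty
    assert select_top(sel, 10).table["variant_id"].tolist() == ["b", "c", "a"]
    assert select_top(sel, 1).table["variant_id"].tolist() == ["b"]


# ---------------------------------------------------------------------------
# scoring


def _score_panel(dosages, counted="A", other="G"):
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(dosages.shape[1])],
            "chrom": "1",
            "pos": np.arange(1, dosages.shape[1] + 1) * 1000,
            "allele_counted": counted,
            "allele_other": other,
        }
    )
    return GenotypePanel(variants, [f"s{i}" for i in range(len(dosages))], dosages)


def test_score_simple_sum():
    panel = _score_panel(np.array([[2.0], [1.0], [0.0]]))
    sel = SNPSelection(_stats([["v0", "1", 1000, "A", "G", 0.5, 0.1, 0.01, 10, 0.3]]))
    vec = score(panel, sel)
    assert np.allclose(vec.scores, [1.0, 0.5, 0.0])
    assert (vec.table["N_SNPS_USED"] == 1).all()


def test_score_reflects_flipped_alleles():
    panel = _score_panel(np.array([[2.0], [0.0]]))
    # selection counts G, the panel counts A -> dosage reflected to 2 - d
    sel = SNPSelection(_stats([["v0", "1", 1000, "G", "A", 0.5, 0.1, 0.01, 10, 0.3]]))
    vec = score(panel, sel)
    assert np.allclose(vec.scores, [0.0, 1.0])
    assert vec.match_report["flipped"] == 1


def test_score_drops_ambiguous_and_absent():
    panel = _score_panel(np.array([[1.0, 1.0], [2.0, 0.0]]))
    sel = SNPSelection(
        _stats(
            [
                ["v0", "1", 1000, "A", "T", 0.5, 0.1, 0.01, 10, 0.3],  # ambiguous
                ["v1", "1", 2000, "A", "G", 0.2, 0.1, 0.01, 10, 0.3],
                ["vX", "1", 9000, "A", "G", 0.9, 0.1, 0.01, 10, 0.3],  # absent
            ]
        )
    )
    vec = score(panel, sel)
    assert vec.match_report == {
        "used": 1, "flipped": 0, "ambiguous_dropped": 1, "absent_dropped": 1,
        "mismatch_dropped": 0,
    }
    assert np.allclose(vec.scores, [0.2, 0.0])


def test_score_zero_usable_snps_errors():
    panel = _score_panel(np.array([[1.0]]))
    sel = SNPSelection(_stats([["vX", "1", 1000, "A", "G", 0.5, 0.1, 0.01, 10, 0.3]]))
    with pytest.raises(ValueError, match="usable"):
        score(panel, sel)


def test_score_missing_dosage_mean_imputed():
    dosage = np.array([[2.0], [0.0], [np.nan]])
    panel = _score_panel(dosage)
    sel = SNPSelection(_stats([["v0", "1", 1000, "A", "G", 1.0, 0.1, 0.01, 10, 0.3]]))
    vec = score(panel, sel)
    # effect-allele frequency among observed = 0.5 -> imputed dosage 1.0
    assert np.allclose(vec.scores, [2.0, 0.0, 1.0])


def test_score_linear_in_beta(rng):
    panel = _score_panel(rng.binomial(2, 0.4, size=(30, 8)).astype(float))
    rows = [[f"v{j}", "1", (j + 1) * 1000, "A", "G", rng.normal(), 0.1, 0.01, 10, 0.3]
            for j in range(8)]
    sel1 = SNPSelection(_stats(rows))
    doubled = [[r[0], r[1], r[2], r[3], r[4], 2 * r[5], *r[6:]] for r in rows]
    sel2 = SNPSelection(_stats(doubled))
    assert np.allclose(2 * score(panel, sel1).scores, score(panel, sel2).scores)
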