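"""Hit calling: normalisation, filtering, classification, overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import poolscreen as ps
from poolscreen.counts import CountMatrix


def _matrix(library, columns: dict, conditions: dict) -> CountMatrix:
    counts = pd.DataFrame(columns, index=list(library.hairpin_ids))
    meta = pd.DataFrame(
        {
            "condition": [conditions[c] for c in counts.columns],
            "replicate": list(range(1, len(counts.columns) + 1)),
        },
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountMatrix(counts=counts, samples=meta, library=library)


@pytest.fixture(scope="module")
def planted_screen():
    """Triplicate screen with 20 hairpins planted at 8x depletion, 2 lost."""
    lib = ps.generate_library(n_genes=300, hairpins_per_gene=2, seed=11)
    prof = ps.generate_abundance(lib, dispersion=0.5, seed=12)
    planted = list(lib.hairpin_ids)[:20]
    lost = frozenset(list(lib.hairpin_ids)[20:22])
    eff = ps.EffectSpec(condition="dox", multipliers={h: 1 / 8 for h in planted}, lost=lost)
    matrix = ps.generate_screen_counts(
        lib, prof, [eff], depth=300_000, n_replicates=3, replicate_cv=0.1, seed=13
    )
    return lib, matrix, set(planted), lost


class TestNormalizeCounts:
    def test_small_example(self, small_library):
        lib = ps.generate_library(n_genes=3, hairpins_per_gene=1, seed=0)
        m = _matrix(lib, {"s": [1, 1, 2]}, {"s": "c"})
        norm = ps.normalize_counts(m)
        assert norm["s"].tolist() == [250000.0, 250000.0, 500000.0]

    def test_columns_sum_to_million_and_scale_invariance(self, planted_screen):
        _, matrix, _, _ = planted_screen
        norm = ps.normalize_counts(matrix)
        assert np.allclose(norm.sum(axis=0), 1e6)
        scaled = CountMatrix(
            counts=matrix.counts * 10, samples=matrix.samples, library=matrix.library
        )
        pd.testing.assert_frame_equal(ps.normalize_counts(scaled), norm)

    def test_zero_total_sample_named(self):
        lib = ps.generate_library(n_genes=3, hairpins_per_gene=1, seed=0)
        m = _matrix(lib, {"good": [1, 1, 2], "empty": [0, 0, 0]},
                    {"good": "c", "empty": "c"})
        with pytest.raises(ValueError, match="empty"):
            ps.normalize_counts(m)


class TestFilterLowAbundance:
    def test_threshold_behaviour(self):
        lib = ps.generate_library(n_genes=3, hairpins_per_gene=1, seed=0)
        m = _matrix(
            lib,
            {"c1": [150, 0, 100], "c2": [150, 0, 100], "c3": [150, 0, 101]},
            {"c1": "u", "c2": "u", "c3": "u"},
        )
        kept = ps.filter_low_abundance(m, ["c1", "c2", "c3"], min_raw=100)
        assert kept.tolist() == [True, False, True]  # mean 100.33 is > 100
        kept = ps.filter_low_abundance(m, ["c1"], min_raw=100)
        assert kept.tolist() == [True, False, False]  # 100 is not > 100 (strict)

    def test_min_raw_zero_keeps_any_signal(self):
        lib = ps.generate_library(n_genes=2, hairpins_per_gene=1, seed=0)
        m = _matrix(lib, {"c": [1, 0]}, {"c": "u"})
        kept = ps.filter_low_abundance(m, ["c"], min_raw=0)
        assert kept.tolist() == [True, False]


class TestCallHits:
    def test_identical_arms_no_hits(self, planted_screen):
        lib, matrix, _, _ = planted_screen
        dup = CountMatrix(
            counts=pd.concat(
                [
                    matrix.counts[matrix.samples_for("untreated")],
                    matrix.counts[matrix.samples_for("untreated")].set_axis(
                        ["t_1", "t_2", "t_3"], axis=1
                    ),
                ],
                axis=1,
            ),
            samples=pd.DataFrame(
                {"condition": ["untreated"] * 3 + ["t"] * 3, "replicate": [1, 2, 3] * 2},
                index=pd.Index(
                    matrix.samples_for("untreated") + ["t_1", "t_2", "t_3"],
                    name="sample_id",
                ),
            ),
            library=lib,
        )
        table = ps.call_hits(dup, treated="t", control="untreated")
        counts = table.class_counts()
        assert counts["depleted"] == 0 and counts["enriched"] == 0 and counts["lost"] == 0

    def test_planted_depletion_recovered(self, planted_screen):
        lib, matrix, planted, lost = planted_screen
        table = ps.call_hits(matrix, treated="dox", control="untreated")
        kept_planted = {
            h for h in planted if table.records.loc[h, "hit_class"] != "filtered"
        }
        called = table.hairpins("depleted")
        assert kept_planted <= called
        assert table.hairpins("lost") == {
            h for h in lost if table.records.loc[h, "hit_class"] == "lost"
        }
        # lost hairpins that passed the filter must be classed lost, not depleted
        for h in lost:
            assert table.records.loc[h, "hit_class"] in ("lost", "filtered")

    def test_false_positive_rate_near_alpha(self):
        """Planted-null hairpins reach p < alpha at about the nominal rate."""
        lib = ps.generate_library(n_genes=400, hairpins_per_gene=2, seed=20)
        prof = ps.generate_abundance(lib, dispersion=0.3, seed=21)
        pvals = []
        for seed in range(50):
            m = ps.generate_screen_counts(
                lib, prof, [ps.EffectSpec(condition="d")],
                depth=250_000, replicate_cv=0.2, seed=seed,
            )
            t = ps.call_hits(m, treated="d", control="untreated")
            kept = t.records["hit_class"] != "filtered"
            pvals.append(t.records.loc[kept, "p_value"].to_numpy())
        frac = float(np.mean(np.concatenate(pvals) < 0.01))
        assert 0.005 <= frac <= 0.015

    def test_subthreshold_fold_change_stays_unchanged(self):
        """log2 ratio of -0.8 with tiny p is still not a hit (two-fold rule)."""
        lib = ps.generate_library(n_genes=2, hairpins_per_gene=1, seed=0)
        ctrl = 10000
        trt = int(round(ctrl * 2 ** -0.8))
        m = _matrix(
            lib,
            {
                "c1": [ctrl, ctrl], "c2": [ctrl + 1, ctrl], "c3": [ctrl - 1, ctrl],
                "t1": [trt, ctrl], "t2": [trt + 1, ctrl], "t3": [trt - 1, ctrl],
            },
            dict.fromkeys(["c1", "c2", "c3"], "u") | dict.fromkeys(["t1", "t2", "t3"], "d"),
        )
        table = ps.call_hits(m, treated="d", control="u")
        row = table.records.iloc[0]
        assert row["p_value"] < 0.001
        assert -1 < row["log2_ratio"] < 0
        assert row["hit_class"] == "unchanged"

    def test_t_statistic_matches_closed_form(self, planted_screen):
        """p-values agree with a direct pooled-variance computation to 1e-10."""
        lib, matrix, _, _ = planted_screen
        table = ps.call_hits(matrix, treated="dox", control="untreated")
        cpm = ps.normalize_counts(matrix)
        logt = np.log2(cpm[matrix.samples_for("dox")] + 0.5)
        logc = np.log2(cpm[matrix.samples_for("untreated")] + 0.5)
        for h in list(lib.hairpin_ids)[:40]:
            x, y = logt.loc[h].to_numpy(), logc.loc[h].to_numpy()
            sp = np.sqrt(((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
                         / (len(x) + len(y) - 2))
            if sp == 0:
                continue
            t = (x.mean() - y.mean()) / (sp * np.sqrt(1 / len(x) + 1 / len(y)))
            p = 2 * stats.t.sf(abs(t), len(x) + len(y) - 2)
            assert table.records.loc[h, "p_value"] == pytest.approx(p, abs=1e-10)

    def test_classification_is_a_partition(self, planted_screen):
        lib, matrix, _, _ = planted_screen
        table = ps.call_hits(matrix, treated="dox", control="untreated")
        assert len(table.records) == len(lib)
        assert table.class_counts().sum() == len(lib)
        assert set(table.records["hit_class"]).issubset(
            {"depleted", "enriched", "lost", "unchanged", "filtered"}
        )

    def test_power_monotone_in_effect_size(self):
        lib = ps.generate_library(n_genes=200, hairpins_per_gene=2, seed=30)
        prof = ps.generate_abundance(lib, dispersion=0.0)
        planted = list(lib.hairpin_ids)[:40]
        recall = {}
        for effect in (2, 4, 8):
            hits = 0
            for seed in range(5):
                eff = ps.EffectSpec(condition="d", multipliers={h: 1 / effect for h in planted})
                m = ps.generate_screen_counts(
                    lib, prof, [eff], depth=200_000, replicate_cv=0.25, seed=100 * effect + seed
                )
                t = ps.call_hits(m, treated="d", control="untreated")
                hits += len(t.hairpins("depleted") & set(planted))
            recall[effect] = hits
        assert recall[2] <= recall[4] <= recall[8]

    def test_degenerate_replicates_rejected(self, planted_screen):
        lib, matrix, _, _ = planted_screen
        with pytest.raises(ValueError, match="replicates"):
            ps.call_hits(matrix, treated=["dox_1"], control="untreated")


@pytest.fixture(scope="module")
def three_contrasts():
    lib = ps.generate_library(n_genes=300, hairpins_per_gene=2, seed=40)
    prof = ps.generate_abundance(lib, dispersion=0.3, seed=41)
    genes = sorted(set(lib.gene_symbols))
    shared = genes[:4]
    extras = {d: genes[4 + 6 * i : 10 + 6 * i] for i, d in enumerate("ABC")}
    tables = []
    for i, drug in enumerate("ABC"):
        target = {
            h: 1 / 8
            for g in shared + extras[drug]
            for h in lib.hairpins_of_gene(g)
        }
        eff = ps.EffectSpec(condition=drug, multipliers=target)
        m = ps.generate_screen_counts(
            lib, prof, [eff], depth=400_000, replicate_cv=0.1, seed=50 + i
        )
        tables.append(ps.call_hits(m, treated=drug, control="untreated"))
    return lib, tables, set(shared), extras


class TestIntersectHits:
    def test_idempotent_self_intersection(self, three_contrasts):
        _, tables, _, _ = three_contrasts
        ov = ps.intersect_hits([tables[0], tables[0]], "depleted")
        assert ov.hairpins == tables[0].hairpins("depleted")

    def test_shared_genes_recovered(self, three_contrasts):
        lib, tables, shared, _ = three_contrasts
        ov = ps.intersect_hits(tables, "depleted")
        assert ov.genes == shared
        assert ov.hairpins <= tables[0].hairpins("depleted")

    def test_disjoint_effects_empty_intersection(self):
        lib = ps.generate_library(n_genes=100, hairpins_per_gene=2, seed=60)
        prof = ps.generate_abundance(lib, dispersion=0.0)
        hp = list(lib.hairpin_ids)
        tables = []
        for drug, picks in (("A", hp[:10]), ("B", hp[10:20])):
            eff = ps.EffectSpec(condition=drug, multipliers={h: 1 / 10 for h in picks})
            m = ps.generate_screen_counts(
                lib, prof, [eff], depth=200_000, replicate_cv=0.1, seed=61
            )
            tables.append(ps.call_hits(m, treated=drug, control="untreated"))
        ov = ps.intersect_hits(tables, "depleted")
        assert ov.hairpins == set()

    def test_mismatched_libraries_rejected(self, three_contrasts):
        _, tables, _, _ = three_contrasts
        other_lib = ps.generate_library(n_genes=300, hairpins_per_gene=2, seed=99)
        prof = ps.generate_abundance(other_lib, dispersion=0.0)
        m = ps.generate_screen_counts(
            other_lib, prof, [ps.EffectSpec(condition="X")], depth=200_000, seed=1
        )
        t = ps.call_hits(m, treated="X", control="untreated")
        with pytest.raises(ValueError, match="librar"):
            ps.intersect_hits([tables[0], t], "depleted")
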