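import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uvomics.essentiality import (
    ScreenMatrix,
    center_by_controls,
    collapse_to_gene,
    gene_consistency_test,
    normalize_shrna,
    run_essentiality_pipeline,
    skin_specificity_test,
)


class TestNormalize:
    def test_unit_cpm_gives_one(self):
        raw = pd.DataFrame({"r1": [1.0, 999_999.0]}, index=["a", "b"])
        ds = normalize_shrna(raw)
        assert ds.loc["a", "r1"] == pytest.approx(math.log2(1.0) + 1)

    def test_cpm_1024_gives_eleven(self):
        raw = pd.DataFrame({"r1": [1024.0, 998_976.0]}, index=["a", "b"])
        assert normalize_shrna(raw).loc["a", "r1"] == pytest.approx(11.0)

    def test_library_scale_invariance(self):
        raw = pd.DataFrame({"r1": [10.0, 30.0, 60.0]}, index=list("abc"))
        assert np.allclose(normalize_shrna(raw), normalize_shrna(raw * 2))

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            normalize_shrna(pd.DataFrame({"r1": [0.0, 0.0]}, index=["a", "b"]))


class TestCenter:
    def _flags(self, controls, others):
        return {**{c: True for c in controls}, **{o: False for o in others}}

    def test_zero_median_controls_leave_matrix_unchanged(self):
        ds = pd.DataFrame(
            {"s1": [-1.0, 0.0, 1.0, 5.0]}, index=["c1", "c2", "c3", "x"]
        )
        out = center_by_controls(ds, self._flags(["c1", "c2", "c3"], ["x"]))
        assert out.equals(ds)

    def test_constant_controls_shift_everything(self):
        ds = pd.DataFrame({"s1": [2.0, 2.0, 7.0]}, index=["c1", "c2", "x"])
        out = center_by_controls(ds, self._flags(["c1", "c2"], ["x"]))
        assert out.loc["x", "s1"] == 5.0

    def test_centered_control_median_zero_and_idempotent(self):
        rng = np.random.default_rng(0)
        ds = pd.DataFrame(
            rng.normal(size=(10, 4)),
            index=[f"c{i}" for i in range(3)] + [f"s{i}" for i in range(7)],
            columns=[f"L{i}" for i in range(4)],
        )
        flags = self._flags([f"c{i}" for i in range(3)], [f"s{i}" for i in range(7)])
        once = center_by_controls(ds, flags)
        controls = [s for s, f in flags.items() if f]
        assert np.allclose(once.loc[controls].median(axis=0), 0.0)
        twice = center_by_controls(once, flags)
        assert np.allclose(once, twice)

    def test_no_controls_errors(self):
        ds = pd.DataFrame({"s1": [1.0]}, index=["x"])
        with pytest.raises(ValueError):
            center_by_controls(ds, {"x": False})


class TestConsistency:
    def test_identical_shrnas_pass_against_dispersed_null(self):
        rng = np.random.default_rng(1)
        rows = {"g1_a": np.zeros(6), "g1_b": np.zeros(6), "g1_c": np.zeros(6)}
        for i in range(40):
            rows[f"x{i}"] = rng.normal(0, 3, size=6)
        ds = pd.DataFrame.from_dict(rows, orient="index")
        mapping = {"g1_a": "G1", "g1_b": "G1", "g1_c": "G1"}
        mapping.update({f"x{i}": f"X{i // 2}" for i in range(40)})
        out = gene_consistency_test(ds, mapping, seed=0)
        assert out.set_index("gene_id").loc["G1", "consistency_p"] < 0.1

    def test_single_shrna_gene_untestable(self):
        ds = pd.DataFrame({"s": [0.0, 1.0, 2.0]}, index=["a", "b", "c"])
        out = gene_consistency_test(ds, {"a": "G1", "b": "G2", "c": "G2"}, seed=0)
        row = out.set_index("gene_id").loc["G1"]
        assert row.untestable and not row.passes

    def test_two_shrnas_still_defined(self):
        rng = np.random.default_rng(2)
        rows = {"a": [0.0, 0.0], "b": [0.01, -0.01]}
        for i in range(20):
            rows[f"x{i}"] = rng.normal(0, 2, size=2)
        ds = pd.DataFrame.from_dict(rows, orient="index")
        mapping = {"a": "G", "b": "G", **{f"x{i}": f"X{i}" for i in range(20)}}
        out = gene_consistency_test(ds, mapping, seed=0)
        assert np.isfinite(out.set_index("gene_id").loc["G", "consistency_p"])


class TestCollapse:
    def test_median_per_line(self):
        ds = pd.DataFrame({"L1": [-2.0, -4.0, -3.0]}, index=["a", "b", "c"])
        out = collapse_to_gene(ds, {s: "G" for s in "abc"}, ["G"])
        assert out.loc["G", "L1"] == -3.0

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        ds = pd.DataFrame(rng.normal(size=(6, 3)), index=list("abcdef"),
                          columns=["L1", "L2", "L3"])
        mapping = {s: ("G1" if s in "abc" else "G2") for s in "abcdef"}
        a = collapse_to_gene(ds, mapping, ["G1", "G2"])
        b = collapse_to_gene(ds.iloc[::-1], mapping, ["G2", "G1"])
        assert np.allclose(a.sort_index(), b.sort_index())


class TestSpecificity:
    def test_extreme_separation_exact_p(self):
        gene_ds = pd.DataFrame(
            [[-5, -4, -6, -5, 0, 0.2, -0.1, 0.1, 0, 0.1]],
            index=["G"],
            columns=[f"S{i}" for i in range(4)] + [f"N{i}" for i in range(6)],
        )
        lineage = {f"S{i}": "skin" for i in range(4)}
        lineage.update({f"N{i}": "non-skin" for i in range(6)})
        out = skin_specificity_test(gene_ds, lineage)
        assert out.specificity_p[0] == pytest.approx(1 / math.comb(10, 4), rel=1e-9)
        assert bool(out.skin_specific[0])

    def test_one_sided_never_flags_higher_skin_ds(self):
        gene_ds = pd.DataFrame(
            [[5, 4, 6, 5, 0, 0, 0, 0, 0, 0]],
            index=["G"],
            columns=[f"S{i}" for i in range(4)] + [f"N{i}" for i in range(6)],
        )
        lineage = {f"S{i}": "skin" for i in range(4)}
        lineage.update({f"N{i}": "non-skin" for i in range(6)})
        out = skin_specificity_test(gene_ds, lineage)
        assert not bool(out.skin_specific[0])

    def test_degenerate_lineage_errors(self):
        gene_ds = pd.DataFrame([[0.0, 1.0]], index=["G"], columns=["A", "B"])
        with pytest.raises(ValueError):
            skin_specificity_test(gene_ds, {"A": "skin", "B": "non-skin"})

    def test_ranksum_matches_exact_enumeration(self):
        # oracle: exact one-sided p by enumerating all label assignments
        rng = np.random.default_rng(7)
        for _ in range(20):
            nx, ny = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            p = stats.mannwhitneyu(x, y, alternative="less", method="exact").pvalue
            pooled = np.concatenate([x, y])

            def u_stat(xs, ys):
                # scipy's U: pairs where x exceeds y (ties count half)
                return sum(1 for xi in xs for yj in ys if xi > yj) + 0.5 * sum(
                    1 for xi in xs for yj in ys if xi == yj
                )

            u_obs = u_stat(x, y)
            count = total = 0
            for idx in itertools.combinations(range(nx + ny), nx):
                xs = pooled[list(idx)]
                ys = np.delete(pooled, list(idx))
                count += u_stat(xs, ys) <= u_obs
                total += 1
            assert p == pytest.approx(count / total, rel=1e-9)


class TestPipeline:
    def _small_screen(self, seed=0, shift=-3.0):
        from uvomics.simulate import SimulationConfig, generate_screen

        cfg = SimulationConfig(
            seed=seed, n_screen_genes=60, n_planted_essential=4,
            essential_ds_shift=shift,
        )
        return generate_screen(cfg)

    def test_planted_genes_recovered(self):
        screen, truth = self._small_screen(seed=5)
        res = run_essentiality_pipeline(screen, seed=5)
        called = set(res.loc[res.skin_specific, "gene_id"])
        assert set(truth.essential_genes) <= called
        assert len(called - set(truth.essential_genes)) <= 0.08 * (len(res) - 4) + 2

    def test_ordering_invariance(self):
        screen, _ = self._small_screen(seed=6)
        res_a = run_essentiality_pipeline(screen, seed=1)
        shuffled = ScreenMatrix(
            screen.ds.iloc[::-1, ::-1],
            screen.shrna_to_gene,
            screen.is_negative_control,
            screen.lineage,
        )
        res_b = run_essentiality_pipeline(shuffled, seed=1)
        a = res_a.set_index("gene_id").sort_index()
        b = res_b.set_index("gene_id").sort_index()
        assert np.allclose(a.consistency_p, b.consistency_p)
        assert (a.skin_specific == b.skin_specific).all()

    def test_no_skin_lines_errors(self):
        from uvomics.simulate import SimulationConfig, generate_screen

        cfg = SimulationConfig(seed=1, n_screen_genes=20, n_skin_lines=0,
                               n_planted_essential=0)
        screen, _ = generate_screen(cfg)
        with pytest.raises(ValueError):
            run_essentiality_pipeline(screen, seed=1)

    def test_raw_count_input_path(self):
        rng = np.random.default_rng(4)
        idx = ["ctrl_1", "ctrl_2"] + [f"sh_{g}_{k}" for g in ("G1", "G2") for k in (1, 2)]
        raw = pd.DataFrame(
            rng.integers(100, 10_000, size=(6, 4)).astype(float),
            index=idx, columns=["S1", "S2", "N1", "N2"],
        )
        screen = ScreenMatrix(
            raw,
            {f"sh_{g}_{k}": g for g in ("G1", "G2") for k in (1, 2)},
            {s: s.startswith("ctrl") for s in idx},
            {"S1": "skin", "S2": "skin", "N1": "non-skin", "N2": "non-skin"},
        )
        res = run_essentiality_pipeline(screen, raw_counts=True, seed=0)
        assert set(res.gene_id) == {"G1", "G2"}
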