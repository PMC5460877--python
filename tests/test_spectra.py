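"""Category spectra, skewness equilibrium test and MK-style statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gcforces.alignments import CHANGE_COLUMNS
from gcforces.spectra import (
    CategorySfsSet,
    ContingencyTable,
    binned_mk,
    build_sfs,
    crossed_mk,
    dos,
    gc_allele_frequencies,
    mk_chi2,
    mk_table,
    ni,
    read_sfs_table,
    skewness,
    skewness_test,
    split_first_part,
    table_from_sfs,
    write_sfs_table,
)


def change_row(contig="c0", position=10, kind="SNP", anc="A", der="G", i=2, n=10,
               gc="WS", pref="NA", syn=True, first=True):
    return dict(zip(CHANGE_COLUMNS, [contig, position, kind, anc, der, i, n, gc, pref, syn, first]))


def changes_frame(rows):
    return pd.DataFrame(rows, columns=CHANGE_COLUMNS)


class TestBuildSfs:
    def test_empty_table_all_zero(self):
        data = build_sfs(changes_frame([]), "gBGC")
        assert data.total_snps() == 0
        assert all(v == 0 for v in data.div.values())

    def test_direct_tally(self):
        rows = [change_row(i=1, gc="WS") for _ in range(3)]
        rows.append(change_row(kind="substitution", anc="G", der="A", i=10, gc="SW"))
        data = build_sfs(changes_frame(rows), "gBGC")
        assert data.sfs["WS"][0] == 3
        assert data.div["SW"] == 1

    def test_joint_conserves_synonymous_changes(self):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(200):
            gc = rng.choice(["WS", "SW", "GC_CONS"])
            pref = rng.choice(["UP", "PU", "PREF_NEUTRAL"])
            anc, der = ("A", "G") if gc == "WS" else (("G", "A") if gc == "SW" else ("A", "T"))
            rows.append(change_row(anc=anc, der=der, gc=gc, pref=pref, i=int(rng.integers(1, 10))))
        df = changes_frame(rows)
        data = build_sfs(df, "joint")
        assert data.total_snps() == len(df)

    def test_joint_margins_match_gbgc_set(self):
        rng = np.random.default_rng(1)
        rows = []
        for _ in range(150):
            gc = rng.choice(["WS", "SW"])
            pref = rng.choice(["UP", "PU", "PREF_NEUTRAL"])
            anc, der = ("A", "G") if gc == "WS" else ("G", "A")
            kind = rng.choice(["SNP", "substitution"], p=[0.8, 0.2])
            i = int(rng.integers(1, 10)) if kind == "SNP" else 10
            rows.append(change_row(anc=anc, der=der, gc=gc, pref=pref, i=i, kind=kind))
        df = changes_frame(rows)
        joint = build_sfs(df, "joint")
        gbgc = build_sfs(df, "gBGC")
        for gc in ("WS", "SW"):
            margin = sum(joint.sfs[f"{gc}:{p}"] for p in ("UP", "PU", "PREF_NEUTRAL"))
            assert np.array_equal(margin, gbgc.sfs[gc])

    def test_mixed_sample_sizes_error(self):
        rows = [change_row(n=10), change_row(n=12)]
        with pytest.raises(ValueError, match="mixed"):
            build_sfs(changes_frame(rows), "gBGC")


class TestGcAlleleFrequencies:
    def test_polarization_free(self):
        # WS SNP derived G at i=2/n=10 -> S freq 0.2; SW derived A at i=2 -> 0.8
        rows = [change_row(gc="WS", anc="A", der="G", i=2),
                change_row(gc="SW", anc="G", der="A", i=2)]
        f = gc_allele_frequencies(changes_frame(rows))
        assert f == pytest.approx([0.2, 0.8])

    def test_label_swap_invariance(self):
        rows = [change_row(gc="WS", anc="A", der="G", i=3)]
        swapped = [change_row(gc="SW", anc="G", der="A", i=7)]
        f1 = gc_allele_frequencies(changes_frame(rows))
        f2 = gc_allele_frequencies(changes_frame(swapped))
        assert f1 == pytest.approx(f2)

    def test_balanced_set_centres_on_half(self):
        rng = np.random.default_rng(2)
        rows = []
        for _ in range(4000):
            i = int(rng.integers(1, 10))
            if rng.random() < 0.5:
                rows.append(change_row(gc="WS", anc="A", der="G", i=i))
            else:
                rows.append(change_row(gc="SW", anc="G", der="A", i=i))
        f = gc_allele_frequencies(changes_frame(rows))
        assert abs(f.mean() - 0.5) < 0.01


class TestSkewness:
    def test_symmetric_sample_zero(self):
        assert skewness([0.2, 0.5, 0.8]) == pytest.approx(0.0, abs=1e-12)

    def test_known_value(self):
        assert skewness([0.1, 0.1, 0.8]) == pytest.approx(0.7071, abs=1e-3)

    @given(st.lists(st.floats(0.01, 0.99), min_size=4, max_size=30))
    def test_mirror_antisymmetry(self, xs):
        xs = np.asarray(xs)
        if np.var(xs) < 1e-12:
            return
        assert skewness(1 - xs) == pytest.approx(-skewness(xs), abs=1e-9)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            skewness([0.5, 0.5])
        with pytest.raises(ValueError):
            skewness([0.5] * 20)


class TestSkewnessTest:
    def test_strong_skew_detected(self):
        rng = np.random.default_rng(3)
        x = rng.beta(5, 1.5, 10_000)  # strongly left-skewed
        assert skewness(x) < -0.3
        assert skewness_test(x, n_boot=2000, seed=0) < 0.001

    def test_symmetric_not_rejected(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 5000)
        assert skewness_test(x, n_boot=2000, seed=0) > 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x = rng.beta(2, 3, 500)
        assert skewness_test(x, seed=11, n_boot=500) == skewness_test(x, seed=11, n_boot=500)

    def test_calibration_near_nominal(self):
        """Uniform-null rejection rate at alpha=0.05 stays near 5%."""
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 120
        for k in range(n_rep):
            x = rng.normal(0.5, 0.1, 300)
            if skewness_test(x, n_boot=400, seed=k) < 0.05:
                rejections += 1
        assert rejections / n_rep < 0.11


TABLE = ContingencyTable(p_ws=100, p_sw=120, d_ws=80, d_sw=60)


class TestMkStatistics:
    def test_chi2_example(self):
        assert mk_chi2(TABLE) == pytest.approx(0.0306, abs=2e-3)

    def test_proportional_rows_p_one(self):
        t = ContingencyTable(50, 100, 20, 40)
        assert mk_chi2(t) == pytest.approx(1.0)

    def test_row_swap_symmetric(self):
        swapped = ContingencyTable(80, 60, 100, 120)
        assert mk_chi2(swapped) == pytest.approx(mk_chi2(TABLE))

    def test_zero_margin_undefined(self):
        with pytest.raises(ValueError):
            mk_chi2(ContingencyTable(0, 0, 10, 10))

    def test_ni_dos_examples(self):
        assert ni(TABLE) == pytest.approx(0.625)
        assert dos(TABLE) == pytest.approx(80 / 140 - 100 / 220)

    def test_balanced_table(self):
        t = ContingencyTable(50, 50, 30, 30)
        assert ni(t) == pytest.approx(1.0)
        assert dos(t) == pytest.approx(0.0)

    @given(st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500))
    def test_dos_positive_iff_ni_below_one(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        if dos(t) > 0:
            assert ni(t) < 1
        elif dos(t) < 0:
            assert ni(t) > 1

    def test_undefined_denominators_nan(self):
        assert np.isnan(ni(ContingencyTable(10, 0, 5, 5)))
        assert np.isnan(dos(ContingencyTable(0, 0, 5, 5)))

    def test_mk_table_tally_and_empty(self):
        rows = (
            [change_row(gc="WS") for _ in range(5)]
            + [change_row(gc="SW", anc="G", der="A") for _ in range(3)]
            + [change_row(gc="WS", kind="substitution", i=10)]
        )
        t = mk_table(changes_frame(rows), "gBGC")
        assert (t.p_ws, t.p_sw, t.d_ws, t.d_sw) == (5, 3, 1, 0)
        t0 = mk_table(changes_frame([]), "gBGC")
        assert (t0.p_ws, t0.p_sw, t0.d_ws, t0.d_sw) == (0, 0, 0, 0)


class TestPolarizationErrorRobustness:
    """Symmetric polarization error never flips DoS and always attenuates it
    on expected counts (the modified MK test is conservative to mislabeled
    ancestral states below 50%)."""

    @pytest.mark.parametrize("B", [0.2, 0.5, 1.0])
    def test_sign_preserved_and_magnitude_attenuated(self, B):
        from gcforces.sfsmodel import SpectrumParams, expected_counts

        lam = 1.7

        def expected_table(e):
            p = SpectrumParams(
                n=20, set_name="gBGC", lam=lam,
                theta={"WS": 100.0, "NEUTRAL": 100.0}, b0=B, b1=B, e=e,
            )
            mu_sfs, mu_div = expected_counts(p)
            return ContingencyTable(
                p_ws=mu_sfs["WS"].sum(), p_sw=mu_sfs["SW"].sum(),
                d_ws=mu_div["WS"], d_sw=mu_div["SW"],
            )

        base = expected_table(0.0)
        assert ni(base) < 1 and dos(base) > 0
        for e in (0.1, 0.2, 0.3, 0.4, 0.45):
            t = expected_table(e)
            assert dos(t) > 0, f"sign flip at e={e}"
            assert ni(t) < 1
            assert abs(dos(t)) <= abs(dos(base)) + 1e-12


class TestStratifications:
    def _changes_with_metric(self, trend, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        metric = {}
        for g in range(40):
            contig = f"c{g:02d}"
            metric[contig] = g / 40
            # fixation bias toward S grows with the metric when trend is set
            p_ws_sub = 0.5 + (0.35 * (g / 40 - 0.5) if trend else 0.0)
            for _ in range(30):
                if rng.random() < 0.5:
                    rows.append(change_row(contig=contig, gc="WS", anc="A", der="G",
                                           i=int(rng.integers(1, 10))))
                else:
                    rows.append(change_row(contig=contig, gc="SW", anc="G", der="A",
                                           i=int(rng.integers(1, 10))))
            for _ in range(15):
                if rng.random() < p_ws_sub:
                    rows.append(change_row(contig=contig, gc="WS", anc="A", der="G",
                                           kind="substitution", i=10))
                else:
                    rows.append(change_row(contig=contig, gc="SW", anc="G", der="A",
                                           kind="substitution", i=10))
        return changes_frame(rows), pd.Series(metric)

    def test_planted_gradient_orders_dos(self):
        changes, metric = self._changes_with_metric(trend=True)
        out = binned_mk(changes, metric, k=8)
        from scipy.stats import spearmanr

        rho, p = spearmanr(out["bin"], out["dos"])
        assert rho > 0.7 and p < 0.05

    def test_homogeneous_data_no_trend(self):
        from scipy.stats import spearmanr

        hits = 0
        for rep in range(12):
            changes, metric = self._changes_with_metric(trend=False, seed=100 + rep)
            out = binned_mk(changes, metric, k=8)
            rho, p = spearmanr(out["bin"], out["dos"])
            if p < 0.05:
                hits += 1
        assert hits <= 2

    def test_crossed_design_has_four_cells(self):
        changes, metric = self._changes_with_metric(trend=False)
        expr = pd.Series(np.linspace(1, 100, len(metric)), index=metric.index)
        out = crossed_mk(changes, metric, expr)
        assert len(out) == 4
        assert set(out["gc3_group"]) == {"low", "high"}

    def test_split_first_part(self):
        rows = [change_row(position=100), change_row(position=300),
                change_row(contig="nostart", position=50)]
        df = changes_frame(rows)
        first, rest = split_first_part(df, cutoff=252)
        assert list(first["position"]) == [100, 50]
        assert list(rest["position"]) == [300]
        first, rest = split_first_part(df, cutoff=252, require_start=True,
                                       start_contigs={"c0"})
        assert list(first["position"]) == [100]


class TestSfsExchangeFormat:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        data = CategorySfsSet(
            n=10, set_name="gBGC",
            sfs={c: rng.poisson(20, 9).astype(float) for c in ("WS", "SW", "NEUTRAL")},
            div={"WS": 11, "SW": 7, "NEUTRAL": 13},
        )
        path = tmp_path / "sfs.tsv"
        write_sfs_table(data, path)
        back = read_sfs_table(path)
        assert back.n == 10 and back.set_name == "gBGC"
        for c in data.categories:
            assert np.array_equal(back.sfs[c], data.sfs[c])
            assert back.div[c] == data.div[c]

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("set_name\tcategory\tclass_i\tcount\n")
        with pytest.raises(ValueError, match="header"):
            read_sfs_table(path)

    def test_table_from_sfs_totals(self):
        data = CategorySfsSet(
            n=5, set_name="gBGC",
            sfs={"WS": np.array([5, 3, 2, 1.0]), "SW": np.array([4, 2, 1, 1.0]),
                 "NEUTRAL": np.zeros(4)},
            div={"WS": 9, "SW": 6},
        )
        t = table_from_sfs(data)
        assert (t.p_ws, t.p_sw, t.d_ws, t.d_sw) == (11, 8, 9, 6)
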