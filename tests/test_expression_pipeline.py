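"""Normalization, ratios, changed-gene calling, enrichment and summaries."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xylevo import expression_pipeline as ep
from xylevo import synthetic_data as sd


def _hypergeom_tail_enumeration(overlap, universe, group, changed):
    """Exact upper-tail P(X >= overlap) by direct summation of the
    hypergeometric pmf using integer binomials."""
    total = comb(universe, changed)
    acc = 0
    for k in range(overlap, min(group, changed) + 1):
        acc += comb(group, k) * comb(universe - group, changed - k)
    return acc / total


@pytest.fixture()
def small_counts(rng):
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(20, 4)),
        index=[f"g{i}" for i in range(20)],
        columns=["a", "b", "c", "d"],
    )
    return counts


class TestNormalization:
    def test_column_sums_hit_one_million(self, small_counts):
        norm = ep.normalize_to_million(small_counts)
        sums = norm.sum(axis=0).to_numpy()
        # independent re-summation oracle
        manual = np.array([norm[c].to_numpy().sum() for c in norm.columns])
        assert np.allclose(sums, 1e6, rtol=1e-6)
        assert np.allclose(sums, manual)

    def test_halving_and_identity(self):
        counts = pd.DataFrame({"s": [1_500_000, 500_000]}, index=["g1", "g2"])
        norm = ep.normalize_to_million(counts)
        assert norm["s"].tolist() == [750_000.0, 250_000.0]
        assert ep.normalize_to_million(norm).equals(norm)

    def test_idempotence(self, small_counts):
        once = ep.normalize_to_million(small_counts)
        assert np.allclose(ep.normalize_to_million(once), once)

    def test_all_zero_sample_named_in_error(self, small_counts):
        small_counts["dead"] = 0
        with pytest.raises(ValueError, match="dead"):
            ep.normalize_to_million(small_counts)


class TestAverageReplicates:
    def _design(self, n_rep):
        rows = []
        for sugar in ("glucose", "xylulose"):
            for r in range(1, n_rep + 1):
                rows.append({"sample_id": f"s1_wt_{sugar}_r{r}", "strain": "s1",
                             "status": "wt", "sugar": sugar, "replicate": r})
        return pd.DataFrame(rows)

    def test_mean_of_two_replicates(self):
        design = self._design(2)
        counts = pd.DataFrame(
            {sid: [v] for sid, v in zip(design.sample_id, [10, 30, 5, 15])}, index=["g1"]
        )
        avg, avg_design = ep.average_replicates(counts, design)
        assert avg.loc["g1", "s1_wt_glucose"] == 20
        assert avg.loc["g1", "s1_wt_xylulose"] == 10
        assert "replicate" not in avg_design.columns

    def test_single_replicate_passthrough(self):
        design = self._design(1)
        counts = pd.DataFrame({sid: [7.0] for sid in design.sample_id}, index=["g1"])
        avg, _ = ep.average_replicates(counts, design)
        assert (avg.loc["g1"] == 7.0).all()

    def test_three_replicates_match_direct_mean(self, rng):
        design = self._design(3)
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(5, 6)).astype(float),
            index=[f"g{i}" for i in range(5)],
            columns=list(design.sample_id),
        )
        avg, _ = ep.average_replicates(counts, design)
        glu_cols = [c for c in counts.columns if "glucose" in c]
        assert np.allclose(avg["s1_wt_glucose"], counts[glu_cols].sum(axis=1) / 3)


class TestLogRatios:
    def _setup(self, xyl_vals, glu_vals):
        design = pd.DataFrame(
            [
                {"sample_id": "s1_wt_glucose_r1", "strain": "s1", "status": "wt",
                 "sugar": "glucose", "replicate": 1},
                {"sample_id": "s1_wt_xylulose_r1", "strain": "s1", "status": "wt",
                 "sugar": "xylulose", "replicate": 1},
            ]
        )
        counts = pd.DataFrame(
            {"s1_wt_glucose_r1": glu_vals, "s1_wt_xylulose_r1": xyl_vals},
            index=[f"g{i}" for i in range(len(xyl_vals))],
        )
        avg, avg_design = ep.average_replicates(counts, design)
        return avg, avg_design

    def test_equal_conditions_give_zero(self):
        avg, design = self._setup([5.0, 10.0], [5.0, 10.0])
        r = ep.log_ratio_xyl_glu(avg, design, "s1", "wt")
        assert np.allclose(r, 0.0)

    def test_fourfold_is_two_log2_units(self):
        avg, design = self._setup([40.0, 8.0], [10.0, 2.0])
        r = ep.log_ratio_xyl_glu(avg, design, "s1", "wt", pseudocount=0.0)
        assert np.allclose(r, 2.0)

    def test_sugar_swap_negates_ratios(self):
        avg, design = self._setup([40.0, 3.0], [10.0, 9.0])
        r = ep.log_ratio_xyl_glu(avg, design, "s1", "wt", pseudocount=1.0)
        swapped = design.copy()
        swapped["sugar"] = swapped["sugar"].map({"glucose": "xylulose", "xylulose": "glucose"})
        r_swapped = ep.log_ratio_xyl_glu(avg, swapped, "s1", "wt", pseudocount=1.0)
        assert np.allclose(r.to_numpy(), -r_swapped.to_numpy())

    def test_missing_condition_errors(self):
        avg, design = self._setup([1.0], [1.0])
        with pytest.raises(ValueError):
            ep.log_ratio_xyl_glu(avg, design, "s1", "evolved")

    def test_gene_permutation_equivariance(self):
        avg, design = self._setup([40.0, 3.0, 7.0, 1.0], [10.0, 9.0, 7.0, 4.0])
        r = ep.log_ratio_xyl_glu(avg, design, "s1", "wt")
        perm = avg.sample(frac=1.0, random_state=0)
        r_perm = ep.log_ratio_xyl_glu(perm, design, "s1", "wt")
        assert r_perm.loc[r.index].equals(r) or np.allclose(r_perm.loc[r.index], r)

    def test_recovers_injected_aa_induction(self, expression_dataset, analyzed_expression):
        """Recovered aa-module mean ratios track the truth record's
        expected post-normalization values (RMS < 0.1 log2 over strains)."""
        params, _, _, truth = expression_dataset
        _, _, ratios = analyzed_expression
        aa_genes = [g for g, grp in params.group_assignment.items() if grp == sd.AA_MODULE]
        recovered = ratios["wt"].loc[aa_genes].mean(axis=0)
        expected = (
            truth.query("group == 'aa_module' and status == 'wt'")
            .set_index("strain")["expected_log2_cpm"]
        )
        dev = recovered - expected.loc[recovered.index]
        assert math.sqrt(float((dev**2).mean())) < 0.1


class TestChangedGenes:
    def test_all_zero_ratios_empty_sets(self):
        ratios = pd.DataFrame(np.zeros((5, 4)), index=[f"g{i}" for i in range(5)])
        up, down, _ = ep.identify_changed_genes(ratios)
        assert up == set() and down == set()

    def test_consistent_strong_gene_called_up(self):
        ratios = pd.DataFrame(np.zeros((3, 6)), index=["g0", "g1", "g2"])
        ratios.loc["g1"] = 2.0
        up, down, table = ep.identify_changed_genes(ratios, threshold=1.0)
        assert up == {"g1"} and down == set()
        assert table.loc["g1", "direction"] == "up"

    def test_null_ratios_rarely_called(self, rng):
        """N(0, 0.1) ratios across 12 strains: expected changed count < 1
        at the default threshold of 1 log2 unit."""
        ratios = pd.DataFrame(
            rng.normal(0, 0.1, size=(1000, 12)), index=[f"g{i}" for i in range(1000)]
        )
        up, down, _ = ep.identify_changed_genes(ratios)
        # direct count oracle
        med = ratios.median(axis=1)
        assert len(up) + len(down) == int((med.abs() >= 1.0).sum()) == 0


class TestEnrichment:
    def test_zero_overlap_boundary_p_is_one(self):
        res = ep.enrichment_test(
            {"g1", "g2"}, {"grp": {"g5", "g6"}}, {f"g{i}" for i in range(10)}
        )
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_full_overlap_matches_enumeration(self):
        universe = {f"g{i}" for i in range(20)}
        group = {f"g{i}" for i in range(5)}
        res = ep.enrichment_test(group, {"grp": group}, universe)
        assert res.loc[0, "overlap"] == 5
        assert res.loc[0, "p"] == pytest.approx(_hypergeom_tail_enumeration(5, 20, 5, 5))

    def test_changed_equals_universe_saturates(self):
        universe = {f"g{i}" for i in range(12)}
        group = {f"g{i}" for i in range(4)}
        res = ep.enrichment_test(universe, {"grp": group}, universe)
        assert res.loc[0, "overlap"] == 4
        assert res.loc[0, "p"] == pytest.approx(1.0)

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_p_matches_enumeration_random_sets(self, data):
        universe_size = data.draw(st.integers(2, 50))
        group_size = data.draw(st.integers(1, universe_size))
        changed_size = data.draw(st.integers(0, universe_size))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        universe = {f"g{i}" for i in range(universe_size)}
        group = set(rng.choice(sorted(universe), size=group_size, replace=False))
        changed = set(rng.choice(sorted(universe), size=changed_size, replace=False))
        res = ep.enrichment_test(changed, {"grp": group}, universe)
        overlap = int(res.loc[0, "overlap"])
        expected = _hypergeom_tail_enumeration(overlap, universe_size, group_size, changed_size)
        assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_bh_q_monotone_and_bounded(self, rng):
        universe = {f"g{i}" for i in range(100)}
        genes = sorted(universe)
        groups = {
            f"set{j}": set(rng.choice(genes, size=rng.integers(5, 30), replace=False))
            for j in range(8)
        }
        changed = set(rng.choice(genes, size=30, replace=False))
        res = ep.enrichment_test(changed, groups, universe).sort_values("p").reset_index(drop=True)
        assert (np.diff(res["q"]) >= -1e-12).all()
        assert res["q"].iloc[-1] >= res["p"].iloc[-1] - 1e-12
        assert (res["q"] <= 1.0 + 1e-12).all()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ep.enrichment_test(set(), {"grp": {"g"}}, set())


class TestGroupSummary:
    def _ratios(self, values):
        # genes x strains
        return pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))])

    def test_single_strain_flagged(self):
        ratios = {"wt": self._ratios([[1.0], [3.0]])}
        (summ,) = ep.group_summary(ratios, "grp", {"g0", "g1"})
        assert summ.single_strain and summ.se == 0.0 and summ.mean == pytest.approx(2.0)

    def test_two_strain_closed_form(self):
        """Strain means +1 and -1: mean 0, SE = SD/sqrt(2) = 1."""
        ratios = {"wt": self._ratios([[1.0, -1.0]])}
        (summ,) = ep.group_summary(ratios, "grp", {"g0"})
        assert summ.mean == pytest.approx(0.0)
        assert summ.se == pytest.approx(1.0)

    def test_recovers_injected_group_means(self, expression_dataset, analyzed_expression):
        """Group means land within 3 SE of the truth-record expectations
        for both the ancestral induction and the evolved residual."""
        params, _, _, truth = expression_dataset
        _, _, ratios = analyzed_expression
        aa_genes = {g for g, grp in params.group_assignment.items() if grp == sd.AA_MODULE}
        summaries = {s.status: s for s in ep.group_summary(ratios, "aa", aa_genes)}
        for status in ("wt", "evolved"):
            expected = truth.query("group == 'aa_module' and status == @status")[
                "expected_log2_cpm"
            ].mean()
            s = summaries[status]
            assert abs(s.mean - expected) < 3 * max(s.se, 0.02)

    def test_absent_group_skipped_with_warning(self):
        ratios = {"wt": self._ratios([[0.5, 0.5]])}
        with pytest.warns(UserWarning):
            assert ep.group_summary(ratios, "missing", {"nope"}) == []


class TestPerGeneProfile:
    def _avg(self, values, strains=("s1",)):
        rows = []
        cols = {}
        for strain in strains:
            for status in ("wt", "evolved"):
                sid = f"{strain}_{status}_xylulose"
                rows.append({"sample_id": sid, "strain": strain, "status": status,
                             "sugar": "xylulose"})
        mat = pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))],
                           columns=[r["sample_id"] for r in rows])
        return mat, pd.DataFrame(rows)

    def test_two_sample_closed_form(self):
        """Values 30 (wt) and 10 (evolved): normalized pair (0.75, 0.25)."""
        mat, design = self._avg([[30.0, 10.0]])
        prof = ep.per_gene_group_profile(mat, design, ["g0"])
        assert prof.loc[0, "wt_value"] == pytest.approx(0.75)
        assert prof.loc[0, "evolved_value"] == pytest.approx(0.25)

    def test_symmetric_gene_equal_pair(self):
        mat, design = self._avg([[5.0, 5.0]])
        prof = ep.per_gene_group_profile(mat, design, ["g0"])
        assert prof.loc[0, "wt_value"] == pytest.approx(prof.loc[0, "evolved_value"])

    def test_matches_two_pass_recomputation(self, rng):
        strains = ("s1", "s2", "s3")
        values = rng.uniform(1, 100, size=(6, 6))
        mat, design = self._avg(values, strains)
        prof = ep.per_gene_group_profile(mat, design, [f"g{i}" for i in range(6)])
        wt_cols = [c for c in mat.columns if "_wt_" in c]
        ev_cols = [c for c in mat.columns if "_evolved_" in c]
        for _, row in prof.iterrows():
            g = row["gene_id"]
            total = mat.loc[g].sum()
            assert row["wt_value"] == pytest.approx(mat.loc[g, wt_cols].mean() / total)
            assert row["evolved_value"] == pytest.approx(mat.loc[g, ev_cols].mean() / total)

    def test_zero_total_gene_excluded(self):
        mat, design = self._avg([[30.0, 10.0], [0.0, 0.0]])
        with pytest.warns(UserWarning):
            prof = ep.per_gene_group_profile(mat, design, ["g0", "g1"])
        assert prof["gene_id"].tolist() == ["g0"]
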