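"""Instrument selection: LD, greedy pruning, the selection cascade, F-statistics."""

import numpy as np
import pytest

from drugmr.instruments import (
    DegenerateLDError,
    EmptyInstrumentSetError,
    PanelLookupError,
    ReferencePanel,
    SelectionConfig,
    f_statistic,
    greedy_prune,
    is_weak,
    ld_r2,
    select_instruments,
)
from drugmr.sumstats import GeneRegion
from tests.conftest import make_record


def make_panel(rng, ids, rho=0.0, n=500):
    """Dosage panel with pairwise-exchangeable latent correlation rho."""
    m = len(ids)
    shared = rng.standard_normal((n, 1))
    z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n, m))
    dos = (z < 0).astype(float) + (np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n, m)) < 0)
    return ReferencePanel(variant_ids=list(ids), dosages=dos)


class TestLdR2:
    def test_identical_columns(self):
        panel = ReferencePanel(["a", "b"], np.array([[0, 0], [1, 1], [2, 2], [1, 1]], float))
        assert ld_r2(panel, "a", "b") == pytest.approx(1.0)

    def test_orthogonal_columns(self):
        panel = ReferencePanel(["a", "b"], np.array([[0, 1], [2, 1], [0, 1], [2, 1], [1, 0], [1, 2]], float))
        assert ld_r2(panel, "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_matches_pearson_oracle(self, rng):
        panel = make_panel(rng, [f"v{i}" for i in range(5)], rho=0.5)
        for a, b in [("v0", "v1"), ("v2", "v4")]:
            expected = np.corrcoef(panel.column(a), panel.column(b))[0, 1] ** 2
            assert ld_r2(panel, a, b) == pytest.approx(expected, abs=1e-12)

    def test_absent_variant(self, rng):
        panel = make_panel(rng, ["v0"])
        with pytest.raises(PanelLookupError):
            ld_r2(panel, "v0", "nope")

    def test_zero_variance(self):
        panel = ReferencePanel(["a", "b"], np.array([[1, 0], [1, 1], [1, 2]], float))
        with pytest.raises(DegenerateLDError):
            ld_r2(panel, "a", "b")


def brute_force_prune(candidates, panel, threshold):
    """Independent re-statement of the greedy rule by explicit enumeration."""
    remaining = sorted(candidates, key=lambda c: (c.pval, c.pos))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            c for c in remaining
            if ld_r2(panel, best.variant_id, c.variant_id) < threshold
        ]
    return sorted(kept, key=lambda c: (c.chrom, c.pos))


class TestGreedyPrune:
    def test_correlated_pair_keeps_most_significant(self, rng):
        # two near-duplicate columns -> r2 well above 0.3
        base = rng.integers(0, 3, 400).astype(float)
        noisy = base.copy()
        noisy[:20] = 2 - noisy[:20]
        panel = ReferencePanel(["v1", "v2"], np.column_stack([base, noisy]))
        assert ld_r2(panel, "v1", "v2") >= 0.3
        cands = [
            make_record("v1", pos=100, pval=1e-10),
            make_record("v2", pos=200, pval=1e-9),
        ]
        kept = greedy_prune(cands, panel, 0.3)
        assert [c.variant_id for c in kept] == ["v1"]

    def test_independent_variants_all_kept(self, rng):
        ids = [f"v{i}" for i in range(6)]
        panel = make_panel(rng, ids, rho=0.0)
        cands = [make_record(v, pos=100 * i, pval=10 ** -(9 + i)) for i, v in enumerate(ids)]
        assert len(greedy_prune(cands, panel, 0.3)) == 6

    @pytest.mark.parametrize("threshold", [0.1, 0.3, 0.6])
    def test_matches_brute_force_oracle(self, rng, threshold):
        ids = [f"v{i}" for i in range(10)]
        panel = make_panel(rng, ids, rho=0.6)
        cands = [
            make_record(v, pos=100 * i, pval=float(rng.uniform(1e-12, 1e-8)))
            for i, v in enumerate(ids)
        ]
        got = greedy_prune(cands, panel, threshold)
        want = brute_force_prune(cands, panel, threshold)
        assert [c.variant_id for c in got] == [c.variant_id for c in want]

    def test_retained_pairs_below_threshold(self, rng):
        ids = [f"v{i}" for i in range(8)]
        panel = make_panel(rng, ids, rho=0.7)
        cands = [make_record(v, pos=10 * i, pval=1e-9) for i, v in enumerate(ids)]
        kept = greedy_prune(cands, panel, 0.3)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert ld_r2(panel, a.variant_id, b.variant_id) < 0.3

    def test_monotone_in_threshold(self, rng):
        ids = [f"v{i}" for i in range(12)]
        panel = make_panel(rng, ids, rho=0.5)
        cands = [make_record(v, pos=10 * i, pval=1e-9) for i, v in enumerate(ids)]
        sizes = [len(greedy_prune(cands, panel, t)) for t in (0.8, 0.4, 0.2, 0.05)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_input(self, rng):
        assert greedy_prune([], make_panel(rng, ["v0"]), 0.3) == []


class TestFStatistic:
    def test_direct_formula(self):
        assert f_statistic(make_record(beta=0.1, se=0.01)) == pytest.approx(100.0)

    def test_zero_beta_flagged_weak(self):
        f = f_statistic(make_record(beta=0.0))
        assert f == 0.0 and is_weak(f)

    def test_boundary_f_equal_10_is_weak(self):
        # "exceeding 10" indicates strength, so exactly 10 is still weak
        f = f_statistic(make_record(beta=0.1, se=0.1 / np.sqrt(10)))
        assert f == pytest.approx(10.0)
        assert is_weak(10.0)
        assert not is_weak(10.0 + 1e-9)


def _region():
    return GeneRegion(gene="G", chrom="1", start=400, end=600)


class TestSelectInstruments:
    def _stats(self):
        # 5 significant variants inside the window, plus distractors
        recs = [make_record(f"v{i}", pos=400 + 50 * i, pval=1e-10) for i in range(5)]
        recs.append(make_record("weak", pos=500, pval=1e-4))          # fails p filter
        recs.append(make_record("far", pos=10_000_000, pval=1e-10))   # fails window
        recs.append(make_record("palin", pos=520, ea="A", oa="T", pval=1e-10))
        return recs

    def test_cascade_counts(self, rng):
        recs = self._stats()
        panel = make_panel(rng, [r.variant_id for r in recs], rho=0.0)
        iv = select_instruments(recs, SelectionConfig.cis(_region(), window_kb=1.0), panel)
        assert len(iv) == 5
        assert iv.stage_counts["exposure_p_filter"] == 7
        assert iv.stage_counts["window_filter"] == 6
        assert iv.stage_counts["palindromic_filter"] == 5
        assert np.all(iv.f_stats > 0)
        assert iv.mean_f == pytest.approx(np.mean(iv.f_stats))

    def test_outcome_overlap_removal(self, rng):
        recs = self._stats()
        panel = make_panel(rng, [r.variant_id for r in recs], rho=0.0)
        outcome = [make_record("v0", pos=400, pval=1e-9)]  # GW-significant for outcome too
        iv = select_instruments(
            recs, SelectionConfig.cis(_region(), window_kb=1.0), panel, outcome_sumstats=outcome
        )
        assert "v0" not in {r.variant_id for r in iv.records}
        assert iv.stage_counts["outcome_overlap_filter"] == 6

    def test_empty_set_names_stage(self, rng):
        recs = [make_record("v0", pval=0.5)]
        panel = make_panel(rng, ["v0"])
        with pytest.raises(EmptyInstrumentSetError) as err:
            select_instruments(recs, SelectionConfig.genome_wide(), panel)
        assert err.value.stage == "exposure_p_filter"

    def test_wide_window_loose_r2_equals_p_filtered_nonpalindromic(self, rng):
        recs = self._stats()
        panel = make_panel(rng, [r.variant_id for r in recs], rho=0.5)
        cfg = SelectionConfig(p_threshold=5e-8, window_kb=0, r2_threshold=1.0, region=None)
        iv = select_instruments(recs, cfg, panel)
        expected = {r.variant_id for r in recs if r.pval < 5e-8 and r.variant_id != "palin"}
        assert {r.variant_id for r in iv.records} == expected

    def test_stage_wise_oracle_on_seeded_scenario(self, rng):
        """Selection equals an independent step-by-step filter on a cis scenario."""
        from drugmr.simulate import ScenarioConfig, simulate_gwas, simulate_panel
        from drugmr.sumstats import is_palindromic

        cfg = ScenarioConfig(n_variants=60, n_blocks=3, seed=77, palindromic_fraction=0.2)
        study = simulate_gwas(cfg)
        panel = simulate_panel(cfg)
        region = study.truth.region()
        sel = SelectionConfig.cis(region)
        iv = select_instruments(study.exposure, sel, panel)

        lo, hi = region.start - 100_000, region.end + 100_000
        stage = [r for r in study.exposure if r.pval < 5e-8]
        stage = [r for r in stage if lo <= r.pos <= hi]
        stage = [r for r in stage if not is_palindromic(r)]
        stage = brute_force_prune(stage, panel, 0.3)
        assert [r.variant_id for r in iv.records] == [r.variant_id for r in stage]
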