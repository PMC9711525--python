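import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import phipkit as pk
from phipkit.counts_io import ValidationError
from phipkit.enrichment import FoldChangeMatrix, ZScoreMatrix

from conftest import random_instance
from oracles import call_hits_oracle


def _toy(n_cases=128, n_controls=186, case_z=None, ctrl_z=None,
         case_fc=None, genes=("g1",)):
    """Single-gene (or few-gene) constructed matrices for criterion checks."""
    cases = [f"case{i}" for i in range(n_cases)]
    controls = [f"ctrl{i}" for i in range(n_controls)]
    roles = {**{s: "case" for s in cases}, **{s: "control" for s in controls},
             "m": "mock_ip"}
    sheet = pk.SampleSheet.from_roles(roles)
    z = pd.DataFrame(0.0, index=list(genes), columns=cases + controls)
    fc = pd.DataFrame(1.0, index=list(genes), columns=cases + controls)
    for (g, s), v in (case_z or {}).items():
        z.at[g, s] = v
    for (g, s), v in (ctrl_z or {}).items():
        z.at[g, s] = v
    for (g, s), v in (case_fc or {}).items():
        fc.at[g, s] = v
    return ZScoreMatrix(z=z), FoldChangeMatrix(fc=fc, mock_ids=["m"]), sheet


class TestCallHits:
    def test_all_four_criteria_met_passes(self):
        # 13/128 cases (10.2%) positive, 0 controls, one case at FC 60
        case_z = {("g1", f"case{i}"): 20.0 for i in range(13)}
        case_fc = {("g1", "case0"): 60.0}
        z, fc, sheet = _toy(case_z=case_z, case_fc=case_fc)
        hits = pk.call_hits(z, fc, sheet)
        assert hits.passed_genes == ["g1"]
        row = hits.table.loc["g1"]
        assert row["n_cases_positive"] == 13
        assert row["failed_criteria"] == ""

    def test_dominant_control_fails_gene(self):
        case_z = {("g1", f"case{i}"): 20.0 for i in range(13)}
        case_fc = {("g1", "case0"): 60.0}
        ctrl_z = {("g1", "ctrl0"): 99.0}  # above every case but not "positive-many"
        z, fc, sheet = _toy(case_z=case_z, ctrl_z=ctrl_z, case_fc=case_fc)
        hits = pk.call_hits(z, fc, sheet)
        assert not hits.table.at["g1", "passed"]
        assert "dominance" in hits.table.at["g1", "failed_criteria"]

    def test_case_fraction_boundary(self):
        # 12/128 = 9.4% misses the 10% requirement
        case_z = {("g1", f"case{i}"): 20.0 for i in range(12)}
        case_fc = {("g1", "case0"): 60.0}
        z, fc, sheet = _toy(case_z=case_z, case_fc=case_fc)
        hits = pk.call_hits(z, fc, sheet)
        assert "case_frac" in hits.table.at["g1", "failed_criteria"]

    def test_strong_case_requires_positive_sample(self):
        # the FC-50 case must itself be z-positive
        case_z = {("g1", f"case{i}"): 20.0 for i in range(13)}
        case_fc = {("g1", "case127"): 60.0}  # z = 0 there
        z, fc, sheet = _toy(case_z=case_z, case_fc=case_fc)
        hits = pk.call_hits(z, fc, sheet)
        assert "strong_case" in hits.table.at["g1", "failed_criteria"]

    def test_control_limit_modes(self):
        # 4 positive controls out of 186: frac mode allows <ceil(3.72)=4 → fail;
        # absolute <5 would pass
        case_z = {("g1", f"case{i}"): 20.0 for i in range(13)}
        case_fc = {("g1", "case0"): 60.0}
        ctrl_z = {("g1", f"ctrl{i}"): 11.0 for i in range(4)}
        z, fc, sheet = _toy(case_z=case_z, ctrl_z=ctrl_z, case_fc=case_fc)
        frac = pk.call_hits(z, fc, sheet, pk.HitCriteria())
        assert "control_limit" in frac.table.at["g1", "failed_criteria"]
        absolute = pk.call_hits(z, fc, sheet, pk.HitCriteria(
            control_max_frac=None, control_max_count=5))
        assert absolute.table.at["g1", "passed"]

    def test_positivity_inequality_flag(self):
        # value exactly at threshold counts under ≥ (default) but not under >
        case_z = {("g1", f"case{i}"): 10.0 for i in range(13)}
        case_fc = {("g1", "case0"): 60.0}
        z, fc, sheet = _toy(case_z=case_z, case_fc=case_fc)
        assert pk.call_hits(z, fc, sheet).table.at["g1", "passed"]
        strict = pk.call_hits(z, fc, sheet, pk.HitCriteria(strict_inequality=True))
        assert not strict.table.at["g1", "passed"]

    def test_infinite_zscores_exceed_any_threshold(self):
        case_z = {("g1", f"case{i}"): np.inf for i in range(13)}
        case_fc = {("g1", "case0"): 60.0}
        z, fc, sheet = _toy(case_z=case_z, case_fc=case_fc)
        assert pk.call_hits(z, fc, sheet).table.at["g1", "passed"]

    def test_positive_added_control_never_rescues_a_gene(self):
        """Monotone specificity: adding a z-positive control cannot flip a
        failing gene to passing."""
        case_z = {("g1", f"case{i}"): 20.0 for i in range(13)}
        case_fc = {("g1", "case0"): 60.0}
        ctrl_z = {("g1", f"ctrl{i}"): 12.0 for i in range(4)}
        z, fc, sheet = _toy(n_controls=186, case_z=case_z, ctrl_z=ctrl_z,
                            case_fc=case_fc)
        before = pk.call_hits(z, fc, sheet)
        assert not before.table.at["g1", "passed"]
        z2 = ZScoreMatrix(z=z.z.assign(extra=15.0))
        fc2 = FoldChangeMatrix(fc=fc.fc.assign(extra=1.0), mock_ids=["m"])
        tab = sheet.table.copy()
        tab.loc["extra"] = {"role": "control", "cohort": "default"}
        after = pk.call_hits(z2, fc2, pk.SampleSheet(tab))
        assert not after.table.at["g1", "passed"]

    def test_missing_samples_is_error(self):
        z, fc, sheet = _toy(n_cases=3, n_controls=3)
        z2 = ZScoreMatrix(z=z.z.drop(columns=["case0"]))
        with pytest.raises(ValidationError):
            pk.call_hits(z2, fc, sheet)

    @pytest.mark.parametrize("metric,strict", [("zscore", False), ("fold_change", True)])
    def test_matches_triple_loop_oracle(self, metric, strict):
        cm, sheet = random_instance(13, n_genes=20, n_cases=12, n_controls=14,
                                    n_mock=4)
        fc = pk.fold_change(pk.normalize(cm), sheet)
        z = pk.zscore(fc, sheet)
        # low thresholds so all criteria are exercised on random data
        crit = pk.HitCriteria(metric=metric, positive_threshold=1.5,
                              case_min_frac=0.25, strong_fc_min=1.2,
                              strict_inequality=strict)
        hits = pk.call_hits(z, fc, sheet, crit)
        expected = call_hits_oracle(
            z.z, fc.fc, sheet.case_ids, sheet.control_ids, metric=metric,
            positive_threshold=1.5, case_min_frac=0.25, strong_fc_min=1.2,
            strict=strict)
        for col in ["n_cases_positive", "n_controls_positive", "passed",
                    "strong_case_present"]:
            assert hits.table[col].tolist() == expected[col].tolist(), col
        np.testing.assert_allclose(hits.table["max_case_signal"],
                                   expected["max_case_signal"], rtol=1e-9)


class TestDownsampling:
    def test_full_size_single_rep_equals_direct_call(self, tiny_data):
        cm, pmap, sheet, _ = tiny_data
        gene = pk.aggregate_to_gene(cm, pmap)
        fc = pk.fold_change(pk.normalize(gene), sheet)
        z = pk.zscore(fc, sheet)
        crit = pk.HitCriteria(positive_threshold=3.0, strong_fc_min=2.0)
        direct = pk.call_hits(z, fc, sheet, crit)
        curve = pk.downsample_controls(fc, sheet, crit,
                                       sizes=(len(sheet.control_ids),), reps=1, seed=0)
        assert curve.per_rep["n_hits"].iloc[0] == direct.n_passed

    def test_same_seed_reproduces_counts(self, tiny_data):
        cm, pmap, sheet, _ = tiny_data
        gene = pk.aggregate_to_gene(cm, pmap)
        fc = pk.fold_change(pk.normalize(gene), sheet)
        a = pk.downsample_controls(fc, sheet, sizes=(2, 3), reps=3, seed=5)
        b = pk.downsample_controls(fc, sheet, sizes=(2, 3), reps=3, seed=5)
        assert a.per_rep.equals(b.per_rep)

    def test_oversized_subset_rejected(self, tiny_data):
        cm, pmap, sheet, _ = tiny_data
        gene = pk.aggregate_to_gene(cm, pmap)
        fc = pk.fold_change(pk.normalize(gene), sheet)
        with pytest.raises(ValidationError):
            pk.downsample_controls(fc, sheet, sizes=(99,))

    def test_small_control_sets_inflate_apparent_hits(self, aps1_run):
        """Fewer controls → more apparent hits (the cohort-size effect)."""
        crit = pk.HitCriteria(control_max_frac=None, control_max_count=2)
        curve = pk.downsample_controls(aps1_run["fc"], aps1_run["sheet"], crit,
                                       sizes=(5, 150), reps=5, seed=7)
        means = curve.summary["mean_hits"]
        assert means.loc[5] > means.loc[150]


class TestOverlap:
    @staticmethod
    def _hits_from(sim_cfg):
        cm, pmap, sheet, truth = pk.simulate_dataset(sim_cfg)
        gene = pk.aggregate_to_gene(cm, pmap)
        fc = pk.fold_change(pk.normalize(gene), sheet)
        z = pk.zscore(fc, sheet)
        return pk.call_hits(z, fc, sheet), truth

    def test_identical_hit_tables_fully_overlap(self):
        z, fc, sheet = _toy(case_z={("g1", f"case{i}"): 20.0 for i in range(13)},
                            case_fc={("g1", "case0"): 60.0}, genes=("g1", "g2"))
        hits = pk.call_hits(z, fc, sheet)
        rep = pk.cross_cohort_overlap(hits, hits)
        assert rep.shared == hits.passed_genes
        assert rep.a_only == [] and rep.b_only == []

    def test_constructed_partial_overlap(self):
        # A passes g1 and g2; B has positive samples for g2 only
        za, fca, sheet = _toy(
            case_z={**{(g, f"case{i}"): 20.0 for i in range(13) for g in ("g1", "g2")}},
            case_fc={("g1", "case0"): 60.0, ("g2", "case0"): 60.0},
            genes=("g1", "g2"))
        hits_a = pk.call_hits(za, fca, sheet)
        assert set(hits_a.passed_genes) == {"g1", "g2"}
        zb, fcb, sheet_b = _toy(case_z={("g2", "case0"): 20.0}, genes=("g1", "g2"))
        hits_b = pk.call_hits(zb, fcb, sheet_b)
        rep = pk.cross_cohort_overlap(hits_a, hits_b)
        assert rep.shared == ["g2"]
        assert rep.a_only == ["g1"]

    def test_two_disease_fixture_shares_the_common_spike(self):
        import math as _math
        # mild background skew so a 200x spike is not compositionally saturated
        base = dict(n_genes=500, peptides_per_gene=2, n_cases=20, n_controls=30,
                    n_mock=3, depth_log_mean=_math.log(100_000), depth_log_sd=0.2,
                    background_log_sd=1.0, n_private=0, n_common=0,
                    penetrance=0.9, disease_effect=200.0, overdispersion=1e5)
        hits_a, truth_a = self._hits_from(
            pk.SimConfig(**base, disease_genes=("G00001", "G00050"), seed=21))
        hits_b, truth_b = self._hits_from(
            pk.SimConfig(**base, disease_genes=("G00002", "G00050"), seed=22))
        rep = pk.cross_cohort_overlap(hits_a, hits_b)
        assert "G00050" in rep.shared
        assert "G00001" in rep.a_only
        assert "G00002" in rep.b_only
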