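"""The semi-supervised curation pipeline on stubs and tiny worlds."""

import numpy as np
import pandas as pd
import pytest

from conftest import StubModel, el_frame, tiny_config
from mhcbind.affinity import BINDER_SCORE
from mhcbind.curation import (
    CurationConfig,
    deconvolve_multi_allele,
    filter_negatives,
    merge_datasets,
    run_curation,
)
from mhcbind.simulate import make_world, sample_ba, sample_el

PSEUDO = {"A0101": "AAAA", "A0201": "CCCC", "B0702": "DDDD", "B0801": "EEEE"}


class TestDeconvolution:
    def test_argmax_assignment(self):
        df = el_frame([("ACDEFGHIK", "A0201,B0702", 1)])
        model = StubModel(lambda p, a: {"A0201": 0.9, "B0702": 0.4}[a])
        out = deconvolve_multi_allele(df, model, PSEUDO)
        assert out["assigned_allele"].tolist() == ["A0201"]
        assert out["alleles"].tolist() == ["A0201"]

    def test_single_candidate_wins_without_scoring(self):
        df = el_frame([("ACDEFGHIK", "B0702", 1)])
        out = deconvolve_multi_allele(df, StubModel(lambda p, a: 0.0), PSEUDO)
        assert out["assigned_allele"].tolist() == ["B0702"]

    def test_exact_tie_goes_lexicographic(self):
        df = el_frame([("ACDEFGHIK", "B0801,A0101", 1)])
        out = deconvolve_multi_allele(df, StubModel(lambda p, a: 0.5), PSEUDO)
        assert out["assigned_allele"].tolist() == ["A0101"]

    def test_missing_pseudo_sequence_names_allele(self):
        df = el_frame([("ACDEFGHIK", "A0101,Z9999", 1)])
        with pytest.raises(KeyError, match="Z9999"):
            deconvolve_multi_allele(df, StubModel(lambda p, a: 0.5), PSEUDO)

    def test_negative_samples_rejected(self):
        df = el_frame([("ACDEFGHIK", "A0101", 0)])
        with pytest.raises(ValueError, match="positive"):
            deconvolve_multi_allele(df, StubModel(lambda p, a: 0.5), PSEUDO)

    def test_matches_brute_force_argmax_random_stub(self):
        rng = np.random.default_rng(0)
        names = sorted(PSEUDO)
        table = {}

        def scorer(p, a):
            key = (p, a)
            if key not in table:
                table[key] = float(np.round(rng.random(), 2))
            return table[key]

        rows = []
        for i in range(200):
            k = int(rng.integers(1, len(names) + 1))
            cands = sorted(rng.choice(names, size=k, replace=False))
            rows.append((f"PEP{i:04d}AX"[:9], ",".join(cands), 1))
        df = el_frame(rows)
        out = deconvolve_multi_allele(df, StubModel(scorer), PSEUDO)
        for (_, row), assigned in zip(df.iterrows(),
                                      out["assigned_allele"]):
            cands = sorted(row["alleles"].split(","))
            scores = [scorer(row["peptide"], a) for a in cands]
            best = max(scores)
            expect = min(a for a, s in zip(cands, scores) if s == best)
            assert assigned == expect


class TestFilterNegatives:
    def make(self, scores):
        rows = [(f"PEPTIDE{i}A"[:9], "A0101", 0) for i in range(len(scores))]
        df = el_frame(rows)
        model = StubModel(lambda p, a, s=dict(zip(df["peptide"], scores)):
                          s[p])
        return df, model

    def test_threshold_partitions(self):
        df, model = self.make([0.9, 0.1, 0.5])
        kept, removed, report = filter_negatives(df, model, BINDER_SCORE)
        assert len(removed) == 2 and len(kept) == 1
        assert report["n_negatives_removed"] == 2

    def test_infinite_threshold_removes_nothing(self):
        df, model = self.make([0.9, 0.99, 1.5])
        kept, removed, _ = filter_negatives(df, model, np.inf)
        assert len(removed) == 0 and len(kept) == 3

    def test_positives_never_removed(self):
        df = el_frame([("ACDEFGHIK", "A0101", 1), ("CDEFGHIKL", "A0101", 0)])
        kept, removed, _ = filter_negatives(df, StubModel(lambda p, a: 99.0),
                                            0.0)
        assert (kept["label"] == 1).sum() == 1
        assert (removed["label"] == 1).sum() == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        df, model = self.make(scores)
        removed_counts = []
        for thr in np.linspace(0, 1, 11):
            _, removed, _ = filter_negatives(df, model, thr)
            removed_counts.append(len(removed))
        assert all(a >= b for a, b in zip(removed_counts, removed_counts[1:]))


class TestMerge:
    def test_duplicate_collapses_with_provenance_union(self):
        ba = pd.DataFrame({"peptide": ["ACDEFGHIK"], "allele": ["A0101"],
                           "ic50_nM": [499.0]})
        els_sa = el_frame([("ACDEFGHIK", "A0101", 1)])
        out = merge_datasets(ba, els_sa, els_sa.iloc[0:0])
        assert len(out) == 1
        assert out["label"].iloc[0] == 1
        assert set(out["provenance"].iloc[0].split(",")) == {"BA", "ELS_SA"}

    def test_disjoint_inputs_concatenate(self):
        ba = pd.DataFrame({"peptide": [f"AAAAAAAA{c}" for c in "CD"],
                           "allele": ["A0101"] * 2, "ic50_nM": [10.0, 10.0]})
        sa = el_frame([(f"CCCCCCCC{c}", "A0101", 1) for c in "DEF"])
        ma = el_frame([(f"DDDDDDDD{c}", "B0702", 1) for c in "EFGH"])
        out = merge_datasets(ba, sa, ma)
        assert len(out) == 9

    def test_conflict_keeps_eluted_positive(self, caplog):
        ba = pd.DataFrame({"peptide": ["ACDEFGHIK"], "allele": ["A0101"],
                           "ic50_nM": [600.0]})  # label 0
        els_sa = el_frame([("ACDEFGHIK", "A0101", 1)])
        with caplog.at_level("WARNING"):
            out = merge_datasets(ba, els_sa, els_sa.iloc[0:0])
        assert len(out) == 1 and out["label"].iloc[0] == 1
        assert any("conflict" in r.message for r in caplog.records)

    def test_empty_everything(self):
        empty_ba = pd.DataFrame(columns=["peptide", "allele", "ic50_nM"])
        out = merge_datasets(empty_ba, el_frame([]), el_frame([]))
        assert len(out) == 0


class TestRunCuration:
    def world_setup(self):
        world = make_world(n_alleles=3, peptide_length=9, seed=3,
                           pseudo_len=10)
        ba = sample_ba(world, 300, seed=4)
        el_sa, _ = sample_el(world, 40, 40, multi_allele=False, seed=5)
        el_ma, truth = sample_el(world, 40, 0, multi_allele=True, seed=6)
        return world, ba, el_sa, el_ma, truth

    def oracle_model(self, world):
        from mhcbind.affinity import ic50_to_score
        import math

        return StubModel(lambda p, a: ic50_to_score(
            math.exp(world.true_ln_ic50(p, a))))

    def test_empty_ba_rejected(self):
        world, ba, el_sa, el_ma, _ = self.world_setup()
        cfg = CurationConfig(model_config=tiny_config(max_pep_len=9),
                             pseudo_sequences=world.alleles)
        with pytest.raises(ValueError, match="empty"):
            run_curation(ba.iloc[0:0], el_sa, el_ma, cfg)

    def test_pipeline_with_oracle_scorer(self):
        """With the generative model itself as scorer, deconvolution
        recovers every hidden allele and all contaminating decoys are
        removed."""
        world, ba, el_sa, el_ma, truth = self.world_setup()
        cfg = CurationConfig(model_config=tiny_config(max_pep_len=9),
                             pseudo_sequences=world.alleles)
        model = self.oracle_model(world)
        table, report, _ = run_curation(ba, el_sa, el_ma, cfg, model=model)
        assert report.n_ma_deconvolved == 40
        assert report.n_input == len(ba) + len(el_sa) + len(el_ma)
        # every true-binder decoy negative was filtered out
        el_pool_truth = truth  # MA set has no negatives here
        sa_truth = sample_el(world, 40, 40, multi_allele=False, seed=5)[1]
        contaminated = [
            pep for (pep, lab), binder in zip(
                el_sa[["peptide", "label"]].itertuples(index=False),
                sa_truth["true_binder"])
            if lab == 0 and binder
        ]
        kept_negatives = set(table[table["label"] == 0]["peptide"])
        assert not (set(contaminated) & kept_negatives)

    def test_empty_ma_completes(self):
        world, ba, el_sa, el_ma, _ = self.world_setup()
        cfg = CurationConfig(model_config=tiny_config(max_pep_len=9),
                             pseudo_sequences=world.alleles)
        table, report, _ = run_curation(ba, el_sa, el_ma.iloc[0:0], cfg,
                                        model=self.oracle_model(world))
        assert report.n_ma_deconvolved == 0
        assert len(table) > 0

    def test_two_rounds_fixed_point_with_frozen_scorer(self):
        world, ba, el_sa, el_ma, _ = self.world_setup()
        model = self.oracle_model(world)
        base = dict(model_config=tiny_config(max_pep_len=9),
                    pseudo_sequences=world.alleles, refit_each_round=False)
        t1, _, _ = run_curation(ba, el_sa, el_ma,
                                CurationConfig(rounds=1, **base), model=model)
        t2, _, _ = run_curation(ba, el_sa, el_ma,
                                CurationConfig(rounds=2, **base), model=model)
        pd.testing.assert_frame_equal(
            t1.sort_values(["peptide", "allele"]).reset_index(drop=True),
            t2.sort_values(["peptide", "allele"]).reset_index(drop=True))

    def test_positives_and_peptides_preserved(self):
        world, ba, el_sa, el_ma, _ = self.world_setup()
        cfg = CurationConfig(model_config=tiny_config(max_pep_len=9),
                             pseudo_sequences=world.alleles)
        table, _, _ = run_curation(ba, el_sa, el_ma, cfg,
                                   model=self.oracle_model(world))
        in_peptides = (set(ba["peptide"]) | set(el_sa["peptide"])
                       | set(el_ma["peptide"]))
        assert set(table["peptide"]) <= in_peptides
        el_positives = (set(el_sa[el_sa["label"] == 1]["peptide"])
                        | set(el_ma[el_ma["label"] == 1]["peptide"]))
        pos_out = set(table[table["label"] == 1]["peptide"])
        assert el_positives <= pos_out
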