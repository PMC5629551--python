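import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from deepsubtype.aberration import aberration_matrix
from deepsubtype.synthdata import (CONTROL_SUBTYPE, CohortConfig,
                                   ExpressionCohort, LatentHierarchy,
                                   generate_cohort, read_cohort, write_cohort)


class TestHierarchy:
    def test_balanced_covers_every_gene_tf_pathway_process(self):
        h = LatentHierarchy.balanced(50, n_tfs=6, n_pathways=3, n_processes=3)
        assert h.covered_genes() == set(range(50))
        tfs = {t for v in h.pathway_to_tfs.values() for t in v}
        assert tfs == set(range(h.n_tfs))

    def test_invalid_hierarchies_rejected(self):
        with pytest.raises(ValueError, match="effect_size"):
            LatentHierarchy.balanced(10, effect_size=-1)
        with pytest.raises(ValueError):
            LatentHierarchy(n_processes=1, n_pathways=1, n_tfs=1,
                            tf_to_genes={0: ()},  # empty target set
                            pathway_to_tfs={0: (0,)},
                            process_to_pathways={0: (0,)})


class TestGenerate:
    def test_seeded_determinism(self):
        cfg = CohortConfig(seed=7, n_genes=40, tumors_per_tissue=10,
                           controls_per_tissue=5,
                           hierarchy=LatentHierarchy.balanced(40))
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.expression.equals(b.expression)
        assert a.mutations.equals(b.mutations)
        assert a.survival_time.equals(b.survival_time)

    def test_subtype_labels_cover_all_tumors(self):
        cfg = CohortConfig(n_tissues=1, tumors_per_tissue=100,
                           controls_per_tissue=10, n_subtypes=3, n_genes=30,
                           hierarchy=LatentHierarchy.balanced(30), seed=1)
        c = generate_cohort(cfg)
        tum = c.true_subtype[c.is_tumor.astype(bool)]
        assert set(tum) == {0, 1, 2} and len(tum) == 100
        ctrl = c.true_subtype[~c.is_tumor.astype(bool)]
        assert (ctrl == CONTROL_SUBTYPE).all()

    def test_too_many_subtypes_rejected(self):
        h = LatentHierarchy.balanced(30, n_processes=2, n_pathways=2, n_tfs=4)
        with pytest.raises(ValueError, match="process combinations"):
            generate_cohort(CohortConfig(n_subtypes=4, n_genes=30,
                                         hierarchy=h, seed=0))

    def test_nonpositive_ranges_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(control_sd_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            CohortConfig(cnv_rate=1.5)

    def test_null_config_tumors_match_control_distribution(self):
        """With effect_size=0 and cnv_rate=0, downstream aberration
        frequency is the two-sided tail mass of the fitted Gaussians."""
        h = LatentHierarchy.balanced(80, effect_size=0.0)
        cfg = CohortConfig(n_tissues=1, tumors_per_tissue=400,
                           controls_per_tissue=200, n_genes=80,
                           hierarchy=h, cnv_rate=0.0, seed=3)
        c = generate_cohort(cfg)
        binary, _ = aberration_matrix(c)
        obs = int(binary.to_numpy().sum())
        lo, hi = stats.binom.interval(0.999, binary.size, 2 * 0.001)
        assert lo <= obs <= hi

    def test_subtype_separability_on_discretized_data(self):
        """effect_size >= 3 with >= 30 genes/TF: between-subtype distance
        exceeds within-subtype distance on binarized tumors."""
        h = LatentHierarchy.balanced(270, n_tfs=9, n_pathways=3,
                                     n_processes=3, effect_size=3.0,
                                     signal_fraction=1.0)
        cfg = CohortConfig(n_tissues=1, tumors_per_tissue=60,
                           controls_per_tissue=30, n_genes=270,
                           n_subtypes=3, hierarchy=h, cnv_rate=0.0, seed=4)
        c = generate_cohort(cfg)
        binary, _ = aberration_matrix(c)
        sub = c.true_subtype[binary.index].to_numpy()
        d = squareform(pdist(binary.to_numpy(), metric="euclidean"))
        same = sub[:, None] == sub[None, :]
        iu = np.triu_indices(len(sub), 1)
        within = d[iu][same[iu]]
        between = d[iu][~same[iu]]
        assert len(within) >= 100 and len(between) >= 100
        assert between.mean() > within.mean()

    def test_empirical_event_rate_ratio_tracks_hazard_ratio(self):
        """Exponential survival: event-rate ratio converges to the planted
        hazard ratio within 20% at n=500 per arm."""
        h = LatentHierarchy.balanced(20, n_processes=2, n_pathways=2, n_tfs=4)
        cfg = CohortConfig(n_tissues=1, tumors_per_tissue=1000,
                           controls_per_tissue=5, n_genes=20, n_subtypes=2,
                           hierarchy=h, subtype_hazard_ratios=(1.0, 2.5),
                           seed=9)
        c = generate_cohort(cfg)
        tum = c.is_tumor.astype(bool)
        sub = c.true_subtype[tum]
        t = c.survival_time[tum]
        e = c.survival_event[tum]
        # exponential MLE of rate = events / total exposure
        rate = {s: e[sub == s].sum() / t[sub == s].sum() for s in (0, 1)}
        assert rate[1] / rate[0] == pytest.approx(2.5, rel=0.2)

    def test_cnv_shifts_expression_with_matching_sign(self):
        h = LatentHierarchy.balanced(60, effect_size=0.0)
        cfg = CohortConfig(n_tissues=1, tumors_per_tissue=300,
                           controls_per_tissue=100, n_genes=60, hierarchy=h,
                           cnv_rate=0.1, cnv_expression_shift=3.0, seed=2)
        c = generate_cohort(cfg)
        tum = c.is_tumor.astype(bool)
        x = c.expression[tum].to_numpy()
        g = c.cnv[tum].to_numpy()
        mu = c.truth["control_mean"][0]
        resid = x - mu[None, :]
        assert resid[g == 1].mean() > 0
        assert resid[g == -1].mean() < 0


class TestRoundTrip:
    def test_write_read_equal(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path / "c")
        back = read_cohort(tmp_path / "c")
        assert back == small_cohort

    def test_refuses_overwrite_without_flag(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path / "c")
        with pytest.raises(FileExistsError):
            write_cohort(small_cohort, tmp_path / "c")
        write_cohort(small_cohort, tmp_path / "c", overwrite=True)

    def test_optional_tables_omitted_and_tolerated(self, tmp_path):
        idx = pd.Index(["s1", "s2", "s3", "s4"], name="sample_id")
        genes = pd.Index([f"g{i}" for i in range(4)], name="gene_id")
        cohort = ExpressionCohort(
            expression=pd.DataFrame(np.ones((4, 4)), index=idx, columns=genes),
            tissue=pd.Series(["a"] * 4, index=idx, name="tissue"),
            is_tumor=pd.Series([0, 0, 1, 1], index=idx, name="is_tumor"),
            true_subtype=pd.Series([-1, -1, 0, 0], index=idx,
                                   name="true_subtype"),
        )
        write_cohort(cohort, tmp_path / "c")
        assert not (tmp_path / "c" / "cnv.tsv").exists()
        assert not (tmp_path / "c" / "mutations.tsv").exists()
        back = read_cohort(tmp_path / "c")
        assert back.cnv is None and back.mutations is None

    def test_expression_tsv_is_gene_per_row(self, tmp_path):
        idx = pd.Index(["s1", "s2", "s3"], name="sample_id")
        genes = pd.Index([f"g{i}" for i in range(4)], name="gene_id")
        cohort = ExpressionCohort(
            expression=pd.DataFrame(np.arange(12.0).reshape(3, 4),
                                    index=idx, columns=genes),
            tissue=pd.Series(["a"] * 3, index=idx, name="tissue"),
            is_tumor=pd.Series([0, 1, 1], index=idx, name="is_tumor"),
        )
        write_cohort(cohort, tmp_path / "c")
        lines = (tmp_path / "c" / "expression.tsv").read_text().strip().split("\n")
        assert len(lines) == 5  # header + 4 gene rows
        assert lines[0].split("\t") == ["gene_id", "s1", "s2", "s3"]
        assert len(lines[1].split("\t")) == 4  # gene id + 3 values

    def test_sidecar_json_records_seed(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path / "c")
        import json
        sidecar = json.loads((tmp_path / "c" / "cohort.json").read_text())
        assert sidecar["seed"] == small_cohort.config.seed
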