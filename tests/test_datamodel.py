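"""Data model: block-consistent reading, task decomposition, shared features."""

import numpy as np
import pytest

from mlpd import (
    BlockConsistencyError,
    MultiSourceDataset,
    NoTrainableTaskError,
    decompose_tasks,
    read_feature_table,
    reorder_shared_first,
    shared_feature_set,
    write_feature_table,
)
from mlpd.errors import MLPDError
from mlpd.slpd import fit_slpd, pooled_stats
from mlpd.synthetic import simulate_dataset, two_block_config

from conftest import tiny_two_source_dataset

SCHEMA = {"MRI": ["m1", "m2"], "PET": ["p1", "p2"]}


def _write_csv(tmp_path, rows, header="id,label,m1,m2,p1,p2"):
    f = tmp_path / "t.csv"
    f.write_text("\n".join([header] + rows) + "\n")
    return f


class TestReadFeatureTable:
    def test_block_missingness_yields_availability_mask(self, tmp_path):
        f = _write_csv(
            tmp_path,
            ["a,1,0.1,0.2,0.3,0.4", "b,-1,1.1,1.2,1.3,1.4", "c,1,2.1,2.2,,", "d,-1,3.1,3.2,3.3,3.4"],
        )
        ds = read_feature_table(f, SCHEMA, "label", id_column="id")
        assert ds.availability.tolist() == [[True, True], [True, True], [True, False], [True, True]]
        assert ds.subject_ids == ["a", "b", "c", "d"]
        assert np.isnan(ds.values[2, 2:]).all()

    def test_partially_missing_block_rejected(self, tmp_path):
        f = _write_csv(tmp_path, ["a,1,0.1,0.2,0.3,", "b,-1,1.1,1.2,1.3,1.4"])
        with pytest.raises(BlockConsistencyError):
            read_feature_table(f, SCHEMA, "label", id_column="id")

    def test_coerce_to_absent_flag(self, tmp_path):
        f = _write_csv(
            tmp_path,
            ["a,1,0.1,0.2,0.3,", "b,-1,1.1,1.2,1.3,1.4", "c,1,2.1,2.2,2.3,2.4", "d,-1,3.1,3.2,3.3,3.4"],
        )
        ds = read_feature_table(f, SCHEMA, "label", id_column="id", coerce_partial_blocks=True)
        assert ds.availability[0].tolist() == [True, False]
        assert np.isnan(ds.values[0, 2:]).all()

    def test_unknown_label_code_rejected(self, tmp_path):
        f = _write_csv(tmp_path, ["a,pMCI,0.1,0.2,0.3,0.4", "b,sMCI,1.1,1.2,1.3,1.4"])
        with pytest.raises(MLPDError, match="positive_label"):
            read_feature_table(f, SCHEMA, "label", id_column="id")
        ds = read_feature_table(f, SCHEMA, "label", id_column="id", positive_label="pMCI")
        assert ds.labels.tolist() == [1, -1]

    def test_roundtrip_identity(self, tmp_path):
        ds = simulate_dataset(two_block_config(p_block=4, seed=7))
        path = tmp_path / "sim.csv"
        write_feature_table(ds, path)
        back = read_feature_table(
            path, dict(ds.sources), "label", id_column="subject_id"
        )
        np.testing.assert_array_equal(np.isnan(ds.values), np.isnan(back.values))
        np.testing.assert_allclose(
            ds.values[~np.isnan(ds.values)], back.values[~np.isnan(back.values)]
        )
        np.testing.assert_array_equal(ds.availability, back.availability)
        np.testing.assert_array_equal(ds.labels, back.labels)
        assert ds.subject_ids == back.subject_ids


class TestDecomposeTasks:
    def test_study_shaped_dataset_gives_two_tasks(self):
        ds = simulate_dataset(two_block_config(p_block=5, seed=0))
        tasks = decompose_tasks(ds)
        assert [(t.task_id, sorted(t.pattern), t.n1, t.n2, t.p) for t in tasks] == [
            (1, ["MRI", "PET"], 76, 126, 10),
            (2, ["MRI"], 91, 100, 5),
        ]
        # subject conservation
        assert sum(t.n1 + t.n2 for t in tasks) == ds.n_subjects

    def test_complete_dataset_gives_one_task(self):
        ds = simulate_dataset(
            two_block_config(p_block=3, counts={("MRI", "PET"): (5, 6)}, seed=1)
        )
        tasks = decompose_tasks(ds)
        assert len(tasks) == 1
        assert tasks[0].n1 + tasks[0].n2 == 11

    def test_three_source_patterns_against_brute_force_grouping(self, rng):
        dims = {"A": 2, "B": 3, "C": 4}
        sources = [(n, [f"{n}{i}" for i in range(d)]) for n, d in dims.items()]
        patterns = [("A",), ("A", "B"), ("A", "B", "C")]
        values, labels, avail = [], [], []
        for pat in patterns:
            for lab in (1, -1):
                for _ in range(3):
                    row = np.full(9, np.nan)
                    mask = []
                    off = 0
                    for n, d in dims.items():
                        if n in pat:
                            row[off : off + d] = rng.standard_normal(d)
                        mask.append(n in pat)
                        off += d
                    values.append(row)
                    labels.append(lab)
                    avail.append(mask)
        ds = MultiSourceDataset(
            subject_ids=[str(i) for i in range(len(labels))],
            labels=np.array(labels),
            sources=sources,
            values=np.array(values),
            availability=np.array(avail),
        )
        tasks = decompose_tasks(ds)
        # brute force: group rows by their NaN signature
        sig_groups = {}
        for i in range(ds.n_subjects):
            sig_groups.setdefault(tuple(np.isnan(ds.values[i])), []).append(i)
        assert len(tasks) == len(sig_groups) == 3
        assert [t.p for t in tasks] == [9, 5, 2]  # descending number of sources

    def test_row_order_invariance(self):
        ds = tiny_two_source_dataset(seed=3)
        perm = np.random.default_rng(0).permutation(ds.n_subjects)
        t_a = decompose_tasks(ds)
        t_b = decompose_tasks(ds.subset(perm))
        for a, b in zip(t_a, t_b):
            assert a.pattern == b.pattern
            # same multiset of rows per class
            for Xa, Xb in ((a.X1, b.X1), (a.X2, b.X2)):
                ka = sorted(map(tuple, np.round(Xa, 12)))
                kb = sorted(map(tuple, np.round(Xb, 12)))
                assert ka == kb

    def test_no_trainable_task_errors(self):
        ds = tiny_two_source_dataset(n_both=(1, 1), n_first=(1, 1))
        with pytest.raises(NoTrainableTaskError):
            decompose_tasks(ds, min_per_class=2)


class TestSharedFeatures:
    def test_full_block_shared(self):
        ds = simulate_dataset(two_block_config(p_block=5, seed=0))
        t1, t2 = decompose_tasks(ds)
        s = shared_feature_set(t1, t2)
        assert s.m == 5
        assert all(t1.global_index[a] == t2.global_index[b] for a, b in s.pairs)

    def test_disjoint_sources_share_nothing(self):
        ds = tiny_two_source_dataset()
        t1, t2 = decompose_tasks(ds)
        t1_b_only = t1.restrict_features(range(3, 6))  # only source B columns
        assert shared_feature_set(t1_b_only, t2).m == 0

    def test_matches_set_intersection_oracle(self, rng):
        for _ in range(20):
            ds = tiny_two_source_dataset(seed=int(rng.integers(1000)))
            t1, t2 = decompose_tasks(ds)
            keep1 = sorted(rng.choice(t1.p, size=int(rng.integers(1, t1.p + 1)), replace=False))
            keep2 = sorted(rng.choice(t2.p, size=int(rng.integers(1, t2.p + 1)), replace=False))
            a, b = t1.restrict_features(keep1), t2.restrict_features(keep2)
            expect = len(set(a.global_index) & set(b.global_index))
            assert shared_feature_set(a, b).m == expect


class TestReorderSharedFirst:
    def test_shared_block_first_and_aligned(self):
        ds = simulate_dataset(two_block_config(p_block=4, seed=2))
        t1, t2 = decompose_tasks(ds)
        s = shared_feature_set(t1, t2)
        r1, r2, rs = reorder_shared_first(t1, t2, s)
        assert rs.pairs == [(k, k) for k in range(s.m)]
        np.testing.assert_array_equal(r1.global_index[: s.m], r2.global_index[: s.m])

    def test_identity_on_already_ordered(self):
        ds = simulate_dataset(two_block_config(p_block=3, seed=2))
        t1, t2 = decompose_tasks(ds)
        s = shared_feature_set(t1, t2)
        r1, _, _ = reorder_shared_first(t1, t2, s)
        np.testing.assert_array_equal(r1.global_index, t1.global_index)
        np.testing.assert_array_equal(r1.X1, t1.X1)

    def test_fit_invariant_to_reordering(self):
        ds = simulate_dataset(two_block_config(p_block=3, seed=5))
        t1, t2 = decompose_tasks(ds)
        # scramble task-1 columns, then reorder; the fitted objective and the
        # beta entries (mapped by global feature id) must match the plain fit
        perm = np.random.default_rng(1).permutation(t1.p)
        t1_scr = t1.restrict_features(perm)
        s = shared_feature_set(t1_scr, t2)
        r1, _, _ = reorder_shared_first(t1_scr, t2, s)
        m_plain = fit_slpd(pooled_stats(t1), 0.3)
        m_re = fit_slpd(pooled_stats(r1), 0.3)
        assert m_plain.objective == pytest.approx(m_re.objective, abs=1e-8)
        by_gid_plain = dict(zip(t1.global_index.tolist(), m_plain.beta))
        by_gid_re = dict(zip(r1.global_index.tolist(), m_re.beta))
        for g in by_gid_plain:
            assert by_gid_plain[g] == pytest.approx(by_gid_re[g], abs=1e-6)
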