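import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nmari as nm
from nmari.data import rebase_block

from conftest import blocks_from_net, simulated_net


class TestPMatrix:
    def test_scalar_case(self):
        assert nm.p_matrix(1) == pytest.approx(np.array([[1.0]]))

    def test_two_by_two(self):
        assert nm.p_matrix(2) == pytest.approx(np.array([[1.0, 0.5], [0.5, 1.0]]))

    def test_eigenvalues_k3(self):
        # P_k = (I + J)/2 has eigenvalues (k+1)/2 and 1/2 (k-1 times)
        eig = np.sort(np.linalg.eigvalsh(nm.p_matrix(3)))
        assert eig == pytest.approx([0.5, 0.5, 2.0])

    def test_invalid_k(self):
        with pytest.raises(nm.InvalidDataError):
            nm.p_matrix(0)


class TestBinaryContrasts:
    def test_two_arm_log_odds_ratio(self):
        arms = [
            nm.BinaryArm("s", "A", 10, 100),
            nm.BinaryArm("s", "B", 20, 100),
        ]
        block = nm.contrasts_from_binary(arms)
        assert block.y[0] == pytest.approx(np.log((20 / 80) / (10 / 90)))
        assert block.S[0, 0] == pytest.approx(1 / 10 + 1 / 90 + 1 / 20 + 1 / 80)

    def test_identical_arms_give_zero(self):
        arms = [nm.BinaryArm("s", "A", 10, 100), nm.BinaryArm("s", "B", 10, 100)]
        assert nm.contrasts_from_binary(arms).y[0] == pytest.approx(0.0)

    def test_three_arm_off_diagonal_is_baseline_variance(self):
        arms = [
            nm.BinaryArm("s", "A", 10, 100),
            nm.BinaryArm("s", "B", 20, 100),
            nm.BinaryArm("s", "C", 30, 100),
        ]
        block = nm.contrasts_from_binary(arms)
        v_a = 1 / 10 + 1 / 90
        assert block.S[0, 1] == pytest.approx(v_a)
        assert block.comparators == ("B", "C")

    def test_continuity_correction_applied_study_wide(self):
        arms = [nm.BinaryArm("s", "A", 0, 10), nm.BinaryArm("s", "B", 5, 10)]
        block = nm.contrasts_from_binary(arms)
        lo_a = np.log(0.5 / 10.5)
        lo_b = np.log(5.5 / 5.5)
        assert block.y[0] == pytest.approx(lo_b - lo_a)

    def test_invalid_events(self):
        with pytest.raises(nm.InvalidDataError):
            nm.BinaryArm("s", "A", -1, 10)
        with pytest.raises(nm.InvalidDataError):
            nm.BinaryArm("s", "A", 11, 10)


class TestContinuousContrasts:
    def test_two_arm_mean_difference(self):
        arms = [
            nm.ContinuousArm("s", "A", 5.0, 2.0, 4),
            nm.ContinuousArm("s", "B", 7.0, 3.0, 9),
        ]
        block = nm.contrasts_from_continuous(arms)
        assert block.y[0] == pytest.approx(2.0)
        assert block.S[0, 0] == pytest.approx(4 / 4 + 9 / 9)

    def test_three_arm_covariance_is_baseline_share(self):
        arms = [
            nm.ContinuousArm("s", "A", 0.0, 2.0, 8),
            nm.ContinuousArm("s", "B", 1.0, 1.0, 10),
            nm.ContinuousArm("s", "C", 2.0, 3.0, 5),
        ]
        block = nm.contrasts_from_continuous(arms)
        assert block.S[0, 1] == pytest.approx(4 / 8)

    def test_small_arm_rejected(self):
        with pytest.raises(nm.InvalidDataError):
            nm.ContinuousArm("s", "A", 0.0, 1.0, 1)


class TestAssembly:
    def test_two_design_example(self, ab_ac_net):
        net = ab_ac_net
        assert net.X == pytest.approx(np.array([[1, 0], [1, 0], [0, 1]], float))
        assert net.M1 == pytest.approx(np.eye(3))
        assert net.M2 == pytest.approx(
            np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], float)
        )

    def test_single_multiarm_study(self, abc_net):
        expected = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert abc_net.M1 == pytest.approx(expected)
        assert abc_net.M2 == pytest.approx(expected)

    def test_single_two_arm_study(self):
        net = nm.assemble_network(
            [nm.ContrastBlock("s1", "A", ("B",), [0.3], [[1.0]])]
        )
        assert net.X == pytest.approx(np.array([[1.0]]))
        assert net.M1 == pytest.approx(np.array([[1.0]]))
        assert net.M2 == pytest.approx(np.array([[1.0]]))

    def test_design_without_reference(self):
        blocks = [
            nm.ContrastBlock("s1", "A", ("B",), [0.1], [[1.0]]),
            nm.ContrastBlock("s2", "A", ("C",), [0.1], [[1.0]]),
            nm.ContrastBlock("s3", "C", ("D", "E"), [0.2, 0.3], nm.p_matrix(2)),
        ]
        net = nm.assemble_network(blocks, reference="A")
        # CDE rows encode delta_AD - delta_AC and delta_AE - delta_AC
        cols = {t: i for i, t in enumerate(net.basic_labels)}
        row_d = net.X[2]
        assert row_d[cols["D"]] == 1 and row_d[cols["C"]] == -1
        row_e = net.X[3]
        assert row_e[cols["E"]] == 1 and row_e[cols["C"]] == -1

    def test_disconnected_network_raises(self):
        blocks = [
            nm.ContrastBlock("s1", "A", ("B",), [0.1], [[1.0]]),
            nm.ContrastBlock("s2", "C", ("D",), [0.1], [[1.0]]),
        ]
        with pytest.raises(nm.DisconnectedNetworkError) as err:
            nm.assemble_network(blocks)
        assert any("A" in c for c in err.value.components)

    def test_duplicate_study_rejected(self):
        blocks = [
            nm.ContrastBlock("s1", "A", ("B",), [0.1], [[1.0]]),
            nm.ContrastBlock("s1", "A", ("C",), [0.1], [[1.0]]),
        ]
        with pytest.raises(nm.InvalidDataError):
            nm.assemble_network(blocks)

    def test_rebase_roundtrip(self):
        block = nm.ContrastBlock(
            "s", "B", ("A", "C"), [0.4, -0.1], [[0.5, 0.2], [0.2, 0.7]]
        )
        back = rebase_block(rebase_block(block, "C"), "B")
        assert back.y == pytest.approx(block.y[[0, 1]])
        assert back.S == pytest.approx(block.S)


class TestDesignSubmodels:
    def test_df_counts(self):
        y = np.zeros(4)
        blocks = [
            nm.ContrastBlock(f"s{i}", "A", ("B", "C"),
                             [0.1 * i, 0.2 * i], nm.p_matrix(2))
            for i in range(4)
        ] + [nm.ContrastBlock("t1", "A", ("B",), [0.1], [[1.0]])]
        net = nm.assemble_network(blocks)
        by_id = {d.design_id: d for d in nm.split_by_design(net)}
        assert by_id[("A", "B", "C")].df_het == (4 - 1) * 2
        assert by_id[("A", "B")].df_het == 0

    def test_kronecker_structure(self):
        blocks = [
            nm.ContrastBlock(f"s{i}", "A", ("B", "C"),
                             [0.1, 0.2], nm.p_matrix(2))
            for i in range(2)
        ] + [nm.ContrastBlock("t1", "A", ("B",), [0.0], [[1.0]])]
        net = nm.assemble_network(blocks)
        d = next(x for x in net.designs if x.c_d == 2)
        expected = np.kron(np.eye(2), nm.p_matrix(2))
        assert d.M_d == pytest.approx(expected)
        assert d.X_d == pytest.approx(np.tile(np.eye(2), (2, 1)))

    def test_row_count_identity(self):
        for seed in range(3):
            net = simulated_net(seed)
            assert sum(d.n_d * d.c_d for d in net.designs) == net.n
            assert net.X.shape[1] == net.c


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_m_matrices_are_psd_unit_diagonal(seed):
    net = simulated_net(seed % 50, n_treatments=4, design_mix={2: 5, 3: 2})
    for M in (net.M1, net.M2):
        assert np.allclose(np.diag(M), 1.0)
        assert np.allclose(M, M.T)
        assert np.linalg.eigvalsh(M).min() >= -1e-10
        assert set(np.round(np.unique(M), 12)) <= {0.0, 0.5, 1.0}


def test_relabeling_preserves_structure(medium_net):
    """A bijection on treatment labels permutes the design matrix columns
    (up to sign) and leaves the pairwise effect estimates unchanged."""
    labels = medium_net.treatments
    rename = dict(zip(labels, [f"Z{9 - i}" for i in range(len(labels))]))
    blocks = blocks_from_net(medium_net, rename=lambda t: rename[t])
    relabeled = nm.assemble_network(blocks)
    fit_old = nm.fit_network(medium_net, "dl", "full")
    fit_new = nm.fit_network(relabeled, "dl", "full")
    old = {
        (rename[r.treatment_1], rename[r.treatment_2]): r.estimate
        for r in fit_old.pairwise.itertuples()
    }
    for r in fit_new.pairwise.itertuples():
        key = (r.treatment_1, r.treatment_2)
        if key in old:
            assert r.estimate == pytest.approx(old[key], abs=1e-8)
        else:
            assert r.estimate == pytest.approx(-old[key[::-1]], abs=1e-8)
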