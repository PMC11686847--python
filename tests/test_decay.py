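"""Decay taxonomy: stage profiles, cluster truth table, trajectories, flows, quadrants."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oodyn import (
    CLUSTERS,
    STATUS_TO_CLUSTER,
    ValidationError,
    classify_decay_clusters,
    cluster_trajectories,
    compute_tpm,
    quadrant_analysis,
    stage_profiles,
    transition_sankey,
    transition_status,
)
from oodyn.decay import StageProfile

from helpers import toy_experiment


def make_profile(rows, base_log2=10.0):
    """StageProfile from a list of (gene, d1, d2) control log2 deltas.

    Mutant columns copy control unless 4-tuples (gene, d1c, d2c, (d1m, d2m))
    are given.  TPM summaries are set high enough to pass the filter.
    """
    log_cols = {}
    genes = [r[0] for r in rows]
    gv = pd.Series(base_log2, index=genes)
    d1c = pd.Series({r[0]: r[1] for r in rows})
    d2c = pd.Series({r[0]: r[2] for r in rows})
    mut = {r[0]: r[3] if len(r) > 3 else (r[1], r[2]) for r in rows}
    d1m = pd.Series({g: v[0] for g, v in mut.items()})
    d2m = pd.Series({g: v[1] for g, v in mut.items()})
    log_cols[("control", "GV")] = gv
    log_cols[("control", "MII")] = gv + d1c
    log_cols[("control", "D3")] = gv + d1c + d2c
    log_cols[("mutant", "GV")] = gv
    log_cols[("mutant", "MII")] = gv + d1m
    log_cols[("mutant", "D3")] = gv + d1m + d2m
    log_summary = pd.DataFrame(log_cols)
    log_summary.columns = pd.MultiIndex.from_tuples(
        log_summary.columns, names=["genotype", "stage"]
    )
    tpm_summary = 2.0**log_summary - 1.0
    return StageProfile(log_summary=log_summary, tpm_summary=tpm_summary)


class TestStageProfiles:
    def test_single_sample_equals_its_log_transform(self):
        counts = np.array([[30], [10], [5]] * 1)
        exps = []
        # one sample per (stage, genotype) cell
        stages = ["GV", "MII", "D3", "GV", "MII", "D3"]
        genos = ["control"] * 3 + ["mutant"] * 3
        exp = toy_experiment(np.tile(counts, (1, 6)), stages, genos)
        mat = compute_tpm(exp)
        prof = stage_profiles(mat, exp)
        s_gv = exp.samples_for("GV", "control")[0]
        np.testing.assert_allclose(
            prof.value("control", "GV"),
            np.log2(mat.calibrated[s_gv] + 1.0),
        )

    def test_tpm_three_maps_to_two(self):
        # log2(3 + 1) = 2 exactly
        assert np.log2(3.0 + 1.0) == 2.0

    def test_median_then_transform(self):
        # median of TPM (0, 10, 1000) is 10 -> log2(11); median commutes with log
        exp = toy_experiment(
            np.ones((2, 6), dtype=int),
            ["GV"] * 3 + ["MII", "D3", "GV"],
            ["control"] * 3 + ["mutant"] * 3,
        )
        # incomplete design: missing cells must be reported
        mat = compute_tpm(exp)
        with pytest.raises(ValidationError, match="MII"):
            stage_profiles(mat, exp)

    def test_median_over_samples_on_log_scale(self):
        stages = ["GV"] * 3 + ["MII", "D3"] + ["GV", "MII", "D3"]
        genos = ["control"] * 5 + ["mutant"] * 3
        counts = np.ones((1, 8), dtype=int)
        exp = toy_experiment(counts, stages, genos)
        mat = compute_tpm(exp)
        gv_ids = exp.samples_for("GV", "control")
        mat.tpm.loc["g0", gv_ids] = [0.0, 10.0, 1000.0]
        prof = stage_profiles(mat, exp)
        assert prof.value("control", "GV")["g0"] == pytest.approx(np.log2(11.0))


class TestClassifyDecayClusters:
    def test_exhaustive_truth_table(self):
        """All combinations of signed 2-log2 steps map to their defining cluster."""
        deltas = [-2.0, 0.0, 2.0]
        rows = [
            (f"g_{d1}_{d2}", d1, d2)
            for d1, d2 in itertools.product(deltas, deltas)
        ]
        cmap = classify_decay_clusters(make_profile(rows))
        sign = {-2.0: "degraded", 0.0: "stable", 2.0: "elevated"}
        for d1, d2 in itertools.product(deltas, deltas):
            expected = STATUS_TO_CLUSTER[(sign[d1], sign[d2])]
            assert cmap.assignment[f"g_{d1}_{d2}"] == expected

    def test_boundary_is_inclusive(self):
        # |delta| exactly equal to the threshold counts as changed ("2-fold" = >= 2-fold)
        cmap = classify_decay_clusters(make_profile([("g", -1.0, 1.0)]), fc_log2=1.0)
        assert cmap.assignment["g"] == "VIII"

    def test_low_expression_gene_filtered(self):
        prof = make_profile([("lo", -2.0, 0.0), ("hi", -2.0, 0.0)])
        prof.tpm_summary.loc["lo"] = 1.0  # never above the floor of 2
        cmap = classify_decay_clusters(prof)
        assert cmap.assignment["lo"] == "filtered"
        assert cmap.assignment["hi"] == "I"
        assert cmap.cluster_counts().sum() == 1

    def test_recovers_simulated_clusters(self, default_sim, default_cluster_map):
        """>= 90% of unfiltered genes recover their planted trajectory cluster."""
        _, _, _, truth = default_sim
        cmap = default_cluster_map
        genes = truth.cluster.index[truth.cluster != "spike"]
        assigned = cmap.assignment[genes]
        unfiltered = assigned != "filtered"
        recovery = (assigned[unfiltered] == truth.cluster[genes][unfiltered]).mean()
        assert recovery >= 0.9

    def test_global_scaling_changes_only_the_filter(self):
        prof = make_profile([("a", -2.0, 0.0), ("b", 0.0, 2.0)])
        scaled = StageProfile(
            log_summary=prof.log_summary + np.log2(4.0),  # x4 on the TPM scale
            tpm_summary=prof.tpm_summary * 4.0,
        )
        a = classify_decay_clusters(prof)
        b = classify_decay_clusters(scaled)
        both = (a.assignment != "filtered") & (b.assignment != "filtered")
        assert (a.assignment[both] == b.assignment[both]).all()


class TestClusterTrajectories:
    def test_identical_genotypes_give_zero_impairment(self):
        rows = [(f"g{i}", -2.0, 0.0) for i in range(5)]
        prof = make_profile(rows)
        cmap = classify_decay_clusters(prof)
        traj = cluster_trajectories(cmap, prof)
        assert traj.impairment.loc["I", "statistic"] == pytest.approx(0.0)
        assert traj.impairment.loc["I", "p"] == 1.0

    def test_attenuated_decay_detected_in_clusters_i_to_iii(
        self, default_sim, default_calibrated, default_profile, default_cluster_map
    ):
        """Mutants retaining 30% of each degradation step show positive impairment."""
        traj = cluster_trajectories(default_cluster_map, default_profile)
        for cluster in ("I", "II", "III"):
            assert traj.impairment.loc[cluster, "statistic"] > 0
            assert traj.impairment.loc[cluster, "p"] < 0.05

    def test_attenuated_zga_elevation_in_cluster_vi(
        self, default_profile, default_cluster_map
    ):
        traj = cluster_trajectories(default_cluster_map, default_profile)
        # mutant day-3 elevation falls short of control elevation
        assert traj.elevation_deficit.loc["VI", "statistic"] > 0
        assert traj.elevation_deficit.loc["VI", "p"] < 0.05
        ctrl = traj.trajectories.loc[("VI", "control")]
        mut = traj.trajectories.loc[("VI", "mutant")]
        assert (mut["D3"] - mut["MII"]) < (ctrl["D3"] - ctrl["MII"])

    def test_empty_cluster_omitted(self):
        prof = make_profile([("g", -2.0, 0.0)])
        cmap = classify_decay_clusters(prof)
        traj = cluster_trajectories(cmap, prof)
        assert list(traj.trajectories.index.get_level_values("cluster").unique()) == ["I"]


def _call_table(calls: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame({"call": pd.Series(calls)})


class TestTransitionSankey:
    def test_all_ns_everywhere(self):
        calls = {f"g{i}": "ns" for i in range(4)}
        flows = transition_sankey({s: _call_table(calls) for s in ("GV", "MII", "D3")})
        assert flows["GV->MII"].loc["ns", "ns"] == 4
        assert flows["GV->MII"].to_numpy().sum() == 4

    def test_hand_built_flow_counts(self):
        gv = _call_table({"a": "up", "b": "up", "c": "down", "d": "ns", "e": "ns"})
        mii = _call_table({"a": "up", "b": "ns", "c": "down", "d": "down", "e": "ns"})
        flows = transition_sankey({"GV": gv, "MII": mii})
        f = flows["GV->MII"]
        assert f.loc["up", "up"] == 1
        assert f.loc["up", "ns"] == 1
        assert f.loc["down", "down"] == 1
        assert f.loc["ns", "down"] == 1
        assert f.loc["ns", "ns"] == 1
        assert f.to_numpy().sum() == 5

    def test_marginals_conserved(self, default_sim):
        from oodyn import deg_per_stage

        exp, *_ = default_sim
        degs = deg_per_stage(exp)
        flows = transition_sankey(degs)
        universe = degs["GV"].index
        for key, earlier in (("GV->MII", "GV"), ("MII->D3", "MII")):
            row_sums = flows[key].sum(axis=1)
            status_counts = degs[earlier].loc[universe, "call"].value_counts()
            for status in ("up", "down", "ns"):
                assert row_sums[status] == status_counts.get(status, 0)
            assert flows[key].to_numpy().sum() == len(universe)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            transition_sankey({
                "GV": _call_table({"a": "ns"}),
                "MII": _call_table({"b": "ns"}),
            })


class TestQuadrantAnalysis:
    def _deg(self, calls):
        return pd.DataFrame({"call": pd.Series(calls)})

    def test_decay_escape_quadrant(self):
        # up in mutant MII while control says it should have been degraded
        prof = make_profile([("g", -3.0, 0.0)])
        res = quadrant_analysis(self._deg({"g": "up"}), prof)
        assert res.labels["g"] == "up_in_mutant__degraded_in_control"
        assert list(res.headline) == ["g"]

    def test_ns_gene_unassigned(self):
        prof = make_profile([("g", -3.0, 0.0)])
        res = quadrant_analysis(self._deg({"g": "ns"}), prof)
        assert res.labels["g"] == "unassigned"
        assert res.counts.sum() == 0

    def test_hand_built_eight_gene_assignment(self):
        rows = [
            ("a", -3.0, 0.0), ("b", -2.0, 0.0), ("c", 3.0, 0.0), ("d", 2.0, 0.0),
            ("e", -3.0, 0.0), ("f", 3.0, 0.0), ("g", 0.5, 0.0), ("h", -0.5, 0.0),
        ]
        calls = {"a": "up", "b": "up", "c": "up", "d": "down",
                 "e": "down", "f": "ns", "g": "up", "h": "down"}
        res = quadrant_analysis(self._deg(calls), make_profile(rows))
        expected = {
            "a": "up_in_mutant__degraded_in_control",
            "b": "up_in_mutant__degraded_in_control",
            "c": "up_in_mutant__elevated_in_control",
            "d": "down_in_mutant__elevated_in_control",
            "e": "down_in_mutant__degraded_in_control",
            "f": "unassigned",  # not a DEG
            "g": "unassigned",  # |delta1| below threshold
            "h": "unassigned",
        }
        assert res.labels.to_dict() == expected
        assert res.counts["up_in_mutant__degraded_in_control"] == 2
        assert set(res.headline) == {"a", "b"}

    def test_quadrants_partition_eligible_degs(self, default_sim, default_profile):
        from oodyn import deg_per_stage

        exp, *_ = default_sim
        deg_mii = deg_per_stage(exp, stages=("MII",))["MII"]
        res = quadrant_analysis(deg_mii, default_profile)
        d1 = default_profile.deltas("control")["delta1"].reindex(deg_mii.index)
        eligible = (deg_mii["call"] != "ns") & (d1.abs() >= 1.0)
        assert res.counts.sum() == int(eligible.sum())
        assert set(res.labels[eligible.to_numpy()]) <= set(res.counts.index)


def test_transition_status_boundaries():
    np.testing.assert_array_equal(
        transition_status([-1.0, -0.99, 0.99, 1.0], fc_log2=1.0),
        ["degraded", "stable", "stable", "elevated"],
    )
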