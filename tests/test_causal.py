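"""Causal matching logic, label-randomization activity calls, sweep, SIF I/O."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosnet import causal
from phosnet.causal import ChangeSet
from phosnet.synthetic import PriorNetwork, PriorRelation


def site_results_frame(rows):
    """Minimal DiffResult-like table: feature, b, adj_p."""
    return pd.DataFrame(rows, columns=["feature", "b", "adj_p"])


def truth_table_oracle(prior: PriorNetwork, changes: ChangeSet) -> set[tuple]:
    """Independent re-derivation of the edge set by exhaustive evaluation:
    for each relation, enumerate the evidence rules and the consistency
    equation d = sigma * a directly."""
    edges = set()
    for r in prior.relations:
        d = changes.site_direction.get(r.site_id)
        if d is None:
            continue
        evid = set()
        for r2 in prior.relations:
            if r2.target == r.source and r2.site_effect != 0:
                d2 = changes.site_direction.get(r2.site_id)
                if d2 is not None:
                    evid.add(r2.site_effect * d2)
        if len(evid) == 1:
            a = next(iter(evid))
        elif len(evid) > 1:
            continue
        elif r.source in changes.protein_direction:
            a = changes.protein_direction[r.source]
        else:
            continue
        if d == r.relation_sign * a:
            edges.add((r.source, r.target, r.target_site))
    return edges


class TestInferChangeDirections:
    def test_significant_site_gets_sign_of_fold_change(self):
        res = site_results_frame([("S1_T10", 1.2, 0.0005)])
        cs = causal.infer_change_directions(res, 0.001)
        assert cs.site_direction == {"S1_T10": 1}

    def test_site_above_cutoff_absent(self):
        res = site_results_frame([("S1_T10", 1.2, 0.005)])
        cs = causal.infer_change_directions(res, 0.001)
        assert cs.site_direction == {}

    def test_cutoff_sequence_gives_nested_changesets(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"P{i}_S{i + 1}", rng.normal(0, 2), 10 ** rng.uniform(-5, 0)) for i in range(200)
        ]
        res = site_results_frame(rows)
        previous = None
        for cutoff in (0.1, 0.01, 0.001, 0.0001):
            current = set(causal.infer_change_directions(res, cutoff).site_direction)
            if previous is not None:
                assert current <= previous
            previous = current


class TestMatchCausalRelations:
    def test_inactive_kinase_explains_reduced_target_phosphorylation(self):
        # CDK1 -> EZH2 T487 (phosphorylation); CDK1 inferred inactive via its
        # own activatory site going down; EZH2 T487 down: -1 = +1 * -1
        prior = PriorNetwork(
            [
                PriorRelation("CDK1", "EZH2", 1, "T487", -1),
                PriorRelation("CDK7", "CDK1", 1, "T161", 1),  # activatory site on CDK1
            ]
        )
        cs = ChangeSet({"EZH2_T487": -1, "CDK1_T161": -1})
        net = causal.match_causal_relations(prior, cs)
        assert len(net) >= 1
        edge = net.edges[net.edges["target"] == "EZH2"].iloc[0]
        assert edge["source"] == "CDK1"
        assert edge["source_activity"] == -1

    def test_site_mismatch_blocks_edge(self):
        prior = PriorNetwork([PriorRelation("K", "T", 1, "S200", 1)])
        cs = ChangeSet({"T_S100": -1}, protein_direction={"K": -1})
        net = causal.match_causal_relations(prior, cs)
        assert len(net) == 0

    def test_truth_table_exactly_four_of_eight_combinations(self):
        for sigma, a, d in itertools.product((1, -1), repeat=3):
            prior = PriorNetwork([PriorRelation("K", "T", sigma, "S10", 1)])
            cs = ChangeSet({"T_S10": d}, protein_direction={"K": a})
            net = causal.match_causal_relations(prior, cs)
            assert (len(net) == 1) == (d == sigma * a)

    def test_conflicting_source_evidence_excludes_source(self):
        prior = PriorNetwork(
            [
                PriorRelation("K", "T", 1, "S10", 1),
                PriorRelation("U1", "K", 1, "S1", 1),
                PriorRelation("U2", "K", 1, "S2", -1),
            ]
        )
        cs = ChangeSet({"T_S10": 1, "K_S1": 1, "K_S2": 1})  # says a=+1 and a=-1
        net = causal.match_causal_relations(prior, cs)
        assert len(net.edges[net.edges["source"] == "K"]) == 0

    def test_site_evidence_outranks_protein_evidence(self):
        prior = PriorNetwork(
            [
                PriorRelation("K", "T", 1, "S10", 1),
                PriorRelation("U", "K", 1, "S1", 1),
            ]
        )
        cs = ChangeSet({"T_S10": -1, "K_S1": -1}, protein_direction={"K": 1})
        net = causal.match_causal_relations(prior, cs)
        # site evidence says a=-1, so the down target is explained
        assert len(net.edges[net.edges["target"] == "T"]) == 1

    def test_matches_oracle_on_enumerated_small_networks(self):
        rng = np.random.default_rng(7)
        names = ["A", "B", "C", "D"]
        for _ in range(300):
            n_rel = rng.integers(1, 5)
            relations = []
            for i in range(n_rel):
                src, tgt = rng.choice(names, 2, replace=False)
                sigma = int(rng.choice([1, -1]))
                effect = int(rng.choice([1, -1, 0]))
                site = f"S{i + 1}"
                if any(
                    (r.source, r.target, r.target_site, r.relation_sign)
                    == (src, tgt, site, sigma)
                    for r in relations
                ):
                    continue
                relations.append(PriorRelation(src, tgt, sigma, site, effect))
            prior = PriorNetwork(relations)
            all_sites = [r.site_id for r in relations]
            dirs = {
                s: int(rng.choice([1, -1]))
                for s in all_sites
                if rng.random() < 0.7
            }
            prots = {n: int(rng.choice([1, -1])) for n in names if rng.random() < 0.3}
            cs = ChangeSet(dirs, protein_direction=prots)
            got = {
                (e.source, e.target, e.site) for e in causal.match_causal_relations(prior, cs).edges.itertuples()
            }
            assert got == truth_table_oracle(prior, cs)

    def test_edge_count_monotone_in_changeset(self):
        rng = np.random.default_rng(3)
        prior = PriorNetwork(
            [PriorRelation("K1", f"T{i}", 1, f"S{i + 1}", 1) for i in range(20)]
            + [PriorRelation("U", "K1", 1, "S99", 1)]
        )
        full = {f"T{i}_S{i + 1}": -1 for i in range(20)}
        full["K1_S99"] = -1
        small = dict(list(full.items())[:8])
        small["K1_S99"] = -1
        n_full = len(causal.match_causal_relations(prior, ChangeSet(full)))
        n_small = len(causal.match_causal_relations(prior, ChangeSet(small)))
        assert n_small <= n_full


class TestProteinActivities:
    def test_protein_without_measured_targets_absent(self):
        prior = PriorNetwork([PriorRelation("K", "T", 1, "S10", 1)])
        cs = ChangeSet({}, measured_sites=("X_S1", "X_S2"))
        table = causal.test_protein_activities(prior, cs, B=1000, seed=0)
        assert table.empty

    def test_permutation_p_matches_hypergeometric_oracle(self):
        """50 measured sites, 10 significant (down), kinase with 6 targets of
        which 4 changed: the permutation null is Hypergeom(N=50, K=10, n=6)."""
        targets = [PriorRelation("K", f"T{i}", 1, f"S{i + 1}", 0) for i in range(6)]
        prior = PriorNetwork(targets)
        measured = [f"T{i}_S{i + 1}" for i in range(6)] + [f"BG{i}_S1" for i in range(44)]
        down = {f"T{i}_S{i + 1}": -1 for i in range(4)}
        down.update({f"BG{i}_S1": -1 for i in range(6)})  # 10 significant total
        cs = ChangeSet(down, measured_sites=tuple(measured))
        B = 20000
        table = causal.test_protein_activities(prior, cs, B=B, seed=1)
        row = table[(table["protein"] == "K") & (table["activity"] == -1)].iloc[0]
        assert row["n_consistent"] == 4
        exact = stats.hypergeom.sf(3, 50, 10, 6)
        mc_se = np.sqrt(exact * (1 - exact) / B)
        assert abs(row["p"] - exact) < 3 * mc_se + 2 / B

    def test_best_call_reports_smaller_adjusted_p(self):
        prior = PriorNetwork([PriorRelation("K", f"T{i}", 1, f"S{i + 1}", 0) for i in range(8)])
        cs = ChangeSet(
            {f"T{i}_S{i + 1}": -1 for i in range(8)},
            measured_sites=tuple([f"T{i}_S{i + 1}" for i in range(8)] + [f"BG{i}_S1" for i in range(40)]),
        )
        table = causal.test_protein_activities(prior, cs, B=2000, seed=2)
        best = causal.best_activity_calls(table)
        assert len(best) == 1
        assert best.iloc[0]["direction"] == "inactivated"
        assert best.iloc[0]["called"]

    def test_too_few_permutations_rejected(self):
        prior = PriorNetwork([PriorRelation("K", "T", 1, "S10", 1)])
        with pytest.raises(ValueError):
            causal.test_protein_activities(prior, ChangeSet({"T_S10": 1}), B=10)


class TestFdrSweep:
    def test_single_cutoff_equals_direct_calls(self):
        rng = np.random.default_rng(4)
        prior = PriorNetwork([PriorRelation("K", f"T{i}", 1, f"S{i + 1}", 0) for i in range(10)])
        rows = [(f"T{i}_S{i + 1}", -1.0, 0.001) for i in range(10)]
        rows += [(f"BG{i}_S1", rng.normal(), 0.5) for i in range(30)]
        res = site_results_frame(rows)
        sweep, _ = causal.fdr_sweep(res, prior, cutoffs=[0.01], B=1000, seed=5)
        net_direct = causal.match_causal_relations(
            prior, causal.infer_change_directions(res, 0.01)
        )
        acts_direct = causal.test_protein_activities(
            prior, causal.infer_change_directions(res, 0.01), B=1000, seed=5
        )
        net, acts = sweep[0.01]
        pd.testing.assert_frame_equal(net.edges, net_direct.edges)
        pd.testing.assert_frame_equal(acts, acts_direct)

    def test_stricter_cutoff_can_yield_more_calls(self):
        """Noise sites significant only at the loose cutoff dilute the label
        null; removing them at the strict cutoff sharpens the activity test."""
        prior = PriorNetwork(
            [
                PriorRelation(f"K{k}", f"K{k}T{i}", 1, f"S{i + 1}", 0)
                for k in range(5)
                for i in range(10)
            ]
        )
        rows = [(f"K{k}T{i}_S{i + 1}", -1.0, 1e-5) for k in range(5) for i in range(10)]
        rows += [(f"NOISE{i}_S1", -1.0, 0.04) for i in range(200)]
        res = site_results_frame(rows)
        sweep, heatmap = causal.fdr_sweep(res, prior, cutoffs=[0.1, 0.001], B=2000, seed=6)
        n_loose = int(causal.best_activity_calls(sweep[0.1][1])["called"].sum())
        n_strict = int(causal.best_activity_calls(sweep[0.001][1])["called"].sum())
        assert n_strict > n_loose
        assert n_strict == 5

    def test_empty_cutoff_list_rejected(self):
        prior = PriorNetwork([PriorRelation("K", "T", 1, "S10", 1)])
        with pytest.raises(ValueError):
            causal.fdr_sweep(site_results_frame([]), prior, cutoffs=[])

    def test_heatmap_signed_log_p(self):
        prior = PriorNetwork([PriorRelation("K", f"T{i}", 1, f"S{i + 1}", 0) for i in range(10)])
        rows = [(f"T{i}_S{i + 1}", -1.0, 1e-4) for i in range(10)]
        rows += [(f"BG{i}_S1", 0.1, 0.9) for i in range(40)]
        res = site_results_frame(rows)
        _, heatmap = causal.fdr_sweep(res, prior, cutoffs=[0.01], B=2000, seed=7)
        assert "K" in heatmap.index
        # inactivated: activity -1 times a negative log10 adj p -> positive
        assert heatmap.loc["K", 0.01] > 0


class TestSubgraphAndIO:
    def _chain(self):
        prior = PriorNetwork(
            [
                PriorRelation("PRKCA", "MARCKS", 1, "S159", 0),
                PriorRelation("MARCKS", "X", 1, "S1", 0),
                PriorRelation("U", "PRKCA", 1, "S657", 1),
            ]
        )
        cs = ChangeSet({"MARCKS_S159": -1, "X_S1": -1, "PRKCA_S657": -1})
        return causal.match_causal_relations(prior, cs)

    def test_radius_zero_keeps_only_listed_gene(self):
        net = self._chain()
        sub = causal.extract_subgraph(net, ["PRKCA"], radius=0)
        assert len(sub) == 0  # no edge has both endpoints in {PRKCA}

    def test_radius_one_neighborhood(self):
        net = self._chain()
        sub = causal.extract_subgraph(net, ["PRKCA"], radius=1)
        assert set(sub.edges["target"]) == {"MARCKS"}
        assert set(sub.edges["source"]) == {"PRKCA"}

    def test_absent_gene_warns_and_contributes_nothing(self):
        net = self._chain()
        with pytest.warns(UserWarning, match="NOT_THERE"):
            sub = causal.extract_subgraph(net, ["NOT_THERE"], radius=1)
        assert len(sub) == 0

    def test_single_edge_sif_line(self, tmp_path):
        prior = PriorNetwork([PriorRelation("CDK1", "EZH2", 1, "T487", -1)])
        cs = ChangeSet({"EZH2_T487": -1}, protein_direction={"CDK1": -1})
        net = causal.match_causal_relations(prior, cs)
        sif = tmp_path / "net.sif"
        causal.write_network(net, sif)
        assert sif.read_text() == "CDK1\tphosphorylates\tEZH2\n"

    def test_empty_network_round_trip(self, tmp_path):
        net = causal.CausalNetwork(edges=pd.DataFrame(columns=causal.CausalNetwork.EDGE_COLUMNS))
        sif, attrs = tmp_path / "n.sif", tmp_path / "n.tsv"
        causal.write_network(net, sif, attrs)
        assert sif.read_text() == ""
        again = causal.read_network(sif, attrs)
        assert len(again) == 0

    def test_write_read_write_identical_bytes(self, tmp_path):
        net = self._chain()
        sif1, attr1 = tmp_path / "a.sif", tmp_path / "a.tsv"
        causal.write_network(net, sif1, attr1)
        again = causal.read_network(sif1, attr1)
        sif2, attr2 = tmp_path / "b.sif", tmp_path / "b.tsv"
        causal.write_network(again, sif2, attr2)
        assert sif1.read_bytes() == sif2.read_bytes()
        assert attr1.read_bytes() == attr2.read_bytes()
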