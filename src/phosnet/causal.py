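"""Site-specific causal network inference from significant phosphosite
changes plus a signed prior network, with permutation-based protein-activity
calls, an FDR sweep, subgraph extraction, and SIF export.

An edge "A (de)phosphorylates B@s" explains an observed change at B@s iff
the prior site matches the detected site exactly (residue + position), A's
activity direction is evidenced (by an activatory/inhibitory site change on
A itself or by A's total-protein change), and the target direction equals
the relation sign times the source activity: d = sigma * a.

Protein activity significance uses label randomization: the observed
statistic is the number of measured prior target sites whose direction is
consistent with the hypothesized activity, and the null redistributes the
significant up/down labels over all measured sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .differential import bh_adjust
from .synthetic import PriorNetwork, PriorRelation

log = logging.getLogger(__name__)

DEFAULT_CUTOFFS = (0.1, 0.01, 0.001, 0.0001)
ACTIVITY_FDR = 0.1


@dataclass
class ChangeSet:
    """Directions of significant changes at one FDR cutoff, plus the
    universe of measured features the permutation null is drawn from."""

    site_direction: dict[str, int]
    protein_direction: dict[str, int] = field(default_factory=dict)
    measured_sites: tuple[str, ...] = ()
    fdr_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if not self.measured_sites:
            self.measured_sites = tuple(self.site_direction)
        missing = set(self.site_direction) - set(self.measured_sites)
        if missing:
            raise ValueError(f"changed sites absent from measured universe: {sorted(missing)[:3]}")


@dataclass
class CausalNetwork:
    """Edges consistent with the prior and the observed changes."""

    edges: pd.DataFrame  # source, relation, target, site, sigma, effect, source_activity, target_direction
    source_activity: dict[str, int] = field(default_factory=dict)
    node_attrs: pd.DataFrame | None = None

    EDGE_COLUMNS = [
        "source",
        "relation",
        "target",
        "site",
        "sigma",
        "effect",
        "source_activity",
        "target_direction",
    ]

    def __len__(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in self.edges.itertuples():
            g.add_edge(row.source, row.target, relation=row.relation, site=row.site)
        return g


def infer_change_directions(
    site_results: pd.DataFrame,
    fdr_cutoff: float,
    protein_results: pd.DataFrame | None = None,
    abs_log2fc_threshold: float = 0.58,
) -> ChangeSet:
    """Significant features at the cutoff become signed directions; every
    feature in the tables defines the measured universe."""
    sites: dict[str, int] = {}
    for row in site_results.itertuples():
        if row.adj_p < fdr_cutoff and abs(row.b) > abs_log2fc_threshold:
            sites[row.feature] = 1 if row.b > 0 else -1
    proteins: dict[str, int] = {}
    if protein_results is not None:
        for row in protein_results.itertuples():
            if row.adj_p < fdr_cutoff and abs(row.b) > abs_log2fc_threshold:
                proteins[row.feature] = 1 if row.b > 0 else -1
    return ChangeSet(
        site_direction=sites,
        protein_direction=proteins,
        measured_sites=tuple(site_results["feature"]),
        fdr_cutoff=fdr_cutoff,
    )


def infer_source_activities(prior: PriorNetwork, changes: ChangeSet) -> dict[str, int]:
    """Evidence a direction of activity for each potential source protein.

    An activatory site (effect +1) moving in direction d on protein P says
    a(P) = d; an inhibitory site says a(P) = -d; P's total-protein change
    says a(P) = sign of that change. Site evidence outranks protein
    evidence; contradictory evidence excludes the protein.
    """
    site_evidence: dict[str, set[int]] = {}
    for r in prior.relations:
        if r.site_effect == 0:
            continue
        d = changes.site_direction.get(r.site_id)
        if d is None:
            continue
        site_evidence.setdefault(r.target, set()).add(r.site_effect * d)
    activities: dict[str, int] = {}
    candidates = set(site_evidence) | set(changes.protein_direction)
    for protein in candidates:
        ev = site_evidence.get(protein)
        if ev is not None:
            if len(ev) == 1:
                activities[protein] = next(iter(ev))
            continue  # conflicting site evidence: excluded
        activities[protein] = changes.protein_direction[protein]
    return activities


def match_causal_relations(prior: PriorNetwork, changes: ChangeSet) -> CausalNetwork:
    """Emit every prior relation whose target site changed in the direction
    the relation sign and the evidenced source activity predict."""
    activities = infer_source_activities(prior, changes)
    rows = []
    for r in prior.relations:
        d = changes.site_direction.get(r.site_id)
        if d is None:
            continue
        a = activities.get(r.source)
        if a is None or a == 0:
            continue
        if d != r.relation_sign * a:
            continue
        rows.append(
            {
                "source": r.source,
                "relation": "phosphorylates" if r.relation_sign > 0 else "dephosphorylates",
                "target": r.target,
                "site": r.target_site,
                "sigma": r.relation_sign,
                "effect": r.site_effect,
                "source_activity": a,
                "target_direction": d,
            }
        )
    edges = pd.DataFrame(rows, columns=CausalNetwork.EDGE_COLUMNS)
    return CausalNetwork(edges=edges, source_activity=activities)


def test_protein_activities(
    prior: PriorNetwork,
    changes: ChangeSet,
    B: int = 10_000,
    seed: int = 0,
    randomized_p: bool = False,
) -> pd.DataFrame:
    """Label-randomization significance of protein activities.

    For each protein with measured prior targets and each hypothesized
    activity a in {+1, -1}, the statistic is the number of its measured
    target sites whose direction d satisfies d = sigma * a. The null
    reshuffles the direction labels over all measured sites, preserving the
    global up/down/unchanged counts; p = (#null >= observed + 1) / (B + 1).
    BH is applied across proteins within each hypothesis; each protein is
    reported once with the smaller adjusted p (ties broken toward the
    larger consistent-target count), and called at adjusted p < 0.1.

    ``randomized_p`` adds the uniform tie-break that makes the discrete
    permutation p exactly U(0,1) under the null (used for calibration
    checks, not for inference).
    """
    if B < 1000:
        raise ValueError("use at least 1000 permutations")
    rng = np.random.default_rng(seed)
    sites = list(changes.measured_sites)
    index = {s: i for i, s in enumerate(sites)}
    labels = np.zeros(len(sites), dtype=np.int8)
    for s, d in changes.site_direction.items():
        labels[index[s]] = d

    # measured prior targets per protein: site row index and relation sign
    per_protein: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for protein in prior.kinases:
        idx, sig = [], []
        for r in prior.targets_of(protein):
            i = index.get(r.site_id)
            if i is not None:
                idx.append(i)
                sig.append(r.relation_sign)
        if idx:
            per_protein[protein] = (np.array(idx), np.array(sig, dtype=np.int8))

    perm = np.tile(labels, (B, 1))
    perm = rng.permuted(perm, axis=1)

    rows = []
    for protein, (idx, sig) in per_protein.items():
        null_vals = perm[:, idx]  # B x n_targets
        for a in (+1, -1):
            want = sig * a
            observed = int((labels[idx] == want).sum())
            null_counts = (null_vals == want[None, :]).sum(axis=1)
            n_ge = int((null_counts >= observed).sum())
            p = (n_ge + 1) / (B + 1)
            if randomized_p:
                n_gt = int((null_counts > observed).sum())
                u = rng.random()
                p = (n_gt + u * (n_ge - n_gt + 1)) / (B + 1)
            rows.append(
                {
                    "protein": protein,
                    "direction": "activated" if a > 0 else "inactivated",
                    "activity": a,
                    "n_consistent": observed,
                    "n_measured_targets": len(idx),
                    "p": p,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["protein", "direction", "activity", "n_consistent", "n_measured_targets", "p"],
    )
    if len(table):
        table["adj_p"] = np.nan
        for a in (+1, -1):
            mask = table["activity"] == a
            table.loc[mask, "adj_p"] = bh_adjust(table.loc[mask, "p"].to_numpy())
        table["called"] = table["adj_p"] < ACTIVITY_FDR
    else:
        table["adj_p"] = pd.Series(dtype=float)
        table["called"] = pd.Series(dtype=bool)
    table.attrs["B"] = B
    table.attrs["seed"] = seed
    table.attrs["fdr_cutoff"] = changes.fdr_cutoff
    return table


def best_activity_calls(activity_table: pd.DataFrame) -> pd.DataFrame:
    """One row per protein: the hypothesis with the smaller adjusted p
    (ties -> larger consistent-target count)."""
    if activity_table.empty:
        return activity_table
    ordered = activity_table.sort_values(
        ["protein", "adj_p", "n_consistent"], ascending=[True, True, False]
    )
    return ordered.groupby("protein", sort=False).head(1).reset_index(drop=True)


def fdr_sweep(
    site_results: pd.DataFrame,
    prior: PriorNetwork,
    cutoffs=DEFAULT_CUTOFFS,
    protein_results: pd.DataFrame | None = None,
    B: int = 10_000,
    seed: int = 0,
) -> tuple[dict[float, tuple[CausalNetwork, pd.DataFrame]], pd.DataFrame]:
    """Run matching + activity testing at each change-detection FDR cutoff.

    Returns {cutoff: (network, activity table)} and the heatmap matrix of
    direction * log10(adjusted p) for every called protein at every cutoff.
    """
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("cutoff list must not be empty")
    results: dict[float, tuple[CausalNetwork, pd.DataFrame]] = {}
    heat: dict[float, dict[str, float]] = {}
    for cutoff in cutoffs:
        changes = infer_change_directions(site_results, cutoff, protein_results)
        net = match_causal_relations(prior, changes)
        acts = test_protein_activities(prior, changes, B=B, seed=seed)
        results[cutoff] = (net, acts)
        col: dict[str, float] = {}
        for row in best_activity_calls(acts).itertuples():
            if row.called:
                col[row.protein] = row.activity * float(np.log10(max(row.adj_p, 1e-300)))
        heat[cutoff] = col
    proteins = sorted({p for col in heat.values() for p in col})
    heatmap = pd.DataFrame(
        {cutoff: [heat[cutoff].get(p, np.nan) for p in proteins] for cutoff in cutoffs},
        index=proteins,
    )
    return results, heatmap


def extract_subgraph(net: CausalNetwork, genes, radius: int = 1) -> CausalNetwork:
    """Induced subgraph of nodes within ``radius`` undirected hops of any
    listed gene; absent genes warn and contribute nothing."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    g = net.to_graph().to_undirected()
    keep: set[str] = set()
    for gene in genes:
        if gene not in g:
            warnings.warn(f"gene {gene!r} not in network", stacklevel=2)
            continue
        lengths = nx.single_source_shortest_path_length(g, gene, cutoff=radius)
        keep.update(lengths)
    edges = net.edges[net.edges["source"].isin(keep) & net.edges["target"].isin(keep)]
    return CausalNetwork(edges=edges.reset_index(drop=True), source_activity=net.source_activity)


def write_network(net: CausalNetwork, sif_path, attr_path=None) -> None:
    """SIF triples plus a node/edge attribute table; round-trip stable."""
    with open(sif_path, "w") as fh:
        for row in net.edges.itertuples():
            fh.write(f"{row.source}\t{row.relation}\t{row.target}\n")
    if attr_path is not None:
        net.edges.to_csv(attr_path, sep="\t", index=False)


def read_network(sif_path, attr_path=None) -> CausalNetwork:
    if attr_path is not None:
        edges = pd.read_csv(attr_path, sep="\t")
        if edges.empty:
            edges = pd.DataFrame(columns=CausalNetwork.EDGE_COLUMNS)
        return CausalNetwork(edges=edges[CausalNetwork.EDGE_COLUMNS])
    rows = []
    with open(sif_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            source, relation, target = line.split("\t")
            rows.append(
                {
                    "source": source,
                    "relation": relation,
                    "target": target,
                    "site": "",
                    "sigma": 1 if relation == "phosphorylates" else -1,
                    "effect": 0,
                    "source_activity": 0,
                    "target_direction": 0,
                }
            )
    return CausalNetwork(edges=pd.DataFrame(rows, columns=CausalNetwork.EDGE_COLUMNS))
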