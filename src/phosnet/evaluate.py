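"""Benchmark routines that measure the pipeline against known ground truth.

These run the actual analysis code on generated data and report recovery /
calibration summaries: Dixon outlier recall and clean loss, mixture-mode
shift error, null p-value calibration for the moderated t and the two
permutation tests, planted-kinase recovery, and the FDR-sweep behavior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import causal, differential, ptmsea, synthetic, tmt
from .causal import ChangeSet
from .design import StudyDesign, make_plex
from .differential import FilterConfig
from .synthetic import GroundTruth, PriorNetwork, PriorRelation
from .tmt import PHOSPHOSITE, QuantMatrix

STUDY_KINASES = (
    "CDK1",
    "CDK2",
    "PRKCA",
    "RPS6KB1",
    "MAPK1",
    "GSK3B",
    "CSNK2A1",
    "AKT1",
    "PRKACA",
    "CAMK2A",
)


def named_kinase_prior(targets_per_kinase: int = 10, seed: int = 0) -> PriorNetwork:
    """A ten-kinase prior using canonical kinase gene symbols."""
    base = synthetic.generate_prior_network(
        len(STUDY_KINASES), targets_per_kinase, frac_inhibitory=0.2, seed=seed
    )
    mapping = dict(zip(base.kinases, STUDY_KINASES))
    return PriorNetwork(
        [
            PriorRelation(mapping[r.source], r.target, r.relation_sign, r.target_site, r.site_effect)
            for r in base.relations
        ]
    )


def dixon_outlier_recovery(
    n_sites: int = 250,
    psm_per_peptide: int = 4,
    outlier_rate: float = 0.05,
    outlier_shift: float = 4.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[float, float]:
    """Fraction of planted outlier cells removed, and fraction of clean
    cells removed, by recursive Dixon filtering at the PSM level."""
    design = StudyDesign((make_plex("p1", "CL1"),))
    truth = GroundTruth({}, {}, 0.0)
    truth = synthetic.add_decoy_sites(truth, n_sites, seed=seed)
    tables, tt = synthetic.generate_reporter_tables(
        truth,
        design,
        noise_sd=noise_sd,
        psm_per_peptide=psm_per_peptide,
        outlier_rate=outlier_rate,
        outlier_shift=outlier_shift,
        seed=seed + 1,
        protein_peptides=0,
    )
    ratios, n_dropped = tmt.compute_log_ratios(tables[0], design)
    assert n_dropped == 0
    channel_to_sample = {c.index: c.sample_id for c in design.plexes[0].sample_channels}
    planted = {
        (int(r.row), channel_to_sample[int(r.channel)])
        for r in tt[tt["kind"] == "outlier"].itertuples()
    }
    removed: set[tuple[int, str]] = set()
    n_cells = 0
    for sample in design.sample_ids:
        for _, grp in ratios.groupby("peptide", sort=False):
            vals = grp[sample].to_numpy(dtype=float)
            n_cells += len(vals)
            if len(vals) >= 3:
                keep = tmt.dixon_outlier_filter(vals)
                removed.update((int(grp.index[j]), sample) for j in np.flatnonzero(~keep))
    recall = len(planted & removed) / len(planted)
    clean_loss = len(removed - planted) / (n_cells - len(planted))
    return recall, clean_loss


def mixture_shift_error(
    true_shift: float = 0.2, n: int = 5000, seed: int = 0
) -> float:
    """|recovered - planted| mode shift for an 80/20 two-component sample."""
    rng = np.random.default_rng(seed)
    x = np.concatenate(
        [rng.normal(true_shift, 0.1, int(0.8 * n)), rng.normal(2.0, 0.3, n - int(0.8 * n))]
    )
    model = tmt.fit_sample_mixture(x)
    return abs(model.shift - true_shift)


def null_pvalue_fraction(n_features: int = 2000, seed: int = 0) -> float:
    """Fraction of raw moderated-t p-values below 0.05 on pure-noise data."""
    design = StudyDesign((make_plex("p1", "CL1"),))
    rng = np.random.default_rng(seed)
    data = rng.normal(0, 0.5, (n_features, 8))
    vals = pd.DataFrame(
        data, columns=design.sample_ids, index=[f"F{i}" for i in range(n_features)]
    )
    res = differential.fit_moderated_t(QuantMatrix(PHOSPHOSITE, vals, design), design)
    return float((res["p"] < 0.05).mean())


def activity_null_pvalues(
    n_seeds: int = 50,
    n_sites: int = 200,
    n_kinases: int = 20,
    targets_per_kinase: int = 8,
    n_up: int = 20,
    n_down: int = 20,
    B: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Randomized permutation p-values for the activation hypothesis under a
    null in which significance labels are assigned at random."""
    pvals: list[float] = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        prior = synthetic.generate_prior_network(
            n_kinases, targets_per_kinase, frac_inhibitory=0.0, seed=seed + s
        )
        target_sites = [r.site_id for r in prior.relations]
        extra = [f"BG{i}_S1" for i in range(max(0, n_sites - len(target_sites)))]
        sites = target_sites + extra
        chosen = rng.choice(len(sites), size=n_up + n_down, replace=False)
        dirs = {sites[i]: 1 for i in chosen[:n_up]}
        dirs.update({sites[i]: -1 for i in chosen[n_up:]})
        cs = ChangeSet(dirs, measured_sites=tuple(sites))
        table = causal.test_protein_activities(
            prior, cs, B=B, seed=seed + 1000 + s, randomized_p=True
        )
        pvals.extend(table.loc[table["activity"] == 1, "p"])
    return np.asarray(pvals)


def enrichment_null_pvalues(
    n_seeds: int = 50,
    n_sites: int = 150,
    n_sets: int = 10,
    set_size: int = 10,
    B: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p-values for random signatures over random statistics."""
    pvals: list[float] = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        stats = {f"G{i}_S1": float(v) for i, v in enumerate(rng.normal(0, 1, n_sites))}
        names = list(stats)
        sets = []
        for j in range(n_sets):
            members = rng.choice(names, size=set_size, replace=False)
            sets.append(
                ptmsea.SignatureSet(f"NULL{j}", "kinase", [(m, None) for m in members])
            )
        res = ptmsea.permute_enrichment(stats, sets, B=B, seed=seed + 1000 + s)
        pvals.extend(res["p"])
    return np.asarray(pvals)


def kinase_recovery(
    effect_size: float = 1.0,
    noise_sd: float = 0.2,
    targets_per_kinase: int = 10,
    B: int = 10_000,
    fdr_cutoff: float = 0.1,
    n_decoys: int = 60,
    seed: int = 0,
) -> dict:
    """Full-chain recovery of five kinases perturbed down.

    Generates one plex (4 treated vs 4 vehicle), runs quantification,
    protein-adjusted moderated-t statistics, change detection at the given
    FDR cutoff, and the label-randomization activity test. Reports how many
    of the five planted kinases were called inactivated and how many calls
    (on any protein) went in the activated direction.
    """
    design = StudyDesign((make_plex("p1", "CL1"),))
    prior = named_kinase_prior(targets_per_kinase, seed=seed)
    perturbed = {k: -1 for k in STUDY_KINASES[:5]}
    truth = synthetic.simulate_perturbation(prior, perturbed, effect_size)
    truth = synthetic.add_decoy_sites(truth, n_decoys, seed=seed + 1)
    tables, _ = synthetic.generate_reporter_tables(
        truth, design, noise_sd=noise_sd, psm_per_peptide=3, seed=seed + 2
    )
    ratios, _ = tmt.compute_log_ratios(tables[0], design)
    mats = tmt.collapse_features(ratios, design)
    site_qm = tmt.align_and_scale(mats[PHOSPHOSITE])
    prot_qm = tmt.align_and_scale(mats["protein"])
    site_res = differential.fit_moderated_t(site_qm, design)
    prot_res = differential.fit_moderated_t(prot_qm, design)
    site_adj, _ = differential.adjust_phospho_for_protein(site_res, prot_res)
    flagged, _ = differential.apply_significance_filters(site_adj, FilterConfig())
    changes = causal.infer_change_directions(flagged, fdr_cutoff)
    acts = causal.test_protein_activities(prior, changes, B=B, seed=seed + 3)
    best = causal.best_activity_calls(acts)
    called = best[best["called"]]
    inactivated = set(called.loc[called["activity"] == -1, "protein"])
    n_recovered = len(inactivated & set(STUDY_KINASES[:5]))
    n_wrong_direction = int((called["activity"] == 1).sum())
    return {
        "n_recovered": n_recovered,
        "n_wrong_direction": n_wrong_direction,
        "calls": called,
        "n_significant_sites": len(changes.site_direction),
    }


def sweep_call_counts(B: int = 2000, seed: int = 0) -> tuple[int, int]:
    """Activity calls at a loose (0.1) vs strict (0.001) change-detection
    FDR on a fixture where 200 noise sites are significant only at the loose
    cutoff: returns (n_calls_loose, n_calls_strict)."""
    prior = PriorNetwork(
        [
            PriorRelation(f"K{k}", f"K{k}T{i}", 1, f"S{i + 1}", 0)
            for k in range(5)
            for i in range(10)
        ]
    )
    rows = [(f"K{k}T{i}_S{i + 1}", -1.0, 1e-5) for k in range(5) for i in range(10)]
    rows += [(f"NOISE{i}_S1", -1.0, 0.04) for i in range(200)]
    res = pd.DataFrame(rows, columns=["feature", "b", "adj_p"])
    sweep, _ = causal.fdr_sweep(res, prior, cutoffs=[0.1, 0.001], B=B, seed=seed)
    n_loose = int(causal.best_activity_calls(sweep[0.1][1])["called"].sum())
    n_strict = int(causal.best_activity_calls(sweep[0.001][1])["called"].sum())
    return n_loose, n_strict
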