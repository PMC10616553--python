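"""End-to-end orchestration: simulate -> quantify -> test -> infer -> enrich.

A run is fully specified by a :class:`RunConfig`; every stage is seeded and
all outputs land in one artifact directory together with a manifest that
records the verbatim config, its hash, package versions and seeds. Each
cell line is analyzed as an independent sub-run and overlap sets of shared
same-direction significant changes are computed across cell lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, causal, differential, ptmsea, synthetic, tmt
from .design import StudyDesign, default_design

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mode: str = "synthetic"  # synthetic | files
    outdir: str = "phosnet_run"
    seed: int = 0
    # synthetic design
    cell_lines: tuple[str, ...] = ("CL1", "CL2", "CL3")
    n_kinases: int = 10
    targets_per_kinase: int = 10
    frac_inhibitory: float = 0.2
    frac_dephospho: float = 0.0
    perturbed_kinases: dict[str, int] = field(default_factory=dict)
    effect_size: float = 1.0
    n_decoy_sites: int = 50
    noise_sd: float = 0.2
    psm_per_peptide: int = 3
    outlier_rate: float = 0.01
    outlier_shift: float = 4.0
    missing_rate: float = 0.01
    # input files (mode = "files")
    reporter_paths: tuple[str, ...] = ()
    prior_path: str | None = None
    signature_path: str | None = None
    # analysis parameters
    fdr_threshold: float = 0.05
    abs_log2fc_threshold: float = 0.58
    min_localization_probability: float = 0.75
    causal_cutoffs: tuple[float, ...] = causal.DEFAULT_CUTOFFS
    n_permutations_activity: int = 10_000
    n_permutations_enrichment: int = 1000
    enrichment_weight: float = ptmsea.DEFAULT_WEIGHT

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        cfg = cls(**data)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config_hash: str, index=False, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index, **kw)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis and return the artifact directory."""
    outdir = Path(cfg.outdir)
    chash = cfg.config_hash()
    try:
        return _run(cfg, outdir, chash)
    except Exception:
        if outdir.exists():
            shutil.rmtree(outdir, ignore_errors=True)
        raise


def _run(cfg: RunConfig, outdir: Path, chash: str) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.mode == "synthetic":
        design = default_design(tuple(cfg.cell_lines))
        prior = synthetic.generate_prior_network(
            cfg.n_kinases,
            cfg.targets_per_kinase,
            cfg.frac_inhibitory,
            cfg.frac_dephospho,
            seed=cfg.seed,
        )
        perturbed = dict(cfg.perturbed_kinases)
        if not perturbed:  # default: inactivate the first half of the kinases
            for k in prior.kinases[: max(1, cfg.n_kinases // 2)]:
                perturbed[k] = -1
        truth = synthetic.simulate_perturbation(prior, perturbed, cfg.effect_size, seed=cfg.seed)
        truth = synthetic.add_decoy_sites(truth, cfg.n_decoy_sites, seed=cfg.seed + 1)
        tables, truth_table = synthetic.generate_reporter_tables(
            truth,
            design,
            noise_sd=cfg.noise_sd,
            psm_per_peptide=cfg.psm_per_peptide,
            outlier_rate=cfg.outlier_rate,
            outlier_shift=cfg.outlier_shift,
            missing_rate=cfg.missing_rate,
            seed=cfg.seed + 2,
        )
        prior.write(outdir / "prior_network.tsv")
        _write_table(truth_table, outdir / "ground_truth.tsv", chash)
        sig_sets = ptmsea.signatures_from_prior(prior.to_frame())
    else:
        missing = [p for p in cfg.reporter_paths if not Path(p).exists()]
        if cfg.prior_path is None:
            raise ValueError("config field 'prior_path' is required in files mode")
        if not Path(cfg.prior_path).exists():
            missing.append(cfg.prior_path)
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")
        design = default_design(tuple(cfg.cell_lines))
        tables = [synthetic.read_reporter_table(p) for p in cfg.reporter_paths]
        prior = synthetic.PriorNetwork.read(cfg.prior_path)
        sig_sets = (
            ptmsea.load_signatures(cfg.signature_path)
            if cfg.signature_path
            else ptmsea.signatures_from_prior(prior.to_frame())
        )

    # --- quantification -------------------------------------------------
    combined = pd.concat(tables, ignore_index=True)
    ratios, n_dropped = tmt.compute_log_ratios(combined, design)
    log.info("quant: %d PSM rows in, %d dropped (no reference)", len(combined), n_dropped)
    matrices = tmt.collapse_features(ratios, design)
    norm: dict[str, tmt.QuantMatrix] = {}
    for level, qm in matrices.items():
        norm[level] = tmt.align_and_scale(qm)
        norm[level].write(outdir / f"quant_{level}.tsv", config_hash=chash)
        _write_table(
            tmt.normalization_report(norm[level]),
            outdir / f"normalization_{level}.tsv",
            chash,
        )
    mds = tmt.mds_embed(norm["protein"], k=2)
    _write_table(mds, outdir / "mds_protein.tsv", chash, index=True, index_label="sample")

    fcfg = differential.FilterConfig(
        fdr_threshold=cfg.fdr_threshold,
        abs_log2fc_threshold=cfg.abs_log2fc_threshold,
        min_localization_probability=cfg.min_localization_probability,
    )

    overlap_frames: dict[str, pd.DataFrame] = {}
    for cell_line in design.cell_lines:
        sub = outdir / cell_line
        sub.mkdir(exist_ok=True)

        # --- differential ----------------------------------------------
        prot_res = differential.fit_moderated_t(norm["protein"], design, cell_line=cell_line)
        site_res = differential.fit_moderated_t(norm["phosphosite"], design, cell_line=cell_line)
        site_adj, n_no_prot = differential.adjust_phospho_for_protein(site_res, prot_res)
        log.info("%s: %d sites removed (no protein quant)", cell_line, n_no_prot)
        prot_flagged, prot_volcano = differential.apply_significance_filters(prot_res, fcfg)
        site_flagged, site_volcano = differential.apply_significance_filters(site_adj, fcfg)
        _write_table(prot_flagged, sub / "diff_protein.tsv", chash)
        _write_table(site_flagged, sub / "diff_phosphosite.tsv", chash)
        _write_table(prot_volcano, sub / "volcano_protein.tsv", chash)
        _write_table(site_volcano, sub / "volcano_phosphosite.tsv", chash)
        overlap_frames[cell_line] = site_flagged

        # --- causal inference -------------------------------------------
        sweep, heatmap = causal.fdr_sweep(
            site_flagged,
            prior,
            cutoffs=cfg.causal_cutoffs,
            protein_results=prot_flagged,
            B=cfg.n_permutations_activity,
            seed=cfg.seed + 3,
        )
        _write_table(heatmap, sub / "activity_heatmap.tsv", chash, index=True, index_label="protein")
        for cutoff, (net, acts) in sweep.items():
            tag = f"fdr_{cutoff:g}"
            causal.write_network(net, sub / f"network_{tag}.sif", sub / f"network_{tag}_edges.tsv")
            _write_table(acts, sub / f"activity_{tag}.tsv", chash)
        log.info(
            "%s: causal sweep at %s: %s edges",
            cell_line,
            list(sweep),
            [len(net) for net, _ in sweep.values()],
        )

        # --- enrichment --------------------------------------------------
        stats = dict(zip(site_flagged["feature"], site_flagged["t"]))
        enr = ptmsea.permute_enrichment(
            stats,
            sig_sets,
            w=cfg.enrichment_weight,
            B=cfg.n_permutations_enrichment,
            seed=cfg.seed + 4,
        )
        _write_table(enr, sub / "enrichment.tsv", chash)

    overlap = shared_significant_changes(overlap_frames)
    _write_table(overlap, outdir / "overlap_phosphosite.tsv", chash)

    manifest = {
        "phosnet_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": chash,
        "seed": cfg.seed,
        "n_dropped_psms": n_dropped,
        "cell_lines": design.cell_lines,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def shared_significant_changes(per_cell_line: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Features significant in the same direction across cell lines
    (the overlap-set construction behind multi-line Venn comparisons)."""
    rows: dict[str, dict] = {}
    for cl, df in per_cell_line.items():
        for row in df[df["significant"]].itertuples():
            rows.setdefault(row.feature, {})[cl] = int(row.direction)
    out = []
    for feature, dirs in rows.items():
        vals = set(dirs.values())
        out.append(
            {
                "feature": feature,
                "cell_lines": ",".join(sorted(dirs)),
                "n_cell_lines": len(dirs),
                "same_direction": len(vals) == 1,
                "direction": dirs[next(iter(dirs))] if len(vals) == 1 else 0,
            }
        )
    return pd.DataFrame(
        out, columns=["feature", "cell_lines", "n_cell_lines", "same_direction", "direction"]
    )
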