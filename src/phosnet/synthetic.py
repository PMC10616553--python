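"""Synthetic kinase-substrate priors, planted perturbations, and TMT-like
PSM reporter tables.

The generator produces data with the statistical structure the downstream
analysis assumes: a signed, site-specific prior network; a ground truth of
kinase activity changes propagated to target phosphosites; and PSM-level
reporter-ion intensity tables (one per plex) with reference-pool channels,
multiplicative (log-normal) feature abundances, Gaussian channel noise on
the log2 scale, sporadic gross outliers, and missing values. Every planted
effect, outlier, and missing cell is recorded so recovery is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import REFERENCE, TREATED, StudyDesign

RESIDUES = ("S", "T", "Y")

#: log2-scale baseline abundance distribution for features (mean, sd).
BASELINE_LOG2_MEAN = 20.0
BASELINE_LOG2_SD = 2.0


@dataclass(frozen=True)
class PriorRelation:
    """A signed, site-specific kinase->substrate relation.

    ``relation_sign`` is +1 for phosphorylates, -1 for dephosphorylates.
    ``site_effect`` says what the phosphosite does to the *target's* own
    activity: +1 activatory, -1 inhibitory, 0 unknown.
    """

    source: str
    target: str
    relation_sign: int
    target_site: str  # residue + 1-based position, e.g. "T487"
    site_effect: int

    def __post_init__(self) -> None:
        if self.relation_sign not in (+1, -1):
            raise ValueError("relation_sign must be +1 or -1")
        if self.site_effect not in (+1, -1, 0):
            raise ValueError("site_effect must be +1, -1 or 0")
        residue, pos = self.target_site[0], self.target_site[1:]
        if residue not in RESIDUES:
            raise ValueError(f"site residue must be one of {RESIDUES}: {self.target_site}")
        if not pos.isdigit() or int(pos) < 1:
            raise ValueError(f"site position must be a 1-based integer: {self.target_site}")

    @property
    def site_id(self) -> str:
        return f"{self.target}_{self.target_site}"


@dataclass
class PriorNetwork:
    relations: list[PriorRelation]

    def __post_init__(self) -> None:
        keys = [(r.source, r.target, r.target_site, r.relation_sign) for r in self.relations]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (source, target, site, sign) relation")

    def __len__(self) -> int:
        return len(self.relations)

    @property
    def kinases(self) -> list[str]:
        seen: list[str] = []
        for r in self.relations:
            if r.source not in seen:
                seen.append(r.source)
        return seen

    def targets_of(self, kinase: str) -> list[PriorRelation]:
        return [r for r in self.relations if r.source == kinase]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "relation": "phosphorylates" if r.relation_sign > 0 else "dephosphorylates",
                    "target": r.target,
                    "site": r.target_site,
                    "effect": {1: "a", -1: "i", 0: "u"}[r.site_effect],
                }
                for r in self.relations
            ],
            columns=["source", "relation", "target", "site", "effect"],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "PriorNetwork":
        df = pd.read_csv(path, sep="\t", dtype=str)
        sign = {"phosphorylates": 1, "dephosphorylates": -1}
        eff = {"a": 1, "i": -1, "u": 0}
        return cls(
            [
                PriorRelation(
                    row.source, row.target, sign[row.relation], row.site, eff[row.effect]
                )
                for row in df.itertuples()
            ]
        )


@dataclass
class GroundTruth:
    """Planted kinase activities and the expected site-level log2 changes."""

    kinase_activity: dict[str, int]  # +1 activated, -1 inactivated
    site_log2fc: dict[str, float]  # site_id -> expected log2FC (0 if absent)
    effect_size: float
    decoy_sites: list[str] = field(default_factory=list)

    def expected(self, site_id: str) -> float:
        return self.site_log2fc.get(site_id, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": list(self.site_log2fc), "expected_log2fc": list(self.site_log2fc.values())}
        )


def generate_prior_network(
    n_kinases: int,
    targets_per_kinase: int,
    frac_inhibitory: float = 0.2,
    frac_dephospho: float = 0.0,
    seed: int = 0,
) -> PriorNetwork:
    """Random signed site-specific prior with ``n_kinases * targets_per_kinase``
    relations; each target phosphosite belongs to a distinct substrate protein
    and positions are unique per protein."""
    if n_kinases < 0 or targets_per_kinase < 0:
        raise ValueError("counts must be non-negative")
    for frac in (frac_inhibitory, frac_dephospho):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    relations: list[PriorRelation] = []
    used_positions: dict[str, set[int]] = {}
    for ki in range(n_kinases):
        kinase = f"KIN{ki + 1:02d}"
        for ti in range(targets_per_kinase):
            target = f"SUB{ki + 1:02d}_{ti + 1:02d}"
            positions = used_positions.setdefault(target, set())
            while True:
                pos = int(rng.integers(1, 2000))
                if pos not in positions:
                    positions.add(pos)
                    break
            residue = RESIDUES[rng.integers(0, len(RESIDUES))]
            sign = -1 if rng.random() < frac_dephospho else 1
            effect = -1 if rng.random() < frac_inhibitory else 1
            relations.append(PriorRelation(kinase, target, sign, f"{residue}{pos}", effect))
    return PriorNetwork(relations)


def simulate_perturbation(
    network: PriorNetwork,
    perturbed: dict[str, int],
    effect_size: float,
    seed: int = 0,
) -> GroundTruth:
    """Propagate planted kinase activity changes to target sites.

    The expected log2FC of a site targeted by kinase k through a relation of
    sign sigma is sigma * a(k) * effect_size; sites of unperturbed kinases
    have expected change 0.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    kinases = set(network.kinases)
    for k, a in perturbed.items():
        if k not in kinases:
            raise KeyError(f"kinase {k!r} not in network")
        if a not in (+1, -1, 0):
            raise ValueError("activity must be +1, -1 or 0")
    site_fc: dict[str, float] = {}
    for r in network.relations:
        a = perturbed.get(r.source, 0)
        site_fc[r.site_id] = r.relation_sign * a * effect_size
    activity = {k: perturbed.get(k, 0) for k in network.kinases}
    return GroundTruth(kinase_activity=activity, site_log2fc=site_fc, effect_size=effect_size)


def add_decoy_sites(truth: GroundTruth, n_decoys: int, seed: int = 0) -> GroundTruth:
    """Add unchanged background sites on proteins outside the prior network,
    widening the measured-site universe the permutation null is drawn from."""
    rng = np.random.default_rng(seed)
    decoys = []
    for i in range(n_decoys):
        residue = RESIDUES[rng.integers(0, len(RESIDUES))]
        pos = int(rng.integers(1, 2000))
        decoys.append(f"DEC{i + 1:03d}_{residue}{pos}")
    truth.site_log2fc.update({d: 0.0 for d in decoys})
    truth.decoy_sites = list(truth.decoy_sites) + decoys
    return truth


REPORTER_COLUMNS = ["plex", "peptide", "protein", "site", "loc_prob"] + [
    f"channel_{i}" for i in range(1, 11)
]


def generate_reporter_tables(
    truth: GroundTruth,
    design: StudyDesign,
    noise_sd: float = 0.2,
    psm_per_peptide: int = 3,
    outlier_rate: float = 0.0,
    outlier_shift: float = 4.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    protein_peptides: int = 3,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate per-plex PSM reporter tables carrying the planted effects.

    Each phosphosite yields one phosphopeptide; each substrate protein also
    yields ``protein_peptides`` unmodified peptides so protein-level
    quantification (and phosphosite-to-protein adjustment) is exercised.
    Treated channels carry the ground-truth site effect; reference channels
    are the within-plex geometric mean of the eight sample channels plus
    channel noise. Outliers hit one random sample channel of an affected PSM
    row (an isolated reporter-ion spike); missing cells are erased uniformly.

    Returns the list of per-plex tables and a truth table recording every
    expected effect, planted outlier, and missing cell.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if psm_per_peptide < 1:
        raise ValueError("psm_per_peptide must be >= 1")
    for rate in (outlier_rate, missing_rate):
        if not 0.0 <= rate < 1.0:
            raise ValueError("rates must lie in [0, 1)")
    if len(design.plexes) < 1:
        raise ValueError("design must contain at least one plex")

    rng = np.random.default_rng(seed)

    # feature catalogue: (peptide, protein, site or None, expected fc)
    features: list[tuple[str, str, str | None, float]] = []
    proteins: list[str] = []
    for site_id, fc in truth.site_log2fc.items():
        protein, site = site_id.rsplit("_", 1)
        features.append((f"pep_{site_id}", protein, site, fc))
        if protein not in proteins:
            proteins.append(protein)
    for protein in proteins:
        for j in range(protein_peptides):
            features.append((f"pep_{protein}_tot{j + 1}", protein, None, 0.0))

    n_feat = len(features)
    baseline = rng.normal(BASELINE_LOG2_MEAN, BASELINE_LOG2_SD, size=n_feat)
    # localization probabilities: mostly confident, a tail of ambiguous sites
    loc_prob = np.where(
        rng.random(n_feat) < 0.9,
        rng.uniform(0.9, 1.0, size=n_feat),
        rng.uniform(0.3, 0.75, size=n_feat),
    )

    tables: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for plex in design.plexes:
        sample_ch = plex.sample_channels
        ref_ch = plex.reference_channels
        n_rows = n_feat * psm_per_peptide
        rows = {
            "plex": np.repeat(plex.plex_id, n_rows),
            "peptide": np.repeat([f[0] for f in features], psm_per_peptide),
            "protein": np.repeat([f[1] for f in features], psm_per_peptide),
            "site": np.repeat([f[2] if f[2] is not None else "" for f in features], psm_per_peptide),
            "loc_prob": np.repeat(
                [loc_prob[i] if features[i][2] is not None else np.nan for i in range(n_feat)],
                psm_per_peptide,
            ),
        }
        base_psm = np.repeat(baseline, psm_per_peptide) + rng.normal(0, 0.3, n_rows)
        expected = np.repeat([f[3] for f in features], psm_per_peptide)

        log2_sample = np.empty((n_rows, len(sample_ch)))
        for j, ch in enumerate(sample_ch):
            effect = expected if ch.role == TREATED else 0.0
            log2_sample[:, j] = base_psm + effect + rng.normal(0, noise_sd, n_rows)

        # reference pool reflects the underlying abundances, so it is formed
        # before measurement artifacts are planted
        log2_ref = np.empty((n_rows, len(ref_ch)))
        pooled = log2_sample.mean(axis=1)  # geometric mean on the raw scale
        for j in range(len(ref_ch)):
            log2_ref[:, j] = pooled + rng.normal(0, noise_sd, n_rows)

        # gross outliers: one random sample channel per affected PSM row
        if outlier_rate > 0:
            hit = rng.random(n_rows) < outlier_rate
            cols = rng.integers(0, len(sample_ch), size=n_rows)
            signs = np.where(rng.random(n_rows) < 0.5, 1.0, -1.0)
            for i in np.flatnonzero(hit):
                log2_sample[i, cols[i]] += signs[i] * outlier_shift
                truth_rows.append(
                    {
                        "kind": "outlier",
                        "plex": plex.plex_id,
                        "row": int(i),
                        "peptide": rows["peptide"][i],
                        "channel": sample_ch[cols[i]].index,
                        "shift": signs[i] * outlier_shift,
                    }
                )

        intens = np.empty((n_rows, 10))
        for j, ch in enumerate(sample_ch):
            intens[:, ch.index - 1] = 2.0 ** log2_sample[:, j]
        for j, ch in enumerate(ref_ch):
            intens[:, ch.index - 1] = 2.0 ** log2_ref[:, j]

        if missing_rate > 0:
            miss = rng.random(intens.shape) < missing_rate
            intens[miss] = np.nan
            for i, j in zip(*np.nonzero(miss)):
                truth_rows.append(
                    {
                        "kind": "missing",
                        "plex": plex.plex_id,
                        "row": int(i),
                        "peptide": rows["peptide"][i],
                        "channel": int(j) + 1,
                        "shift": np.nan,
                    }
                )

        table = pd.DataFrame(rows)
        for c in range(10):
            table[f"channel_{c + 1}"] = intens[:, c]
        tables.append(table[REPORTER_COLUMNS])

    for site_id, fc in truth.site_log2fc.items():
        protein, site = site_id.rsplit("_", 1)
        truth_rows.append(
            {
                "kind": "effect",
                "plex": "",
                "row": -1,
                "peptide": f"pep_{site_id}",
                "channel": -1,
                "shift": fc,
            }
        )
    truth_table = pd.DataFrame(
        truth_rows, columns=["kind", "plex", "row", "peptide", "channel", "shift"]
    )
    return tables, truth_table


def write_reporter_tables(tables: list[pd.DataFrame], paths) -> None:
    for table, path in zip(tables, paths):
        table.to_csv(path, sep="\t", index=False, na_rep="")


def read_reporter_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"plex": str, "peptide": str, "protein": str})
    df["site"] = df["site"].fillna("")
    return df
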