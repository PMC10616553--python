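"""Reporter-ion quantification: PSM log2 ratios against the in-plex
reference pool, recursive Dixon outlier removal, median rollup to peptides
and then proteins/phosphosites, mixture-model mode alignment, trimmed
scaling normalization, and classical metric MDS of the samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar
from sklearn.mixture import GaussianMixture

from .design import StudyDesign

log = logging.getLogger(__name__)

PROTEIN = "protein"
PHOSPHOSITE = "phosphosite"

# Dixon r10 two-sided critical values at alpha = 0.05, n = 3..30
# (Rorabacher 1991, 95% confidence).
DIXON_Q95 = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493,
    10: 0.466, 11: 0.444, 12: 0.426, 13: 0.410, 14: 0.396, 15: 0.384,
    16: 0.374, 17: 0.365, 18: 0.356, 19: 0.349, 20: 0.342, 21: 0.337,
    22: 0.331, 23: 0.326, 24: 0.321, 25: 0.317, 26: 0.312, 27: 0.308,
    28: 0.305, 29: 0.301, 30: 0.298,
}


@dataclass
class MixtureModel:
    """Two-component Gaussian mixture fitted to one sample's log ratios."""

    weight: float  # mixing weight of component 1
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    shift: float  # density mode subtracted from the sample
    converged: bool = True
    fallback: bool = False

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        d1 = np.exp(-0.5 * ((x - self.mu1) / self.sigma1) ** 2) / (
            self.sigma1 * np.sqrt(2 * np.pi)
        )
        d2 = np.exp(-0.5 * ((x - self.mu2) / self.sigma2) ** 2) / (
            self.sigma2 * np.sqrt(2 * np.pi)
        )
        return self.weight * d1 + (1.0 - self.weight) * d2


@dataclass
class QuantMatrix:
    """Features x samples of normalized log2 ratios at one rollup level."""

    level: str  # protein | phosphosite
    values: pd.DataFrame  # index = feature id, columns = sample ids
    design: StudyDesign
    intensity: pd.DataFrame | None = None  # mean log2 reference intensity
    loc_prob: pd.Series | None = None  # site-level localization probability
    protein_of: pd.Series | None = None  # site -> parent protein group
    scale_factors: pd.Series | None = None
    mixtures: dict[str, MixtureModel] = field(default_factory=dict)

    def write(self, path, config_hash: str | None = None) -> None:
        with open(path, "w") as fh:
            if config_hash:
                fh.write(f"# config_hash={config_hash}\n")
            out = self.values.copy()
            out.insert(0, "level", self.level)
            out.to_csv(fh, sep="\t", index_label="feature")


def compute_log_ratios(
    table: pd.DataFrame, design: StudyDesign
) -> tuple[pd.DataFrame, int]:
    """PSM-level log2 ratios relative to the in-plex reference pool.

    value(sample) = log2(intensity) - mean(log2 of the reference channels):
    the denominator is the geometric mean of the reference intensities.
    Rows with no positive reference intensity are dropped and counted.
    Output columns: plex, peptide, protein, site, loc_prob, ref_log2
    (the intensity covariate used later for trimmed scaling), then one
    column per sample id; reference columns are removed.
    """
    pieces: list[pd.DataFrame] = []
    n_dropped = 0
    plex_map = {p.plex_id: p for p in design.plexes}
    for plex_id, sub in table.groupby("plex", sort=False):
        plex = plex_map[str(plex_id)]
        ref_cols = [f"channel_{c.index}" for c in plex.reference_channels]
        ref = sub[ref_cols].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ref_log2 = np.log2(np.where(ref > 0, ref, np.nan))
        ok = np.isfinite(ref_log2).any(axis=1)
        n_dropped += int((~ok).sum())
        sub = sub.loc[ok]
        ref_mean = np.nanmean(ref_log2[ok], axis=1)
        out = sub[["plex", "peptide", "protein", "site", "loc_prob"]].copy()
        out["ref_log2"] = ref_mean
        for ch in plex.sample_channels:
            inten = sub[f"channel_{ch.index}"].to_numpy(dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                val = np.log2(np.where(inten > 0, inten, np.nan))
            out[ch.sample_id] = val - ref_mean
        pieces.append(out)
    if n_dropped:
        log.info("compute_log_ratios: dropped %d rows without reference signal", n_dropped)
    result = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame()
    return result, n_dropped


def dixon_outlier_filter(values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Recursively remove the most extreme value while Dixon's Q exceeds the
    critical value; returns a boolean mask of retained entries.

    Q = (gap of the more extreme end) / range, tested against the two-sided
    alpha = 0.05 r10 table for n in 3..30. For n > 30 the Q table runs out
    and values beyond 3 x MAD of the median are trimmed instead. Inputs with
    n < 3 or zero range are returned unchanged.
    """
    if alpha != 0.05:
        raise ValueError("only the alpha = 0.05 critical table is provided")
    values = np.asarray(values, dtype=float)
    keep = np.ones(len(values), dtype=bool)
    if len(values) > 30:
        med = np.median(values)
        mad = np.median(np.abs(values - med)) * 1.4826
        if mad > 0:
            keep = np.abs(values - med) <= 3 * mad
        return keep
    active = list(np.flatnonzero(keep))
    while len(active) >= 3:
        vals = values[active]
        order = np.argsort(vals, kind="stable")
        v = vals[order]
        rng = v[-1] - v[0]
        if rng == 0:
            break
        gap_low = v[1] - v[0]
        gap_high = v[-1] - v[-2]
        q = max(gap_low, gap_high) / rng
        if q <= DIXON_Q95[len(v)]:
            break
        pos = order[0] if gap_low > gap_high else order[-1]
        keep[active[pos]] = False
        active.pop(pos)
    return keep


def _median_rollup(
    frame: pd.DataFrame,
    group_cols: list[str],
    sample_ids: list[str],
    dixon: bool,
) -> pd.DataFrame:
    """Per-sample median of grouped values, optionally after Dixon removal
    (applied per group per sample when more than two values are present)."""
    if not dixon:
        return frame.groupby(group_cols, sort=False)[sample_ids].median()

    def agg(col: pd.Series) -> float:
        x = col.dropna().to_numpy()
        if len(x) == 0:
            return np.nan
        if len(x) >= 3:
            x = x[dixon_outlier_filter(x)]
        return float(np.median(x))

    return frame.groupby(group_cols, sort=False)[sample_ids].agg(agg)


def collapse_features(
    psm_ratios: pd.DataFrame, design: StudyDesign, dixon: bool = True
) -> dict[str, QuantMatrix]:
    """Roll PSM ratios up to peptides (median of PSMs after Dixon removal)
    and then to proteins and phosphosites (median of peptides).

    Unmodified peptides aggregate per protein group; phosphopeptides
    aggregate per (protein, site). Returns {"protein": ..., "phosphosite": ...}.
    """
    out: dict[str, QuantMatrix] = {}
    sample_ids = [s for s in design.sample_ids if s in psm_ratios.columns]
    if psm_ratios.empty:
        for level in (PROTEIN, PHOSPHOSITE):
            out[level] = QuantMatrix(level, pd.DataFrame(columns=sample_ids), design)
        return out
    is_phospho = psm_ratios["site"].fillna("").astype(str) != ""

    for level, sub in ((PROTEIN, psm_ratios[~is_phospho]), (PHOSPHOSITE, psm_ratios[is_phospho])):
        if sub.empty:
            out[level] = QuantMatrix(level, pd.DataFrame(columns=sample_ids), design)
            continue
        pep = _median_rollup(sub, ["peptide"], sample_ids, dixon=dixon)
        pep_meta = sub.drop_duplicates("peptide").set_index("peptide")
        pep = pep.join(pep_meta[["protein", "site", "loc_prob"]])
        pep_int = sub.groupby("peptide", sort=False)["ref_log2"].median()
        pep = pep.join(pep_int)

        if level == PROTEIN:
            feat = pep.groupby("protein", sort=False)[sample_ids].median()
            inten = pep.groupby("protein", sort=False)["ref_log2"].median()
            qm = QuantMatrix(level, feat, design, intensity=inten.to_frame("ref_log2"))
        else:
            pep["feature"] = pep["protein"].astype(str) + "_" + pep["site"].astype(str)
            feat = pep.groupby("feature", sort=False)[sample_ids].median()
            inten = pep.groupby("feature", sort=False)["ref_log2"].median()
            locp = pep.groupby("feature", sort=False)["loc_prob"].max()
            parent = pep.drop_duplicates("feature").set_index("feature")["protein"]
            qm = QuantMatrix(
                level,
                feat,
                design,
                intensity=inten.to_frame("ref_log2"),
                loc_prob=locp,
                protein_of=parent.reindex(feat.index),
            )
        qm.values.index.name = "feature"
        out[level] = qm
    return out


def _fit_mixture_1d(x: np.ndarray) -> GaussianMixture:
    """Two-component Gaussian mixture by EM, initialized by a 25th/90th
    percentile split (tol 1e-8, <=500 iterations, variance floor 1e-6)."""
    q25, q90 = np.percentile(x, [25, 90])
    centers = np.array([q25, q90])
    assign = np.abs(x[:, None] - centers[None, :]).argmin(axis=1)
    means, variances, weights = [], [], []
    for k in (0, 1):
        grp = x[assign == k]
        if len(grp) < 2:
            grp = x
        means.append(grp.mean())
        variances.append(max(grp.var(), 1e-6))
        weights.append(max(len(x[assign == k]), 1) / len(x))
    weights = np.array(weights) / np.sum(weights)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="spherical",
        tol=1e-8,
        max_iter=500,
        reg_covar=1e-6,
        weights_init=weights,
        means_init=np.array(means)[:, None],
        precisions_init=1.0 / np.array(variances),
    )
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    with _warnings.catch_warnings():
        # non-convergence is handled by the caller's median/MAD fallback
        _warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(x[:, None])
    return gm


def _mixture_mode(model: MixtureModel) -> float:
    """Global mode of the fitted density: dense grid then bounded refinement."""
    lo = min(model.mu1 - 4 * model.sigma1, model.mu2 - 4 * model.sigma2)
    hi = max(model.mu1 + 4 * model.sigma1, model.mu2 + 4 * model.sigma2)
    grid = np.linspace(lo, hi, 2001)
    dens = model.density(grid)
    i = int(np.argmax(dens))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    if a == b:
        return float(grid[i])
    res = minimize_scalar(lambda t: -model.density(t), bounds=(a, b), method="bounded")
    return float(res.x)


def fit_sample_mixture(x: np.ndarray) -> MixtureModel:
    """Fit the two-component mixture to one sample's log ratios and locate
    the density mode; falls back to median/MAD when the sample is too small,
    degenerate, or EM does not converge."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 30 or np.ptp(x) == 0:
        med = float(np.median(x)) if len(x) else 0.0
        mad = float(np.median(np.abs(x - med)) * 1.4826) if len(x) else 1.0
        return MixtureModel(1.0, med, med, max(mad, 1e-3), max(mad, 1e-3), med, fallback=True)
    try:
        gm = _fit_mixture_1d(x)
        converged = bool(gm.converged_)
    except Exception:  # numerical failure -> robust fallback
        converged = False
    if not converged:
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)) * 1.4826)
        log.warning("mixture EM did not converge; falling back to median/MAD")
        return MixtureModel(1.0, med, med, max(mad, 1e-3), max(mad, 1e-3), med, fallback=True)
    sig = np.sqrt(np.maximum(gm.covariances_, 1e-6))
    model = MixtureModel(
        weight=float(gm.weights_[0]),
        mu1=float(gm.means_[0, 0]),
        mu2=float(gm.means_[1, 0]),
        sigma1=float(max(sig[0], 1e-3)),
        sigma2=float(max(sig[1], 1e-3)),
        shift=0.0,
    )
    model.shift = _mixture_mode(model)
    return model


def _trimmed_sd(x: np.ndarray, intensity: np.ndarray | None) -> float:
    """SD over values inside the 5th-95th percentile band of the log ratios
    and (when available) of the reporter intensities."""
    ok = np.isfinite(x)
    x = x[ok]
    if len(x) < 3:
        return 1.0
    lo, hi = np.percentile(x, [5, 95])
    band = (x >= lo) & (x <= hi)
    if intensity is not None:
        inten = intensity[ok]
        fin = np.isfinite(inten)
        if fin.sum() >= 3:
            ilo, ihi = np.percentile(inten[fin], [5, 95])
            band &= np.where(fin, (inten >= ilo) & (inten <= ihi), True)
    if band.sum() < 3:
        band = np.ones(len(x), dtype=bool)
    sd = float(np.std(x[band], ddof=1))
    return sd if sd > 0 else 1.0


def align_and_scale(matrix: QuantMatrix) -> QuantMatrix:
    """Center each sample at its fitted mixture-density mode, then scale.

    Per sample the two-component mixture is fitted and the density mode
    subtracted ("maximum likelihood centered at zero"). Scaling standardizes
    the samples jointly: each sample is divided by its trimmed SD (values
    within the 5th-95th percentile of both log ratios and intensities) and
    multiplied by the geometric mean of all samples' trimmed SDs, so the
    average spread is preserved.
    """
    values = matrix.values.copy()
    intensity = matrix.intensity["ref_log2"] if matrix.intensity is not None else None
    mixtures: dict[str, MixtureModel] = {}
    sds: dict[str, float] = {}
    for sample in values.columns:
        x = values[sample].to_numpy(dtype=float)
        model = fit_sample_mixture(x)
        mixtures[sample] = model
        values[sample] = x - model.shift
        inten = intensity.reindex(values.index).to_numpy() if intensity is not None else None
        sds[sample] = _trimmed_sd(values[sample].to_numpy(dtype=float), inten)
    gmean_sd = float(np.exp(np.mean(np.log(list(sds.values()))))) if sds else 1.0
    scale = pd.Series({s: sd / gmean_sd for s, sd in sds.items()})
    for sample in values.columns:
        if not mixtures[sample].fallback:
            values[sample] = values[sample] / scale[sample]
        # degenerate/fallback samples keep scale 1
    scale[[s for s in values.columns if mixtures[s].fallback]] = 1.0
    return QuantMatrix(
        matrix.level,
        values,
        matrix.design,
        intensity=matrix.intensity,
        loc_prob=matrix.loc_prob,
        protein_of=matrix.protein_of,
        scale_factors=scale,
        mixtures=mixtures,
    )


def normalization_report(matrix: QuantMatrix) -> pd.DataFrame:
    rows = []
    for sample, m in matrix.mixtures.items():
        rows.append(
            {
                "sample": sample,
                "shift": m.shift,
                "scale": matrix.scale_factors[sample] if matrix.scale_factors is not None else 1.0,
                "pi": m.weight,
                "mu1": m.mu1,
                "mu2": m.mu2,
                "sigma1": m.sigma1,
                "sigma2": m.sigma2,
                "fallback": m.fallback,
            }
        )
    return pd.DataFrame(rows)


def mds_embed(matrix: QuantMatrix, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS of the samples.

    Pairwise Euclidean distances are computed on complete-case features,
    the squared-distance matrix is double-centered, and the top-k
    eigenvectors scaled by sqrt(eigenvalue) give the coordinates (defined
    up to sign and rotation).
    """
    complete = matrix.values.dropna(axis=0)
    samples = list(matrix.values.columns)
    n = len(samples)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}]")
    if complete.empty:
        raise ValueError("no complete-case features for MDS")
    X = complete.to_numpy(dtype=float).T  # samples x features
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    w, v = eigh(B)
    order = np.argsort(w)[::-1][:k]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    return pd.DataFrame(coords, index=samples, columns=[f"dim{i + 1}" for i in range(k)])
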