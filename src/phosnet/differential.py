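"""Per-feature differential statistics between treated and vehicle samples.

The model is a per-feature two-group comparison with empirical-Bayes
variance moderation: the pooled residual variance s^2 (d residual df) is
shrunk toward a prior variance s0^2 with d0 prior df estimated from the
ensemble of all features' variances by moment matching on log s^2, and the
moderated t = b / (s_post * sqrt(1/n_t + 1/n_v)) is referred to a
t-distribution with d0 + d degrees of freedom. Benjamini-Hochberg controls
the FDR; phosphosites are normalized to their parent protein's change; the
significance filters combine the FDR cutoff, an absolute log2FC threshold
(0.58, i.e. +/-50%), a site-localization probability floor, and the
requirement of protein-level quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .design import TREATED, VEHICLE, StudyDesign
from .tmt import PHOSPHOSITE, QuantMatrix


@dataclass(frozen=True)
class FilterConfig:
    fdr_threshold: float = 0.05
    abs_log2fc_threshold: float = 0.58
    min_localization_probability: float = 0.75
    require_protein_quant: bool = True

    def __post_init__(self) -> None:
        if min(self.fdr_threshold, self.abs_log2fc_threshold, self.min_localization_probability) <= 0:
            raise ValueError("thresholds must be positive")


def log2fc_threshold(fold_change_fraction: float = 0.5) -> float:
    """log2-scale threshold equivalent to a +/-``fold_change_fraction``
    change, rounded to 2 decimals: 50% -> log2(1.5) -> 0.58."""
    return round(float(np.log2(1.0 + fold_change_fraction)), 2)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior_variance(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the observed sample variances.

    Under the hierarchical model, log s^2 - log s0^2 is a log-F variate;
    matching the mean and excess variance of z = log s^2 on the digamma /
    trigamma scale yields d0 (possibly infinite) and s0^2. Features with
    zero residual df are excluded.
    """
    ok = (df > 0) & np.isfinite(s2) & (s2 > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        return np.inf, float(np.median(s2)) if len(s2) else 1.0
    z = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    e_var = np.var(z, ddof=1) - np.mean(special.polygamma(1, df / 2))
    if e_var <= 0:
        d0 = np.inf
        s0_log = np.mean(z)
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_log = np.mean(z) + special.digamma(d0 / 2) - np.log(d0 / 2)
    return float(d0), float(np.exp(s0_log))


def moderated_t_stat(
    b: float, s2: float, d: float, s0_sq: float, d0: float, c: float
) -> tuple[float, float, float]:
    """Moderated t, its df, and the two-sided p for one feature."""
    if np.isinf(d0):
        s_post2 = s0_sq
        df_total = np.inf
    else:
        s_post2 = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    t = b / np.sqrt(s_post2 * c)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(abs(t))
    else:
        p = 2 * stats.t.sf(abs(t), df_total)
    return float(t), float(df_total), float(p)


def fit_moderated_t(
    matrix: QuantMatrix,
    design: StudyDesign,
    cell_line: str | None = None,
    moderate: bool = True,
) -> pd.DataFrame:
    """Treated-vs-vehicle moderated-t table for every feature with at least
    two non-missing replicates per condition (others are skipped).

    When ``cell_line`` is given only that plex's samples enter the contrast
    (each cell line is analyzed separately). ``moderate=False`` gives the
    ordinary two-sample t (d0 = 0 limit).
    """
    samples = design.samples
    if cell_line is not None:
        samples = [s for s in samples if design.cell_line_of(s.sample_id) == cell_line]
    t_cols = [s.sample_id for s in samples if s.role == TREATED and s.sample_id in matrix.values.columns]
    v_cols = [s.sample_id for s in samples if s.role == VEHICLE and s.sample_id in matrix.values.columns]
    if not t_cols or not v_cols:
        raise ValueError("design provides no treated/vehicle samples for this matrix")

    T = matrix.values[t_cols].to_numpy(dtype=float)
    V = matrix.values[v_cols].to_numpy(dtype=float)
    nt = np.isfinite(T).sum(axis=1)
    nv = np.isfinite(V).sum(axis=1)
    usable = (nt >= 2) & (nv >= 2)

    mt = np.nanmean(np.where(np.isfinite(T), T, np.nan), axis=1)
    mv = np.nanmean(np.where(np.isfinite(V), V, np.nan), axis=1)
    b = mt - mv
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Degrees of freedom")
        vt = np.nanvar(T, axis=1, ddof=1)
        vv = np.nanvar(V, axis=1, ddof=1)
    d = nt + nv - 2.0
    s2 = np.where(usable, ((nt - 1) * vt + (nv - 1) * vv) / np.maximum(d, 1), np.nan)
    c = 1.0 / np.maximum(nt, 1) + 1.0 / np.maximum(nv, 1)

    if moderate:
        d0, s0_sq = estimate_prior_variance(s2[usable], d[usable])
    else:
        d0, s0_sq = 0.0, 1.0

    rows = []
    for i, feat in enumerate(matrix.values.index):
        if not usable[i]:
            continue
        if d0 == 0.0:
            s_post2, df_total = s2[i], d[i]
            t = b[i] / np.sqrt(s_post2 * c[i]) if s_post2 > 0 else np.nan
            p = 2 * stats.t.sf(abs(t), df_total) if np.isfinite(t) else np.nan
        else:
            t, df_total, p = moderated_t_stat(b[i], s2[i], d[i], s0_sq, d0, c[i])
            s_post2 = s0_sq if np.isinf(d0) else (d0 * s0_sq + d[i] * s2[i]) / (d0 + d[i])
        rows.append(
            {
                "feature": feat,
                "level": matrix.level,
                "b": b[i],
                "se": float(np.sqrt(s_post2 * c[i])),
                "df": df_total if np.isfinite(df_total) else np.inf,
                "residual_df": d[i],
                "t": t,
                "p": p,
            }
        )
    res = pd.DataFrame(
        rows, columns=["feature", "level", "b", "se", "df", "residual_df", "t", "p"]
    )
    if len(res):
        res["adj_p"] = bh_adjust(res["p"].to_numpy())
    else:
        res["adj_p"] = pd.Series(dtype=float)
    res.attrs["d0"] = d0
    res.attrs["s0_sq"] = s0_sq
    res.attrs["n_skipped"] = int((~usable).sum())
    if matrix.level == PHOSPHOSITE:
        if matrix.loc_prob is not None:
            res["loc_prob"] = matrix.loc_prob.reindex(res["feature"]).to_numpy()
        if matrix.protein_of is not None:
            res["protein"] = matrix.protein_of.reindex(res["feature"]).to_numpy()
    return res


def adjust_phospho_for_protein(
    site_results: pd.DataFrame, protein_results: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Normalize phosphosite changes to the parent protein's abundance change.

    adjusted b = b_site - b_protein; SE combines in quadrature; the df comes
    from the Satterthwaite approximation; p-values are recomputed and re-BH
    adjusted. Sites whose parent protein lacks quantification are removed
    and counted.
    """
    prot = protein_results.set_index("feature")
    rows = []
    n_removed = 0
    for row in site_results.itertuples():
        parent = getattr(row, "protein", None)
        if parent is None or parent not in prot.index:
            n_removed += 1
            continue
        pr = prot.loc[parent]
        b = row.b - pr.b
        se = float(np.sqrt(row.se**2 + pr.se**2))
        if np.isinf(row.df) or np.isinf(pr.df):
            df = np.inf
        else:
            df = se**4 / (row.se**4 / row.df + pr.se**4 / pr.df)
        t = b / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(t)) if np.isinf(df) else 2 * stats.t.sf(abs(t), df)
        rows.append(
            {
                "feature": row.feature,
                "level": row.level,
                "b": b,
                "se": se,
                "df": df,
                "t": t,
                "p": float(p),
                "loc_prob": getattr(row, "loc_prob", np.nan),
                "protein": parent,
            }
        )
    out = pd.DataFrame(
        rows, columns=["feature", "level", "b", "se", "df", "t", "p", "loc_prob", "protein"]
    )
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    else:
        out["adj_p"] = pd.Series(dtype=float)
    out.attrs["n_removed_no_protein"] = n_removed
    return out, n_removed


def apply_significance_filters(
    results: pd.DataFrame, cfg: FilterConfig = FilterConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag significant features and build the volcano table.

    A feature is significant iff adjusted p < fdr_threshold and
    |b| > abs_log2fc_threshold; at site level it must additionally have
    localization probability >= the floor (sites below it are removed before
    flagging) and, when required, a quantified parent protein. Direction is
    sign(b) for significant features and 0 otherwise.
    """
    res = results.copy()
    site_level = "loc_prob" in res.columns and res["level"].eq(PHOSPHOSITE).any()
    res["filtered_reason"] = ""
    if site_level:
        low_loc = res["loc_prob"].notna() & (res["loc_prob"] < cfg.min_localization_probability)
        res.loc[low_loc, "filtered_reason"] = "low_localization"
        if cfg.require_protein_quant and "protein" in res.columns:
            no_prot = res["protein"].isna()
            res.loc[no_prot, "filtered_reason"] = "no_protein_quant"
    testable = res["filtered_reason"] == ""
    sig = (
        testable
        & (res["adj_p"] < cfg.fdr_threshold)
        & (res["b"].abs() > cfg.abs_log2fc_threshold)
    )
    res["significant"] = sig
    res["direction"] = np.where(sig, np.sign(res["b"]).astype(int), 0)
    volcano = pd.DataFrame(
        {
            "feature": res["feature"],
            "b": res["b"],
            "neg_log10_adj_p": -np.log10(res["adj_p"].clip(lower=1e-300)),
            "significant": res["significant"],
            "direction": res["direction"],
        }
    )
    return res, volcano
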