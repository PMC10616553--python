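"""Site-specific PTM signature enrichment (PTM-SEA style).

Signatures are sets of phosphosites (GENE_residuePosition) optionally
annotated with an expected direction: "u" members go up and "d" members go
down when the signature's kinase/perturbation is active. Scoring is the
weighted Kolmogorov-Smirnov running sum over the full ranked site list:
"d" members have their signed statistic flipped before ranking, hits add
|stat|^w normalized by the total hit weight, misses subtract 1/(N - N_hits),
and the enrichment score (ES) is the running-sum value of maximal absolute
deviation (ties resolved toward the positive extreme). Significance comes
from site-label permutation; NES divides ES by the mean |null ES| of the
same sign.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import bh_adjust

DEFAULT_WEIGHT = 0.75

_SITE_RE = re.compile(r"^\S+_[STY]\d+$")


@dataclass
class SignatureSet:
    name: str
    category: str  # kinase | perturbation | pathway
    members: list[tuple[str, str | None]]  # (site id, "u" | "d" | None)

    def __post_init__(self) -> None:
        ids = [m[0] for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate member site in signature {self.name}")
        if not self.members:
            raise ValueError(f"signature {self.name} is empty")


def load_signatures(path, category: str = "kinase") -> list[SignatureSet]:
    """Read a GMT-dialect file: name, description, then members as
    "SITE;u", "SITE;d" or bare "SITE". Unparseable lines are rejected with
    their line numbers; an empty file is an error."""
    sets: list[SignatureSet] = []
    rejected: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                rejected.append(lineno)
                continue
            name, _desc, *raw_members = fields
            members: list[tuple[str, str | None]] = []
            ok = True
            for m in raw_members:
                if not m:
                    continue
                if ";" in m:
                    site, direction = m.rsplit(";", 1)
                    if direction not in ("u", "d"):
                        ok = False
                        break
                else:
                    site, direction = m, None
                if not _SITE_RE.match(site):
                    ok = False
                    break
                members.append((site, direction))
            if not ok or not members:
                rejected.append(lineno)
                continue
            sets.append(SignatureSet(name=name, category=category, members=members))
    if rejected:
        warnings.warn(f"rejected unparseable GMT lines: {rejected}", stacklevel=2)
    if not sets:
        raise ValueError(f"no valid signatures in {path}")
    return sets


def _resolve_members(stats: dict[str, float], sset: SignatureSet) -> dict[str, int]:
    """Matched members mapped to a sign multiplier (+1, or -1 for "d").
    Sites annotated both u and d in the same set are excluded with a warning."""
    seen: dict[str, set[str | None]] = {}
    for site, direction in sset.members:
        if site in stats:
            seen.setdefault(site, set()).add(direction)
    out: dict[str, int] = {}
    for site, dirs in seen.items():
        if "u" in dirs and "d" in dirs:
            warnings.warn(f"site {site} is both 'u' and 'd' in {sset.name}; excluded", stacklevel=2)
            continue
        out[site] = -1 if "d" in dirs else 1
    return out


def score_enrichment(stats: dict[str, float], sset: SignatureSet, w: float = DEFAULT_WEIGHT) -> float:
    """Weighted-KS enrichment score of one signature over the ranked sites."""
    if not stats:
        raise ValueError("empty statistic map")
    flips = _resolve_members(stats, sset)
    if not flips:
        raise ValueError(f"no members of {sset.name} are measured")
    sites = list(stats)
    values = np.array([stats[s] * flips.get(s, 1) for s in sites])
    is_hit = np.array([s in flips for s in sites])
    return _running_sum_es(values, is_hit, w)


def _running_sum_es(values: np.ndarray, is_hit: np.ndarray, w: float) -> float:
    """ES over a ranked list: descending by value, stable within ties."""
    order = np.argsort(-values, kind="stable")
    v = values[order]
    hit = is_hit[order]
    n = len(v)
    n_hit = int(hit.sum())
    if n_hit == n:
        return 0.0
    weights = np.where(hit, np.abs(v) ** w, 0.0)
    total = weights.sum()
    if total == 0:
        weights = hit.astype(float)
        total = weights.sum()
    step = np.where(hit, weights / total, -1.0 / (n - n_hit))
    running = np.cumsum(step)
    i_max = int(np.argmax(np.abs(running)))
    peak = running[i_max]
    # ties between equal positive and negative deviations resolve positive
    if peak < 0 and np.isclose(running.max(initial=-np.inf), -peak):
        peak = -peak
    return float(peak)


def _null_es_fixed_ranking(
    sorted_abs_w: np.ndarray, n: int, n_hit: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution for sets without directional members: the
    ranking is fixed, so each permutation just redraws the hit positions."""
    if n_hit >= n:
        return np.zeros(B)
    out = np.empty(B)
    miss_step = 1.0 / (n - n_hit)
    for b in range(B):
        pos = np.sort(rng.choice(n, size=n_hit, replace=False))
        wts = sorted_abs_w[pos]
        total = wts.sum()
        if total == 0:
            wts = np.ones(n_hit)
            total = float(n_hit)
        cum = np.cumsum(wts) / total
        # candidate extrema just before and just after each hit
        before = cum - wts / total - (pos - np.arange(n_hit)) * miss_step
        after = cum - (pos + 1 - np.arange(1, n_hit + 1)) * miss_step
        cand = np.concatenate([before, after])
        i = int(np.argmax(np.abs(cand)))
        peak = cand[i]
        if peak < 0 and np.isclose(cand.max(initial=-np.inf), -peak):
            peak = -peak
        out[b] = peak
    return out


def permute_enrichment(
    stats: dict[str, float],
    sets: list[SignatureSet],
    w: float = DEFAULT_WEIGHT,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Site-label permutation test for a collection of signatures.

    p = (#{same-sign null with |ES_null| >= |ES|} + 1) / (B_same_sign + 1);
    NES = ES / mean(|null ES| of the same sign); BH across signatures.
    Signatures with no measured members are skipped and counted in
    ``result.attrs["n_unmatched"]``.
    """
    if B < 1000:
        raise ValueError("use at least 1000 permutations")
    rng = np.random.default_rng(seed)
    sites = list(stats)
    raw = np.array([stats[s] for s in sites])
    n = len(sites)
    rows = []
    n_unmatched = 0
    for sset in sets:
        flips = _resolve_members(stats, sset)
        if not flips:
            n_unmatched += 1
            continue
        values = np.array([stats[s] * flips.get(s, 1) for s in sites])
        is_hit = np.array([s in flips for s in sites])
        es = _running_sum_es(values, is_hit, w)
        n_hit = int(is_hit.sum())
        any_flip = any(f < 0 for f in flips.values())
        if not any_flip:
            order = np.argsort(-raw, kind="stable")
            null = _null_es_fixed_ranking(np.abs(raw[order]) ** w, n, n_hit, B, rng)
        else:
            n_down = sum(f < 0 for f in flips.values())
            null = np.empty(B)
            for b in range(B):
                pos = rng.choice(n, size=n_hit, replace=False)
                vals_b = raw.copy()
                flip_pos = pos[:n_down]
                vals_b[flip_pos] = -vals_b[flip_pos]
                hit_b = np.zeros(n, dtype=bool)
                hit_b[pos] = True
                null[b] = _running_sum_es(vals_b, hit_b, w)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        b_same = len(same)
        n_ge = int((np.abs(same) >= abs(es)).sum())
        p = (n_ge + 1) / (b_same + 1)
        denom = np.mean(np.abs(same)) if b_same else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        rows.append(
            {
                "name": sset.name,
                "category": sset.category,
                "ES": es,
                "NES": nes,
                "p": p,
                "n_matched": n_hit,
                "w": w,
            }
        )
    result = pd.DataFrame(rows, columns=["name", "category", "ES", "NES", "p", "n_matched", "w"])
    if len(result):
        result["adj_p"] = bh_adjust(result["p"].to_numpy())
    else:
        result["adj_p"] = pd.Series(dtype=float)
    result.attrs["n_unmatched"] = n_unmatched
    result.attrs["B"] = B
    result.attrs["seed"] = seed
    result.attrs["ranking"] = "signed statistic, descending"
    return result


def signatures_from_prior(prior_frame: pd.DataFrame, category: str = "kinase") -> list[SignatureSet]:
    """Kinase-activity signatures derived from a prior network table:
    each kinase's targets, annotated "u" for phosphorylation targets and
    "d" for dephosphorylation targets (site behavior when the kinase is
    active)."""
    sets = []
    for kinase, sub in prior_frame.groupby("source", sort=False):
        members = []
        for row in sub.itertuples():
            direction = "u" if row.relation == "phosphorylates" else "d"
            members.append((f"{row.target}_{row.site}", direction))
        sets.append(SignatureSet(name=f"KINASE_{kinase}", category=category, members=members))
    return sets
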