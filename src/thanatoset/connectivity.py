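"""Preranked enrichment and signature-reversal connectivity screening.

Two related rank statistics live here.  The *preranked running-sum
enrichment score* (ES) walks a profile sorted by a per-gene statistic and
accumulates weighted hits against uniform misses; its normalized form
(NES) and permutation p-value come from a gene-label permutation null.

The *connectivity score* compares an up/down query signature against a
compound's ranked perturbation profile with the classic two-tag
Kolmogorov-Smirnov statistic: for each tag set the maximum deviations
``a`` and ``b`` of the tag rank distribution from uniform are combined as
``ks = a if a > b else -b``, and the compound score is
``s = (ks_up - ks_down)/2`` when the two arms deviate in opposite
directions, else 0.  Negative ``s`` means the compound's profile opposes
(reverses) the query signature.  Raw scores are library-scaled to the
conventional [-100, 100] range per sign.

A compound passes the multi-dataset consensus screen when its scaled
score is negative with permutation ``p < alpha`` in every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import Panel

__all__ = [
    "EnrichmentResult",
    "QuerySignature",
    "preranked_enrichment",
    "build_query_signature",
    "ks_connectivity",
    "scale_scores",
    "connectivity_pvalue",
    "null_connectivity_scores",
    "correlation_connectivity",
    "screen_library",
    "consensus_screen",
]


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    p: float
    n_perm: int
    leading_edge: list[str] = field(default_factory=list)


def _running_es(stat_sorted: np.ndarray, hit_mask: np.ndarray, weight: float) -> tuple[float, int]:
    """Signed maximum deviation of P_hit - P_miss along a sorted profile.

    Returns (es, index of the extremum).
    """
    n = stat_sorted.size
    m = int(hit_mask.sum())
    w = np.abs(stat_sorted) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom_hit = hit_w.sum()
    if denom_hit == 0:
        # all hit weights zero (e.g. weight>0 with zero statistics): fall back to unweighted
        hit_w = hit_mask.astype(float)
        denom_hit = float(m)
    p_hit = np.cumsum(hit_w) / denom_hit
    p_miss = np.cumsum(~hit_mask) / (n - m)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i]), i


def preranked_enrichment(
    profile: pd.Series,
    panel: Panel | Iterable[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked running-sum enrichment of a gene panel in a ranked profile.

    ``profile`` maps gene -> real statistic (e.g. log2FC); genes are
    sorted descending with seeded-random tie-breaking.  The null is built
    by permuting gene labels ``n_perm`` times; ``nes = es / mean|es_pi|``
    over same-sign permutations, and the p-value uses the add-one
    estimator ``(1 + #{same-sign |es_pi| >= |es|}) / (1 + #same-sign)``.
    """
    genes = list(panel.genes) if isinstance(panel, Panel) else list(panel)
    prof = profile.dropna()
    hit_set = set(genes) & set(prof.index)
    n = prof.size
    m = len(hit_set)
    if m == 0 or m == n:
        raise ValueError(f"panel/profile overlap must satisfy 1 <= m < n (m={m}, n={n})")
    rng = np.random.default_rng(seed)
    stat = prof.to_numpy(dtype=float)
    order = np.lexsort((rng.random(n), -stat))
    stat_sorted = stat[order]
    names_sorted = prof.index.to_numpy()[order]
    hit_mask = np.isin(names_sorted, list(hit_set))
    es, i_max = _running_es(stat_sorted, hit_mask, weight)

    es_null = np.empty(n_perm)
    positions = np.arange(n)
    for b in range(n_perm):
        perm_hits = np.zeros(n, dtype=bool)
        perm_hits[rng.choice(positions, size=m, replace=False)] = True
        es_null[b], _ = _running_es(stat_sorted, perm_hits, weight)

    same_sign = es_null * np.sign(es) > 0 if es != 0 else np.ones(n_perm, dtype=bool)
    n_same = int(same_sign.sum())
    if n_same:
        nes = es / np.abs(es_null[same_sign]).mean()
        p = (1 + int((np.abs(es_null[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    else:  # no same-sign permutation: fall back to the full null magnitude
        nes = es / max(np.abs(es_null).mean(), np.finfo(float).tiny)
        p = 1.0 / (1 + n_perm)

    if es >= 0:
        leading = names_sorted[: i_max + 1][hit_mask[: i_max + 1]]
    else:
        leading = names_sorted[i_max:][hit_mask[i_max:]]
    return EnrichmentResult(
        es=float(es), nes=float(nes), p=float(p), n_perm=n_perm, leading_edge=list(leading)
    )


@dataclass
class QuerySignature:
    """Up/down gene signature with the full statistic vector retained."""

    up: frozenset[str]
    down: frozenset[str]
    logfc: pd.Series
    description: str = ""

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down arms must be disjoint")


def build_query_signature(
    deg: pd.DataFrame, panel: Panel | Iterable[str], description: str = ""
) -> QuerySignature:
    """Split panel genes by the sign of their contrast log-fold-change.

    Genes with logFC exactly 0 are excluded.  Raises if either arm is
    empty, pointing the user to correlation-mode connectivity, which
    accepts one-sided signatures.
    """
    genes = list(panel.genes) if isinstance(panel, Panel) else list(panel)
    present = [g for g in genes if g in deg.index]
    lfc = deg.loc[present, "logFC"].astype(float)
    up = frozenset(lfc.index[lfc > 0])
    down = frozenset(lfc.index[lfc < 0])
    if not up or not down:
        raise ValueError(
            "one signature arm is empty; KS connectivity needs both — "
            "use correlation_connectivity for one-sided signatures"
        )
    return QuerySignature(up=up, down=down, logfc=lfc, description=description)


def _ks_tag(v_sorted: np.ndarray, n: int) -> float:
    """Classic tag-set KS statistic from ascending 1-based tag ranks."""
    t = v_sorted.size
    j = np.arange(1, t + 1)
    a = np.max(j / t - v_sorted / n)
    b = np.max(v_sorted / n - (j - 1) / t)
    return float(a) if a > b else float(-b)


def ks_connectivity(signature: QuerySignature, profile_genes: Sequence[str]) -> float:
    """Raw KS connectivity of a signature against one ranked profile.

    ``profile_genes`` is the full gene list ordered by perturbation
    statistic descending.  Tag genes absent from the profile are dropped;
    an entirely missing arm raises.  Returns ``s`` in [-1, 1].
    """
    pos = {g: i + 1 for i, g in enumerate(profile_genes)}  # 1-based ascending ranks
    n = len(pos)
    v_up = np.sort([pos[g] for g in signature.up if g in pos])
    v_down = np.sort([pos[g] for g in signature.down if g in pos])
    if v_up.size == 0 or v_down.size == 0:
        raise ValueError("a whole signature arm is missing from the profile")
    ks_up = _ks_tag(np.asarray(v_up, dtype=float), n)
    ks_down = _ks_tag(np.asarray(v_down, dtype=float), n)
    if np.sign(ks_up) == np.sign(ks_down):
        return 0.0
    return (ks_up - ks_down) / 2.0


def scale_scores(raw: pd.Series) -> pd.Series:
    """Scale raw per-compound scores to [-100, 100] per sign.

    Positive raws are divided by the maximum positive raw, negative raws
    by the magnitude of the most negative raw, then multiplied by 100.
    Zero stays zero; an all-zero library stays all-zero.
    """
    if raw.empty:
        raise ValueError("need at least one compound")
    scaled = pd.Series(0.0, index=raw.index)
    pos = raw > 0
    neg = raw < 0
    if pos.any():
        scaled[pos] = 100.0 * raw[pos] / raw[pos].max()
    if neg.any():
        scaled[neg] = 100.0 * raw[neg] / abs(raw[neg].min())
    return scaled


def null_connectivity_scores(
    n_genes: int, t_up: int, t_down: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distribution of the KS connectivity score: random up/down tag
    sets of the observed sizes drawn from an ``n_genes`` universe."""
    out = np.empty(n_perm)
    for b in range(n_perm):
        tags = rng.choice(n_genes, size=t_up + t_down, replace=False) + 1
        ks_up = _ks_tag(np.sort(tags[:t_up]).astype(float), n_genes)
        ks_down = _ks_tag(np.sort(tags[t_up:]).astype(float), n_genes)
        out[b] = 0.0 if np.sign(ks_up) == np.sign(ks_down) else (ks_up - ks_down) / 2.0
    return out


def connectivity_pvalue(
    signature: QuerySignature,
    profile_genes: Sequence[str],
    s_obs: float,
    n_perm: int = 1000,
    seed: int = 0,
    null: np.ndarray | None = None,
) -> float:
    """Two-sided permutation p-value for a raw connectivity score.

    ``p = (1 + #{|s_pi| >= |s_obs|}) / (1 + n_perm)`` with the null drawn
    by :func:`null_connectivity_scores` (a precomputed ``null`` may be
    passed to share one null across a library, since it depends only on
    the universe size and the arm sizes).
    """
    if null is None:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        pos = set(profile_genes)
        t_up = sum(g in pos for g in signature.up)
        t_down = sum(g in pos for g in signature.down)
        rng = np.random.default_rng(seed)
        null = null_connectivity_scores(len(profile_genes), t_up, t_down, n_perm, rng)
    return float((1 + int((np.abs(null) >= abs(s_obs)).sum())) / (1 + null.size))


def correlation_connectivity(
    query: pd.Series,
    profile: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation connectivity with a permutation p-value.

    Correlates the query statistic vector with a compound profile over
    their shared genes (>= 5 required); the null shuffles the profile
    values among the shared genes.  Returns ``(rho, p)``; negative rho
    flags signature reversal.
    """
    shared = query.index.intersection(profile.index)
    if len(shared) < 5:
        raise ValueError(f"need >=5 shared genes, got {len(shared)}")
    q = query.loc[shared].to_numpy(dtype=float)
    v = profile.loc[shared].to_numpy(dtype=float)
    rho = float(stats.spearmanr(q, v).statistic)
    rng = np.random.default_rng(seed)
    # rank once; permuting value order == permuting ranks
    qr = stats.rankdata(q)
    vr = stats.rankdata(v)
    qc = qr - qr.mean()
    denom = np.sqrt((qc**2).sum())
    perm = np.argsort(rng.random((n_perm, vr.size)), axis=1)
    vp = vr[perm]
    vc = vp - vp.mean(axis=1, keepdims=True)
    r_null = (vc @ qc) / (denom * np.sqrt((vc**2).sum(axis=1)))
    count = int((np.abs(r_null) >= abs(rho) - 1e-12).sum())
    p = (1 + count) / (1 + n_perm)
    return rho, float(p)


def screen_library(
    library: pd.DataFrame,
    signature: QuerySignature,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "ks",
) -> pd.DataFrame:
    """Score every compound of a perturbation library against a signature.

    ``library`` is compounds x genes.  Returns a ConnectivityTable with
    columns ``raw``, ``scaled`` (in [-100, 100]) and ``p``.  In ``ks``
    mode one permutation null is shared across compounds (it depends only
    on universe and arm sizes); in ``correlation`` mode each compound gets
    its own profile-shuffle null.
    """
    if mode not in ("ks", "correlation"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    rows = []
    if mode == "ks":
        genes = list(library.columns)
        t_up = sum(g in set(genes) for g in signature.up)
        t_down = sum(g in set(genes) for g in signature.down)
        null = null_connectivity_scores(len(genes), t_up, t_down, n_perm, rng)
        for compound, prof in library.iterrows():
            ranked = prof.sort_values(ascending=False, kind="stable").index.tolist()
            s = ks_connectivity(signature, ranked)
            p = connectivity_pvalue(signature, ranked, s, null=null)
            rows.append({"compound": compound, "raw": s, "p": p})
    else:
        for compound, prof in library.iterrows():
            rho, p = correlation_connectivity(
                signature.logfc, prof, n_perm=n_perm, seed=int(rng.integers(2**31))
            )
            rows.append({"compound": compound, "raw": rho, "p": p})
    out = pd.DataFrame(rows).set_index("compound")
    out["scaled"] = scale_scores(out["raw"])
    return out[["raw", "scaled", "p"]]


def consensus_screen(
    tables: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Multi-dataset consensus: keep compounds negative and significant everywhere.

    ``tables`` maps dataset name -> ConnectivityTable (columns ``scaled``,
    ``p``).  A compound is retained iff ``scaled < 0`` and ``p < alpha``
    in *every* dataset; retained compounds are ranked by ascending mean
    scaled score.  The returned frame carries per-dataset evidence columns
    and a ``retained`` flag for all compounds (outer join; compounds
    missing from a dataset are flagged and never retained).
    """
    if len(tables) < 2:
        raise ValueError("consensus_screen needs >=2 datasets")
    all_compounds = sorted(set().union(*(set(t.index) for t in tables.values())))
    out = pd.DataFrame(index=pd.Index(all_compounds, name="compound"))
    retained = pd.Series(True, index=out.index)
    for name, t in tables.items():
        out[f"scaled_{name}"] = t["scaled"].reindex(out.index)
        out[f"p_{name}"] = t["p"].reindex(out.index)
        ok = (out[f"scaled_{name}"] < 0) & (out[f"p_{name}"] < alpha)
        retained &= ok.fillna(False)
        out[f"missing_{name}"] = out[f"scaled_{name}"].isna()
    out["mean_scaled"] = out[[f"scaled_{n}" for n in tables]].mean(axis=1)
    out["n_datasets_negative_significant"] = sum(
        ((out[f"scaled_{n}"] < 0) & (out[f"p_{n}"] < alpha)).astype(int) for n in tables
    )
    out["retained"] = retained
    return out.sort_values(["retained", "mean_scaled"], ascending=[False, True])
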