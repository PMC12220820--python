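"""Injury-specific pan-PCD panel derivation from bulk expression time courses.

The derivation pipeline mirrors how an injury-specific cell-death panel is
distilled from multi-model expression data:

1. per-time-point differential expression (empirical-Bayes moderated t) of
   injured vs sham samples in a primary injury model;
2. DEG calling at ``|log2FC| > 1.5`` and ``p < 0.05`` (strict);
3. union of DEGs over the acute time points, intersected with the pan-PCD
   catalog (the *injury-responsive* set);
4. a two-sided Wilcoxon rank-sum filter of each candidate in additional
   injury models (injured vs sham, unadjusted ``p < 0.05``);
5. intersection across models, yielding the core panel.

The moderated t-statistic shrinks per-gene residual variances toward a
pooled prior whose degrees of freedom ``d0`` and scale ``s0^2`` are
estimated by moment matching on ``log s^2`` (digamma/trigamma equations,
trigamma inverse solved by Newton iteration).  With ``prior_df=0`` the
statistic reduces exactly to the ordinary pooled two-sample t; with
``prior_df=inf`` all genes share the prior variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .genesets import PanPCDCatalog, normalize_symbol

__all__ = [
    "BulkExpression",
    "Panel",
    "moderated_t_test",
    "call_degs",
    "injury_responsive_set",
    "cross_model_ranksum_filter",
    "derive_panel",
    "fit_variance_prior",
]

TIMEPOINT_ORDER = ("sham", "1dpi", "3dpi", "5dpi", "7dpi")


@dataclass
class BulkExpression:
    """log2-scale expression matrix (genes x samples) with sample metadata.

    ``values``: DataFrame indexed by gene symbol, columns are sample ids.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``group``, ``timepoint``, ``model``, ``age``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose metadata match all conditions (values may be
        scalars or collections)."""
        mask = pd.Series(True, index=self.sample_meta.index)
        for col, want in conditions.items():
            if isinstance(want, (list, tuple, set, frozenset)):
                mask &= self.sample_meta[col].isin(list(want))
            else:
                mask &= self.sample_meta[col] == want
        return [s for s in self.values.columns if mask.get(s, False)]

    def to_tsv(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene")
        self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, meta_path: str | Path) -> "BulkExpression":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values=values, sample_meta=meta)


@dataclass
class Panel:
    """Ordered core gene list with PCD-type annotations and derivation provenance."""

    genes: tuple[str, ...]
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = tuple(normalize_symbol(g) for g in self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def pcd_types(self) -> set[str]:
        return set().union(*self.annotations.values()) if self.annotations else set()

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\ttypes\tprovenance\n")
            for g in self.genes:
                types = ";".join(sorted(self.annotations.get(g, ())))
                prov = self.provenance.get(g, {})
                prov_s = ";".join(f"{k}={v}" for k, v in sorted(prov.items()))
                fh.write(f"{g}\t{types}\t{prov_s}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Panel":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        genes = tuple(df["gene"])
        annotations = {
            normalize_symbol(g): frozenset(t for t in ts.split(";") if t)
            for g, ts in zip(df["gene"], df.get("types", [""] * len(df)))
        }
        return cls(genes=genes, annotations=annotations)

    def to_gmt(self, path: str | Path, name: str = "panel", source: str = "derived") -> None:
        with open(path, "w") as fh:
            fh.write("\t".join([name, source, *self.genes]) + "\n")


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Estimate prior degrees of freedom d0 and scale s0^2 from per-gene
    residual variances by moment matching on log s^2.

    Returns ``(d0, s0_sq)``; ``d0`` may be ``inf`` when the observed
    log-variance spread is no larger than expected from chi-square sampling
    alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    n = e.size
    emean = e.mean()
    evar = np.sum((e - emean) ** 2) / (n - 1) - special.polygamma(1, df_resid / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(float(evar))
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def moderated_t_test(
    expr: BulkExpression,
    group_a: Sequence[str],
    group_b: Sequence[str],
    prior_df: float | None = None,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test per gene.

    ``logFC = mean(group_b) - mean(group_a)`` on the log2 scale.  The
    posterior variance is ``(d0*s0^2 + d*s^2)/(d0 + d)`` with residual df
    ``d = n_a + n_b - 2``; the t-statistic has ``d0 + d`` degrees of
    freedom.  ``prior_df`` overrides the estimated ``d0`` (0 gives the
    ordinary pooled t, ``inf`` full shrinkage to the prior scale).

    Returns a DEG table indexed by gene with columns
    ``logFC, t, p, df, is_deg``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    a = expr.values[group_a].to_numpy(dtype=float)
    b = expr.values[group_b].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    d_g = n_a + n_b - 2

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    logfc = mean_b - mean_a
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / d_g

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, d_g)
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise ValueError("prior_df must be non-negative")
        _, s0_sq = fit_variance_prior(s2, d_g) if d0 > 0 else (None, 0.0)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(d_g)
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g

    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), np.where(logfc == 0, 0.0, np.inf * np.sign(logfc)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # zero variance in both groups and zero logFC -> no evidence, p = 1
    degenerate = (se == 0) & (logfc == 0)
    p = np.where(degenerate, 1.0, p)
    p = np.where((se == 0) & (logfc != 0), 0.0, p)

    df = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p": p,
            "df": np.full(len(logfc), df_total, dtype=float),
        },
        index=expr.genes,
    )
    df["is_deg"] = (df["logFC"].abs() > fc_threshold) & (df["p"] < p_threshold)
    return df


def call_degs(
    deg: pd.DataFrame, fc_threshold: float = 1.5, p_threshold: float = 0.05
) -> set[str]:
    """Genes with ``|logFC| > fc_threshold`` and ``p < p_threshold`` (strict)."""
    mask = (deg["logFC"].abs() > fc_threshold) & (deg["p"] < p_threshold)
    return set(deg.index[mask])


def injury_responsive_set(
    deg_by_timepoint: Mapping[str, pd.DataFrame],
    catalog: PanPCDCatalog,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    combine: str = "union",
) -> tuple[set[str], dict[str, list[str]]]:
    """Catalog genes differentially expressed at any acute time point.

    Takes the union (default; ``combine="intersection"`` available) of DEG
    calls across time points, then intersects with the catalog.  Returns
    the gene set and a provenance map gene -> time points passed.
    """
    if not deg_by_timepoint:
        raise ValueError("need at least one time point")
    if combine not in ("union", "intersection"):
        raise ValueError(f"unknown combine mode {combine!r}")
    per_tp = {tp: call_degs(deg, fc_threshold, p_threshold) for tp, deg in deg_by_timepoint.items()}
    all_measured = set().union(*(set(d.index) for d in deg_by_timepoint.values()))
    if not all_measured & set(catalog.entries):
        raise ValueError("catalog and DEG gene universes are disjoint")
    if combine == "union":
        pooled = set().union(*per_tp.values())
    else:
        pooled = set.intersection(*per_tp.values())
    hits = pooled & set(catalog.entries)
    provenance = {
        g: sorted(tp for tp, degs in per_tp.items() if g in degs) for g in sorted(hits)
    }
    return hits, provenance


def cross_model_ranksum_filter(
    candidates: Iterable[str],
    expr: BulkExpression,
    alpha: float = 0.05,
    injured_timepoints: Sequence[str] | None = None,
) -> tuple[set[str], list[str]]:
    """Wilcoxon rank-sum filter of candidate genes in one injury model.

    Injured samples (all non-sham time points pooled, or the given
    ``injured_timepoints``) are compared against sham per candidate gene
    with a two-sided rank-sum test; genes with ``p < alpha`` are retained.
    Exact p-values are used when both groups have <= 10 samples and no
    ties; the normal approximation with tie correction otherwise.

    Returns ``(retained, dropped_missing)`` where ``dropped_missing`` lists
    candidates absent from the expression matrix (not testable on this
    platform).
    """
    sham = expr.samples_where(timepoint="sham")
    if injured_timepoints is None:
        injured = [s for s in expr.values.columns if s not in sham]
    else:
        injured = expr.samples_where(timepoint=list(injured_timepoints))
    if len(sham) < 2 or len(injured) < 2:
        raise ValueError(
            f"need >=2 samples per side (sham={len(sham)}, injured={len(injured)})"
        )
    retained: set[str] = set()
    dropped: list[str] = []
    for gene in sorted({normalize_symbol(g) for g in candidates}):
        if gene not in expr.values.index:
            dropped.append(gene)
            continue
        x = expr.values.loc[gene, injured].to_numpy(dtype=float)
        y = expr.values.loc[gene, sham].to_numpy(dtype=float)
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) else "asymptotic"
        p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        if p < alpha:
            retained.add(gene)
    return retained, dropped


def derive_panel(
    per_model_sets: Mapping[str, Iterable[str]],
    catalog: PanPCDCatalog,
    provenance: Mapping[str, dict] | None = None,
) -> Panel:
    """Intersect per-model retained gene sets into the core panel.

    Requires at least two models; raises on an empty intersection, naming
    the per-model set sizes.  Genes are ordered alphabetically and
    annotated with their catalog PCD-type memberships.
    """
    if len(per_model_sets) < 2:
        raise ValueError("derive_panel needs gene sets from at least 2 models")
    sets = {m: {normalize_symbol(g) for g in gs} for m, gs in per_model_sets.items()}
    core = set.intersection(*sets.values())
    if not core:
        sizes = {m: len(s) for m, s in sets.items()}
        raise ValueError(f"empty cross-model intersection; per-model sizes: {sizes}")
    genes = tuple(sorted(core))
    annotations = {g: catalog.entries.get(g, frozenset()) for g in genes}
    prov = {
        g: {"models": ",".join(sorted(sets)), **(dict(provenance.get(g, {})) if provenance else {})}
        for g in genes
    }
    return Panel(genes=genes, annotations=annotations, provenance=prov)
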