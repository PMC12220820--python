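"""Synthetic expression data with planted ground truth.

Every pipeline stage has a matching generator here so the whole analysis
is testable without external downloads:

* :func:`simulate_bulk_timecourse` — log-normal bulk expression over an
  injury time course (sham, 1/3/7 dpi) in several injury models, with a
  planted core of catalog responder genes shared across models,
  model-specific responders, and non-catalog background responders.  The
  injury effect persists across time points in the "persistent" age
  profile and decays in the "attenuating" one.
* :func:`simulate_cell_population` — negative-binomial single-cell counts
  with a latent high/low pan-PCD activity label per cell whose prevalence
  differs by condition; panel genes are elevated (a fraction suppressed)
  in high-activity cells.
* :func:`simulate_score_table` — per-cell activity scores with planted
  group mean shifts per arm, for slope and slope-ratio calibration.
* :func:`simulate_perturbation_library` — compound x gene perturbation
  profiles containing planted signature reversers and mimics among inert
  compounds.

All generators are pure functions of their config: the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .genesets import GeneSet, PanPCDCatalog, build_catalog
from .panel import BulkExpression

__all__ = [
    "BulkSimConfig",
    "CellSimConfig",
    "LibrarySimConfig",
    "SimTruth",
    "simulate_bulk_timecourse",
    "simulate_cell_population",
    "simulate_score_table",
    "simulate_perturbation_library",
]

ATTENUATION_PROFILES = {
    "persistent": (1.0, 1.0, 1.0),
    "attenuating": (1.0, 0.4, 0.1),
}


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    responder_genes: dict[str, list[str]] = field(default_factory=dict)
    cell_labels: pd.Series | None = None
    compound_classes: dict[str, str] = field(default_factory=dict)
    score_shifts: dict[str, float] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


@dataclass
class BulkSimConfig:
    """Conditions for the bulk injury time-course generator.

    Defaults mirror the derivation benchmark: three injury models sharing
    a planted core of 30 catalog responders plus 10 model-specific
    responders each, log2 effect size 2.0 against Gaussian noise sd 0.2,
    3 replicates per arm.
    """

    n_genes: int = 2000
    n_catalog_genes: int = 300
    n_core_responders: int = 30
    n_model_specific_responders: int = 10
    n_background_responders: int = 60
    models: tuple[str, ...] = ("crush", "contusion", "hemisection")
    timepoints: tuple[str, ...] = ("1dpi", "3dpi", "7dpi")
    n_reps: int = 3
    effect_size: float = 2.0
    attenuation_profile: Mapping[str, str] = field(
        default_factory=lambda: {"adult": "persistent", "neonatal": "attenuating"}
    )
    noise_sd: float = 0.2
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.n_core_responders <= self.n_catalog_genes <= self.n_genes:
            raise ValueError("need n_core_responders <= n_catalog_genes <= n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        n_specific = self.n_model_specific_responders * len(self.models)
        if self.n_core_responders + n_specific > self.n_catalog_genes:
            raise ValueError("catalog too small for core + model-specific responders")
        for age, prof in self.attenuation_profile.items():
            if prof not in ATTENUATION_PROFILES:
                raise ValueError(f"unknown attenuation profile {prof!r} for age {age!r}")


def _gene_ids(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def simulate_bulk_timecourse(
    config: BulkSimConfig,
) -> tuple[dict[str, BulkExpression], SimTruth]:
    """Simulate per-model bulk expression matrices with planted responders.

    Per gene, baseline log2 means are Uniform(2, 10); injured samples of
    responder genes receive ``+effect_size`` scaled by the age's
    attenuation multiplier at that time point; Gaussian noise with
    ``noise_sd`` is added everywhere.  Core responders respond in every
    model, model-specific responders only in theirs, background
    responders (outside the catalog) in every model.

    Returns ``(per_model, truth)``; ``truth.responder_genes`` has keys
    ``catalog``, ``core``, ``background`` and ``specific_<model>``, and
    ``truth.extras["catalog"]`` holds a single-type PanPCDCatalog over the
    planted catalog genes.
    """
    cfg = config
    genes = _gene_ids(cfg.n_genes)
    catalog_genes = genes[: cfg.n_catalog_genes]
    core = genes[: cfg.n_core_responders]
    specific: dict[str, list[str]] = {}
    offset = cfg.n_core_responders
    for model in cfg.models:
        specific[model] = genes[offset : offset + cfg.n_model_specific_responders]
        offset += cfg.n_model_specific_responders
    background = genes[cfg.n_catalog_genes : cfg.n_catalog_genes + cfg.n_background_responders]

    ages = tuple(cfg.attenuation_profile)
    rng = np.random.default_rng(cfg.seed)
    per_model: dict[str, BulkExpression] = {}
    for model in cfg.models:
        responders = set(core) | set(specific[model]) | set(background)
        resp_mask = np.array([g in responders for g in genes])
        baseline = rng.uniform(2.0, 10.0, size=cfg.n_genes)
        cols: dict[str, np.ndarray] = {}
        meta_rows = []
        for age in ages:
            mult = ATTENUATION_PROFILES[cfg.attenuation_profile[age]]
            for tp_i, tp in enumerate(("sham", *cfg.timepoints)):
                for rep in range(1, cfg.n_reps + 1):
                    mean = baseline.copy()
                    if tp != "sham":
                        mean = mean + resp_mask * cfg.effect_size * mult[tp_i - 1]
                    sample = f"{model}_{age}_{tp}_r{rep}"
                    cols[sample] = mean + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
                    meta_rows.append(
                        {
                            "sample": sample,
                            "group": f"{age}_{tp}",
                            "timepoint": tp,
                            "model": model,
                            "age": age,
                        }
                    )
        values = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
        meta = pd.DataFrame(meta_rows).set_index("sample")
        per_model[model] = BulkExpression(values=values, sample_meta=meta)

    sim_catalog = build_catalog(
        [GeneSet(name="pan_pcd_sim", source="synthetic", genes=tuple(catalog_genes))]
    )
    truth = SimTruth(
        responder_genes={
            "catalog": list(catalog_genes),
            "core": list(core),
            "background": list(background),
            **{f"specific_{m}": list(gs) for m, gs in specific.items()},
        },
        extras={"catalog": sim_catalog, "config": asdict(cfg)},
    )
    return per_model, truth


@dataclass
class CellSimConfig:
    """Conditions for the single-cell count generator.

    Defaults plant a 3-fold elevation of panel genes in high-activity
    cells, with high-cell prevalence 0.6 in injured and 0.2 in sham arms
    (2000 cells each) — echoing the sham-to-injured rise in
    high-activity-cell fraction the panel is meant to detect.  A quarter
    of the panel is suppressed instead of elevated in high cells so that
    group contrasts carry a two-armed (up/down) signature.
    """

    n_cells: int = 2000  # per (cell_type x group x age) arm
    n_genes: int = 2000
    cell_types: tuple[str, ...] = ("microglia",)
    groups: tuple[str, ...] = ("sham", "injured")
    ages: tuple[str, ...] = ("adult",)
    panel: tuple[str, ...] | None = None  # default: first 68 gene ids
    high_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"sham": 0.2, "injured": 0.6}
    )
    fold_elevation: float = 3.0
    panel_down_fraction: float = 0.25
    nb_dispersion: float = 0.3
    library_size_lognorm: tuple[float, float] = (8.7, 0.35)
    seed: int = 1

    def __post_init__(self) -> None:
        for g, f in self.high_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"high_fraction[{g!r}] must be in [0, 1]")
        if self.fold_elevation < 1.0:
            raise ValueError("fold_elevation must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 <= self.panel_down_fraction < 1.0:
            raise ValueError("panel_down_fraction must be in [0, 1)")


def simulate_cell_population(config: CellSimConfig) -> tuple[ad.AnnData, SimTruth]:
    """Simulate UMI counts for cells with a latent high/low activity label.

    Per cell: library size ~ LogNormal(mu, sigma); gene relative
    abundances come from a fixed gamma-draw baseline (dirichlet-like);
    panel "up" genes are multiplied by ``fold_elevation`` (and "down"
    panel genes divided by it) in high-activity cells; counts are
    negative binomial via a gamma-Poisson mixture with shared dispersion.

    Returns an AnnData (cells x genes, sparse counts; obs columns
    cell_type, group, age, dataset) and a SimTruth whose ``cell_labels``
    Series gives the latent label per cell and whose ``responder_genes``
    lists the planted panel direction ("panel_up" / "panel_down").
    """
    cfg = config
    genes = _gene_ids(cfg.n_genes)
    panel = list(cfg.panel) if cfg.panel is not None else genes[:68]
    missing = set(panel) - set(genes)
    if missing:
        raise ValueError(f"panel genes absent from simulated universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng(cfg.seed)

    # fixed dirichlet-like baseline abundances
    base = rng.gamma(shape=0.7, scale=1.0, size=cfg.n_genes) + 1e-9
    panel_idx = np.array([genes.index(g) for g in panel])
    n_down = int(round(cfg.panel_down_fraction * len(panel)))
    down_idx = panel_idx[len(panel) - n_down :] if n_down else np.array([], dtype=int)
    up_idx = panel_idx[: len(panel) - n_down]

    high_profile = base.copy()
    high_profile[up_idx] *= cfg.fold_elevation
    if n_down:
        high_profile[down_idx] /= cfg.fold_elevation
    low_p = base / base.sum()
    high_p = high_profile / high_profile.sum()

    mu, sigma = cfg.library_size_lognorm
    blocks: list[sparse.csr_matrix] = []
    obs_rows = []
    labels = []
    cell_counter = 0
    r = 1.0 / cfg.nb_dispersion  # gamma shape for the NB mixture
    for cell_type in cfg.cell_types:
        for age in cfg.ages:
            for group in cfg.groups:
                frac = cfg.high_fraction.get(group, cfg.high_fraction.get((group, age), 0.0))
                n_high = int(round(frac * cfg.n_cells))
                is_high = np.zeros(cfg.n_cells, dtype=bool)
                is_high[rng.permutation(cfg.n_cells)[:n_high]] = True
                libsize = rng.lognormal(mu, sigma, size=cfg.n_cells)
                p = np.where(is_high[:, None], high_p[None, :], low_p[None, :])
                mean = libsize[:, None] * p
                lam = rng.gamma(shape=r, scale=mean / r)
                counts = rng.poisson(lam)
                blocks.append(sparse.csr_matrix(counts))
                for i in range(cfg.n_cells):
                    cell_counter += 1
                    obs_rows.append(
                        {
                            "cell": f"C{cell_counter:06d}",
                            "cell_type": cell_type,
                            "group": group,
                            "age": age,
                            "dataset": "sim",
                        }
                    )
                labels.extend(["high" if h else "low" for h in is_high])

    X = sparse.vstack(blocks).tocsr()
    obs = pd.DataFrame(obs_rows).set_index("cell")
    adata = ad.AnnData(
        X=X.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    truth = SimTruth(
        responder_genes={
            "panel_up": [genes[i] for i in up_idx],
            "panel_down": [genes[i] for i in down_idx],
        },
        cell_labels=pd.Series(labels, index=obs.index, name="truth_label"),
        extras={"config": asdict(cfg)},
    )
    return adata, truth


def simulate_score_table(
    shifts: Mapping[str, float],
    n_per_group: int = 2000,
    baseline_mean: float = 0.12,
    score_sd: float = 0.03,
    seed: int = 1,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate per-cell activity scores with planted group mean shifts.

    ``shifts`` maps an arm name (e.g. ``"adult"``, ``"neonatal"``) to the
    planted injured-minus-sham score shift.  Each arm gets
    ``n_per_group`` sham and injured cells with Normal(baseline, sd) and
    Normal(baseline + shift, sd) scores, clipped to [0, 1] (negligible at
    the defaults).  Returns a score table (columns ``cell_type``,
    ``group``, ``auc_score``) and the truth with ``score_shifts``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for arm, shift in shifts.items():
        for group, mean in (("sham", baseline_mean), ("injured", baseline_mean + shift)):
            scores = np.clip(rng.normal(mean, score_sd, size=n_per_group), 0.0, 1.0)
            for s in scores:
                rows.append({"cell_type": arm, "group": group, "auc_score": s})
    table = pd.DataFrame(rows)
    truth = SimTruth(score_shifts=dict(shifts))
    return table, truth


@dataclass
class LibrarySimConfig:
    """Conditions for the perturbation-library generator.

    The query signature vector defaults to 68 standard-normal statistics
    (matching the panel size the screen consumes); reversers are
    ``-gain * query`` plus noise, mimics ``+gain * query`` plus noise,
    inert compounds pure noise, embedded in a larger gene universe of
    pure-noise background genes.
    """

    query: pd.Series | None = None
    n_reversers: int = 5
    n_mimics: int = 2
    n_inert: int = 43
    gain: float = 1.0
    noise_sd: float = 0.5
    n_background_genes: int = 910
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_reversers, self.n_mimics, self.n_inert) < 0:
            raise ValueError("compound counts must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_query(seed: int = 1, n_genes: int = 68) -> pd.Series:
    """Standard-normal query signature over synthetic gene ids."""
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(size=n_genes), index=_gene_ids(n_genes, prefix="Q"))


def simulate_perturbation_library(
    config: LibrarySimConfig,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a compounds x genes perturbation-statistic library.

    Returns the library DataFrame (rows: compound ids, columns: gene ids)
    and a SimTruth whose ``compound_classes`` maps compound id to
    ``reverser`` / ``mimic`` / ``inert``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    query = cfg.query if cfg.query is not None else default_query(cfg.seed)
    sig_genes = list(query.index)
    bg_genes = _gene_ids(cfg.n_background_genes, prefix="BG")
    all_genes = sig_genes + bg_genes
    q = query.to_numpy(dtype=float)

    compounds: list[str] = []
    classes: dict[str, str] = {}
    rows = []
    for kind, count, sign in (
        ("reverser", cfg.n_reversers, -1.0),
        ("mimic", cfg.n_mimics, +1.0),
        ("inert", cfg.n_inert, 0.0),
    ):
        for i in range(1, count + 1):
            cid = f"{kind[:3].upper()}{i:03d}"
            profile = rng.normal(0.0, cfg.noise_sd, size=len(all_genes))
            if sign != 0.0:
                profile[: len(sig_genes)] += sign * cfg.gain * q
            compounds.append(cid)
            classes[cid] = kind
            rows.append(profile)
    library = pd.DataFrame(
        np.vstack(rows), index=pd.Index(compounds, name="compound"), columns=all_genes
    )
    truth = SimTruth(
        compound_classes=classes,
        extras={"query": query, "config": {k: v for k, v in asdict(cfg).items() if k != "query"}},
    )
    return library, truth
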