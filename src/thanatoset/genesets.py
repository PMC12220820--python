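"""Programmed-cell-death gene-set collections and the pan-PCD catalog.

A *pan-PCD catalog* is the union of several programmed-cell-death (PCD)
pathway gene sets (apoptosis, pyroptosis, ferroptosis, ...), stored as a
mapping from gene symbol to the set of PCD types it belongs to.  Gene sets
are exchanged in GMT format (one tab-separated line per set: name,
description, genes...), the format the source pathway databases export.

Gene symbols are case-normalized to mouse title-case (``Gsdmd``) so that
collections mixing styles (``GSDMD``, ``gsdmd``) merge correctly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "PanPCDCatalog",
    "normalize_symbol",
    "read_gmt",
    "write_gmt",
    "build_catalog",
    "catalog_summary",
    "restrict_to_universe",
]


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol to mouse title-case (first letter upper, rest lower)."""
    s = symbol.strip()
    if not s:
        raise ValueError("empty gene symbol")
    return s[0].upper() + s[1:].lower()


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with source provenance.

    ``genes`` preserves first-seen order; symbols are unique after case
    normalization (enforced at construction).
    """

    name: str
    source: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        normalized: list[str] = []
        seen: set[str] = set()
        for g in self.genes:
            n = normalize_symbol(g)
            if n not in seen:
                seen.add(n)
                normalized.append(n)
        object.__setattr__(self, "genes", tuple(normalized))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PanPCDCatalog:
    """Gene -> set-of-PCD-types mapping with per-type source provenance.

    Invariants: every gene maps to at least one type; every type referenced
    by a gene appears in ``sources``.
    """

    entries: dict[str, frozenset[str]]
    sources: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, types in self.entries.items():
            if not types:
                raise ValueError(f"gene {gene!r} has no PCD-type membership")
            for t in types:
                if t not in self.sources:
                    raise ValueError(f"type {t!r} of gene {gene!r} missing from sources")

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries)

    @property
    def types(self) -> list[str]:
        return sorted(self.sources)

    @property
    def n_types(self) -> int:
        return len(self.sources)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def as_sets(self) -> list[GeneSet]:
        """Reconstruct one GeneSet per PCD type (genes alphabetical)."""
        by_type: dict[str, list[str]] = {t: [] for t in self.sources}
        for gene in sorted(self.entries):
            for t in self.entries[gene]:
                by_type[t].append(gene)
        return [
            GeneSet(name=t, source=";".join(self.sources[t]), genes=tuple(gs))
            for t, gs in sorted(by_type.items())
            if gs
        ]

    def to_tsv(self, path: str | Path) -> None:
        """Export as TSV with columns gene, types (semicolon-joined), sources."""
        with open(path, "w") as fh:
            fh.write("gene\ttypes\tsources\n")
            for gene in sorted(self.entries):
                types = sorted(self.entries[gene])
                srcs = sorted({s for t in types for s in self.sources[t]})
                fh.write(f"{gene}\t{';'.join(types)}\t{';'.join(srcs)}\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file into a list of :class:`GeneSet`.

    Each non-empty line must have at least three tab-separated fields
    (name, description, gene, ...).  Duplicate symbols within a line are
    collapsed after case normalization.

    Raises
    ------
    ValueError
        On a malformed line (fewer than 3 fields), naming the line number,
        or if the file contains no gene sets.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name, source, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, source=source, genes=tuple(genes)))
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source, *gs.genes]) + "\n")


def build_catalog(sets: Sequence[GeneSet]) -> PanPCDCatalog:
    """Merge gene sets into a :class:`PanPCDCatalog` (union of symbols).

    Deterministic regardless of input order: entries and sources are kept
    sorted.  Raises ``ValueError`` on empty input.
    """
    if not sets:
        raise ValueError("build_catalog requires at least one gene set")
    if all(len(gs) == 0 for gs in sets):
        raise ValueError("build_catalog requires at least one non-empty gene set")
    entries: dict[str, set[str]] = {}
    sources: dict[str, list[str]] = {}
    for gs in sorted(sets, key=lambda s: s.name):
        sources.setdefault(gs.name, [])
        if gs.source and gs.source not in sources[gs.name]:
            sources[gs.name].append(gs.source)
        for gene in gs.genes:
            entries.setdefault(gene, set()).add(gs.name)
    frozen = {g: frozenset(ts) for g, ts in sorted(entries.items())}
    return PanPCDCatalog(entries=frozen, sources=sources)


def catalog_summary(catalog: PanPCDCatalog) -> dict:
    """Summarize a catalog: per-type gene counts, union size, multi-membership count."""
    per_type: dict[str, int] = {t: 0 for t in catalog.sources}
    multi = 0
    for types in catalog.entries.values():
        if len(types) > 1:
            multi += 1
        for t in types:
            per_type[t] += 1
    return {
        "per_type_counts": dict(sorted(per_type.items())),
        "union_size": len(catalog.entries),
        "multi_membership_count": multi,
        "n_types": catalog.n_types,
    }


def restrict_to_universe(
    catalog: PanPCDCatalog, universe: Iterable[str]
) -> tuple[PanPCDCatalog, list[str]]:
    """Drop catalog genes absent from a measured gene universe.

    Returns the restricted catalog and the sorted list of dropped symbols.
    Logs a warning when more than 10% of the catalog is dropped; raises
    ``ValueError`` if the intersection is empty (downstream scoring would
    be undefined).
    """
    uni = {normalize_symbol(g) for g in universe}
    if not uni:
        raise ValueError("universe must be non-empty")
    kept = {g: ts for g, ts in catalog.entries.items() if g in uni}
    dropped = sorted(set(catalog.entries) - set(kept))
    if not kept:
        raise ValueError(
            f"no catalog gene found in the universe ({len(catalog.entries)} catalog "
            f"genes vs {len(uni)} universe genes)"
        )
    if dropped and len(dropped) / len(catalog.entries) > 0.10:
        logger.warning(
            "restrict_to_universe dropped %d/%d catalog genes (>10%%)",
            len(dropped),
            len(catalog.entries),
        )
    used_types = {t for ts in kept.values() for t in ts}
    sources = {t: list(s) for t, s in catalog.sources.items() if t in used_types}
    return PanPCDCatalog(entries=dict(sorted(kept.items())), sources=sources), dropped
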