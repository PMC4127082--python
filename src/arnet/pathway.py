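"""Gene-set (GO-style) enrichment of module gene lists.

Replaces web-based annotation tools with a plain GMT-driven one-sided
Fisher's exact test over a configurable gene universe, BH-adjusted across
all (module, set) tests. A tiny synthetic "mitochondria-like" collection
ships with the package for demonstrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .integrate import bh_adjust, fisher_enrichment_2x2

ENRICH_COLUMNS = ["module", "set_name", "overlap", "set_size", "module_size", "fold", "p", "q"]


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets not allowed: {empty}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(source) -> GeneSetCollection:
    """Parse a GMT file (or iterable of lines): name, description, gene ids.

    Duplicate gene ids within a line are collapsed; duplicate set names and
    lines with fewer than 3 tab-separated fields are errors (reported with
    their line number).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.read().splitlines()
    else:
        lines = [str(l).rstrip("\n") for l in source]

    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"GMT line {lineno}: expected at least 3 tab-separated fields "
                f"(name, description, genes), got {len(fields)}"
            )
        name, desc, *genes = fields
        if name in sets:
            raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
        sets[name] = frozenset(g for g in genes if g)
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def toy_collection() -> GeneSetCollection:
    """The packaged synthetic demo collection (mitochondria-like and friends)."""
    ref = resources.files("arnet.data").joinpath("toy_pathways.gmt")
    return read_gmt(ref.read_text().splitlines())


def enrich_module(
    module_genes,
    collection: GeneSetCollection,
    universe,
    module_label: str = "module",
) -> pd.DataFrame:
    """One-sided Fisher enrichment of one module against every gene set.

    Sets are intersected with the universe before testing; fold =
    (overlap / module size) / (set-in-universe size / universe size).
    The returned q is BH-adjusted across the sets tested for this module;
    use :func:`enrich_modules` to adjust across several modules at once.
    """
    universe = frozenset(universe)
    module_genes = frozenset(module_genes)
    if not universe:
        raise ValueError("empty gene universe")
    if not module_genes:
        raise ValueError("empty module gene list")
    if not module_genes <= universe:
        raise ValueError("module genes must be a subset of the universe")

    rows = []
    for name, genes in collection.sets.items():
        in_univ = genes & universe
        if not in_univ:
            continue
        overlap = len(module_genes & in_univ)
        fold, p = fisher_enrichment_2x2(
            overlap, len(module_genes), len(in_univ), len(universe)
        )
        rows.append(
            {"module": module_label, "set_name": name, "overlap": overlap,
             "set_size": len(in_univ), "module_size": len(module_genes),
             "fold": fold, "p": p}
        )
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def enrich_modules(
    module_map: dict[str, set[str]],
    collection: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Enrichment for several modules with BH across all (module, set) tests."""
    frames = [
        enrich_module(genes, collection, universe, module_label=label)
        for label, genes in module_map.items()
        if genes
    ]
    if not frames:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
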