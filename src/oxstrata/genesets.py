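"""Named gene-set collections with GMT round-trip and a synthetic generator.

Gene sets are the scoring unit of the composite oxidative-stress score:
five curated pathway collections (HALLMARK / KEGG / REACTOME / GOBP / WP
sources in the real study) whose member genes partially overlap.  The
synthetic generator reproduces that structure: sets of prescribed sizes
drawn from a gene universe, sharing a designated common core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import InvalidConfigError

#: source labels used for the five default oxidative-stress sets
DEFAULT_SOURCES = ("HALLMARK", "KEGG", "REACTOME", "GOBP", "WP")

#: set sizes of the five curated oxidative-stress collections
DEFAULT_SET_SIZES = (23, 18, 17, 16, 16)


@dataclass
class GeneSetCollection:
    """Ordered mapping of set name -> member genes, with a source label each."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.sets.items()}

    def union(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.sets.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Drop genes absent from `universe`, keeping set order."""
        uni = set(universe)
        return GeneSetCollection(
            sets={n: [g for g in gs if g in uni] for n, gs in self.sets.items()},
            sources=dict(self.sources),
        )

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                desc = self.sources.get(name, "na")
                fh.write("\t".join([name, desc, *genes]) + "\n")

    @classmethod
    def read_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        sources: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                name, desc, *genes = line.split("\t")
                sets[name] = [g for g in genes if g]
                sources[name] = desc
        return cls(sets=sets, sources=sources)


def generate_gene_sets(
    sizes: Sequence[int],
    universe: Sequence[str],
    overlap_frac: float = 0.25,
    seed: int = 0,
    sources: Sequence[str] | None = None,
) -> GeneSetCollection:
    """Draw gene sets of the requested sizes sharing a common core.

    A core of ``round(overlap_frac * min(sizes))`` genes is sampled once and
    placed in every set; the remainder of each set is drawn (without
    replacement within the set) from the rest of the universe.

    Parameters
    ----------
    sizes
        Exact size of each set.
    universe
        Gene identifiers to draw from.
    overlap_frac
        Fraction of the smallest set shared by all sets.
    seed
        Seed for the one generator used for all draws.
    sources
        Optional source label per set; defaults to HALLMARK/KEGG/... cycling.
    """
    universe = list(universe)
    if not sizes:
        raise InvalidConfigError("at least one set size required")
    if not 0 <= overlap_frac <= 1:
        raise InvalidConfigError(f"overlap_frac must be in [0,1], got {overlap_frac}")
    for s in sizes:
        if s < 1:
            raise InvalidConfigError(f"set size must be positive, got {s}")
        if s > len(universe):
            raise InvalidConfigError(
                f"set size {s} exceeds universe of {len(universe)} genes"
            )
    rng = np.random.default_rng(seed)
    n_core = int(round(overlap_frac * min(sizes)))
    n_core = min(n_core, min(sizes))
    core = list(rng.choice(universe, size=n_core, replace=False)) if n_core else []
    rest = [g for g in universe if g not in set(core)]

    if sources is None:
        sources = [DEFAULT_SOURCES[i % len(DEFAULT_SOURCES)] for i in range(len(sizes))]
    coll = GeneSetCollection()
    for i, size in enumerate(sizes):
        extra = list(rng.choice(rest, size=size - n_core, replace=False))
        name = f"{sources[i]}_OXIDATIVE_STRESS_{i}"
        coll.sets[name] = core + extra
        coll.sources[name] = sources[i]
    return coll


def default_oxidative_stress_sets(
    universe: Sequence[str], overlap_frac: float = 0.25, seed: int = 0
) -> GeneSetCollection:
    """The five-set collection (sizes 23/18/17/16/16) used throughout."""
    return generate_gene_sets(
        DEFAULT_SET_SIZES, universe, overlap_frac=overlap_frac, seed=seed,
        sources=list(DEFAULT_SOURCES),
    )
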