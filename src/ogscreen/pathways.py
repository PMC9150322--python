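"""Overlapping gene groups and the latent-effect expansion.

A collection of (possibly overlapping) gene groups is turned into a binary
expansion map ``S`` (genes x latent columns) so that gene-level coefficients
can be written as sums of per-group latent coefficients, ``beta = S @ gamma``.
Latent columns are stacked group by group, genes in within-group order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PathwayCollection",
    "ExpansionMap",
    "build_expansion",
    "collapse_latent",
    "chain_layout",
]


@dataclass(frozen=True)
class PathwayCollection:
    """Named, possibly overlapping groups of genes.

    Parameters
    ----------
    group_names:
        Identifier per group.
    members:
        Per group, the ordered list of gene identifiers it contains.
    genes:
        Master list of unique gene identifiers. If omitted it is derived
        from the members in order of first appearance.
    """

    group_names: tuple[str, ...]
    members: tuple[tuple[str, ...], ...]
    genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.group_names) != len(self.members):
            raise ValueError("group_names and members must have equal length")
        if len(self.group_names) < 1:
            raise ValueError("need at least one group")
        if len(set(self.group_names)) != len(self.group_names):
            raise ValueError("duplicate group names")
        for name, genes in zip(self.group_names, self.members):
            if len(genes) == 0:
                raise ValueError(f"group {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"group {name!r} contains a duplicated gene")
        if not self.genes:
            seen: dict[str, None] = {}
            for genes in self.members:
                for g in genes:
                    seen.setdefault(g, None)
            object.__setattr__(self, "genes", tuple(seen))
        universe = set(self.genes)
        for name, genes in zip(self.group_names, self.members):
            for g in genes:
                if g not in universe:
                    raise ValueError(
                        f"group {name!r} references unknown gene {g!r}"
                    )

    @property
    def G(self) -> int:
        """Number of groups."""
        return len(self.group_names)

    @property
    def p(self) -> int:
        """Number of unique genes."""
        return len(self.genes)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(m) for m in self.members)

    def genes_of(self, group_ids: Sequence[str]) -> tuple[str, ...]:
        """Deduplicated union of member genes over the named groups,
        in master-gene-list order."""
        wanted = set()
        for gid in group_ids:
            wanted.update(self.members[self.group_names.index(gid)])
        return tuple(g for g in self.genes if g in wanted)


@dataclass(frozen=True)
class ExpansionMap:
    """Binary map from latent (group-specific) coefficients to gene coefficients.

    ``S`` is ``p x d`` with exactly one 1 per column; row *k* carries one 1
    for every group containing gene *k*. ``column_index[j]`` is the
    ``(group_name, gene)`` pair latent column *j* represents.
    """

    S: np.ndarray
    column_index: tuple[tuple[str, str], ...]
    pathways: PathwayCollection

    @property
    def d(self) -> int:
        """Total latent-effect count (sum of group sizes)."""
        return self.S.shape[1]

    @property
    def p(self) -> int:
        return self.S.shape[0]

    def group_column_slices(self) -> dict[str, slice]:
        """Contiguous latent-column slice per group (columns are stacked
        group by group)."""
        out: dict[str, slice] = {}
        start = 0
        for name, members in zip(self.pathways.group_names, self.pathways.members):
            out[name] = slice(start, start + len(members))
            start += len(members)
        return out


def build_expansion(pathways: PathwayCollection) -> ExpansionMap:
    """Build the latent-effect expansion map ``S`` for a group collection.

    Column *j* of ``S`` corresponds to one (group, gene) membership; the
    number of latent columns ``d`` equals the sum of the group sizes.
    """
    gene_pos = {g: i for i, g in enumerate(pathways.genes)}
    d = sum(pathways.sizes)
    S = np.zeros((pathways.p, d), dtype=np.int8)
    column_index: list[tuple[str, str]] = []
    j = 0
    for name, members in zip(pathways.group_names, pathways.members):
        for g in members:
            S[gene_pos[g], j] = 1
            column_index.append((name, g))
            j += 1
    return ExpansionMap(S=S, column_index=tuple(column_index), pathways=pathways)


def collapse_latent(gamma: np.ndarray, expansion: ExpansionMap) -> np.ndarray:
    """Collapse a latent coefficient vector to the gene scale: ``beta = S @ gamma``."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (expansion.d,):
        raise ValueError(
            f"gamma has length {gamma.shape}, expected ({expansion.d},)"
        )
    return expansion.S.astype(float) @ gamma


def chain_layout(
    sizes: Sequence[int],
    overlaps: Sequence[int],
    gene_prefix: str = "G",
) -> PathwayCollection:
    """Lay out groups on consecutive gene indices with pairwise chained overlap.

    Group ``j+1`` starts ``overlaps[j]`` genes before group ``j`` ends, so the
    unique gene count is ``sum(sizes) - sum(overlaps)``. Genes are named
    ``{gene_prefix}1 .. {gene_prefix}p`` (1-based).
    """
    sizes = list(sizes)
    overlaps = list(overlaps)
    if len(overlaps) != len(sizes) - 1:
        raise ValueError("need exactly len(sizes) - 1 overlap counts")
    for j, ov in enumerate(overlaps):
        if ov < 0 or ov >= min(sizes[j], sizes[j + 1]):
            raise ValueError(
                f"overlap {ov} between groups {j + 1} and {j + 2} must be "
                f"smaller than both adjacent sizes"
            )
    p = sum(sizes) - sum(overlaps)
    genes = tuple(f"{gene_prefix}{i}" for i in range(1, p + 1))
    members: list[tuple[str, ...]] = []
    start = 0  # 0-based index of the group's first gene
    for j, size in enumerate(sizes):
        members.append(genes[start : start + size])
        if j < len(overlaps):
            start += size - overlaps[j]
    return PathwayCollection(
        group_names=tuple(str(j + 1) for j in range(len(sizes))),
        members=tuple(members),
        genes=genes,
    )
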