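"""Reference taxonomy: rank order, lineages and name resolution.

The taxonomy is a rank-annotated tree of nodes loaded from two TSV files
modelled on the NCBI dump columns (``nodes``: taxid, parent, rank;
``names``: taxid, name, name class). Lineages are reported over the fixed
rank list ``R = (species, genus, family, order, class, phylum,
superkingdom)``; ranks outside R (``strain``, ``no rank``, ...) are
carried on the nodes but take no part in the rank order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered rank list, lowest (most specific) first.
RANKS: tuple[str, ...] = (
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "superkingdom",
)

DEFAULT_R_MAX = "family"


def rank_below(r_i: str, r_j: str) -> bool:
    """True iff rank ``r_i`` is strictly below (more specific than) ``r_j``.

    Both ranks must be members of :data:`RANKS`; the relation is the strict
    total order induced by the list, so it is irreflexive and transitive.
    """
    for r in (r_i, r_j):
        if r not in RANKS:
            raise ValueError(f"unknown rank: {r!r} (expected one of {RANKS})")
    return RANKS.index(r_i) < RANKS.index(r_j)


def ranks_up_to(r_max: str) -> tuple[str, ...]:
    """The ranks searched during community design: species up to ``r_max`` inclusive."""
    if r_max not in RANKS:
        raise ValueError(f"unknown rank: {r_max!r} (expected one of {RANKS})")
    return RANKS[: RANKS.index(r_max) + 1]


@dataclass
class TaxNode:
    taxid: str
    parent: str
    rank: str
    name: str = ""
    synonyms: list[str] = field(default_factory=list)


@dataclass
class TaxonomyDB:
    """A loaded reference taxonomy.

    ``nodes`` maps taxon id to :class:`TaxNode`; ``root`` is the id whose
    parent is itself (NCBI convention) or empty. Taxon ids are opaque
    strings throughout.
    """

    nodes: dict[str, TaxNode]
    root: str

    def __post_init__(self) -> None:
        self._name_index: dict[str, str] = {}
        self._synonym_index: dict[str, str] = {}
        self._ci_index: dict[str, str] = {}
        for tid, node in self.nodes.items():
            if node.name:
                self._name_index.setdefault(node.name, tid)
                self._ci_index.setdefault(node.name.casefold(), tid)
            for syn in node.synonyms:
                self._synonym_index.setdefault(syn, tid)
                self._ci_index.setdefault(syn.casefold(), tid)
        self._validate()

    def _validate(self) -> None:
        if self.root not in self.nodes:
            raise ValueError(f"root taxid {self.root!r} missing from nodes")
        for tid in self.nodes:
            seen = set()
            cur = tid
            while cur != self.root:
                if cur in seen:
                    raise ValueError(f"cycle in parent chain at taxid {cur!r}")
                seen.add(cur)
                parent = self.nodes[cur].parent
                if parent not in self.nodes:
                    raise ValueError(f"taxid {cur!r} has unknown parent {parent!r}")
                cur = parent

    # -- loading ----------------------------------------------------------

    @classmethod
    def from_tsv(
        cls, nodes_path: str | Path, names_path: str | Path | None = None, sep: str = "\t"
    ) -> "TaxonomyDB":
        """Load from ``nodes``/``names`` TSV files.

        ``nodes``: three columns taxid, parent taxid, rank. ``names``: three
        columns taxid, name, name class with class in {``scientific name``,
        ``synonym``}. NCBI-style ``\\t|\\t`` separators are normalised away.
        """
        nodes_df = pd.read_csv(
            nodes_path, sep=sep, header=None, dtype=str, comment=None, keep_default_na=False
        )
        nodes_df = nodes_df.apply(lambda col: col.str.strip().str.strip("|").str.strip())
        nodes: dict[str, TaxNode] = {}
        root = ""
        for taxid, parent, rank in nodes_df.iloc[:, :3].itertuples(index=False):
            nodes[taxid] = TaxNode(taxid=taxid, parent=parent, rank=rank)
            if taxid == parent:
                root = taxid
        if not root:
            # fall back: a node whose parent is absent from the table
            for node in nodes.values():
                if node.parent not in nodes:
                    root = node.taxid
                    node.parent = node.taxid
                    break
        if names_path is not None:
            names_df = pd.read_csv(
                names_path, sep=sep, header=None, dtype=str, keep_default_na=False
            )
            names_df = names_df.apply(lambda col: col.str.strip().str.strip("|").str.strip())
            for taxid, name, name_class in names_df.iloc[:, :3].itertuples(index=False):
                node = nodes.get(taxid)
                if node is None:
                    logger.warning("names entry for unknown taxid %s ignored", taxid)
                    continue
                if name_class == "scientific name":
                    node.name = name
                else:
                    node.synonyms.append(name)
        return cls(nodes=nodes, root=root)

    # -- queries ----------------------------------------------------------

    def __contains__(self, taxid: str) -> bool:
        return taxid in self.nodes

    def rank(self, taxid: str) -> str:
        return self._node(taxid).rank

    def name(self, taxid: str) -> str:
        return self._node(taxid).name

    def _node(self, taxid: str) -> TaxNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise KeyError(f"unknown taxid: {taxid!r}") from None

    def lineage(self, taxid: str) -> dict[str, str | None]:
        """Project the ancestor chain of ``taxid`` onto :data:`RANKS`.

        Returns a map rank -> taxon id for every rank in R at which the
        node itself or one of its ancestors is annotated, else ``None``.
        """
        out: dict[str, str | None] = {r: None for r in RANKS}
        cur = self._node(taxid)
        while True:
            if cur.rank in out and out[cur.rank] is None:
                out[cur.rank] = cur.taxid
            if cur.taxid == self.root:
                break
            cur = self.nodes[cur.parent]
        return out

    def map_name_to_taxid(self, name: str) -> str | None:
        """Resolve a free-text scientific name to a taxon id.

        Resolution cascade: exact scientific-name match, exact synonym
        match, case-insensitive match over both, then genus fallback on the
        first whitespace token. Unresolvable names return ``None`` with a
        warning; this never raises.
        """
        name = name.strip()
        if not name:
            logger.warning("NAME-UNRESOLVED empty name")
            return None
        hit = self._name_index.get(name)
        if hit is not None:
            logger.debug("name %r resolved by exact scientific name -> %s", name, hit)
            return hit
        hit = self._synonym_index.get(name)
        if hit is not None:
            logger.debug("name %r resolved by exact synonym -> %s", name, hit)
            return hit
        hit = self._ci_index.get(name.casefold())
        if hit is not None:
            logger.debug("name %r resolved case-insensitively -> %s", name, hit)
            return hit
        genus_token = name.split()[0]
        if genus_token != name:
            hit = self._ci_index.get(genus_token.casefold())
            if hit is not None and self.nodes[hit].rank == "genus":
                logger.debug("name %r resolved by genus fallback -> %s", name, hit)
                return hit
        logger.warning("NAME-UNRESOLVED could not map name %r to a taxid", name)
        return None
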