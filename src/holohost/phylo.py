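"""Phylogeny-ordered parasite-genus x host-family interaction matrices.

Columns of the presence matrix follow the left-to-right tip order of a
family-level seed-plant phylogeny (newick), so that phylogenetic
structure in host preference is visible directly in the matrix.  Host
families recorded in the data but absent from the tree are appended after
the ordered columns and reported, never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .records import RecordSet

logger = logging.getLogger(__name__)


@dataclass
class FamilyTree:
    tree: dendropy.Tree
    tip_order: list[str]

    @property
    def n_tips(self) -> int:
        return len(self.tip_order)


@dataclass
class InteractionMatrix:
    #: bool DataFrame; index = parasite genus, columns = host families
    matrix: pd.DataFrame
    #: parasite genus -> parasite family (row grouping)
    genus_family: dict[str, str]
    #: host families in the data but not on the tree (appended columns)
    families_not_in_tree: list[str] = field(default_factory=list)
    provenance: str = ""


def _norm(name: str) -> str:
    return " ".join(name.split()).strip()


def read_tree(path) -> FamilyTree:
    """Parse a newick family-level tree; tips must be uniquely labelled.

    Branch lengths are preserved but unused.  Tip order is the
    left-to-right order of the newick as written (no ladderization).
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick in {path}: {exc}") from exc
    tips = [_norm(leaf.taxon.label) for leaf in tree.leaf_node_iter()
            if leaf.taxon is not None]
    if len(set(tips)) != len(tips):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise ValueError(f"duplicate tip label(s): {', '.join(dupes)}")
    logger.info("read tree with %d tips from %s", len(tips), path)
    return FamilyTree(tree=tree, tip_order=tips)


def interaction_matrix(analysis_set: RecordSet,
                       tree: FamilyTree) -> InteractionMatrix:
    """Presence matrix: cell (genus, family) is True iff at least one
    analysis-set record links that parasite genus to that host family."""
    pairs: set[tuple[str, str]] = set()
    genus_family: dict[str, str] = {}
    families: set[str] = set()
    for r in analysis_set:
        genus = _norm(r.parasite_genus)
        fam = _norm(r.host_family)
        pairs.add((genus, fam))
        genus_family.setdefault(genus, r.parasite_family)
        families.add(fam)

    tip_set = set(tree.tip_order)
    ordered = [f for f in tree.tip_order if f in families]
    extra = sorted(families - tip_set)
    if extra:
        logger.warning("host families not on the tree (appended): %s",
                       ", ".join(extra))
    cols = ordered + extra
    # rows grouped by parasite family, then genus name
    rows = sorted(genus_family, key=lambda g: (genus_family[g], g))
    m = pd.DataFrame(False, index=pd.Index(rows, name="parasite_genus"),
                     columns=pd.Index(cols, name="host_family"))
    for genus, fam in pairs:
        m.loc[genus, fam] = True
    return InteractionMatrix(matrix=m, genus_family=genus_family,
                             families_not_in_tree=extra,
                             provenance=analysis_set.provenance)


def top_hosts(m: InteractionMatrix, k: int) -> pd.DataFrame:
    """Rank host families by number of parasite genera recorded on them.

    Ties break by number of parasite lineages, then family name.  If
    ``k`` exceeds the number of families, the full ranking is returned
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    genus_counts = m.matrix.sum(axis=0)
    lineage_counts = {}
    for fam in m.matrix.columns:
        genera = m.matrix.index[m.matrix[fam]]
        lineage_counts[fam] = len({m.genus_family[g] for g in genera})
    ranking = pd.DataFrame({
        "host_family": m.matrix.columns,
        "n_parasite_genera": genus_counts.values,
        "n_parasite_lineages": [lineage_counts[f] for f in m.matrix.columns],
    }).sort_values(
        ["n_parasite_genera", "n_parasite_lineages", "host_family"],
        ascending=[False, False, True], ignore_index=True)
    if k > len(ranking):
        logger.warning("k=%d exceeds %d host families; returning all",
                       k, len(ranking))
        return ranking
    return ranking.head(k)


def matrix_to_edge_list(m: InteractionMatrix) -> pd.DataFrame:
    """Long-format edge list (parasite_genus, host_family) of the matrix."""
    stacked = m.matrix.stack()
    edges = stacked[stacked].index.to_frame(index=False)
    edges.columns = ["parasite_genus", "host_family"]
    return edges
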