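"""Readers and writers for every external representation the pipeline touches.

The pipeline works with five external formats:

* aligned amino-acid FASTA (per gene family, ``-`` gaps, lowercase or ``X``
  masked residues),
* Newick trees with jplace-style ``{n}`` edge annotations,
* jplace v3 JSON placement files,
* a TSV sample map (``read_id``, ``sample_id``, ``depth_m``),
* a TSV taxonomy table (``taxon_id``, semicolon-delimited ranked lineage).

Validation is strict: inputs violating an invariant raise :class:`FormatError`
or :class:`ConsistencyError`; nothing is silently repaired.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residue alphabet: upper-case amino acids, lower-case masked, X unknown, - gap.
ALPHABET = frozenset(AMINO_ACIDS + AMINO_ACIDS.lower() + "Xx-")

#: Canonical rank order used by the synthetic taxonomy and the TSV reader.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


class FormatError(ValueError):
    """An external file violates its format contract."""


class ConsistencyError(ValueError):
    """Inputs are individually valid but mutually inconsistent."""


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedSequence:
    """One aligned row: uppercase = unmasked residue, lowercase/X = masked."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"sequence {self.id!r}: empty residues")
        for pos, ch in enumerate(self.residues):
            if ch not in ALPHABET:
                raise FormatError(
                    f"sequence {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    @property
    def n_unmasked(self) -> int:
        """Number of unmasked standard amino acids (excludes gaps, X, lowercase)."""
        return sum(c in AMINO_ACIDS for c in self.residues)


@dataclass
class GeneFamilyAlignment:
    """All aligned members of one marker gene family."""

    family_id: str
    members: list[AlignedSequence]
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"family {self.family_id!r}: no sequences")
        lengths = {len(m.residues) for m in self.members}
        if len(lengths) != 1:
            bad = next(
                m.id for m in self.members
                if len(m.residues) != len(self.members[0].residues)
            )
            raise FormatError(
                f"family {self.family_id!r}: ragged lengths (offending id {bad!r})"
            )
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"family {self.family_id!r}: duplicate id {dup!r}")
        self.n_columns = lengths.pop()

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def row(self, seq_id: str) -> str:
        for m in self.members:
            if m.id == seq_id:
                return m.residues
        raise KeyError(seq_id)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]


def read_alignment(path, family_id: str) -> GeneFamilyAlignment:
    """Read an aligned FASTA file, preserving masked-residue casing."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    members = [AlignedSequence(r.id, str(r.seq)) for r in records]
    return GeneFamilyAlignment(family_id, members)


def write_alignment(aln: GeneFamilyAlignment, path) -> None:
    records = [
        SeqRecord(Seq(m.residues), id=m.id, description="") for m in aln.members
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Sample map and taxonomy
# ---------------------------------------------------------------------------

@dataclass
class SampleMap:
    """Read-to-sample assignment plus per-sample water depth in metres."""

    read_to_sample: dict[str, str]
    sample_depth: dict[str, float]

    def __post_init__(self) -> None:
        for sid, depth in self.sample_depth.items():
            if not depth > 0:
                raise FormatError(f"sample {sid!r}: depth {depth} must be > 0")
        missing = set(self.read_to_sample.values()) - set(self.sample_depth)
        if missing:
            raise ConsistencyError(f"samples without depth: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return sorted(self.sample_depth)

    def reads_of(self, sample_id: str) -> list[str]:
        return sorted(r for r, s in self.read_to_sample.items() if s == sample_id)


def read_sample_map(path) -> SampleMap:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "sample_id": str})
    required = {"read_id", "sample_id", "depth_m"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: sample map needs columns {sorted(required)}")
    if df["read_id"].duplicated().any():
        dup = df.loc[df["read_id"].duplicated(), "read_id"].iloc[0]
        raise FormatError(f"{path}: duplicate read id {dup!r}")
    depth = {}
    for sid, grp in df.groupby("sample_id"):
        vals = set(grp["depth_m"])
        if len(vals) != 1:
            raise ConsistencyError(f"sample {sid!r}: conflicting depths {sorted(vals)}")
        depth[str(sid)] = float(vals.pop())
    return SampleMap(dict(zip(df["read_id"], df["sample_id"])), depth)


def write_sample_map(sm: SampleMap, path) -> None:
    rows = [
        {"read_id": r, "sample_id": s, "depth_m": sm.sample_depth[s]}
        for r, s in sorted(sm.read_to_sample.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class TaxonomyTable:
    """Ranked lineages (root rank first) for every reference taxon."""

    lineage: dict[str, tuple[tuple[str, str], ...]]

    def __post_init__(self) -> None:
        roots = {lin[0][0] for lin in self.lineage.values() if lin}
        if len(roots) > 1:
            raise FormatError(f"lineages start at inconsistent root ranks: {sorted(roots)}")

    @property
    def root_rank(self) -> str:
        return next(iter(self.lineage.values()))[0][0]

    def of(self, taxon_id: str) -> tuple[tuple[str, str], ...]:
        try:
            return self.lineage[taxon_id]
        except KeyError:
            raise ConsistencyError(f"taxon {taxon_id!r} missing from taxonomy") from None


def read_taxonomy(path, ranks: tuple[str, ...] = RANKS) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"taxon_id", "lineage"}.issubset(df.columns):
        raise FormatError(f"{path}: taxonomy needs columns taxon_id, lineage")
    out = {}
    for _, row in df.iterrows():
        names = [n for n in str(row["lineage"]).split(";") if n]
        if len(names) > len(ranks):
            raise FormatError(
                f"{path}: lineage for {row['taxon_id']!r} deeper than ranks {ranks}"
            )
        out[str(row["taxon_id"])] = tuple(zip(ranks, names))
    return TaxonomyTable(out)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    rows = [
        {"taxon_id": tid, "lineage": ";".join(name for _, name in lin)}
        for tid, lin in sorted(tax.lineage.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

_EDGE_ANNOT = re.compile(r"\{(\d+)\}")


class Phylogeny:
    """An edge-numbered phylogeny with branch lengths in substitutions/site.

    The tree is canonicalized on construction: it is rooted at the internal
    node adjacent to the lexicographically smallest leaf (a fixed, arbitrary
    convention — the underlying model is reversible so the likelihood does
    not depend on it), children are ordered by their smallest descendant
    label, and edges are numbered in preorder.  This makes edge numbers
    stable across runs and across serialisation round-trips, which the
    bootstrap aggregation relies on.
    """

    def __init__(self, tree: dendropy.Tree):
        self._t = tree
        self._canonicalize()
        self._number_edges()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        stripped = _EDGE_ANNOT.sub("", newick)
        try:
            tree = dendropy.Tree.get(
                data=stripped, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as err:
            raise FormatError(f"invalid Newick: {err}") from err
        return cls(tree)

    def _canonicalize(self) -> None:
        t = self._t
        labels = [lf.taxon.label for lf in t.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dup = next(l for l in labels if labels.count(l) > 1)
            raise FormatError(f"duplicate leaf label {dup!r}")
        if len(labels) < 2:
            raise FormatError("tree must have at least 2 leaves")
        # a degree-2 seed node is an artifact of a rooted serialization, not a
        # node of the unrooted topology: collapse it so the canonical form is
        # unique per unrooted tree (likelihood is root-invariant anyway)
        seed_children = t.seed_node.child_nodes()
        if len(seed_children) == 2:
            internal = [c for c in seed_children if not c.is_leaf()]
            if internal:
                t.reroot_at_node(internal[0], update_bipartitions=False,
                                 suppress_unifurcations=True)
        anchor_label = min(labels)
        anchor = next(
            lf for lf in t.leaf_node_iter() if lf.taxon.label == anchor_label
        )
        new_root = anchor.parent_node
        if new_root is not t.seed_node:
            t.reroot_at_node(new_root, update_bipartitions=False,
                             suppress_unifurcations=True)
        while len(t.seed_node.child_nodes()) == 1:
            child = t.seed_node.child_nodes()[0]
            t.reroot_at_node(child, update_bipartitions=False,
                             suppress_unifurcations=True)
        for nd in t.preorder_node_iter():
            if nd is t.seed_node:
                nd.edge.length = None
                continue
            if nd.edge.length is None:
                raise FormatError(
                    f"missing branch length on edge above "
                    f"{nd.taxon.label if nd.taxon else 'an internal node'}"
                )
            if nd.edge.length < 0:
                raise FormatError(f"negative branch length {nd.edge.length}")
        # order children by smallest descendant leaf label
        for nd in t.postorder_node_iter():
            if nd.is_leaf():
                nd._min_label = nd.taxon.label
            else:
                nd._child_nodes.sort(key=lambda c: c._min_label)
                nd._min_label = nd._child_nodes[0]._min_label

    def _number_edges(self) -> None:
        self._edge_nodes: list[dendropy.Node] = []
        for nd in self._t.preorder_node_iter():
            if nd is self._t.seed_node:
                nd.edge_num = None
                continue
            nd.edge_num = len(self._edge_nodes)
            self._edge_nodes.append(nd)

    # -- basic queries ------------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._t

    @property
    def root(self) -> dendropy.Node:
        return self._t.seed_node

    @property
    def n_edges(self) -> int:
        return len(self._edge_nodes)

    @property
    def edge_numbers(self) -> list[int]:
        return list(range(len(self._edge_nodes)))

    def node_of_edge(self, edge_num: int) -> dendropy.Node:
        """The head (child-side) node of a numbered edge."""
        return self._edge_nodes[edge_num]

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._t.leaf_node_iter()]

    def pendant_edge_of(self, leaf_label: str) -> int:
        for lf in self._t.leaf_node_iter():
            if lf.taxon.label == leaf_label:
                return lf.edge_num
        raise KeyError(leaf_label)

    def distal_leaves(self, edge_num: int) -> list[str]:
        """Leaf labels on the side of the edge away from the canonical root."""
        nd = self.node_of_edge(edge_num)
        return [lf.taxon.label for lf in nd.leaf_iter()]

    def patristic_distances(self) -> tuple[list[str], "object"]:
        """Leaf labels and the dense matrix of leaf-to-leaf path lengths."""
        import numpy as np

        # root-to-node distance, then d(i,j) = d(i) + d(j) - 2 d(mrca)
        labels = sorted(self.leaf_labels)
        pdm = self._t.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._t.taxon_namespace if t.label in set(labels)}
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(
                    taxa[labels[i]], taxa[labels[j]]
                )
        return labels, d

    # -- serialization ------------------------------------------------------

    def to_newick(self, annotate_edges: bool = True) -> str:
        def fmt(nd: dendropy.Node) -> str:
            if nd.is_leaf():
                core = nd.taxon.label
            else:
                core = "(" + ",".join(fmt(c) for c in nd.child_nodes()) + ")"
            if nd is self._t.seed_node:
                return core
            suffix = f":{nd.edge.length!r}"
            if annotate_edges:
                suffix += f"{{{nd.edge_num}}}"
            return core + suffix

        return fmt(self._t.seed_node) + ";"

    def clone(self) -> "Phylogeny":
        return Phylogeny.from_newick(self.to_newick(annotate_edges=False))


def read_tree(path) -> Phylogeny:
    with open(path) as fh:
        text = fh.read().strip()
    if not text:
        raise FormatError(f"{path}: empty tree file")
    return Phylogeny.from_newick(text)


def write_tree(phy: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(phy.to_newick() + "\n")


# ---------------------------------------------------------------------------
# jplace
# ---------------------------------------------------------------------------

def write_placements(placements, distributions, phy: Phylogeny, path) -> None:
    """Write placements as jplace v3 with a bootstrap-frequency extension.

    ``placements`` is an iterable of :class:`~phylopd.placement.Placement`;
    ``distributions`` maps read id -> ``PlacementDistribution`` (may be empty).
    """
    valid = set(phy.edge_numbers)
    entries = []
    for p in placements:
        if p.edge_num not in valid:
            raise ConsistencyError(
                f"read {p.read_id!r}: edge {p.edge_num} not in reference tree"
            )
        entries.append(
            {"p": [[p.edge_num, p.log_likelihood, p.pendant_length]],
             "n": [p.read_id]}
        )
    boots = {}
    for read_id, dist in distributions.items():
        total = sum(dist.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ConsistencyError(
                f"read {read_id!r}: bootstrap frequencies sum to {total}, not 1"
            )
        for e in dist.freq:
            if e not in valid:
                raise ConsistencyError(
                    f"read {read_id!r}: edge {e} not in reference tree"
                )
        boots[read_id] = {str(e): f for e, f in sorted(dist.freq.items())}
    doc = {
        "version": 3,
        "tree": phy.to_newick(),
        "fields": ["edge_num", "likelihood", "pendant_length"],
        "placements": entries,
        "metadata": {"invocation": "phylopd"},
        "bootstrap_frequencies": boots,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_placements(path):
    """Read back a jplace file written by :func:`write_placements`."""
    from .placement import Placement, PlacementDistribution

    with open(path) as fh:
        doc = json.load(fh)
    fields = doc["fields"]
    idx = {f: i for i, f in enumerate(fields)}
    placements = []
    for entry in doc["placements"]:
        row = entry["p"][0]
        placements.append(
            Placement(
                read_id=entry["n"][0],
                edge_num=int(row[idx["edge_num"]]),
                pendant_length=float(row[idx["pendant_length"]]),
                log_likelihood=float(row[idx["likelihood"]]),
            )
        )
    distributions = {
        read_id: PlacementDistribution(
            read_id=read_id, freq={int(e): f for e, f in d.items()}
        )
        for read_id, d in doc.get("bootstrap_frequencies", {}).items()
    }
    tree = Phylogeny.from_newick(doc["tree"])
    return placements, distributions, tree
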