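"""Shared domain types and file I/O.

The pipeline's currency is three objects: :class:`Specimen` (one sampled
individual with its life stage and species label), :class:`GeneTree` (a rooted
gene tree whose tips map to one or more specimens — more than one when tips
are collapsed haplotypes), and :class:`ClusterPartition` (a disjoint
assignment of specimens to delimited clusters, tagged by gene and method).

Trees are carried as :class:`dendropy.Tree` objects; this module only adds
the thin domain layer (tip maps, node supports, ultrametricity checks) that
the delimiters and the association engine need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

UNKNOWN = "UNKNOWN"
STAGES = ("adult", "larva", "pupa")

#: Columns of the specimen table that are not per-gene availability flags.
_RESERVED_COLUMNS = {"id", "stage", "species", "sex"}


class FormatError(ValueError):
    """A file does not conform to the expected format."""


class DataError(ValueError):
    """A file parses but its content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Specimens


@dataclass(frozen=True)
class Specimen:
    """One sampled individual.

    Adults may carry ``species=UNKNOWN`` (e.g. unidentified females); larvae
    and pupae always enter the analysis as UNKNOWN — associating them with an
    adult morphospecies is the point of the pipeline.
    """

    id: str
    stage: str
    species: str = UNKNOWN
    sex: str | None = None
    has_gene: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise DataError(f"unknown life stage {self.stage!r} for specimen {self.id!r}")
        if self.sex not in (None, "M", "F"):
            raise DataError(f"unknown sex code {self.sex!r} for specimen {self.id!r}")

    @property
    def is_adult(self) -> bool:
        return self.stage == "adult"

    @property
    def is_immature(self) -> bool:
        """Larvae and pupae are processed identically throughout."""
        return self.stage in ("larva", "pupa")

    @property
    def is_identified(self) -> bool:
        return self.species != UNKNOWN


def read_specimen_table(path) -> list[Specimen]:
    """Read a TSV/CSV specimen table into validated :class:`Specimen` objects.

    Required columns: ``id``, ``stage``; optional ``species`` (empty/NA coded
    as UNKNOWN) and ``sex``. Every remaining column is interpreted as a gene
    availability flag (0/1, true/false, yes/no).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    missing = {"id", "stage"} - set(df.columns)
    if missing:
        raise FormatError(f"specimen table lacks required column(s): {sorted(missing)}")
    genes = [c for c in df.columns if c not in _RESERVED_COLUMNS]

    specimens: list[Specimen] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["id"].strip()
        if not sid:
            raise DataError("empty specimen id")
        if sid in seen:
            raise DataError(f"duplicate specimen id {sid!r}")
        seen.add(sid)
        species = row.get("species", "").strip() or UNKNOWN
        if species.upper() in ("NA", "UNKNOWN", "?"):
            species = UNKNOWN
        sex = row.get("sex", "").strip() or None
        has_gene = {g: _parse_flag(row[g], sid, g) for g in genes}
        stage = row["stage"].strip().lower()
        if stage in ("larva", "pupa") and species != UNKNOWN:
            # immatures are unidentified by definition; a filled species
            # column would smuggle in the answer the pipeline must produce
            raise DataError(
                f"specimen {sid!r}: stage {stage!r} must have species UNKNOWN, got {species!r}"
            )
        specimens.append(Specimen(id=sid, stage=stage, species=species, sex=sex, has_gene=has_gene))
    return specimens


def _parse_flag(value: str, sid: str, gene: str) -> bool:
    v = str(value).strip().lower()
    if v in ("1", "true", "yes", "y"):
        return True
    if v in ("0", "false", "no", "n", ""):
        return False
    raise DataError(f"specimen {sid!r}: cannot parse availability flag {value!r} for gene {gene!r}")


def write_specimen_table(specimens: list[Specimen], path) -> None:
    genes = sorted({g for s in specimens for g in s.has_gene})
    rows = [
        {
            "id": s.id,
            "stage": s.stage,
            "species": "" if s.species == UNKNOWN else s.species,
            "sex": s.sex or "",
            **{g: int(s.has_gene.get(g, False)) for g in genes},
        }
        for s in specimens
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene trees


@dataclass
class GeneTree:
    """A rooted gene tree with branch lengths and (optional) node supports.

    ``tip_map`` maps each tip label to the set of specimen ids it represents
    (singletons unless tips are collapsed haplotypes). Supports are posterior
    probabilities in [0, 1], stored as ``node.support``; the root is assigned
    1.0 by convention.
    """

    gene: str
    tree: dendropy.Tree
    tip_map: dict[str, frozenset[str]] = field(default_factory=dict)
    #: False when the tip map was defaulted to the identity (no haplotype
    #: membership supplied) — GMYC uses this to warn about uncollapsed trees.
    tip_map_explicit: bool = True

    def __post_init__(self):
        labels = self.tip_labels()
        if not self.tip_map:
            self.tip_map = {lab: frozenset([lab]) for lab in labels}
            self.tip_map_explicit = False
        else:
            missing = [lab for lab in labels if lab not in self.tip_map]
            if missing:
                raise DataError(f"tip(s) without tip-map entry: {missing[:5]}")
            # a specimen must not appear under two different tips
            seen: dict[str, str] = {}
            for lab in labels:
                for sid in self.tip_map[lab]:
                    if sid in seen and seen[sid] != lab:
                        raise DataError(f"specimen {sid!r} mapped to tips {seen[sid]!r} and {lab!r}")
                    seen[sid] = lab
            self.tip_map = {lab: frozenset(self.tip_map[lab]) for lab in labels}

    # -- basic accessors ----------------------------------------------------

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def specimen_ids(self) -> set[str]:
        return {sid for ids in self.tip_map.values() for sid in ids}

    def specimens_of(self, labels) -> set[str]:
        return {sid for lab in labels for sid in self.tip_map[lab]}

    def tips_of_specimens(self, specimen_ids) -> set[str]:
        """Tip labels containing at least one of the given specimens."""
        wanted = set(specimen_ids)
        return {lab for lab, ids in self.tip_map.items() if ids & wanted}

    # -- geometry -----------------------------------------------------------

    def node_ages(self) -> dict:
        """Age (time before the youngest tip) of every node."""
        depths = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        height = max(depths[leaf] for leaf in self.tree.leaf_node_iter())
        return {node: height - d for node, d in depths.items()}

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        ages = self.node_ages()
        height = max(ages[n] for n in self.tree.preorder_node_iter())
        scale = max(height, 1e-300)
        return all(abs(ages[leaf]) <= tol * scale for leaf in self.tree.leaf_node_iter())

    def n_zero_length_edges(self) -> int:
        return sum(
            1
            for e in self.tree.preorder_edge_iter()
            if e.head_node.parent_node is not None and (e.length or 0.0) == 0.0
        )

    # -- I/O ----------------------------------------------------------------

    def write(self, path, schema: str = "newick") -> None:
        s = self.as_string(schema=schema)
        with open(path, "w") as fh:
            fh.write(s)

    def as_string(self, schema: str = "newick") -> str:
        tree = self.tree.clone(depth=1)
        for node in tree.preorder_internal_node_iter():
            sup = getattr(node, "support", None)
            if sup is not None and node.parent_node is not None:
                node.label = format(sup, "g")
        return tree.as_string(
            schema=schema, suppress_rooting=False, unquoted_underscores=True
        )

    def clone(self) -> "GeneTree":
        t = self.tree.clone(depth=1)
        for src, dst in zip(self.tree.preorder_node_iter(), t.preorder_node_iter()):
            if hasattr(src, "support"):
                dst.support = src.support
        return GeneTree(gene=self.gene, tree=t, tip_map=dict(self.tip_map),
                        tip_map_explicit=self.tip_map_explicit)


def read_gene_tree(
    path_or_string,
    gene: str,
    format: str = "newick",
    tip_map: dict[str, frozenset[str]] | None = None,
    support_source: str = "label",
    outgroup: str | None = None,
) -> GeneTree:
    """Read a rooted gene tree from newick or NEXUS.

    Node supports are parsed from internal-node labels by default
    (``support_source="label"``); ``support_source="comment"`` reads
    BEAST-style ``[&posterior=...]`` comment fields instead. A basal
    trifurcation (unrooted tree) is rejected unless ``outgroup`` names a tip:
    the tree is then rooted on that tip's edge and the outgroup pruned.
    """
    if format not in ("newick", "nexus"):
        raise FormatError(f"unsupported tree format {format!r}")
    src = str(path_or_string)
    kwargs = dict(schema=format, preserve_underscores=True,
                  suppress_internal_node_taxa=True,
                  extract_comment_metadata=(support_source == "comment"))
    try:
        if "(" in src and ";" in src:
            tree = dendropy.Tree.get(data=src, **kwargs)
        else:
            tree = dendropy.Tree.get(path=src, **kwargs)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise DataError(f"duplicate tip label(s): {exc}") from exc
    except dendropy.utility.error.DataParseError as exc:
        raise FormatError(f"cannot parse tree: {exc}") from exc

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise DataError(f"duplicate tip label(s): {dupes}")

    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise FormatError("tree has edges without branch lengths")

    root = tree.seed_node
    if len(root.child_nodes()) > 2:
        if outgroup is None:
            raise FormatError(
                "basal multifurcation (unrooted tree); supply an outgroup tip to root on"
            )
        _root_on_outgroup(tree, outgroup)
        root = tree.seed_node

    _attach_supports(tree, support_source)

    if outgroup is not None:
        og = [l for l in tree.leaf_node_iter() if l.taxon.label == outgroup]
        if og:
            tree.prune_taxa([og[0].taxon], suppress_unifurcations=True)
            tree.seed_node.support = 1.0

    return GeneTree(gene=gene, tree=tree, tip_map=tip_map or {})


def _root_on_outgroup(tree: dendropy.Tree, outgroup: str) -> None:
    matches = [l for l in tree.leaf_node_iter() if l.taxon.label == outgroup]
    if not matches:
        raise DataError(f"outgroup tip {outgroup!r} not found in tree")
    node = matches[0]
    length = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0,
                        update_bipartitions=False)


def _attach_supports(tree: dendropy.Tree, support_source: str) -> None:
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        sup = None
        if support_source == "label":
            if node.label is not None:
                try:
                    sup = float(node.label)
                except ValueError:
                    sup = None
        elif support_source == "comment":
            value = node.annotations.get_value("posterior", None)
            if value is not None:
                try:
                    sup = float(value)
                except (TypeError, ValueError):
                    sup = None
        else:
            raise FormatError(f"unknown support source {support_source!r}")
        if sup is not None and not (0.0 <= sup <= 1.0):
            raise DataError(f"node support {sup} outside [0, 1]")
        node.support = sup
    # root support 1.0 by convention
    tree.seed_node.support = 1.0


def read_tip_map(path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV ``tip_label<TAB>comma-separated specimen ids``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("tip map needs two columns: tip label, specimen ids")
    out: dict[str, frozenset[str]] = {}
    for _, row in df.iterrows():
        tip = row.iloc[0].strip()
        ids = frozenset(x.strip() for x in row.iloc[1].split(",") if x.strip())
        if tip in out:
            raise DataError(f"duplicate tip {tip!r} in tip map")
        if not ids:
            raise DataError(f"tip {tip!r} maps to no specimens")
        out[tip] = ids
    return out


def write_tip_map(tip_map: dict[str, frozenset[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("tip\tspecimens\n")
        for tip in sorted(tip_map):
            fh.write(f"{tip}\t{','.join(sorted(tip_map[tip]))}\n")


# ---------------------------------------------------------------------------
# Cluster partitions


@dataclass
class ClusterPartition:
    """A disjoint assignment of specimens to delimited clusters."""

    gene: str
    method: str
    clusters: list[frozenset[str]]

    def __post_init__(self):
        self.clusters = [frozenset(c) for c in self.clusters]
        if any(not c for c in self.clusters):
            raise DataError("empty cluster in partition")
        seen: set[str] = set()
        for c in self.clusters:
            if seen & c:
                raise DataError(f"overlapping clusters in {self.gene}/{self.method} partition")
            seen |= c

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def specimen_ids(self) -> set[str]:
        return {sid for c in self.clusters for sid in c}

    def cluster_of(self, specimen_id: str) -> frozenset[str] | None:
        for c in self.clusters:
            if specimen_id in c:
                return c
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": self.gene, "method": self.method, "cluster": i, "specimen": sid}
            for i, c in enumerate(
                sorted(self.clusters, key=lambda c: sorted(c)), start=1
            )
            for sid in sorted(c)
        ]
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_partition(path) -> ClusterPartition:
    df = pd.read_csv(path, sep="\t", dtype={"specimen": str})
    gene = str(df["gene"].iloc[0])
    method = str(df["method"].iloc[0])
    clusters = [frozenset(g["specimen"]) for _, g in df.groupby("cluster")]
    return ClusterPartition(gene=gene, method=method, clusters=clusters)
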