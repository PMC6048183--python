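"""Synthetic datasets with the structure the association pipeline assumes.

The generator draws a species tree from a Yule process, grafts an
independent single-population Kingman coalescent genealogy onto each species
tip for each gene (this is exactly the generating model GMYC fits, which
makes parameter-recovery experiments interpretable), scales branches by a
per-gene substitution rate to obtain PTP-style trees, evolves Jukes-Cantor
sequences, and labels specimens as identified adults or unidentified
larvae/pupae with per-gene missing data.

Defaults emulate the two-marker caddisfly study design this pipeline is
built around: a nuclear locus (CAD, 736 bp, ~33% of specimens without data)
and a mitochondrial barcode (COI, 658 bp, ~14% missing) whose effective
population size is a quarter of the nuclear one, 38 species, ~14 specimens
per species, and roughly 60% immatures.

:func:`inject_paraphyly` re-attaches a fraction of one species' tips inside
another species' clade on one gene, emulating the non-monophyly produced by
incomplete lineage sorting or introgression without modelling either
mechanism explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .core import GeneTree, Specimen, UNKNOWN
from .haplotypes import Alignment

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


def _default_ne():
    return {"CAD": 0.05, "COI": 0.0125}  # mito Ne = 1/4 nuclear


def _default_missing():
    return {"CAD": 0.33, "COI": 0.14}


def _default_rate():
    return {"CAD": 0.5, "COI": 2.0}


def _default_length():
    return {"CAD": 736, "COI": 658}


@dataclass
class SimConfig:
    """Study-design parameters of one synthetic dataset.

    ``depth_ratio``, when set, rescales all effective sizes so that the
    expected ratio (mean species stem age) / (mean within-species TMRCA) of
    the largest-Ne gene hits the target — the knob controlling how cleanly
    species are separated from their internal coalescence.
    """

    n_species: int = 38
    yule_rate: float = 1.0
    coal_ne: dict[str, float] = field(default_factory=_default_ne)
    samples_per_species: int | tuple[int, int] = 14
    larva_fraction: float = 313 / 525
    pupa_fraction: float = 8 / 525
    missing_gene_prob: dict[str, float] = field(default_factory=_default_missing)
    subst_rate: dict[str, float] = field(default_factory=_default_rate)
    seq_length: dict[str, int] = field(default_factory=_default_length)
    gamma_jitter_shape: float | None = None
    depth_ratio: float | None = None
    seed: int = 0

    @property
    def genes(self) -> list[str]:
        return list(self.coal_ne)

    def validate(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        if self.yule_rate <= 0:
            raise ConfigError("yule_rate must be > 0")
        for g, ne in self.coal_ne.items():
            if ne <= 0:
                raise ConfigError(f"coal_ne[{g!r}] must be > 0")
        for name, frac in (("larva_fraction", self.larva_fraction),
                           ("pupa_fraction", self.pupa_fraction)):
            if not 0 <= frac <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.larva_fraction + self.pupa_fraction > 1:
            raise ConfigError("larva_fraction + pupa_fraction must be <= 1")
        for g in self.genes:
            if not 0 <= self.missing_gene_prob.get(g, 0.0) <= 1:
                raise ConfigError(f"missing_gene_prob[{g!r}] must be in [0, 1]")
            if self.subst_rate.get(g, 1.0) <= 0:
                raise ConfigError(f"subst_rate[{g!r}] must be > 0")
            if self.seq_length.get(g, 1) < 1:
                raise ConfigError(f"seq_length[{g!r}] must be >= 1")
        if self.depth_ratio is not None and self.depth_ratio <= 0:
            raise ConfigError("depth_ratio must be > 0")


@dataclass
class GeneData:
    """Per-gene outputs: the time-scaled (ultrametric) tree, the
    substitution-scaled tree, and the alignment."""

    time_tree: GeneTree
    subst_tree: GeneTree
    alignment: Alignment


@dataclass
class SyntheticDataset:
    config: SimConfig
    specimens: list[Specimen]
    species_truth: dict[str, str]        # specimen id -> true species
    genes: dict[str, GeneData]
    species_tree_newick: str
    depth_ratio: dict[str, float | None]  # realized, per gene

    def specimens_with(self, gene: str) -> list[Specimen]:
        return [s for s in self.specimens if s.has_gene.get(gene)]

    def write(self, outdir) -> None:
        """Emit the same plain-text formats the readers consume."""
        import os

        from .core import write_specimen_table, write_tip_map

        os.makedirs(outdir, exist_ok=True)
        write_specimen_table(self.specimens, os.path.join(outdir, "specimens.tsv"))
        with open(os.path.join(outdir, "species_truth.tsv"), "w") as fh:
            fh.write("specimen\tspecies\n")
            for sid in sorted(self.species_truth):
                fh.write(f"{sid}\t{self.species_truth[sid]}\n")
        with open(os.path.join(outdir, "species_tree.nwk"), "w") as fh:
            fh.write(self.species_tree_newick + "\n")
        for gene, gd in self.genes.items():
            gd.time_tree.write(os.path.join(outdir, f"{gene}_time.nwk"))
            gd.subst_tree.write(os.path.join(outdir, f"{gene}_subst.nwk"))
            gd.alignment.to_fasta(os.path.join(outdir, f"{gene}.fasta"))
            write_tip_map(gd.time_tree.tip_map, os.path.join(outdir, f"{gene}_tipmap.tsv"))


# ---------------------------------------------------------------------------
# Species tree (Yule)


class _SpNode:
    __slots__ = ("children", "age", "label")

    def __init__(self):
        self.children: list[_SpNode] = []
        self.age = 0.0
        self.label: str | None = None


def _simulate_yule(n: int, rate: float, rng: np.random.Generator):
    """Forward Yule simulation; returns (root, tips) with node ages (time
    before present) filled in."""
    root = _SpNode()
    active = [root]
    t = 0.0
    split_time = {}
    while len(active) < n:
        t += rng.exponential(1.0 / (rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active[i]
        split_time[id(node)] = t
        c1, c2 = _SpNode(), _SpNode()
        node.children = [c1, c2]
        active[i] = c1
        active.append(c2)
    total = t + rng.exponential(1.0 / (rate * n))

    def set_ages(node):
        if node.children:
            node.age = total - split_time[id(node)]
            for c in node.children:
                set_ages(c)
        else:
            node.age = 0.0

    set_ages(root)
    return root, active


def _species_newick(node) -> str:
    if not node.children:
        return node.label
    parts = ",".join(
        f"{_species_newick(c)}:{node.age - c.age:.10g}" for c in node.children
    )
    return f"({parts})"


# ---------------------------------------------------------------------------
# Within-species coalescent


def _simulate_coalescent(ids: list[str], ne: float, rng: np.random.Generator):
    """Kingman coalescent over `ids`; returns (newick fragment, root age).

    Pairwise coalescence happens at rate 1/ne, i.e. j lineages merge at rate
    j*(j-1)/(2*ne); the expected TMRCA of m samples is 2*ne*(1 - 1/m).
    """
    if len(ids) == 1:
        return ids[0], 0.0
    lineages = [(sid, 0.0) for sid in ids]
    t = 0.0
    while len(lineages) > 1:
        j = len(lineages)
        t += rng.exponential(2.0 * ne / (j * (j - 1)))
        a, b = rng.choice(j, size=2, replace=False)
        a, b = int(a), int(b)
        na, age_a = lineages[a]
        nb, age_b = lineages[b]
        merged = (f"({na}:{t - age_a:.10g},{nb}:{t - age_b:.10g})", t)
        lineages = [l for k, l in enumerate(lineages) if k not in (a, b)]
        lineages.append(merged)
    return lineages[0]


def _coalescent_in_stem(ids, ne, stem_age, rng, max_tries: int = 200):
    """Coalescent genealogy conditioned (by rejection) to fit under the
    species' stem; rescaled as a last resort (randomized squash factor so
    rescaled genealogies of different species never share exact node ages)."""
    for _ in range(max_tries):
        nwk, h = _simulate_coalescent(ids, ne, rng)
        if stem_age is None or h < 0.95 * stem_age:
            return nwk, h
    # fall back: squash the genealogy under the stem
    scale = float(rng.uniform(0.8, 0.95)) * stem_age / h
    tree = dendropy.Tree.get(data=nwk + ";", schema="newick", preserve_underscores=True)
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= scale
    out = tree.as_string(schema="newick", suppress_rooting=True).strip().rstrip(";")
    return out, h * scale


# ---------------------------------------------------------------------------
# Dataset assembly


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Draw one complete dataset. Deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # 1. species tree and specimen roster
    species_names = [f"sp{i + 1:02d}" for i in range(cfg.n_species)]
    if cfg.n_species > 1:
        root, tips = _simulate_yule(cfg.n_species, cfg.yule_rate, rng)
        for tip, name in zip(tips, species_names):
            tip.label = name
        stem_age = {}
        stack = [root]
        while stack:
            node = stack.pop()
            for c in node.children:
                if not c.children:
                    stem_age[c.label] = node.age
                stack.append(c)
        species_newick = _species_newick(root) + ";"
        mean_stem = float(np.mean(list(stem_age.values())))
    else:
        stem_age = {species_names[0]: None}
        species_newick = f"{species_names[0]};"
        mean_stem = None

    specimens_by_species: dict[str, list[str]] = {}
    stages: dict[str, str] = {}
    counter = 0
    for sp in species_names:
        if isinstance(cfg.samples_per_species, int):
            m = cfg.samples_per_species
        else:
            lo, hi = cfg.samples_per_species
            m = int(rng.integers(lo, hi + 1))
        ids = []
        for _ in range(m):
            counter += 1
            sid = f"i{counter:04d}"
            ids.append(sid)
            u = rng.random()
            if u < cfg.larva_fraction:
                stages[sid] = "larva"
            elif u < cfg.larva_fraction + cfg.pupa_fraction:
                stages[sid] = "pupa"
            else:
                stages[sid] = "adult"
        specimens_by_species[sp] = ids
    species_truth = {sid: sp for sp, ids in specimens_by_species.items() for sid in ids}

    # 2. per-gene availability (every specimen keeps at least one gene)
    genes = cfg.genes
    fallback_gene = min(genes, key=lambda g: cfg.missing_gene_prob.get(g, 0.0))
    has_gene: dict[str, dict[str, bool]] = {}
    for sid in species_truth:
        flags = {g: bool(rng.random() >= cfg.missing_gene_prob.get(g, 0.0)) for g in genes}
        if not any(flags.values()):
            flags[fallback_gene] = True
        has_gene[sid] = flags

    specimens = [
        Specimen(
            id=sid,
            stage=stages[sid],
            species=species_truth[sid] if stages[sid] == "adult" else UNKNOWN,
            has_gene=has_gene[sid],
        )
        for sid in species_truth
    ]

    # 3. effective sizes, optionally pinned to a target depth ratio
    ne_map = dict(cfg.coal_ne)
    if cfg.depth_ratio is not None and mean_stem is not None:
        m_bar = float(np.mean([len(v) for v in specimens_by_species.values()]))
        if m_bar > 1:
            ref = max(ne_map, key=ne_map.get)
            target_ne = mean_stem / (cfg.depth_ratio * 2.0 * (1.0 - 1.0 / m_bar))
            scale = target_ne / ne_map[ref]
            ne_map = {g: ne * scale for g, ne in ne_map.items()}

    # 4. per-gene genealogies, trees, sequences
    gene_data: dict[str, GeneData] = {}
    realized_ratio: dict[str, float | None] = {}
    for gene in genes:
        sampled = {
            sp: [sid for sid in ids if has_gene[sid][gene]]
            for sp, ids in specimens_by_species.items()
        }
        sampled = {sp: ids for sp, ids in sampled.items() if ids}
        if sum(len(v) for v in sampled.values()) < 3:
            raise ConfigError(f"fewer than 3 specimens carry gene {gene!r}")

        fragments: dict[str, tuple[str, float]] = {}
        tmrcas = []
        for sp in species_names:
            ids = sampled.get(sp)
            if not ids:
                continue
            nwk, h = _coalescent_in_stem(ids, ne_map[gene], stem_age[sp], rng)
            fragments[sp] = (nwk, h)
            if len(ids) > 1:
                tmrcas.append(h)

        newick = _graft_newick(cfg, species_newick, fragments)
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        _assign_supports(tree, species_truth, rng)
        tip_map = {l.taxon.label: frozenset([l.taxon.label]) for l in tree.leaf_node_iter()}
        time_tree = GeneTree(gene=gene, tree=tree, tip_map=tip_map)
        subst_tree = _scale_tree(time_tree, cfg.subst_rate.get(gene, 1.0),
                                 cfg.gamma_jitter_shape, rng)
        aln = _evolve_jc(subst_tree, cfg.seq_length.get(gene, 600), rng)

        if mean_stem is not None and tmrcas:
            realized_ratio[gene] = mean_stem / float(np.mean(tmrcas))
        else:
            realized_ratio[gene] = None
        gene_data[gene] = GeneData(time_tree=time_tree, subst_tree=subst_tree, alignment=aln)

    return SyntheticDataset(
        config=cfg,
        specimens=specimens,
        species_truth=species_truth,
        genes=gene_data,
        species_tree_newick=species_newick,
        depth_ratio=realized_ratio,
    )


def _graft_newick(cfg, species_newick: str, fragments: dict[str, tuple[str, float]]) -> str:
    """Replace each species tip of the species tree by its coalescent
    genealogy, pruning species without samples."""
    tree = dendropy.Tree.get(data=species_newick, schema="newick", preserve_underscores=True)
    keep = [l.taxon for l in tree.leaf_node_iter() if l.taxon.label in fragments]
    if len(keep) == 0:
        raise ConfigError("no species carries data for this gene")
    if len(keep) < sum(1 for _ in tree.leaf_node_iter()):
        if len(keep) == 1:
            nwk, _h = fragments[keep[0].label]
            return nwk + ";"
        tree.retain_taxa(keep, suppress_unifurcations=True)

    ages = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            ages[node] = 0.0
        else:
            ages[node] = ages[node.parent_node] + (node.edge.length or 0.0)
    height = max(ages[l] for l in tree.leaf_node_iter())

    def render(node) -> str:
        age = height - ages[node]
        if node.is_leaf():
            nwk, h = fragments[node.taxon.label]
            return nwk, h
        parts = []
        for c in node.child_nodes():
            # for a grafted genealogy the branch runs from this node down to
            # the genealogy's root (at age `top`)
            frag, top = render(c)
            parts.append(f"{frag}:{age - top:.10g}")
        return "(" + ",".join(parts) + ")", age

    body, _ = render(tree.seed_node)
    return body + ";"


def _assign_supports(tree: dendropy.Tree, species_truth: dict[str, str],
                     rng: np.random.Generator) -> None:
    """Posterior-probability stand-ins: 1.0 on true between-species nodes,
    Uniform(0.5, 1) on within-species nodes."""
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        species = {species_truth[l.taxon.label] for l in node.leaf_iter()}
        node.support = 1.0 if len(species) >= 2 else float(rng.uniform(0.5, 1.0))
    tree.seed_node.support = 1.0


def _scale_tree(time_tree: GeneTree, rate: float, jitter_shape: float | None,
                rng: np.random.Generator) -> GeneTree:
    gt = time_tree.clone()
    for edge in gt.tree.preorder_edge_iter():
        if edge.length is not None:
            factor = rate
            if jitter_shape is not None:
                factor *= rng.gamma(jitter_shape, 1.0 / jitter_shape)
            edge.length *= factor
    return GeneTree(gene=gt.gene, tree=gt.tree, tip_map=dict(time_tree.tip_map))


def _evolve_jc(subst_tree: GeneTree, length: int, rng: np.random.Generator) -> Alignment:
    """Jukes-Cantor sequence evolution along the substitution tree."""
    seqs: dict[str, np.ndarray] = {}
    root_seq = rng.integers(0, 4, size=length)
    states = {subst_tree.tree.seed_node: root_seq}
    for node in subst_tree.tree.preorder_node_iter():
        if node.parent_node is not None:
            b = node.edge.length or 0.0
            p_change = 0.75 * (1.0 - math.exp(-4.0 * b / 3.0))
            seq = states[node.parent_node].copy()
            mask = rng.random(length) < p_change
            n_mut = int(mask.sum())
            if n_mut:
                seq[mask] = (seq[mask] + rng.integers(1, 4, size=n_mut)) % 4
            states[node] = seq
        if node.is_leaf():
            seqs[node.taxon.label] = states[node]
    return Alignment(
        gene=subst_tree.gene,
        sequences={sid: "".join(_BASES[v]) for sid, v in sorted(seqs.items())},
    )


# ---------------------------------------------------------------------------
# Paraphyly injection


def inject_paraphyly(
    dataset: SyntheticDataset,
    species_pair: tuple[str, str],
    swap_fraction: float,
    seed: int,
    gene: str | None = None,
) -> SyntheticDataset:
    """Re-attach a fraction of one species' lineages inside the other's clade
    on one gene, creating a non-monophyletic species pair (a species-complex
    condition). Other genes are untouched; sequences are not re-evolved
    (the delimiters consume trees). Deterministic given ``seed``."""
    sp_a, sp_b = species_pair
    for sp in species_pair:
        if sp not in dataset.species_truth.values():
            raise ConfigError(f"unknown species {sp!r}")
    if not 0 <= swap_fraction <= 1:
        raise ConfigError("swap_fraction must be in [0, 1]")
    gene = gene or ("COI" if "COI" in dataset.genes else next(iter(dataset.genes)))
    rng = np.random.default_rng(seed)

    new_genes = {
        g: GeneData(gd.time_tree.clone(), gd.subst_tree.clone(), gd.alignment)
        for g, gd in dataset.genes.items()
    }
    out = replace(dataset, genes=new_genes)
    if swap_fraction == 0:
        return out

    gd = new_genes[gene]
    time_tree = gd.time_tree
    labels_a = sorted(
        l for l in time_tree.tip_labels() if dataset.species_truth[l] == sp_a
    )
    labels_b = sorted(
        l for l in time_tree.tip_labels() if dataset.species_truth[l] == sp_b
    )
    if not labels_a or not labels_b:
        raise ConfigError(f"species pair has no data on gene {gene!r}")
    n_move = max(1, math.ceil(swap_fraction * len(labels_a)))
    n_move = min(n_move, len(labels_a))
    movers = list(rng.choice(labels_a, size=n_move, replace=False))

    for mover in movers:
        _move_tip(time_tree, mover, labels_b, rng)
    _assign_supports(time_tree.tree, dataset.species_truth, rng)
    gd.subst_tree = _scale_tree(time_tree, dataset.config.subst_rate.get(gene, 1.0),
                                None, rng)
    return out


def _move_tip(gt: GeneTree, mover_label: str, host_labels: list[str],
              rng: np.random.Generator) -> None:
    tree = gt.tree
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    mover = leaves[mover_label]

    # detach, suppressing the resulting unifurcation
    parent = mover.parent_node
    parent.remove_child(mover)
    sibling = parent.child_nodes()[0]
    grand = parent.parent_node
    if grand is None:
        sibling.parent_node = None
        sibling.edge.length = None
        tree.seed_node = sibling
    else:
        extra = parent.edge.length or 0.0
        grand.remove_child(parent)
        grand.add_child(sibling)
        sibling.edge.length = (sibling.edge.length or 0.0) + extra

    # attach onto the pendant edge of a random host tip, keeping ultrametry
    ages = GeneTree(gene=gt.gene, tree=tree, tip_map={}, tip_map_explicit=False).node_ages()
    hosts = [h for h in host_labels if h != mover_label]
    host = tree.find_node_with_taxon_label(str(rng.choice(hosts)))
    host_parent = host.parent_node
    top_age = ages[host_parent]
    u = float(rng.uniform(0.0, top_age))
    new_node = dendropy.Node()
    host_parent.remove_child(host)
    host_parent.add_child(new_node)
    new_node.edge.length = top_age - u
    new_node.add_child(host)
    host.edge.length = u
    new_node.add_child(mover)
    mover.edge.length = u
    tree.update_taxon_namespace()
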