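"""Support-aware monophyly and reciprocal-monophyly tests.

A candidate species (its adults plus a hypothesized set of larvae) passes on
one gene tree if the smallest clade containing all its tips contains no
foreign tips and, when support filtering is on, that clade's posterior
probability reaches the threshold (0.95 by default; the root counts as
support 1.0). Reciprocal monophyly requires the same test to pass on both
gene trees with the *same* larval set — restricted to larvae with data on
both genes, since specimens missing a gene cannot testify on that gene.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import GeneTree, Specimen

YES, NO, NOT_EVALUABLE = "yes", "no", "not_evaluable"
DEFAULT_SUPPORT = 0.95


@dataclass
class MonophylyResult:
    species: str
    gene: str
    is_monophyletic: str                 # yes / no / not_evaluable
    clade_support: float | None
    clade_members: frozenset[str]        # specimen ids inside the defining clade
    reason: str = ""


def test_monophyly(
    tree: GeneTree,
    target: set[str],
    support_threshold: float = DEFAULT_SUPPORT,
    species: str = "",
) -> MonophylyResult:
    """Test whether `target` specimens form an exclusive (supported) clade.

    Verdicts: ``yes`` if the MRCA clade of the target tips contains only
    target specimens and its support passes the threshold (a threshold of 0
    disables support filtering); ``no`` otherwise; ``not_evaluable`` when
    fewer than two target tips are present in the tree.
    """
    if not target:
        raise ValueError("empty target specimen set")
    target = set(target)
    tip_labels = tree.tips_of_specimens(target)
    if len(tip_labels) == 0:
        return MonophylyResult(species, tree.gene, NOT_EVALUABLE, None, frozenset(),
                               reason="no target specimens in tree")
    if len(tip_labels) < 2:
        return MonophylyResult(species, tree.gene, NOT_EVALUABLE, None, frozenset(),
                               reason="fewer than 2 target tips in tree")

    leaves = {l.taxon.label: l for l in tree.tree.leaf_node_iter()}
    nodes = [leaves[lab] for lab in tip_labels]
    mrca = _mrca_nodes(nodes)
    clade_tips = {l.taxon.label for l in mrca.leaf_iter()}
    members = tree.specimens_of(clade_tips)
    support = getattr(mrca, "support", None)
    if mrca.parent_node is None:
        support = 1.0  # root convention

    exclusive = members <= target
    if not exclusive:
        return MonophylyResult(species, tree.gene, NO, support, frozenset(members),
                               reason="clade contains non-target specimens")
    if support_threshold > 0:
        if support is None or support < support_threshold:
            return MonophylyResult(
                species, tree.gene, NO, support, frozenset(members),
                reason=f"clade support {support} below threshold {support_threshold}",
            )
    return MonophylyResult(species, tree.gene, YES, support, frozenset(members))


def _mrca_nodes(nodes):
    paths = []
    for n in nodes:
        path = []
        while n is not None:
            path.append(n)
            n = n.parent_node
        paths.append(path[::-1])
    mrca = paths[0][0]
    k = 0
    while all(len(p) > k for p in paths) and len({id(p[k]) for p in paths}) == 1:
        mrca = paths[0][k]
        k += 1
    return mrca


def reciprocal_monophyly(
    tree_a: GeneTree,
    tree_b: GeneTree,
    species: str,
    specimens: list[Specimen],
    larvae_hypothesis: set[str] | frozenset[str] = frozenset(),
    support_threshold: float = DEFAULT_SUPPORT,
) -> str:
    """Reciprocal-monophyly verdict (yes/no/not_evaluable) for one species.

    The target on each gene is the species' adults plus the hypothesized
    larvae, restricted to specimens with data on that gene; the larval set is
    further restricted to larvae with data on *both* genes so that the same
    larvae are tested on each. Not evaluable unless both genes carry at
    least two target specimens.
    """
    adults = {s.id for s in specimens if s.is_adult and s.species == species}
    return _reciprocal(tree_a, tree_b, adults, set(larvae_hypothesis),
                       support_threshold, species)


def reciprocal_monophyly_of_set(
    tree_a: GeneTree,
    tree_b: GeneTree,
    adults: set[str],
    larvae_hypothesis: set[str] | frozenset[str] = frozenset(),
    support_threshold: float = DEFAULT_SUPPORT,
    label: str = "",
) -> str:
    """Reciprocal monophyly of an explicit adult set (used for OTUs that are
    species complexes or larva-only clusters)."""
    return _reciprocal(tree_a, tree_b, set(adults), set(larvae_hypothesis),
                       support_threshold, label)


def _reciprocal(tree_a, tree_b, adults, larvae, support_threshold, label) -> str:
    in_a, in_b = tree_a.specimen_ids(), tree_b.specimen_ids()
    larvae_both = {x for x in larvae if x in in_a and x in in_b}
    verdicts = []
    for tree, present in ((tree_a, in_a), (tree_b, in_b)):
        target = {x for x in adults if x in present} | larvae_both
        if len(target) < 2:
            return NOT_EVALUABLE
        res = test_monophyly(tree, target, support_threshold, species=label)
        if res.is_monophyletic == NOT_EVALUABLE:
            return NOT_EVALUABLE
        verdicts.append(res.is_monophyletic)
    return YES if all(v == YES for v in verdicts) else NO
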