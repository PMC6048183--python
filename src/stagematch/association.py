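"""Five-criterion life-stage association engine.

For every candidate species the pipeline evaluates five yes/no criteria:
a PTP cluster criterion and a GMYC cluster criterion on each of two genes
(larvae are conspecific with an adult species if they share a delimited
cluster containing only that one identified adult species), plus reciprocal
monophyly across the two gene trees. Association is successful when at
least three of the five criteria are fulfilled; a criterion that cannot be
evaluated (no adult with data on a gene, no sequenced larvae) counts as not
fulfilled.

Species whose adults mix in delimited clusters or intrude into each other's
clades are unresolvable per gene and are pooled into species complexes;
clusters holding only immatures become larva-only OTUs. Both are reported
as OTU rows alongside clean single-species OTUs, mirroring the summary
table of the study this pipeline reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .core import ClusterPartition, DataError, GeneTree, Specimen, UNKNOWN
from .monophyly import (NO, NOT_EVALUABLE, YES, reciprocal_monophyly_of_set)

RECIP_MONO = "RECIP_MONO"


@dataclass(frozen=True)
class CriterionOutcome:
    """Outcome of one association criterion for one candidate OTU."""

    criterion: str            # e.g. "CAD_PTP", "COI_GMYC", "RECIP_MONO"
    outcome: str              # yes / no / not_evaluable
    detail: str = ""

    def __post_init__(self):
        if self.outcome not in (YES, NO, NOT_EVALUABLE):
            raise DataError(f"invalid criterion outcome {self.outcome!r}")


@dataclass
class AssociationRow:
    """Per-OTU association summary (one table row)."""

    otu: str
    species_members: tuple[str, ...]
    larvae: frozenset[str]
    outcomes: tuple[CriterionOutcome, ...]
    n_fulfilled: int
    success: bool
    larval_association_level: str     # species / otu_only / none
    flags: tuple[str, ...] = ()

    @property
    def is_complex(self) -> bool:
        return len(self.species_members) > 1

    @property
    def is_larva_only(self) -> bool:
        return len(self.species_members) == 0


def vote(outcomes) -> tuple[int, bool]:
    """Count fulfilled criteria; success needs at least three of five.

    Not-evaluable outcomes count as not fulfilled.
    """
    outcomes = list(outcomes)
    if len(outcomes) != 5:
        raise DataError(f"vote needs exactly five criterion outcomes, got {len(outcomes)}")
    labels = [o.criterion for o in outcomes]
    if len(set(labels)) != 5:
        raise DataError(f"duplicate criterion labels in vote: {labels}")
    n = sum(1 for o in outcomes if o.outcome == YES)
    return n, n >= 3


def cluster_criterion(
    partition: ClusterPartition,
    specimens: list[Specimen],
    species: str,
    larvae: set[str] | frozenset[str] | None = None,
) -> CriterionOutcome:
    """PTP/GMYC cluster criterion for one species on one partition.

    Fulfilled when sequenced candidate larvae exist, every cluster holding
    an adult of `species` holds no other identified adult species, and every
    hypothesis larva with data on this gene sits in a cluster that also
    holds adults of `species`. Unidentified adults (species UNKNOWN) never
    veto a cluster but are recorded in the detail string.

    When ``larvae`` is None the hypothesis defaults to the immatures
    co-clustered with the species' adults in this very partition (the
    adult-free-cluster clause is then vacuous); the OTU assembler always
    passes the OTU's pooled larva set.
    """
    label = f"{partition.gene}_{partition.method}"
    by_id = {s.id: s for s in specimens}
    if species not in {s.species for s in specimens}:
        raise DataError(f"species {species!r} absent from the specimen table")

    covered = partition.specimen_ids()
    adults_here = {
        sid for sid in covered
        if (sp := by_id.get(sid)) is not None and sp.is_adult and sp.species == species
    }
    if not adults_here:
        return CriterionOutcome(label, NOT_EVALUABLE,
                                detail=f"no adult of {species} with {partition.gene} data")

    if larvae is None:
        hypothesis = {
            sid
            for cluster in partition.clusters
            if cluster & adults_here
            for sid in cluster
            if (sp := by_id.get(sid)) is not None and sp.is_immature
        }
    else:
        hypothesis = {sid for sid in larvae
                      if sid in covered and by_id[sid].is_immature}
    if not hypothesis:
        return CriterionOutcome(label, NOT_EVALUABLE,
                                detail=f"no sequenced larvae to associate with {species}")

    notes = []
    foreign: set[str] = set()
    unknown_adults: set[str] = set()
    for cluster in partition.clusters:
        if not (cluster & adults_here):
            continue
        for sid in cluster:
            sp = by_id.get(sid)
            if sp is None or not sp.is_adult:
                continue
            if sp.species == UNKNOWN:
                unknown_adults.add(sid)
            elif sp.species != species:
                foreign.add(sp.species)
    if unknown_adults:
        notes.append(f"unidentified adults present: {sorted(unknown_adults)}")
    if foreign:
        return CriterionOutcome(
            label, NO,
            detail=f"cluster mixes adults of {species} with {sorted(foreign)}",
        )

    stranded = {
        sid for sid in hypothesis
        if not ((c := partition.cluster_of(sid)) and c & adults_here)
    }
    if stranded:
        return CriterionOutcome(
            label, NO,
            detail=f"larvae in clusters lacking {species} adults: {sorted(stranded)[:5]}",
        )
    notes.insert(0, f"{len(hypothesis)} larvae associated")
    return CriterionOutcome(label, YES, detail="; ".join(notes))


# ---------------------------------------------------------------------------
# OTU assembly


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller label wins
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo

    def components(self) -> dict:
        comps: dict = {}
        for x in self.parent:
            comps.setdefault(self.find(x), set()).add(x)
        return comps


def assemble_otus(
    partitions: list[ClusterPartition],
    specimens: list[Specimen],
    trees: dict[str, GeneTree] | None = None,
    support_threshold: float = 0.95,
    criterion_order: list[tuple[str, str]] | None = None,
) -> list[AssociationRow]:
    """Build the per-OTU association table from delimited partitions.

    Species whose adults share any delimited cluster (or intrude into each
    other's minimal clades on a gene tree, when trees are supplied) are
    merged into species complexes named after their alphabetically first
    member. Immatures never co-clustered with an identified adult are
    grouped into larva-only OTUs named ``sp. <smallest specimen id> (L)``.
    """
    by_id = {s.id: s for s in specimens}
    ids = set(by_id)
    for p in partitions:
        unknown = p.specimen_ids() - ids
        if unknown:
            raise DataError(f"partition {p.gene}/{p.method} contains unknown "
                            f"specimen ids: {sorted(unknown)[:5]}")

    species_list = sorted({s.species for s in specimens if s.is_adult and s.is_identified})
    uf = _UnionFind(species_list)

    def adult_species_in(cluster) -> set[str]:
        return {
            by_id[sid].species
            for sid in cluster
            if by_id[sid].is_adult and by_id[sid].is_identified
        }

    for p in partitions:
        for cluster in p.clusters:
            present = sorted(adult_species_in(cluster))
            for a, b in zip(present, present[1:]):
                uf.union(a, b)

    if trees:
        from .monophyly import test_monophyly

        for tree in trees.values():
            present_ids = tree.specimen_ids()
            for sp in species_list:
                target = {s.id for s in specimens
                          if s.is_adult and s.species == sp and s.id in present_ids}
                if len(target) < 1:
                    continue
                res = test_monophyly(tree, target, support_threshold=0.0, species=sp)
                others = {by_id[x].species for x in res.clade_members
                          if x in by_id and by_id[x].is_adult and by_id[x].is_identified}
                others.discard(sp)
                # only an unambiguous pairwise intrusion merges species here: the
                # minimal clade of `sp` holds exactly one other identified
                # species (a scattered species' clade can span the whole tree
                # without implying a complex with everything in it)
                if len(others) == 1:
                    uf.union(sp, others.pop())

    components = sorted(
        (tuple(sorted(members)) for members in uf.components().values())
    )

    # larvae attach to the OTU whose adults they share a cluster with
    adults_of = {
        comp: {s.id for s in specimens if s.is_adult and s.species in comp}
        for comp in components
    }
    larva_otus: dict[str, set[tuple[str, ...]]] = {}
    for p in partitions:
        for cluster in p.clusters:
            for comp in components:
                if cluster & adults_of[comp]:
                    for sid in cluster:
                        if by_id[sid].is_immature:
                            larva_otus.setdefault(sid, set()).add(comp)
    larvae_of: dict[tuple[str, ...], set[str]] = {comp: set() for comp in components}
    conflicted: set[str] = set()
    for sid, comps in larva_otus.items():
        if len(comps) == 1:
            larvae_of[next(iter(comps))].add(sid)
        else:
            conflicted.add(sid)

    # immatures never seen with an identified adult: larva-only OTUs
    unassigned = [s.id for s in specimens
                  if s.is_immature and s.id not in larva_otus]
    luf = _UnionFind(unassigned)
    un_set = set(unassigned)
    for p in partitions:
        for cluster in p.clusters:
            members = sorted(cluster & un_set)
            for a, b in zip(members, members[1:]):
                luf.union(a, b)
    larva_only = sorted(
        (tuple(sorted(m)) for m in luf.components().values()), key=lambda m: m[0]
    )

    if criterion_order is None:
        # the vote is structurally five-way: two genes x two methods plus
        # reciprocal monophyly; a missing gene contributes two
        # not-evaluable slots
        genes = sorted({p.gene for p in partitions})[:2]
        while len(genes) < 2:
            genes.append("NA")
        criterion_order = [(g, m) for g in genes for m in ["PTP", "GMYC"]]
    part_lookup = {(p.gene, p.method): p for p in partitions}
    tree_pair = list(trees.values())[:2] if trees else []

    rows: list[AssociationRow] = []
    for comp in components:
        rows.append(
            _build_row(comp, sorted(larvae_of[comp]), partitions, part_lookup,
                       criterion_order, specimens, by_id, tree_pair, support_threshold)
        )
    for members in larva_only:
        rows.append(
            _build_row((), list(members), partitions, part_lookup,
                       criterion_order, specimens, by_id, tree_pair, support_threshold)
        )
    # larvae co-clustered with adults of more than one OTU stay unassociated;
    # they appear in no row (the delimitations contradict each other there)
    rows.sort(key=lambda r: r.otu)
    return rows


def _aggregate(outcomes: list[CriterionOutcome], label: str) -> CriterionOutcome:
    """Combine per-member-species verdicts into one OTU verdict."""
    if any(o.outcome == NO for o in outcomes):
        detail = "; ".join(o.detail for o in outcomes if o.outcome == NO)
        return CriterionOutcome(label, NO, detail=detail)
    if all(o.outcome == NOT_EVALUABLE for o in outcomes):
        return CriterionOutcome(label, NOT_EVALUABLE,
                                detail="; ".join(o.detail for o in outcomes))
    return CriterionOutcome(label, YES, detail="; ".join(
        o.detail for o in outcomes if o.outcome == YES))


def _build_row(comp, larvae, partitions, part_lookup, criterion_order,
               specimens, by_id, tree_pair, support_threshold) -> AssociationRow:
    larvae_set = frozenset(larvae)
    flags: list[str] = []
    outcomes: list[CriterionOutcome] = []
    for gene, method in criterion_order:
        label = f"{gene}_{method}"
        part = part_lookup.get((gene, method))
        if part is None:
            outcomes.append(CriterionOutcome(label, NOT_EVALUABLE, detail="no partition"))
            continue
        if not comp:
            outcomes.append(CriterionOutcome(label, NOT_EVALUABLE,
                                             detail="larva-only OTU (no adults)"))
            continue
        per_member = [
            cluster_criterion(part, specimens, sp, larvae=larvae_set) for sp in comp
        ]
        outcomes.append(_aggregate(per_member, label))
        if len(comp) > 1:
            adult_ids = {s.id for s in specimens if s.is_adult and s.species in comp}
            for cluster in part.clusters:
                spanned = {by_id[sid].species for sid in cluster & adult_ids}
                if len(spanned) > 1 and "merged_cluster" not in flags:
                    flags.append("merged_cluster")

    if len(tree_pair) == 2:
        adult_ids = {s.id for s in specimens if s.is_adult and s.species in comp}
        recip = reciprocal_monophyly_of_set(
            tree_pair[0], tree_pair[1], adult_ids, larvae_set,
            support_threshold=support_threshold, label="+".join(comp) or "larva-only",
        )
        outcomes.append(CriterionOutcome(RECIP_MONO, recip))
    else:
        outcomes.append(CriterionOutcome(RECIP_MONO, NOT_EVALUABLE,
                                         detail="fewer than two gene trees"))

    n, success = vote(outcomes)
    if not comp:
        otu = f"sp. {min(larvae)} (L)" if larvae else "sp. ? (L)"
        level = "otu_only" if larvae else "none"
    else:
        otu = comp[0] if len(comp) == 1 else f"{comp[0]}-complex"
        if not larvae_set:
            level = "none"
        elif success and len(comp) == 1:
            level = "species"
        else:
            level = "otu_only"
    return AssociationRow(
        otu=otu,
        species_members=tuple(comp),
        larvae=larvae_set,
        outcomes=tuple(outcomes),
        n_fulfilled=n,
        success=success,
        larval_association_level=level,
        flags=tuple(flags),
    )


def summarize(rows: list[AssociationRow]) -> dict:
    """Headline counts: OTUs, species-level and OTU-level associations, and
    larvae (incl. pupae) attached at each level."""
    if not rows:
        raise DataError("no association rows to summarize")
    species_rows = [r for r in rows if r.larval_association_level == "species"]
    otu_rows = [r for r in rows if r.larval_association_level == "otu_only"]
    return {
        "n_otus": len(rows),
        "n_species_level": len(species_rows),
        "n_otu_level": len(otu_rows),
        "n_larvae_species": sum(len(r.larvae) for r in species_rows),
        "n_larvae_otu": sum(len(r.larvae) for r in otu_rows),
    }


def rows_to_frame(rows: list[AssociationRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        rec = {
            "otu": r.otu,
            "species": ";".join(r.species_members),
            "n_larvae": len(r.larvae),
        }
        for o in r.outcomes:
            rec[o.criterion] = o.outcome
        rec.update(
            n_fulfilled=r.n_fulfilled,
            success=r.success,
            level=r.larval_association_level,
            flags=";".join(r.flags),
        )
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# statsmodels-style front end


@dataclass
class AssociationResults:
    rows: list[AssociationRow]

    def summary(self) -> pd.DataFrame:
        return rows_to_frame(self.rows)

    def summarize(self) -> dict:
        return summarize(self.rows)

    def larvae_assignments(self) -> pd.DataFrame:
        records = [
            {"specimen": sid, "otu": r.otu, "level": r.larval_association_level}
            for r in self.rows
            for sid in sorted(r.larvae)
        ]
        return pd.DataFrame(records, columns=["specimen", "otu", "level"])


class LifeStageAssociation:
    """Association model over delimited partitions and (optionally) trees.

    Parameters
    ----------
    specimens
        Full specimen table (adults identified to species, immatures
        UNKNOWN).
    partitions
        Delimited :class:`ClusterPartition` objects, typically one per
        gene x method (PTP and GMYC on each of two genes).
    trees
        Gene trees keyed by gene name, used for the reciprocal-monophyly
        criterion; with fewer than two trees that criterion is not
        evaluable and the vote proceeds on the cluster criteria.
    """

    def __init__(
        self,
        specimens: list[Specimen],
        partitions: list[ClusterPartition],
        trees: dict[str, GeneTree] | None = None,
        support_threshold: float = 0.95,
    ):
        self.specimens = specimens
        self.partitions = partitions
        self.trees = trees
        self.support_threshold = support_threshold

    def fit(self) -> AssociationResults:
        rows = assemble_otus(
            self.partitions,
            self.specimens,
            trees=self.trees,
            support_threshold=self.support_threshold,
        )
        return AssociationResults(rows=rows)


# ---------------------------------------------------------------------------
# Packaged reference table


def load_reference_table() -> pd.DataFrame:
    """The packaged per-OTU association table of the two-marker caddisfly
    study (criterion cells and printed criteria counts, transcribed
    verbatim)."""
    with resources.files("stagematch").joinpath("data/table5.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


_CELL = {"yes": YES, "no": NO, "ne": NOT_EVALUABLE}


def reference_rows() -> list[tuple[AssociationRow, int | None]]:
    """Association rows reconstructed from the packaged reference table.

    Returns ``(row, printed_count)`` pairs; ``printed_count`` is the
    criteria-fulfilled number printed in the source table (None where the
    table prints a dash), while ``row.n_fulfilled`` is recomputed by
    :func:`vote` from the per-criterion cells.
    """
    df = load_reference_table()
    out = []
    for _, rec in df.iterrows():
        outcomes = tuple(
            CriterionOutcome(crit, _CELL[rec[col]])
            for crit, col in [
                ("CAD_PTP", "cad_ptp"), ("CAD_GMYC", "cad_gmyc"),
                ("COI_PTP", "coi_ptp"), ("COI_GMYC", "coi_gmyc"),
                (RECIP_MONO, "recip_mono"),
            ]
        )
        n, success = vote(outcomes)
        members = tuple(x for x in rec["species"].split(";") if x)
        has_larvae = rec["larvae"] == "yes"
        sequenced = rec["larvae_sequenced"] == "yes"
        if not has_larvae or not sequenced:
            level = "none"
        elif success and len(members) == 1:
            level = "species"
        else:
            level = "otu_only"
        row = AssociationRow(
            otu=rec["otu"],
            species_members=members,
            larvae=frozenset(),
            outcomes=outcomes,
            n_fulfilled=n,
            success=success,
            larval_association_level=level,
        )
        cell = rec.get("printed_n_criteria")
        printed = int(cell) if isinstance(cell, str) and cell.strip() else None
        out.append((row, printed))
    return out
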