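"""Gene-tree concordance factors, CF-asymmetry admixture estimates, tree conflict.

The concordance factor (CF) of a clade is the proportion of the genome for
which that clade is true, estimated here empirically from per-locus gene
trees (clade indicator per locus) or per-locus tree samples (posterior clade
frequency per locus), with percentile-bootstrap credibility intervals over
loci.  Under incomplete lineage sorting alone the two conflicting secondary
resolutions around a branch have equal CFs; if their intervals are disjoint
the asymmetry implicates introgression, and the excess of the dominant
secondary CF over its mirror estimates the admixed genome fraction.

Trees are handled as newick via dendropy; clades/bipartitions are sets of
taxon labels so the concordance logic stays independent of any particular
tree container.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# clades and bipartitions


@dataclass(frozen=True)
class Clade:
    """One side of a bipartition of a fixed taxon universe.

    Stored canonically: the smaller side (ties broken lexicographically on
    the sorted taxon tuple).
    """

    side: frozenset
    universe: frozenset
    label: str = ""

    def __post_init__(self) -> None:
        if not self.side or self.side == self.universe:
            raise TreeError("clade sides must be proper non-empty subsets")
        if not self.side <= self.universe:
            raise TreeError("clade side must lie within the universe")

    @classmethod
    def of(cls, taxa, universe, label: str = "") -> "Clade":
        side = frozenset(taxa)
        universe = frozenset(universe)
        other = universe - side
        a, b = sorted((side, other), key=lambda s: (len(s), tuple(sorted(s))))
        return cls(side=a, universe=universe, label=label)

    @property
    def other(self) -> frozenset:
        return self.universe - self.side

    def sort_key(self) -> tuple:
        return (len(self.side), tuple(sorted(self.side)))

    def conflicts_with(self, o: "Clade") -> bool:
        """True iff the two bipartitions cannot occur in one tree."""
        shared = (self.side | self.other) & (o.side | o.other)
        a1, a2 = self.side & shared, self.other & shared
        b1, b2 = o.side & shared, o.other & shared
        return all((a1 & b1, a1 & b2, a2 & b1, a2 & b2))


def parse_tree(source: str, taxon_namespace=None) -> dendropy.Tree:
    """Newick string or file path -> dendropy Tree (support in node labels
    or bracket comments)."""
    kwargs = dict(schema="newick", suppress_internal_node_taxa=True,
                  taxon_namespace=taxon_namespace)
    if "(" in source:
        return dendropy.Tree.get(data=source, **kwargs)
    return dendropy.Tree.get(path=source, **kwargs)


def tree_taxa(tree: dendropy.Tree) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _node_support(node) -> float | None:
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            pass
    for comment in node.comments or []:
        try:
            return float(comment)
        except ValueError:
            continue
    return None


def tree_bipartitions(tree: dendropy.Tree,
                      universe: frozenset | None = None,
                      with_support: bool = False):
    """Non-trivial bipartitions of a tree, as canonical Clades.

    With ``with_support`` each entry is ``(Clade, support-or-None)``; support
    is taken from internal node labels (or bracket comments).
    """
    taxa = tree_taxa(tree)
    if universe is None:
        universe = taxa
    out = []
    seen = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(below) < 2 or len(taxa - below) < 2:
            continue
        clade = Clade.of(below, taxa)
        if clade in seen:
            continue
        seen.add(clade)
        out.append((clade, _node_support(node)) if with_support else clade)
    return out


def clade_in_tree(tree_bips: set, clade: Clade, taxa: frozenset) -> bool:
    """Is the clade present on the tree (restricted to the tree's taxa)?

    A clade whose restriction to the tree's taxa is trivial imposes no
    constraint and counts as present.
    """
    a = clade.side & taxa
    b = clade.other & taxa
    if len(a) < 2 or len(b) < 2:
        return True
    return Clade.of(a, taxa) in tree_bips


# ---------------------------------------------------------------------------
# concordance factors


@dataclass
class ConcordanceEstimate:
    clade: Clade
    cf: float
    ci_low: float
    ci_high: float
    n_genes: int
    method: str  # "indicator" | "posterior-mean"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.cf <= self.ci_high <= 1.0):
            raise TreeError(
                f"inconsistent estimate cf={self.cf} ci=({self.ci_low},{self.ci_high})")


@dataclass
class AdmixtureEstimate:
    focal: ConcordanceEstimate
    alternatives: list
    excess: float
    significant: bool
    interpretation: str


def _locus_clade_frequency(entry, clade: Clade) -> float:
    trees = entry if isinstance(entry, (list, tuple)) else [entry]
    hits = 0
    for tree in trees:
        taxa = tree_taxa(tree)
        bips = set(tree_bipartitions(tree))
        hits += clade_in_tree(bips, clade, taxa)
    return hits / len(trees)


def concordance_factor(gene_trees: list, clade: Clade, n_boot: int = 1000,
                       seed: int = 0) -> ConcordanceEstimate:
    """Empirical CF of a clade with a percentile bootstrap CI over loci.

    ``gene_trees`` holds, per locus, either one tree (indicator method) or a
    list of trees (posterior clade frequency per locus).  The bootstrap
    resamples loci with replacement; the interval is the 2.5/97.5 percentile
    of resampled means.
    """
    if not gene_trees:
        raise TreeError("no gene trees supplied")
    seen_taxa: set = set()
    for e in gene_trees:
        seen_taxa |= tree_taxa(e[0] if isinstance(e, (list, tuple)) else e)
    if not clade.side & seen_taxa:
        raise TreeError(f"clade taxa absent from all gene trees: {sorted(clade.side)}")
    freqs = np.array([_locus_clade_frequency(e, clade) for e in gene_trees])
    cf = float(freqs.mean())
    rng = np.random.default_rng(seed)
    n = len(freqs)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = freqs[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    lo, hi = min(float(lo), cf), max(float(hi), cf)
    method = ("posterior-mean"
              if any(isinstance(e, (list, tuple)) for e in gene_trees)
              else "indicator")
    return ConcordanceEstimate(clade=clade, cf=cf, ci_low=lo, ci_high=hi,
                               n_genes=n, method=method)


def asymmetry_test(a: ConcordanceEstimate | tuple,
                   b: ConcordanceEstimate | tuple) -> bool:
    """Significant iff the two credibility intervals are disjoint.

    A shared endpoint counts as overlap (conservative).  Accepts estimates or
    bare ``(low, high)`` interval tuples.
    """
    lo_a, hi_a = (a.ci_low, a.ci_high) if isinstance(a, ConcordanceEstimate) else a
    lo_b, hi_b = (b.ci_low, b.ci_high) if isinstance(b, ConcordanceEstimate) else b
    return hi_a < lo_b or hi_b < lo_a


def excess_cf(focal: ConcordanceEstimate,
              alternatives: list) -> AdmixtureEstimate:
    """Admixture estimate: focal CF minus the mean of its conflicting mirrors.

    Under ILS alone the conflicting resolutions are equally frequent, so the
    mirror CFs estimate the ILS contribution; the remainder is attributed to
    introgression and reported as a whole genome percentage.
    """
    if not alternatives:
        raise TreeError("excess_cf needs at least one alternative")
    alt_mean = sum(a.cf for a in alternatives) / len(alternatives)
    excess = focal.cf - alt_mean
    significant = all(asymmetry_test(focal, a) for a in alternatives)
    pct = round(excess * 100)
    interp = (f"as much as {pct:.0f}% of the genome could have been introgressed"
              if significant else
              f"asymmetry not significant (excess {pct:.0f}%)")
    return AdmixtureEstimate(focal=focal, alternatives=list(alternatives),
                             excess=excess, significant=significant,
                             interpretation=interp)


# ---------------------------------------------------------------------------
# primary concordance tree


def primary_concordance_tree(cf_table: list) -> dendropy.Tree:
    """Greedy tree from the highest-CF mutually compatible clades.

    Clades are accepted in descending CF order (ties broken by canonical
    clade order) and skipped when incompatible with anything already
    accepted; the result may contain polytomies.
    """
    if not cf_table:
        raise TreeError("empty cf table")
    universe = cf_table[0].clade.universe
    if any(e.clade.universe != universe for e in cf_table):
        raise TreeError("cf table mixes taxon universes")
    ordered = sorted(cf_table, key=lambda e: (-e.cf, e.clade.sort_key()))
    accepted: list[Clade] = []
    for entry in ordered:
        if not any(entry.clade.conflicts_with(c) for c in accepted):
            accepted.append(entry.clade)
    anchor = min(universe)
    groups = sorted({c.side if anchor not in c.side else c.other
                     for c in accepted}, key=len)

    def nest(taxa: frozenset, subsets: list) -> str:
        maximal = []
        for s in subsets:
            if not any(s < t for t in subsets):
                maximal.append(s)
        parts = []
        covered: set = set()
        for s in sorted(maximal, key=lambda s: tuple(sorted(s))):
            inner = [t for t in subsets if t < s]
            parts.append(nest(s, inner))
            covered |= s
        for t in sorted(taxa - covered):
            parts.append(t)
        return "(" + ",".join(parts) + ")"

    newick = nest(universe, groups) + ";"
    return parse_tree(newick)


# ---------------------------------------------------------------------------
# tree conflict


def bipartition_conflicts(tree_a: dendropy.Tree, tree_b: dendropy.Tree,
                          min_support: float = 0.0) -> list[tuple[Clade, Clade]]:
    """Conflicting bipartition pairs between two trees on their shared taxa.

    Reports every bipartition with support >= ``min_support`` in one tree
    that is incompatible with some bipartition of the other (pairs are
    de-duplicated across the two directions).  Bipartitions without a support
    annotation pass any threshold.
    """
    shared = tree_taxa(tree_a) & tree_taxa(tree_b)
    if len(shared) < 4:
        raise TreeError(f"need >= 4 shared taxa, got {len(shared)}")

    def restricted(tree):
        out = []
        for clade, sup in tree_bipartitions(tree, with_support=True):
            a, b = clade.side & shared, clade.other & shared
            if len(a) >= 2 and len(b) >= 2:
                out.append((Clade.of(a, shared), sup))
        return out

    bips_a, bips_b = restricted(tree_a), restricted(tree_b)
    conflicts = []
    seen = set()
    for (ca, sa) in bips_a:
        if sa is not None and sa < min_support:
            continue
        for (cb, _) in bips_b:
            if ca.conflicts_with(cb) and (ca, cb) not in seen:
                seen.add((ca, cb))
                conflicts.append((ca, cb))
    for (cb, sb) in bips_b:
        if sb is not None and sb < min_support:
            continue
        for (ca, _) in bips_a:
            if cb.conflicts_with(ca) and (ca, cb) not in seen:
                seen.add((ca, cb))
                conflicts.append((ca, cb))
    return conflicts


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Robinson-Foulds distance: symmetric difference of bipartition sets
    on the shared taxon set."""
    shared = tree_taxa(tree_a) & tree_taxa(tree_b)

    def bips(tree):
        out = set()
        for clade in tree_bipartitions(tree):
            a, b = clade.side & shared, clade.other & shared
            if len(a) >= 2 and len(b) >= 2:
                out.add(Clade.of(a, shared))
        return out

    return len(bips(tree_a) ^ bips(tree_b))


def constraint_skeleton(tree: dendropy.Tree,
                        min_support: float = 90.0) -> dendropy.Tree:
    """Collapse every internal edge with support below ``min_support``.

    Builds the constraint skeleton used to anchor well-supported nodes while
    letting weaker ones float; unlabeled internal nodes count as support 0
    (with a warning).
    """
    tree = tree.clone(depth=1)
    to_collapse = []
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        if len(node.leaf_nodes()) < 2:
            continue
        sup = _node_support(node)
        if sup is None:
            warnings.warn("internal node without support label treated as 0")
            sup = 0.0
        if sup < min_support:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return tree


# ---------------------------------------------------------------------------
# i/o


CF_COLUMNS = ["clade", "cf", "ci_low", "ci_high", "n_genes", "method"]


def write_cf_tsv(estimates: list, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CF_COLUMNS) + "\n")
        for e in estimates:
            fh.write("\t".join([",".join(sorted(e.clade.side)),
                                f"{e.cf:.4f}", f"{e.ci_low:.4f}",
                                f"{e.ci_high:.4f}", str(e.n_genes),
                                e.method]) + "\n")


def write_conflict_json(conflicts: list, path: str) -> None:
    payload = [{"tree_a_bipartition": sorted(a.side),
                "tree_b_bipartition": sorted(b.side)} for a, b in conflicts]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
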