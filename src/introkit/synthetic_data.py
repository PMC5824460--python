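"""Synthetic inputs: coalescent gene trees, JC69 alignments, QC fixtures.

Gene trees are drawn from a 4- or 5-taxon multispecies coalescent (MSC) on a
pectinate/balanced species tree, with an optional introgression *pulse*: with
per-locus probability ``gamma`` every lineage sitting in the recipient
population at time ``t_m`` jumps into the donor population.  This discrete
pulse (rather than continuous migration) matches the discrete hybridization
events the downstream site-pattern tests are designed to detect.

Sequences evolve on the gene trees under Jukes-Cantor (JC69): equal base
frequencies and exchangeabilities, i.i.d. sites.  Counting-based statistics
(ABBA-BABA, D_FOIL, concordance factors) depend only on which lineages share
derived states, so a richer substitution model would add nothing here.

Times are in coalescent units (2N generations); ``theta`` converts them to
expected substitutions per site.  Everything is deterministic under a seed:
locus ``i`` of a scenario uses an independent stream keyed ``[seed, i]``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .seqio_qc import (AMBIGUITY, GAP, LocusAlignment, QcConfig, find_orfs)

BASES = np.frombuffer(b"ACGT", dtype="S1")

QUARTET_ROLES = ("P1", "P2", "P3", "O")
QUINTET_ROLES = ("P1", "P2", "P3", "P4", "O")


class ScenarioError(ValueError):
    pass


# ---------------------------------------------------------------------------
# gene trees


class GeneTreeNode:
    """Minimal ultrametric tree node; ``time`` is the node age in coalescent units."""

    __slots__ = ("name", "time", "children")

    def __init__(self, name: str | None = None, time: float = 0.0,
                 children: list["GeneTreeNode"] | None = None):
        self.name = name
        self.time = time
        self.children = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["GeneTreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[GeneTreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, scale: float = 1.0) -> str:
        return self._nwk(None, scale) + ";"

    def _nwk(self, parent_time: float | None, scale: float) -> str:
        if self.is_leaf:
            body = self.name or ""
        else:
            body = "(" + ",".join(c._nwk(self.time, scale) for c in self.children) + ")"
        if parent_time is None:
            return body
        return f"{body}:{(parent_time - self.time) * scale:.8g}"

    def topology_key(self) -> str:
        """Canonical label-only newick (sorted at every node); topology identity."""
        if self.is_leaf:
            return self.name or ""
        return "(" + ",".join(sorted(c.topology_key() for c in self.children)) + ")"


@dataclass
class IntrogressionEvent:
    """A pulse: at time ``t_m`` the recipient population's lineages jump to the donor."""

    donor: str
    recipient: str
    t_m: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ScenarioError(f"gamma must be in [0,1], got {self.gamma}")
        if self.t_m < 0:
            raise ScenarioError("t_m must be non-negative")


@dataclass
class Scenario:
    """A simulation condition: species tree, times, optional gene flow.

    ``topology`` is ``"quartet"`` ((((P1,P2),P3),O)) or ``"quintet"``
    ((((P1,P2),(P3,P4)),O)).  ``tau_root`` is the ingroup root (P12+P3 or
    P12+P34); the outgroup attaches at ``tau_out`` (default ``2 * tau_root``).
    Populations addressable by introgression events: tips ``P1..P4``/``O`` and
    ancestors ``P12``, ``P34``, ``ING``.
    """

    topology: str = "quartet"
    tau12: float = 1.0
    tau34: float | None = None
    tau_root: float = 2.0
    tau_out: float | None = None
    pop_scale: dict[str, float] = field(default_factory=dict)
    introgression: IntrogressionEvent | None = None
    n_loci: int = 100
    locus_len: int = 500
    theta: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("quartet", "quintet"):
            raise ScenarioError(f"unknown topology {self.topology!r}")
        if self.tau_out is None:
            self.tau_out = 2.0 * self.tau_root
        if self.topology == "quintet" and self.tau34 is None:
            raise ScenarioError("quintet scenarios need tau34")
        if not 0 < self.tau12 < self.tau_root < self.tau_out:
            raise ScenarioError("need 0 < tau12 < tau_root < tau_out")
        if self.topology == "quintet" and not self.tau12 < self.tau34 < self.tau_root:
            raise ScenarioError("need tau12 < tau34 < tau_root (T12 < T34)")
        if self.introgression is not None:
            self._check_event(self.introgression)

    # population origin (tipward end) and end (rootward merge) times
    def _pop_span(self, pop: str) -> tuple[float, float]:
        quintet = self.topology == "quintet"
        spans = {
            "P1": (0.0, self.tau12), "P2": (0.0, self.tau12),
            "O": (0.0, self.tau_out),
            "P12": (self.tau12, self.tau_root),
            "ING": (self.tau_root, self.tau_out),
        }
        if quintet:
            spans["P3"] = (0.0, self.tau34)
            spans["P4"] = (0.0, self.tau34)
            spans["P34"] = (self.tau34, self.tau_root)
        else:
            spans["P3"] = (0.0, self.tau_root)
        if pop not in spans:
            raise ScenarioError(f"unknown population {pop!r}")
        return spans[pop]

    def _check_event(self, ev: IntrogressionEvent) -> None:
        for pop in (ev.donor, ev.recipient):
            lo, hi = self._pop_span(pop)
            if not lo <= ev.t_m < hi:
                raise ScenarioError(
                    f"t_m={ev.t_m} outside lifespan [{lo},{hi}) of population {pop!r}")
        if ev.donor == ev.recipient:
            raise ScenarioError("donor and recipient must differ")

    @property
    def roles(self) -> tuple[str, ...]:
        return QUINTET_ROLES if self.topology == "quintet" else QUARTET_ROLES

    def mergers(self) -> list[tuple[float, str, tuple[str, str]]]:
        """(time, new_pop, (child_pop, child_pop)) sorted by time."""
        if self.topology == "quintet":
            ev = [(self.tau12, "P12", ("P1", "P2")),
                  (self.tau34, "P34", ("P3", "P4")),
                  (self.tau_root, "ING", ("P12", "P34")),
                  (self.tau_out, "ROOT", ("ING", "O"))]
        else:
            ev = [(self.tau12, "P12", ("P1", "P2")),
                  (self.tau_root, "ING", ("P12", "P3")),
                  (self.tau_out, "ROOT", ("ING", "O"))]
        return sorted(ev)


def _coalesce_in_pop(lineages: list[GeneTreeNode], t0: float, t1: float,
                     scale: float, rng: np.random.Generator) -> float:
    """Coalesce ``lineages`` (in place) over [t0, t1) at rate k(k-1)/(2*scale)."""
    t = t0
    while len(lineages) >= 2:
        k = len(lineages)
        t += rng.exponential(2.0 * scale / (k * (k - 1)))
        if t >= t1:
            break
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        for idx in sorted((i, j), reverse=True):
            del lineages[idx]
        lineages.append(GeneTreeNode(time=t, children=[a, b]))
    return t


def simulate_gene_tree(sc: Scenario, rng: np.random.Generator) -> GeneTreeNode:
    """One MSC gene tree (one sampled lineage per species) under ``sc``."""
    pops: dict[str, list[GeneTreeNode]] = {r: [GeneTreeNode(name=r, time=0.0)]
                                           for r in sc.roles}
    events: list[tuple[float, int, str, object]] = []
    for t, newpop, children in sc.mergers():
        events.append((t, 1, newpop, children))
    ev = sc.introgression
    if ev is not None and ev.gamma > 0 and rng.random() < ev.gamma:
        events.append((ev.t_m, 0, "pulse", ev))
    events.sort(key=lambda e: (e[0], e[1]))

    t_prev = 0.0
    for t_ev, _, tag, payload in events:
        for pop, lin in pops.items():
            _coalesce_in_pop(lin, t_prev, t_ev, sc.pop_scale.get(pop, 1.0), rng)
        if tag == "pulse":
            pe: IntrogressionEvent = payload  # type: ignore[assignment]
            pops.setdefault(pe.donor, [])
            pops[pe.donor].extend(pops.get(pe.recipient, []))
            pops[pe.recipient] = []
        else:
            a, b = payload  # type: ignore[misc]
            merged = pops.pop(a, []) + pops.pop(b, [])
            pops[tag] = pops.get(tag, []) + merged
        t_prev = t_ev

    root_lin = pops["ROOT"]
    _coalesce_in_pop(root_lin, t_prev, np.inf,
                     sc.pop_scale.get("ROOT", 1.0), rng)
    return root_lin[0]


def simulate_gene_trees(sc: Scenario) -> list[GeneTreeNode]:
    """Per-locus MSC gene trees; locus i uses an independent seeded stream."""
    return [simulate_gene_tree(sc, np.random.default_rng([sc.seed, i]))
            for i in range(sc.n_loci)]


def introgression_indicators(sc: Scenario) -> list[bool]:
    """Which loci carry the introgression pulse (recomputed from the seeds).

    The pulse decision is the first draw of each locus's stream, so the truth
    labels are recoverable without re-simulating the trees.
    """
    ev = sc.introgression
    if ev is None or ev.gamma == 0:
        return [False] * sc.n_loci
    return [bool(np.random.default_rng([sc.seed, i]).random() < ev.gamma)
            for i in range(sc.n_loci)]


def expected_hypothesis(sc: Scenario) -> str:
    """The signature-chart hypothesis a scenario's introgression should produce."""
    ev = sc.introgression
    if ev is None or ev.gamma == 0:
        return "none"
    donor, recipient = ev.donor, ev.recipient
    if "P12" in (donor, recipient):
        partner = donor if recipient == "P12" else recipient
        return f"anc12_{partner}"
    return f"{donor}_into_{recipient}"


# ---------------------------------------------------------------------------
# sequences


def simulate_sequences(tree: GeneTreeNode, locus_len: int, theta: float,
                       seed: int | np.random.Generator,
                       locus_id: str = "locus") -> LocusAlignment:
    """Evolve i.i.d. JC69 sites on a gene tree; branch lengths = dt * theta.

    The root base is uniform on {A,C,G,T}; along a branch of ``d`` expected
    substitutions per site each site changes with probability
    (3/4)(1 - e^(-4d/3)), uniformly to one of the three other bases.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if theta < 0:
        raise ScenarioError("theta must be non-negative")
    states: dict[int, np.ndarray] = {}
    leaves: dict[str, np.ndarray] = {}

    def visit(node: GeneTreeNode, parent_state: np.ndarray | None,
              parent_time: float | None) -> None:
        if parent_state is None:
            state = rng.integers(0, 4, size=locus_len, dtype=np.int8)
        else:
            d = (parent_time - node.time) * theta
            if d < 0:
                raise ScenarioError(f"negative branch length {d}")
            p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            state = parent_state.copy()
            hit = rng.random(locus_len) < p_change
            n_hit = int(hit.sum())
            if n_hit:
                # uniform among the three non-current bases
                state[hit] = (state[hit] + rng.integers(1, 4, size=n_hit,
                                                        dtype=np.int8)) % 4
        if node.is_leaf:
            leaves[node.name] = state
        for c in node.children:
            visit(c, state, node.time)

    visit(tree, None, None)
    taxa = sorted(leaves, key=_role_order)
    seqs = {t: BASES[leaves[t]].tobytes().decode() for t in taxa}
    return LocusAlignment(locus_id=locus_id, taxa=taxa, seqs=seqs)


def _role_order(name: str) -> tuple[int, str]:
    order = {"P1": 0, "P2": 1, "P3": 2, "P4": 3, "O": 4}
    return (order.get(name, 99), name)


def simulate_scenario(sc: Scenario) -> tuple[list[GeneTreeNode], list[LocusAlignment]]:
    """Gene trees plus JC69 alignments for every locus of a scenario."""
    trees = simulate_gene_trees(sc)
    alns = [simulate_sequences(t, sc.locus_len, sc.theta,
                               np.random.default_rng([sc.seed, i, 1]),
                               locus_id=f"locus{i:05d}")
            for i, t in enumerate(trees)]
    return trees, alns


# ---------------------------------------------------------------------------
# QC fixtures


@dataclass
class FixtureConfig:
    """How many loci of each labelled QC category to fabricate."""

    n_clean: int = 3
    n_over_ambiguous: int = 3
    n_boundary_ambiguous: int = 1
    n_short: int = 2
    n_low_occupancy: int = 2
    n_ms: int = 2
    n_noncoding: int = 2
    n_taxa: int = 26
    ms_taxa: int = 20
    sparse_taxa: int = 10
    locus_len: int = 400
    qc: QcConfig = field(default_factory=lambda: QcConfig(min_orf_codons=30))


def _random_orf_sequence(length: int, orf_codons: int, rng: np.random.Generator) -> str:
    """ACGT sequence of ``length`` containing one clean ORF of ``orf_codons``."""
    non_stop = [a + b + c for a, b, c in itertools.product("ACGT", repeat=3)
                if a + b + c not in ("TAA", "TAG", "TGA")]
    body = "".join(rng.choice(non_stop) for _ in range(orf_codons - 2))
    orf = "ATG" + body + "TAA"
    pad = length - len(orf)
    if pad < 0:
        raise ScenarioError("locus_len too short for requested ORF")
    # pad with stop-rich junk so no second ORF appears
    junk = ("TAA" * (pad // 3 + 1))[:pad]
    return orf + junk


def _no_orf_sequence(length: int, min_orf_codons: int,
                     rng: np.random.Generator) -> str:
    for _ in range(200):
        seq = "".join(rng.choice(list("ACGT")) for _ in range(length))
        if not find_orfs(seq, min_orf_codons):
            return seq
    raise ScenarioError("could not build an ORF-free sequence")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            alt = [b for b in "ACGT" if b != out[i]]
            out[i] = alt[rng.integers(0, 3)]
    return "".join(out)


def _ambiguate(aln: LocusAlignment, n_cells: int, rng: np.random.Generator) -> None:
    """Overwrite exactly ``n_cells`` non-reference cells with ambiguity codes."""
    ref = aln.reference_taxon
    targets = [t for t in aln.taxa if t != ref]
    cells = [(t, i) for t in targets for i in range(aln.length)]
    pick = rng.choice(len(cells), size=n_cells, replace=False)
    codes = sorted(AMBIGUITY)
    for k in pick:
        t, i = cells[k]
        s = list(aln.seqs[t])
        s[i] = codes[int(rng.integers(0, len(codes)))]
        aln.seqs[t] = "".join(s)


def make_qc_fixtures(cfg: FixtureConfig, seed: int) -> list[tuple[LocusAlignment, str]]:
    """Loci that each violate exactly one QC rule, with truth subset labels.

    The ambiguity categories bracket the strict 3% boundary: boundary loci sit
    at exactly ``max_ambiguity_frac`` (retained), over-ambiguous loci one cell
    above it (discarded).
    """
    rng = np.random.default_rng([seed, 9090])
    out: list[tuple[LocusAlignment, str]] = []
    counter = 0

    def build(n_taxa: int, length: int, coding: bool) -> LocusAlignment:
        nonlocal counter
        counter += 1
        orf_codons = max(cfg.qc.min_orf_codons, 30)
        if coding:
            base = _random_orf_sequence(length, min(orf_codons + 10, length // 3),
                                        rng)
        else:
            base = _no_orf_sequence(length, cfg.qc.min_orf_codons, rng)
        taxa = [f"t{j:02d}" for j in range(n_taxa)]
        seqs = {taxa[0]: base}
        for t in taxa[1:]:
            seqs[t] = _mutate(base, 0.02, rng)
        aln = LocusAlignment(locus_id=f"fx{counter:04d}", taxa=taxa, seqs=seqs,
                             reference_taxon=taxa[0])
        from .seqio_qc import assign_column_classes
        return assign_column_classes(aln, cfg.qc.min_orf_codons)

    for _ in range(cfg.n_clean):
        out.append((build(cfg.n_taxa, cfg.locus_len, True), "primary"))
    for _ in range(cfg.n_over_ambiguous):
        aln = build(cfg.n_taxa, cfg.locus_len, True)
        cells = cfg.n_taxa * cfg.locus_len
        _ambiguate(aln, int(np.floor(cells * cfg.qc.max_ambiguity_frac)) + 1, rng)
        out.append((aln, "discard"))
    for _ in range(cfg.n_boundary_ambiguous):
        aln = build(cfg.n_taxa, cfg.locus_len, True)
        cells = cfg.n_taxa * cfg.locus_len
        n_exact = int(round(cells * cfg.qc.max_ambiguity_frac))
        assert abs(n_exact / cells - cfg.qc.max_ambiguity_frac) < 1e-12, \
            "fixture geometry must hit the ambiguity boundary exactly"
        _ambiguate(aln, n_exact, rng)
        out.append((aln, "primary"))
    for _ in range(cfg.n_short):
        short_len = (cfg.qc.min_len_bp - 3) // 3 * 3  # below min_len_bp, in codons
        out.append((build(cfg.n_taxa, short_len, True), "discard"))
    for _ in range(cfg.n_low_occupancy):
        out.append((build(cfg.sparse_taxa, cfg.locus_len, True), "discard"))
    for _ in range(cfg.n_ms):
        out.append((build(cfg.ms_taxa, cfg.locus_len, True), "MS"))
    for _ in range(cfg.n_noncoding):
        out.append((build(cfg.n_taxa, cfg.locus_len, False), "NL"))
    return out
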