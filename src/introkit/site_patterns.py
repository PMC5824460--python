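"""Polarized biallelic site-pattern counting for taxon quartets and quintets.

For an ordered quartet (((P1,P2),P3),O) or quintet (((P1,P2),(P3,P4)),O) each
alignment column is reduced to a pattern string over {A,B} in role order with
the outgroup allele labelled 'A'.  Sites containing gaps, Ns or IUPAC
ambiguity codes are excluded, as are non-biallelic sites (invariant or
multiallelic across the chosen taxa).  Invariant-in-pattern sites
("AAAA"/"AAAAA") are never stored; all-'B'-ingroup patterns (outgroup carries
a private allele) are counted, since they enter the D_FOIL concordant
classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .seqio_qc import LocusAlignment

ROLES4 = ("P1", "P2", "P3", "O")
ROLES5 = ("P1", "P2", "P3", "P4", "O")

_VALID = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _VALID[_b] = True
_BASE_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class TaxonSet:
    """role -> taxon-id map for an ordered quartet or quintet test."""

    mapping: tuple[tuple[str, str], ...]
    label: str = ""

    @classmethod
    def quartet(cls, p1: str, p2: str, p3: str, o: str, label: str = "") -> "TaxonSet":
        return cls(mapping=(("P1", p1), ("P2", p2), ("P3", p3), ("O", o)),
                   label=label or f"{p1},{p2},{p3};{o}")

    @classmethod
    def quintet(cls, p1: str, p2: str, p3: str, p4: str, o: str,
                label: str = "") -> "TaxonSet":
        return cls(mapping=(("P1", p1), ("P2", p2), ("P3", p3), ("P4", p4),
                            ("O", o)),
                   label=label or f"{p1},{p2},{p3},{p4};{o}")

    def __post_init__(self) -> None:
        roles = tuple(r for r, _ in self.mapping)
        if roles not in (ROLES4, ROLES5):
            raise PatternError(f"roles must be {ROLES4} or {ROLES5}, got {roles}")
        taxa = [t for _, t in self.mapping]
        if len(set(taxa)) != len(taxa):
            raise PatternError(f"taxa must be distinct: {taxa}")

    @property
    def arity(self) -> int:
        return len(self.mapping)

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(r for r, _ in self.mapping)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(t for _, t in self.mapping)

    def taxon(self, role: str) -> str:
        for r, t in self.mapping:
            if r == role:
                return t
        raise PatternError(f"role {role!r} not in taxon set")

    def swap(self, role_a: str, role_b: str) -> "TaxonSet":
        m = dict(self.mapping)
        m[role_a], m[role_b] = m[role_b], m[role_a]
        return TaxonSet(mapping=tuple((r, m[r]) for r, _ in self.mapping),
                        label=self.label + f"[{role_a}<->{role_b}]")


@dataclass
class PatternCounts:
    """Counts of polarized biallelic patterns for one ordered taxon set."""

    arity: int
    counts: Counter = field(default_factory=Counter)
    n_sites_used: int = 0
    n_sites_excluded: int = 0
    excluded_by_reason: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.arity not in (4, 5):
            raise PatternError(f"arity must be 4 or 5, got {self.arity}")
        for pat, c in self.counts.items():
            if (len(pat) != self.arity or set(pat) - {"A", "B"}
                    or pat[-1] != "A" or c < 0 or set(pat) == {"A"}):
                raise PatternError(f"invalid pattern entry {pat!r}: {c}")

    def __add__(self, other: "PatternCounts") -> "PatternCounts":
        if self.arity != other.arity:
            raise PatternError("cannot add counts of different arity")
        return PatternCounts(
            arity=self.arity,
            counts=self.counts + other.counts,
            n_sites_used=self.n_sites_used + other.n_sites_used,
            n_sites_excluded=self.n_sites_excluded + other.n_sites_excluded,
            excluded_by_reason=self.excluded_by_reason + other.excluded_by_reason)

    def __getitem__(self, pattern: str) -> int:
        return self.counts.get(pattern, 0)


def polarize_site(column: dict[str, str], taxa: TaxonSet) -> str | tuple[None, str]:
    """Classify one column: a pattern string, or ``(None, reason)`` if excluded.

    Exclusion reasons: ``ambiguous`` (gap, N or IUPAC code), ``invariant``,
    ``multiallelic``.
    """
    residues = []
    for role in taxa.roles:
        t = taxa.taxon(role)
        if t not in column:
            raise PatternError(f"column missing residue for role {role} ({t})")
        residues.append(column[t].upper())
    if any(r not in "ACGT" for r in residues):
        return (None, "ambiguous")
    alleles = set(residues)
    if len(alleles) == 1:
        return (None, "invariant")
    if len(alleles) > 2:
        return (None, "multiallelic")
    anc = residues[-1]  # outgroup allele -> 'A'
    return "".join("A" if r == anc else "B" for r in residues)


def _locus_matrix(aln: LocusAlignment, taxa: TaxonSet) -> np.ndarray | None:
    if any(t not in aln.seqs for t in taxa.taxa):
        return None
    rows = [np.frombuffer(aln.seqs[t].upper().encode(), dtype=np.uint8)
            for t in taxa.taxa]
    return np.vstack(rows)


def count_patterns(loci: list[LocusAlignment] | LocusAlignment,
                   taxa: TaxonSet) -> PatternCounts:
    """Sum polarized site patterns over all columns of all loci.

    Loci missing any role's taxon are skipped (occupancy varies by subset);
    it is an error if *no* locus contains all roles.  Column classification is
    vectorized but agrees column-for-column with :func:`polarize_site`.
    """
    if isinstance(loci, LocusAlignment):
        loci = [loci]
    out = PatternCounts(arity=taxa.arity)
    n_with_roles = 0
    for aln in loci:
        mat = _locus_matrix(aln, taxa)
        if mat is None:
            continue
        n_with_roles += 1
        _count_matrix(mat, out)
    if n_with_roles == 0:
        raise PatternError(
            f"no locus contains all roles of taxon set {taxa.label!r}")
    return out


def _count_matrix(mat: np.ndarray, out: PatternCounts) -> None:
    k, n = mat.shape
    valid = _VALID[mat].all(axis=0)
    n_ambig = int(n - valid.sum())
    idx = _BASE_IDX[mat[:, valid]]  # k x m, values 0..3
    anc = idx[-1]
    is_anc = idx == anc[None, :]
    # biallelic: every residue equals either the outgroup allele or one
    # single alternative allele
    alt = np.where(is_anc, -1, idx)
    alt_max = alt.max(axis=0)
    biallelic = np.ones(alt.shape[1], dtype=bool)
    for r in range(k):
        biallelic &= (alt[r] == -1) | (alt[r] == alt_max)
    variant = ~is_anc.all(axis=0)
    multi = variant & ~biallelic
    invariant = ~variant
    used = variant & biallelic
    out.n_sites_excluded += n_ambig + int(multi.sum()) + int(invariant.sum())
    out.excluded_by_reason.update({"ambiguous": n_ambig,
                                   "invariant": int(invariant.sum()),
                                   "multiallelic": int(multi.sum())})
    if used.any():
        bits = (~is_anc[:, used]).astype(np.uint8)
        weights = (1 << np.arange(k - 1, -1, -1)).astype(np.uint32)
        codes = (bits.T * weights).sum(axis=1)
        vals, cnts = np.unique(codes, return_counts=True)
        for v, c in zip(vals, cnts):
            pat = format(int(v), f"0{k}b").replace("0", "A").replace("1", "B")
            out.counts[pat] += int(c)
    out.n_sites_used += int(used.sum())


def write_counts_tsv(results: dict[str, PatternCounts], path: str) -> None:
    """TSV of pattern counts per taxon-set label."""
    with open(path, "w") as fh:
        fh.write("label\tarity\tpattern\tcount\tn_sites_used\tn_sites_excluded\n")
        for label, pc in results.items():
            for pat in sorted(pc.counts):
                fh.write(f"{label}\t{pc.arity}\t{pat}\t{pc.counts[pat]}"
                         f"\t{pc.n_sites_used}\t{pc.n_sites_excluded}\n")
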