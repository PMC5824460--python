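"""Per-locus alignment i/o, cleaning, filtering and coding-region partitioning.

Transcriptome-derived locus alignments arrive with ragged ends, assembly-error
indels, fragmented sequences and ambiguity-rich loci.  This module applies the
cleaning rules used for phylogenomic locus curation and sorts each locus into
one of four subsets:

``primary``
    well-occupied (>= 25 species by default), >= 200 bp, has an identified
    coding region, and at most 3% IUPAC-ambiguous cells;
``MS`` ("missing species")
    like primary but present in only 15-24 species;
``NL`` ("noncoding loci")
    well-occupied but with no identifiable open reading frame;
``discard``
    everything else.

All coordinates are 0-based half-open.  Codon position 1 is the first base of
the ORF start codon.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

GAP = "-"
MISSING = "N"
CANONICAL = frozenset("ACGT")
#: IUPAC nucleotide ambiguity codes (excluding N, which is treated as missing)
AMBIGUITY = frozenset("RYSWKMBDHV")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

CODING_CLASSES = ("codon1", "codon2", "codon3")
NONCODING = "noncoding"


class QcError(ValueError):
    """Raised for malformed QC inputs (overlapping fragments, ragged alignments)."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class QcConfig:
    """Thresholds for locus cleaning and subset assignment.

    Defaults follow the curation protocol for a ~36-taxon transcriptome
    matrix; ``min_orf_codons`` follows the TransDecoder convention of 100
    codons but may be lowered for small fixtures.
    """

    min_len_bp: int = 200
    min_species_primary: int = 25
    min_species_ms: int = 15
    max_ambiguity_frac: float = 0.03
    trailing_occupancy_frac: float = 0.30
    short_seq_frac: float = 0.30
    noncoding_gap_frac: float = 0.50
    min_orf_codons: int = 100

    def __post_init__(self) -> None:
        for name in ("max_ambiguity_frac", "trailing_occupancy_frac",
                     "short_seq_frac", "noncoding_gap_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise QcError(f"{name} must be in [0,1], got {v}")
        if self.min_species_ms >= self.min_species_primary:
            raise QcError("min_species_ms must be < min_species_primary")


@dataclass
class LocusAlignment:
    """One aligned locus: a rectangular taxon->sequence map plus column classes.

    ``column_class[i]`` is one of ``codon1``/``codon2``/``codon3``/``noncoding``;
    codon labels cycle 1->2->3 within each contiguous coding block.
    ``reference_taxon`` names the (high-quality) sequence whose gaps license
    coding-column gaps during cleaning.
    """

    locus_id: str
    taxa: list[str]
    seqs: dict[str, str]
    column_class: list[str] = field(default_factory=list)
    reference_taxon: str | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) > 1:
            raise QcError(f"{self.locus_id}: alignment is not rectangular ({lengths})")
        if not self.column_class and self.seqs:
            self.column_class = [NONCODING] * self.length
        if self.seqs and len(self.column_class) != self.length:
            raise QcError(f"{self.locus_id}: column_class length != alignment length")

    @property
    def length(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def has_coding(self) -> bool:
        return any(c in CODING_CLASSES for c in self.column_class)

    def column(self, i: int) -> dict[str, str]:
        return {t: self.seqs[t][i] for t in self.taxa}

    def ambiguity_fraction(self) -> float:
        """IUPAC-ambiguity cells as a fraction of non-gap cells.

        'N' counts neither as ambiguity nor as a gap: scaffolding inserts Ns
        deliberately, so they sit in the denominator but never the numerator.
        """
        ambig = nongap = 0
        for s in self.seqs.values():
            for c in s:
                if c == GAP:
                    continue
                nongap += 1
                if c in AMBIGUITY:
                    ambig += 1
        return ambig / nongap if nongap else 0.0

    def take_columns(self, idx: list[int]) -> "LocusAlignment":
        seqs = {t: "".join(self.seqs[t][i] for i in idx) for t in self.taxa}
        cc = [self.column_class[i] for i in idx]
        return replace(self, seqs=seqs, column_class=cc)

    def drop_taxa(self, drop: set[str]) -> "LocusAlignment":
        taxa = [t for t in self.taxa if t not in drop]
        return replace(self, taxa=taxa,
                       seqs={t: self.seqs[t] for t in taxa})


@dataclass
class QcRecord:
    """Per-locus cleaning/assignment record (one per input locus)."""

    locus_id: str
    n_taxa: int = 0
    length: int = 0
    columns_trimmed: int = 0
    columns_excluded: int = 0
    sequences_dropped: int = 0
    ambiguity_frac: float = 0.0
    subset: str = "discard"
    reasons: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "locus_id": self.locus_id,
            "n_taxa": self.n_taxa,
            "length": self.length,
            "columns_trimmed": self.columns_trimmed,
            "columns_excluded": self.columns_excluded,
            "sequences_dropped": self.sequences_dropped,
            "ambiguity_frac": f"{self.ambiguity_frac:.6f}",
            "subset": self.subset,
            "actions": ";".join(self.reasons) if self.reasons else ".",
        }


QC_REPORT_COLUMNS = ["locus_id", "n_taxa", "length", "columns_trimmed",
                     "columns_excluded", "sequences_dropped", "ambiguity_frac",
                     "subset", "actions"]


# ---------------------------------------------------------------------------
# operations


def scaffold_fragments(fragments: list[tuple[int, str]],
                       min_total_len: int) -> str | None:
    """Join non-overlapping fragments into one sequence, padding gaps with Ns.

    ``fragments`` are (start_in_reference, sequence) pairs, 0-based half-open
    against the reference transcript.  Accepted only if the summed fragment
    length (Ns excluded) reaches ``min_total_len``; returns ``None`` on
    rejection.  Overlapping fragments raise :class:`QcError`.
    """
    if not fragments:
        return None
    frags = sorted(fragments, key=lambda f: f[0])
    for (s1, q1), (s2, q2) in zip(frags, frags[1:]):
        if s1 + len(q1) > s2:
            raise QcError(
                f"overlapping fragments at {s1}..{s1 + len(q1)} and {s2}..{s2 + len(q2)}")
    total = sum(len(q) - q.upper().count(MISSING) for _, q in frags)
    if total < min_total_len:
        return None
    start = frags[0][0]
    end = frags[-1][0] + len(frags[-1][1])
    out = [MISSING] * (end - start)
    for s, q in frags:
        out[s - start:s - start + len(q)] = q
    return "".join(out)


def find_orfs(seq: str, min_orf_codons: int) -> list[tuple[int, int, str]]:
    """Six-frame scan for start-to-stop open reading frames.

    Returns ``(start, end, strand)`` spans on the input sequence (0-based
    half-open, forward-strand coordinates) for the longest ORF of at least
    ``min_orf_codons`` codons plus any further non-overlapping qualifying
    ORFs, ordered by (length desc, start asc).  The span covers the start
    codon through the stop codon when a stop is present.

    Ns and ambiguity codes never match start/stop codons, so ORFs are broken
    only by genuine in-frame stops or sequence ends.
    """
    seq = seq.upper().replace(GAP, "")
    n = len(seq)
    candidates: list[tuple[int, int, str]] = []
    for strand in "+-":
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            start_at: int | None = None
            for pos in range(frame, n - 2, 3):
                codon = s[pos:pos + 3]
                if start_at is None:
                    if codon == START_CODON:
                        start_at = pos
                elif codon in STOP_CODONS:
                    end = pos + 3
                    if (end - start_at) // 3 >= min_orf_codons:
                        candidates.append((start_at, end, strand))
                    start_at = None
            if start_at is not None:
                # open-ended ORF running off the sequence end
                end = start_at + ((n - start_at) // 3) * 3
                if (end - start_at) // 3 >= min_orf_codons:
                    candidates.append((start_at, end, strand))
    # map reverse-strand spans back to forward coordinates
    mapped = [(n - e, n - s, st) if st == "-" else (s, e, st)
              for s, e, st in candidates]
    mapped.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    chosen: list[tuple[int, int, str]] = []
    for c in mapped:
        if all(c[1] <= s or c[0] >= e for s, e, _ in chosen):
            chosen.append(c)
    chosen.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    return chosen


def assign_column_classes(aln: LocusAlignment, min_orf_codons: int) -> LocusAlignment:
    """Label alignment columns codon1/2/3 or noncoding from the reference ORFs.

    ORFs are found on the ungapped reference sequence; codon phase is then
    mapped through the reference's gaps onto alignment columns.  Columns where
    the reference is gapped (or outside any ORF) are noncoding.
    """
    ref = aln.reference_taxon
    if ref is None or ref not in aln.seqs:
        return replace(aln, column_class=[NONCODING] * aln.length)
    refseq = aln.seqs[ref]
    ungapped = refseq.replace(GAP, "")
    orfs = find_orfs(ungapped, min_orf_codons)
    phase = [None] * len(ungapped)  # type: list[str | None]
    for start, end, strand in orfs:
        for i, p in enumerate(range(start, end)):
            phase[p] = CODING_CLASSES[i % 3]
    cc: list[str] = []
    u = 0
    for c in refseq:
        if c == GAP:
            cc.append(NONCODING)
        else:
            cc.append(phase[u] or NONCODING)
            u += 1
    return replace(aln, column_class=cc)


def _occupancy(aln: LocusAlignment, col: int) -> float:
    vals = [aln.seqs[t][col] for t in aln.taxa]
    return sum(v != GAP for v in vals) / len(vals) if vals else 0.0


def clean_alignment(aln: LocusAlignment, cfg: QcConfig) -> tuple[LocusAlignment, QcRecord]:
    """Trim terminal overhangs, drop short sequences, excise indel columns.

    Steps, in order:

    1. trim terminal columns whose non-gap occupancy is <= the trailing
       threshold, working inward from each end until a dense column is hit;
    2. drop any sequence whose non-gap length is <= ``short_seq_frac`` x the
       mean non-gap sequence length;
    3. exclude every coding column containing a gap unless the reference
       taxon is also gapped there (reference-absent insertions are taken to
       be assembly errors, not real indels);
    4. exclude every noncoding column in which the inserted residue is
       present in fewer than ``noncoding_gap_frac`` of the retained taxa.

    An alignment emptied by cleaning is flagged ``discard`` rather than
    raising.  The operation is idempotent.
    """
    rec = QcRecord(locus_id=aln.locus_id)
    if not aln.seqs:
        rec.reasons.append("empty-input")
        return aln, rec

    # 1. terminal trim
    lo, hi = 0, aln.length
    while lo < hi and _occupancy(aln, lo) <= cfg.trailing_occupancy_frac:
        lo += 1
    while hi > lo and _occupancy(aln, hi - 1) <= cfg.trailing_occupancy_frac:
        hi -= 1
    rec.columns_trimmed = aln.length - (hi - lo)
    if rec.columns_trimmed:
        rec.reasons.append(f"trimmed:{rec.columns_trimmed}")
    aln = aln.take_columns(list(range(lo, hi)))

    # 2. drop short sequences
    nongap = {t: len(aln.seqs[t]) - aln.seqs[t].count(GAP) for t in aln.taxa}
    if nongap:
        mean_len = sum(nongap.values()) / len(nongap)
        short = {t for t, L in nongap.items() if L <= cfg.short_seq_frac * mean_len}
        if short:
            rec.sequences_dropped = len(short)
            rec.reasons.append("dropped:" + ",".join(sorted(short)))
            aln = aln.drop_taxa(short)

    # 3 + 4. column exclusions
    ref = aln.reference_taxon
    keep: list[int] = []
    for i in range(aln.length):
        col = [aln.seqs[t][i] for t in aln.taxa]
        has_gap = GAP in col
        if not has_gap:
            keep.append(i)
            continue
        if aln.column_class[i] in CODING_CLASSES:
            ref_gapped = ref in aln.seqs and aln.seqs[ref][i] == GAP
            if ref_gapped:
                keep.append(i)
        else:
            present = sum(c != GAP for c in col)
            if aln.taxa and present / len(aln.taxa) >= cfg.noncoding_gap_frac:
                keep.append(i)
    rec.columns_excluded = aln.length - len(keep)
    if rec.columns_excluded:
        rec.reasons.append(f"excluded:{rec.columns_excluded}")
    aln = aln.take_columns(keep)

    rec.n_taxa = aln.n_taxa
    rec.length = aln.length
    rec.ambiguity_frac = aln.ambiguity_fraction()
    if aln.length == 0 or aln.n_taxa == 0:
        rec.subset = "discard"
        rec.reasons.append("empty-after-cleaning")
    return aln, rec


def assign_subset(aln: LocusAlignment, cfg: QcConfig) -> str:
    """Classify a cleaned locus as ``primary`` / ``MS`` / ``NL`` / ``discard``.

    The ambiguity rule is strict: a locus at exactly the threshold (e.g. 3.0%)
    is retained; only loci with *more* ambiguity are discarded.
    """
    if aln.length == 0 or aln.n_taxa == 0:
        return "discard"
    ambig_ok = aln.ambiguity_fraction() <= cfg.max_ambiguity_frac
    long_enough = aln.length >= cfg.min_len_bp
    coding = aln.has_coding()
    n = aln.n_taxa
    if coding and long_enough and ambig_ok:
        if n >= cfg.min_species_primary:
            return "primary"
        if cfg.min_species_ms <= n < cfg.min_species_primary:
            return "MS"
    if not coding and n >= cfg.min_species_primary:
        return "NL"
    return "discard"


def qc_locus(aln: LocusAlignment, cfg: QcConfig) -> tuple[LocusAlignment, QcRecord]:
    """Clean a locus, then assign its subset; one-stop entry point."""
    if aln.seqs and not aln.has_coding() and aln.reference_taxon is not None:
        aln = assign_column_classes(aln, cfg.min_orf_codons)
    cleaned, rec = clean_alignment(aln, cfg)
    rec.subset = assign_subset(cleaned, cfg)
    rec.n_taxa, rec.length = cleaned.n_taxa, cleaned.length
    rec.ambiguity_frac = cleaned.ambiguity_fraction()
    return cleaned, rec


# ---------------------------------------------------------------------------
# i/o


def read_fasta_locus(path: str, locus_id: str | None = None,
                     reference_taxon: str | None = None) -> LocusAlignment:
    """Read one locus alignment from a FASTA file (headers are taxon ids)."""
    records = list(SeqIO.parse(path, "fasta"))
    taxa = [r.id for r in records]
    seqs = {r.id: str(r.seq).upper() for r in records}
    if locus_id is None:
        locus_id = os.path.splitext(os.path.basename(path))[0]
    return LocusAlignment(locus_id=locus_id, taxa=taxa, seqs=seqs,
                          reference_taxon=reference_taxon)


def write_fasta_locus(aln: LocusAlignment, path: str) -> None:
    with open(path, "w") as fh:
        for t in aln.taxa:
            fh.write(f">{t}\n{aln.seqs[t]}\n")


def write_qc_report(records: list[QcRecord], path: str) -> None:
    """Write the per-locus QC report as a TSV with a header row."""
    with open(path, "w") as fh:
        fh.write("\t".join(QC_REPORT_COLUMNS) + "\n")
        for rec in records:
            row = rec.as_row()
            fh.write("\t".join(str(row[c]) for c in QC_REPORT_COLUMNS) + "\n")
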