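"""Shared fixtures: hand-built alignments with manually classified columns."""

import pytest

from introkit.seqio_qc import LocusAlignment
from introkit.site_patterns import TaxonSet


@pytest.fixture
def quartet_taxa() -> TaxonSet:
    return TaxonSet.quartet("p1", "p2", "p3", "out")


@pytest.fixture
def hand_quartet_alignment() -> tuple[LocusAlignment, dict]:
    """12-column quartet alignment with per-column manual classification.

    Columns (classified by hand, independent of the counting code):
      0  A G G A   ABBA
      1  C T T C   ABBA
      2  A C C A   ABBA
      3  G A G A   BABA
      4  T C T C   BABA
      5  C C A A   BBAA
      6  A - G A   excluded (gap)
      7  A G T A   excluded (multiallelic)
      8  G A A A   BAAA
      9  T A T T   ABAA  (p2 carries the derived allele)
     10  A A A A   invariant (excluded)
     11  C C C C   invariant (excluded)
    """
    cols = ["AGGA", "CTTC", "ACCA", "GAGA", "TCTC", "CCAA",
            "A-GA", "AGTA", "GAAA", "TATT", "AAAA", "CCCC"]
    taxa = ["p1", "p2", "p3", "out"]
    seqs = {t: "".join(c[i] for c in cols) for i, t in enumerate(taxa)}
    truth = {
        "counts": {"ABBA": 3, "BABA": 2, "BBAA": 1, "BAAA": 1, "ABAA": 1},
        "n_used": 8,
        "n_excluded": 4,
        "per_column": ["ABBA", "ABBA", "ABBA", "BABA", "BABA", "BBAA",
                       None, None, "BAAA", "ABAA", None, None],
    }
    aln = LocusAlignment(locus_id="hand12", taxa=taxa, seqs=seqs)
    return aln, truth
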