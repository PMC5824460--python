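"""Patterson's D and D_FOIL statistics with chi-square significance testing.

Patterson's D on an ordered quartet (((P1,P2),P3),O)::

    D = (n_ABBA - n_BABA) / (n_ABBA + n_BABA)

Under incomplete lineage sorting alone the two discordant pattern classes are
expected in equal numbers; a significant imbalance indicates introgression
between the taxon pair sharing the excess derived alleles (D > 0: P2-P3;
D < 0: P1-P3).  Significance is a chi-square goodness-of-fit test against the
50:50 null, chi2 = (n_ABBA - n_BABA)^2 / (n_ABBA + n_BABA), df = 1, with a
Bonferroni correction across the test battery.

D_FOIL extends this to a symmetric quintet (((P1,P2),(P3,P4)),O) with
T12 < T34: four components D_FO, D_IL, D_FI, D_OL, each a normalized
left-minus-right contrast of site-pattern sums (membership shipped in
``data/dfoil_components.tsv``).  The joint sign signature of the four
components localizes the introgression event and, for events between single
taxa of opposite pairs, can polarize its direction.  In ``alt`` mode the
three-derived pattern classes that contain a full sister-pair synapomorphy
(BBBAA/BBABA and BABBA/ABBBA) are removed from the sums: those classes are
dominated by homoplasy leaking from the large synapomorphic classes and add
noise rather than signal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

from scipy import stats

from .site_patterns import PatternCounts, TaxonSet

COMPONENTS = ("DFO", "DIL", "DFI", "DOL")


class DstatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# packaged tables


def _load_components() -> dict[str, dict[str, dict[str, list[str]]]]:
    table: dict[str, dict[str, dict[str, list[str]]]] = {
        m: {c: {"L": [], "R": []} for c in COMPONENTS}
        for m in ("standard", "alt")}
    src = resources.files("introkit.data").joinpath("dfoil_components.tsv")
    with src.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            for mode in row["modes"].split(","):
                table[mode][row["component"]][row["side"]].append(row["pattern"])
    return table


def _load_signatures() -> dict[str, tuple[str, str]]:
    """signature string -> (hypothesis id, human-readable description)."""
    out: dict[str, tuple[str, str]] = {}
    src = resources.files("introkit.data").joinpath("dfoil_signatures.tsv")
    with src.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["signature"]] = (row["hypothesis"], row["description"])
    return out


_COMPONENT_TABLE = _load_components()


# ---------------------------------------------------------------------------
# results


@dataclass
class TestBattery:
    """A family of D/D_FOIL tests sharing one Bonferroni correction."""

    n_comparisons: int
    family_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_comparisons < 1:
            raise DstatError("battery needs at least one comparison")
        if not 0 < self.family_alpha < 1:
            raise DstatError("family_alpha must be in (0,1)")

    @property
    def threshold(self) -> float:
        return self.family_alpha / self.n_comparisons


@dataclass
class DTestResult:
    taxa: TaxonSet | None
    n_abba: int
    n_baba: int
    D: float | None
    chi2: float
    p: float
    significant: bool = False

    @property
    def defined(self) -> bool:
        return self.D is not None

    def implicated_pair(self) -> tuple[str, str] | None:
        """The taxon pair sharing excess derived alleles, if significant."""
        if not self.significant or not self.defined or self.taxa is None:
            return None
        if self.D > 0:
            return (self.taxa.taxon("P2"), self.taxa.taxon("P3"))
        return (self.taxa.taxon("P1"), self.taxa.taxon("P3"))


@dataclass
class DfoilComponent:
    name: str
    left: int
    right: int
    value: float | None
    chi2: float
    p: float
    sign: str = "0"  # {+,0,-}; 0 iff not significant under the battery


@dataclass
class DfoilResult:
    taxa: TaxonSet | None
    mode: str
    components: dict[str, DfoilComponent]
    signature: tuple[str, str, str, str]
    interpretation: str
    interpretation_label: str
    t12: float
    t34: float
    t1234: float
    t_order_ok: bool


# ---------------------------------------------------------------------------
# operations


def bonferroni(p_values: list[float], family_alpha: float = 0.05
               ) -> tuple[float, list[bool]]:
    """Family-wise threshold alpha/m and per-test significance flags."""
    if not p_values:
        raise DstatError("empty p-value list")
    thr = family_alpha / len(p_values)
    return thr, [p < thr for p in p_values]


def _chi2_binomial(left: int, right: int) -> tuple[float, float]:
    n = left + right
    if n == 0:
        return 0.0, 1.0
    chi2 = (left - right) ** 2 / n
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _binom_exact(left: int, right: int) -> float:
    n = left + right
    if n == 0:
        return 1.0
    return float(stats.binomtest(left, n, 0.5).pvalue)


def patterson_d(counts: PatternCounts, taxa: TaxonSet | None = None,
                exact: bool = False) -> DTestResult:
    """Patterson's D from quartet pattern counts.

    Zero discordant sites yields a flagged-undefined result (D is None,
    p = 1) rather than an exception.  ``exact`` swaps the chi-square
    approximation for an exact two-sided binomial test.
    """
    if counts.arity != 4:
        raise DstatError(f"patterson_d needs arity-4 counts, got {counts.arity}")
    n_abba, n_baba = counts["ABBA"], counts["BABA"]
    n = n_abba + n_baba
    chi2, p = _chi2_binomial(n_abba, n_baba)
    if exact:
        p = _binom_exact(n_abba, n_baba)
    d = (n_abba - n_baba) / n if n > 0 else None
    return DTestResult(taxa=taxa, n_abba=n_abba, n_baba=n_baba, D=d,
                       chi2=chi2, p=p)


def apply_battery(results: list, battery: TestBattery) -> None:
    """Set significance flags / component signs under the battery threshold."""
    thr = battery.threshold
    for r in results:
        if isinstance(r, DTestResult):
            r.significant = r.defined and r.p < thr
        elif isinstance(r, DfoilResult):
            for comp in r.components.values():
                comp.sign = _sign(comp, thr)
            r.signature = tuple(r.components[c].sign for c in COMPONENTS)
            r.interpretation, r.interpretation_label = classify_signature(r.signature)
        else:
            raise DstatError(f"cannot apply battery to {type(r)!r}")


def _sign(comp: DfoilComponent, threshold: float) -> str:
    if comp.value is None or comp.p >= threshold or comp.value == 0:
        return "0"
    return "+" if comp.value > 0 else "-"


def _pattern_mismatch_fraction(counts: PatternCounts, i: int, j: int) -> float:
    if counts.n_sites_used == 0:
        return 0.0
    m = sum(c for pat, c in counts.counts.items() if pat[i] != pat[j])
    return m / counts.n_sites_used


def dfoil(counts: PatternCounts, mode: str = "alt",
          battery: TestBattery | None = None,
          taxa: TaxonSet | None = None) -> DfoilResult:
    """The four D_FOIL components, their signs, and the signature's reading.

    Divergence proxies t12/t34/t1234 are mean pairwise mismatch fractions
    (within (P1,P2), within (P3,P4), and across the pairs) over the sites
    used; only the ordering t12 < t34 < t1234 is consumed, as a check that
    the quintet respects the T12 < T34 convention the signature chart
    assumes.  Without a battery, component signs use an uncorrected 0.05.
    """
    if counts.arity != 5:
        raise DstatError(f"dfoil needs arity-5 counts, got {counts.arity}")
    if mode not in _COMPONENT_TABLE:
        raise DstatError(f"unknown mode {mode!r}")
    import warnings
    if battery is None:
        warnings.warn("no test battery supplied; using uncorrected alpha=0.05")
        threshold = 0.05
    else:
        threshold = battery.threshold

    comps: dict[str, DfoilComponent] = {}
    for name in COMPONENTS:
        sides = _COMPONENT_TABLE[mode][name]
        left = sum(counts[p] for p in sides["L"])
        right = sum(counts[p] for p in sides["R"])
        chi2, p = _chi2_binomial(left, right)
        value = (left - right) / (left + right) if left + right > 0 else None
        comps[name] = DfoilComponent(name=name, left=left, right=right,
                                     value=value, chi2=chi2, p=p)
        comps[name].sign = _sign(comps[name], threshold)

    t12 = _pattern_mismatch_fraction(counts, 0, 1)
    t34 = _pattern_mismatch_fraction(counts, 2, 3)
    t1234 = (sum(_pattern_mismatch_fraction(counts, i, j)
                 for i in (0, 1) for j in (2, 3)) / 4.0)
    signature = tuple(comps[c].sign for c in COMPONENTS)
    hyp, label = classify_signature(signature)
    return DfoilResult(taxa=taxa, mode=mode, components=comps,
                       signature=signature, interpretation=hyp,
                       interpretation_label=label,
                       t12=t12, t34=t34, t1234=t1234,
                       t_order_ok=(t12 < t34 < t1234))


def classify_signature(signature: tuple[str, str, str, str] | str
                       ) -> tuple[str, str]:
    """Map a (D_FO, D_IL, D_FI, D_OL) sign signature to an introgression hypothesis.

    Canonical signatures come from the packaged chart
    (``data/dfoil_signatures.tsv``); anything else is ``complex`` — a sign
    combination not produced by any single introgression event.
    """
    if isinstance(signature, str):
        sig = signature
    else:
        sig = "".join(signature)
    if len(sig) != 4 or set(sig) - {"+", "-", "0"}:
        raise DstatError(f"malformed signature {sig!r}")
    table = _load_signatures()
    if sig in table:
        return table[sig]
    return ("complex", "no single introgression event explains this signature")


def hypothesis_class(hypothesis: str) -> str:
    """Coarse event class of a signature hypothesis.

    ``none`` / ``ancestral`` (ancestor(P1,P2) with P3 or P4) /
    ``intertaxon`` (an event between single taxa of opposite pairs) /
    ``complex``.
    """
    if hypothesis == "none":
        return "none"
    if hypothesis.startswith("anc12_"):
        return "ancestral"
    if hypothesis == "complex":
        return "complex"
    return "intertaxon"


def hypothesis_pair(hypothesis: str) -> frozenset[str] | None:
    """The role pair a signature hypothesis implicates, if any."""
    if hypothesis.startswith("anc12_"):
        return frozenset(("P12", hypothesis.split("_")[1]))
    if "_into_" in hypothesis:
        donor, recipient = hypothesis.split("_into_")
        return frozenset((donor, recipient))
    if hypothesis.endswith("_uncertain"):
        a, b, _ = hypothesis.split("_")
        return frozenset((a, b))
    return None


def ghost_direction(test_excl: DTestResult, test_incl: DTestResult,
                    roles: dict[str, str]) -> str:
    """Polarize introgression using a ghost-lineage contrast of two D tests.

    ``roles`` names the ``focal`` taxon A, the ``candidate`` partner B and
    B's ``relative`` C.  ``test_excl`` omits B and pairs A with C;
    ``test_incl`` includes B.  If the A-C signal seen without B shifts to
    A-B once B is included, the A-C sharing is explained as alleles that
    flowed through B's lineage, which implies direction: B into A.  If both
    signals persist the call is ambiguous; with no significant excluded-test
    signal there is no call.
    """
    a, b, c = roles["focal"], roles["candidate"], roles["relative"]
    if test_excl.taxa is None or test_incl.taxa is None:
        raise DstatError("ghost_direction needs taxon sets on both tests")
    excl_taxa, incl_taxa = set(test_excl.taxa.taxa), set(test_incl.taxa.taxa)
    if b in excl_taxa or b not in incl_taxa or not {a, c} <= excl_taxa:
        raise DstatError("role map inconsistent with the two tests")
    pair_excl = test_excl.implicated_pair()
    pair_incl = test_incl.implicated_pair()
    if pair_excl is None or set(pair_excl) != {a, c}:
        return "none"
    if pair_incl is not None and set(pair_incl) == {a, b}:
        return f"{b} into {a} (directional)"
    if pair_incl is not None and set(pair_incl) == {a, c}:
        return "ambiguous"
    return "ambiguous"


# ---------------------------------------------------------------------------
# reporting


def battery_report_rows(results: list) -> list[dict]:
    rows = []
    for r in results:
        if isinstance(r, DTestResult):
            rows.append({
                "test": "D", "taxa": r.taxa.label if r.taxa else ".",
                "counts": f"ABBA={r.n_abba};BABA={r.n_baba}",
                "statistic": f"{r.D:.4f}" if r.defined else "NA",
                "chi2": f"{r.chi2:.4f}", "p": f"{r.p:.3e}",
                "significant": str(r.significant).lower(),
                "signature": ".", "interpretation":
                    (" <-> ".join(r.implicated_pair()) if r.implicated_pair()
                     else "none"),
            })
        else:
            for comp in r.components.values():
                rows.append({
                    "test": f"DFOIL:{comp.name}",
                    "taxa": r.taxa.label if r.taxa else ".",
                    "counts": f"L={comp.left};R={comp.right}",
                    "statistic": (f"{comp.value:.4f}"
                                  if comp.value is not None else "NA"),
                    "chi2": f"{comp.chi2:.4f}", "p": f"{comp.p:.3e}",
                    "significant": str(comp.sign != "0").lower(),
                    "signature": "".join(r.signature),
                    "interpretation": r.interpretation_label,
                })
    return rows


BATTERY_COLUMNS = ["test", "taxa", "counts", "statistic", "chi2", "p",
                   "significant", "signature", "interpretation"]


def write_battery_tsv(results: list, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(BATTERY_COLUMNS) + "\n")
        for row in battery_report_rows(results):
            fh.write("\t".join(str(row[c]) for c in BATTERY_COLUMNS) + "\n")
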