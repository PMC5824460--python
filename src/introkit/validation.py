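"""Canonical validation studies: calibration, recovery, and QC determinism.

These functions define the package's reference study conditions and measure
its operating characteristics on data from :mod:`introkit.synthetic_data`:

* chi-square calibration under a pure binomial 50:50 null;
* ILS-only false-positive behaviour of Patterson's D on coalescent data
  (the *null scenario*: a quartet with a short internal branch and a mutation
  scale low enough that pooled counts are near-binomial — with more mutation
  per locus, sites within a locus share gene-tree branches and the pooled
  chi-square becomes overdispersed);
* CF symmetry of the two discordant quartet resolutions under ILS;
* D_FOIL signature-class recovery and ghost-direction recovery under pulse
  introgression (the *power scenario*: a deeper quintet at gamma = 0.3);
* agreement of subset assignment with the QC fixture truth labels.

All randomness is controlled by an integer seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .dstats import (TestBattery, apply_battery, dfoil, ghost_direction,
                     hypothesis_class, patterson_d)
from .seqio_qc import qc_locus
from .site_patterns import TaxonSet, count_patterns
from .synthetic_data import (FixtureConfig, IntrogressionEvent, Scenario,
                             make_qc_fixtures, simulate_gene_trees,
                             simulate_scenario)
from .trees_concordance import Clade, concordance_factor, parse_tree

TS4 = TaxonSet.quartet("P1", "P2", "P3", "O")
TS5 = TaxonSet.quintet("P1", "P2", "P3", "P4", "O")

#: ILS-only calibration conditions: rapid-radiation quartet, sparse mutation
NULL_SCENARIO = dict(topology="quartet", tau12=1.0, tau_root=1.3, tau_out=2.6,
                     n_loci=500, locus_len=500, theta=0.00015)
#: introgression power conditions: symmetric quintet, gamma = 0.3 pulses
POWER_SCENARIO = dict(topology="quintet", tau12=1.0, tau34=2.0, tau_root=3.0,
                      n_loci=500, theta=0.0005)


def _sub(seed: int, k: int) -> int:
    return (seed * 131071 + k) % (2 ** 31 - 1)


def binomial_null_rejection_rate(n_reps: int = 10_000, n_sites: int = 500,
                                 alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the chi-square D-test under a binomial 50:50 null."""
    rng = np.random.default_rng(seed)
    a = rng.binomial(n_sites, 0.5, size=n_reps)
    chi2 = (2 * a - n_sites) ** 2 / n_sites
    crit = stats.chi2.isf(alpha, df=1)
    return float((chi2 > crit).mean())


def ils_null_nonsignificant_count(n_reps: int = 100, alpha: float = 0.05,
                                  seed: int = 0) -> int:
    """How many ILS-only replicates leave Patterson's D non-significant.

    Counts are small under the null scenario (a few dozen discordant sites),
    so the exact binomial test replaces the chi-square approximation.
    """
    ok = 0
    for rep in range(n_reps):
        sc = Scenario(**NULL_SCENARIO, seed=_sub(seed, rep))
        _, alns = simulate_scenario(sc)
        r = patterson_d(count_patterns(alns, TS4), TS4, exact=True)
        ok += (not r.defined) or (r.p >= alpha)
    return ok


def discordant_cf_gap_sigmas(n_loci: int = 500, seed: int = 0) -> float:
    """|CF(P1,P3) - CF(P2,P3)| on ILS-only gene trees, in sigma units.

    Under ILS alone the two discordant quartet resolutions are equally
    frequent, so the gap between their CFs should sit within sampling noise.
    """
    sc = Scenario(**{**NULL_SCENARIO, "n_loci": n_loci}, seed=_sub(seed, 991))
    trees = [parse_tree(t.newick()) for t in simulate_gene_trees(sc)]
    universe = frozenset({"P1", "P2", "P3", "O"})
    cf_a = concordance_factor(trees, Clade.of({"P1", "P3"}, universe),
                              n_boot=200, seed=seed)
    cf_b = concordance_factor(trees, Clade.of({"P2", "P3"}, universe),
                              n_boot=200, seed=seed)
    var = (cf_a.cf * (1 - cf_a.cf) + cf_b.cf * (1 - cf_b.cf)) / n_loci
    return abs(cf_a.cf - cf_b.cf) / max(np.sqrt(var), 1e-12)


def signature_class_recovery(n_per_class: int = 20, locus_len: int = 1000,
                             gamma: float = 0.3, seed: int = 0
                             ) -> tuple[int, int]:
    """(recovered, total) for ancestral vs inter-taxon scenario classes.

    Ancestral events place the pulse in the (P1,P2) ancestor; inter-taxon
    events connect P3 to P1.  Signatures are computed in standard mode (on
    homoplasy-free simulated data the standard sums keep the chart's zero
    components exactly zero) against a four-comparison Bonferroni battery.
    """
    battery = TestBattery(n_comparisons=4)
    cases = [("ancestral", IntrogressionEvent("P3", "P12", 1.05, gamma)),
             ("intertaxon", IntrogressionEvent("P3", "P1", 0.1, gamma))]
    got = total = 0
    for rep in range(n_per_class):
        for kind, event in cases:
            sc = Scenario(**POWER_SCENARIO, locus_len=locus_len,
                          introgression=event, seed=_sub(seed, 2000 + rep))
            _, alns = simulate_scenario(sc)
            r = dfoil(count_patterns(alns, TS5), mode="standard",
                      battery=battery)
            got += hypothesis_class(r.interpretation) == kind
            total += 1
    return got, total


def ghost_recovery(n_reps: int = 50, gamma: float = 0.3, seed: int = 0
                   ) -> tuple[int, int]:
    """(recovered, total) for the ghost-lineage direction rule.

    True event: P3 (the candidate donor) into P2 (the focal recipient).  The
    excluded test omits P3 and pairs P2 with P3's sister P4 — the ghost
    signal; the included test adds P3.  Recovery means the rule names P3 as
    the donor into P2.
    """
    ts_excl = TaxonSet(mapping=(("P1", "P1"), ("P2", "P2"), ("P3", "P4"),
                                ("O", "O")), label="excl")
    ts_incl = TaxonSet(mapping=(("P1", "P4"), ("P2", "P3"), ("P3", "P2"),
                                ("O", "O")), label="incl")
    roles = {"focal": "P2", "candidate": "P3", "relative": "P4"}
    got = 0
    for rep in range(n_reps):
        sc = Scenario(**POWER_SCENARIO, locus_len=500,
                      introgression=IntrogressionEvent("P3", "P2", 0.1, gamma),
                      seed=_sub(seed, 5000 + rep))
        _, alns = simulate_scenario(sc)
        r_excl = patterson_d(count_patterns(alns, ts_excl), taxa=ts_excl)
        r_incl = patterson_d(count_patterns(alns, ts_incl), taxa=ts_incl)
        apply_battery([r_excl, r_incl], TestBattery(n_comparisons=2))
        verdict = ghost_direction(r_excl, r_incl, roles)
        got += verdict == "P3 into P2 (directional)"
    return got, n_reps


def qc_label_agreement(seed: int = 0) -> tuple[int, int]:
    """(matching, total) subset labels on the QC fixture set."""
    cfg = FixtureConfig()
    fixtures = make_qc_fixtures(cfg, seed=seed)
    ok = 0
    for aln, expected in fixtures:
        _, rec = qc_locus(aln, cfg.qc)
        ok += rec.subset == expected
    return ok, len(fixtures)
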