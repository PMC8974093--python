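"""Codon-usage Monte-Carlo test: co-ancestry versus convergent evolution.

Two populations occupying the same habitat in different lakes can share
similar antigen-binding residues either because the alleles descend from a
common ancestral lineage (co-ancestry) or because selection assembled the
same amino acids independently (convergence).  The codon record separates
the scenarios: identical amino acids inherited from a shared lineage tend
to be encoded by the *same* codon (eroded only by synonymous turnover),
whereas independently derived residues draw their codons from the genomic
codon usage.

For a population pair, every (allele-of-A, allele-of-B, PSS position) event
with identical amino acids is scored for codon identity.  The observed
proportion is compared against two Monte-Carlo nulls:

* convergence null -- both codons drawn independently from the pooled
  per-amino-acid codon usage of the full sequences (expected identity
  per event: sum of squared codon frequencies);
* co-ancestry null -- codon identical unless a synonymous change hit either
  lineage, with the per-event identity probability
  (1 - p_syn) + p_syn * sum(f_i^2), p_syn estimated from amino-acid-
  conserved non-PSS sites of the same pair.

Significance per scenario comes from an exact binomial proportion test
against the null's mean proportion and from the two-sided Monte-Carlo
empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from Bio.Seq import Seq

from .selection import PSSSet
from .synthdata import empirical_codon_usage

__all__ = [
    "CodonIdentityCounts",
    "ConvergenceTestResult",
    "observed_codon_identity",
    "convergence_null",
    "ancestry_null",
    "estimate_p_syn",
    "convergence_test",
    "expected_identity",
]


def _codons(seq: str) -> list[str]:
    return [seq[3 * i : 3 * i + 3] for i in range(len(seq) // 3)]


def _aa(codon: str) -> str | None:
    if len(codon) == 3 and set(codon) <= set("ACGT"):
        aa = str(Seq(codon).translate())
        return None if aa == "*" else aa
    return None


@dataclass
class CodonIdentityCounts:
    n_identical_aa: int
    n_identical_codon: int
    aa_events: dict[str, int]  # amino acid -> number of identical-aa events

    def __post_init__(self) -> None:
        if not 0 <= self.n_identical_codon <= self.n_identical_aa:
            raise ValueError("0 <= n_identical_codon <= n_identical_aa violated")

    @property
    def proportion(self) -> float:
        if self.n_identical_aa == 0:
            raise ValueError("no shared amino-acid states")
        return self.n_identical_codon / self.n_identical_aa


def _positions(pss: PSSSet | Sequence[int]) -> list[int]:
    return list(pss.positions) if isinstance(pss, PSSSet) else sorted(set(pss))


def observed_codon_identity(
    pop_a: Mapping[str, str],
    pop_b: Mapping[str, str],
    pss: PSSSet | Sequence[int],
) -> CodonIdentityCounts:
    """Count identical amino acids (and identical codons) at PSS over all
    cross-population allele pairs.

    ``pop_a``/``pop_b`` map allele id to the codon-aligned nucleotide
    sequence used in that population; positions are 1-based codons.
    """
    if not pop_a or not pop_b:
        raise ValueError("empty allele pool")
    positions = _positions(pss)
    n_aa = 0
    n_codon = 0
    aa_events: dict[str, int] = {}
    cod_a = {a: _codons(s) for a, s in pop_a.items()}
    cod_b = {b: _codons(s) for b, s in pop_b.items()}
    for a, ca in cod_a.items():
        for b, cb in cod_b.items():
            for p in positions:
                if p > len(ca) or p > len(cb):
                    continue
                x, y = ca[p - 1], cb[p - 1]
                ax, ay = _aa(x), _aa(y)
                if ax is None or ay is None or ax != ay:
                    continue
                n_aa += 1
                aa_events[ax] = aa_events.get(ax, 0) + 1
                if x == y:
                    n_codon += 1
    return CodonIdentityCounts(n_identical_aa=n_aa, n_identical_codon=n_codon,
                               aa_events=aa_events)


def pooled_codon_usage(pop_a: Mapping[str, str], pop_b: Mapping[str, str],
                       pseudocount: float = 0.5) -> dict[str, dict[str, float]]:
    """Per-amino-acid codon usage of the full sequences of both populations."""
    return empirical_codon_usage(
        list(pop_a.values()) + list(pop_b.values()), pseudocount=pseudocount
    )


def expected_identity(usage: Mapping[str, Mapping[str, float]],
                      aa_events: Mapping[str, int],
                      p_syn: float | None = None) -> float:
    """Event-weighted expected codon-identity proportion.

    With ``p_syn`` None this is the convergence expectation (sum of squared
    codon frequencies per amino acid); otherwise the co-ancestry form
    (1 - p_syn) + p_syn * sum(f_i^2).
    """
    total = sum(aa_events.values())
    if total == 0:
        raise ValueError("no events")
    exp = 0.0
    for aa, m in aa_events.items():
        f2 = sum(f * f for f in usage[aa].values())
        q = f2 if p_syn is None else (1.0 - p_syn) + p_syn * f2
        exp += m * q
    return exp / total


def convergence_null(
    counts: CodonIdentityCounts,
    usage: Mapping[str, Mapping[str, float]],
    reps: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Null distribution of identical-codon counts under convergent evolution.

    Per replicate, each identical-amino-acid event draws two codons
    independently from the usage distribution of that amino acid.
    """
    missing = [aa for aa in counts.aa_events if aa not in usage]
    if missing:
        raise ValueError(f"amino acids absent from codon-usage table: {missing}")
    rng = np.random.default_rng(seed)
    out = np.zeros(reps, dtype=np.int64)
    for aa, m in counts.aa_events.items():
        probs = np.array(list(usage[aa].values()))
        probs = probs / probs.sum()
        draws = rng.choice(len(probs), size=(reps, m, 2), p=probs)
        out += (draws[..., 0] == draws[..., 1]).sum(axis=1)
    return out


def ancestry_null(
    counts: CodonIdentityCounts,
    p_syn: float,
    usage: Mapping[str, Mapping[str, float]],
    reps: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Null distribution of identical-codon counts under co-ancestry.

    Each event stays codon-identical with probability
    (1 - p_syn) + p_syn * sum(f_i^2) -- no synonymous change on the pair's
    joint history, plus the chance that changes re-coincide.
    """
    if not 0.0 <= p_syn <= 1.0:
        raise ValueError("p_syn must be in [0, 1]")
    missing = [aa for aa in counts.aa_events if aa not in usage]
    if missing:
        raise ValueError(f"amino acids absent from codon-usage table: {missing}")
    rng = np.random.default_rng(seed)
    out = np.zeros(reps, dtype=np.int64)
    for aa, m in counts.aa_events.items():
        f2 = sum(f * f for f in usage[aa].values())
        q = (1.0 - p_syn) + p_syn * f2
        out += rng.binomial(m, q, size=reps)
    return out


def estimate_p_syn(
    pop_a: Mapping[str, str],
    pop_b: Mapping[str, str],
    exclude_positions: Iterable[int] = (),
    usage: Mapping[str, Mapping[str, float]] | None = None,
) -> float:
    """Per-codon synonymous-change probability between the two populations.

    Over all cross-population allele pairs and codon positions outside
    ``exclude_positions`` (normally the PSS), among events with identical
    amino acids, the fraction ``d`` encoded by *different* codons is
    measured.  Under the co-ancestry model an event differs with
    probability p_syn * (1 - sum f_i^2) (a synonymous change that did not
    re-coincide), so the method-of-moments estimate is
    p_syn = d / (1 - sum f_i^2), with the squared-frequency term
    event-weighted over the amino acids observed at those sites.
    """
    excluded = set(exclude_positions)
    n_aa = 0
    n_diff = 0
    aa_events: dict[str, int] = {}
    cod_a = {a: _codons(s) for a, s in pop_a.items()}
    cod_b = {b: _codons(s) for b, s in pop_b.items()}
    for ca in cod_a.values():
        for cb in cod_b.values():
            for p in range(1, min(len(ca), len(cb)) + 1):
                if p in excluded:
                    continue
                x, y = ca[p - 1], cb[p - 1]
                ax, ay = _aa(x), _aa(y)
                if ax is None or ay is None or ax != ay:
                    continue
                n_aa += 1
                aa_events[ax] = aa_events.get(ax, 0) + 1
                if x != y:
                    n_diff += 1
    if n_aa == 0:
        raise ValueError("no amino-acid-conserved sites to estimate p_syn from")
    d = n_diff / n_aa
    if usage is None:
        usage = pooled_codon_usage(pop_a, pop_b)
    f2_w = expected_identity(usage, aa_events)  # event-weighted sum f_i^2
    if f2_w >= 1.0 - 1e-12:
        return 0.0
    return float(min(1.0, d / (1.0 - f2_w)))


def _mc_pvalue(null: np.ndarray, observed: int) -> float:
    reps = len(null)
    p_hi = (1 + int((null >= observed).sum())) / (reps + 1)
    p_lo = (1 + int((null <= observed).sum())) / (reps + 1)
    return min(1.0, 2.0 * min(p_hi, p_lo))


@dataclass
class ConvergenceTestResult:
    counts: CodonIdentityCounts
    observed_proportion: float
    expected_convergence: float
    expected_ancestry: float
    convergence_null: np.ndarray
    ancestry_null: np.ndarray
    p_convergence_prop: float
    p_ancestry_prop: float
    p_convergence_mc: float
    p_ancestry_mc: float
    p_syn: float
    seed: int | None

    @property
    def preferred_scenario(self) -> str:
        """Scenario least inconsistent with the observation (larger MC p)."""
        if self.p_ancestry_mc != self.p_convergence_mc:
            return ("co_ancestry" if self.p_ancestry_mc > self.p_convergence_mc
                    else "convergence")
        d_anc = abs(self.observed_proportion - self.expected_ancestry)
        d_con = abs(self.observed_proportion - self.expected_convergence)
        return "co_ancestry" if d_anc <= d_con else "convergence"


def convergence_test(
    pop_a: Mapping[str, str],
    pop_b: Mapping[str, str],
    pss: PSSSet | Sequence[int],
    reps: int = 1000,
    seed: int | None = None,
    usage: Mapping[str, Mapping[str, float]] | None = None,
    p_syn: float | None = None,
    pseudocount: float = 0.5,
) -> ConvergenceTestResult:
    """Run the full codon-usage test for one population pair.

    ``usage`` defaults to the pooled per-amino-acid codon frequencies of the
    full sequences of both populations (with a small pseudocount); ``p_syn``
    defaults to the estimate from amino-acid-conserved non-PSS sites.
    """
    counts = observed_codon_identity(pop_a, pop_b, pss)
    if counts.n_identical_aa == 0:
        raise ValueError("no shared amino-acid states at the given positions")
    if usage is None:
        usage = pooled_codon_usage(pop_a, pop_b, pseudocount=pseudocount)
    if p_syn is None:
        p_syn = estimate_p_syn(pop_a, pop_b, exclude_positions=_positions(pss),
                               usage=usage)
    ss = np.random.SeedSequence(seed).spawn(2)
    conv = convergence_null(counts, usage, reps=reps,
                            seed=int(ss[0].generate_state(1)[0] % 2**31))
    anc = ancestry_null(counts, p_syn, usage, reps=reps,
                        seed=int(ss[1].generate_state(1)[0] % 2**31))
    exp_conv = expected_identity(usage, counts.aa_events)
    exp_anc = expected_identity(usage, counts.aa_events, p_syn=p_syn)
    p_conv_prop = stats.binomtest(counts.n_identical_codon, counts.n_identical_aa,
                                  p=min(max(exp_conv, 1e-12), 1 - 1e-12)).pvalue
    p_anc_prop = stats.binomtest(counts.n_identical_codon, counts.n_identical_aa,
                                 p=min(max(exp_anc, 1e-12), 1 - 1e-12)).pvalue
    return ConvergenceTestResult(
        counts=counts,
        observed_proportion=counts.proportion,
        expected_convergence=exp_conv,
        expected_ancestry=exp_anc,
        convergence_null=conv,
        ancestry_null=anc,
        p_convergence_prop=float(p_conv_prop),
        p_ancestry_prop=float(p_anc_prop),
        p_convergence_mc=_mc_pvalue(conv, counts.n_identical_codon),
        p_ancestry_mc=_mc_pvalue(anc, counts.n_identical_codon),
        p_syn=float(p_syn),
        seed=seed,
    )
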