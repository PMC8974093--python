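"""Consensus of site-level positive-selection scans and PSS reduction.

Codon-model fitting (CodeML, BUSTED/MEME, MrBayes) happens outside this
package; their per-site calls are combined here with the rule that a codon
position counts as positively selected when at least ``min_methods``
independent methods flag it.  Alleles are then reduced to the concatenated
residues at those positions -- the representation used for supertype
clustering and the codon-usage convergence test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io import AlleleCatalog

__all__ = [
    "MethodPSSReport",
    "PSSSet",
    "consensus_pss",
    "reduce_to_pss",
    "load_pss_reports",
]


@dataclass
class MethodPSSReport:
    """Positively selected codon positions reported by one method (1-based)."""

    method: str
    sites: list[int]
    metadata: dict = field(default_factory=dict)
    fragment_codons: int = 47

    def __post_init__(self) -> None:
        sites = sorted(set(int(s) for s in self.sites))
        bad = [s for s in sites if not 1 <= s <= self.fragment_codons]
        if bad:
            raise ValueError(
                f"report {self.method!r} has sites outside 1..{self.fragment_codons}: {bad}"
            )
        self.sites = sites


@dataclass
class PSSSet:
    """Consensus positively selected sites with per-site method support."""

    positions: list[int]
    support: dict[int, int]
    min_methods: int = 2

    def __post_init__(self) -> None:
        self.positions = sorted(set(self.positions))
        under = [p for p in self.positions if self.support.get(p, 0) < self.min_methods]
        if under:
            raise ValueError(f"positions below min_methods support: {under}")

    def __len__(self) -> int:
        return len(self.positions)

    def supported_by(self, n_methods: int) -> list[int]:
        """Positions flagged by at least ``n_methods`` methods."""
        return [p for p in self.positions if self.support[p] >= n_methods]


def consensus_pss(
    reports: Iterable[MethodPSSReport],
    min_methods: int = 2,
    exclude: Iterable[int] = (),
) -> PSSSet:
    """Sites identified by at least ``min_methods`` of the reports.

    ``exclude`` removes positions before counting (used for the codon
    carrying the in-frame deletion, which the codon models skipped).
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one method report")
    if min_methods > len(reports):
        raise ValueError(
            f"min_methods={min_methods} exceeds the number of reports ({len(reports)})"
        )
    excluded = set(exclude)
    counts: dict[int, int] = {}
    for rep in reports:
        for s in rep.sites:
            if s not in excluded:
                counts[s] = counts.get(s, 0) + 1
    positions = [p for p, c in counts.items() if c >= min_methods]
    return PSSSet(
        positions=positions,
        support={p: counts[p] for p in positions},
        min_methods=min_methods,
    )


def load_pss_reports(path: str | Path) -> list[MethodPSSReport]:
    """Read per-method site calls from a two-column CSV (method, site)."""
    df = pd.read_csv(path)
    if not {"method", "site"} <= set(df.columns):
        raise ValueError("PSS report CSV needs columns 'method' and 'site'")
    return [
        MethodPSSReport(method=str(m), sites=g["site"].tolist())
        for m, g in df.groupby("method", sort=True)
    ]


def reduce_to_pss(
    catalog: AlleleCatalog, pss: PSSSet
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Concatenate each allele's residues at the PSS and collapse duplicates.

    Returns ``(reduced_to_alleles, allele_to_reduced)`` where the first maps
    each unique reduced amino-acid string to the alleles carrying it.  The
    in-frame-deletion allele contributes ``'-'`` at its missing position via
    its aligned translation.
    """
    if not pss.positions:
        raise ValueError("empty PSS set")
    reduced_to_alleles: dict[str, list[str]] = {}
    allele_to_reduced: dict[str, str] = {}
    for allele_id, tr in catalog.aligned_translations.items():
        if max(pss.positions) > len(tr):
            raise ValueError(
                f"allele {allele_id!r} translation has {len(tr)} residues, "
                f"shorter than PSS position {max(pss.positions)}; supply an "
                f"aligned catalog so deleted codons appear as gaps"
            )
        reduced = "".join(tr[p - 1] for p in pss.positions)
        allele_to_reduced[allele_id] = reduced
        reduced_to_alleles.setdefault(reduced, []).append(allele_id)
    return reduced_to_alleles, allele_to_reduced
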