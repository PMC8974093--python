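"""Readers, writers and validation for the data model of the MHC IIB pipeline.

Three containers travel through the pipeline:

* :class:`AlleleCatalog` -- the unique exon-2 nucleotide variants ("alleles"),
  optionally alignment-aware, with their translations and coding-status flags.
* a sample table -- one row per individual with population / lake / habitat
  labels (kept as a plain :class:`pandas.DataFrame`, validated on load).
* :class:`GenotypeTable` -- a binary individuals x alleles presence matrix
  joined to the sample table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlleleCatalog",
    "GenotypeTable",
    "load_allele_fasta",
    "write_allele_fasta",
    "load_sample_table",
    "validate_sample_table",
    "load_genotypes",
    "write_genotypes",
    "load_study_alleles",
    "translate_nt",
]

_VALID_NT = set("ACGT")
_GAP = "-"

#: habitats and lake types the sample-table validator accepts
HABITATS = ("shallow_benthic", "deep_benthic", "limnetic", "rocky")
LAKE_TYPES = ("tectonic", "crater")


def translate_nt(seq: str, frame_offset: int = 0) -> str:
    """Translate ``seq`` from ``frame_offset``, ignoring a trailing partial codon.

    Gap-containing codons (from an aligned sequence) translate to ``'-'``;
    internal stops appear as ``'*'``.  The 142-bp exon-2 fragment carries
    47 codons plus one trailing base, which is dropped.
    """
    if not 0 <= frame_offset <= 2:
        raise ValueError("frame_offset must be 0, 1 or 2")
    coding = seq[frame_offset:]
    n_codons = len(coding) // 3
    out = []
    for i in range(n_codons):
        codon = coding[3 * i : 3 * i + 3]
        if _GAP in codon:
            out.append(_GAP)
        else:
            out.append(str(Seq(codon).translate()))
    return "".join(out)


@dataclass
class AlleleCatalog:
    """Unique exon-2 alleles with translations and coding-status flags.

    ``alleles`` maps allele id to the ungapped nucleotide sequence; if the
    input was an alignment, ``aligned`` preserves the gapped form (equal
    lengths, gap-only columns removed).  ``classical`` flags alleles from
    the classical locus; non-classical alleles (identified by id) and
    frameshifted alleles are removed downstream by the genotyping filters.
    """

    alleles: dict[str, str]
    frame_offset: int = 0
    classical: dict[str, bool] = field(default_factory=dict)
    aligned: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.classical:
            self.classical = {a: True for a in self.alleles}
        self.translations: dict[str, str] = {
            a: translate_nt(s, self.frame_offset) for a, s in self.alleles.items()
        }
        if self.aligned is not None:
            lengths = {len(s) for s in self.aligned.values()}
            if len(lengths) > 1:
                raise ValueError("aligned sequences must have equal length")
            self.aligned_translations: dict[str, str] = {
                a: translate_nt(s, self.frame_offset) for a, s in self.aligned.items()
            }
        else:
            self.aligned_translations = dict(self.translations)

    # -- basic queries -------------------------------------------------
    @property
    def allele_ids(self) -> list[str]:
        return list(self.alleles)

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, allele_id: str) -> bool:
        return allele_id in self.alleles

    def unique_translations(self) -> int:
        """Number of distinct amino-acid sequences among the alleles."""
        return len(set(self.aligned_translations.values()))

    def alignment(self) -> dict[str, str]:
        """Gapped nucleotide alignment (identity alignment if input was flat)."""
        if self.aligned is not None:
            return self.aligned
        lengths = {len(s) for s in self.alleles.values()}
        if len(lengths) > 1:
            raise ValueError(
                "catalog holds unaligned sequences of unequal length; "
                "provide an aligned FASTA"
            )
        return self.alleles

    def variable_sites(self, level: str = "nt") -> int:
        """Count alignment columns with >=2 distinct non-gap states.

        ``level`` is ``'nt'`` (nucleotide columns) or ``'aa'`` (translated
        columns).
        """
        if level == "nt":
            seqs = list(self.alignment().values())
        elif level == "aa":
            seqs = list(self.aligned_translations.values())
        else:
            raise ValueError("level must be 'nt' or 'aa'")
        n_var = 0
        for col in zip(*seqs):
            states = {c for c in col if c != _GAP}
            if len(states) >= 2:
                n_var += 1
        return n_var

    def subset(self, allele_ids: Iterable[str]) -> "AlleleCatalog":
        ids = list(allele_ids)
        missing = [a for a in ids if a not in self.alleles]
        if missing:
            raise KeyError(f"alleles not in catalog: {missing}")
        return AlleleCatalog(
            alleles={a: self.alleles[a] for a in ids},
            frame_offset=self.frame_offset,
            classical={a: self.classical[a] for a in ids},
            aligned=None if self.aligned is None else {a: self.aligned[a] for a in ids},
        )


def _check_nt(seq: str, record_id: str) -> None:
    bad = set(seq) - _VALID_NT - {_GAP}
    if bad:
        raise ValueError(
            f"record {record_id!r} contains invalid nucleotide characters: {sorted(bad)}"
        )


def _drop_gap_only_columns(seqs: dict[str, str]) -> dict[str, str]:
    cols = list(zip(*seqs.values()))
    keep = [i for i, col in enumerate(cols) if any(c != _GAP for c in col)]
    if len(keep) == len(cols):
        return seqs
    return {a: "".join(s[i] for i in keep) for a, s in seqs.items()}


def load_allele_fasta(
    path: str | Path,
    frame_offset: int = 0,
    non_classical_ids: Iterable[str] = (),
    length_range: tuple[int, int] | None = (139, 142),
    require_classical_clean: bool = True,
) -> AlleleCatalog:
    """Load an allele FASTA (aligned or not) into an :class:`AlleleCatalog`.

    The expected input is the 142-bp exon-2 amplicon fragment (47 codons plus
    one trailing base); a 3-bp in-frame deletion allele is 139 bp.  With
    ``require_classical_clean`` the loader verifies that every classical
    allele translates without internal stop in the chosen frame, which guards
    against a wrong ``frame_offset``.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    raw: dict[str, str] = {}
    for rec in records:
        if rec.id in raw:
            raise ValueError(f"duplicate allele ID in FASTA: {rec.id!r}")
        seq = str(rec.seq).upper()
        _check_nt(seq, rec.id)
        raw[rec.id] = seq
    has_gaps = any(_GAP in s for s in raw.values())
    aligned: dict[str, str] | None = None
    if has_gaps:
        lengths = {len(s) for s in raw.values()}
        if len(lengths) > 1:
            raise ValueError("gapped input must be an alignment of equal lengths")
        aligned = _drop_gap_only_columns(raw)
    flat = {a: s.replace(_GAP, "") for a, s in raw.items()}
    if length_range is not None:
        lo, hi = length_range
        for a, s in flat.items():
            if not lo <= len(s) <= hi:
                raise ValueError(
                    f"allele {a!r} has length {len(s)}, outside expected range "
                    f"[{lo}, {hi}]"
                )
    non_classical = set(non_classical_ids)
    classical = {a: a not in non_classical for a in flat}
    catalog = AlleleCatalog(
        alleles=flat, frame_offset=frame_offset, classical=classical, aligned=aligned
    )
    if require_classical_clean:
        bad = [
            a
            for a, tr in catalog.aligned_translations.items()
            if catalog.classical[a] and "*" in tr
        ]
        if bad:
            raise ValueError(
                f"classical alleles translate with internal stops in frame "
                f"{frame_offset}: {bad}; check frame_offset or flag these as "
                f"non-classical"
            )
    return catalog


def write_allele_fasta(catalog: AlleleCatalog, path: str | Path, aligned: bool = False) -> None:
    seqs = catalog.alignment() if aligned else catalog.alleles
    records = [SeqRecord(Seq(s), id=a, description="") for a, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def load_study_alleles(path: str | Path | None = None) -> AlleleCatalog:
    """Load the deposited Midas cichlid exon-2 allele alignment, if present.

    The alleles recovered in the original field survey are archived in public
    sequence repositories (GenBank accessions MZ368756-MZ368841 and
    MZ368843-MZ368885 plus previously described alleles) and are not bundled
    here.  Place a transcribed, aligned FASTA of the 150 retained alleles at
    ``data/study_alleles.fasta`` (relative to the repository root) to run the
    analyses that depend on the real sequences.
    """
    if path is None:
        path = Path(__file__).resolve().parents[2] / "data" / "study_alleles.fasta"
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"study allele alignment not found at {path}; download the deposited "
            f"allele sequences (GenBank MZ368756-MZ368841, MZ368843-MZ368885 and "
            f"the previously described Amphilophus alleles), align them, and save "
            f"the 150-allele alignment as FASTA at this path"
        )
    return load_allele_fasta(path)


# ---------------------------------------------------------------------------
# sample metadata


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the individual -> population -> lake/habitat design table.

    Requires columns ``individual_id, population, lake, lake_type, habitat``;
    each individual appears once, every population maps to exactly one
    (lake, habitat), and factor levels stay within the sampling design
    (<=6 lakes, <=4 habitat classes, lake_type in {tectonic, crater}).
    """
    required = {"individual_id", "population", "lake", "lake_type", "habitat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if df["individual_id"].duplicated().any():
        dupes = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
        raise ValueError(f"duplicated individuals in sample table: {dupes}")
    bad_hab = set(df["habitat"]) - set(HABITATS)
    if bad_hab:
        raise ValueError(f"unknown habitat labels: {sorted(bad_hab)}")
    bad_lt = set(df["lake_type"]) - set(LAKE_TYPES)
    if bad_lt:
        raise ValueError(f"unknown lake_type labels: {sorted(bad_lt)}")
    if df["lake"].nunique() > 6:
        raise ValueError("more than 6 lakes in sample table")
    pop_map = df.groupby("population")[["lake", "habitat"]].nunique()
    bad_pops = pop_map[(pop_map > 1).any(axis=1)].index.tolist()
    if bad_pops:
        raise ValueError(
            f"populations mapping to multiple (lake, habitat) combinations: {bad_pops}"
        )
    return df.reset_index(drop=True)


def load_sample_table(path: str | Path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path))


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenotypeTable:
    """Binary individuals x alleles presence matrix joined to sample metadata."""

    matrix: pd.DataFrame  # index: individual_id, columns: allele ids, values 0/1
    samples: pd.DataFrame  # validated sample table

    def __post_init__(self) -> None:
        self.matrix = self.matrix.astype(int)
        if not set(self.matrix.values.ravel()) <= {0, 1}:
            raise ValueError("genotype matrix must be binary")
        row_sums = self.matrix.sum(axis=1)
        empty = row_sums[row_sums == 0].index.tolist()
        if empty:
            raise ValueError(f"individuals with zero alleles: {empty}")
        meta_ids = set(self.samples["individual_id"])
        missing = [i for i in self.matrix.index if i not in meta_ids]
        if missing:
            raise ValueError(f"individuals missing from sample table: {missing}")
        self.samples = (
            self.samples.set_index("individual_id")
            .loc[self.matrix.index]
            .rename_axis("individual_id")
            .reset_index()
        )

    @property
    def individuals(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def allele_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def alleles_of(self, individual_id: str) -> list[str]:
        row = self.matrix.loc[individual_id]
        return list(row.index[row == 1])

    def subset_individuals(self, individuals: Iterable[str]) -> "GenotypeTable":
        ids = list(individuals)
        return GenotypeTable(
            matrix=self.matrix.loc[ids],
            samples=self.samples[self.samples["individual_id"].isin(ids)].copy(),
        )

    def drop_alleles(self, allele_ids: Iterable[str]) -> "GenotypeTable":
        drop = set(allele_ids)
        keep = [a for a in self.matrix.columns if a not in drop]
        return GenotypeTable(matrix=self.matrix[keep], samples=self.samples.copy())


def load_genotypes(
    genotype_csv: str | Path,
    metadata_csv: str | Path,
    catalog: AlleleCatalog,
) -> GenotypeTable:
    """Load genotypes from CSV (wide binary or long two-column format).

    Wide format: first column ``individual_id``, remaining columns one per
    allele with 0/1 entries.  Long format: exactly the two columns
    ``individual_id, allele_id``, one row per carried allele.
    """
    samples = load_sample_table(metadata_csv)
    df = pd.read_csv(genotype_csv)
    if "individual_id" not in df.columns:
        raise ValueError("genotype CSV must have an 'individual_id' column")
    if list(df.columns) == ["individual_id", "allele_id"]:
        if df.duplicated().any():
            warnings.warn("duplicate (individual, allele) rows collapsed")
        matrix = (
            pd.crosstab(df["individual_id"], df["allele_id"]).clip(upper=1)
        )
        matrix.index.name = None
        matrix.columns.name = None
    else:
        if df["individual_id"].duplicated().any():
            dupes = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
            raise ValueError(f"duplicated individuals in genotype CSV: {dupes}")
        matrix = df.set_index("individual_id")
        matrix.index.name = None
    unknown = [a for a in matrix.columns if a not in catalog]
    if unknown:
        raise ValueError(f"genotype CSV references alleles absent from catalog: {unknown}")
    return GenotypeTable(matrix=matrix, samples=samples)


def write_genotypes(genotypes: GenotypeTable, genotype_csv: str | Path,
                    metadata_csv: str | Path | None = None) -> None:
    out = genotypes.matrix.copy()
    out.insert(0, "individual_id", out.index)
    out.to_csv(genotype_csv, index=False)
    if metadata_csv is not None:
        genotypes.samples.to_csv(metadata_csv, index=False)
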