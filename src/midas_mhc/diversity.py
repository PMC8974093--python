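"""Sequence-diversity statistics for the exon-2 allele set.

Implements the distance stack of the analysis:

* mean pairwise p-distance (nucleotide ``pi`` and amino-acid ``aa p-dist``)
  with bootstrap standard errors over alignment sites;
* dN and dS by the Nei-Gojobori (1986) method with Jukes-Cantor correction,
  averaged over all sequence pairs;
* the codon-based Z-test of gene-wide positive selection,
  Z = (dN - dS) / SE(dN - dS) with the SE bootstrapped over codon sites;
* per-individual diversity indices over each individual's allele set.

Site-counting convention: every codon contributes 3 sites, split into
synonymous and nonsynonymous fractions by the proportion of the three
possible changes at each position that preserve the amino acid; changes to
stop codons count as nonsynonymous.  Differences between codons are counted
over all minimal substitution paths with equal weight, excluding paths that
pass through a stop codon (falling back to all paths if every path does).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq

from .io import AlleleCatalog, GenotypeTable

__all__ = [
    "DistanceConfig",
    "PDistanceResult",
    "NeiGojoboriResult",
    "ZTestResult",
    "p_distance",
    "nei_gojobori",
    "codon_z_test",
    "pairwise_nei_gojobori",
    "individual_diversity",
    "summarize_by",
    "codon_site_fractions",
    "codon_differences",
]

_NT = "TCAG"
_CODON_LIST = ["".join(c) for c in itertools.product(_NT, repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(_CODON_LIST)}
_AA = {c: str(Seq(c).translate()) for c in _CODON_LIST}
_STOPS = {c for c, a in _AA.items() if a == "*"}


def codon_site_fractions(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) of one codon, s+n=3."""
    if codon in _STOPS or codon not in _AA:
        raise ValueError(f"invalid or stop codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in _NT:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut not in _STOPS and _AA[mut] == _AA[codon]:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous differences (sd, nd) between two codons.

    All orderings of the differing positions are enumerated as substitution
    paths; paths whose intermediates are stop codons are discarded (unless
    that discards every path); each surviving path's synonymous /
    nonsynonymous step counts are averaged.
    """
    for c in (c1, c2):
        if c in _STOPS or c not in _AA:
            raise ValueError(f"invalid or stop codon: {c!r}")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    all_paths: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            if nxt in _STOPS or _AA[cur] != _AA[nxt]:
                nd += 1.0
            else:
                sd += 1.0
            cur = nxt
        all_paths.append((sd, nd))
        if not blocked:
            paths.append((sd, nd))
    use = paths if paths else all_paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    s_site = np.full(64, np.nan)
    n_site = np.full(64, np.nan)
    for c, i in _CODON_INDEX.items():
        if c not in _STOPS:
            s_site[i], n_site[i] = codon_site_fractions(c)
    sd_tab = np.full((64, 64), np.nan)
    nd_tab = np.full((64, 64), np.nan)
    for c1, i in _CODON_INDEX.items():
        if c1 in _STOPS:
            continue
        for c2, j in _CODON_INDEX.items():
            if c2 in _STOPS:
                continue
            sd_tab[i, j], nd_tab[i, j] = codon_differences(c1, c2)
    return s_site, n_site, sd_tab, nd_tab


_S_SITE, _N_SITE, _SD_TAB, _ND_TAB = _build_tables()


@dataclass
class DistanceConfig:
    """Options shared by the distance estimators.

    ``gamma_shape`` switches p-distances to the gamma-corrected form
    d = a((1-p)^(-1/a) - 1); the default (None) is the plain p-distance.
    ``deletion`` is ``'pairwise'``, ``'complete'`` or ``'partial'`` (keep
    sites covered in at least ``site_coverage`` of sequences).
    """

    gamma_shape: float | None = None
    deletion: str = "pairwise"
    site_coverage: float = 0.95
    bootstrap: int = 9999
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.deletion not in ("pairwise", "complete", "partial"):
            raise ValueError("deletion must be 'pairwise', 'complete' or 'partial'")
        if not 0 < self.site_coverage <= 1:
            raise ValueError("site_coverage must be in (0, 1]")


# ---------------------------------------------------------------------------
# p-distance


@dataclass
class PDistanceResult:
    distance: float
    se: float
    n_sequences: int
    n_sites: int
    pairwise: np.ndarray  # condensed per-pair distances


def _char_matrix(seqs: Sequence[str], alphabet_gap: str = "-*X?N") -> tuple[np.ndarray, np.ndarray]:
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal aligned length")
    arr = np.array([list(s.upper()) for s in seqs])
    valid = ~np.isin(arr, list(alphabet_gap))
    return arr, valid


def _apply_deletion_mask(valid: np.ndarray, config: DistanceConfig) -> np.ndarray:
    if config.deletion == "complete":
        keep = valid.all(axis=0)
    elif config.deletion == "partial":
        keep = valid.mean(axis=0) >= config.site_coverage
    else:
        keep = np.ones(valid.shape[1], dtype=bool)
    return keep


def _gamma_correct(p: np.ndarray | float, a: float | None):
    if a is None:
        return p
    return a * ((1.0 - np.asarray(p)) ** (-1.0 / a) - 1.0)


def p_distance(seqs: Sequence[str], config: DistanceConfig | None = None) -> PDistanceResult:
    """Mean pairwise proportion of differing sites, with bootstrap SE.

    Works for nucleotide or amino-acid alignments; gaps and ambiguous
    characters are excluded per pair (pairwise deletion) or per site
    (complete / partial deletion).
    """
    config = config or DistanceConfig()
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    arr, valid = _char_matrix(seqs)
    keep = _apply_deletion_mask(valid, config)
    arr, valid = arr[:, keep], valid[:, keep]
    n, length = arr.shape
    if length == 0:
        raise ValueError("no comparable sites after deletion handling")
    pairs = list(itertools.combinations(range(n), 2))
    diff = np.empty((len(pairs), length))
    vmat = np.empty((len(pairs), length))
    for k, (i, j) in enumerate(pairs):
        both = valid[i] & valid[j]
        diff[k] = both & (arr[i] != arr[j])
        vmat[k] = both
    denom = vmat.sum(axis=1)
    if (denom == 0).any():
        bad = [pairs[k] for k in np.nonzero(denom == 0)[0][:3]]
        raise ValueError(f"sequence pairs with zero comparable sites: {bad}")
    p_pair = diff.sum(axis=1) / denom
    d_pair = np.asarray(_gamma_correct(p_pair, config.gamma_shape))
    point = float(d_pair.mean())

    rng = np.random.default_rng(config.seed)
    reps = np.empty(config.bootstrap)
    for b in range(config.bootstrap):
        w = np.bincount(rng.integers(0, length, size=length), minlength=length)
        den = vmat @ w
        with np.errstate(invalid="ignore"):
            pb = (diff @ w) / den
        db = np.asarray(_gamma_correct(pb, config.gamma_shape))
        reps[b] = np.nanmean(db)
    se = float(np.std(reps, ddof=1)) if config.bootstrap > 1 else float("nan")
    return PDistanceResult(distance=point, se=se, n_sequences=n, n_sites=length,
                           pairwise=d_pair)


# ---------------------------------------------------------------------------
# Nei-Gojobori


def _encode_codons(seqs: Sequence[str], frame_offset: int = 0) -> np.ndarray:
    """Codon-index array (n_seqs x n_codons); -1 marks gap/ambiguous/stop codons."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal aligned length")
    length = lengths.pop()
    n_codons = (length - frame_offset) // 3
    if n_codons < 1:
        raise ValueError("alignment shorter than one codon")
    codes = np.full((len(seqs), n_codons), -1, dtype=np.int64)
    for i, s in enumerate(seqs):
        s = s.upper()
        for c in range(n_codons):
            codon = s[frame_offset + 3 * c : frame_offset + 3 * c + 3]
            idx = _CODON_INDEX.get(codon)
            if idx is not None and codon not in _STOPS:
                codes[i, c] = idx
    return codes


def _jc(p: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = 1.0 - 4.0 * p / 3.0
        d = np.where(arg > 0, -0.75 * np.log(np.where(arg > 0, arg, 1.0)), np.nan)
    return d


@dataclass
class NeiGojoboriResult:
    dn: float
    ds: float
    se_dn: float
    se_ds: float
    n_sequences: int
    n_codons: int
    pairwise_dn: np.ndarray  # condensed
    pairwise_ds: np.ndarray  # condensed


def _codon_pair_arrays(codes: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-pair, per-codon S, N, Sd, Nd contribution matrices (invalid -> 0)."""
    n = codes.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    P, C = len(pairs), codes.shape[1]
    Smat = np.zeros((P, C))
    Nmat = np.zeros((P, C))
    SDmat = np.zeros((P, C))
    NDmat = np.zeros((P, C))
    for k, (i, j) in enumerate(pairs):
        ci, cj = codes[i], codes[j]
        ok = (ci >= 0) & (cj >= 0)
        a, b = ci[ok], cj[ok]
        Smat[k, ok] = 0.5 * (_S_SITE[a] + _S_SITE[b])
        Nmat[k, ok] = 0.5 * (_N_SITE[a] + _N_SITE[b])
        SDmat[k, ok] = _SD_TAB[a, b]
        NDmat[k, ok] = _ND_TAB[a, b]
    return Smat, Nmat, SDmat, NDmat


def _proportions(Smat, Nmat, SDmat, NDmat, w):
    S = Smat @ w
    N = Nmat @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        ps = np.where(S > 0, (SDmat @ w) / np.where(S > 0, S, 1.0), np.nan)
        pn = np.where(N > 0, (NDmat @ w) / np.where(N > 0, N, 1.0), np.nan)
    return ps, pn


def _prepare_codes(seqs: Sequence[str], config: DistanceConfig, frame_offset: int) -> np.ndarray:
    codes = _encode_codons(seqs, frame_offset)
    valid = codes >= 0
    keep = _apply_deletion_mask(valid, config)
    codes = codes[:, keep]
    if codes.shape[1] == 0:
        raise ValueError("no codon sites left after deletion handling")
    return codes


def nei_gojobori(
    seqs: Sequence[str],
    config: DistanceConfig | None = None,
    frame_offset: int = 0,
) -> NeiGojoboriResult:
    """Mean pairwise dN and dS (Nei-Gojobori counts, Jukes-Cantor corrected).

    Per pair: S and N sites averaged between the two sequences, Sd and Nd
    summed over codons, pS = Sd/S and pN = Nd/N mapped through
    d = -(3/4) ln(1 - 4p/3).  Reported dN/dS are means over all pairs;
    standard errors are bootstrapped over codon sites.
    """
    config = config or DistanceConfig()
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    codes = _prepare_codes(seqs, config, frame_offset)
    C = codes.shape[1]
    Smat, Nmat, SDmat, NDmat = _codon_pair_arrays(codes)
    w = np.ones(C)
    ps, pn = _proportions(Smat, Nmat, SDmat, NDmat, w)
    for label, p in (("pS", ps), ("pN", pn)):
        too_big = np.nonzero(p >= 0.75)[0]
        if too_big.size:
            pairs = list(itertools.combinations(range(len(seqs)), 2))
            raise ValueError(
                f"Jukes-Cantor correction undefined ({label} >= 3/4) for sequence "
                f"pair(s) {[pairs[k] for k in too_big[:3]]}"
            )
    ds_pair = _jc(ps)
    dn_pair = _jc(pn)
    dn = float(np.nanmean(dn_pair))
    ds = float(np.nanmean(ds_pair))

    rng = np.random.default_rng(config.seed)
    dn_reps, ds_reps = _bootstrap_codon(
        Smat, Nmat, SDmat, NDmat, C, config.bootstrap, rng
    )
    se_dn = float(np.nanstd(dn_reps, ddof=1)) if config.bootstrap > 1 else float("nan")
    se_ds = float(np.nanstd(ds_reps, ddof=1)) if config.bootstrap > 1 else float("nan")
    return NeiGojoboriResult(
        dn=dn, ds=ds, se_dn=se_dn, se_ds=se_ds,
        n_sequences=len(seqs), n_codons=C,
        pairwise_dn=dn_pair, pairwise_ds=ds_pair,
    )


def _bootstrap_codon(Smat, Nmat, SDmat, NDmat, C, reps, rng, chunk=500):
    """Bootstrap over codon columns; returns per-replicate mean dN and dS."""
    dn_reps = np.empty(reps)
    ds_reps = np.empty(reps)
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        idx = rng.integers(0, C, size=(m, C))
        W = np.zeros((C, m))
        for b in range(m):
            W[:, b] = np.bincount(idx[b], minlength=C)
        S = Smat @ W
        N = Nmat @ W
        with np.errstate(invalid="ignore", divide="ignore"):
            ps = np.where(S > 0, (SDmat @ W) / np.where(S > 0, S, 1.0), np.nan)
            pn = np.where(N > 0, (NDmat @ W) / np.where(N > 0, N, 1.0), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            ds_reps[done : done + m] = np.nanmean(_jc(ps), axis=0)
            dn_reps[done : done + m] = np.nanmean(_jc(pn), axis=0)
        done += m
    return dn_reps, ds_reps


def pairwise_nei_gojobori(
    seqs: Sequence[str], frame_offset: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Square pairwise dN and dS matrices (no bootstrap, pairwise deletion)."""
    config = DistanceConfig(bootstrap=0)
    seqs = list(seqs)
    codes = _prepare_codes(seqs, config, frame_offset)
    Smat, Nmat, SDmat, NDmat = _codon_pair_arrays(codes)
    w = np.ones(codes.shape[1])
    ps, pn = _proportions(Smat, Nmat, SDmat, NDmat, w)
    dn_c, ds_c = _jc(pn), _jc(ps)
    n = len(seqs)
    dn = np.zeros((n, n))
    ds = np.zeros((n, n))
    for k, (i, j) in enumerate(itertools.combinations(range(n), 2)):
        dn[i, j] = dn[j, i] = dn_c[k]
        ds[i, j] = ds[j, i] = ds_c[k]
    return dn, ds


# ---------------------------------------------------------------------------
# codon Z-test


@dataclass
class ZTestResult:
    z: float
    p_value: float
    dn: float
    ds: float
    se_diff: float
    bootstrap: int


def codon_z_test(
    seqs: Sequence[str],
    config: DistanceConfig | None = None,
    frame_offset: int = 0,
) -> ZTestResult:
    """One-tailed codon-based Z-test of positive selection (dN > dS).

    Z = (dN - dS) / SE(dN - dS) with the SE taken from a bootstrap over
    codon sites; the p-value uses the standard-normal approximation.  The
    conventional setting for this test is partial deletion
    (``DistanceConfig(deletion='partial')``) so that near-complete codon
    columns are analysed once for all pairs.
    """
    config = config or DistanceConfig(deletion="partial")
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    codes = _prepare_codes(seqs, config, frame_offset)
    C = codes.shape[1]
    Smat, Nmat, SDmat, NDmat = _codon_pair_arrays(codes)
    w = np.ones(C)
    ps, pn = _proportions(Smat, Nmat, SDmat, NDmat, w)
    dn = float(np.nanmean(_jc(pn)))
    ds = float(np.nanmean(_jc(ps)))
    if config.bootstrap < 2:
        raise ValueError("codon_z_test requires bootstrap replicates")
    rng = np.random.default_rng(config.seed)
    dn_reps, ds_reps = _bootstrap_codon(Smat, Nmat, SDmat, NDmat, C, config.bootstrap, rng)
    diff = dn_reps - ds_reps
    se = float(np.nanstd(diff, ddof=1))
    if not np.isfinite(se) or se == 0:
        if dn == ds:
            # no nonsynonymous/synonymous excess anywhere: Z is exactly 0
            return ZTestResult(z=0.0, p_value=0.5, dn=dn, ds=ds, se_diff=0.0,
                               bootstrap=config.bootstrap)
        raise ValueError("degenerate bootstrap: zero variance of dN - dS")
    z = (dn - ds) / se
    p = float(stats.norm.sf(z))
    return ZTestResult(z=z, p_value=p, dn=dn, ds=ds, se_diff=se, bootstrap=config.bootstrap)


# ---------------------------------------------------------------------------
# per-individual indices


def _mean_over_pairs(mat: np.ndarray, idx: np.ndarray) -> float:
    sub = mat[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(np.nanmean(sub[iu]))


def individual_diversity(
    genotypes: GenotypeTable,
    catalog: AlleleCatalog,
    supertypes: Mapping[str, str] | None = None,
    frame_offset: int | None = None,
) -> pd.DataFrame:
    """Per-individual diversity indices over each individual's allele set.

    Columns: ``n_alleles``, ``pi`` (mean pairwise nucleotide p-distance),
    ``aa_p_dist``, ``dn``, ``ds`` and, when an allele -> supertype map is
    given, ``n_supertypes``.  Individuals carrying a single allele get NaN
    for the distance indices (a distance needs a pair), not zero.
    """
    if frame_offset is None:
        frame_offset = catalog.frame_offset
    allele_ids = [a for a in catalog.allele_ids if a in set(genotypes.allele_ids)]
    missing = set(genotypes.allele_ids) - set(catalog.allele_ids)
    if missing:
        raise ValueError(f"genotype alleles missing from catalog: {sorted(missing)}")
    pos = {a: i for i, a in enumerate(allele_ids)}
    nt_seqs = [catalog.alignment()[a] for a in allele_ids]
    aa_seqs = [catalog.aligned_translations[a] for a in allele_ids]

    pi_mat = _square_from_condensed(p_distance(nt_seqs, DistanceConfig(bootstrap=0)).pairwise,
                                    len(allele_ids)) if len(allele_ids) > 1 else np.zeros((1, 1))
    aa_mat = _square_from_condensed(p_distance(aa_seqs, DistanceConfig(bootstrap=0)).pairwise,
                                    len(allele_ids)) if len(allele_ids) > 1 else np.zeros((1, 1))
    dn_mat, ds_mat = pairwise_nei_gojobori(nt_seqs, frame_offset)

    rows = []
    for ind in genotypes.individuals:
        alleles = genotypes.alleles_of(ind)
        idx = np.array([pos[a] for a in alleles])
        row = {"individual_id": ind, "n_alleles": len(alleles)}
        if supertypes is not None:
            row["n_supertypes"] = len({supertypes[a] for a in alleles})
        if len(alleles) >= 2:
            row["pi"] = _mean_over_pairs(pi_mat, idx)
            row["aa_p_dist"] = _mean_over_pairs(aa_mat, idx)
            row["dn"] = _mean_over_pairs(dn_mat, idx)
            row["ds"] = _mean_over_pairs(ds_mat, idx)
        else:
            row.update({"pi": np.nan, "aa_p_dist": np.nan, "dn": np.nan, "ds": np.nan})
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.merge(genotypes.samples, on="individual_id")


def _square_from_condensed(cond: np.ndarray, n: int) -> np.ndarray:
    mat = np.zeros((n, n))
    for k, (i, j) in enumerate(itertools.combinations(range(n), 2)):
        mat[i, j] = mat[j, i] = cond[k]
    return mat


def summarize_by(indices: pd.DataFrame, by: str,
                 columns: Iterable[str] = ("n_alleles", "n_supertypes", "pi",
                                           "aa_p_dist", "dn", "ds")) -> pd.DataFrame:
    """Group means with standard errors (mean +/- SE tables per population/lake)."""
    cols = [c for c in columns if c in indices.columns]
    g = indices.groupby(by)[cols]
    mean = g.mean()
    se = g.sem()
    out = pd.concat({"mean": mean, "se": se}, axis=1)
    out.columns = [f"{stat}_{col}" for stat, col in out.columns]
    return out.reset_index()
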