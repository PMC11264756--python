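"""SSR genotype diversity, Shannon-partitioned molecular variance, Evanno ΔK.

Genotypes are diploid band-score calls ("a/b", top band / bottom band)
for a panel of individuals typed at microsatellite (SSR) loci.  Per
locus the module reports the allele count, allele frequencies, observed
heterozygosity Ho, gene diversity He = 1 − Σp_i², and the polymorphism
information content

    PIC = 1 − Σp_i² − Σ_{i<j} 2 p_i² p_j².

Molecular variance is partitioned with Shannon information statistics:
for each locus the total Shannon information of the pooled allele
frequencies splits exactly into the (copy-weighted) mean
within-population information and the among-population mutual
information,

    I_total = I_within + I_among,

and 2N·I (N = allele copies) is the corresponding G statistic of the
alleles x populations contingency table, summed over loci.  Variance
components come from a standard two-level AMOVA on allele-mismatch
distances computed alongside, and P values from permuting individuals
across populations with sizes held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "LocusSummary",
    "ShannonAmovaResult",
    "locus_summaries",
    "panel_summary",
    "shannon_amova",
    "evanno_delta_k",
    "band_matrix_to_calls",
]

MISSING = "NA"


class AssignmentError(ValueError):
    pass


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid SSR calls for individuals x loci.

    ``calls`` is a DataFrame indexed by individual with one column per
    locus; each cell is an ``"a/b"`` string (allele labels, ``a == b``
    for homozygotes) or ``"NA"`` for missing.
    """

    calls: pd.DataFrame

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)

    def alleles_at(self, locus: str) -> pd.DataFrame:
        """Two-column frame (allele1, allele2) of non-missing calls at a locus."""
        col = self.calls[locus]
        col = col[col != MISSING].dropna()
        split = col.str.split("/", expand=True)
        if split.shape[1] != 2 or split.isna().any().any():
            raise ValueError(f"locus {locus!r}: calls must be 'a/b' pairs")
        return split

    @classmethod
    def from_csv(cls, source) -> "GenotypeMatrix":
        df = pd.read_csv(source, index_col=0, dtype=str).fillna(MISSING)
        return cls(calls=df)


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    allele_count: int
    frequencies: dict[str, float]
    Ho: float
    He: float
    PIC: float


@dataclass(frozen=True)
class ShannonAmovaResult:
    I_within: float
    I_among: float
    G_among: float
    G_within: float
    G_total: float
    df_among: int
    df_within: int
    df_total: int
    var_among: float
    var_within: float
    var_total: float
    pct_among: float
    pct_within: float
    p_among: float
    p_within: float
    n_permutations: int

    def as_table(self) -> pd.DataFrame:
        """Among/within/total summary in the conventional AMOVA layout."""
        return pd.DataFrame(
            {
                "source": ["Among pop.", "Within pop.", "Total"],
                "df": [self.df_among, self.df_within, self.df_total],
                "G": [self.G_among, self.G_within, self.G_total],
                "variance": [self.var_among, self.var_within, self.var_total],
                "pct": [self.pct_among, self.pct_within, 100.0],
                "p": [self.p_among, self.p_within, np.nan],
            }
        )


# ---------------------------------------------------------------------------
# per-locus diversity

def pic_from_frequencies(p: np.ndarray) -> float:
    """Polymorphism information content from allele frequencies."""
    p = np.asarray(p, dtype=float)
    sum_p2 = np.sum(p**2)
    cross = sum_p2**2 - np.sum(p**4)  # Σ_{i≠j} p_i² p_j² = Σ_{i<j} 2 p_i² p_j²
    return float(1.0 - sum_p2 - cross)


def locus_summaries(g: GenotypeMatrix) -> list[LocusSummary]:
    """Allele counts, frequencies, Ho, He and PIC per locus.

    Frequencies are computed over non-missing allele copies; loci with no
    calls at all are skipped.
    """
    out = []
    for locus in g.loci:
        alleles = g.alleles_at(locus)
        if alleles.empty:
            continue
        copies = pd.concat([alleles[0], alleles[1]])
        freqs = copies.value_counts(normalize=True).sort_index()
        p = freqs.to_numpy()
        ho = float((alleles[0] != alleles[1]).mean())
        he = float(1.0 - np.sum(p**2))
        out.append(
            LocusSummary(
                locus=locus,
                allele_count=len(freqs),
                frequencies=freqs.to_dict(),
                Ho=ho,
                He=he,
                PIC=pic_from_frequencies(p),
            )
        )
    return out


def panel_summary(summaries: list[LocusSummary]) -> dict:
    """Panel-level aggregates: total alleles, mean alleles per locus, Ho/PIC ranges."""
    if not summaries:
        raise ValueError("no locus summaries")
    counts = np.array([s.allele_count for s in summaries])
    ho = np.array([s.Ho for s in summaries])
    pic = np.array([s.PIC for s in summaries])
    return {
        "n_loci": len(summaries),
        "total_alleles": int(counts.sum()),
        "mean_alleles_per_locus": float(counts.mean()),
        "Ho_min": float(ho.min()),
        "Ho_max": float(ho.max()),
        "PIC_min": float(pic.min()),
        "PIC_max": float(pic.max()),
        "PIC_mean": float(pic.mean()),
    }


# ---------------------------------------------------------------------------
# Shannon AMOVA

def _encode(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """One-hot allele-copy counts (n_ind, n_loci, max_alleles) + validity mask.

    counts[i, l, a] is the number of copies (0..2) of allele a carried by
    individual i at locus l; mask[i, l] marks non-missing calls.
    """
    n, L = len(g.individuals), len(g.loci)
    per_locus = []
    max_a = 1
    for locus in g.loci:
        col = g.calls[locus]
        labels = sorted(
            set(
                a
                for cell in col[col != MISSING].dropna()
                for a in str(cell).split("/")
            )
        )
        per_locus.append(labels)
        max_a = max(max_a, len(labels))
    counts = np.zeros((n, L, max_a), dtype=np.int64)
    mask = np.zeros((n, L), dtype=bool)
    for l, locus in enumerate(g.loci):
        index = {a: k for k, a in enumerate(per_locus[l])}
        for i, ind in enumerate(g.individuals):
            cell = g.calls.at[ind, locus]
            if pd.isna(cell) or cell == MISSING:
                continue
            a, b = str(cell).split("/")
            counts[i, l, index[a]] += 1
            counts[i, l, index[b]] += 1
            mask[i, l] = True
    return counts, mask


def _xlogx(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    nz = x > 0
    out[nz] = x[nz] * np.log(x[nz])
    return out


def _shannon_partition(counts: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """(I_within, I_among, G-normalising copy total) summed over loci.

    ``counts``: (n_ind, n_loci, n_alleles) copy counts; ``labels``:
    integer population per individual.  Information is copy-weighted per
    locus; the identity I_total = I_within + I_among holds exactly.
    Returns per-locus-summed 2N·I for among and within via the caller.
    """
    k = labels.max() + 1
    # population allele-copy counts per locus: (k, L, A)
    pop_counts = np.zeros((k, counts.shape[1], counts.shape[2]), dtype=float)
    for j in range(k):
        pop_counts[j] = counts[labels == j].sum(axis=0)
    pooled = pop_counts.sum(axis=0)  # (L, A)
    N_l = pooled.sum(axis=1)  # copies per locus
    Nj_l = pop_counts.sum(axis=2)  # (k, L)
    valid = N_l > 0
    # Shannon information per locus, pooled and per population
    with np.errstate(divide="ignore", invalid="ignore"):
        I_tot = np.where(valid, np.log(N_l) - _xlogx(pooled).sum(axis=1) / np.where(valid, N_l, 1), 0.0)
        I_j = np.where(
            Nj_l > 0,
            np.log(np.where(Nj_l > 0, Nj_l, 1)) - _xlogx(pop_counts).sum(axis=2) / np.where(Nj_l > 0, Nj_l, 1),
            0.0,
        )
    w = np.where(valid, Nj_l / np.where(valid, N_l, 1), 0.0)  # copy weights (k, L)
    I_with = (w * I_j).sum(axis=0)
    I_amg = I_tot - I_with
    # G = 2 N_l I_l summed over loci; report information as locus mean
    G_within = float(np.sum(2.0 * N_l * I_with))
    G_among = float(np.sum(2.0 * N_l * I_amg))
    n_valid = int(valid.sum())
    return G_within, G_among, n_valid


def _mismatch_distance(counts: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Squared inter-individual distance: allele copy mismatches summed over loci.

    For two diploid calls the mismatch is (Σ_a |c1_a − c2_a|)/2 ∈ {0, 1, 2};
    loci missing in either individual are skipped.
    """
    n = counts.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(counts[i][None, :, :] - counts).sum(axis=2) / 2.0  # (n, L)
        both = mask[i][None, :] & mask
        d[i] = np.where(both, diff, 0.0).sum(axis=1)
    return d


def _amova_components(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Two-level AMOVA variance components from a squared-distance matrix."""
    n = len(labels)
    k = labels.max() + 1
    ssd_total = d2.sum() / (2.0 * n)
    ssd_within = 0.0
    sizes = np.zeros(k)
    for j in range(k):
        idx = np.flatnonzero(labels == j)
        sizes[j] = len(idx)
        if len(idx) > 1:
            ssd_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ssd_among = ssd_total - ssd_within
    df_among = k - 1
    df_within = n - k
    ms_within = ssd_within / df_within if df_within > 0 else 0.0
    n0 = (n - np.sum(sizes**2) / n) / df_among
    ms_among = ssd_among / df_among
    var_among = (ms_among - ms_within) / n0
    return float(var_among), float(ms_within)


def shannon_amova(
    g: GenotypeMatrix,
    populations: dict[str, str] | pd.Series,
    permutations: int = 1000,
    seed: int | None = None,
) -> ShannonAmovaResult:
    """Shannon-statistics analysis of molecular variance.

    Parameters
    ----------
    populations
        Mapping individual -> population label covering every individual.
    permutations
        Number of random reassignments of individuals to populations
        (sizes fixed) for the P values, with the +1/(perm+1) correction.
    seed
        Seed for the permutation stream; same seed, same P values.
    """
    pops = pd.Series(populations)
    missing = set(g.individuals) - set(pops.index)
    if missing:
        raise AssignmentError(f"individuals without population: {sorted(missing)}")
    pops = pops.loc[g.individuals]
    labels_cat = pops.astype("category")
    labels = labels_cat.cat.codes.to_numpy()
    k = labels.max() + 1
    if k < 2:
        raise AssignmentError("need >= 2 populations")
    if np.min(np.bincount(labels, minlength=k)) == 0:
        raise AssignmentError("every population needs >= 1 individual")

    counts, mask = _encode(g)
    G_within, G_among, n_loci = _shannon_partition(counts, labels)
    # copy-weighted mean information per locus, from the G = Σ_l 2 N_l I_l identity
    N_copies = counts.sum()
    I_within = G_within / (2.0 * N_copies) if N_copies else 0.0
    I_among = G_among / (2.0 * N_copies) if N_copies else 0.0

    d2 = _mismatch_distance(counts, mask)
    var_among, var_within = _amova_components(d2, labels)
    var_total = var_among + var_within

    n = len(labels)
    rng = np.random.default_rng(seed)
    hits_among = 0
    hits_within = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        gw, ga, _ = _shannon_partition(counts[perm], labels)
        if ga >= G_among - 1e-12:
            hits_among += 1
        if gw <= G_within + 1e-12:
            hits_within += 1
    p_among = (hits_among + 1) / (permutations + 1)
    p_within = (hits_within + 1) / (permutations + 1)

    pct_den = var_total if var_total != 0 else np.nan
    return ShannonAmovaResult(
        I_within=I_within,
        I_among=I_among,
        G_among=G_among,
        G_within=G_within,
        G_total=G_among + G_within,
        df_among=k - 1,
        df_within=n - k,
        df_total=n - 1,
        var_among=var_among,
        var_within=var_within,
        var_total=var_total,
        pct_among=100.0 * var_among / pct_den,
        pct_within=100.0 * var_within / pct_den,
        p_among=p_among,
        p_within=p_within,
        n_permutations=permutations,
    )


def assemble_amova_table(
    df_among: int,
    df_within: int,
    G_among: float,
    G_within: float,
    var_among: float,
    var_within: float,
    p_among: float = np.nan,
    p_within: float = np.nan,
    n_permutations: int = 0,
) -> ShannonAmovaResult:
    """Assemble a full AMOVA result from its among/within components.

    Totals, percentages and the information means follow the additivity
    identities; useful for completing a partially reported partition.
    """
    var_total = var_among + var_within
    pct_den = var_total if var_total != 0 else np.nan
    return ShannonAmovaResult(
        I_within=np.nan,
        I_among=np.nan,
        G_among=G_among,
        G_within=G_within,
        G_total=G_among + G_within,
        df_among=df_among,
        df_within=df_within,
        df_total=df_among + df_within,
        var_among=var_among,
        var_within=var_within,
        var_total=var_total,
        pct_among=100.0 * var_among / pct_den,
        pct_within=100.0 * var_within / pct_den,
        p_among=p_among,
        p_within=p_within,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# band-score ingestion and Evanno ΔK

def band_matrix_to_calls(bands: pd.DataFrame, marker: str) -> pd.Series:
    """Convert a presence/absence (1/0) band matrix for one marker to calls.

    Columns are band labels ordered top to bottom; one scored band makes a
    homozygote, two make a heterozygote (top band first), more than two
    raise, none is missing.
    """
    calls = {}
    for ind, row in bands.iterrows():
        present = [b for b in bands.columns if row[b] == 1]
        if len(present) > 2:
            raise ValueError(f"{ind}/{marker}: more than 2 bands scored")
        if not present:
            calls[ind] = MISSING
        elif len(present) == 1:
            calls[ind] = f"{present[0]}/{present[0]}"
        else:
            calls[ind] = f"{present[0]}/{present[1]}"
    return pd.Series(calls, name=marker)


def evanno_delta_k(runs: pd.DataFrame) -> pd.DataFrame:
    """Evanno ΔK from replicate STRUCTURE log-probabilities.

    ``runs`` has columns ``K, replicate, lnP``.  For each interior K with
    both neighbours present,

        ΔK = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)),

    with sd the sample standard deviation over replicates; ΔK is NaN
    (flagged) where sd = 0.
    """
    for col in ("K", "replicate", "lnP"):
        if col not in runs.columns:
            raise ValueError(f"runs table missing column {col!r}")
    grp = runs.groupby("K")["lnP"]
    means = grp.mean()
    sds = grp.std(ddof=1)
    counts = grp.count()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per K")
    ks = sorted(means.index)
    rows = []
    for k in ks:
        if (k - 1) not in means.index or (k + 1) not in means.index:
            continue
        second = abs(means[k + 1] - 2 * means[k] + means[k - 1])
        dk = second / sds[k] if sds[k] > 0 else np.nan
        rows.append({"K": k, "mean_lnP": means[k], "sd_lnP": sds[k], "deltaK": dk})
    if len(rows) == 0:
        raise ValueError("need >= 3 consecutive K values")
    return pd.DataFrame(rows)
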