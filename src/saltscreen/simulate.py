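"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the study data — a
panel of 18 sorghum varieties phenotyped at 6 replicates per variety x
stage x salinity-platform cell, genotyped at 30 SSR loci carrying 2–5
alleles each — without attempting to reproduce any real variety's
values.

* OJIP transients are phenomenological: a sum of saturating
  exponentials rising from F0* to FM* with time constants for the J, I
  and P phases, sampled log-uniformly over the 10 µs – 1 s acquisition
  window with the JIP mark times included exactly.
* Phenotype panels plant a per-parameter medium-salinity depression per
  stage, so the marker parameter's reduction factor and the SPI–dry
  matter correlation are configurable design points (defaults follow the
  field study: marker RF ≈ 2.3, correlation ≈ 0.8).
* Genotypes follow the Balding–Nichols island model: ancestral allele
  frequencies are Dirichlet, population frequencies are Beta-distributed
  around them with the planted FST, and diploid calls are drawn
  independently.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import MISSING, GenotypeMatrix
from .ojip import FluorescenceTransient, MarkConfig
from .performance import PARAMETERS, STAGES

__all__ = [
    "OjipSimConfig",
    "PanelSimConfig",
    "PopSimConfig",
    "simulate_transient",
    "simulate_panel",
    "simulate_genotypes",
    "simulate_proteins",
    "simulate_ct",
    "simulate_structure_runs",
]


# ---------------------------------------------------------------------------
# OJIP transients

@dataclass(frozen=True)
class OjipSimConfig:
    """Phenomenological OJIP rise: F(t) = F0* + Fv*·Σ w_k (1 − exp(−t/τ_k))."""

    F0: float = 500.0
    FM: float = 2500.0
    w_J: float = 0.5
    w_I: float = 0.3
    w_P: float = 0.2
    tau_J: float = 0.5e-3
    tau_I: float = 10e-3
    tau_P: float = 100e-3
    noise_sd: float = 0.0
    n_points: int = 118
    t_min: float = 1e-5
    t_max: float = 1.0
    # the fluorescence rise starts after the F0 mark: the origin level is
    # read at 50 µs, so the kinetic clock starts there
    t_lag: float = 50e-6

    def __post_init__(self) -> None:
        w = (self.w_J, self.w_I, self.w_P)
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("phase weights must be non-negative and sum to 1")
        if not self.tau_J < self.tau_I < self.tau_P:
            raise ValueError("need tau_J < tau_I < tau_P")
        if self.F0 >= self.FM:
            raise ValueError("need F0 < FM")


def ojip_skeleton(c: OjipSimConfig, times: np.ndarray) -> np.ndarray:
    """Noise-free fluorescence at the given times (F0 level held until t_lag)."""
    t = np.maximum(np.asarray(times, dtype=float) - c.t_lag, 0.0)
    rise = (
        c.w_J * (1.0 - np.exp(-t / c.tau_J))
        + c.w_I * (1.0 - np.exp(-t / c.tau_I))
        + c.w_P * (1.0 - np.exp(-t / c.tau_P))
    )
    return c.F0 + (c.FM - c.F0) * rise


def simulate_transient(
    c: OjipSimConfig,
    seed: int | None = None,
    sample_id: str = "sim",
    marks: MarkConfig | None = None,
) -> FluorescenceTransient:
    """One synthetic transient, log-uniform sampling with mark times exact."""
    marks = marks or MarkConfig()
    rng = np.random.default_rng(seed)
    grid = np.logspace(np.log10(c.t_min), np.log10(c.t_max), c.n_points)
    times = np.unique(np.concatenate([grid, [marks.t_f0, marks.t_f300, marks.t_fj]]))
    values = ojip_skeleton(c, times)
    if c.noise_sd > 0:
        values = np.clip(values + rng.normal(0.0, c.noise_sd, len(values)), 0.0, None)
    return FluorescenceTransient(sample_id=sample_id, times=times, values=values)


# ---------------------------------------------------------------------------
# stage-measurement panels

# low-platform baseline means per parameter (units as measured)
_BASELINES = {"NPQ": 1.2, "ETR": 120.0, "FvFm": 0.82, "A": 25.0, "PIabs": 3.0}

# medium/low depression per (parameter, stage); the marker (PIabs) declines
# from 0.85 at leaf 3 to 0.37 at flowering, a reduction factor of ~2.3 as in
# the field study; other parameters decline mildly
_DEFAULT_DEPRESSION = {
    "NPQ": {"leaf3": 0.95, "boot": 0.9, "flowering": 0.82},
    "ETR": {"leaf3": 0.92, "boot": 0.85, "flowering": 0.72},
    "FvFm": {"leaf3": 0.98, "boot": 0.95, "flowering": 0.9},
    "A": {"leaf3": 0.9, "boot": 0.75, "flowering": 0.58},
    "PIabs": {"leaf3": 0.85, "boot": 0.6, "flowering": 0.37},
}


@dataclass(frozen=True)
class PanelSimConfig:
    """Planted structure for a variety x stage x platform replicate panel."""

    n_varieties: int = 18
    n_replicates: int = 6
    depression: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_DEPRESSION.items()})
    replicate_cv: float = 0.04       # replicate noise, coefficient of variation
    variety_rf_sd: float = 0.08      # log-scale spread of the marker RF across varieties
    dm_spi_correlation: float = 0.8  # planted Pearson r between dry-matter gain and SPI
    dm_low: float = 180.0            # low-platform dry matter (g)
    seed: int = 0

    def __post_init__(self) -> None:
        for p, stages in self.depression.items():
            for s, d in stages.items():
                if not 0.0 < d <= 1.0:
                    raise ValueError(f"depression[{p}][{s}] must be in (0, 1]")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")


def simulate_panel(c: PanelSimConfig) -> pd.DataFrame:
    """Replicate-level stage-measurement panel with planted ground truth.

    Low-platform cells fluctuate around per-variety baselines; medium
    cells are depressed by the configured factors, with the marker
    (PIabs) depression varying across varieties so that SPI spreads, and
    per-variety dry-matter gain correlated with the planted SPI at the
    configured level.
    """
    rng = np.random.default_rng(c.seed)
    varieties = [f"V{i + 1}" for i in range(c.n_varieties)]
    params = list(c.depression)
    # per-variety multiplier on the marker's flowering depression: spreads RF
    rf_noise = rng.normal(0.0, c.variety_rf_sd, c.n_varieties)
    # planted SPI per variety (log10 A + 2 log10 B at the planted depressions)
    marker = "PIabs"
    a_rel = np.array([c.depression[marker]["leaf3"]] * c.n_varieties)
    b_rel = c.depression[marker]["flowering"] * np.exp(rf_noise)
    spi_true = np.log10(a_rel) + 2.0 * np.log10(b_rel)
    z_spi = (spi_true - spi_true.mean()) / (spi_true.std() if spi_true.std() > 0 else 1.0)
    eps = rng.normal(0.0, 1.0, c.n_varieties)
    r = c.dm_spi_correlation
    z_dm = r * z_spi + np.sqrt(max(0.0, 1.0 - r**2)) * eps
    dm_gain = np.clip(0.75 + 0.12 * z_dm, 0.05, None)

    rows = []
    base = {
        v: {p: _BASELINES.get(p, 1.0) * rng.uniform(0.9, 1.1) for p in params}
        for v in varieties
    }
    for vi, v in enumerate(varieties):
        for stage in STAGES:
            for platform in ("low", "medium"):
                for rep in range(1, c.n_replicates + 1):
                    row = {"variety": v, "stage": stage, "platform": platform, "replicate": rep}
                    for p in params:
                        mean = base[v][p]
                        if platform == "medium":
                            d = c.depression[p][stage]
                            if p == marker and stage == "flowering":
                                d = float(np.clip(d * np.exp(rf_noise[vi]), 1e-6, 1.0))
                            mean = mean * d
                        row[p] = mean * (1.0 + rng.normal(0.0, c.replicate_cv))
                    dm_mean = c.dm_low * (dm_gain[vi] if platform == "medium" else 1.0)
                    row["dry_matter"] = (
                        dm_mean * (1.0 + rng.normal(0.0, c.replicate_cv))
                        if stage == "flowering"
                        else np.nan
                    )
                    rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# island-model genotypes

@dataclass(frozen=True)
class PopSimConfig:
    """Balding–Nichols island model with a planted FST."""

    n_populations: int = 2
    n_individuals: int = 9       # per population
    n_loci: int = 30
    min_alleles: int = 2
    max_alleles: int = 5
    fst: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.min_alleles <= self.max_alleles <= 5:
            raise ValueError("alleles per locus must lie in [2, 5]")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("FST must be in [0, 1)")


def simulate_genotypes(c: PopSimConfig) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Diploid SSR calls plus the individual -> population assignment.

    Ancestral frequencies per locus are symmetric Dirichlet; population
    frequencies follow Beta/Dirichlet(p(1−F)/F) around them (Balding–
    Nichols); allele copies are drawn independently within individuals.
    """
    rng = np.random.default_rng(c.seed)
    individuals = [
        f"P{j + 1}I{i + 1}" for j in range(c.n_populations) for i in range(c.n_individuals)
    ]
    pops = {
        ind: f"pop{j + 1}"
        for j in range(c.n_populations)
        for ind in individuals[j * c.n_individuals : (j + 1) * c.n_individuals]
    }
    calls = {}
    for l in range(c.n_loci):
        n_all = int(rng.integers(c.min_alleles, c.max_alleles + 1))
        ancestral = rng.dirichlet(np.ones(n_all))
        labels = [f"a{a + 1}" for a in range(n_all)]
        col = []
        for j in range(c.n_populations):
            if c.fst > 0:
                conc = ancestral * (1.0 - c.fst) / c.fst
                p = rng.dirichlet(np.clip(conc, 1e-6, None))
            else:
                p = ancestral
            draws = rng.choice(n_all, size=(c.n_individuals, 2), p=p)
            for pair in draws:
                a, b = sorted(pair)
                cell = f"{labels[a]}/{labels[b]}"
                if c.missing_rate > 0 and rng.random() < c.missing_rate:
                    cell = MISSING
                col.append(cell)
        calls[f"SSR{l + 1:02d}"] = col
    df = pd.DataFrame(calls, index=individuals)
    return GenotypeMatrix(calls=df), pops


# ---------------------------------------------------------------------------
# proteins, Ct tables, STRUCTURE runs

def simulate_proteins(n: int = 8, length: tuple[int, int] = (150, 500), seed: int = 0) -> list[tuple[str, str]]:
    """Random peptides over the 20 standard residues (uniform composition)."""
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out = []
    for i in range(n):
        L = int(rng.integers(length[0], length[1] + 1))
        seq = "".join(rng.choice(aas, L))
        out.append((f"prot{i + 1}", seq))
    return out


def simulate_ct(
    fold_changes: dict[str, dict[str, float]],
    reference_gene: str = "EF1",
    n_replicates: int = 3,
    ct_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long Ct table realising the given fold changes exactly (at sd = 0).

    ``fold_changes[sample][gene]`` is the target 2^-ΔΔCt value.  The
    reference gene sits near Ct 18 in both conditions; target control
    ΔCt is drawn once per gene and the treated Ct is offset by
    −log2(fold).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample, genes in fold_changes.items():
        ref_ct = 18.0 + rng.uniform(-0.5, 0.5)
        for cond in ("control", "treated"):
            for _ in range(n_replicates):
                rows.append(
                    {"sample": sample, "condition": cond, "gene": reference_gene,
                     "Ct": ref_ct + rng.normal(0.0, ct_sd)}
                )
        for gene, fold in genes.items():
            d_control = rng.uniform(2.0, 8.0)
            for cond in ("control", "treated"):
                dct = d_control if cond == "control" else d_control - np.log2(fold)
                for _ in range(n_replicates):
                    rows.append(
                        {"sample": sample, "condition": cond, "gene": gene,
                         "Ct": ref_ct + dct + rng.normal(0.0, ct_sd)}
                    )
    return pd.DataFrame(rows)


def simulate_structure_runs(
    true_k: int = 2,
    k_range: tuple[int, int] = (1, 6),
    n_replicates: int = 10,
    sd: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate LnP(D) values with a kink in the mean at the true K.

    Mean log-probability rises steeply up to ``true_k`` then flattens,
    which is the signature the Evanno ΔK statistic detects.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(k_range[0], k_range[1] + 1):
        mean = -6000.0 + 800.0 * min(k, true_k) + 20.0 * max(0, k - true_k)
        for rep in range(1, n_replicates + 1):
            rows.append({"K": k, "replicate": rep, "lnP": mean + rng.normal(0.0, sd)})
    return pd.DataFrame(rows)
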