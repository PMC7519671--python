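"""Combinatorial promoter library design and coverage simulation.

A design assigns one promoter (out of a per-gene bin, default six) to each
of five precursor-supply genes (PCK1, TAL1, TKL1, CDC19, PFK1), giving a
6^5 = 7776-membered design space assembled in one pot from a fixed pool of
DNA parts. This module enumerates the space, does the parts arithmetic,
estimates how much of the space a colony sample covers (Monte Carlo over
assembly success and promoter pick probabilities), and summarizes
genotyping outcomes of a sampled library.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENES: tuple[str, ...] = ("PCK1", "TAL1", "TKL1", "CDC19", "PFK1")

_TOL = 1e-9


@dataclass(frozen=True)
class Promoter:
    name: str
    relative_strength: float  # share of the bin's mRNA abundance, in [0, 1]
    pick_probability: float  # probability of being picked in the assembled library


@dataclass
class PromoterCatalog:
    """Ordered genes, each with an ordered bin of candidate promoters."""

    genes: tuple[str, ...]
    bins: dict[str, tuple[Promoter, ...]]

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        for g in self.genes:
            if g not in self.bins or len(self.bins[g]) == 0:
                raise ValueError(f"gene {g} has no promoter bin")
            s = sum(p.relative_strength for p in self.bins[g])
            q = sum(p.pick_probability for p in self.bins[g])
            if abs(s - 1.0) > _TOL:
                raise ValueError(f"relative strengths for {g} sum to {s}, not 1")
            if abs(q - 1.0) > _TOL:
                raise ValueError(f"pick probabilities for {g} sum to {q}, not 1")

    @property
    def bin_sizes(self) -> tuple[int, ...]:
        return tuple(len(self.bins[g]) for g in self.genes)

    @property
    def n_designs(self) -> int:
        return math.prod(self.bin_sizes)

    def promoter_names(self, gene: str) -> tuple[str, ...]:
        return tuple(p.name for p in self.bins[gene])

    def pick_probabilities(self, gene: str) -> np.ndarray:
        return np.array([p.pick_probability for p in self.bins[gene]])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, p.name, p.relative_strength, p.pick_probability)
            for g in self.genes
            for p in self.bins[g]
        ]
        return pd.DataFrame(
            rows, columns=["gene", "promoter", "relative_strength", "pick_probability"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PromoterCatalog":
        genes = tuple(dict.fromkeys(df["gene"]))
        bins = {
            g: tuple(
                Promoter(r.promoter, float(r.relative_strength), float(r.pick_probability))
                for r in df[df["gene"] == g].itertuples()
            )
            for g in genes
        }
        return cls(genes=genes, bins=bins)


@dataclass(frozen=True)
class Genotype:
    """One promoter index per gene, in catalog gene order."""

    indices: tuple[int, ...]

    def key(self, catalog: PromoterCatalog) -> str:
        """Canonical, injective string key: ``gene=promoter`` joined by ``|``."""
        parts = []
        for g, i in zip(catalog.genes, self.indices):
            parts.append(f"{g}={catalog.bins[g][i].name}")
        return "|".join(parts)

    def promoters(self, catalog: PromoterCatalog) -> tuple[str, ...]:
        return tuple(catalog.bins[g][i].name for g, i in zip(catalog.genes, self.indices))


# --- default catalog -----------------------------------------------------

# Native promoter first in each bin, then five promoters spanning a wide
# expression range. Promoter #14 of 30 (bin 3, TKL1) is pPGK1 and #15 pMLS1,
# the least/most picked promoters in the characterized library. Relative
# strengths are synthetic placeholders shaped like mid-log mRNA shares.
_DEFAULT_BINS: dict[str, tuple[str, ...]] = {
    "PCK1": ("pPCK1", "pREV1", "pRNR2", "pCYC1", "pACT1", "pTDH3"),
    "TAL1": ("pTAL1", "pPSP2", "pRAD27", "pPDA1", "pADH1", "pTEF1"),
    "TKL1": ("pTKL1", "pPGK1", "pMLS1", "pPOP6", "pRPL18B", "pHXT7"),
    "CDC19": ("pCDC19", "pRNR1", "pSAC6", "pTPI1", "pPGI1", "pTEF2"),
    "PFK1": ("pPFK1", "pTPK2", "pURE2", "pENO2", "pFBA1", "pGPD1"),
}

# One strength profile reused per bin (native mid-range, weak → strong spread).
_STRENGTHS = np.array([0.18, 0.02, 0.05, 0.10, 0.25, 0.40])

# Skewed pick profile: rarest promoter at 1%, most common at 35% of its bin,
# matching the extremes observed when a one-pot library is characterized.
_SKEWED_PICKS = np.array([0.01, 0.04, 0.09, 0.19, 0.32, 0.35])


def default_catalog(pick: str = "uniform") -> PromoterCatalog:
    """The 5-gene × 6-promoter catalog.

    ``pick`` sets the library pick probabilities per bin:

    - ``"uniform"`` — every promoter equally likely (the design target of a
      one-pot assembly with equimolar parts);
    - ``"skewed"`` — an uneven profile with the rarest promoter near 1% and
      the most common near 35%, mimicking the representation bias observed
      in real one-pot libraries. pPGK1 (TKL1 bin) is pinned rarest and
      pMLS1 most common; other bins rotate the profile so the bias differs
      between genes.
    """
    if pick not in ("uniform", "skewed"):
        raise ValueError(f"pick must be 'uniform' or 'skewed', got {pick!r}")
    bins = {}
    for gi, g in enumerate(GENES):
        names = _DEFAULT_BINS[g]
        if pick == "uniform":
            p = np.full(6, 1 / 6)
        elif g == "TKL1":
            # names: (pTKL1, pPGK1, pMLS1, pPOP6, pRPL18B, pHXT7)
            p = _SKEWED_PICKS[[2, 0, 5, 1, 3, 4]]
        else:
            p = np.roll(_SKEWED_PICKS, gi)
        p = p / p.sum()
        bins[g] = tuple(
            Promoter(name, float(_STRENGTHS[i] / _STRENGTHS.sum()), float(p[i]))
            for i, name in enumerate(names)
        )
    return PromoterCatalog(genes=GENES, bins=bins)


# --- operations ----------------------------------------------------------


def enumerate_design_space(catalog: PromoterCatalog) -> list[Genotype]:
    """All genotypes in lexicographic gene-major order (first gene slowest)."""
    ranges = [range(n) for n in catalog.bin_sizes]
    return [Genotype(indices=t) for t in itertools.product(*ranges)]


def parts_accounting(
    catalog: PromoterCatalog, n_markers: int = 1, n_homology_arms: int = 2
) -> tuple[int, int]:
    """DNA parts arithmetic for a one-pot assembly.

    Returns ``(parts_per_assembly, unique_parts_pool)``: each assembly uses
    one promoter + one ORF unit per gene plus the marker cassette(s) and
    homology arms; the pool holds every distinct promoter, one ORF per gene,
    and the fixed parts.
    """
    n_genes = len(catalog.genes)
    total_promoters = sum(catalog.bin_sizes)
    parts_per_assembly = 2 * n_genes + n_markers + n_homology_arms
    unique_pool = total_promoters + n_genes + n_markers + n_homology_arms
    return parts_per_assembly, unique_pool


@dataclass
class CoverageResult:
    mean_unique: float
    sd_unique: float
    coverage: float  # mean_unique / |design space|
    n_reps: int
    n_colonies: int
    p_correct: float


def expected_unique_closed_form(G: int, n_effective: float) -> float:
    """Occupancy closed form: E[unique] = G·(1 − (1 − 1/G)^n) under uniform picks."""
    return G * (1.0 - (1.0 - 1.0 / G) ** n_effective)


def simulate_coverage(
    catalog: PromoterCatalog,
    n_colonies: int = 10_000,
    p_correct: float = 0.82,
    n_reps: int = 10_000,
    seed: int = 0,
) -> CoverageResult:
    """Monte Carlo estimate of unique genotypes among sampled colonies.

    Each repetition draws ``n_colonies`` colonies; a colony assembles
    correctly with probability ``p_correct``; correct colonies draw one
    promoter per gene independently from the catalog's pick probabilities
    (incorrect assemblies contribute no genotype). Reports the mean ± sd of
    the unique-genotype count over repetitions and the implied coverage of
    the design space.
    """
    if n_colonies < 1 or n_reps < 1:
        raise ValueError("n_colonies and n_reps must be >= 1")
    if not (0.0 <= p_correct <= 1.0):
        raise ValueError("p_correct must be a probability")
    rng = np.random.default_rng(seed)
    sizes = catalog.bin_sizes
    probs = [catalog.pick_probabilities(g) for g in catalog.genes]
    radix = np.ones(len(sizes), dtype=np.int64)
    for i in range(len(sizes) - 2, -1, -1):
        radix[i] = radix[i + 1] * sizes[i + 1]
    counts = np.empty(n_reps)
    for rep in range(n_reps):
        n_ok = rng.binomial(n_colonies, p_correct)
        if n_ok == 0:
            counts[rep] = 0
            continue
        code = np.zeros(n_ok, dtype=np.int64)
        for gi in range(len(sizes)):
            # inverse-CDF draw: faster and bit-stable vs rng.choice
            u = rng.random(n_ok)
            idx = np.searchsorted(np.cumsum(probs[gi]), u, side="right")
            code += idx * radix[gi]
        counts[rep] = np.unique(code).size
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if n_reps > 1 else 0.0
    return CoverageResult(
        mean_unique=mean,
        sd_unique=sd,
        coverage=mean / catalog.n_designs,
        n_reps=n_reps,
        n_colonies=n_colonies,
        p_correct=p_correct,
    )


def summarize_genotyping(sample: pd.DataFrame) -> dict:
    """Key library statistics from a colony table.

    ``sample`` needs boolean columns ``growing, cured, correctly_assembled,
    is_control`` and a nullable ``genotype_call`` (present only for correct,
    cured colonies). Percentages use the denominators of the study design:
    cured/growing, correct/growing, and duplicate genotype calls among the
    filtered *library* genotypes (controls excluded). Undefined ratios
    (zero denominator) are reported as ``None``, never as 0.
    """
    if len(sample) == 0:
        raise ValueError("empty library sample")
    growing = sample[sample["growing"]]
    n_growing = len(growing)

    def pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    n_cured = int(growing["cured"].sum())
    n_correct = int(growing["correctly_assembled"].sum())
    filtered = growing[
        growing["cured"] & growing["correctly_assembled"] & ~growing["is_control"]
    ]
    calls = filtered["genotype_call"].dropna()
    n_filtered = len(calls)
    n_dup = int(n_filtered - calls.nunique()) if n_filtered else 0
    return {
        "n_colonies": int(len(sample)),
        "n_growing": n_growing,
        "pct_cured": pct(n_cured, n_growing),
        "pct_correct": pct(n_correct, n_growing),
        "n_filtered_genotypes": n_filtered,
        "n_duplicates": n_dup,
        "pct_duplicates": pct(n_dup, n_filtered),
    }
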