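"""Synthetic study generator: genotype libraries, response surfaces, plates.

Emulates the statistical structure of a biosensor-screened combinatorial
promoter library so the whole pipeline is testable without external data:

- a hidden genotype → rate surface, log-additive per-promoter effects with
  small pairwise gene×gene interactions (defaults calibrated so the 7776
  designs span ≈40–260 MFI/h and the all-native reference design sits at
  ≈145 MFI/h);
- a sampled training library (default 250 strains × 3 replicates) with
  multiplicative measurement noise tuned so the CV of the replicate mean is
  ≈4.3%, plus assembly/curing/duplicate defects at realistic rates;
- rendered 96-well plate time series (82 points × 15 min from OD 0.025,
  logistic growth, media background) from which the windowed rate
  estimator recovers the true rate.

Everything is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trpml.library import Genotype, PromoterCatalog, default_catalog, enumerate_design_space

# study-shaped defaults
RATE_MIN, RATE_MAX, ANCHOR_RATE = 40.0, 260.0, 145.0
DEFAULT_CV = 0.043  # CV of the replicate mean
N_TIMEPOINTS, DT_H = 82, 0.25
OD0 = 0.025


@dataclass
class DefectRates:
    """Library defect probabilities applied to QC metadata."""

    p_correct_assembly: float = 0.82
    p_cured: float = 0.92
    p_duplicate: float = 0.037
    p_growing: float = 0.91  # fraction of colonies that grow sufficiently
    p_sequenced: float = 1.0

    def none(self) -> "DefectRates":
        return DefectRates(1.0, 1.0, 0.0, 1.0, 1.0)


@dataclass
class GroundTruthModel:
    """Hidden genotype → rate (MFI/h) surface.

    Latent score = Σ_g effect[g][promoter] + Σ_{g<h} interaction[g,h][p_g,p_h];
    a monotone piecewise-linear calibration hinged at the anchor maps the
    latent range onto [rate_min, rate_max] with the native design (all
    promoter index 0) exactly at the anchor rate.
    """

    catalog: PromoterCatalog
    effects: dict[str, np.ndarray]
    interactions: dict[tuple[str, str], np.ndarray]
    rate_min: float
    rate_max: float
    anchor_rate: float
    seed: int
    _cal: tuple[float, float, float] = field(default=None, repr=False)  # L_anchor, s_lo, s_hi

    def latent(self, genotypes: list[Genotype]) -> np.ndarray:
        idx = np.array([g.indices for g in genotypes])
        genes = self.catalog.genes
        L = np.zeros(len(genotypes))
        for j, g in enumerate(genes):
            L += self.effects[g][idx[:, j]]
        for (ga, gb), mat in self.interactions.items():
            ja, jb = genes.index(ga), genes.index(gb)
            L += mat[idx[:, ja], idx[:, jb]]
        return L

    def rate(self, genotypes: list[Genotype]) -> np.ndarray:
        L = self.latent(genotypes)
        La, s_lo, s_hi = self._cal
        return np.where(L >= La, self.anchor_rate + (L - La) * s_hi, self.anchor_rate + (L - La) * s_lo)

    @property
    def native_design(self) -> Genotype:
        return Genotype(indices=(0,) * len(self.catalog.genes))


def make_ground_truth(
    catalog: PromoterCatalog | None = None,
    seed: int = 0,
    effect_sd: float = 0.35,
    interaction_sd: float = 0.08,
    interactions: bool = True,
    rate_min: float = RATE_MIN,
    rate_max: float = RATE_MAX,
    anchor_rate: float = ANCHOR_RATE,
) -> GroundTruthModel:
    """Draw a reproducible response surface and calibrate it.

    Calibration evaluates the latent score over the exhaustive design space
    and solves the two hinge slopes so min → rate_min, max → rate_max and
    the native design → anchor_rate exactly. With all effects zero every
    design equals the anchor. Raises when rate_min == rate_max while
    effects are nonzero (no monotone calibration exists).
    """
    catalog = catalog if catalog is not None else default_catalog()
    rng = np.random.default_rng(seed)
    effects = {g: effect_sd * rng.standard_normal(len(catalog.bins[g])) for g in catalog.genes}
    inter: dict[tuple[str, str], np.ndarray] = {}
    if interactions:
        for ga, gb in itertools.combinations(catalog.genes, 2):
            inter[(ga, gb)] = interaction_sd * rng.standard_normal(
                (len(catalog.bins[ga]), len(catalog.bins[gb]))
            )
    truth = GroundTruthModel(
        catalog=catalog,
        effects=effects,
        interactions=inter,
        rate_min=rate_min,
        rate_max=rate_max,
        anchor_rate=anchor_rate,
        seed=seed,
        _cal=(0.0, 0.0, 0.0),
    )
    space = enumerate_design_space(catalog)
    L = truth.latent(space)
    La = truth.latent([truth.native_design])[0]
    L_min, L_max = float(L.min()), float(L.max())
    spread = max(L_max - La, La - L_min)
    if spread == 0.0:
        truth._cal = (La, 0.0, 0.0)  # flat surface: everything at the anchor
        return truth
    if rate_min == rate_max:
        raise ValueError("rate_min == rate_max but the response surface is not flat")
    s_hi = (rate_max - anchor_rate) / (L_max - La) if L_max > La else 0.0
    s_lo = (anchor_rate - rate_min) / (La - L_min) if La > L_min else 0.0
    truth._cal = (La, s_lo, s_hi)
    return truth


@dataclass
class TrainingSet:
    """A sampled mock library ready for phenotyping/modeling."""

    genotypes: pd.DataFrame  # strain + one promoter column per gene + QC metadata
    replicates: pd.DataFrame  # strain, replicate, rate (noisy)
    true_rates: pd.DataFrame  # strain, true_rate
    catalog: PromoterCatalog
    truth: GroundTruthModel


def sample_training_set(
    truth: GroundTruthModel,
    n_strains: int = 250,
    n_reps: int = 3,
    cv: float = DEFAULT_CV,
    defects: DefectRates | None = None,
    seed: int = 1,
) -> TrainingSet:
    """Draw a training library with replicate noise and QC defects.

    Replicate rates are ``true·(1 + N(0, cv·√n_reps))`` so the CV of the
    replicate *mean* is ≈``cv``. A fraction ``p_duplicate`` of strains
    reuse an earlier strain's genotype; assembly/curing/sequencing defects
    are injected into the metadata flags at the stated rates (they do not
    alter the measured signal — defective strains are meant to be removed
    by QC downstream).
    """
    defects = defects if defects is not None else DefectRates()
    catalog = truth.catalog
    if n_strains > catalog.n_designs:
        raise ValueError("n_strains exceeds the design space")
    rng = np.random.default_rng(seed)
    probs = [catalog.pick_probabilities(g) for g in catalog.genes]

    chosen: list[Genotype] = []
    seen: set[tuple[int, ...]] = set()
    n_dup = int(round(defects.p_duplicate * n_strains))
    while len(chosen) < n_strains - n_dup:
        idx = tuple(int(rng.choice(len(p), p=p)) for p in probs)
        if idx not in seen:
            seen.add(idx)
            chosen.append(Genotype(indices=idx))
    for _ in range(n_dup):
        chosen.append(chosen[int(rng.integers(len(chosen)))])
    rng.shuffle(chosen)  # list shuffle keeps Genotype objects intact

    strains = [f"S{i:04d}" for i in range(1, n_strains + 1)]
    true = truth.rate(chosen)
    rep_sd = cv * np.sqrt(n_reps)
    rep_rows = []
    for s, tr in zip(strains, true):
        noise = rng.standard_normal(n_reps) * rep_sd
        for r in range(n_reps):
            rep_rows.append((s, r + 1, float(tr * (1.0 + noise[r]))))
    replicates = pd.DataFrame(rep_rows, columns=["strain", "replicate", "rate"])

    meta_rows = []
    dup_count: dict[tuple[int, ...], int] = {}
    for s, g in zip(strains, chosen):
        dup_count[g.indices] = dup_count.get(g.indices, 0) + 1
    for s, g in zip(strains, chosen):
        meta_rows.append(
            {
                "strain": s,
                **{gene: catalog.bins[gene][i].name for gene, i in zip(catalog.genes, g.indices)},
                "key": g.key(catalog),
                "growing": bool(rng.random() < defects.p_growing),
                "sequencing_complete": bool(rng.random() < defects.p_sequenced),
                "assembly_exact": bool(rng.random() < defects.p_correct_assembly),
                "cured": bool(rng.random() < defects.p_cured),
                "single_genotype": True,
                "is_duplicate": dup_count[g.indices] > 1,
            }
        )
    genotypes = pd.DataFrame(meta_rows)
    true_rates = pd.DataFrame({"strain": strains, "true_rate": true})
    return TrainingSet(genotypes, replicates, true_rates, catalog, truth)


# --- plate rendering ------------------------------------------------------


@dataclass
class GrowthParams:
    """Logistic growth + GFP accumulation parameters for rendering wells.

    The synthesis shape function ramps up below the OD window and is
    exactly 1 throughout a slightly widened window [0.07, 0.16], then
    declines — so at zero noise the windowed endpoint estimator recovers
    the true rate exactly. ``carrying_capacity`` of 0.30 with
    ``growth_rate`` 0.35 h⁻¹ puts ~13 of the 82 grid points inside the
    default OD window.
    """

    od0: float = OD0
    carrying_capacity: float = 0.30
    growth_rate: float = 0.35  # h^-1
    od_noise_sd: float = 0.0
    gfp_noise_sd: float = 0.0
    media_od: float = 0.04
    media_gfp: float = 30.0
    gfp0: float = 20.0


def _logistic_od(t: np.ndarray, gp: GrowthParams) -> np.ndarray:
    K, r, x0 = gp.carrying_capacity, gp.growth_rate, gp.od0
    return K / (1.0 + (K - x0) / x0 * np.exp(-r * t))


def _synthesis_shape(od: np.ndarray) -> np.ndarray:
    """0 below OD 0.04, linear ramp to 1 at 0.07, 1 until 0.16, decline after."""
    s = np.clip((od - 0.04) / 0.03, 0.0, 1.0)
    s = np.where(od > 0.16, np.clip(1.0 - (od - 0.16) / 0.10, 0.0, 1.0), s)
    return s


def render_timeseries(
    true_rate: float,
    growth: GrowthParams | None = None,
    n_points: int = N_TIMEPOINTS,
    dt_h: float = DT_H,
    seed: int = 0,
) -> pd.DataFrame:
    """Render one well: columns ``time_h, od600, gfp`` (background included).

    GFP accumulates as the cumulative integral of ``true_rate`` gated by the
    OD-dependent shape function (full rate inside the widened window), so
    per-cell fluorescence plateaus inside the rate window and declines
    above it. Media wells are rendered by ``true_rate=0`` with
    ``carrying_capacity→0`` via :func:`render_media_well`.
    """
    if true_rate < 0:
        raise ValueError("true_rate must be positive")
    gp = growth if growth is not None else GrowthParams()
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt_h
    od = _logistic_od(t, gp)
    # per-interval integration at midpoint OD keeps the in-window slope exact
    od_mid = _logistic_od((t[:-1] + t[1:]) / 2.0, gp)
    incr = true_rate * _synthesis_shape(od_mid) * dt_h
    gfp = gp.gfp0 + np.concatenate([[0.0], np.cumsum(incr)])
    od_meas = od + gp.media_od + rng.standard_normal(n_points) * gp.od_noise_sd
    gfp_meas = gfp + gp.media_gfp + rng.standard_normal(n_points) * gp.gfp_noise_sd
    return pd.DataFrame({"time_h": t, "od600": od_meas, "gfp": gfp_meas})


def render_media_well(
    growth: GrowthParams | None = None, n_points: int = N_TIMEPOINTS, dt_h: float = DT_H, seed: int = 0
) -> pd.DataFrame:
    """Background-only well: media offsets plus measurement noise."""
    gp = growth if growth is not None else GrowthParams()
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt_h
    od = gp.media_od + rng.standard_normal(n_points) * gp.od_noise_sd
    gfp = gp.media_gfp + rng.standard_normal(n_points) * gp.gfp_noise_sd
    return pd.DataFrame({"time_h": t, "od600": od, "gfp": gfp})


def render_plates(
    replicate_rates: pd.DataFrame,
    growth: GrowthParams | None = None,
    seed: int = 0,
    wells_per_plate: int = 96,
    n_media_wells: int = 2,
    low_growth_strains: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out replicate wells onto 96-well plates and render them.

    ``replicate_rates`` has columns ``strain, replicate, rate`` — one row
    per well, each rendered at its (already noisy) rate. Strains in
    ``low_growth_strains`` are rendered with a low carrying capacity
    (max OD < window top) so they fail QC criterion 1. Returns
    ``(reads, well_map)`` in the long CSV schemas the phenotyping stage
    consumes; every plate carries ``n_media_wells`` background wells.
    """
    gp = growth if growth is not None else GrowthParams()
    rng = np.random.default_rng(seed)
    low_growth_strains = low_growth_strains or set()
    capacity = wells_per_plate - n_media_wells
    jobs = list(replicate_rates[["strain", "replicate", "rate"]].itertuples(index=False))
    reads_parts, map_rows = [], []
    wellnames = [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)]
    for plate_no in range((len(jobs) + capacity - 1) // capacity):
        plate = f"P{plate_no + 1:02d}"
        chunk = jobs[plate_no * capacity : (plate_no + 1) * capacity]
        for w in range(n_media_wells):
            well = wellnames[w]
            df = render_media_well(gp, seed=int(rng.integers(2**31)))
            df.insert(0, "well", well)
            df.insert(0, "plate", plate)
            reads_parts.append(df)
            map_rows.append((plate, well, "media", w + 1))
        for k, job in enumerate(chunk):
            well = wellnames[n_media_wells + k]
            gpw = gp
            if job.strain in low_growth_strains:
                gpw = GrowthParams(**{**gp.__dict__, "carrying_capacity": 0.10})
            df = render_timeseries(float(job.rate), gpw, seed=int(rng.integers(2**31)))
            df.insert(0, "well", well)
            df.insert(0, "plate", plate)
            reads_parts.append(df)
            map_rows.append((plate, well, job.strain, int(job.replicate)))
    reads = pd.concat(reads_parts, ignore_index=True)
    well_map = pd.DataFrame(map_rows, columns=["plate", "well", "strain", "replicate"])
    return reads, well_map


def generate_mock_study(
    n_strains: int = 250,
    n_reps: int = 3,
    cv: float = DEFAULT_CV,
    seed: int = 7,
    catalog: PromoterCatalog | None = None,
    defects: DefectRates | None = None,
    render: bool = False,
) -> dict:
    """One-call mock study: truth + training set (+ rendered plates).

    Returns a dict with keys ``truth, training, catalog`` and, when
    ``render`` is true, ``reads, well_map`` plate tables whose windowed
    rates reproduce the training replicates' noisy rates. Strains flagged
    non-growing in the metadata are rendered with insufficient growth so
    QC criterion 1 fails for exactly those strains.
    """
    catalog = catalog if catalog is not None else default_catalog()
    truth = make_ground_truth(catalog, seed=seed)
    training = sample_training_set(
        truth, n_strains=n_strains, n_reps=n_reps, cv=cv, defects=defects, seed=seed + 1
    )
    out = {"truth": truth, "training": training, "catalog": catalog}
    if render:
        low = set(training.genotypes.loc[~training.genotypes["growing"], "strain"])
        reads, well_map = render_plates(
            training.replicates, seed=seed + 2, low_growth_strains=low
        )
        out["reads"], out["well_map"] = reads, well_map
    return out
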