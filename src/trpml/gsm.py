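"""Constraint-based scoring of expression targets.

Simulates how metabolic flux redistributes as a cell shifts resources from
growth to tryptophan production, and scores every reaction/gene by its
average flux fold change across a grid of suboptimal growth fractions.
Genes whose associated reactions carry more flux under production
(score > 1) are overexpression candidates; genes whose reactions carry less
(score < 1) are downregulation candidates. Pathway overrepresentation among
the classified targets is assessed with a two-sided Fisher exact test.

All linear programs are solved with scipy's HiGHS backend with a fixed
variable ordering, so repeated runs return identical flux vectors.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.stats import fisher_exact


class InfeasibleModelError(RuntimeError):
    """LP infeasibility, annotated with the solve stage that failed."""

    def __init__(self, stage: str, detail: str = ""):
        self.stage = stage
        super().__init__(f"infeasible model at stage '{stage}'" + (f": {detail}" if detail else ""))


@dataclass(frozen=True)
class Reaction:
    """One stoichiometric reaction with bounds (mmol·gDW⁻¹·h⁻¹) and gene links."""

    id: str
    stoich: Mapping[str, float]
    lb: float
    ub: float
    genes: tuple[str, ...] = ()
    pathway: str | None = None


@dataclass
class StoichiometricModel:
    """Generic container for a (genome-scale) stoichiometric model.

    ``objective`` is the growth reaction id; ``target`` is the production
    sink (tryptophan) reaction id.
    """

    metabolites: list[str]
    reactions: list[Reaction]
    objective: str
    target: str

    def __post_init__(self) -> None:
        mets = set(self.metabolites)
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate reaction ids: {sorted(dupes)}")
        for r in self.reactions:
            missing = set(r.stoich) - mets
            if missing:
                raise ValueError(f"reaction {r.id} references undeclared metabolites {sorted(missing)}")
            if r.lb > r.ub:
                raise ValueError(f"reaction {r.id} has lb > ub ({r.lb} > {r.ub})")
        if self.objective not in set(ids):
            raise ValueError(f"objective reaction {self.objective!r} not in model")
        if self.target not in set(ids):
            raise ValueError(f"target reaction {self.target!r} not in model")

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S matrix, metabolites × reactions, in declaration order."""
        midx = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoich.items():
                S[midx[m], j] = c
        return S

    def gene_reactions(self) -> dict[str, list[str]]:
        """Map gene id → ids of reactions it is associated with."""
        out: dict[str, list[str]] = {}
        for r in self.reactions:
            for g in r.genes:
                out.setdefault(g, []).append(r.id)
        return out

    def pathway_membership(self) -> dict[str, set[str]]:
        """Map pathway label → set of associated gene ids."""
        out: dict[str, set[str]] = {}
        for r in self.reactions:
            if r.pathway:
                out.setdefault(r.pathway, set()).update(r.genes)
        return out

    # --- JSON round trip (native schema) --------------------------------
    def to_dict(self) -> dict:
        return {
            "metabolites": list(self.metabolites),
            "reactions": [
                {
                    "id": r.id,
                    "stoich": dict(r.stoich),
                    "lb": r.lb,
                    "ub": r.ub,
                    "genes": list(r.genes),
                    "pathway": r.pathway,
                }
                for r in self.reactions
            ],
            "objective": self.objective,
            "target": self.target,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StoichiometricModel":
        return cls(
            metabolites=list(d["metabolites"]),
            reactions=[
                Reaction(
                    id=r["id"],
                    stoich=dict(r["stoich"]),
                    lb=float(r["lb"]),
                    ub=float(r["ub"]),
                    genes=tuple(r.get("genes", ())),
                    pathway=r.get("pathway"),
                )
                for r in d["reactions"]
            ],
            objective=d["objective"],
            target=d["target"],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StoichiometricModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FluxDistribution:
    """A mass-balanced flux vector and the growth fraction it was solved at."""

    fluxes: dict[str, float]
    growth_fraction: float

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    @property
    def total_flux(self) -> float:
        return float(sum(abs(v) for v in self.fluxes.values()))


_FIX_EPS = 1e-9


def _solve(c, A_eq, b_eq, bounds, stage):
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise InfeasibleModelError(stage, res.message)
    return res


def solve_pfba(model: StoichiometricModel, growth_fraction: float = 1.0) -> FluxDistribution:
    """Parsimonious FBA at a fixed fraction of the maximum growth rate.

    Three LP stages: (1) maximize growth to obtain μ_max and fix growth at
    ``growth_fraction·μ_max``; (2) maximize the tryptophan target flux with
    growth fixed; (3) with both fixed, minimize the total absolute flux
    Σ|v| (parsimony). Stage 3 uses the standard positive/negative split
    v = v⁺ − v⁻.
    """
    if not (0 < growth_fraction <= 1):
        raise ValueError(f"growth_fraction must be in (0, 1], got {growth_fraction}")
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    b = np.zeros(S.shape[0])
    bounds = [(r.lb, r.ub) for r in model.reactions]
    rid_idx = {r.id: j for j, r in enumerate(model.reactions)}
    j_obj, j_tgt = rid_idx[model.objective], rid_idx[model.target]

    # stage 1: max growth
    c = np.zeros(n)
    c[j_obj] = -1.0
    res = _solve(c, S, b, bounds, "max-growth")
    mu_max = -res.fun
    g_fix = growth_fraction * mu_max

    # stage 2: max target with growth fixed
    bounds2 = list(bounds)
    bounds2[j_obj] = (g_fix - _FIX_EPS * max(1.0, abs(g_fix)), g_fix + _FIX_EPS * max(1.0, abs(g_fix)))
    c = np.zeros(n)
    c[j_tgt] = -1.0
    res = _solve(c, S, b, bounds2, "max-target")
    t_fix = -res.fun

    # stage 3: min Σ|v| with growth and target fixed; v = p - q, p,q >= 0
    bounds3 = list(bounds2)
    bounds3[j_tgt] = (t_fix - _FIX_EPS * max(1.0, abs(t_fix)), t_fix + _FIX_EPS * max(1.0, abs(t_fix)))
    A = np.hstack([S, -S])
    c = np.ones(2 * n)
    split_bounds = []
    for lb, ub in bounds3:
        split_bounds.append((max(lb, 0.0), max(ub, 0.0)))  # v⁺
    for lb, ub in bounds3:
        split_bounds.append((max(-ub, 0.0), max(-lb, 0.0)))  # v⁻
    res = _solve(c, A, b, split_bounds, "min-total-flux")
    v = res.x[:n] - res.x[n:]
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    return FluxDistribution(fluxes=fluxes, growth_fraction=growth_fraction)


DEFAULT_FRACTIONS: tuple[float, ...] = tuple(np.round(np.linspace(0.30, 0.80, 11), 2))
"""Suboptimal growth grid: 30–80% of μ_max in 5% steps (11 conditions)."""


def suboptimal_scan(
    model: StoichiometricModel, fractions: Sequence[float] = DEFAULT_FRACTIONS
) -> list[FluxDistribution]:
    """pFBA at every growth fraction; remaining capacity goes to the target."""
    fractions = list(fractions)
    if not fractions:
        raise ValueError("fractions must be nonempty")
    out = []
    for f in fractions:
        try:
            out.append(solve_pfba(model, growth_fraction=f))
        except InfeasibleModelError as e:
            raise InfeasibleModelError(e.stage, f"at growth fraction {f}") from e
    return out


DEFAULT_PSEUDO_FLUX = 1e-4


def reaction_scores(
    scan: Sequence[FluxDistribution],
    reference: FluxDistribution,
    pseudo_flux: float = DEFAULT_PSEUDO_FLUX,
) -> pd.DataFrame:
    """Per-reaction average flux fold change vs the max-growth reference.

    s_r = mean over scan of (|v_f| + δ) / (|v_ref| + δ), with pseudo-flux δ
    guarding zero reference fluxes. Reactions whose |flux| stays below δ in
    the reference *and* every scan point are marked ``scored=False``
    (fold change is meaningless noise there). ``sign_change`` notes
    reversible reactions whose direction differs from the reference at any
    scan point.

    Returns a DataFrame indexed by reaction id with columns
    ``score, scored, sign_change``.
    """
    ref_ids = set(reference.fluxes)
    for d in scan:
        if set(d.fluxes) != ref_ids:
            diff = sorted(set(d.fluxes) ^ ref_ids)
            raise ValueError(f"scan/reference reaction sets differ: {diff}")
    d = pseudo_flux
    rows = []
    for rid in reference.fluxes:
        v_ref = reference.fluxes[rid]
        vs = np.array([s.fluxes[rid] for s in scan])
        scored = not (abs(v_ref) < d and np.all(np.abs(vs) < d))
        score = float(np.mean((np.abs(vs) + d) / (abs(v_ref) + d)))
        sign_change = bool(np.any(np.sign(vs) * np.sign(v_ref) < 0))
        rows.append((rid, score if scored else np.nan, scored, sign_change))
    return pd.DataFrame(rows, columns=["reaction", "score", "scored", "sign_change"]).set_index(
        "reaction"
    )


_CLASS_TOL = 1e-9


def classify(score: float) -> str:
    if score > 1 + _CLASS_TOL:
        return "overexpress"
    if score < 1 - _CLASS_TOL:
        return "downregulate"
    return "neutral"


def gene_scores(reaction_part: pd.DataFrame, model: StoichiometricModel) -> pd.DataFrame:
    """Gene scores = unweighted mean of the gene's scored reaction scores.

    Genes whose reactions are all unscored are reported with ``score=NaN``;
    genes of the model with no associated reactions appear in the
    ``unmapped`` attribute of the returned frame (``df.attrs['unmapped']``).
    AND/OR structure of gene–reaction rules is deliberately ignored: each
    associated reaction contributes equally.
    """
    g2r = model.gene_reactions()
    rows = []
    for gene, rids in sorted(g2r.items()):
        scores = reaction_part.loc[[r for r in rids if r in reaction_part.index]]
        scored = scores[scores["scored"]]
        if len(scored) == 0:
            rows.append((gene, np.nan, "unscored", len(rids)))
        else:
            s = float(scored["score"].mean())
            rows.append((gene, s, classify(s), len(rids)))
    df = pd.DataFrame(rows, columns=["gene", "score", "classification", "n_reactions"]).set_index(
        "gene"
    )
    df.attrs["unmapped"] = []  # genes known to the model always map via reactions
    return df


def score_targets(
    model: StoichiometricModel,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    pseudo_flux: float = DEFAULT_PSEUDO_FLUX,
) -> pd.DataFrame:
    """End-to-end: reference pFBA → suboptimal scan → gene score table."""
    reference = solve_pfba(model, growth_fraction=1.0)
    scan = suboptimal_scan(model, fractions)
    rxn = reaction_scores(scan, reference, pseudo_flux)
    return gene_scores(rxn, model)


def regime_overlap(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> dict[str, set[str]]:
    """Targets classified identically under two carbon-source regimes.

    Returns per classification the intersection of gene sets, e.g. genes
    called ``overexpress`` under both glucose and ethanol configurations.
    """
    out: dict[str, set[str]] = {}
    for cls in ("overexpress", "downregulate"):
        a = set(scores_a.index[scores_a["classification"] == cls])
        b = set(scores_b.index[scores_b["classification"] == cls])
        out[cls] = a & b
    return out


def demo_model() -> StoichiometricModel:
    """Minimal synthetic central-carbon network for demos and smoke runs.

    Glucose uptake feeds glycolysis toward PEP/pyruvate and biomass, with a
    pentose-phosphate branch supplying E4P; E4P + PEP condense into a
    shikimate-pathway sink representing tryptophan. Not a curated
    reconstruction — a stand-in network whose flux redistribution
    qualitatively mirrors the precursor competition the scoring procedure
    probes (PPP/PCK-like reactions gain flux as production rises, the
    pyruvate drain loses it).
    """
    rxn = [
        Reaction("glc_uptake", {"g6p": 1}, 0, 10, ("HXT1",), "transport"),
        Reaction("pgi", {"g6p": -1, "f6p": 1}, -1000, 1000, ("PGI1",), "glycolysis"),
        Reaction("pfk", {"f6p": -1, "fbp": 1}, 0, 1000, ("PFK1",), "glycolysis"),
        Reaction("lower_glycolysis", {"fbp": -1, "pep": 2}, 0, 1000, ("FBA1",), "glycolysis"),
        Reaction("pyk", {"pep": -1, "pyr": 1}, 0, 1000, ("CDC19",), "glycolysis"),
        Reaction("ppp_oxidative", {"g6p": -1, "x5p": 1}, 0, 1000, ("ZWF1",), "ppp"),
        Reaction("tkl", {"x5p": -2, "e4p": 1, "f6p": 1}, -1000, 1000, ("TKL1",), "ppp"),
        Reaction("tal", {"x5p": -1, "e4p": 1}, -1000, 1000, ("TAL1",), "ppp"),
        Reaction("pck", {"pyr": -1, "pep": 1}, 0, 1000, ("PCK1",), "anaplerosis"),
        Reaction("shikimate", {"e4p": -1, "pep": -1, "trp_pool": 1}, 0, 1000, ("ARO4", "TRP2"), "shikimate"),
        Reaction("biomass", {"pyr": -1, "f6p": -0.2}, 0, 1000, (), None),
        Reaction("trp_sink", {"trp_pool": -1}, 0, 1000, (), "shikimate"),
    ]
    mets = ["g6p", "f6p", "fbp", "pep", "pyr", "x5p", "e4p", "trp_pool"]
    return StoichiometricModel(metabolites=mets, reactions=rxn, objective="biomass", target="trp_sink")


def pathway_enrichment(
    targets: Iterable[str],
    pathway_membership: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Two-sided Fisher exact test of target overrepresentation per pathway.

    For each pathway the 2×2 table is
    ``[[in-pathway targets, in-pathway non-targets],
    [out-pathway targets, out-pathway non-targets]]`` over the gene
    universe. Fold representation compares the target rate inside the
    pathway with the rate over the whole universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe is empty")
    targets = set(targets)
    if not targets <= universe:
        raise ValueError(f"targets outside universe: {sorted(targets - universe)[:5]}")
    rows = []
    for pw, genes in sorted(pathway_membership.items()):
        genes = set(genes)
        if not genes <= universe:
            raise ValueError(f"pathway {pw!r} has genes outside universe")
        a = len(genes & targets)
        b = len(genes - targets)
        c = len(targets - genes)
        dd = len(universe - genes - targets)
        _, p = fisher_exact([[a, b], [c, dd]], alternative="two-sided")
        overall = len(targets) / len(universe)
        fold = (a / len(genes)) / overall if genes and overall > 0 else np.nan
        rows.append((pw, a, b, c, dd, fold, float(p)))
    return pd.DataFrame(
        rows, columns=["pathway", "a", "b", "c", "d", "fold_representation", "p_two_sided"]
    ).set_index("pathway")
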