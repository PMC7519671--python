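"""Design recommendation over the combinatorial space.

Exploit mode ranks unseen designs by predictive mean; explore mode by
expected improvement (EI), which also rewards predictive uncertainty. The
design space (7776 points by default) is small enough that exhaustive
enumeration gives the exact optimum — no stochastic optimizer is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from trpml.encoding import GenotypeOneHotEncoder
from trpml.library import Genotype, PromoterCatalog, enumerate_design_space


def expected_improvement(mu, sigma, f_best) -> np.ndarray | float:
    """Gaussian expected improvement E[max(X − f*, 0)], X ~ N(μ, σ²).

    Closed form (μ−f*)·Φ(z) + σ·φ(z) with z = (μ−f*)/σ; degenerates to
    max(μ−f*, 0) at σ = 0. Vectorized over μ/σ.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be nonnegative")
    diff = mu - f_best
    ei = np.where(diff > 0, diff, 0.0).astype(float)
    pos = sigma > 0
    if np.any(pos):
        with np.errstate(over="ignore"):
            z = np.divide(diff, sigma, out=np.zeros_like(diff), where=pos)
        z = np.clip(z, -40.0, 40.0)  # Φ/φ saturate; avoids overflow at tiny σ
        ei = np.where(pos, diff * norm.cdf(z) + sigma * norm.pdf(z), ei)
    return ei if ei.ndim else float(ei)


@dataclass
class RecommendationSet:
    table: pd.DataFrame  # rank, key, per-gene promoters, mu, sigma, score
    mode: str
    f_best: float | None

    @property
    def keys(self) -> list[str]:
        return list(self.table["key"])


def recommend(
    model,
    catalog: PromoterCatalog,
    mode: str = "exploit",
    n: int = 30,
    exclude: set[str] | None = None,
    f_best: float | None = None,
    encoder: GenotypeOneHotEncoder | None = None,
) -> RecommendationSet:
    """Top-n unseen designs by predictive mean (exploit) or EI (explore).

    The full space is enumerated and scored; ``exclude`` (canonical
    genotype keys, normally the training genotypes) is removed first. In
    explore mode ``f_best`` defaults must be supplied by the caller as the
    best observed training mean — the standard Bayesian-optimization
    incumbent. Ties break lexicographically on the genotype key so runs
    are reproducible.
    """
    if mode not in ("exploit", "explore"):
        raise ValueError(f"mode must be 'exploit' or 'explore', got {mode!r}")
    exclude = exclude or set()
    space = enumerate_design_space(catalog)
    keys = [g.key(catalog) for g in space]
    mask = np.array([k not in exclude for k in keys])
    available = int(mask.sum())
    if n > available:
        raise ValueError(
            f"requested {n} recommendations but only {available} unseen designs "
            f"remain ({len(space)} total, {len(exclude)} excluded)"
        )
    cand = [g for g, m in zip(space, mask) if m]
    cand_keys = [k for k, m in zip(keys, mask) if m]
    enc = encoder if encoder is not None else GenotypeOneHotEncoder(catalog).fit()
    X = enc.transform(cand)
    mu, sigma = model.predict(X, return_std=True)
    if mode == "exploit":
        score = mu
    else:
        if f_best is None:
            raise ValueError("explore mode requires f_best (best observed training mean)")
        score = expected_improvement(mu, sigma, f_best)
    order = sorted(range(len(cand)), key=lambda i: (-score[i], cand_keys[i]))[:n]
    rows = []
    for rank, i in enumerate(order, start=1):
        rows.append(
            (rank, cand_keys[i], *cand[i].promoters(catalog), float(mu[i]), float(sigma[i]), float(score[i]))
        )
    cols = ["rank", "key", *catalog.genes, "mu", "sigma", "score"]
    return RecommendationSet(pd.DataFrame(rows, columns=cols), mode=mode, f_best=f_best)


def overlap(a: RecommendationSet | list[str], b: RecommendationSet | list[str]) -> tuple[int, float]:
    """Shared genotype keys between two recommendation lists: (count, count/|a|)."""
    ka = a.keys if isinstance(a, RecommendationSet) else list(a)
    kb = b.keys if isinstance(b, RecommendationSet) else list(b)
    shared = len(set(ka) & set(kb))
    return shared, shared / len(ka) if ka else 0.0
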