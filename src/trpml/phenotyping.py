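"""Plate-reader phenotyping: OD/GFP time series → per-strain GFP synthesis rates.

The GFP synthesis rate (MFI/h) inside a fixed OD600 window is the study's
proxy for tryptophan productivity: per-cell fluorescence of the biosensor
reporter stabilizes once cultures reach OD ≈ 0.075 and starts to decay
above OD ≈ 0.15, so only that interval yields a clean rate.

Input layout (long format):

- reads: columns ``plate, well, time_h, od600, gfp``
- well map: columns ``plate, well, strain, replicate`` where ``strain`` is a
  strain id or the literal ``"media"`` for blank wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

OD_WINDOW: tuple[float, float] = (0.075, 0.150)

MEDIA = "media"

QC_CRITERIA = (
    "od_range_ok",
    "sequencing_complete",
    "assembly_exact",
    "plasmid_cured",
    "single_genotype",
)


def subtract_background(reads: pd.DataFrame, well_map: pd.DataFrame) -> pd.DataFrame:
    """Subtract per-plate, per-timepoint media means from OD and GFP.

    Background is estimated independently on every plate as the mean of its
    media wells at each time point and subtracted from all wells (media
    wells included, so they read ≈0 afterwards). Raises if any plate lacks
    a media well.
    """
    media_wells = well_map[well_map["strain"] == MEDIA][["plate", "well"]]
    plates = reads["plate"].unique()
    missing = set(plates) - set(media_wells["plate"].unique())
    if missing:
        raise ValueError(f"plates without media wells: {sorted(missing)}")
    media_reads = reads.merge(media_wells, on=["plate", "well"])
    bg = (
        media_reads.groupby(["plate", "time_h"])[["od600", "gfp"]]
        .mean()
        .rename(columns={"od600": "bg_od", "gfp": "bg_gfp"})
        .reset_index()
    )
    out = reads.merge(bg, on=["plate", "time_h"], how="left")
    out["od600"] = out["od600"] - out["bg_od"]
    out["gfp"] = out["gfp"] - out["bg_gfp"]
    return out.drop(columns=["bg_od", "bg_gfp"])


@dataclass
class StrainQCRecord:
    """Five-criteria quality control verdict for one strain.

    Criterion 1 (``od_range_ok``) is read from the background-subtracted
    series (max OD must reach the top of the rate window); criteria 2–5
    come from genotyping metadata. A missing metadata field fails its
    criterion with reason ``"missing"`` rather than silently passing.
    """

    strain: str
    flags: dict[str, bool]
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(self.flags.get(c, False) for c in QC_CRITERIA)


_META_FIELDS = {
    "sequencing_complete": "sequencing_complete",
    "assembly_exact": "assembly_exact",
    "plasmid_cured": "cured",
    "single_genotype": "single_genotype",
}


def apply_qc(
    strain: str,
    od600: Sequence[float],
    metadata: Mapping[str, object],
    od_threshold: float = OD_WINDOW[1],
) -> StrainQCRecord:
    """Evaluate the five QC criteria for one strain."""
    flags: dict[str, bool] = {}
    reasons: list[str] = []
    max_od = float(np.nanmax(od600)) if len(od600) else float("nan")
    flags["od_range_ok"] = bool(max_od >= od_threshold)
    if not flags["od_range_ok"]:
        reasons.append(f"od_range_ok: max OD {max_od:.3f} < {od_threshold}")
    for crit, col in _META_FIELDS.items():
        val = metadata.get(col) if hasattr(metadata, "get") else None
        if val is None or (isinstance(val, float) and np.isnan(val)):
            flags[crit] = False
            reasons.append(f"{crit}: missing")
        else:
            flags[crit] = bool(val)
            if not flags[crit]:
                reasons.append(f"{crit}: failed")
    return StrainQCRecord(strain=strain, flags=flags, reasons=reasons)


@dataclass
class RateResult:
    rate: float | None  # MFI/h; None when undefined
    n_points: int
    estimator: str
    reason: str | None = None


def _first_window_run(od: np.ndarray, low: float, high: float) -> np.ndarray:
    """Indices of the first contiguous run of points with low <= OD <= high."""
    mask = (od >= low) & (od <= high)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return idx
    breaks = np.flatnonzero(np.diff(idx) > 1)
    end = breaks[0] + 1 if breaks.size else idx.size
    return idx[:end]


def gfp_synthesis_rate(
    time_h: Sequence[float],
    od600: Sequence[float],
    gfp: Sequence[float],
    od_window: tuple[float, float] = OD_WINDOW,
    estimator: str = "endpoint",
) -> RateResult:
    """GFP synthesis rate over the first contiguous in-window run of points.

    ``estimator="endpoint"`` uses ΔGFP/Δt between the first and last
    in-window points (the study's literal definition);
    ``estimator="slope"`` fits a least-squares line to all in-window points
    — with ~15 usable points the regression slope is less noise-sensitive.
    Both coincide exactly for linear GFP(t). Later re-entries into the OD
    window (transient dips) are ignored.
    """
    t = np.asarray(time_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    g = np.asarray(gfp, dtype=float)
    if not (t.shape == od.shape == g.shape):
        raise ValueError("time/od/gfp must have equal lengths")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    idx = _first_window_run(od, *od_window)
    if idx.size < 2:
        return RateResult(None, int(idx.size), estimator, reason="fewer than 2 points in OD window")
    tw, gw = t[idx], g[idx]
    if estimator == "endpoint":
        rate = (gw[-1] - gw[0]) / (tw[-1] - tw[0])
    elif estimator == "slope":
        rate = float(np.polyfit(tw, gw, 1)[0])
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return RateResult(float(rate), int(idx.size), estimator)


@dataclass
class RatePhenotype:
    """Replicate-aggregated rate for one strain (MFI/h)."""

    strain: str
    rates: tuple[float, ...]
    mean: float
    sem: float | None  # sd/sqrt(n); None at n=1
    cv_pct: float | None  # SEM/mean·100; CV of the mean
    n: int


def aggregate_replicates(strain: str, rates: Iterable[float]) -> RatePhenotype:
    """Mean, SEM and CV-of-the-mean over finite replicate rates.

    At n=1 the SEM/CV are undefined (``None``); such strains are kept but
    excluded from model training downstream. Raises when no finite
    replicate remains.
    """
    r = np.asarray([x for x in rates if x is not None and np.isfinite(x)], dtype=float)
    if r.size == 0:
        raise ValueError(f"strain {strain}: no finite replicate rates")
    mean = float(r.mean())
    if r.size == 1:
        return RatePhenotype(strain, tuple(r), mean, None, None, 1)
    sem = float(r.std(ddof=1) / np.sqrt(r.size))
    cv = 100.0 * sem / mean if mean > 0 else None
    return RatePhenotype(strain, tuple(r), mean, sem, cv, int(r.size))


# --- outlier removal ------------------------------------------------------


def outlier_filter_percentile(
    replicates: pd.DataFrame, fraction: float = 0.01
) -> tuple[pd.DataFrame, list[str]]:
    """Drop whole strains owning any of the most extreme replicate deviations.

    ``replicates`` has columns ``strain, rate``. Each replicate's deviation
    is |rate − strain mean| / strain mean; replicates strictly above the
    (1 − fraction) quantile of all deviations are flagged, and every strain
    with a flagged replicate is removed entirely. ``fraction=0`` removes
    nothing.
    """
    if replicates["strain"].nunique() < 2:
        raise ValueError("need at least 2 strains")
    df = replicates.copy()
    means = df.groupby("strain")["rate"].transform("mean")
    dev = (df["rate"] - means).abs() / means.abs()
    thr = float(np.quantile(dev, 1.0 - fraction))
    flagged = df.loc[dev > thr, "strain"].unique().tolist()
    kept = df[~df["strain"].isin(flagged)].reset_index(drop=True)
    return kept, sorted(flagged)


MAD_SCALE = 1.4826  # consistency factor for normal data


def outlier_filter_robust(
    replicates: pd.DataFrame, c: float = 3.0, pair_rel_cutoff: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strain robust replicate filter (median ± c·scaled-MAD rule).

    A replicate is flagged when |rate − median| > c·MAD·1.4826 within its
    strain. For duplicate strains (n=2) the MAD rule is degenerate (both
    deviations are equal), so an irreproducible pair — relative difference
    above ``pair_rel_cutoff`` of the pair mean — flags the replicate
    farther from zero deviation symmetry (one of the two), which leaves a
    single survivor. Strains left with ≤1 replicate are dropped whole.

    Returns ``(kept replicates, removed replicates)`` with a ``reason``
    column on the removed frame. Idempotent: a second pass removes nothing.
    """
    df = replicates.copy().reset_index(drop=True)
    removed_rows = []
    keep_mask = np.ones(len(df), dtype=bool)
    for strain, grp in df.groupby("strain"):
        x = grp["rate"].to_numpy(dtype=float)
        if x.size >= 3:
            med = np.median(x)
            mad = MAD_SCALE * np.median(np.abs(x - med))
            flag = np.abs(x - med) > c * mad
        elif x.size == 2:
            mean = x.mean()
            flag = np.zeros(2, dtype=bool)
            if mean != 0 and abs(x[1] - x[0]) / abs(mean) > pair_rel_cutoff:
                flag[int(np.argmax(np.abs(x - mean)))] = True
        else:
            flag = np.zeros(x.size, dtype=bool)
        for i, f in zip(grp.index, flag):
            if f:
                keep_mask[i] = False
                removed_rows.append((strain, df.loc[i, "rate"], "mad_outlier"))
        n_left = int((~flag).sum())
        if n_left <= 1:
            for i, f in zip(grp.index, flag):
                if not f and keep_mask[i]:
                    keep_mask[i] = False
                    removed_rows.append((strain, df.loc[i, "rate"], "single_survivor"))
    kept = df[keep_mask].reset_index(drop=True)
    removed = pd.DataFrame(removed_rows, columns=["strain", "rate", "reason"])
    return kept, removed


# --- end-to-end convenience ----------------------------------------------


def phenotype_study(
    reads: pd.DataFrame,
    well_map: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    od_window: tuple[float, float] = OD_WINDOW,
    estimator: str = "endpoint",
) -> pd.DataFrame:
    """Raw reads → per-strain phenotype table.

    Subtracts background, computes a windowed rate per well, aggregates
    replicates per strain and attaches the five-criteria QC verdict
    (``metadata`` indexed by strain with columns ``sequencing_complete,
    assembly_exact, cured, single_genotype``). Returns a DataFrame with
    columns ``strain, rate_mean, sem, cv, n, qc_pass, qc_reasons``.
    """
    sub = subtract_background(reads, well_map)
    sub = sub.merge(well_map, on=["plate", "well"])
    meta_idx = metadata.set_index("strain") if metadata is not None and "strain" in metadata else metadata
    rows = []
    for strain, grp in sub[sub["strain"] != MEDIA].groupby("strain"):
        rates = []
        max_od = -np.inf
        for (_, well), wgrp in grp.groupby(["plate", "well"]):
            wgrp = wgrp.sort_values("time_h")
            res = gfp_synthesis_rate(
                wgrp["time_h"], wgrp["od600"], wgrp["gfp"], od_window, estimator
            )
            max_od = max(max_od, float(wgrp["od600"].max()))
            if res.rate is not None:
                rates.append(res.rate)
        meta_row: Mapping = {}
        if meta_idx is not None and strain in meta_idx.index:
            meta_row = meta_idx.loc[strain].to_dict()
        qc = apply_qc(strain, [max_od], meta_row, od_threshold=od_window[1])
        if rates:
            ph = aggregate_replicates(strain, rates)
            rows.append(
                (strain, ph.mean, ph.sem, ph.cv_pct, ph.n, qc.passed, ";".join(qc.reasons))
            )
        else:
            rows.append((strain, np.nan, np.nan, np.nan, 0, False, "no defined replicate rate"))
    return pd.DataFrame(
        rows, columns=["strain", "rate_mean", "sem", "cv", "n", "qc_pass", "qc_reasons"]
    )
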