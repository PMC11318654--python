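"""Quality scoring of variant predictions against sparse time-course data.

The per-point quality score is the natural log of a Gaussian probability
density evaluated at the distance between log-experimental and log-simulated
concentration: ``score = ln N(E; mean=S, sd=sigma)`` with ``E = ln(exp)`` and
``S = ln(sim)``.  The score is maximal (``-ln(sigma sqrt(2 pi))``) when the
prediction matches the measurement exactly and falls off quadratically in
log-fold error; scores closer to zero therefore indicate better variants.

Three ensemble-level Psi scores summarise how much of the ensemble lands
"relatively close" to the data: the percentage of variants with point score
> -10 (per metabolite and time point), with per-metabolite cumulative score
> -40, and with total cumulative score > -500.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import Trajectory

__all__ = [
    "DEFAULT_SIGMA",
    "DEFAULT_THRESHOLDS",
    "ExperimentalDataset",
    "ScoreTable",
    "PsiScores",
    "point_quality_score",
    "score_trajectories",
    "cumulative_scores",
    "psi_scores",
]

#: ln-space width of the scoring Gaussian
DEFAULT_SIGMA = 1.0
#: simulated concentrations are floored here (mM) before taking the log
SIM_FLOOR_MM = 1e-30
#: (point, metabolite-cumulative, total-cumulative) pass thresholds
DEFAULT_THRESHOLDS = (-10.0, -40.0, -500.0)


@dataclass
class ExperimentalDataset:
    """Sparse eicosanoid time-course measurements in model units (mM).

    ``data`` columns: metabolite, time_h, conc_mM, below_loq.  Below-LOQ rows
    are retained for bookkeeping but excluded from scoring.
    """

    data: pd.DataFrame
    label: str = ""

    REQUIRED = ("metabolite", "time_h", "conc_mM", "below_loq")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        bad = self.data[(~self.data["below_loq"]) & (self.data["conc_mM"] <= 0)]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"non-positive concentration for {row['metabolite']} at "
                f"{row['time_h']} h without a below-LOQ flag"
            )

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.data["metabolite"].unique())

    def scored_points(self) -> pd.DataFrame:
        return self.data[~self.data["below_loq"]].reset_index(drop=True)

    # -- CSV dialect: metabolite, time_h, conc, below_loq, unit,
    #    conversion_factor (multiplies conc into mM; required unless unit==mM)
    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "ExperimentalDataset":
        raw = pd.read_csv(path)
        if "conc_mM" not in raw.columns:
            if "unit" not in raw.columns or "conc" not in raw.columns:
                raise ValueError("dataset CSV needs conc_mM, or conc + unit columns")
            factors = []
            for _, row in raw.iterrows():
                if str(row["unit"]) == "mM":
                    factors.append(1.0)
                elif "conversion_factor" in raw.columns and not pd.isna(
                    row.get("conversion_factor")
                ):
                    factors.append(float(row["conversion_factor"]))
                else:
                    raise ValueError(
                        f"no conversion_factor for unit {row['unit']!r} "
                        f"({row['metabolite']}); refusing a silent default"
                    )
            raw = raw.assign(conc_mM=raw["conc"].astype(float) * np.array(factors))
        if "below_loq" not in raw.columns:
            raw = raw.assign(below_loq=False)
        raw["below_loq"] = raw["below_loq"].astype(bool)
        cols = ["metabolite", "time_h", "conc_mM", "below_loq"]
        return cls(raw[cols].copy(), label=label or Path(path).stem)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.data.copy()
        out["unit"] = "mM"
        out.to_csv(path, index=False)
        return path


def point_quality_score(
    experimental_mM: float,
    simulated_mM: float,
    sigma: float = DEFAULT_SIGMA,
    floor_mM: float = SIM_FLOOR_MM,
) -> float:
    """Gaussian log-density of the log-space prediction error.

    Maximal iff simulation equals experiment; symmetric and strictly
    decreasing in |ln(exp) - ln(sim)|.
    """
    if not experimental_mM > 0:
        raise ValueError("experimental concentration must be > 0 (or below-LOQ)")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    E = math.log(experimental_mM)
    S = math.log(max(simulated_mM, floor_mM))
    return -math.log(sigma * math.sqrt(2.0 * math.pi)) - (E - S) ** 2 / (2.0 * sigma**2)


@dataclass
class ScoreTable:
    """Point, per-metabolite and total cumulative scores per variant."""

    points: pd.DataFrame  # columns: variant, metabolite, time_h, score
    sigma: float = DEFAULT_SIGMA
    n_below_loq: int = 0

    def metabolite_totals(self) -> pd.DataFrame:
        return (
            self.points.groupby(["variant", "metabolite"], as_index=False)["score"]
            .sum()
            .rename(columns={"score": "cumulative"})
        )

    def variant_totals(self) -> pd.DataFrame:
        return (
            self.points.groupby("variant", as_index=False)["score"]
            .sum()
            .rename(columns={"score": "total"})
        )

    @property
    def variants(self) -> np.ndarray:
        return np.sort(self.points["variant"].unique())

    @property
    def score_max(self) -> float:
        return -math.log(self.sigma * math.sqrt(2.0 * math.pi))


def score_trajectories(
    trajs: Sequence[Trajectory],
    dataset: ExperimentalDataset,
    sigma: float = DEFAULT_SIGMA,
    compartment: str = "extracellular",
    species_map: Mapping[str, tuple[str, str]] | None = None,
) -> ScoreTable:
    """Score every successful trajectory against every quantified data point.

    Dataset metabolite ids map to extracellular model species of the same name
    unless ``species_map`` overrides them with (species id, compartment).
    """
    pts = dataset.scored_points()
    if species_map is None:
        species_map = {}
    for met in pts["metabolite"].unique():
        sid, comp = species_map.get(met, (met, compartment))
        probe = next((t for t in trajs if t.success), None)
        if probe is not None and f"{sid}@{comp}" not in probe.states:
            raise KeyError(f"dataset metabolite {met!r} has no model species {sid}@{comp}")

    rows = []
    for traj in trajs:
        if not traj.success:
            continue
        for _, rec in pts.iterrows():
            sid, comp = species_map.get(rec["metabolite"], (rec["metabolite"], compartment))
            sim = traj.value(sid, comp, float(rec["time_h"]))
            rows.append((
                traj.variant_index,
                rec["metabolite"],
                float(rec["time_h"]),
                point_quality_score(float(rec["conc_mM"]), sim, sigma=sigma),
            ))
    if not rows:
        raise ValueError("no successful trajectories to score")
    points = pd.DataFrame(rows, columns=["variant", "metabolite", "time_h", "score"])
    n_loq = int(dataset.data["below_loq"].sum())
    return ScoreTable(points=points, sigma=sigma, n_below_loq=n_loq)


def cumulative_scores(table: ScoreTable) -> pd.DataFrame:
    """Per-variant totals with per-metabolite cumulative columns alongside."""
    met = table.metabolite_totals().pivot(index="variant", columns="metabolite",
                                          values="cumulative")
    tot = table.variant_totals().set_index("variant")["total"]
    out = met.assign(total=tot).reset_index()
    out.columns.name = None
    return out


@dataclass
class PsiScores:
    """Ensemble closeness percentages at the three threshold levels."""

    psi_timepoint: pd.DataFrame  # metabolite, time_h, psi
    psi_metabolite: pd.DataFrame  # metabolite, psi
    psi_total: float
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    n_variants: int = 0


def psi_scores(
    table: ScoreTable,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> PsiScores:
    """Percentage of scored variants passing each closeness threshold."""
    if table.points.empty:
        raise ValueError("psi_scores: empty score table")
    t_point, t_met, t_total = thresholds
    n = len(table.variants)

    tp = (
        table.points.assign(ok=table.points["score"] > t_point)
        .groupby(["metabolite", "time_h"], as_index=False)["ok"]
        .mean()
    )
    tp["psi"] = 100.0 * tp.pop("ok")

    mt = table.metabolite_totals()
    mt = (
        mt.assign(ok=mt["cumulative"] > t_met)
        .groupby("metabolite", as_index=False)["ok"]
        .mean()
    )
    mt["psi"] = 100.0 * mt.pop("ok")

    vt = table.variant_totals()
    psi_total = 100.0 * float((vt["total"] > t_total).mean())
    return PsiScores(psi_timepoint=tp, psi_metabolite=mt, psi_total=psi_total,
                     thresholds=thresholds, n_variants=n)
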