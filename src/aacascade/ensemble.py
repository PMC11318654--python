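"""Run an ensemble of model variants and summarise prediction bands."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .network import Network
from .priors import Ensemble
from .simulate import SimulationProtocol, Trajectory, run_variant

__all__ = ["run_ensemble", "summarize_ensemble", "summary_table"]

log = logging.getLogger(__name__)


def run_ensemble(
    net: Network,
    ens: Ensemble,
    protocol: SimulationProtocol,
) -> list[Trajectory]:
    """One trajectory per variant, order-stable; failures flagged, not raised."""
    if ens.network_name != net.name:
        raise ValueError(
            f"ensemble was sampled for network {ens.network_name!r}, "
            f"not {net.name!r}"
        )
    trajs = [run_variant(net, v, protocol) for v in ens.variants]
    n_failed = sum(not t.success for t in trajs)
    if n_failed:
        log.warning("%d/%d variants failed integration", n_failed, len(trajs))
    else:
        log.info("all %d variants integrated", len(trajs))
    return trajs


def summarize_ensemble(
    trajs: Sequence[Trajectory],
    species_id: str,
    compartment: str = "extracellular",
    times_h: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Median and interquartile band over successful variants.

    Returns a frame with columns (time_h, median, q25, q75, n).
    """
    ok = [t for t in trajs if t.success]
    if not ok:
        raise ValueError("summarize_ensemble: no successful trajectories")
    if times_h is None:
        times_h = ok[0].times_h
    times_h = np.asarray(times_h, dtype=float)
    mat = np.vstack([t.series(species_id, compartment, times_h) for t in ok])
    q25, med, q75 = np.percentile(mat, [25, 50, 75], axis=0)
    return pd.DataFrame({
        "time_h": times_h, "median": med, "q25": q25, "q75": q75,
        "n": len(ok),
    })


def summary_table(
    trajs: Sequence[Trajectory],
    species: Sequence[tuple[str, str]],
    times_h: Sequence[float],
) -> pd.DataFrame:
    """Long-format band summary for several (species, compartment) pairs."""
    frames = []
    for sid, comp in species:
        df = summarize_ensemble(trajs, sid, comp, times_h)
        df.insert(0, "compartment", comp)
        df.insert(0, "species", sid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
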