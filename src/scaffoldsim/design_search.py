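"""Stochastic generate-and-test search over scaffold-unit designs.

Candidate units are drawn by sampling one displacement per fiber-pair face
(indicator points on the same face share a displacement) independently and
uniformly from the admissible range, each candidate is scored by its
simulated culture efficiency, and the ranked table identifies the improved
design.  The routine is deliberately blind — no gradients, no surrogate —
matching the screening strategy it implements; its value lies in coupling
the full coupled-physics evaluation to a reproducible sampling loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .culture import OperatingConditions, run_culture
from .geometry import UnitDesign, attachment_area, diameter_from_delta
from .kinetics import KineticParams

__all__ = ["DesignCampaign", "sample_candidates", "run_campaign",
           "ratio_report"]

log = logging.getLogger(__name__)

#: |delta_y / delta_z| band expected to contain the best designs.
FAVORABLE_RATIO_BAND = (0.0, 1.0)
#: |delta_y / delta_z| threshold beyond which efficiency degrades.
RISK_RATIO_THRESHOLD = 5.5


def sample_candidates(n: int, seed: int, range_um=(0.0, 100.0),
                      r: float = 100.0,
                      cultured_surfaces=("bottom",)) -> list[UnitDesign]:
    """Draw ``n`` unit designs with uniform displacements.

    One displacement is drawn for each face pair (delta_y for the primary
    top/bottom pair, delta_z for the secondary front/back pair) from
    ``range_um``; the draw is reproducible for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one candidate")
    lo, hi = range_um
    if not (0.0 <= lo < hi <= r):
        raise ValueError(f"displacement range {range_um} invalid for r={r}")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(lo, hi, size=(n, 2))
    return [UnitDesign(r=r, delta_y=float(dy), delta_z=float(dz),
                       cultured_surfaces=tuple(cultured_surfaces))
            for dy, dz in draws]


@dataclass
class DesignCampaign:
    """Completed generate-and-test campaign.

    ``results`` holds one entry per candidate: ``(design, ce, result)``
    with ``ce = nan`` and ``result = None`` for failed evaluations.
    ``best`` is the index of the highest finite CE; ties break toward the
    larger attachment area, then the lower candidate index.
    """

    n_candidates: int
    seed: int
    delta_range: tuple
    results: list = field(default_factory=list)

    @property
    def completed(self) -> list[int]:
        return [i for i, (_, ce, _) in enumerate(self.results)
                if np.isfinite(ce)]

    @property
    def best(self) -> int:
        done = self.completed
        if not done:
            raise RuntimeError("campaign has no completed candidates")

        def keyfun(i):
            design, ce, _ = self.results[i]
            area = attachment_area(
                design.d_primary, design.edge, design.edge)
            return (ce, area, -i)

        return max(done, key=keyfun)

    @property
    def best_design(self) -> UnitDesign:
        return self.results[self.best][0]

    def table(self) -> pd.DataFrame:
        """Ranked candidate table (best first, failures last)."""
        rows = []
        for i, (d, ce, res) in enumerate(self.results):
            ratio = np.inf if d.delta_z == 0 else \
                abs(d.delta_y) / abs(d.delta_z)
            rows.append({
                "candidate": i,
                "delta_y_um": d.delta_y,
                "delta_z_um": d.delta_z,
                "D1_um": d.d_primary,
                "D2_um": d.d_secondary,
                "ratio": ratio,
                "ce": ce,
                "attachment_area_m2": attachment_area(
                    d.d_primary, d.edge, d.edge),
                "tau_mean_Pa": res.tau_mean_Pa if res is not None
                else np.nan,
                "occluded": res.occluded if res is not None else True,
            })
        df = pd.DataFrame(rows)
        return df.sort_values("ce", ascending=False,
                              na_position="last").reset_index(drop=True)


def run_campaign(n: int, seed: int, oc: OperatingConditions | None = None,
                 p: KineticParams | None = None, range_um=(0.0, 100.0),
                 r: float = 100.0, cultured_surfaces=("bottom",),
                 resolution: int = 16, evaluator=None,
                 **run_kwargs) -> DesignCampaign:
    """Sample, evaluate and rank ``n`` candidate designs.

    ``evaluator`` may replace the physics run with any callable
    ``design -> ce`` (used for search-logic verification with known
    objective functions); by default each candidate runs
    :func:`scaffoldsim.culture.run_culture` at ``resolution``.  Failed
    candidates are logged and excluded from the ranking; the campaign
    errors only if every candidate fails.
    """
    oc = oc or OperatingConditions()
    designs = sample_candidates(n, seed, range_um, r, cultured_surfaces)
    campaign = DesignCampaign(n_candidates=n, seed=seed,
                              delta_range=tuple(range_um))
    for i, design in enumerate(designs):
        try:
            if evaluator is not None:
                ce = float(evaluator(design))
                res = None
            else:
                res = run_culture(design, oc, p, resolution=resolution,
                                  **run_kwargs)
                ce = res.ce
        except Exception as exc:  # noqa: BLE001 - candidate-level isolation
            log.warning("candidate %d (dy=%.1f, dz=%.1f) failed: %s",
                        i, design.delta_y, design.delta_z, exc)
            ce, res = np.nan, None
        campaign.results.append((design, ce, res))
    if not campaign.completed:
        raise RuntimeError("all campaign candidates failed")
    return campaign


def ratio_report(campaign: DesignCampaign, bins=None) -> pd.DataFrame:
    """Culture efficiency binned against the displacement ratio.

    The ratio |delta_y / delta_z| is the key shape descriptor: designs in
    the [0, 1] band couple a gently curved cultured fiber with a narrow
    flow cross-section and tend to score best, while ratios above 5.5 risk
    poor efficiency.  Candidates with delta_z = 0 (flat secondary walls)
    fall in a separate unbounded band.
    """
    df = campaign.table()
    finite = df[np.isfinite(df["ce"])]
    if bins is None:
        top = finite["ratio"].replace(np.inf, np.nan).max()
        top = 1.0 if not np.isfinite(top) else max(1.0, top)
        bins = np.unique(np.concatenate([
            np.linspace(0, 1, 5), np.linspace(1, RISK_RATIO_THRESHOLD, 4),
            [max(top, RISK_RATIO_THRESHOLD)]]))
    rows = []
    last_hi = bins[-1]
    for lo, hi in zip(bins[:-1], bins[1:]):
        upper = (finite["ratio"] <= hi) if hi == last_hi else \
            (finite["ratio"] < hi)
        sel = finite[(finite["ratio"] >= lo) & upper]
        if len(sel) == 0:
            continue
        rows.append({"ratio_lo": lo, "ratio_hi": hi, "n": len(sel),
                     "ce_mean": sel["ce"].mean(), "ce_max": sel["ce"].max(),
                     "favorable_band": hi <= FAVORABLE_RATIO_BAND[1],
                     "risk_band": lo >= RISK_RATIO_THRESHOLD})
    inf_sel = finite[np.isinf(finite["ratio"])]
    if len(inf_sel):
        rows.append({"ratio_lo": np.inf, "ratio_hi": np.inf,
                     "n": len(inf_sel), "ce_mean": inf_sel["ce"].mean(),
                     "ce_max": inf_sel["ce"].max(),
                     "favorable_band": False, "risk_band": True})
    return pd.DataFrame(rows)
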