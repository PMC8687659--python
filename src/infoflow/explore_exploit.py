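"""Exploration/exploitation labelling against baseline routes.

A flight sample is *exploiting* when it lies within 300 m of the bird's
(or pair's) baseline route — the trajectory of the previous release, or,
at a generation boundary, the last release of the previous generation —
and *exploring* when it lies farther away.  The 300 m threshold is the
point-to-point distance within which an established bird keeps to its
idiosyncratic route; samples exactly at the threshold count as
exploitation.  Distances are the exact minimum Euclidean distance from
the focal point to the closest baseline point (vertex-to-vertex; at 5 Hz
and ~20 m/s the ~4 m inter-point spacing is negligible against 300 m).

Within a pair, the bird at the front (sign of d_EN) at a given sample is
the momentary leader, which supports attributing phases and phase
transitions to one bird.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree

from .encoding import ProjectedDistanceSeries
from .errors import DataError
from .io import Trajectory

logger = logging.getLogger(__name__)

__all__ = ["SegmentLabelSeries", "distance_to_baseline", "select_baseline",
           "label_segments", "exploration_proportion",
           "phase_leadership_share", "transition_initiators"]

DEFAULT_THRESHOLD_M = 300.0


@dataclass
class SegmentLabelSeries:
    """Per-sample exploration(True)/exploitation(False) labels for one flight."""

    explore: np.ndarray          # bool per sample
    dist_to_baseline: np.ndarray  # metres per sample
    valid: np.ndarray
    threshold_m: float
    flight_key: tuple = ()
    baseline_ref: tuple = ()

    def __len__(self) -> int:
        return len(self.explore)

    def proportion_exploration(self) -> float:
        m = self.valid
        if not m.any():
            raise DataError("no valid samples to summarise")
        return float(self.explore[m].mean())

    def phases(self) -> list[tuple[bool, int, int]]:
        """Maximal runs of one label over valid samples: (label, start, stop)."""
        out = []
        lab = self.explore
        m = self.valid
        i = 0
        n = len(lab)
        while i < n:
            if not m[i]:
                i += 1
                continue
            j = i
            while j < n and m[j] and lab[j] == lab[i]:
                j += 1
            out.append((bool(lab[i]), i, j))
            i = j
        return out


def distance_to_baseline(focal: Trajectory, baseline: Trajectory) -> np.ndarray:
    """Minimum distance from each focal point to the closest baseline point."""
    base_xy = baseline.xy[baseline.valid]
    if len(base_xy) == 0:
        raise DataError("empty baseline trajectory")
    tree = cKDTree(base_xy)
    d, _ = tree.query(focal.xy)
    return np.asarray(d, dtype=float)


def select_baseline(flights, model: str = "previous_release") -> tuple[dict, dict]:
    """Map each focal flight to its baseline flight key.

    ``flights`` is an iterable of objects with chain/generation/release
    metadata (ChainFlight, PairFlight or Trajectory).  Under
    ``previous_release`` (model A), release r > 1 compares with release
    r−1 of the same unit and release 1 of generation g > 1 with the last
    release of generation g−1.  Under ``last_of_previous_generation``
    (model B), every release of generation g > 1 compares with the last
    release of generation g−1, generation 1 falling back to model A.
    Returns ``(mapping, excluded)`` keyed by (chain, generation, release);
    focal flights without an available baseline are excluded with a reason.
    """
    if model not in ("previous_release", "last_of_previous_generation"):
        raise ValueError(f"unknown baseline model: {model!r}")
    keys = {}
    for fl in flights:
        chain = getattr(fl, "chain_id")
        keys[(chain, fl.generation, fl.release)] = fl
    last_release = {}
    for chain, g, r in keys:
        last_release[(chain, g)] = max(last_release.get((chain, g), 0), r)

    mapping, excluded = {}, {}
    for (chain, g, r) in sorted(keys):
        if model == "last_of_previous_generation" and g > 1:
            base = (chain, g - 1, last_release.get((chain, g - 1), 0))
        elif r > 1:
            base = (chain, g, r - 1)
        elif g > 1:
            base = (chain, g - 1, last_release.get((chain, g - 1), 0))
        else:
            excluded[(chain, g, r)] = "first release of generation 1 has no baseline"
            continue
        if base not in keys:
            excluded[(chain, g, r)] = f"baseline flight {base} missing"
            logger.info("focal %s excluded: %s", (chain, g, r), excluded[(chain, g, r)])
            continue
        mapping[(chain, g, r)] = base
    return mapping, excluded


def label_segments(dist: np.ndarray, threshold: float = DEFAULT_THRESHOLD_M,
                   valid=None, flight_key=(), baseline_ref=()) -> SegmentLabelSeries:
    """Label samples: exploration strictly beyond ``threshold`` metres."""
    dist = np.asarray(dist, dtype=float)
    if valid is None:
        valid = np.ones(len(dist), dtype=bool)
    return SegmentLabelSeries(explore=dist > threshold, dist_to_baseline=dist,
                              valid=np.asarray(valid, dtype=bool),
                              threshold_m=threshold, flight_key=flight_key,
                              baseline_ref=baseline_ref)


def exploration_proportion(labels_per_flight: dict,
                           by: str = "release") -> pd.DataFrame:
    """Per-flight exploration fraction plus group means.

    ``labels_per_flight`` maps (chain, generation, release) →
    :class:`SegmentLabelSeries`; ``by`` chooses the grouping column of the
    summary attached in ``.attrs['group_means']``.
    """
    rows = []
    for (chain, g, r), lab in labels_per_flight.items():
        rows.append({"chain": chain, "generation": g, "release": r,
                     "proportion_exploration": lab.proportion_exploration()})
    table = pd.DataFrame.from_records(rows)
    if not table.empty and by in table.columns:
        table.attrs["group_means"] = (
            table.groupby(by)["proportion_exploration"].mean().reset_index())
    return table


def _front_role(d: ProjectedDistanceSeries, i: int) -> str | None:
    """Front bird at sample i; falls back to the nearest preceding valid,
    nonzero sample when i is masked or abreast."""
    j = i
    while j >= 0:
        if d.valid[j] and d.d_en[j] != 0.0:
            return "E" if d.d_en[j] > 0 else "N"
        j -= 1
    return None


def phase_leadership_share(labels: SegmentLabelSeries,
                           d: ProjectedDistanceSeries) -> dict:
    """Fraction of each phase type led by each bird, for one flight.

    Within samples of one phase type, the share of the experienced bird is
    the fraction of valid, non-abreast samples with d_EN > 0.  A phase
    type absent from the flight is reported as missing (None), not zero.
    """
    if len(labels) != len(d):
        raise DataError("labels and d_EN series are on different grids")
    out = {}
    for phase, name in ((False, "exploitation"), (True, "exploration")):
        m = labels.valid & d.valid & (labels.explore == phase) & (d.d_en != 0.0)
        n = int(m.sum())
        if n == 0:
            out[name] = {"share_E": None, "share_N": None, "n_samples": 0}
            continue
        e = float((d.d_en[m] > 0).mean())
        out[name] = {"share_E": e, "share_N": 1.0 - e, "n_samples": n}
    return out


def phase_share_table(flights: dict, d_series: dict) -> pd.DataFrame:
    """Long-format per-flight phase shares for a labelled collection."""
    rows = []
    for key, lab in flights.items():
        if key not in d_series:
            continue
        shares = phase_leadership_share(lab, d_series[key])
        for phase, rec in shares.items():
            if rec["share_E"] is None:
                continue
            chain, g, r = key
            rows.append({"chain": chain, "generation": g, "release": r,
                         "phase": phase, **rec})
    return pd.DataFrame.from_records(rows)


def transition_initiators(labels: SegmentLabelSeries,
                          d: ProjectedDistanceSeries,
                          direction: str = "exploit_to_explore") -> list[str]:
    """Initiating bird of each phase transition in one flight.

    The initiator is the bird at the front at the first sample of the new
    phase (front bird causally drives the pair); masked or abreast samples
    fall back to the nearest preceding valid sample.  ``direction`` is
    'exploit_to_explore' or 'explore_to_exploit'.
    """
    if direction not in ("exploit_to_explore", "explore_to_exploit"):
        raise ValueError(f"unknown transition direction: {direction!r}")
    new_phase = direction == "exploit_to_explore"
    phases = labels.phases()
    initiators = []
    for idx in range(1, len(phases)):
        prev_label, _, _ = phases[idx - 1]
        label, start, _ = phases[idx]
        if label == new_phase and prev_label == (not new_phase):
            role = _front_role(d, start)
            if role is not None:
                initiators.append(role)
    return initiators


def initiation_test(initiators, role: str = "N") -> dict:
    """Exact two-sided binomial test of initiation counts against 0.5."""
    initiators = list(initiators)
    n = len(initiators)
    k = sum(1 for x in initiators if x == role)
    if n == 0:
        return {"n": 0, "k": 0, "p": None, "proportion": None}
    res = sps.binomtest(k, n, 0.5, alternative="two-sided")
    return {"n": n, "k": k, "p": float(res.pvalue), "proportion": k / n}
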