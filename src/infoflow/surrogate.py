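"""Surrogate-pairing null model for information transfer.

The significance reference for pairwise TE is a surrogate dataset built by
pairing trajectories of birds that never flew together: the
experienced-role track of each real pair is combined with the naive-role
track of every other real pair (and vice versa), excluding combinations
whose source pairs share a subject.  Surrogate tracks are aligned on their
own elapsed time from release (both birds started at the same site), so
any residual "transfer" reflects shared release-site geometry, not
interaction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import PairFlight, Trajectory

logger = logging.getLogger(__name__)

__all__ = ["build_surrogate_pairs", "compare_real_vs_surrogate"]


def _rebase(tr: Trajectory, n: int) -> Trajectory:
    """Clock the track from its first sample and truncate to n samples."""
    return replace(tr, t=(tr.t - tr.t[0])[:n], xy=tr.xy[:n].copy(),
                   valid=tr.valid[:n].copy())


def build_surrogate_pairs(pairs, within_release: bool = True) -> list[PairFlight]:
    """Cross-pair every experienced track with every foreign naive track.

    For ordered real pairs (P, Q), P ≠ Q, sharing no bird, emit the
    surrogate (experienced of P, naive of Q); iterating ordered pairs
    produces both role-orderings.  ``within_release`` restricts partners to
    the same release index (the default correspondence), else all-vs-all.
    Output may be empty when every combination shares a subject.
    """
    pairs = list(pairs)
    out: list[PairFlight] = []
    for p in pairs:
        for q in pairs:
            if p is q:
                continue
            birds_p = {p.experienced.bird_id, p.naive.bird_id}
            birds_q = {q.experienced.bird_id, q.naive.bird_id}
            if birds_p & birds_q:
                continue
            if within_release and p.release != q.release:
                continue
            n = min(len(p), len(q))
            surr = PairFlight(
                experienced=_rebase(p.experienced, n),
                naive=_rebase(q.naive, n),
                chain_id=f"{p.chain_id}|{q.chain_id}",
                generation=p.generation, release=p.release,
                is_surrogate=True,
                provenance={"experienced_from": p.flight_key,
                            "naive_from": q.flight_key})
            out.append(surr)
    return out


def total_te_per_flight(pairs, k: int = 10, period: float = 0.2) -> pd.DataFrame:
    """Per-flight total transfer of information TE(E→N) + TE(N→E)."""
    from .infotheory import pair_te

    rows = []
    for pf in pairs:
        res_en, res_ne = pair_te(pf, k=k, period=period)
        rows.append({"chain": pf.chain_id, "generation": pf.generation,
                     "release": pf.release,
                     "is_surrogate": pf.is_surrogate,
                     "te_en_bits": res_en.te_bits, "te_ne_bits": res_ne.te_bits,
                     "total_te_bits": res_en.te_bits + res_ne.te_bits})
    return pd.DataFrame.from_records(rows)


def compare_real_vs_surrogate(real: pd.DataFrame, surr: pd.DataFrame,
                              by: str = "overall") -> pd.DataFrame:
    """Mann–Whitney–Wilcoxon of real vs surrogate total TE, per group.

    ``real`` and ``surr`` are tables from :func:`total_te_per_flight`;
    ``by`` is 'overall' or 'generation'.  Groups with fewer than 3 flights
    in either arm are skipped with a warning.
    """
    if real.empty or surr.empty:
        raise ValueError("both real and surrogate collections must be non-empty")
    if by == "overall":
        groups = [("overall", real, surr)]
    elif by == "generation":
        gens = sorted(set(real["generation"]) | set(surr["generation"]))
        groups = [(g, real[real["generation"] == g],
                   surr[surr["generation"] == g]) for g in gens]
    else:
        raise ValueError("by must be 'overall' or 'generation'")

    rows = []
    for name, r, s in groups:
        if len(r) < 3 or len(s) < 3:
            warnings.warn(f"group {name!r}: fewer than 3 flights per arm; skipped")
            continue
        a = r["total_te_bits"].to_numpy()
        b = s["total_te_bits"].to_numpy()
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"group": name, "U": float(res.statistic),
                     "p": float(res.pvalue),
                     "median_real_bits": float(np.median(a)),
                     "median_surrogate_bits": float(np.median(b)),
                     "n_real": len(a), "n_surrogate": len(b)})
    return pd.DataFrame.from_records(rows)
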