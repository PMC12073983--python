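"""HFO-area definition: per-epoch 95th-percentile candidates, then the
>=50% temporal-consistency rule, or an inconclusive verdict.

Per epoch, channels whose HFO rate lies strictly above the 95th percentile of
that epoch's cross-channel rate distribution are candidates. A channel's
temporal consistency is the percentage of its analysable epochs in which it
was a candidate; channels at >=50% form the final HFO area. If no channel
reaches 50%, the measure is inconclusive and no outcome prediction is made.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .containers import HfoArea, RateMatrix

logger = logging.getLogger(__name__)


def candidate_set(
    rates_one_epoch: Mapping[str, float] | pd.Series,
    quantile: float = 0.95,
    method: str = "linear",
) -> tuple[set[str], float]:
    """Channels whose rate strictly exceeds the epoch's rate-quantile
    threshold. Returns (candidates, threshold). All-equal rates give an empty
    set: nothing exceeds the threshold."""
    s = pd.Series(rates_one_epoch, dtype=float).dropna()
    if len(s) < 2:
        raise ValueError(f"need >= 2 channels with defined rates, got {len(s)}")
    threshold = float(np.quantile(s.to_numpy(), quantile, method=method))
    return set(s.index[s > threshold]), threshold


def temporal_consistency(
    candidate_sets: Sequence[set[str]],
    channel_presence: Sequence[set[str]],
) -> dict[str, float]:
    """consistency(c) = 100 * #epochs with c candidate / #epochs c analysable.

    ``channel_presence[e]`` is the set of channels analysable in epoch e.
    Channels never analysable are excluded (logged).
    """
    if len(candidate_sets) != len(channel_presence):
        raise ValueError("candidate_sets and channel_presence must have equal length")
    if not candidate_sets:
        raise ValueError("need >= 1 epoch")
    all_channels = set().union(*channel_presence) | set().union(*candidate_sets)
    out: dict[str, float] = {}
    for ch in sorted(all_channels):
        n_avail = sum(ch in pres for pres in channel_presence)
        if n_avail == 0:
            logger.info("channel %s never analysable; excluded from consistency", ch)
            continue
        n_in = sum(
            ch in cand and ch in pres
            for cand, pres in zip(candidate_sets, channel_presence)
        )
        out[ch] = 100.0 * n_in / n_avail
    return out


def finalize_area(
    consistency: Mapping[str, float],
    n_epochs: int,
    rate_thresholds: Sequence[float] = (),
    threshold_pct: float = 50.0,
) -> HfoArea:
    """Apply the consistency cut (boundary included: >= threshold) and set the
    conclusiveness flag."""
    if not consistency:
        raise ValueError("consistency mapping is empty")
    members = frozenset(ch for ch, pct in consistency.items() if pct >= threshold_pct)
    return HfoArea(
        channels=members,
        consistency=dict(consistency),
        conclusive=bool(members),
        n_epochs=n_epochs,
        rate_thresholds=list(rate_thresholds),
    )


def compute_hfo_area(rate_matrix: RateMatrix, config: AnalysisConfig | None = None) -> HfoArea:
    """Full area computation from a channels x epochs rate matrix."""
    config = config or AnalysisConfig()
    rates = rate_matrix.rates
    candidates: list[set[str]] = []
    presence: list[set[str]] = []
    thresholds: list[float] = []
    for col in rates.columns:
        col_rates = rates[col].dropna()
        presence.append(set(col_rates.index))
        if len(col_rates) < 2:
            candidates.append(set())
            thresholds.append(float("nan"))
            continue
        cand, thr = candidate_set(col_rates, config.rate_quantile, config.quantile_method)
        candidates.append(cand)
        thresholds.append(thr)
    consistency = temporal_consistency(candidates, presence)
    return finalize_area(
        consistency,
        n_epochs=len(rates.columns),
        rate_thresholds=thresholds,
        threshold_pct=config.consistency_threshold_pct,
    )
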