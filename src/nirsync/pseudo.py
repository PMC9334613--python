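"""Pseudo-dyad (random-pair) permutation null for inter-brain coherence.

Each dyad's Subject 1 is re-paired with randomly drawn Subject 2 partners
from *other* dyads (sampling with replacement — the original design draws
1000 partners from ~30 candidates).  Coherence is recomputed for the
pseudo-pairs on the common condition clock and averaged per Subject 1,
channel and condition, giving the random-pair comparison values.

Since the coherence of a pseudo-pair depends only on which partner was
drawn, the average over permutation draws is computed as a multiplicity-
weighted average over the (at most n_dyads - 1) unique partners — an exact
identity that avoids recomputing coherence per draw.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coherence import DEFAULT_BAND_HZ, PIPELINE_PARAMS, SegmentCwtCache, WtcParams
from .preprocess import HbSeries
from .schedule import SessionSchedule


class PairingError(ValueError):
    pass


@dataclass
class PairingPlan:
    """Random partner draws: for each dyad's Subject 1, partner dyad ids."""

    dyad_ids: list[str]
    n_permutations: int
    seed: int
    partners: dict[str, list[str]] = field(default_factory=dict)

    def partner_counts(self, dyad_id: str) -> dict[str, int]:
        return dict(Counter(self.partners[dyad_id]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "dyad_ids": self.dyad_ids,
                    "n_permutations": self.n_permutations,
                    "seed": self.seed,
                    "partners": self.partners,
                },
                fh,
                indent=1,
            )


def make_pairing_plan(
    dyad_ids: list[str], n_permutations: int = 1000, seed: int = 0
) -> PairingPlan:
    """Draw ``n_permutations`` partner dyads per Subject 1, never its own."""
    dyad_ids = list(dyad_ids)
    if len(dyad_ids) < 2:
        raise PairingError("pseudo-dyad permutation requires at least 2 dyads")
    if n_permutations < 1:
        raise PairingError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    partners: dict[str, list[str]] = {}
    for d in dyad_ids:
        others = [o for o in dyad_ids if o != d]
        draws = rng.integers(0, len(others), size=n_permutations)
        partners[d] = [others[i] for i in draws]
    return PairingPlan(dyad_ids, n_permutations, seed, partners)


def null_coherence(
    hb_by_dyad: dict[str, tuple[HbSeries, HbSeries]],
    plan: PairingPlan,
    schedule: SessionSchedule,
    chromophore: str = "HbR",
    *,
    params: WtcParams = PIPELINE_PARAMS,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    exclude_coi: bool = True,
    min_part_s: float = 120.0,
) -> pd.DataFrame:
    """Original and permutation-averaged random-pair coherence tables.

    ``hb_by_dyad`` maps dyad id -> (Subject 1 HbSeries, Subject 2 HbSeries);
    all subjects must share an aligned ``schedule`` (pseudo-pairs are aligned
    by the condition clock).  Returns the combined table with a ``pairing``
    column in {original, random}; random rows are the per-Subject-1 mean over
    permutation draws for each channel and condition.
    """
    missing = [d for d in plan.dyad_ids if d not in hb_by_dyad]
    if missing:
        raise PairingError(f"plan references dyads without recordings: {missing}")

    from .coherence import channel_condition_values, validate_parts

    validate_parts(schedule, min_part_s)
    cache1 = {
        d: SegmentCwtCache(hb_by_dyad[d][0], schedule, chromophore, params)
        for d in plan.dyad_ids
    }
    cache2 = {
        d: SegmentCwtCache(hb_by_dyad[d][1], schedule, chromophore, params)
        for d in plan.dyad_ids
    }

    montage = next(iter(hb_by_dyad.values()))[0].montage
    rows = []
    # channel-major so each channel's transforms can be freed before the next
    for ch in montage.channels:
        for d in plan.dyad_ids:
            for cond, v, k in channel_condition_values(
                cache1[d], cache2[d], ch.index, band_hz, exclude_coi
            ):
                rows.append((d, "original", cond, ch.index, ch.roi, chromophore, v, k))
            counts = plan.partner_counts(d)
            total = sum(counts.values())
            acc: dict[str, float] = {}
            ns: dict[str, int] = {}
            for partner, c in counts.items():
                for cond, v, k in channel_condition_values(
                    cache1[d], cache2[partner], ch.index, band_hz, exclude_coi
                ):
                    acc[cond] = acc.get(cond, 0.0) + v * (c / total)
                    ns[cond] = ns.get(cond, 0) + k * c
            for cond, v in acc.items():
                rows.append(
                    (d, "random", cond, ch.index, ch.roi, chromophore, v,
                     ns[cond] // total)
                )
        for c in list(cache1.values()) + list(cache2.values()):
            c.drop_channel(ch.index)

    out = pd.DataFrame(
        rows,
        columns=["dyad", "pairing", "condition", "channel", "roi", "chromophore",
                 "wtc_value", "n_points"],
    )
    return out
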