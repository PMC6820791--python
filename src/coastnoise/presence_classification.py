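"""Per-second vessel-presence categories and the closest-vessel logic.

Every second of the observation period falls in exactly one of five
categories:

1. only AIS vessels present
2. AIS vessels together with at least one non-AIS vessel
3. at least one motorised non-AIS vessel, no AIS (sail-rigged boats that
   might be motoring do not count as motorised here)
4. only sail-rigged non-AIS sailboats
5. no vessels within the acceptance region

For categories 1–3 the closest *motorised* vessel supplies the range and
speed covariates. Epochs where a second motorised vessel sits within 200 m
of the closest one are flagged for exclusion, so single-source noise–range
statistics are not contaminated; sail-rigged sailboats are exempt from
that rule because of their low speeds under motor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tracking import (
    GROUP_AIS,
    GROUP_SAIL_RIGGED,
    MOTORISED_GROUPS,
    InterpolatedTrack,
)

CATEGORY_LABELS = {
    1: "only_AIS",
    2: "AIS_and_nonAIS",
    3: "nonAIS_motor_only",
    4: "nonAIS_sail_only",
    5: "no_vessels",
}


def category_from_groups(groups: set[str]) -> int:
    """Map the set of vessel groups present in an epoch to a category."""
    if not groups:
        return 5
    has_ais = GROUP_AIS in groups
    non_ais = groups - {GROUP_AIS}
    if has_ais:
        return 2 if non_ais else 1
    motorised_nonais = non_ais & MOTORISED_GROUPS
    return 3 if motorised_nonais else 4


def classify_epochs(
    tracks: list[InterpolatedTrack], epochs: pd.DatetimeIndex
) -> pd.DataFrame:
    """Classify each epoch and resolve the closest motorised vessel.

    ``tracks`` must already carry their spatial acceptance mask (see
    :func:`coastnoise.tracking.apply_spatial_criteria`). Returns a frame
    indexed by epoch with columns category, closest_id, closest_range_m,
    closest_speed_kn, closest_group, excluded (the 200-m flag starts
    False; see :func:`apply_proximity_exclusion`).
    """
    n = len(epochs)
    present = np.zeros((len(tracks), n), dtype=bool)
    rng = np.full((len(tracks), n), np.inf)
    spd = np.zeros((len(tracks), n))
    for k, tr in enumerate(tracks):
        idx = epochs.get_indexer(tr.epoch_times)
        ok = idx >= 0
        cols = idx[ok]
        present[k, cols] = tr.valid[ok]
        rng[k, cols] = np.where(tr.valid[ok], tr.range_m[ok], np.inf)
        spd[k, cols] = tr.speed_kn[ok]

    categories = np.empty(n, dtype=int)
    closest_id = np.full(n, None, dtype=object)
    closest_range = np.full(n, np.nan)
    closest_speed = np.full(n, np.nan)
    closest_group = np.full(n, None, dtype=object)

    motorised = np.array([tr.vessel_group in MOTORISED_GROUPS for tr in tracks])
    ids = [tr.vessel_id for tr in tracks]
    groups = [tr.vessel_group for tr in tracks]
    # deterministic tie-break: scan motorised tracks in id order
    order = sorted((i for i in range(len(tracks)) if motorised[i]), key=lambda i: ids[i])

    for j in range(n):
        gset = {groups[k] for k in range(len(tracks)) if present[k, j]}
        categories[j] = category_from_groups(gset)
        if categories[j] in (1, 2, 3):
            best = None
            for k in order:
                if present[k, j] and (best is None or rng[k, j] < rng[best, j]):
                    best = k
            if best is not None:
                closest_id[j] = ids[best]
                closest_range[j] = rng[best, j]
                closest_speed[j] = spd[best, j]
                closest_group[j] = groups[best]

    return pd.DataFrame(
        {
            "category": categories,
            "closest_id": closest_id,
            "closest_range_m": closest_range,
            "closest_speed_kn": closest_speed,
            "closest_group": closest_group,
            "excluded": np.zeros(n, dtype=bool),
        },
        index=epochs,
    )


def closest_vessel(
    epoch: pd.Timestamp, tracks: list[InterpolatedTrack]
) -> tuple[str, float, float, str] | None:
    """Closest motorised vessel at one epoch: (id, range_m, speed_kn, group).

    Ties in range break to the lexicographically smaller vessel id.
    Returns None when no motorised vessel is present.
    """
    best = None
    for tr in sorted(tracks, key=lambda t: t.vessel_id):
        if tr.vessel_group not in MOTORISED_GROUPS:
            continue
        pos = tr.epoch_times.get_indexer([epoch])[0]
        if pos < 0 or not tr.valid[pos]:
            continue
        r = float(tr.range_m[pos])
        if best is None or r < best[1]:
            best = (tr.vessel_id, r, float(tr.speed_kn[pos]), tr.vessel_group)
    return best


def apply_proximity_exclusion(
    classified: pd.DataFrame,
    tracks: list[InterpolatedTrack],
    radius_m: float = 200.0,
) -> pd.DataFrame:
    """Flag epochs where another motorised vessel crowds the closest one.

    An epoch is excluded when any *other* motorised vessel (sail-rigged
    sailboats exempt) is within ``radius_m`` of the closest vessel's
    position, because the closest vessel can then no longer be assumed to
    dominate the received level. Idempotent.
    """
    out = classified.copy()
    epochs = classified.index
    track_by_id = {tr.vessel_id: tr for tr in tracks}
    pos_cache = {
        tr.vessel_id: (tr, epochs.get_indexer(tr.epoch_times)) for tr in tracks
    }

    excluded = np.zeros(len(epochs), dtype=bool)
    # per-track column index into the epoch grid
    xs = {vid: np.full(len(epochs), np.nan) for vid in track_by_id}
    ys = {vid: np.full(len(epochs), np.nan) for vid in track_by_id}
    pres = {vid: np.zeros(len(epochs), dtype=bool) for vid in track_by_id}
    for vid, (tr, idx) in pos_cache.items():
        ok = idx >= 0
        xs[vid][idx[ok]] = tr.x[ok]
        ys[vid][idx[ok]] = tr.y[ok]
        pres[vid][idx[ok]] = tr.valid[ok]

    closest_ids = classified["closest_id"].to_numpy()
    for j in range(len(epochs)):
        cid = closest_ids[j]
        if cid is None or cid not in track_by_id:
            continue
        cx, cy = xs[cid][j], ys[cid][j]
        for vid, tr in track_by_id.items():
            if vid == cid or tr.vessel_group == GROUP_SAIL_RIGGED:
                continue
            if tr.vessel_group not in MOTORISED_GROUPS:
                continue
            if not pres[vid][j]:
                continue
            if np.hypot(xs[vid][j] - cx, ys[vid][j] - cy) <= radius_m:
                excluded[j] = True
                break
    out["excluded"] = excluded
    return out


def presence_time_fractions(classified: pd.DataFrame) -> dict[int, float]:
    """Fraction of epochs in each category; fractions sum to 1."""
    if len(classified) == 0:
        raise ValueError("empty classification")
    counts = classified["category"].value_counts()
    return {c: float(counts.get(c, 0)) / len(classified) for c in range(1, 6)}


def vessel_census(n_by_group: dict[str, int]) -> dict[str, float]:
    """Percentages of tracked vessels with and without AIS.

    Input maps vessel group (or simply ``"ais"``/``"non_ais"``) to counts;
    returns percentages rounded to whole percent, keyed ``ais_pct`` /
    ``non_ais_pct``.
    """
    ais = sum(v for k, v in n_by_group.items() if k in (GROUP_AIS, "ais"))
    total = sum(n_by_group.values())
    if total == 0:
        raise ValueError("no vessels in census")
    ais_pct = 100.0 * ais / total
    return {
        "ais_pct": float(np.floor(ais_pct + 0.5)),
        "non_ais_pct": float(np.floor((100.0 - ais_pct) + 0.5)),
        "n_total": total,
    }
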