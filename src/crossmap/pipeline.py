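"""Session-level glue: load a session file and run the per-cell analyses.

These functions back the ``crossmap tune / patches / svd / decode`` commands:
they wire the module-level operations together for one recorded bat and one
flight direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import (
    extract_flights,
    preprocess_trajectory,
    segment_modes,
    solo_flight_records,
)
from .io import read_session
from .maps2d import crossover_map, map_edges, patch_analysis, shuffle_map_stack
from .shuffles import classify_distance_cell, solo_projection_shuffle
from .svd import (
    AdmissibilityError,
    cv_dimensionality,
    prepare_matrix,
    separability_significance,
)
from .utils import as_rng, digitize_clipped


def load_segmented_session(path: str, direction: int = 1) -> dict:
    """Read, preprocess and segment a session HDF5 file for one direction."""
    data = read_session(path)
    trajs = [preprocess_trajectory(df.t.to_numpy(), df.x.to_numpy(),
                                   df.y.to_numpy()) for df in data["raw"]]
    flights = [extract_flights(t) for t in trajs]
    table = segment_modes(trajs[0], trajs[1], flights[0], flights[1])
    cross = [c for c in table.valid_crossovers() if c.direction == direction]
    solo = [r for r in solo_flight_records(trajs[0], table)
            if r["direction"] == direction]
    return {"cells": data["cells"], "clicks": data.get("clicks", {}),
            "trajs": trajs, "table": table, "cross": cross, "solo": solo}


def tune_session(path: str, direction: int = 1, n_shuffle: int = 1000,
                 seed: int = 0) -> pd.DataFrame:
    """Per-cell 1D distance-cell classification table."""
    S = load_segmented_session(path, direction)
    rng = as_rng(seed)
    rows = []
    for cid, spikes in sorted(S["cells"].items()):
        res = classify_distance_cell(np.asarray(spikes), S["cross"], S["solo"],
                                     n_shuffle=n_shuffle, rng=rng,
                                     min_ensemble=min(100, n_shuffle))
        rows.append({
            "cell": cid,
            "is_distance_cell": res.is_distance_cell,
            "n_cross_spikes": res.n_cross_spikes,
            "stability_r": res.stability_r,
            "onset_m": (res.significance.onset
                        if res.significance is not None else np.nan),
            "reason": res.reason,
        })
    return pd.DataFrame(rows)


def _spike_flight_bins(spikes, crossovers, pos_edges, dist_edges):
    out = []
    for c in crossovers:
        sel = (spikes >= c.t[0]) & (spikes <= c.t[-1])
        x = np.interp(spikes[sel], c.t, c.x)
        d = np.interp(spikes[sel], c.t, c.d)
        rows = digitize_clipped(x, pos_edges)
        cols = digitize_clipped(d, dist_edges)
        ok = (rows >= 0) & (cols >= 0)
        out.append(np.column_stack([rows[ok], cols[ok]]))
    return out


def patches_session(path: str, direction: int = 1, n_shuffle: int = 1000,
                    seed: int = 0) -> pd.DataFrame:
    """Per-cell 2D patch table from solo-projection shuffle maps."""
    S = load_segmented_session(path, direction)
    rng = as_rng(seed)
    pos_edges, dist_edges = map_edges()
    behav_x = np.concatenate([c.x for c in S["cross"]])
    behav_d = np.concatenate([c.d for c in S["cross"]])
    rows = []
    for cid, spikes in sorted(S["cells"].items()):
        spikes = np.asarray(spikes)
        data_map = crossover_map(spikes, S["cross"], pos_edges, dist_edges)
        ens = solo_projection_shuffle(spikes, S["cross"], S["solo"],
                                      n_shuffle, rng)
        stack = shuffle_map_stack(list(zip(ens.spike_x, ens.spike_d)),
                                  behav_x, behav_d, pos_edges, dist_edges)
        patches = patch_analysis(data_map, stack,
                                 spike_flight_bins=_spike_flight_bins(
                                     spikes, S["cross"], pos_edges, dist_edges),
                                 min_shuffles=min(1000, n_shuffle))
        for p in patches:
            rows.append({"cell": cid, "polarity": p.polarity,
                         "score": p.score, "n_bins": p.n_bins,
                         "percentile": p.percentile})
        if not patches:
            rows.append({"cell": cid, "polarity": "none", "score": 0.0,
                         "n_bins": 0, "percentile": np.nan})
    return pd.DataFrame(rows)


def svd_session(path: str, direction: int = 1, n_shuffle: int = 300,
                n_cv_iter: int = 100, seed: int = 0) -> pd.DataFrame:
    """Per-cell separability indices and significance flags."""
    from .shuffles import spikes_to_distance
    from .tuning import distance_tuning

    S = load_segmented_session(path, direction)
    rng = as_rng(seed)
    pos_edges, dist_edges = map_edges()
    rows = []
    for cid, spikes in sorted(S["cells"].items()):
        spikes = np.asarray(spikes)
        data_map = crossover_map(spikes, S["cross"], pos_edges, dist_edges)
        xs = np.array([c.x_cross for c in S["cross"]])
        try:
            data = prepare_matrix(data_map, crossover_positions=xs)
        except AdmissibilityError as exc:
            rows.append({"cell": cid, "lam": np.nan, "alpha": np.nan,
                         "meaningful_dim": np.nan, "projection_dim": np.nan,
                         "non_separable": False, "excluded": str(exc)})
            continue
        ens = solo_projection_shuffle(spikes, S["cross"], S["solo"],
                                      n_shuffle, rng)
        behav_x = np.concatenate([c.x for c in S["cross"]])
        behav_d = np.concatenate([c.d for c in S["cross"]])
        stack = shuffle_map_stack(list(zip(ens.spike_x, ens.spike_d)),
                                  behav_x, behav_d, pos_edges, dist_edges)
        # crop shuffle maps to the data's rows and fill NaNs with local means
        lo = np.searchsorted(pos_edges, data.row_edges[0])
        hi = lo + data.M.shape[0]
        nulls = []
        for sm in stack:
            sub = sm[lo:hi]
            if np.isnan(sub).any():
                fill = np.nanmean(sub) if np.isfinite(sub).any() else 0.0
                sub = np.where(np.isnan(sub), fill, sub)
            nulls.append(sub)
        solo_median = np.median(np.stack(nulls), axis=0)
        cv = cv_dimensionality(data, solo_median, n_iter=n_cv_iter, rng=rng,
                               max_dim=min(8, min(data.M.shape)))
        d_spk, _ = spikes_to_distance(spikes, S["cross"])
        behav = np.concatenate([c.d for c in S["cross"]])
        tuning = distance_tuning(d_spk, behav)
        flags = separability_significance(
            data, nulls, tuning.rate, tuning.centers,
            projection_dimension=cv.projection_dimension,
            min_null=min(100, n_shuffle))
        rows.append({"cell": cid, "lam": flags.lam, "alpha": flags.alpha,
                     "meaningful_dim": cv.meaningful_dimension,
                     "projection_dim": cv.projection_dimension,
                     "non_separable": flags.non_separable, "excluded": ""})
    return pd.DataFrame(rows)


def decode_session(path: str, direction: int = 1, seed: int = 0) -> pd.DataFrame:
    """Session decode summary (one row)."""
    from .decoding import ml_decode_session, summarize_decoding

    S = load_segmented_session(path, direction)
    spikes = [np.asarray(s) for _, s in sorted(S["cells"].items())]
    res = ml_decode_session(spikes, S["cross"])
    summ = summarize_decoding(res, rng=as_rng(seed))
    return pd.DataFrame([{
        "n_cells": len(spikes),
        "n_windows": len(res.windows),
        "median_err_d": res.median_distance_error,
        "median_err_x": res.median_position_error,
        "chance_err_d": summ.chance_error_d,
        "chance_err_x": summ.chance_error_x,
    }])
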