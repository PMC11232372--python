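"""Colocalization of PI+ and GCaMP-filled detections by centroid proximity.

A colocalized punctum — a dead, Ca2+-overloaded neuron — is a red detection
and a green detection whose planar centroids fall within a match radius and
whose MIPs are at most one section apart (a soma split across a MIP
boundary must still match).  Matching is one-to-one: mutually nearest pairs
are extracted iteratively in ascending distance order, which is exactly the
greedy matching the brute-force oracle performs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detect import DetectionSet
from .errors import ParameterError


@dataclass(frozen=True)
class ColocPair:
    red_id: int
    green_id: int
    distance: float  # planar centroid distance, um
    z: float  # mean of the two MIP depths, um


def _greedy_select(pairs: list[tuple[float, int, int, float]]) -> list[ColocPair]:
    """Select one-to-one pairs by ascending (distance, red_id, green_id)."""
    pairs = sorted(pairs, key=lambda p: (p[0], p[1], p[2]))
    used_r: set = set()
    used_g: set = set()
    out = []
    for dist, rid, gid, z in pairs:
        if rid in used_r or gid in used_g:
            continue
        used_r.add(rid)
        used_g.add(gid)
        out.append(ColocPair(red_id=rid, green_id=gid, distance=dist, z=z))
    return out


def _extract(dets: DetectionSet):
    df = dets.df
    return (
        df["det_id"].to_numpy(),
        df[["x_um", "y_um"]].to_numpy(dtype=float),
        df["mip_index"].to_numpy(),
        df["z_um"].to_numpy(dtype=float),
    )


def match_centroids(
    red: DetectionSet,
    green: DetectionSet,
    match_radius: float = 10.0,
    max_mip_gap: int = 1,
) -> list[ColocPair]:
    """One-to-one nearest matching of red and green centroids.

    Admissible pairs have planar distance <= match_radius and MIP-index gap
    <= max_mip_gap; ties break deterministically by (distance, red_id,
    green_id).  Candidate pairs come from a KD-tree radius query, then
    mutually nearest pairs are extracted iteratively (equivalent to a global
    greedy by ascending distance).
    """
    if match_radius < 0:
        raise ParameterError("match_radius must be >= 0")
    if max_mip_gap < 0:
        raise ParameterError("max_mip_gap must be >= 0")
    if red.empty or green.empty:
        return []
    rid, rxy, rmip, rz = _extract(red)
    gid, gxy, gmip, gz = _extract(green)
    tree = cKDTree(gxy)
    candidates: list[tuple[float, int, int, float]] = []
    for i, neighbors in enumerate(tree.query_ball_point(rxy, r=match_radius)):
        for j in neighbors:
            if abs(int(rmip[i]) - int(gmip[j])) > max_mip_gap:
                continue
            dist = float(np.hypot(rxy[i, 0] - gxy[j, 0], rxy[i, 1] - gxy[j, 1]))
            candidates.append((dist, int(rid[i]), int(gid[j]), 0.5 * (rz[i] + gz[j])))
    return _greedy_select(candidates)


def coloc_oracle(
    red: DetectionSet,
    green: DetectionSet,
    match_radius: float = 10.0,
    max_mip_gap: int = 1,
) -> list[ColocPair]:
    """Brute-force reference matching for small instances (tests only).

    Exhaustively enumerates all admissible pairs and greedily selects by
    ascending distance with the same tie-break as :func:`match_centroids`.
    Refuses instances with |red| * |green| > 10^4.
    """
    if match_radius < 0:
        raise ParameterError("match_radius must be >= 0")
    if len(red) * len(green) > 10_000:
        raise ParameterError("oracle refuses instances with |red|*|green| > 1e4")
    if red.empty or green.empty:
        return []
    rid, rxy, rmip, rz = _extract(red)
    gid, gxy, gmip, gz = _extract(green)
    candidates = []
    for i in range(len(rid)):
        for j in range(len(gid)):
            if abs(int(rmip[i]) - int(gmip[j])) > max_mip_gap:
                continue
            dist = float(np.hypot(rxy[i, 0] - gxy[j, 0], rxy[i, 1] - gxy[j, 1]))
            if dist <= match_radius:
                candidates.append((dist, int(rid[i]), int(gid[j]), 0.5 * (rz[i] + gz[j])))
    return _greedy_select(candidates)


def pairs_to_frame(pairs: list[ColocPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.red_id, p.green_id, p.distance, p.z) for p in pairs],
        columns=["red_id", "green_id", "distance_um", "z_um"],
    )


def write_pairs(pairs: list[ColocPair], path) -> None:
    pairs_to_frame(pairs).to_csv(path, index=False)
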