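"""Brute-force homolog-series oracle for cross-checking detect_series.

Enumerates every mass-sorted feature subset (depth-first with early
termination on the first invalid step) up to a length cap, keeps the valid
chains, and filters to maximal ones by explicitly trying to prepend or
append every feature.  Deliberately independent of the production
successor-graph algorithm.
"""

from __future__ import annotations

import pandas as pd


def _step_ok(mz_a, rt_a, mz_b, rt_b, unit_mass, tol_ppm, direction) -> bool:
    diff = mz_b - mz_a
    window = tol_ppm * 1e-6 * 0.5 * (mz_a + mz_b)
    if abs(diff - unit_mass) > window:
        return False
    if direction == "increasing":
        return rt_b > rt_a
    return rt_b < rt_a


def brute_force_series(
    features: pd.DataFrame,
    unit_mass: float,
    tol_ppm: float = 15.0,
    direction: str = "increasing",
    max_len: int = 5,
) -> set[tuple]:
    """All maximal chains (as id tuples) of length 2..max_len."""
    rows = sorted(
        features[["id", "mz", "rt_min"]].itertuples(index=False),
        key=lambda r: (r.mz, str(r.id)),
    )
    chains: list[list] = []

    def extend(chain_idx: list[int]) -> None:
        if len(chain_idx) >= 2:
            chains.append(list(chain_idx))
        if len(chain_idx) == max_len:
            return
        last = rows[chain_idx[-1]]
        for j in range(chain_idx[-1] + 1, len(rows)):
            nxt = rows[j]
            if _step_ok(last.mz, last.rt_min, nxt.mz, nxt.rt_min,
                        unit_mass, tol_ppm, direction):
                extend(chain_idx + [j])

    for i in range(len(rows)):
        extend([i])

    maximal = set()
    for chain in chains:
        head, tail = rows[chain[0]], rows[chain[-1]]
        extendable = False
        for k, other in enumerate(rows):
            if k in chain:
                continue
            if _step_ok(other.mz, other.rt_min, head.mz, head.rt_min,
                        unit_mass, tol_ppm, direction):
                extendable = True
                break
            if _step_ok(tail.mz, tail.rt_min, other.mz, other.rt_min,
                        unit_mass, tol_ppm, direction):
                extendable = True
                break
        if not extendable:
            maximal.add(tuple(rows[k].id for k in chain))
    return maximal


def random_feature_table(rng, n: int, implant_prob: float = 0.7) -> pd.DataFrame:
    """A random feature table, usually with one implanted C5H10 ladder."""
    mz = list(rng.uniform(600.0, 1600.0, size=n))
    rt = list(rng.uniform(10.0, 40.0, size=n))
    if implant_prob and rng.random() < implant_prob:
        length = int(rng.integers(2, 5))
        start = float(rng.uniform(900.0, 1300.0))
        rt0 = float(rng.uniform(15.0, 30.0))
        for k in range(length):
            jitter = float(rng.normal(0.0, 3e-6)) * start
            mz[k] = start + 70.07825056 * k + jitter
            rt[k] = rt0 + k + float(rng.normal(0.0, 0.05))
    return pd.DataFrame(
        {
            "id": [f"F{i:03d}" for i in range(n)],
            "mz": mz,
            "rt_min": rt,
            "intensity": rng.uniform(1e3, 1e6, size=n),
        }
    )
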