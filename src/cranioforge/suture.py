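"""Suture complexity as a length ratio (LR).

LR = traced path length / straight-line chord between the endpoints; a value
of 1 is a straight suture, larger values mean a more interdigitated suture.
The statistic is invariant under rigid motion and uniform scaling of the
trace, so tracing units are arbitrary.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import SUTURE_ORDER, SutureTrace


def length_ratio(trace: SutureTrace) -> float:
    """Total polyline length divided by the endpoint chord length."""
    v = trace.vertices
    chord = float(np.linalg.norm(v[-1] - v[0]))
    if chord <= 0:
        raise ValueError(
            f"{trace.specimen_id}/{trace.suture.value}: degenerate chord (coincident endpoints)"
        )
    path = float(np.sum(np.linalg.norm(np.diff(v, axis=0), axis=1)))
    return path / chord


def assemble_lr_matrix(traces: Iterable[SutureTrace]) -> pd.DataFrame:
    """Wide per-specimen LR table: one row per specimen, one column per suture.

    Missing sutures stay NaN (explicit missingness, never zero-filled).
    Duplicate (specimen, suture) pairs are an error.
    """
    seen: set[tuple[str, str]] = set()
    rows: dict[str, dict[str, float]] = {}
    for tr in traces:
        key = (tr.specimen_id, tr.suture.value)
        if key in seen:
            raise ValueError(f"duplicate trace for specimen {key[0]}, suture {key[1]}")
        seen.add(key)
        rows.setdefault(tr.specimen_id, {})[f"lr_{tr.suture.value.lower()}"] = length_ratio(tr)
    cols = [f"lr_{s.value.lower()}" for s in SUTURE_ORDER]
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cols)
    df.index.name = "specimen_id"
    return df.reset_index()
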