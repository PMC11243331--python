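"""Tolerance-based assignment between peak lists.

Pairs an experimental peak list with a reference list (quantum-chemistry
simulation, literature, or another phase of the same compound) by
center-frequency proximity. Two modes: strict one-to-one pairing
(globally greedy on |delta nu|) and many-to-one, which lets several
A-peaks share a B-peak — the situation where two close experimental
lines are represented by a single merged line in a simulated spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .peaks import PeakSet

DEFAULT_TOL_ONE_TO_ONE = 0.10
DEFAULT_TOL_MANY_TO_ONE = 0.15


@dataclass(frozen=True)
class MatchResult:
    """Pairing between two peak lists.

    ``pairs`` holds (index_A, index_B, delta_thz) with
    delta = center_A - center_B; unmatched indices complete the
    partition of both lists.
    """

    pairs: tuple[tuple[int, int, float], ...]
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]
    tolerance_thz: float
    mode: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def match_peaks(a: PeakSet, b: PeakSet, tolerance_thz: float | None = None,
                mode: str = "one_to_one") -> MatchResult:
    """Assign peaks of ``a`` to peaks of ``b`` within a center tolerance.

    one_to_one: candidate pairs are sorted by |delta| and accepted
    greedily while both members are free — transparent and
    order-independent, and equal to the optimal assignment whenever
    peaks are separated by more than twice the tolerance.

    many_to_one: every A-peak maps to its nearest B-peak within
    tolerance; B-indices may repeat (merged peaks).
    """
    if mode not in ("one_to_one", "many_to_one"):
        raise ValidationError(f"unknown match mode {mode!r}")
    if tolerance_thz is None:
        tolerance_thz = DEFAULT_TOL_ONE_TO_ONE if mode == "one_to_one" else DEFAULT_TOL_MANY_TO_ONE
    if not tolerance_thz > 0:
        raise ValidationError("tolerance_thz must be positive")

    ca, cb = a.centers, b.centers
    pairs: list[tuple[int, int, float]] = []
    if ca.size and cb.size:
        if mode == "one_to_one":
            cand = [
                (abs(ca[i] - cb[j]), i, j)
                for i in range(ca.size)
                for j in range(cb.size)
                if abs(ca[i] - cb[j]) <= tolerance_thz
            ]
            cand.sort()
            used_a: set[int] = set()
            used_b: set[int] = set()
            for _, i, j in cand:
                if i in used_a or j in used_b:
                    continue
                used_a.add(i)
                used_b.add(j)
                pairs.append((i, j, float(ca[i] - cb[j])))
        else:
            for i in range(ca.size):
                j = int(np.argmin(np.abs(cb - ca[i])))
                if abs(ca[i] - cb[j]) <= tolerance_thz:
                    pairs.append((i, j, float(ca[i] - cb[j])))
    pairs.sort(key=lambda p: p[0])
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_a=tuple(i for i in range(ca.size) if i not in matched_a),
        unmatched_b=tuple(j for j in range(cb.size) if j not in matched_b),
        tolerance_thz=float(tolerance_thz),
        mode=mode,
    )


def correspondence_report(mr: MatchResult, a: PeakSet, b: PeakSet,
                          assignments: list[str] | None = None) -> pd.DataFrame:
    """Tabulate a match as rows of (A frequency, B frequency, delta,
    assignment text).

    ``assignments`` is opaque pass-through metadata, one string per
    pair. Rows sharing a B-peak (merged lines) are grouped together.
    Unmatched peaks appear with the opposite column empty.
    """
    if assignments is not None and len(assignments) != len(mr.pairs):
        raise ValidationError("one assignment string per pair required")
    ca, cb = a.centers, b.centers
    rows = []
    order = sorted(range(len(mr.pairs)), key=lambda k: (mr.pairs[k][1], mr.pairs[k][0]))
    for k in order:
        i, j, d = mr.pairs[k]
        rows.append({
            "a_thz": float(ca[i]),
            "b_thz": float(cb[j]),
            "delta_thz": float(d),
            "assignment": assignments[k] if assignments else "",
        })
    for i in mr.unmatched_a:
        rows.append({"a_thz": float(ca[i]), "b_thz": np.nan, "delta_thz": np.nan, "assignment": ""})
    for j in mr.unmatched_b:
        rows.append({"a_thz": np.nan, "b_thz": float(cb[j]), "delta_thz": np.nan, "assignment": ""})
    return pd.DataFrame(rows, columns=["a_thz", "b_thz", "delta_thz", "assignment"])
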