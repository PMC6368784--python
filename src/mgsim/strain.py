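"""Strain genome evolution by substitutions, to a target ANI.

Simulated strain genomes are derived from a source genome by point
substitutions only — no insertions, deletions or rearrangements — so the
evolved sequence has the same length as its source and the average
nucleotide identity (ANI) between the two is exactly the fraction of
identical columns, no alignment required. To hit a target ANI ``a`` on a
sequence with ``L_e`` unambiguous (ACGT) positions, exactly
``round((1 - a) * L_e)`` positions are chosen uniformly without
replacement and each substituted with a uniformly chosen different base.
Python's ``round`` (half-to-even) decides ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class EvolvedGenome:
    sequence: str
    source_id: str
    target_ani: float
    substituted_positions: np.ndarray  # sorted 0-based positions


def evolve_strain(
    source: str,
    target_ani: float,
    rng: np.random.Generator,
    source_id: str = "",
) -> EvolvedGenome:
    """Evolve a sequence to a target ANI by uniform substitutions.

    Ambiguous (non-ACGT) positions are never mutated and do not count
    toward the eligible length. Raises if the required substitution count
    exceeds the number of eligible positions.
    """
    if not 0.0 < target_ani <= 1.0:
        raise ValueError(f"target ANI must be in (0, 1], got {target_ani}")
    if len(source) < 1:
        raise ValueError("source sequence is empty")
    arr = np.frombuffer(source.upper().encode("ascii"), dtype=np.uint8).copy()
    eligible = np.flatnonzero(np.isin(arr, _BASES))
    n_sub = round((1.0 - target_ani) * len(eligible))
    if n_sub > len(eligible):
        raise ValueError(
            f"{n_sub} substitutions required but only {len(eligible)} eligible positions"
        )
    if n_sub == 0:
        positions = np.array([], dtype=np.int64)
    else:
        positions = np.sort(rng.choice(eligible, size=n_sub, replace=False))
        # substitute with an offset of 1..3 in base space: always a different base
        cur = np.searchsorted(_BASES, arr[positions])
        offsets = rng.integers(1, 4, size=n_sub)
        arr[positions] = _BASES[(cur + offsets) % 4]
    return EvolvedGenome(
        sequence=arr.tobytes().decode("ascii"),
        source_id=source_id,
        target_ani=float(target_ani),
        substituted_positions=positions,
    )


def measure_ani(a: str, b: str) -> float:
    """Fraction of identical positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(
            f"sequences differ in length ({len(a)} vs {len(b)}); "
            "only substitution-related sequences are supported"
        )
    if len(a) == 0:
        raise ValueError("cannot measure ANI of empty sequences")
    xa = np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)
    return float(np.mean(xa == xb))


def default_ani_values() -> list[float]:
    """The standard relatedness sweep: 0.900 to 0.995 in steps of 0.005."""
    return [round(0.900 + 0.005 * i, 3) for i in range(20)]


def ani_sweep(
    source: str,
    ani_values: list[float] | None = None,
    rng: np.random.Generator | None = None,
    source_id: str = "",
) -> list[EvolvedGenome]:
    """One independently evolved genome per target ANI value."""
    if ani_values is None:
        ani_values = default_ani_values()
    if rng is None:
        rng = np.random.default_rng()
    return [evolve_strain(source, a, rng, source_id=source_id) for a in ani_values]
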