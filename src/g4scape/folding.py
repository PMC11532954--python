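"""Secondary-structure folding adapters.

Folding thermodynamics are deliberately external to this package: any engine
that maps a sequence to a set of predicted structures with a free energy and a
melting temperature can plug in. Two adapters ship in-repo:

* :class:`NaiveHairpinFolder` — a deterministic stand-in that enumerates
  maximal complementary hairpin stems with fixed per-pair energies and a
  Wallace-rule melting temperature. It exists so the downstream modules are
  testable offline; it makes no claim to thermodynamic accuracy.
* :class:`TabularFoldingAdapter` — re-ingests (dG, Tm, n) results computed by
  an external engine, keyed by sequence.
"""
from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Protocol


@dataclass(frozen=True)
class Structure:
    """One predicted secondary structure: free energy (kcal/mol) and Tm (degC)."""

    dg: float
    tm: float


@dataclass
class FoldingResult:
    """Per-sequence folding outcome, summarized as (min dG, max Tm, count).

    A sequence predicted to form no structure has ``min_dg == 0.0``,
    ``max_tm == 0.0`` and ``n_structures == 0``.
    """

    structures: tuple[Structure, ...] = field(default_factory=tuple)

    @property
    def min_dg(self) -> float:
        return min((s.dg for s in self.structures), default=0.0)

    @property
    def max_tm(self) -> float:
        return max((s.tm for s in self.structures), default=0.0)

    @property
    def n_structures(self) -> int:
        return len(self.structures)


class FoldingAdapter(Protocol):
    """Anything that folds a nucleotide sequence into a :class:`FoldingResult`."""

    def fold(self, seq: str) -> FoldingResult: ...


_PAIR_ENERGY = {  # kcal/mol per closed pair; G:T wobble allowed, weakly
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}


@dataclass(frozen=True)
class NaiveHairpinFolder:
    """Maximal-complementary-stem hairpin enumeration with fixed pair energies.

    For every candidate loop of ``loop_min``..``loop_max`` bases the stem is
    extended outward while bases pair (Watson-Crick or G:T); hairpins with at
    least ``min_stem`` pairs count as structures. dG is the sum of pair
    energies; Tm is the Wallace rule (2 degC per A:T/G:T pair, 4 per G:C)
    over stem bases. Deterministic; for testing and synthetic landscapes only.
    """

    loop_min: int = 3
    loop_max: int = 12
    min_stem: int = 3

    def fold(self, seq: str) -> FoldingResult:
        s = seq.upper()
        n = len(s)
        structures: list[Structure] = []
        for loop in range(self.loop_min, self.loop_max + 1):
            for lstart in range(1, n - loop):
                i, j = lstart - 1, lstart + loop
                pairs = 0
                dg = 0.0
                tm = 0.0
                while i >= 0 and j < n:
                    e = _PAIR_ENERGY.get((s[i], s[j]))
                    if e is None:
                        break
                    pairs += 1
                    dg += e
                    tm += 4.0 if e == -3.0 else 2.0
                    i -= 1
                    j += 1
                # keep maximal stems only: skip if the stem could extend inward
                # with a smaller loop (it will be found at that loop size)
                if pairs >= self.min_stem:
                    structures.append(Structure(round(dg, 2), round(tm, 2)))
        return FoldingResult(tuple(structures))


@dataclass
class TabularFoldingAdapter:
    """External folding results re-ingested from a table, keyed by sequence."""

    table: Mapping[str, FoldingResult]
    engine: str = "external"

    def fold(self, seq: str) -> FoldingResult:
        key = seq.upper()
        if key not in self.table:
            raise KeyError(f"no external folding result for sequence of length {len(seq)}")
        return self.table[key]
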