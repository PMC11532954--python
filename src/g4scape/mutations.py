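"""Mutation-catalog overlap with pG4 hits, stability stratification, hotspot
ranking and per-substitution folding impact calls.

Germline catalogs (HGMD-like) and somatic catalogs (COSMIC-like) differ in
what counts as a unique mutation: germline records deduplicate on genomic
coordinates alone, somatic records on coordinates plus sample name, so a
variant recurring in many tumors counts once per tumor.

Stability scores (Quadron-style Q-scores) are consumed as input on the hits;
the >= 19 threshold separates pG4s predicted to fold into stable G4
structures (s-pG4) from the rest.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from intervaltree import IntervalTree

from .folding import FoldingAdapter
from .scan import PG4Hit

logger = logging.getLogger(__name__)

MUT_TYPES = ("substitution", "deletion", "insertion", "duplication")
SOURCES = ("germline", "somatic")

STABLE_Q_THRESHOLD = 19.0

Arrow = str  # "down" | "equal" | "up"
_ARROWS = ("down", "equal", "up")


@dataclass
class MutationRecord:
    """A point or small-indel variant (0-based position on the reference)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    mut_type: str
    source: str
    label: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.mut_type not in MUT_TYPES:
            raise ValueError(f"unknown mut_type {self.mut_type!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.mut_type in ("substitution", "deletion") and not self.ref:
            raise ValueError(f"{self.mut_type} at {self.chrom}:{self.pos} needs a ref allele")

    @property
    def affected_span(self) -> tuple[int, int]:
        """Reference bases touched: the ref span for substitutions/deletions,
        the insertion point for insertions and duplications."""
        if self.mut_type in ("substitution", "deletion"):
            return self.pos, self.pos + len(self.ref)
        return self.pos, self.pos + 1


@dataclass
class AnnotatedMutation:
    mutation: MutationRecord
    pg4_index: int | None  # index into the hit list, or None
    pg4: PG4Hit | None = None

    @property
    def in_pg4(self) -> bool:
        return self.pg4_index is not None


def intersect_mutations(
    muts: Iterable[MutationRecord], hits: Sequence[PG4Hit]
) -> list[AnnotatedMutation]:
    """Annotate each mutation with the pG4 hit it overlaps, if any.

    A mutation overlaps a pG4 when any affected reference base lies within
    the hit interval; among several overlapping hits the leftmost (then
    first-listed) wins, deterministically.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, h in enumerate(hits):
        trees[h.chrom].addi(h.start, h.end, idx)
    out: list[AnnotatedMutation] = []
    for m in muts:
        s, e = m.affected_span
        overlaps = trees[m.chrom].overlap(s, e) if m.chrom in trees else ()
        if overlaps:
            idx = min((iv.begin, iv.data) for iv in overlaps)[1]
            out.append(AnnotatedMutation(m, idx, hits[idx]))
        else:
            out.append(AnnotatedMutation(m, None))
    return out


def uniqueness_key(mut: MutationRecord) -> tuple:
    """Deduplication key: coordinates for germline; coordinates + sample for
    somatic (the same variant in two tumors is two mutations)."""
    base = (mut.chrom, mut.pos, mut.ref, mut.alt)
    if mut.source == "germline":
        return base
    if not mut.sample_id:
        raise ValueError(f"somatic mutation at {mut.chrom}:{mut.pos} lacks a sample_id")
    return base + (mut.sample_id,)


@dataclass
class StabilityStrata:
    stable: list[PG4Hit]
    unstable: list[PG4Hit]
    n_missing: int

    @property
    def stable_fraction(self) -> float:
        n = len(self.stable) + len(self.unstable)
        return len(self.stable) / n if n else float("nan")


def stability_stratify(
    hits: Iterable[PG4Hit], threshold: float = STABLE_Q_THRESHOLD
) -> StabilityStrata:
    """Split hits into stable (q_score >= threshold, boundary inclusive) and
    unstable; hits without a score are excluded and counted."""
    stable: list[PG4Hit] = []
    unstable: list[PG4Hit] = []
    missing = 0
    for h in hits:
        if h.q_score is None:
            missing += 1
        elif h.q_score >= threshold:
            stable.append(h)
        else:
            unstable.append(h)
    if missing:
        logger.warning("stability_stratify: %d hits lack a q_score; excluded", missing)
    return StabilityStrata(stable, unstable, missing)


def hotspot_rank(
    annotated: Iterable[AnnotatedMutation], hits: Sequence[PG4Hit]
) -> list[tuple[int, PG4Hit, int]]:
    """Per-pG4 unique-mutation counts, descending (ties by coordinate).

    Returns ``(hit_index, hit, unique_count)`` for every pG4 with >= 1 unique
    overlapping mutation. Order is a permutation-invariant function of the
    input multiset.
    """
    uniques: dict[int, set] = defaultdict(set)
    for am in annotated:
        if am.pg4_index is not None:
            uniques[am.pg4_index].add(uniqueness_key(am.mutation))
    ranked = [
        (idx, hits[idx], len(keys)) for idx, keys in uniques.items()
    ]
    ranked.sort(key=lambda t: (-t[2], t[1].chrom, t[1].start, t[0]))
    return ranked


def indel_recurrence_table(muts: Iterable[MutationRecord]) -> pd.DataFrame:
    """Per-site recurrence of short insertions/deletions/duplications.

    Counts unique mutations (dedup key per source) at each (chrom, pos, ref,
    alt) site, descending; the COSMIC-style global recurrent-site survey.
    """
    counter: Counter[tuple] = Counter()
    meta: dict[tuple, MutationRecord] = {}
    seen: set[tuple] = set()
    for m in muts:
        if m.mut_type == "substitution":
            continue
        key = uniqueness_key(m)
        if key in seen:
            continue
        seen.add(key)
        site = (m.chrom, m.pos, m.ref, m.alt, m.mut_type)
        counter[site] += 1
        meta[site] = m
    rows = [
        {"chrom": c, "pos": p, "ref": r, "alt": a, "mut_type": t, "n_unique": n}
        for (c, p, r, a, t), n in counter.items()
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "mut_type", "n_unique"])
    return df.sort_values(
        ["n_unique", "chrom", "pos"], ascending=[False, True, True]
    ).reset_index(drop=True)


def _arrow(delta: float, eps: float) -> Arrow:
    if delta > eps:
        return "up"
    if delta < -eps:
        return "down"
    return "equal"


_INVERT = {"up": "down", "down": "up", "equal": "equal"}


@dataclass
class ImpactCall:
    """Direction of change of the three folding metrics under a substitution.

    ``stability`` is expressed as G4-stability direction: a dG that becomes
    less negative (raw metric up) weakens the structure, so stability goes
    down. ``tm`` and ``n_structures`` follow the raw metric direction.
    """

    d_min_dg: float
    d_max_tm: float
    d_n_structures: int
    stability: Arrow
    tm: Arrow
    n_structures: Arrow

    def __post_init__(self) -> None:
        for a in (self.stability, self.tm, self.n_structures):
            if a not in _ARROWS:
                raise ValueError(f"bad arrow {a!r}")

    @property
    def any_changed(self) -> bool:
        return (self.stability, self.tm, self.n_structures) != ("equal",) * 3

    @classmethod
    def from_metrics(
        cls,
        wt: tuple[float, float, int],
        mut: tuple[float, float, int],
        eps_dg: float = 0.01,
        eps_tm: float = 0.1,
        eps_n: float = 0.0,
    ) -> "ImpactCall":
        d_dg = mut[0] - wt[0]
        d_tm = mut[1] - wt[1]
        d_n = mut[2] - wt[2]
        return cls(
            d_min_dg=d_dg,
            d_max_tm=d_tm,
            d_n_structures=int(d_n),
            stability=_INVERT[_arrow(d_dg, eps_dg)],
            tm=_arrow(d_tm, eps_tm),
            n_structures=_arrow(float(d_n), eps_n),
        )

    @classmethod
    def from_raw_arrows(cls, dg_arrow: Arrow, tm_arrow: Arrow, n_arrow: Arrow) -> "ImpactCall":
        """Build from printed raw-metric arrows (dG direction as printed);
        stability is the inverse of the raw dG direction."""
        return cls(0.0, 0.0, 0, _INVERT[dg_arrow], tm_arrow, n_arrow)


def substitution_impact(
    wt_extended_seq: str,
    substitution: tuple[int, str, str],
    adapter: FoldingAdapter,
    eps_dg: float = 0.01,
    eps_tm: float = 0.1,
    eps_n: float = 0.0,
) -> ImpactCall:
    """Fold the flank-extended wild-type and mutant sequences and call the
    direction of change of (min dG, max Tm, structure count).

    ``substitution`` is (offset within the sequence, ref base, alt base); a
    ref mismatch with the supplied sequence is an error.
    """
    offset, ref, alt = substitution
    if not (0 <= offset < len(wt_extended_seq)):
        raise ValueError(f"substitution offset {offset} outside the sequence")
    if wt_extended_seq[offset].upper() != ref.upper():
        raise ValueError(
            f"ref mismatch at offset {offset}: sequence has "
            f"{wt_extended_seq[offset]!r}, substitution says {ref!r}"
        )
    mut_seq = wt_extended_seq[:offset] + alt + wt_extended_seq[offset + 1 :]
    wt_res = adapter.fold(wt_extended_seq)
    mut_res = adapter.fold(mut_seq)
    return ImpactCall.from_metrics(
        (wt_res.min_dg, wt_res.max_tm, wt_res.n_structures),
        (mut_res.min_dg, mut_res.max_tm, mut_res.n_structures),
        eps_dg=eps_dg,
        eps_tm=eps_tm,
        eps_n=eps_n,
    )


@dataclass
class ImpactTally:
    stability_down: int
    tm_down: int
    n_structures_down: int
    any_changed: int
    total: int


def tally_impacts(calls: Iterable[ImpactCall]) -> ImpactTally:
    """Summary counts over impact calls: how many substitutions weaken the
    structure, lower Tm, lose structures, or alter any metric at all."""
    calls = list(calls)
    return ImpactTally(
        stability_down=sum(c.stability == "down" for c in calls),
        tm_down=sum(c.tm == "down" for c in calls),
        n_structures_down=sum(c.n_structures == "down" for c in calls),
        any_changed=sum(c.any_changed for c in calls),
        total=len(calls),
    )


def load_cardiac_substitutions() -> pd.DataFrame:
    """The published panel of 36 disease-linked substitutions in pG4s of
    cardiac- and development-related genes, with the reported direction of
    change of each folding metric (dG arrow = raw metric direction)."""
    with resources.files("g4scape.data").joinpath(
        "cardiac_pg4_substitutions.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def impact_calls_from_arrow_table(df: pd.DataFrame) -> list[ImpactCall]:
    """Convert a raw-arrow table (columns dg_arrow, tm_arrow, n_arrow) into
    :class:`ImpactCall` objects."""
    return [
        ImpactCall.from_raw_arrows(r.dg_arrow, r.tm_arrow, r.n_arrow)
        for r in df.itertuples()
    ]
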