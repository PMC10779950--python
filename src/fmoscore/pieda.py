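"""Pair interaction energy decomposition analysis (PIEDA) bookkeeping.

In an FMO2 calculation the system is cut into fragments (one residue per
fragment, plus one ligand fragment) and each fragment-pair interaction energy
(PIE/IFIE) is decomposed into four components:

    dE(I,J) = ES + EX + CT+MIX + DI

electrostatics, exchange repulsion, charge transfer with its mixing term, and
dispersion (the MP2 correlation part).  The sum of all ligand--residue PIEs is
the gas-phase interaction energy ``e_int`` consumed by the scoring functions.
This module holds parsed tables and derives per-residue interaction profiles
of the kind used to rationalise structure--activity relationships.

The QM itself happens upstream; only bookkeeping and analysis live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import FMOScoreError

__all__ = [
    "TOTAL_COMPONENT_TOL",
    "Fragment",
    "PairInteraction",
    "PiedaTable",
    "ComponentSums",
    "ProfileEntry",
    "pair_total",
    "sum_pie",
    "residue_profile",
    "classify_interaction",
]

#: Tolerance (kcal/mol) for a stored pair total vs the sum of its four
#: components, absorbing per-component rounding in printed QM tables.
TOTAL_COMPONENT_TOL = 0.05

COMPONENTS = ("es", "ex", "ct_mix", "di")


@dataclass(frozen=True)
class Fragment:
    """A fragment label (residue identifier or the designated ligand)."""

    label: str
    is_ligand: bool = False


@dataclass(frozen=True)
class PairInteraction:
    """One unordered fragment pair's interaction energy, decomposed (kcal/mol).

    ``i`` and ``j`` are 0-based indices into the owning table's fragment list.
    If ``total`` is omitted it is filled in as the component sum; if supplied
    (e.g. parsed from a printed table) it must agree with the component sum
    within :data:`TOTAL_COMPONENT_TOL`.
    """

    i: int
    j: int
    es: float
    ex: float
    ct_mix: float
    di: float
    total: float | None = None

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError(f"pair indices must differ, got ({self.i}, {self.j})")
        s = self.es + self.ex + self.ct_mix + self.di
        if self.total is None:
            object.__setattr__(self, "total", s)
        elif abs(self.total - s) > TOTAL_COMPONENT_TOL:
            raise ValueError(
                f"pair ({self.i},{self.j}) total {self.total} deviates from component "
                f"sum {s:.4f} by more than {TOTAL_COMPONENT_TOL} kcal/mol"
            )


def pair_total(pair: PairInteraction) -> float:
    """Sum of the four PIEDA components (kcal/mol)."""
    return pair.es + pair.ex + pair.ct_mix + pair.di


@dataclass
class PiedaTable:
    """Fragment list plus decomposed pair interaction energies.

    At most one fragment is flagged as the ligand; unordered pairs are unique.
    """

    fragments: list[Fragment]
    pairs: list[PairInteraction] = field(default_factory=list)

    def __post_init__(self) -> None:
        ligands = [f for f in self.fragments if f.is_ligand]
        if len(ligands) > 1:
            raise ValueError(f"at most one ligand fragment allowed, found {len(ligands)}")
        n = len(self.fragments)
        seen: set[frozenset[int]] = set()
        for p in self.pairs:
            if not (0 <= p.i < n and 0 <= p.j < n):
                raise ValueError(f"pair ({p.i},{p.j}) references a fragment outside 0..{n - 1}")
            key = frozenset((p.i, p.j))
            if key in seen:
                raise ValueError(f"duplicate unordered pair ({p.i},{p.j})")
            seen.add(key)

    @property
    def ligand_index(self) -> int | None:
        for k, f in enumerate(self.fragments):
            if f.is_ligand:
                return k
        return None

    def with_ligand(self, label: str) -> "PiedaTable":
        """Return a copy with the fragment named ``label`` flagged as the ligand."""
        labels = [f.label for f in self.fragments]
        if label not in labels:
            raise FMOScoreError(f"no fragment labelled {label!r}; have {labels}")
        frags = [replace(f, is_ligand=(f.label == label)) for f in self.fragments]
        return PiedaTable(fragments=frags, pairs=list(self.pairs))


@dataclass(frozen=True)
class ComponentSums:
    """Ligand--environment interaction energy and its component subtotals (kcal/mol)."""

    es: float
    ex: float
    ct_mix: float
    di: float
    total: float


def sum_pie(table: PiedaTable) -> ComponentSums:
    """Sum PIEs (and each component) over all pairs involving the ligand fragment.

    The ``total`` of the result is the gas-phase interaction energy ``e_int``
    fed to :class:`fmoscore.thermo.ComplexEnergyRecord`.
    """
    lig = table.ligand_index
    if lig is None:
        raise FMOScoreError("no fragment is flagged as the ligand; use with_ligand() first")
    es = ex = ct = di = tot = 0.0
    for p in table.pairs:
        if lig in (p.i, p.j):
            es += p.es
            ex += p.ex
            ct += p.ct_mix
            di += p.di
            tot += p.total  # type: ignore[operator]
    return ComponentSums(es=es, ex=ex, ct_mix=ct, di=di, total=tot)


def classify_interaction(es: float, ex: float, ct_mix: float, di: float, total: float) -> str:
    """Heuristic character label for a ligand--residue interaction.

    ``"polar"`` when the combined ES + CT+MIX magnitude dominates (> 50% of
    |total|, typical of H-bonds and salt bridges), ``"dispersion"`` when |DI|
    dominates (hydrophobic contacts), ``"mixed"`` otherwise, ``"none"`` for an
    all-zero row.  A heuristic annotation only, not a physical assignment.
    """
    if total == 0 and es == ex == ct_mix == di == 0:
        return "none"
    polar = abs(es + ct_mix)
    disp = abs(di)
    cut = 0.5 * abs(total)
    if polar > cut and polar >= disp:
        return "polar"
    if disp > cut:
        return "dispersion"
    return "mixed"


@dataclass(frozen=True)
class ProfileEntry:
    """One residue's interaction with the ligand, decomposed (kcal/mol)."""

    residue: str
    es: float
    ex: float
    ct_mix: float
    di: float
    total: float
    character: str


def residue_profile(
    table: PiedaTable, top_n: int | None = None, component: str = "total"
) -> list[ProfileEntry]:
    """Per-residue ligand-interaction profile, strongest (most negative) first.

    Every non-ligand fragment appears, residues without a ligand pair as zero
    rows, so profiles over homologous complexes align position-for-position.
    Sorted ascending by ``component`` (one of es/ex/ct_mix/di/total), ties
    broken by fragment order; ``top_n`` truncates after sorting.
    """
    if component not in COMPONENTS + ("total",):
        raise ValueError(f"unknown component {component!r}")
    lig = table.ligand_index
    if lig is None:
        raise FMOScoreError("no fragment is flagged as the ligand; use with_ligand() first")
    by_residue: dict[int, PairInteraction] = {}
    for p in table.pairs:
        if lig in (p.i, p.j):
            other = p.j if p.i == lig else p.i
            by_residue[other] = p
    entries = []
    for idx, frag in enumerate(table.fragments):
        if idx == lig:
            continue
        p = by_residue.get(idx)
        if p is None:
            es = ex = ct = di = tot = 0.0
        else:
            es, ex, ct, di, tot = p.es, p.ex, p.ct_mix, p.di, p.total  # type: ignore[misc]
        entries.append(
            (
                idx,
                ProfileEntry(
                    residue=frag.label,
                    es=es,
                    ex=ex,
                    ct_mix=ct,
                    di=di,
                    total=tot,
                    character=classify_interaction(es, ex, ct, di, tot),
                ),
            )
        )
    entries.sort(key=lambda t: (getattr(t[1], component), t[0]))
    out = [e for _, e in entries]
    if top_n is not None:
        out = out[: max(top_n, 0)]
    return out
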