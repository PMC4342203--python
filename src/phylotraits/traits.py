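"""Binary characters built from use records and habit classes.

The analyses all run on presence/absence characters scored per tip: "any
documented use", "medicinal use", and leaf succulence derived from a
four-way growth-habit classification. A score of 0 means *no reported use*,
not verified absence — ethnobotanical sources rarely record non-use.

Also provides the exact (hypergeometric) test for a 2x2 cross-tabulation of
two such characters, computed by full enumeration in rational arithmetic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping

import numpy as np

from .errors import ValidationError
from .util import normalize_label

__all__ = [
    "BinaryTrait",
    "UseRecord",
    "UseRecordTable",
    "HabitClass",
    "LEVEL1_CATEGORIES",
    "use_records_to_traits",
    "habit_to_succulence",
    "fisher_exact",
    "crosstab",
    "read_trait_table",
    "write_trait_table",
    "read_use_records",
]

#: TDWG Economic Botany Data Standard level-1 use categories.
LEVEL1_CATEGORIES = frozenset(
    {
        "Food",
        "Food_additives",
        "Animal_food",
        "Materials",
        "Fuels",
        "Social_uses",
        "Vertebrate_poisons",
        "Non-vertebrate_poisons",
        "Medicines",
        "Environmental_uses",
        "Gene_sources",
    }
)


@dataclass
class BinaryTrait:
    """A named map tip_label -> {0, 1, missing(None)}.

    Prevalence (the count of 1s) is always recomputed from the states,
    never stored.
    """

    name: str
    states: dict[str, int | None]

    @property
    def prevalence(self) -> int:
        return sum(1 for v in self.states.values() if v == 1)

    @property
    def n_scored(self) -> int:
        return sum(1 for v in self.states.values() if v is not None)

    def defined_on(self, labels: Iterable[str]) -> bool:
        return all(self.states.get(l) is not None for l in labels)

    def restrict(self, labels: Iterable[str]) -> "BinaryTrait":
        labels = list(labels)
        return BinaryTrait(self.name, {l: self.states.get(l) for l in labels})

    def complement(self) -> "BinaryTrait":
        return BinaryTrait(
            f"not_{self.name}",
            {k: (None if v is None else 1 - v) for k, v in self.states.items()},
        )

    def __getitem__(self, label: str) -> int | None:
        return self.states[label]


@dataclass(frozen=True)
class UseRecord:
    species: str
    level1: str
    level2: str = ""


@dataclass
class UseRecordTable:
    records: list[UseRecord]
    level1_vocab: frozenset = LEVEL1_CATEGORIES

    def validate(self) -> None:
        bad = sorted({r.level1 for r in self.records} - set(self.level1_vocab))
        if bad:
            raise ValidationError(f"unknown level-1 use categories: {bad}")


class HabitClass(str, Enum):
    BARELY_SUCCULENT_SHRUB = "barely_succulent_shrub"
    SUCCULENT_SHRUB = "succulent_shrub"
    BRANCHING_TREE = "branching_tree"
    SCRAMBLING_SHRUB = "scrambling_shrub"


def use_records_to_traits(
    records: UseRecordTable,
    species: Iterable[str] | None = None,
    medicinal_category: str = "Medicines",
) -> tuple[BinaryTrait, BinaryTrait]:
    """Collapse per-species use records into two binary characters.

    ``any_use`` is 1 iff the species has at least one record of any level-1
    category; ``medicinal_use`` is 1 iff at least one record falls in the
    level-2 Medicines category. Species in ``species`` with no records score
    0 on both (lack of reported use).
    """
    if not records.records:
        raise ValidationError("use-record table is empty")
    records.validate()
    norm = lambda s: normalize_label(s)
    universe = {norm(r.species) for r in records.records}
    if species is not None:
        universe |= {norm(s) for s in species}
    any_use = {s: 0 for s in sorted(universe)}
    med_use = {s: 0 for s in sorted(universe)}
    for r in records.records:
        s = norm(r.species)
        any_use[s] = 1
        if r.level2 == medicinal_category or r.level1 == medicinal_category:
            med_use[s] = 1
    return BinaryTrait("any_use", any_use), BinaryTrait("medicinal_use", med_use)


def habit_to_succulence(
    classes: Mapping[str, HabitClass | str],
    scrambler_overrides: Mapping[str, int] | None = None,
) -> BinaryTrait:
    """Score growth habit as a binary succulence character.

    Succulent shrubs -> 1; barely succulent shrubs (grass aloes) and
    branching trees -> 0. Scrambling shrubs have variably succulent leaves
    and require an explicit per-species override.
    """
    scrambler_overrides = dict(scrambler_overrides or {})
    out: dict[str, int | None] = {}
    unresolved: list[str] = []
    for sp, cls in classes.items():
        cls = HabitClass(cls)
        sp = normalize_label(sp)
        if cls is HabitClass.SUCCULENT_SHRUB:
            out[sp] = 1
        elif cls in (HabitClass.BARELY_SUCCULENT_SHRUB, HabitClass.BRANCHING_TREE):
            out[sp] = 0
        else:  # scrambling shrub
            if sp in scrambler_overrides:
                out[sp] = int(scrambler_overrides[sp])
            else:
                unresolved.append(sp)
    if unresolved:
        raise ValidationError(
            "scrambling shrubs need an explicit succulence override: "
            f"{sorted(unresolved)}"
        )
    return BinaryTrait("succulence", out)


# ----------------------------------------------------------------------
# Exact 2x2 test


def fisher_exact(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table of counts.

    Returns ``(odds_ratio, p_two_sided)``. The two-sided p-value follows the
    minimum-likelihood rule: with the margins fixed, sum the hypergeometric
    probabilities of every table whose point probability does not exceed that
    of the observed table. The enumeration runs in exact rational arithmetic,
    so ties are handled exactly and the p-value is correct to full floating
    precision.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValidationError("fisher_exact expects a 2x2 table")
    a, b, c, d = (int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))
    if min(a, b, c, d) < 0:
        raise ValidationError("counts must be nonnegative")
    n = a + b + c + d
    if n == 0 or (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        raise ValidationError("at least one positive margin required")
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    denom = comb(n, c1)
    pmf = {x: Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom) for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    p_two = sum((p for p in pmf.values() if p <= p_obs), Fraction(0))
    odds = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else np.nan)
    return float(odds), float(min(p_two, Fraction(1)))


def crosstab(
    trait_rows: BinaryTrait, trait_cols: BinaryTrait
) -> tuple[np.ndarray, int]:
    """2x2 cross-tabulation of two binary traits over their shared tips.

    Rows index ``trait_rows`` state (1 then 0), columns ``trait_cols`` state
    (1 then 0). Tips missing in either trait are excluded pairwise; the
    number excluded is returned alongside the table.
    """
    labels = set(trait_rows.states) & set(trait_cols.states)
    tab = np.zeros((2, 2), dtype=int)
    excluded = 0
    for l in labels:
        r, c = trait_rows.states[l], trait_cols.states[l]
        if r is None or c is None:
            excluded += 1
            continue
        tab[1 - r, 1 - c] += 1
    return tab, excluded


# ----------------------------------------------------------------------
# Delimited I/O


def read_trait_table(path: str, name: str | None = None, delimiter: str = "\t") -> BinaryTrait:
    """Read a 2-column (tip_label, state) table; '?' or 'NA' mean missing."""
    states: dict[str, int | None] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=delimiter):
            if not row or row[0].startswith("#"):
                continue
            if row[0].lower() in ("tip_label", "species", "taxon"):
                continue
            label = normalize_label(row[0])
            tok = row[1].strip()
            states[label] = None if tok in ("?", "NA", "") else int(tok)
    if not states:
        raise ValidationError(f"no trait rows found in {path}")
    bad = {k: v for k, v in states.items() if v not in (0, 1, None)}
    if bad:
        raise ValidationError(f"non-binary states in {path}: {bad}")
    return BinaryTrait(name or path, states)


def write_trait_table(trait: BinaryTrait, path: str, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["tip_label", trait.name])
        for label in sorted(trait.states):
            v = trait.states[label]
            w.writerow([label, "?" if v is None else v])


def read_use_records(path: str, delimiter: str = "\t") -> UseRecordTable:
    """Read a 3-column (species, level1, level2) use-record table."""
    recs: list[UseRecord] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=delimiter):
            if not row or row[0].startswith("#") or row[0].lower() == "species":
                continue
            recs.append(UseRecord(row[0], row[1].strip(), row[2].strip() if len(row) > 2 else ""))
    return UseRecordTable(recs)
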