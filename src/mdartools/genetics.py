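"""Mendelian segregation with lethal genotype classes.

Supports one or two unlinked loci under selfing or a biparental cross:
per-locus gamete frequencies are combined assuming independent assortment,
lethal genotype classes are zeroed, and the remainder renormalized to give
the expected distribution among surviving progeny. A chi-square
goodness-of-fit test compares observed seedling counts against that
expectation — the computation behind arguing embryonic lethality from a
distorted segregation ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats

STATES = ("+/+", "+/-", "-/-")

#: convenient aliases accepted by the CLI and constructors
STATE_ALIASES = {
    "wt": "+/+",
    "het": "+/-",
    "hom": "-/-",
    "+/+": "+/+",
    "+/-": "+/-",
    "-/-": "-/-",
}

Genotype = tuple[str, ...]  # one state per locus, in model locus order


@dataclass(frozen=True)
class SegregationModel:
    """Parental genotypes, lethal classes, and locus bookkeeping.

    ``parents`` holds one genotype for selfing or two for a cross; each is a
    mapping locus name -> state. Loci are assumed unlinked.
    """

    loci: tuple[str, ...]
    parents: tuple[dict, ...]
    lethal: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 1 <= len(self.loci) <= 2:
            raise ValueError("1 or 2 loci supported")
        if len(self.parents) not in (1, 2):
            raise ValueError("one parent (selfing) or two (cross) required")
        for parent in self.parents:
            for locus in self.loci:
                state = parent.get(locus)
                if state not in STATES:
                    raise ValueError(
                        f"locus '{locus}': invalid or missing state {state!r}"
                    )
        for geno in self.lethal:
            if len(geno) != len(self.loci) or any(s not in STATES for s in geno):
                raise ValueError(f"invalid lethal genotype {geno!r}")


def selfing(parent: dict, lethal=()) -> SegregationModel:
    loci = tuple(parent.keys())
    parent = {k: STATE_ALIASES[v] for k, v in parent.items()}
    lethal = frozenset(
        tuple(STATE_ALIASES[s] for s in g) for g in lethal
    )
    return SegregationModel(loci, (parent,), lethal)


def cross(parent1: dict, parent2: dict, lethal=()) -> SegregationModel:
    loci = tuple(parent1.keys())
    p1 = {k: STATE_ALIASES[v] for k, v in parent1.items()}
    p2 = {k: STATE_ALIASES[v] for k, v in parent2.items()}
    lethal = frozenset(
        tuple(STATE_ALIASES[s] for s in g) for g in lethal
    )
    return SegregationModel(loci, (p1, p2), lethal)


def _gamete_freqs(state: str) -> dict[str, float]:
    return {
        "+/+": {"+": 1.0, "-": 0.0},
        "+/-": {"+": 0.5, "-": 0.5},
        "-/-": {"+": 0.0, "-": 1.0},
    }[state]


def _locus_offspring(state1: str, state2: str) -> dict[str, float]:
    g1, g2 = _gamete_freqs(state1), _gamete_freqs(state2)
    out = {s: 0.0 for s in STATES}
    for a1, p1 in g1.items():
        for a2, p2 in g2.items():
            alleles = "".join(sorted((a1, a2)))  # "+-" orders before by sort
            geno = {"++": "+/+", "+-": "+/-", "--": "-/-"}[alleles]
            out[geno] += p1 * p2
    return out


def expected_freqs(model: SegregationModel) -> dict[Genotype, float]:
    """Expected genotype distribution among surviving progeny.

    Per-locus offspring distributions are multiplied across loci
    (independent assortment), the lethal classes are set to zero, and the
    survivors renormalized. Raises if lethality removes everything.
    """
    mother = model.parents[0]
    father = model.parents[-1]  # selfing: same dict
    per_locus = [
        _locus_offspring(mother[locus], father[locus]) for locus in model.loci
    ]
    freqs: dict[Genotype, float] = {}
    for combo in product(STATES, repeat=len(model.loci)):
        p = 1.0
        for locus_dist, state in zip(per_locus, combo):
            p *= locus_dist[state]
        if p > 0.0:
            freqs[combo] = p
    for geno in model.lethal:
        freqs.pop(geno, None)
    total = sum(freqs.values())
    if total == 0.0:
        raise ValueError("every possible genotype is lethal")
    return {g: p / total for g, p in freqs.items()}


def observed_ratio(count_a: int, count_b: int) -> float:
    """Segregation ratio of the second genotype class over the first,
    reported to 2 decimals (e.g. 78 heterozygous over 61 wild type -> 1.28)."""
    if count_a <= 0:
        raise ValueError("first count must be positive")
    return round(count_b / count_a, 2)


def chisq_gof(
    observed_counts: dict, expected_probs: dict
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of observed category counts against
    expected probabilities. Returns (statistic, df, p)."""
    if set(observed_counts) != set(expected_probs):
        raise ValueError(
            "observed and expected category sets differ: "
            f"{sorted(map(str, observed_counts))} vs "
            f"{sorted(map(str, expected_probs))}"
        )
    cats = sorted(observed_counts, key=str)
    obs = np.array([observed_counts[c] for c in cats], dtype=float)
    probs = np.array([expected_probs[c] for c in cats], dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-9):
        raise ValueError("expected probabilities must sum to 1")
    total = obs.sum()
    if total < 1:
        raise ValueError("need at least one observation")
    zero = probs == 0.0
    if np.any(zero & (obs > 0)):
        raise ValueError(
            "expected probability 0 with nonzero observed count; drop the "
            "category first"
        )
    expected = probs * total
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = len(cats) - 1
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p
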