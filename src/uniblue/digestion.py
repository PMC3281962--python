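"""Protease digestion with modification-dependent cleavage blocking.

Trypsin cleaves C-terminal to lysine and arginine (not before proline).
A lysine carrying a charge-neutralizing covalent label (e.g. the Uniblue A
vinyl-sulfone adduct) is no longer recognized, so its site is removed from
the cleavage pattern entirely.  Such chemically blocked sites do not count
toward the missed-cleavage budget: the miss is chemical, not enzymatic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from .mods import ModificationSpec, Modform

__all__ = [
    "ProteaseRule",
    "TRYPSIN",
    "PeptideCandidate",
    "cleavage_sites",
    "digest",
    "enumerate_modforms",
]


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity: cut after ``cleave_after`` unless the next
    residue is in ``suppress_before``."""

    name: str = "trypsin"
    cleave_after: frozenset = frozenset("KR")
    suppress_before: frozenset = frozenset("P")
    max_missed: int = 2

    def __post_init__(self):
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")


TRYPSIN = ProteaseRule()


@dataclass(frozen=True)
class PeptideCandidate:
    """A digestion product: sequence, 0-based half-open span in the parent
    protein, enzymatic missed-cleavage count, and the number of chemically
    blocked sites it spans."""

    sequence: str
    span: tuple
    missed_cleavages: int
    blocked_sites_inside: int = 0

    def __post_init__(self):
        if self.span[1] - self.span[0] != len(self.sequence):
            raise ValueError("span length does not match sequence length")


def cleavage_sites(
    protein: str,
    rule: ProteaseRule = TRYPSIN,
    blocked: Iterable[int] = (),
) -> list[int]:
    """1-based positions after which the protease cleaves.

    ``blocked`` lists 1-based positions of chemically blocked residues; each
    must name a residue in ``rule.cleave_after`` (it makes no sense to block
    a site the enzyme never had).  Blocked positions and positions followed
    by a suppressing residue are absent from the result.
    """
    blocked = set(blocked)
    n = len(protein)
    for p in blocked:
        if not (1 <= p <= n) or protein[p - 1] not in rule.cleave_after:
            res = protein[p - 1] if 1 <= p <= n else "?"
            raise ValueError(
                f"blocked position {p} ({res}) is not a cleavable residue"
            )
    sites = []
    for i in range(1, n + 1):
        if protein[i - 1] not in rule.cleave_after:
            continue
        if i < n and protein[i] in rule.suppress_before:
            continue
        if i in blocked:
            continue
        sites.append(i)
    return sites


def digest(
    protein: str,
    rule: ProteaseRule = TRYPSIN,
    blocked: Iterable[int] = (),
) -> list[PeptideCandidate]:
    """All tryptic peptides of ``protein`` with up to ``rule.max_missed``
    enzymatic missed cleavages, under the given blocked-site set.

    Chemically blocked sites inside a peptide are counted in
    ``blocked_sites_inside`` but never against the missed-cleavage budget.
    Output is sorted by span.
    """
    if not protein:
        return []
    blocked = set(blocked)
    sites = cleavage_sites(protein, rule, blocked)
    bounds = [0] + sites
    if bounds[-1] != len(protein):
        bounds.append(len(protein))
    out = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + rule.max_missed, len(bounds))):
            start, end = bounds[i], bounds[j]
            if end <= start:
                continue
            out.append(
                PeptideCandidate(
                    sequence=protein[start:end],
                    span=(start, end),
                    missed_cleavages=j - i - 1,
                    blocked_sites_inside=sum(1 for p in blocked if start < p < end),
                )
            )
    out.sort(key=lambda c: c.span)
    return out


def enumerate_modforms(
    candidate: PeptideCandidate | str,
    fixed: Sequence[ModificationSpec] = (),
    variable: Sequence[ModificationSpec] = (),
    max_variable: int = 3,
) -> list[Modform]:
    """Every modform of a peptide: fixed mods at all eligible residues plus
    each subset of eligible variable sites of size <= ``max_variable``.

    Positions already claimed by a fixed modification are not eligible for
    variable ones; at most one modification per position.  Zero eligible
    sites yields the single fixed-only form.
    """
    if max_variable < 0:
        raise ValueError("max_variable must be >= 0")
    sequence = candidate if isinstance(candidate, str) else candidate.sequence
    fixed_sites: dict[int, ModificationSpec] = {}
    for spec in fixed:
        for pos, aa in enumerate(sequence, start=1):
            if aa in spec.target_residues and pos not in fixed_sites:
                fixed_sites[pos] = spec
    eligible = []
    for spec in variable:
        for pos, aa in enumerate(sequence, start=1):
            if aa in spec.target_residues and pos not in fixed_sites:
                eligible.append((pos, spec))
    eligible.sort(key=lambda e: (e[0], e[1].name))
    forms = []
    for size in range(min(max_variable, len(eligible)) + 1):
        for combo in itertools.combinations(eligible, size):
            positions = [p for p, _ in combo]
            if len(set(positions)) != len(positions):
                continue
            sites = dict(fixed_sites)
            sites.update(dict(combo))
            forms.append(Modform(sequence, sites))
    return forms
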