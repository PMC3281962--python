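"""FASTA I/O, reverse-decoy databases, and a precursor-mass peptide index.

The decoy construction follows the classic concatenated target-decoy
strategy: each target protein contributes one full-sequence-reversed decoy
whose id carries the ``decoy_`` prefix, and searches run against the merged
database so that the decoy hit rate estimates the false-match rate among
targets.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .digestion import ProteaseRule, TRYPSIN, digest, enumerate_modforms
from .mods import (
    CARBAMIDOMETHYL_C,
    DEAMIDATION_NQ,
    MONO_RESIDUE_MASS,
    STANDARD_RESIDUES,
    UNIBLUE_A,
    WATER_MONO,
    ModificationSpec,
    Modform,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "read_fasta",
    "write_fasta",
    "make_decoy_db",
    "IndexEntry",
    "PeptideIndex",
    "build_index",
    "DECOY_PREFIX",
]

DECOY_PREFIX = "decoy_"


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    description: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self):
        if self.is_decoy and not self.id.startswith(DECOY_PREFIX):
            raise ValueError(f"decoy record {self.id!r} lacks {DECOY_PREFIX!r} prefix")
        if not self.is_decoy and self.id.startswith(DECOY_PREFIX):
            raise ValueError(f"target record {self.id!r} has {DECOY_PREFIX!r} prefix")


def _open_maybe_gzip(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(source) -> list[ProteinRecord]:
    """Read protein records from FASTA (path, gzip path, or text stream).

    The id is the first whitespace-delimited header token; the rest is the
    description.  Records with empty sequences are skipped with a warning.
    """
    if isinstance(source, str):
        handle = _open_maybe_gzip(source)
    else:
        handle = source
    records = []

    def _flush(header, chunks):
        if header is None:
            return
        parts = header.split(None, 1)
        rid = parts[0] if parts else ""
        seq = "".join(chunks).upper()
        if not seq or not rid:
            logger.warning("skipping FASTA record %r: empty sequence or id",
                           header)
            return
        records.append(
            ProteinRecord(
                id=rid,
                description=parts[1] if len(parts) > 1 else "",
                sequence=seq,
                is_decoy=rid.startswith(DECOY_PREFIX),
            )
        )

    header, chunks = None, []
    for line in handle:
        line = line.strip()
        if line.startswith(">"):
            _flush(header, chunks)
            header, chunks = line[1:], []
        elif line:
            chunks.append(line)
    _flush(header, chunks)
    if isinstance(source, str):
        handle.close()
    return records


def write_fasta(records: Iterable[ProteinRecord], destination, width: int = 60):
    """Write records as wrapped FASTA."""
    own = isinstance(destination, str)
    handle = open(destination, "wt") if own else destination
    try:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")
    finally:
        if own:
            handle.close()


def make_decoy_db(targets: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Concatenated target-decoy database: targets followed by one
    full-sequence-reversed decoy per target (id prefixed ``decoy_``)."""
    for rec in targets:
        if rec.id.startswith(DECOY_PREFIX) or rec.is_decoy:
            raise ValueError(f"input record {rec.id!r} already carries the decoy prefix")
    decoys = [
        ProteinRecord(
            id=DECOY_PREFIX + rec.id,
            description=rec.description,
            sequence=rec.sequence[::-1],
            is_decoy=True,
        )
        for rec in targets
    ]
    return list(targets) + decoys


@dataclass(frozen=True)
class IndexEntry:
    modform: Modform
    protein_id: str
    is_decoy: bool
    missed_cleavages: int
    mass: float


class PeptideIndex:
    """Sorted mapping from neutral monoisotopic modform mass to modforms."""

    def __init__(self, entries: Sequence[IndexEntry]):
        entries = sorted(entries, key=lambda e: (e.mass,) + e.modform.key())
        self._entries = entries
        self._masses = np.array([e.mass for e in entries])

    def __len__(self):
        return len(self._entries)

    @property
    def entries(self):
        return list(self._entries)

    def query(self, lo: float, hi: float) -> list[IndexEntry]:
        """All entries with lo <= mass <= hi."""
        i = int(np.searchsorted(self._masses, lo, side="left"))
        j = int(np.searchsorted(self._masses, hi, side="right"))
        return self._entries[i:j]

    def query_window(self, neutral_mass: float, tolerance: float):
        return self.query(neutral_mass - tolerance, neutral_mass + tolerance)


def build_index(
    records: Sequence[ProteinRecord],
    rule: ProteaseRule = TRYPSIN,
    fixed: Sequence[ModificationSpec] = (CARBAMIDOMETHYL_C,),
    variable: Sequence[ModificationSpec] = (DEAMIDATION_NQ, UNIBLUE_A),
    max_variable: int = 3,
    min_length: int = 1,
) -> PeptideIndex:
    """Digest every record and index all modform masses.

    Cleavage-blocking consistency: candidate peptides are generated over the
    unblocked cleavage pattern, allowing extra internal sites for potentially
    blocked residues; for each modform the *effective* missed-cleavage count
    includes only internal sites not occupied by a cleavage-blocking
    modification, and modforms exceeding ``rule.max_missed`` effective misses
    are dropped.  Peptides containing non-standard residue codes are excluded
    (with a logged count); their parent records are retained.
    """
    can_block = any(m.blocks_cleavage for m in variable) or any(
        m.blocks_cleavage for m in fixed
    )
    slack = max_variable if can_block else 0
    generous = ProteaseRule(
        name=rule.name,
        cleave_after=rule.cleave_after,
        suppress_before=rule.suppress_before,
        max_missed=rule.max_missed + slack,
    )
    from .digestion import cleavage_sites

    entries = []
    n_nonstandard = 0
    for rec in records:
        seq = rec.sequence
        try:
            rule_sites = cleavage_sites(seq, rule)
        except ValueError:
            rule_sites = []
        for cand in digest(seq, generous):
            if len(cand.sequence) < min_length:
                continue
            if set(cand.sequence) - STANDARD_RESIDUES:
                n_nonstandard += 1
                continue
            start, end = cand.span
            internal_sites = [
                p - start  # site position local to the peptide, 1-based
                for p in rule_sites
                if start < p < end
            ]
            base_mass = (
                sum(MONO_RESIDUE_MASS[aa] for aa in cand.sequence) + WATER_MONO
            )
            for form in enumerate_modforms(cand, fixed, variable, max_variable):
                effective_mc = sum(
                    1
                    for p in internal_sites
                    if not (p in form.sites and form.sites[p].blocks_cleavage)
                )
                if effective_mc > rule.max_missed:
                    continue
                mass = base_mass + sum(s.mono_delta for s in form.sites.values())
                entries.append(
                    IndexEntry(
                        modform=form.with_protein(rec.id, cand.span),
                        protein_id=rec.id,
                        is_decoy=rec.is_decoy,
                        missed_cleavages=effective_mc,
                        mass=mass,
                    )
                )
    if n_nonstandard:
        logger.warning(
            "excluded %d peptides containing non-standard residues", n_nonstandard
        )
    return PeptideIndex(entries)
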