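"""Mass constants, residue modifications, and OMSSA ``usermods.xml`` I/O.

The central chemistry handled here is covalent derivatization of lysine
ε-amino groups by the vinyl-sulfone dye Uniblue A, which adds a fixed
monoisotopic mass of 484.039891 Da (484.5016 Da average) to each labeled
residue.  Because the derivatized lysine side chain loses its positive
charge, the label also abolishes tryptic cleavage at that residue; the
:class:`ModificationSpec.blocks_cleavage` flag carries that fact into the
digestion and search machinery.

Residue and small-molecule masses come from the standard IUPAC tables as
shipped with :mod:`pyteomics.mass`; modification deltas are stored
explicitly because reactive-dye adducts are not part of the standard
residue tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from lxml import etree
from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "WATER_MONO",
    "WATER_AVG",
    "CO_MONO",
    "NH3_MONO",
    "H2O_MONO",
    "STANDARD_RESIDUES",
    "MONO_RESIDUE_MASS",
    "AVG_RESIDUE_MASS",
    "ModificationSpec",
    "Modform",
    "UNIBLUE_A",
    "CARBAMIDOMETHYL_C",
    "DEAMIDATION_NQ",
    "BUILTIN_MODS",
    "peptide_mass",
    "mz_from_mass",
    "neutral_mass_from_mz",
    "write_usermods",
    "read_usermods",
]

#: Mass of a proton in Da, used for m/z <-> neutral mass conversion.
PROTON_MASS = 1.007276

WATER_MONO = _pmass.calculate_mass(formula="H2O")
WATER_AVG = _pmass.calculate_mass(formula="H2O", average=True)
CO_MONO = _pmass.calculate_mass(formula="CO")
NH3_MONO = _pmass.calculate_mass(formula="NH3")
H2O_MONO = WATER_MONO

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic residue masses (Da) for the 20 standard amino acids.
MONO_RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES
}

#: Average residue masses (Da).
AVG_RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.Composition(parsed_sequence=[aa]).mass(average=True)
    for aa in STANDARD_RESIDUES
}


@dataclass(frozen=True)
class ModificationSpec:
    """A named covalent residue modification.

    Parameters
    ----------
    name:
        Human-readable name, e.g. ``"Uniblue A on K"``.
    mono_delta, avg_delta:
        Monoisotopic / average mass shift in Da added to each modified
        residue.
    target_residues:
        1-letter codes of residues the modification can occupy.
    mode:
        ``"fixed"`` (applied at every eligible residue) or ``"variable"``.
    blocks_cleavage:
        True when the modification abolishes protease recognition at the
        modified residue (Uniblue A on lysine does).
    omssa_id:
        OMSSA integer modification number (usermod slot), if any.
    psimod_accession:
        PSI-MOD controlled-vocabulary accession, if any.
    label:
        Short token used in textual reports, e.g. ``"UniA"``.
    """

    name: str
    mono_delta: float
    avg_delta: float
    target_residues: frozenset
    mode: str = "variable"
    blocks_cleavage: bool = False
    omssa_id: int | None = None
    psimod_accession: str | None = None
    label: str | None = None

    def __post_init__(self):
        if not (math.isfinite(self.mono_delta) and math.isfinite(self.avg_delta)):
            raise ValueError(f"{self.name}: mass deltas must be finite")
        if abs(self.avg_delta - self.mono_delta) >= 1.0:
            raise ValueError(
                f"{self.name}: average and monoisotopic deltas differ by >= 1 Da"
            )
        residues = frozenset(self.target_residues)
        if not residues:
            raise ValueError(f"{self.name}: target_residues must be non-empty")
        bad = residues - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"{self.name}: non-standard target residues {sorted(bad)}")
        object.__setattr__(self, "target_residues", residues)
        if self.mode not in ("fixed", "variable"):
            raise ValueError(f"{self.name}: mode must be 'fixed' or 'variable'")
        if self.label is None:
            object.__setattr__(self, "label", self.name)

    def delta(self, scale: str = "mono") -> float:
        return self.mono_delta if scale == "mono" else self.avg_delta


UNIBLUE_A = ModificationSpec(
    name="Uniblue A on K",
    mono_delta=484.039891,
    avg_delta=484.5016,
    target_residues=frozenset("K"),
    mode="variable",
    blocks_cleavage=True,
    omssa_id=121,
    psimod_accession="MOD:01659",
    label="UniA",
)

CARBAMIDOMETHYL_C = ModificationSpec(
    name="carbamidomethyl C",
    mono_delta=57.021464,
    avg_delta=57.0513,
    target_residues=frozenset("C"),
    mode="fixed",
    omssa_id=3,
    label="CAM",
)

DEAMIDATION_NQ = ModificationSpec(
    name="deamidation N/Q",
    mono_delta=0.984016,
    avg_delta=0.9848,
    target_residues=frozenset("NQ"),
    mode="variable",
    omssa_id=4,
    label="deam",
)

#: Registry of built-in modifications, keyed by OMSSA id.
BUILTIN_MODS: dict[int, ModificationSpec] = {
    m.omssa_id: m for m in (UNIBLUE_A, CARBAMIDOMETHYL_C, DEAMIDATION_NQ)
}


@dataclass(frozen=True)
class Modform:
    """A peptide sequence with a specific assignment of modifications.

    ``sites`` maps 1-based residue positions to :class:`ModificationSpec`;
    at most one modification per position, and the residue at each site must
    be in the modification's ``target_residues``.  ``span`` is the 0-based
    half-open interval in the parent protein, when known.
    """

    sequence: str
    sites: Mapping[int, ModificationSpec] = field(default_factory=dict)
    protein_id: str | None = None
    span: tuple | None = None

    def __post_init__(self):
        sites = dict(self.sites)
        n = len(self.sequence)
        for pos, spec in sites.items():
            if not (1 <= pos <= n):
                raise ValueError(
                    f"modification position {pos} outside 1..{n} of {self.sequence!r}"
                )
            if self.sequence[pos - 1] not in spec.target_residues:
                raise ValueError(
                    f"{spec.name} cannot occupy {self.sequence[pos - 1]}{pos} "
                    f"in {self.sequence!r}"
                )
        object.__setattr__(self, "sites", sites)
        if self.span is not None and self.span[1] - self.span[0] != n:
            raise ValueError("span length does not match sequence length")

    def key(self):
        """Deterministic sort/identity key (sequence + site assignment)."""
        return (
            self.sequence,
            tuple(sorted((p, s.name) for p, s in self.sites.items())),
        )

    def mods_string(self, psimod: bool = False) -> str:
        """Textual site list, e.g. ``"UniA@1+CAM@4"`` or PSI-MOD accessions."""
        parts = []
        for pos in sorted(self.sites):
            spec = self.sites[pos]
            tag = (spec.psimod_accession or spec.label) if psimod else spec.label
            parts.append(f"{tag}@{pos}")
        return "+".join(parts)

    def carries(self, spec: ModificationSpec) -> bool:
        return any(s == spec for s in self.sites.values())

    def with_protein(self, protein_id: str, span: tuple) -> "Modform":
        return replace(self, protein_id=protein_id, span=span)


def _plain_mass(sequence: str, scale: str) -> float:
    table = MONO_RESIDUE_MASS if scale == "mono" else AVG_RESIDUE_MASS
    water = WATER_MONO if scale == "mono" else WATER_AVG
    total = water
    for i, aa in enumerate(sequence, start=1):
        try:
            total += table[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {i}") from None
    return total


def peptide_mass(modform: Modform | str, scale: str = "mono") -> float:
    """Neutral peptide mass in Da: residue masses + water + modification deltas.

    Accepts a plain sequence string as shorthand for an unmodified peptide.
    ``scale`` is ``"mono"`` or ``"average"``.
    """
    if scale not in ("mono", "average"):
        raise ValueError(f"scale must be 'mono' or 'average', got {scale!r}")
    if isinstance(modform, str):
        modform = Modform(modform)
    total = _plain_mass(modform.sequence, scale)
    for spec in modform.sites.values():
        total += spec.delta(scale)
    return total


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a ``charge``-protonated species of the given neutral mass."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def neutral_mass_from_mz(mz: float, charge: int) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON_MASS


# ---------------------------------------------------------------------------
# OMSSA usermods XML dialect
# ---------------------------------------------------------------------------

def _format_mass(value: float) -> str:
    # repr() keeps the shortest decimal that round-trips (e.g. "484.039891")
    return repr(float(value))


def _usermod_slot(omssa_id: int) -> str:
    # OMSSA usermod slots usermod1..usermodN map to ids 119, 120, ...
    return f"usermod{max(1, omssa_id - 118)}"


def write_usermods(mods: Iterable[ModificationSpec]) -> bytes:
    """Serialize modifications in the OMSSA ``usermods.xml`` dialect.

    Emits one ``MSModSpec`` element per entry with ``MSMod``, name,
    monoisotopic and average mass, and one ``MSModSpec_residues_E`` per
    target residue.  Duplicate OMSSA ids are rejected.
    """
    mods = list(mods)
    ids = [m.omssa_id for m in mods]
    if any(i is None for i in ids):
        raise ValueError("every usermods entry needs an omssa_id")
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate omssa_id in {sorted(ids)}")
    root = etree.Element("MSModSpecSet")
    for m in mods:
        spec = etree.SubElement(root, "MSModSpec")
        mod = etree.SubElement(spec, "MSModSpec_mod")
        msmod = etree.SubElement(mod, "MSMod", value=_usermod_slot(m.omssa_id))
        msmod.text = str(m.omssa_id)
        typ = etree.SubElement(spec, "MSModSpec_type")
        mtype = etree.SubElement(typ, "MSModType", value="modaa")
        mtype.text = "0"
        etree.SubElement(spec, "MSModSpec_name").text = m.name
        etree.SubElement(spec, "MSModSpec_monomass").text = _format_mass(m.mono_delta)
        etree.SubElement(spec, "MSModSpec_averagemass").text = _format_mass(m.avg_delta)
        etree.SubElement(spec, "MSModSpec_n15mass").text = "0"
        residues = etree.SubElement(spec, "MSModSpec_residues")
        for aa in sorted(m.target_residues):
            etree.SubElement(residues, "MSModSpec_residues_E").text = aa
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")


def _required_text(elem, path: str, context: str) -> str:
    found = elem.find(path)
    if found is None or found.text is None:
        raise ValueError(f"{context}: missing element {path.split('/')[-1]}")
    return found.text.strip()


def read_usermods(source) -> list[ModificationSpec]:
    """Parse an OMSSA ``usermods.xml`` document into modification specs.

    Entries whose OMSSA id matches a built-in registry entry are resolved to
    that built-in (recovering fields the dialect cannot carry, such as the
    cleavage-blocking flag and PSI-MOD accession); unknown entries default to
    variable mode without cleavage blocking.
    """
    if isinstance(source, (bytes, str)):
        root = etree.fromstring(source.encode() if isinstance(source, str) else source)
    else:
        root = etree.parse(source).getroot()
    specs = []
    for i, elem in enumerate(root.findall(".//MSModSpec"), start=1):
        ctx = f"MSModSpec #{i}"
        name = _required_text(elem, "MSModSpec_name", ctx)
        mono = float(_required_text(elem, "MSModSpec_monomass", ctx))
        avg = float(_required_text(elem, "MSModSpec_averagemass", ctx))
        res_parent = elem.find("MSModSpec_residues")
        if res_parent is None:
            raise ValueError(f"{ctx}: missing element MSModSpec_residues")
        residues = frozenset(
            e.text.strip() for e in res_parent.findall("MSModSpec_residues_E")
            if e.text
        )
        if not residues:
            raise ValueError(f"{ctx}: missing element MSModSpec_residues_E")
        omssa_id = int(_required_text(elem, "MSModSpec_mod/MSMod", ctx))
        builtin = BUILTIN_MODS.get(omssa_id)
        if (
            builtin is not None
            and builtin.name == name
            and abs(builtin.mono_delta - mono) < 1e-9
            and builtin.target_residues == residues
        ):
            specs.append(builtin)
            continue
        specs.append(
            ModificationSpec(
                name=name,
                mono_delta=mono,
                avg_delta=avg,
                target_residues=residues,
                mode="variable",
                omssa_id=omssa_id,
            )
        )
    return specs
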